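"""Color calibration, warping faces onto a mean shape, and masked pixel
extraction for color PCA.

The warp is an inverse-mapped piecewise-affine transform: the mean (target)
shape is Delaunay-triangulated once; every output pixel inside the target
hull is located in its triangle, its barycentric coordinates are computed
once, and for each face those coordinates are combined with the face's own
landmark positions to find the source pixel, which is sampled bilinearly.
Pixels outside the target hull are set to a constant background (0.5 gray by
default).  :class:`PiecewiseAffineWarper` caches the target-side geometry so
a whole sample can be warped cheaply onto the same mean shape.

Color calibration follows the chart-based least-squares approach: reference
patch colors are regressed on an 11-term polynomial expansion of the
measured patch colors, ``[1, R, G, B, R2, G2, B2, RG, RB, GB, RGB]`` (the
term list is configurable), and the fitted transform is applied per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import Delaunay, QhullError
from skimage.draw import polygon as _draw_polygon
from skimage.measure import block_reduce

from .exceptions import DegenerateInputError, ValidationError
from .io import LandmarkSet, validate_image

__all__ = [
    "DEFAULT_TERMS",
    "CalibrationModel",
    "Triangulation",
    "PiecewiseAffineWarper",
    "fit_calibration",
    "apply_calibration",
    "triangulate_mean",
    "warp_to_mean",
    "mask_from_polygon",
    "extract_color_features",
]

BACKGROUND_GRAY = 0.5

#: default polynomial expansion: constant, linear, squares, cross terms, RGB
DEFAULT_TERMS = (
    "1", "r", "g", "b", "rr", "gg", "bb", "rg", "rb", "gb", "rgb",
)

_TERM_FUNCS = {
    "1": lambda r, g, b: np.ones_like(r),
    "r": lambda r, g, b: r,
    "g": lambda r, g, b: g,
    "b": lambda r, g, b: b,
    "rr": lambda r, g, b: r * r,
    "gg": lambda r, g, b: g * g,
    "bb": lambda r, g, b: b * b,
    "rg": lambda r, g, b: r * g,
    "rb": lambda r, g, b: r * b,
    "gb": lambda r, g, b: g * b,
    "rgb": lambda r, g, b: r * g * b,
}


def _expand(rgb: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    r, g, b = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    return np.column_stack([_TERM_FUNCS[t](r, g, b) for t in terms])


@dataclass
class CalibrationModel:
    """Least-squares polynomial color transform fitted on chart patches."""

    coefficients: np.ndarray  # (n_terms, 3)
    terms: tuple[str, ...] = DEFAULT_TERMS
    fit_residual: float = 0.0  # RMS residual on the training patches

    def map_colors(self, rgb: np.ndarray) -> np.ndarray:
        out = _expand(np.atleast_2d(rgb), self.terms) @ self.coefficients
        return np.clip(out, 0.0, 1.0)


def fit_calibration(
    measured: np.ndarray,
    reference: np.ndarray,
    terms: Sequence[str] = DEFAULT_TERMS,
) -> CalibrationModel:
    """Fit the polynomial color transform from measured to reference patches.

    Needs at least as many patches as terms (11 by default) and a full-rank
    design (all-equal patches are degenerate).
    """
    measured = np.asarray(measured, float)
    reference = np.asarray(reference, float)
    if measured.shape != reference.shape or measured.ndim != 2 or measured.shape[1] != 3:
        raise ValidationError("measured and reference must both be (n_patches, 3)")
    n_terms = len(terms)
    if measured.shape[0] < n_terms:
        raise ValidationError(
            f"need at least {n_terms} patches for a {n_terms}-term expansion, "
            f"got {measured.shape[0]}"
        )
    if measured.min() < -1e-9 or measured.max() > 1 + 1e-9:
        raise ValidationError("measured patch values must lie in [0, 1]")
    design = _expand(measured, terms)
    if np.linalg.matrix_rank(design) < n_terms:
        raise DegenerateInputError(
            "rank-deficient calibration design (patches not diverse enough)"
        )
    coef, _, _, _ = np.linalg.lstsq(design, reference, rcond=None)
    resid = design @ coef - reference
    rms = float(np.sqrt(np.mean(resid**2)))
    return CalibrationModel(coef, tuple(terms), rms)


def apply_calibration(image: np.ndarray, model: CalibrationModel) -> np.ndarray:
    """Apply the fitted per-pixel polynomial map; output clipped to [0, 1]."""
    image = validate_image(image)
    h, w, _ = image.shape
    flat = image.reshape(-1, 3)
    return model.map_colors(flat).reshape(h, w, 3)


# ---------------------------------------------------------------------------
# triangulation + warping

@dataclass
class Triangulation:
    points: np.ndarray  # (p, 2) target points
    triangles: np.ndarray  # (m, 3) vertex indices
    _delaunay: Optional[Delaunay] = None


def triangulate_mean(mean_shape: np.ndarray) -> Triangulation:
    """Delaunay triangulation of the mean shape (deterministic for fixed
    input; covers the convex hull without overlap)."""
    pts = np.asarray(mean_shape, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("mean shape must be (p, 2) with p >= 3")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateInputError(f"cannot triangulate mean shape: {exc}") from exc
    if tri.simplices.size == 0:
        raise DegenerateInputError("all mean-shape points are collinear")
    return Triangulation(pts, tri.simplices.copy(), tri)


class PiecewiseAffineWarper:
    """Warps images onto a fixed target shape.

    Precomputes, for every output pixel inside the target hull, its Delaunay
    triangle and barycentric coordinates; ``warp`` then only needs a matmul
    and one bilinear sampling pass per image.
    """

    def __init__(
        self,
        target_points: np.ndarray,
        image_shape: tuple[int, int],
        tri: Optional[Triangulation] = None,
        background: float = BACKGROUND_GRAY,
    ):
        self.target_points = np.asarray(target_points, float)
        self.image_shape = tuple(image_shape)
        self.background = background
        self.tri = tri if tri is not None else triangulate_mean(self.target_points)
        dela = self.tri._delaunay
        if dela is None:
            dela = Delaunay(self.tri.points)
            self.tri._delaunay = dela

        h, w = self.image_shape
        ys, xs = np.mgrid[0:h, 0:w]
        pix = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        simplex = dela.find_simplex(pix)
        inside = simplex >= 0
        self.inside_mask = inside.reshape(h, w)
        sl = simplex[inside]
        T = dela.transform[sl]  # (m, 3, 2): affine map to barycentric
        r = pix[inside] - T[:, 2]
        b = np.einsum("mij,mj->mi", T[:, :2], r)
        self.barycentric = np.column_stack([b, 1.0 - b.sum(axis=1)])  # (m, 3)
        self.vertex_idx = dela.simplices[sl]  # (m, 3)
        self._flat_inside = np.flatnonzero(inside)

    def warp(self, image: np.ndarray, source_points: np.ndarray) -> np.ndarray:
        image = validate_image(image)
        src = np.asarray(source_points, float)
        if src.shape != self.target_points.shape:
            raise ValidationError("source/target point counts do not match")
        # refuse degenerate source triangles (zero area collapses the affine map)
        tri_pts = src[self.tri.triangles]  # (t, 3, 2)
        areas = 0.5 * np.abs(
            np.cross(tri_pts[:, 1] - tri_pts[:, 0], tri_pts[:, 2] - tri_pts[:, 0])
        )
        bad = np.flatnonzero(areas < 1e-12)
        if bad.size:
            raise DegenerateInputError(
                f"zero-area source triangle(s) {bad.tolist()[:5]} in piecewise warp"
            )
        corners = src[self.vertex_idx]  # (m, 3, 2)
        xy = np.einsum("mk,mkj->mj", self.barycentric, corners)
        h, w = self.image_shape
        out = np.full((h * w, 3), self.background, dtype=float)
        coords = [xy[:, 1], xy[:, 0]]  # row, col
        for c in range(3):
            out[self._flat_inside, c] = map_coordinates(
                image[:, :, c], coords, order=1, mode="nearest"
            )
        return np.clip(out.reshape(h, w, 3), 0.0, 1.0)


def warp_to_mean(
    image: np.ndarray,
    source: LandmarkSet,
    target: np.ndarray,
    tri: Optional[Triangulation] = None,
    background: float = BACKGROUND_GRAY,
) -> np.ndarray:
    """One-shot piecewise-affine warp of a face image onto a target shape."""
    src = source.points if isinstance(source, LandmarkSet) else np.asarray(source, float)
    warper = PiecewiseAffineWarper(
        np.asarray(target, float), image.shape[:2], tri=tri, background=background
    )
    return warper.warp(image, src)


# ---------------------------------------------------------------------------
# masks + feature extraction

def mask_from_polygon(outline: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    """Boolean H x W mask of pixels inside a closed polygon (image frame)."""
    outline = np.asarray(outline, float)
    rr, cc = _draw_polygon(outline[:, 1], outline[:, 0], shape=image_shape)
    mask = np.zeros(image_shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def extract_color_features(
    warped: Sequence[np.ndarray], mask: np.ndarray, downsample: int = 1
) -> np.ndarray:
    """Stack masked RGB values into a subjects x features matrix.

    Pixels are taken in row-major order with channels interleaved per pixel
    (R, G, B, R, G, B, ...).  ``downsample`` > 1 block-averages the image by
    that factor first; a downsampled pixel is kept when the majority of its
    block lies inside the mask.  The ordering is identical for every subject.
    """
    if downsample < 1:
        raise ValidationError("downsample must be >= 1")
    mask = np.asarray(mask, bool)
    if downsample > 1:
        mask_ds = block_reduce(mask.astype(float), (downsample, downsample), np.mean) > 0.5
    else:
        mask_ds = mask
    rows = []
    for img in warped:
        img = np.asarray(img, float)
        if img.shape[:2] != mask.shape:
            raise ValidationError(
                f"image shape {img.shape[:2]} does not match mask {mask.shape}"
            )
        if downsample > 1:
            img = block_reduce(img, (downsample, downsample, 1), np.mean)
        rows.append(img[mask_ds].reshape(-1))
    return np.vstack(rows) if rows else np.empty((0, int(mask_ds.sum()) * 3))
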