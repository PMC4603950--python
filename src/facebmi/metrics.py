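"""Coetzee-style facial metrics from a landmark configuration.

Three classical proportions are measured after aligning each face on its
interpupillary distance (a similarity transform, so the two dimensionless
ratios are unaffected and the perimeter-to-area ratio is put on a common
scale):

* ``perimeter_to_area`` — perimeter of the face outline (closed across the
  top by the pupil-to-pupil segment) divided by the enclosed area (1/pixels).
* ``width_to_height`` — horizontal distance between the two most lateral
  facial points divided by the vertical distance between the most inferior
  point of the upper eyelid and the most superior point of the upper lip
  (the facial width-to-height ratio, fWHR).
* ``cheek_to_jaw`` — the same facial width divided by the width of the face
  outline at the midline of the lips.

Which landmark indices play which role is carried by a
:class:`TemplateRoleMap`, serialisable to YAML so users can override the
shipped interpretation for their own templates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon as _ShapelyPolygon

from .exceptions import DegenerateInputError, ValidationError
from .io import LandmarkSet

__all__ = [
    "TemplateRoleMap",
    "MetricSet",
    "align_interpupillary",
    "perimeter_to_area",
    "width_to_height",
    "cheek_to_jaw",
    "metrics_table",
]


@dataclass
class TemplateRoleMap:
    """Binds the metric definitions to concrete landmark indices.

    ``outline`` must be an ordered chain running from the left temple, down
    around the chin, up to the right temple (image frame, y downward).
    ``lateral_candidates`` are the points searched for the most lateral facial
    points (defaults to the outline chain).  ``lip_corners`` are the two
    lip-corner landmarks whose midpoint defines the lip midline.
    """

    left_pupil: int
    right_pupil: int
    outline: list[int]
    upper_eyelids: list[int]
    upper_lip: list[int]
    lip_corners: tuple[int, int]
    lateral_candidates: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.lateral_candidates:
            self.lateral_candidates = list(self.outline)
        self.lip_corners = tuple(self.lip_corners)  # type: ignore[assignment]
        if self.left_pupil == self.right_pupil:
            raise ValidationError("left and right pupil indices must differ")

    def validate(self, n_points: int) -> None:
        all_idx = (
            [self.left_pupil, self.right_pupil]
            + list(self.outline)
            + list(self.upper_eyelids)
            + list(self.upper_lip)
            + list(self.lip_corners)
            + list(self.lateral_candidates)
        )
        arr = np.asarray(all_idx)
        if arr.min() < 0 or arr.max() >= n_points:
            raise ValidationError(
                f"role map indices out of range for a {n_points}-point template"
            )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["lip_corners"] = list(d["lip_corners"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "TemplateRoleMap":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


@dataclass(frozen=True)
class MetricSet:
    perimeter_to_area: float
    width_to_height: float
    cheek_to_jaw: float


def align_interpupillary(
    landmarks: LandmarkSet, roles: TemplateRoleMap, target_ipd: float = 90.0
) -> LandmarkSet:
    """Similarity-align a face so its pupils are horizontal, centred at the
    origin, exactly ``target_ipd`` apart.

    Complex-plane formulation: the unique rotation+scale+translation mapping
    the pupil pair onto the target pair is applied to every landmark (no
    shear, no reflection).
    """
    roles.validate(landmarks.n_points)
    pts = landmarks.points
    z = pts[:, 0] + 1j * pts[:, 1]
    pl, pr = z[roles.left_pupil], z[roles.right_pupil]
    if abs(pr - pl) < 1e-12:
        raise DegenerateInputError(
            f"subject {landmarks.subject_id!r}: coincident pupils"
        )
    tl, tr = -target_ipd / 2 + 0j, target_ipd / 2 + 0j
    w = (tr - tl) / (pr - pl)
    z2 = tl + (z - pl) * w
    out = np.column_stack([z2.real, z2.imag])
    return LandmarkSet(landmarks.subject_id, out, landmarks.image_size)


def _outline_polygon(landmarks: LandmarkSet, roles: TemplateRoleMap) -> np.ndarray:
    """Closed face polygon: left pupil, outline chain, right pupil."""
    pts = landmarks.points
    return np.vstack(
        [pts[roles.left_pupil], pts[roles.outline], pts[roles.right_pupil]]
    )


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter_to_area(landmarks: LandmarkSet, roles: TemplateRoleMap) -> float:
    """Perimeter of the closed face polygon divided by its (shoelace) area.

    The polygon is closed across the top by the pupil-to-pupil segment.  A
    self-intersecting outline produces a warning, not an error.
    """
    roles.validate(landmarks.n_points)
    poly = _outline_polygon(landmarks, roles)
    seg = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    perimeter = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
    area = _shoelace_area(poly)
    if area <= 0:
        raise DegenerateInputError(
            f"subject {landmarks.subject_id!r}: zero-area face polygon"
        )
    if not _ShapelyPolygon(poly).is_valid:
        warnings.warn(
            f"subject {landmarks.subject_id!r}: self-intersecting face outline; "
            "perimeter-to-area value is flagged",
            stacklevel=2,
        )
    return perimeter / area


def _facial_width(landmarks: LandmarkSet, roles: TemplateRoleMap) -> float:
    xs = landmarks.points[roles.lateral_candidates, 0]
    return float(xs.max() - xs.min())


def width_to_height(landmarks: LandmarkSet, roles: TemplateRoleMap) -> float:
    """Facial width-to-height ratio (fWHR).

    Width: max-x minus min-x over the lateral candidate points (left and
    right extremes found independently).  Height: vertical distance between
    the most inferior upper-eyelid point (max y; image y grows downward) and
    the most superior upper-lip point (min y).
    """
    roles.validate(landmarks.n_points)
    width = _facial_width(landmarks, roles)
    eyelid_bottom = landmarks.points[roles.upper_eyelids, 1].max()
    lip_top = landmarks.points[roles.upper_lip, 1].min()
    height = lip_top - eyelid_bottom
    if height <= 1e-12:
        raise DegenerateInputError(
            f"subject {landmarks.subject_id!r}: nonpositive face height"
        )
    return width / height


def _outline_x_at_y(chain: np.ndarray, y_level: float) -> float:
    """x-coordinate where an outline poly-line crosses ``y_level``; linear
    interpolation along segments, nearest vertex as fallback."""
    y = chain[:, 1]
    for i in range(len(chain) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - y_level) * (y1 - y_level) <= 0 and y0 != y1:
            t = (y_level - y0) / (y1 - y0)
            return float(chain[i, 0] + t * (chain[i + 1, 0] - chain[i, 0]))
    return float(chain[np.argmin(np.abs(y - y_level)), 0])


def cheek_to_jaw(landmarks: LandmarkSet, roles: TemplateRoleMap) -> float:
    """Cheek-to-jaw width ratio.

    Numerator: the facial width used by :func:`width_to_height`.  Denominator:
    the horizontal extent of the face outline at the midline of the lips
    (the y-coordinate of the lip-corner midpoint), interpolated along the
    outline chain on each side of the chin.
    """
    roles.validate(landmarks.n_points)
    width = _facial_width(landmarks, roles)
    pts = landmarks.points
    lip_y = pts[list(roles.lip_corners), 1].mean()
    outline = pts[roles.outline]
    chin = int(np.argmax(outline[:, 1]))
    left_x = _outline_x_at_y(outline[: chin + 1], lip_y)
    right_x = _outline_x_at_y(outline[chin:], lip_y)
    jaw = abs(right_x - left_x)
    if jaw <= 1e-12:
        raise DegenerateInputError(
            f"subject {landmarks.subject_id!r}: zero jaw width at lip midline"
        )
    return width / jaw


def metrics_table(
    faces: list[LandmarkSet], roles: TemplateRoleMap, target_ipd: float = 90.0
) -> pd.DataFrame:
    """All three metrics for a list of faces, aligned internally first.

    Returns a DataFrame indexed by subject_id with columns
    ``perimeter_to_area``, ``width_to_height``, ``cheek_to_jaw``.  Errors in
    any single face are re-raised with the subject id attached.
    """
    rows = {}
    for face in faces:
        try:
            aligned = align_interpupillary(face, roles, target_ipd)
            rows[face.subject_id] = {
                "perimeter_to_area": perimeter_to_area(aligned, roles),
                "width_to_height": width_to_height(aligned, roles),
                "cheek_to_jaw": cheek_to_jaw(aligned, roles),
            }
        except (DegenerateInputError, ValidationError) as exc:
            raise type(exc)(f"subject {face.subject_id!r}: {exc}") from exc
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        df = pd.DataFrame(
            columns=["perimeter_to_area", "width_to_height", "cheek_to_jaw"]
        )
    df.index.name = "subject_id"
    return df
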