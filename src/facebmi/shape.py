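"""Generalized Procrustes alignment and variance-thresholded PCA with
fold-safe projection.

Generalized Procrustes analysis (GPA) removes translation, scale and rotation
from a set of landmark configurations: each configuration is centred, scaled
to unit centroid size, and iteratively rotated to the running consensus by
the optimal orthogonal rotation (reflections disallowed — faces have
handedness).  The consensus is renormalised to unit centroid size each
iteration; convergence is measured by the Frobenius norm of the consensus
change (tol 1e-8, max 100 iterations by default).  No tangent-space
projection is applied by default.

PCA is centring-only (covariance, not correlation — coordinates share units)
and retains the smallest number of components whose cumulative explained
variance reaches the threshold (default 95%).  Projection of held-out data
uses only the training-fitted mean and loadings, which is what makes the
cross-validation in :mod:`facebmi.cv` fold-safe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .exceptions import ConvergenceError, DegenerateInputError, ValidationError
from .io import LandmarkSet

__all__ = [
    "AlignedShapes",
    "PCModel",
    "ScoreMatrix",
    "generalized_procrustes",
    "align_to_consensus",
    "fit_pca",
    "project",
    "shapes_to_features",
    "features_to_shapes",
]


def _as_config_array(faces) -> np.ndarray:
    if isinstance(faces, np.ndarray):
        arr = np.asarray(faces, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValidationError("configurations must be a (k, p, 2) array")
        return arr
    pts = [f.points if isinstance(f, LandmarkSet) else np.asarray(f, float) for f in faces]
    counts = {p.shape[0] for p in pts}
    if len(counts) != 1:
        raise ValidationError(f"mismatched point counts across configurations: {counts}")
    return np.stack(pts)


def _centroid_size(config: np.ndarray) -> float:
    centred = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centred**2)))


def _normalize(config: np.ndarray) -> tuple[np.ndarray, float]:
    centred = config - config.mean(axis=0)
    size = np.sqrt(np.sum(centred**2))
    if size < 1e-12:
        raise DegenerateInputError("degenerate configuration: all points coincident")
    return centred / size, float(size)


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||source @ R - target||_F (Kabsch)."""
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


@dataclass
class AlignedShapes:
    """Result of generalized Procrustes alignment."""

    configurations: np.ndarray  # (k, p, 2), centred, unit centroid size, rotated
    consensus: np.ndarray  # (p, 2) mean shape, unit centroid size
    centroid_sizes: np.ndarray  # (k,) pre-normalisation sizes
    iterations_used: int

    @property
    def n_shapes(self) -> int:
        return self.configurations.shape[0]


def generalized_procrustes(
    faces: Union[Sequence[LandmarkSet], np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedShapes:
    """Iterative GPA of >=2 same-size landmark configurations."""
    configs = _as_config_array(faces)
    k = configs.shape[0]
    if k < 2:
        raise ValidationError("generalized Procrustes needs at least 2 configurations")

    normalized, sizes = [], []
    for c in configs:
        n, s = _normalize(c)
        normalized.append(n)
        sizes.append(s)
    aligned = np.stack(normalized)

    consensus = aligned[0].copy()
    last_rss = np.inf
    for it in range(1, max_iter + 1):
        for i in range(k):
            R = _optimal_rotation(aligned[i], consensus)
            aligned[i] = aligned[i] @ R
        new_consensus = aligned.mean(axis=0)
        norm = np.sqrt(np.sum(new_consensus**2))
        if norm < 1e-12:
            raise DegenerateInputError("consensus collapsed to a point")
        new_consensus /= norm
        change = np.linalg.norm(new_consensus - consensus)
        consensus = new_consensus
        rss = float(np.sum((aligned - consensus) ** 2))
        last_rss = rss
        if change < tol:
            # report the plain mean of the aligned shapes (unit size to
            # within the convergence tolerance) as the consensus
            return AlignedShapes(aligned, aligned.mean(axis=0), np.asarray(sizes), it)
    raise ConvergenceError(
        f"GPA did not converge in {max_iter} iterations (last residual {last_rss:.3e})"
    )


def align_to_consensus(config: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Ordinary Procrustes fit of one configuration onto a consensus: centre,
    scale to unit centroid size, rotate (no reflection).  Used to bring
    held-out faces into a training-fold alignment without touching it."""
    n, _ = _normalize(np.asarray(config, float))
    R = _optimal_rotation(n, consensus)
    return n @ R


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCModel:
    """A fitted principal-component model at a variance threshold."""

    mean_vector: np.ndarray  # (n_features,)
    loadings: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray  # retained components only
    n_components: int
    variance_threshold: float
    explained_variance: Optional[np.ndarray] = None  # eigenvalues (retained)
    total_variance: Optional[float] = None

    def save(self, path) -> None:
        np.savez(
            Path(path),
            format_version=np.array([1]),
            mean_vector=self.mean_vector,
            loadings=self.loadings,
            explained_variance_ratio=self.explained_variance_ratio,
            explained_variance=self.explained_variance
            if self.explained_variance is not None
            else np.array([]),
            n_components=np.array([self.n_components]),
            variance_threshold=np.array([self.variance_threshold]),
            total_variance=np.array(
                [self.total_variance if self.total_variance is not None else np.nan]
            ),
        )

    @classmethod
    def load(cls, path) -> "PCModel":
        with np.load(Path(path)) as z:
            if int(z["format_version"][0]) != 1:
                raise ValidationError("unknown PCModel archive version")
            ev = z["explained_variance"]
            tv = float(z["total_variance"][0])
            return cls(
                mean_vector=z["mean_vector"],
                loadings=z["loadings"],
                explained_variance_ratio=z["explained_variance_ratio"],
                n_components=int(z["n_components"][0]),
                variance_threshold=float(z["variance_threshold"][0]),
                explained_variance=ev if ev.size else None,
                total_variance=None if np.isnan(tv) else tv,
            )


@dataclass
class ScoreMatrix:
    scores: np.ndarray  # (n_rows, n_components)
    feature_kind: str = "generic"  # shape | color | combined | generic
    component_ids: Optional[list[str]] = None

    def __post_init__(self):
        if self.component_ids is None:
            self.component_ids = [
                f"{self.feature_kind}_pc{i + 1}" for i in range(self.scores.shape[1])
            ]


def fit_pca(data: np.ndarray, variance_threshold: float = 0.95) -> PCModel:
    """PCA on the centred data, retaining the smallest number of components
    whose cumulative explained-variance ratio reaches the threshold."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValidationError("fit_pca needs a 2D matrix with at least 2 rows")
    if not np.all(np.isfinite(data)):
        raise ValidationError("fit_pca requires finite features")
    if not (0 < variance_threshold <= 1):
        raise ValidationError("variance_threshold must lie in (0, 1]")
    total_var = float(np.sum(np.var(data, axis=0, ddof=1)))
    if total_var <= 1e-300:
        raise DegenerateInputError("zero total variance: PCA undefined")

    full = _SkPCA(n_components=None, svd_solver="full").fit(data)
    cum = np.cumsum(full.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    n_comp = min(n_comp, len(cum))
    return PCModel(
        mean_vector=full.mean_,
        loadings=full.components_[:n_comp],
        explained_variance_ratio=full.explained_variance_ratio_[:n_comp],
        n_components=n_comp,
        variance_threshold=variance_threshold,
        explained_variance=full.explained_variance_[:n_comp],
        total_variance=total_var,
    )


def project(model: PCModel, data: np.ndarray, feature_kind: str = "generic") -> ScoreMatrix:
    """Scores = (data - mean) @ loadings.T; never refits anything."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != model.mean_vector.shape[0]:
        raise ValidationError(
            f"feature count {data.shape[1]} does not match model "
            f"({model.mean_vector.shape[0]})"
        )
    scores = (data - model.mean_vector) @ model.loadings.T
    return ScoreMatrix(scores, feature_kind)


def shapes_to_features(aligned: Union[AlignedShapes, np.ndarray]) -> np.ndarray:
    """Flatten (k, p, 2) configurations to (k, 2p) rows x1,y1,x2,y2,..."""
    configs = aligned.configurations if isinstance(aligned, AlignedShapes) else aligned
    configs = np.asarray(configs, dtype=float)
    if configs.ndim == 2:
        configs = configs[None]
    k, p, _ = configs.shape
    return configs.reshape(k, 2 * p)


def features_to_shapes(features: np.ndarray) -> np.ndarray:
    """Inverse of :func:`shapes_to_features`."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    k, f = features.shape
    if f % 2:
        raise ValidationError("feature count must be even")
    return features.reshape(k, f // 2, 2)
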