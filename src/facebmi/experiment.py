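"""The seven-model BMI-from-faces experiment as a model/results pair.

:class:`BMIExperiment` is built from data (a synthetic dataset, files on
disk, or a precomputed feature table) plus an :class:`ExperimentSettings`;
``run()`` executes repeated stratified 10-fold nested cross-validation for
every configured model and returns a :class:`BMIExperimentResults` carrying
the per-repeat r^2 distributions, the pairwise model comparisons, a
``summary()`` table and a violin plot of Fig-3 style r^2 distributions.

The default model list mirrors the study design: ordinary least squares on
each single facial metric and on all three combined, a naive elastic net on
shape PCs and on color PCs, and an RBF support-vector regression on shape
and color PCs combined.  All models run under shared repeat seeds, hence
identical fold splits, so paired comparisons are meaningful.

Fold safety: the Procrustes consensus, PC loadings, warp target and
standardization constants are fitted per outer fold on the (outlier-
filtered) training subjects only; held-out faces are aligned/warped/
projected into that training frame.  Feature construction is cached per
training-index set so models sharing a feature space do not repeat the
expensive warping.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as fio
from .cv import (
    CVRun,
    ComparisonResult,
    FeatureBuilder,
    FixedFeatures,
    compare_models,
    repeat_cv,
)
from .exceptions import ValidationError
from .metrics import TemplateRoleMap, metrics_table
from .models import (
    DEFAULT_C_GRID,
    DEFAULT_LAMBDA_GRID,
    DEFAULT_SIGMA_GRID,
    ModelSpec,
)
from .shape import (
    align_to_consensus,
    fit_pca,
    generalized_procrustes,
    project,
    shapes_to_features,
)
from .color import (
    PiecewiseAffineWarper,
    extract_color_features,
    mask_from_polygon,
)

__all__ = [
    "ExperimentSettings",
    "ShapePCFeatures",
    "ColorPCFeatures",
    "CombinedPCFeatures",
    "BMIExperiment",
    "BMIExperimentResults",
    "DEFAULT_MODEL_IDS",
]

DEFAULT_MODEL_IDS = (
    "perimeter_to_area",
    "width_to_height",
    "cheek_to_jaw",
    "metrics_combined",
    "shape_pcs",
    "color_pcs",
    "shape_color_pcs",
)


@dataclass
class ExperimentSettings:
    """Cross-validation and feature-space parameters for one study run."""

    k: int = 10
    n_repeats: int = 30
    master_seed: int = 0
    inner_k: int = 10
    inner_repeats: int = 5
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID
    C_grid: Sequence[float] = DEFAULT_C_GRID
    variance_threshold: float = 0.95
    downsample: int = 1
    n_sd_exclusion: float = 3.0
    target_ipd: float = 90.0
    include_combined_enet: bool = False

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")


# ---------------------------------------------------------------------------
# fold-safe PC feature builders

class ShapePCFeatures(FeatureBuilder):
    """Training-fold GPA + shape PCA; held-out faces are Procrustes-fitted to
    the training consensus and projected with training loadings."""

    def __init__(self, configs: np.ndarray, variance_threshold: float = 0.95):
        self.configs = np.asarray(configs, float)
        self.variance_threshold = variance_threshold
        self._cache: dict = {}

    def fit_fold(self, train_idx: np.ndarray):
        key = tuple(np.asarray(train_idx).tolist())
        if key not in self._cache:
            gpa = generalized_procrustes(self.configs[list(key)])
            train_feats = shapes_to_features(gpa)
            pca = fit_pca(train_feats, self.variance_threshold)
            self._cache[key] = (gpa.consensus, pca)
        return self._cache[key]

    def _project(self, idx: np.ndarray, consensus, pca) -> np.ndarray:
        aligned = np.stack(
            [align_to_consensus(self.configs[i], consensus) for i in idx]
        )
        return project(pca, shapes_to_features(aligned), "shape").scores

    def build(self, train_idx, test_idx):
        consensus, pca = self.fit_fold(train_idx)
        return (
            self._project(train_idx, consensus, pca),
            self._project(test_idx, consensus, pca),
        )


class ColorPCFeatures(FeatureBuilder):
    """Training-fold mean shape -> warp target; every face is warped onto it,
    masked face pixels are extracted, and a color PCA is fitted on the
    training rows only."""

    def __init__(
        self,
        configs: np.ndarray,
        images: Sequence[np.ndarray],
        roles: TemplateRoleMap,
        variance_threshold: float = 0.95,
        downsample: int = 1,
        face_outline_parts: Optional[Sequence[np.ndarray]] = None,
    ):
        self.configs = np.asarray(configs, float)
        self.images = list(images)
        self.roles = roles
        self.variance_threshold = variance_threshold
        self.downsample = downsample
        # polygon used for the pixel mask; outline + reversed hairline when
        # the template carries one, otherwise the outline chain alone
        self.face_outline_parts = face_outline_parts
        self._cache: dict = {}

    def _target_shape(self, train_idx) -> np.ndarray:
        """Training-fold mean shape placed back into the image frame at the
        mean training centroid and centroid size."""
        gpa = generalized_procrustes(self.configs[list(train_idx)])
        raw = self.configs[list(train_idx)]
        centroids = raw.mean(axis=1)
        sizes = gpa.centroid_sizes
        return gpa.consensus * sizes.mean() + centroids.mean(axis=0)

    def _mask_polygon(self, target: np.ndarray) -> np.ndarray:
        if self.face_outline_parts is not None:
            return np.vstack([target[list(p)] for p in self.face_outline_parts])
        return target[self.roles.outline]

    def fit_fold(self, train_idx: np.ndarray):
        key = tuple(np.asarray(train_idx).tolist())
        if key not in self._cache:
            target = self._target_shape(train_idx)
            shape_hw = self.images[0].shape[:2]
            warper = PiecewiseAffineWarper(target, shape_hw)
            mask = mask_from_polygon(self._mask_polygon(target), shape_hw)
            warped = [
                warper.warp(self.images[i], self.configs[i])
                for i in range(len(self.images))
            ]
            feats = extract_color_features(warped, mask, self.downsample)
            pca = fit_pca(feats[list(train_idx)], self.variance_threshold)
            self._cache[key] = (feats, pca)
            if len(self._cache) > 40:  # keep memory bounded across repeats
                self._cache.pop(next(iter(self._cache)))
        return self._cache[key]

    def build(self, train_idx, test_idx):
        feats, pca = self.fit_fold(train_idx)
        return (
            project(pca, feats[list(train_idx)], "color").scores,
            project(pca, feats[list(test_idx)], "color").scores,
        )


class CombinedPCFeatures(FeatureBuilder):
    """Column-wise concatenation of fold-safe shape and color PC scores."""

    def __init__(self, shape_builder: ShapePCFeatures, color_builder: ColorPCFeatures):
        self.shape_builder = shape_builder
        self.color_builder = color_builder

    def build(self, train_idx, test_idx):
        s_tr, s_te = self.shape_builder.build(train_idx, test_idx)
        c_tr, c_te = self.color_builder.build(train_idx, test_idx)
        return np.hstack([s_tr, c_tr]), np.hstack([s_te, c_te])


# ---------------------------------------------------------------------------
# the experiment model

class BMIExperiment:
    """The full study: data + settings -> fitted results.

    Construct with :meth:`from_synthetic`, :meth:`from_files` or
    :meth:`from_feature_table`, then call :meth:`run`.
    """

    def __init__(
        self,
        bmi: np.ndarray,
        settings: Optional[ExperimentSettings] = None,
        landmarks: Optional[Sequence] = None,
        images: Optional[Sequence[np.ndarray]] = None,
        roles: Optional[TemplateRoleMap] = None,
        fixed_features: Optional[dict] = None,
        face_outline_parts: Optional[Sequence[np.ndarray]] = None,
        subject_ids: Optional[Sequence[str]] = None,
    ):
        self.bmi = np.asarray(bmi, float)
        if np.any(self.bmi <= 0):
            raise ValidationError("BMI values must be positive")
        self.settings = settings or ExperimentSettings()
        self.landmarks = list(landmarks) if landmarks is not None else None
        self.images = list(images) if images is not None else None
        self.roles = roles
        self.fixed_features = fixed_features or {}
        self.face_outline_parts = face_outline_parts
        self.subject_ids = (
            list(subject_ids)
            if subject_ids is not None
            else [f"S{i + 1:04d}" for i in range(len(self.bmi))]
        )
        self._builders: dict = {}

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_synthetic(cls, dataset, settings: Optional[ExperimentSettings] = None):
        """Build from a :class:`facebmi.synthetic.SyntheticDataset`."""
        parts = dataset.template.parts
        outline_parts = [parts["outline"]]
        if parts.get("hairline") is not None and parts["hairline"].size:
            outline_parts.append(parts["hairline"][::-1])
        return cls(
            bmi=dataset.bmi,
            settings=settings,
            landmarks=dataset.landmarks,
            images=dataset.images,
            roles=dataset.roles,
            face_outline_parts=outline_parts,
            subject_ids=[s.subject_id for s in dataset.subjects],
        )

    @classmethod
    def from_files(
        cls,
        subject_table,
        landmark_dir,
        roles: TemplateRoleMap,
        image_dir=None,
        settings: Optional[ExperimentSettings] = None,
        template_points: Optional[int] = None,
    ):
        """Load subjects, ``.tem`` files (and PNG images) from disk."""
        subjects = fio.read_subject_table(subject_table)
        landmark_dir = Path(landmark_dir)
        landmarks, images = [], []
        for s in subjects:
            lm = fio.read_landmark_template(
                landmark_dir / f"{s.subject_id}.tem",
                subject_id=s.subject_id,
                expected_points=template_points,
            )
            landmarks.append(lm)
            if image_dir is not None:
                images.append(fio.load_image(Path(image_dir) / f"{s.subject_id}.png"))
        return cls(
            bmi=np.array([s.bmi for s in subjects]),
            settings=settings,
            landmarks=landmarks,
            images=images if image_dir is not None else None,
            roles=roles,
            subject_ids=[s.subject_id for s in subjects],
        )

    @classmethod
    def from_feature_table(
        cls,
        table: pd.DataFrame,
        settings: Optional[ExperimentSettings] = None,
        column_map: Optional[dict] = None,
    ):
        """Re-analysis mode: BMI, facial metrics and PC scores are supplied
        as columns; feature construction is skipped and the provided PC
        scores act as fixed features (an approximation of fold-internal
        PCA refitting, documented as such).

        ``column_map`` may rename: bmi, perimeter_to_area, width_to_height,
        cheek_to_jaw, shape_pc_prefix, color_pc_prefix.
        """
        cmap = {
            "bmi": "bmi",
            "perimeter_to_area": "perimeter_to_area",
            "width_to_height": "width_to_height",
            "cheek_to_jaw": "cheek_to_jaw",
            "shape_pc_prefix": "shape_pc",
            "color_pc_prefix": "color_pc",
        }
        cmap.update(column_map or {})
        if cmap["bmi"] not in table.columns:
            raise ValidationError(f"feature table lacks a {cmap['bmi']!r} column")
        fixed: dict = {}
        metric_cols = [
            cmap["perimeter_to_area"], cmap["width_to_height"], cmap["cheek_to_jaw"]
        ]
        have_metrics = [c for c in metric_cols if c in table.columns]
        for name, col in zip(
            ("perimeter_to_area", "width_to_height", "cheek_to_jaw"), metric_cols
        ):
            if col in table.columns:
                fixed[name] = table[[col]].to_numpy(float)
        if len(have_metrics) == 3:
            fixed["metrics_combined"] = table[metric_cols].to_numpy(float)
        shape_cols = [c for c in table.columns if c.startswith(cmap["shape_pc_prefix"])]
        color_cols = [c for c in table.columns if c.startswith(cmap["color_pc_prefix"])]
        if shape_cols:
            fixed["shape_pcs"] = table[shape_cols].to_numpy(float)
        if color_cols:
            fixed["color_pcs"] = table[color_cols].to_numpy(float)
        if shape_cols and color_cols:
            fixed["shape_color_pcs"] = table[shape_cols + color_cols].to_numpy(float)
        return cls(
            bmi=table[cmap["bmi"]].to_numpy(float),
            settings=settings,
            fixed_features=fixed,
        )

    # -- model plumbing ----------------------------------------------------

    def model_specs(self, model_ids: Optional[Sequence[str]] = None) -> list[ModelSpec]:
        st = self.settings
        ids = list(model_ids) if model_ids is not None else list(DEFAULT_MODEL_IDS)
        if st.include_combined_enet and "shape_color_pcs_enet" not in ids:
            ids.append("shape_color_pcs_enet")
        specs = []
        for mid in ids:
            if mid in ("perimeter_to_area", "width_to_height", "cheek_to_jaw",
                       "metrics_combined"):
                specs.append(ModelSpec(mid, "ols", feature_kind=mid, standardize=False))
            elif mid in ("shape_pcs", "color_pcs"):
                specs.append(
                    ModelSpec(
                        mid, "elastic_net", feature_kind=mid,
                        hyper_grid={"lambda": list(st.lambda_grid)},
                    )
                )
            elif mid == "shape_color_pcs":
                specs.append(
                    ModelSpec(
                        mid, "svr_rbf", feature_kind="shape_color_pcs",
                        hyper_grid={"sigma": list(st.sigma_grid),
                                    "C": list(st.C_grid)},
                    )
                )
            elif mid == "shape_color_pcs_enet":
                specs.append(
                    ModelSpec(
                        mid, "elastic_net", feature_kind="shape_color_pcs",
                        hyper_grid={"lambda": list(st.lambda_grid)},
                    )
                )
            else:
                raise ValidationError(f"unknown model id {mid!r}")
        return specs

    def _metric_matrix(self) -> pd.DataFrame:
        if "_metrics" not in self._builders:
            if self.landmarks is None or self.roles is None:
                raise ValidationError("landmarks and a role map are required "
                                      "for facial-metric models")
            self._builders["_metrics"] = metrics_table(
                self.landmarks, self.roles, self.settings.target_ipd
            )
        return self._builders["_metrics"]

    def feature_builder(self, feature_kind: str) -> FeatureBuilder:
        if feature_kind in self.fixed_features:
            return FixedFeatures(self.fixed_features[feature_kind])
        if feature_kind in self._builders:
            return self._builders[feature_kind]

        if feature_kind in ("perimeter_to_area", "width_to_height", "cheek_to_jaw"):
            builder = FixedFeatures(self._metric_matrix()[[feature_kind]].to_numpy())
        elif feature_kind == "metrics_combined":
            builder = FixedFeatures(self._metric_matrix().to_numpy())
        elif feature_kind == "shape_pcs":
            if self.landmarks is None:
                raise ValidationError("landmarks are required for shape PC models")
            configs = np.stack([lm.points for lm in self.landmarks])
            builder = ShapePCFeatures(configs, self.settings.variance_threshold)
        elif feature_kind == "color_pcs":
            if self.images is None or self.landmarks is None:
                raise ValidationError(
                    "landmarks and images are required for color PC models"
                )
            configs = np.stack([lm.points for lm in self.landmarks])
            builder = ColorPCFeatures(
                configs, self.images, self.roles,
                self.settings.variance_threshold, self.settings.downsample,
                self.face_outline_parts,
            )
        elif feature_kind == "shape_color_pcs":
            builder = CombinedPCFeatures(
                self.feature_builder("shape_pcs"), self.feature_builder("color_pcs")
            )
        else:
            raise ValidationError(f"no features available for {feature_kind!r}")
        self._builders[feature_kind] = builder
        return builder

    # -- execution ---------------------------------------------------------

    def run(
        self,
        model_ids: Optional[Sequence[str]] = None,
        progress: bool = False,
    ) -> "BMIExperimentResults":
        st = self.settings
        specs = []
        for spec in self.model_specs(model_ids):
            try:
                self.feature_builder(spec.feature_kind)
            except ValidationError:
                continue  # e.g. PC models skipped when only metrics provided
            specs.append(spec)
        if not specs:
            raise ValidationError("no runnable models for the available features")
        runs: dict[str, CVRun] = {}
        for spec in specs:
            if progress:
                print(f"[facebmi] running {spec.model_id} ({spec.family})")
            runs[spec.model_id] = repeat_cv(
                self.feature_builder(spec.feature_kind),
                self.bmi,
                spec,
                n_repeats=st.n_repeats,
                master_seed=st.master_seed,
                k=st.k,
                n_sd=st.n_sd_exclusion,
                inner_k=st.inner_k,
                inner_repeats=st.inner_repeats,
            )
        spec_by_id = {s.model_id: s for s in specs}
        comparisons = []
        for a, b in itertools.combinations(runs, 2):
            mode = (
                "paired"
                if spec_by_id[a].feature_kind == spec_by_id[b].feature_kind
                else "two_sample"
            )
            comparisons.append(compare_models(runs[a], runs[b], mode=mode))
        return BMIExperimentResults(self, runs, comparisons)

    def provenance(self) -> dict:
        from . import __version__

        cfg = asdict(self.settings)
        cfg_json = json.dumps(cfg, sort_keys=True, default=list)
        return {
            "settings": cfg,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "master_seed": self.settings.master_seed,
            "n_subjects": int(len(self.bmi)),
            "facebmi_version": __version__,
        }


def desk_study_config(master_seed: int = 0):
    """The package's desk-scale reference study: generator at default effect
    and noise settings, with the population, template and image sizes scaled
    so the full seven-model comparison runs on one CPU in minutes.

    Returns ``(SyntheticConfig, ExperimentSettings)``.  Both learner families
    are run on the combined PC set (as in the original comparison design);
    :meth:`BMIExperimentResults.best_per_feature_set` then reports the better
    one as the combined headline.
    """
    from .synthetic import SyntheticConfig

    config = SyntheticConfig(
        n_subjects=200,
        seed=int(master_seed),
        image_size=64,
        template_points=60,
    )
    settings = ExperimentSettings(
        k=10,
        n_repeats=3,
        master_seed=int(master_seed),
        inner_k=5,
        inner_repeats=2,
        lambda_grid=(0.0, 0.1, 1.0, 10.0, 100.0, 1000.0),
        downsample=2,
        include_combined_enet=True,
    )
    return config, settings


@dataclass
class BMIExperimentResults:
    """Per-model CV runs, pairwise comparisons, summary and plots."""

    experiment: BMIExperiment
    runs: dict
    comparisons: list

    @property
    def mean_r2(self) -> dict:
        return {mid: run.mean_r2 for mid, run in self.runs.items()}

    def best_per_feature_set(self) -> dict:
        """Mean r^2 per feature set, taking the better learner where two were
        run on the same features (the combined PC set runs both the elastic
        net and the RBF SVR; the winner defines the combined headline, as in
        the original comparison design)."""
        spec_by_id = {s.model_id: s for s in self.experiment.model_specs(list(self.runs))}
        best: dict = {}
        for mid, run in self.runs.items():
            kind = spec_by_id[mid].feature_kind
            if kind not in best or run.mean_r2 > best[kind]:
                best[kind] = run.mean_r2
        return best

    def summary(self) -> str:
        lines = [
            "BMI-from-faces cross-validated model comparison",
            f"  subjects: {len(self.experiment.bmi)}   "
            f"repeats: {self.experiment.settings.n_repeats}   "
            f"folds: {self.experiment.settings.k}",
            "",
            f"  {'model':<24}{'mean r2':>9}{'sd':>8}{'excl/fold':>11}",
            "  " + "-" * 52,
        ]
        for mid, run in self.runs.items():
            sd = np.std(run.repeat_means, ddof=1) if run.n_repeats > 1 else 0.0
            lines.append(
                f"  {mid:<24}{run.mean_r2:>9.3f}{sd:>8.3f}"
                f"{np.mean(run.exclusions):>11.1f}"
            )
        if self.comparisons:
            lines += ["", f"  {'comparison':<40}{'t':>8}{'df':>5}{'p':>10}",
                      "  " + "-" * 63]
            for c in self.comparisons:
                lines.append(
                    f"  {c.model_a + ' vs ' + c.model_b:<40}"
                    f"{c.t:>8.2f}{c.df:>5d}{c.p:>10.2g}"
                )
        return "\n".join(lines)

    def to_long_frame(self) -> pd.DataFrame:
        """Violin-plot-ready long format: model, repeat, mean_r2."""
        rows = [
            {"model": mid, "repeat": rep, "mean_r2": val}
            for mid, run in self.runs.items()
            for rep, val in enumerate(run.repeat_means)
        ]
        return pd.DataFrame(rows)

    def save(self, path) -> dict:
        return fio.write_report(
            list(self.runs.values()),
            self.comparisons,
            path,
            provenance=self.experiment.provenance(),
        )

    def plot_r2(self, ax=None):
        """Violin plot of the per-repeat mean r^2 distribution per model."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * len(self.runs) + 2, 4))
        data = [run.repeat_means for run in self.runs.values()]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(self.runs) + 1))
        ax.set_xticklabels(list(self.runs), rotation=45, ha="right")
        ax.set_ylabel(r"per-repeat mean $r^2$")
        ax.figure.tight_layout()
        return ax
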