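"""Repeated stratified 10-fold (outer) and nested (inner) cross-validation.

The outer cross-validation estimates generalization performance; the inner
cross-validation, run within each outer training set, selects
hyperparameters.  Strict fold-safety is the organising contract: everything
that is learned from data — the 3-SD outlier thresholds, Procrustes
consensus, PCA means/loadings, warp targets, standardization constants, and
hyperparameters — is computed from the outer training folds only, and
held-out rows are merely projected/predicted.

Folds are stratified on outcome deciles (the natural continuous-outcome
reading of "stratified"): subjects are binned by outcome rank and dealt
round-robin into folds after a seeded shuffle, so fold sizes differ by at
most one within each stratum.  Per-fold performance is the squared Pearson
correlation between observed and predicted held-out values; a constant
vector yields r^2 = 0 with a warning.  Models are compared across repeats by
t-tests: two-sample (pooled variance, df = n_a + n_b - 2) across model
families, paired (df = n_repeats - 1) for two learners evaluated on
identical features and fold splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats as _stats

from .exceptions import ValidationError
from .models import (
    ModelSpec,
    exclude_outliers,
    fit_elastic_net,
    fit_ols,
    fit_svr_rbf,
    predict,
    transform_outcome,
    tune_elastic_net,
    tune_svr_rbf,
)

__all__ = [
    "FoldPlan",
    "CVRun",
    "ComparisonResult",
    "FeatureBuilder",
    "FixedFeatures",
    "stratified_folds",
    "r_squared",
    "run_outer_cv",
    "repeat_cv",
    "compare_models",
    "derive_seed",
]


def derive_seed(master_seed: int, *stream: int) -> int:
    """Deterministic child seed below 2^31 from a master seed and stream ids."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, stream)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class FoldPlan:
    k: int
    assignments: np.ndarray  # subject index -> fold id
    n_bins: int
    seed: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test


def stratified_folds(y: np.ndarray, k: int = 10, seed: int = 0, n_bins: int = 10) -> FoldPlan:
    """Outcome-decile-stratified k-fold assignment, deterministic given seed."""
    y = np.asarray(y, float)
    n = len(y)
    if n < 2 * k:
        raise ValidationError(f"need n >= 2k for stratified folds (n={n}, k={k})")
    n_bins = max(1, min(n_bins, n // k))
    order = np.argsort(y, kind="stable")
    bin_of = np.empty(n, dtype=int)
    bin_of[order] = (np.arange(n) * n_bins) // n  # equal-count outcome bins
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    counter = 0
    for b in range(n_bins):
        members = np.flatnonzero(bin_of == b)
        rng.shuffle(members)
        for idx in members:
            assignments[idx] = counter % k
            counter += 1
    return FoldPlan(k=k, assignments=assignments, n_bins=n_bins, seed=seed)


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted values.

    Defined as 0 (with a warning) when either vector is constant.
    """
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape:
        raise ValidationError("observed and predicted lengths differ")
    if observed.size < 3:
        raise ValidationError("r_squared needs at least 3 pairs")
    if observed.std() < 1e-14 or predicted.std() < 1e-14:
        warnings.warn("constant vector in r_squared; returning 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(observed, predicted)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# feature construction contracts

class FeatureBuilder:
    """Fold-safe feature constructor.

    ``build(train_idx, test_idx)`` must fit every data-dependent piece
    (alignment, PCA, warping, ...) on ``train_idx`` only and return
    (X_train, X_test).
    """

    def build(self, train_idx: np.ndarray, test_idx: np.ndarray):
        raise NotImplementedError


class FixedFeatures(FeatureBuilder):
    """A precomputed feature matrix (facial metrics, supplied PC scores)."""

    def __init__(self, X: np.ndarray):
        self.X = np.atleast_2d(np.asarray(X, float))

    def build(self, train_idx, test_idx):
        return self.X[train_idx], self.X[test_idx]


@dataclass
class CVRun:
    """Per-fold and per-repeat r^2 for one model specification."""

    model_id: str
    fold_r2: np.ndarray  # (n_repeats, k)
    repeat_means: np.ndarray  # (n_repeats,)
    exclusions: np.ndarray  # (n_repeats, k) excluded training subjects per fold
    seeds: list[int] = field(default_factory=list)
    chosen_hyperparams: list = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_means)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.repeat_means))


@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    mode: str  # paired | two_sample
    t: float
    df: int
    p: float


def _fit_predict(spec: ModelSpec, X_tr, y_tr, X_te, inner_seed: int,
                 inner_k: int, inner_repeats: int):
    """Tune (if the family requires it), fit on the training fold, predict."""
    if spec.family == "ols":
        model = fit_ols(X_tr, y_tr)
    elif spec.family == "elastic_net":
        grid = spec.hyper_grid.get("lambda", None)
        from .models import DEFAULT_LAMBDA_GRID

        grid = DEFAULT_LAMBDA_GRID if grid is None else grid
        l1, l2 = tune_elastic_net(
            X_tr, y_tr, grid, inner_k=inner_k, inner_repeats=inner_repeats,
            seed=inner_seed,
        )
        model = fit_elastic_net(X_tr, y_tr, l1, l2, standardize=spec.standardize)
    elif spec.family == "svr_rbf":
        from .models import DEFAULT_C_GRID, DEFAULT_SIGMA_GRID

        sigma_grid = spec.hyper_grid.get("sigma", DEFAULT_SIGMA_GRID)
        c_grid = spec.hyper_grid.get("C", DEFAULT_C_GRID)
        s, c = tune_svr_rbf(
            X_tr, y_tr, sigma_grid, c_grid, inner_k=inner_k,
            inner_repeats=inner_repeats, seed=inner_seed,
        )
        model = fit_svr_rbf(X_tr, y_tr, s, c)
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValidationError(f"unknown family {spec.family!r}")
    return model, predict(model, X_te)


def run_outer_cv(
    features: Union[np.ndarray, FeatureBuilder],
    y_raw: np.ndarray,
    spec: ModelSpec,
    plan: FoldPlan,
    n_sd: float = 3.0,
    inner_k: int = 10,
    inner_repeats: int = 5,
) -> dict:
    """One repeat of the outer cross-validation.

    Per held-out fold: (1) 3-SD exclusion from the training folds' raw BMI;
    (2) reciprocal outcome transform; (3) fold-safe feature construction
    (training-only fitting, held-out projection); (4) inner tuning where the
    family requires it; (5) r^2 between held-out observed and predicted.
    Each fold is held out exactly once.
    """
    y_raw = np.asarray(y_raw, float)
    builder = features if isinstance(features, FeatureBuilder) else FixedFeatures(features)
    if isinstance(builder, FixedFeatures) and builder.X.shape[0] != len(y_raw):
        raise ValidationError("features are not row-aligned with the outcome")

    fold_r2 = np.empty(plan.k)
    exclusions = np.empty(plan.k, dtype=int)
    chosen = []
    for fold in range(plan.k):
        train_idx, test_idx = plan.fold_indices(fold)
        keep, summary = exclude_outliers(y_raw[train_idx], n_sd=n_sd)
        train_idx = train_idx[keep]
        exclusions[fold] = summary.n_excluded
        y_tr = transform_outcome(y_raw[train_idx])
        y_te = transform_outcome(y_raw[test_idx])
        X_tr, X_te = builder.build(train_idx, test_idx)
        inner_seed = derive_seed(plan.seed, fold)
        model, pred = _fit_predict(
            spec, X_tr, y_tr, X_te, inner_seed, inner_k, inner_repeats
        )
        chosen.append(dict(model.hyperparams))
        fold_r2[fold] = r_squared(y_te, pred)
    return {
        "fold_r2": fold_r2,
        "mean_r2": float(fold_r2.mean()),
        "exclusions": exclusions,
        "hyperparams": chosen,
    }


def repeat_cv(
    features: Union[np.ndarray, FeatureBuilder],
    y_raw: np.ndarray,
    spec: ModelSpec,
    n_repeats: int = 30,
    master_seed: int = 0,
    k: int = 10,
    n_sd: float = 3.0,
    inner_k: int = 10,
    inner_repeats: int = 5,
) -> CVRun:
    """Repeat the outer CV with different (seed-derived) fold splits.

    Repeat i uses a fold seed derived deterministically from
    (master_seed, i) — and from nothing model-specific — so every model run
    with the same master seed shares identical fold splits, which is what
    makes paired comparisons meaningful.
    """
    if n_repeats < 2:
        raise ValidationError("need at least 2 repeats")
    y_raw = np.asarray(y_raw, float)
    all_fold_r2, means, excl, seeds, hypers = [], [], [], [], []
    for rep in range(n_repeats):
        seed = derive_seed(master_seed, rep)
        plan = stratified_folds(y_raw, k=k, seed=seed)
        out = run_outer_cv(
            features, y_raw, spec, plan, n_sd=n_sd,
            inner_k=inner_k, inner_repeats=inner_repeats,
        )
        all_fold_r2.append(out["fold_r2"])
        means.append(out["mean_r2"])
        excl.append(out["exclusions"])
        seeds.append(seed)
        hypers.append(out["hyperparams"])
    return CVRun(
        model_id=spec.model_id,
        fold_r2=np.vstack(all_fold_r2),
        repeat_means=np.asarray(means),
        exclusions=np.vstack(excl),
        seeds=seeds,
        chosen_hyperparams=hypers,
    )


def compare_models(a: CVRun, b: CVRun, mode: str = "two_sample") -> ComparisonResult:
    """t-test on per-repeat mean r^2 values of two runs.

    ``two_sample``: pooled-variance t, df = n_a + n_b - 2 (across model
    families).  ``paired``: t on per-repeat differences, df = n - 1 (same
    features and fold splits).
    """
    xa = np.asarray(a.repeat_means, float)
    xb = np.asarray(b.repeat_means, float)
    if mode == "paired":
        if len(xa) != len(xb):
            raise ValidationError("paired comparison needs equal repeat counts")
        df = len(xa) - 1
        if np.allclose(xa, xb):  # identical runs: t defined as 0, not 0/0
            return ComparisonResult(a.model_id, b.model_id, mode, 0.0, df, 1.0)
        res = _stats.ttest_rel(xa, xb)
    elif mode == "two_sample":
        res = _stats.ttest_ind(xa, xb, equal_var=True)
        df = len(xa) + len(xb) - 2
    else:
        raise ValidationError(f"unknown comparison mode {mode!r}")
    return ComparisonResult(
        model_a=a.model_id,
        model_b=b.model_id,
        mode=mode,
        t=float(res.statistic),
        df=int(df),
        p=float(res.pvalue),
    )
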