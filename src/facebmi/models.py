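"""Outcome transforms, training-set outlier exclusion, and the three model
families used to predict BMI from facial features.

Families
--------
``ols``
    Ordinary least squares on the (reciprocal-transformed) outcome; used for
    the facial-metric models.  Left unstandardized — the result is
    scale-free.
``elastic_net``
    The *naive* elastic net: minimise

        ||y - b0 - X b||^2 + lambda2 ||b||_2^2 + lambda1 ||b||_1

    by cyclical coordinate descent with soft-thresholding, intercept
    unpenalized, features standardized from the training data (penalties are
    scale-sensitive).  "Naive" means no (1 + lambda2) coefficient rescaling
    is applied after fitting.
``svr_rbf``
    Epsilon-insensitive support-vector regression with the radial basis
    kernel k(u, v) = exp(-sigma ||u - v||^2); sigma is the *inverse* kernel
    width and C the cost of constraint violation.  Both X and y are
    standardized inside the fit (epsilon defaults to 0.1 on the standardized
    outcome) and predictions are returned on the original outcome scale.

Hyperparameters for the penalized and kernel families are selected by inner
repeated stratified k-fold cross-validation on the training set
(:func:`tune_elastic_net`, :func:`tune_svr_rbf`), maximising the mean
held-out r^2 across inner repeats.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import SVR as _SkSVR

from .exceptions import ConvergenceError, ValidationError

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_SIGMA_GRID",
    "DEFAULT_C_GRID",
    "ModelSpec",
    "FittedModel",
    "ExclusionSummary",
    "transform_outcome",
    "inverse_outcome",
    "exclude_outliers",
    "fit_ols",
    "fit_elastic_net",
    "elastic_net_objective",
    "tune_elastic_net",
    "fit_svr_rbf",
    "tune_svr_rbf",
    "predict",
]

#: logarithmic lambda grid spanning the 0-1000 search range, per axis
DEFAULT_LAMBDA_GRID = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
DEFAULT_SIGMA_GRID = (1e-4, 1e-3, 1e-2, 1e-1)
DEFAULT_C_GRID = (1.0, 10.0, 100.0, 1000.0)


@dataclass
class ModelSpec:
    """What to fit: family, feature set name, hyperparameter grids."""

    model_id: str
    family: str  # ols | elastic_net | svr_rbf
    feature_kind: str = "fixed"
    hyper_grid: dict = field(default_factory=dict)
    standardize: bool = True

    def __post_init__(self):
        if self.family not in ("ols", "elastic_net", "svr_rbf"):
            raise ValidationError(f"unknown model family {self.family!r}")
        for key, values in self.hyper_grid.items():
            arr = np.asarray(values, float)
            if np.any(arr < 0):
                raise ValidationError(f"grid values for {key!r} must be >= 0")
            if key.startswith("lambda") and np.any(arr > 1000):
                raise ValidationError("lambda grid is bounded by 1000")


@dataclass
class ExclusionSummary:
    n_excluded: int
    mean_excluded_bmi: float
    threshold_low: float
    threshold_high: float


def transform_outcome(y: np.ndarray) -> np.ndarray:
    """Reciprocal transform 1/y used to normalise right-skewed BMI."""
    y = np.asarray(y, float)
    if np.any(y <= 0):
        raise ValidationError("outcome transform requires strictly positive values")
    return 1.0 / y


def inverse_outcome(t: np.ndarray) -> np.ndarray:
    """Back-transform: the reciprocal is its own inverse."""
    t = np.asarray(t, float)
    if np.any(t <= 0):
        raise ValidationError("inverse transform requires strictly positive values")
    return 1.0 / t


def exclude_outliers(train_y: np.ndarray, n_sd: float = 3.0):
    """Mask of training values within n_sd sample SDs of the training mean.

    Mean and SD come from the training values only.  With zero SD (all-equal
    input) nothing is excluded.  Returns (keep_mask, ExclusionSummary).
    """
    train_y = np.asarray(train_y, float)
    if train_y.size < 3:
        raise ValidationError("need at least 3 training values for outlier exclusion")
    mu = train_y.mean()
    sd = train_y.std(ddof=1)
    keep = np.abs(train_y - mu) <= n_sd * sd
    excluded = train_y[~keep]
    summary = ExclusionSummary(
        n_excluded=int((~keep).sum()),
        mean_excluded_bmi=float(excluded.mean()) if excluded.size else float("nan"),
        threshold_low=float(mu - n_sd * sd),
        threshold_high=float(mu + n_sd * sd),
    )
    return keep, summary


# ---------------------------------------------------------------------------
# fitted-model container

@dataclass
class FittedModel:
    """Results object for one fitted regression: parameters, chosen
    hyperparameters, and the standardization constants needed to predict."""

    family: str
    intercept: float = 0.0
    coef: Optional[np.ndarray] = None  # on the standardized scale if standardized
    hyperparams: dict = field(default_factory=dict)
    x_mean: Optional[np.ndarray] = None
    x_scale: Optional[np.ndarray] = None
    y_mean: float = 0.0
    y_scale: float = 1.0
    n_features: int = 0
    estimator: object = None  # kernel families keep the underlying estimator
    n_iter: int = 0
    objective: float = float("nan")

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.intercept], np.asarray(self.coef)])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    return (X - mean) / scale, mean, scale


def fit_ols(X: np.ndarray, y: np.ndarray) -> FittedModel:
    """Ordinary least squares with intercept; requires full column rank."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"OLS needs n > p (got n={n}, p={p})")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        raise ValidationError("rank-deficient design matrix in OLS")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    return FittedModel(
        family="ols", intercept=float(beta[0]), coef=beta[1:], n_features=p
    )


def elastic_net_objective(
    X: np.ndarray, y: np.ndarray, intercept: float, beta: np.ndarray,
    lambda1: float, lambda2: float,
) -> float:
    """The naive elastic-net objective at given parameters."""
    r = y - intercept - X @ beta
    return float(r @ r + lambda2 * beta @ beta + lambda1 * np.abs(beta).sum())


def _cd_gram_kernel(G, b, beta, g_beta, lambda1, lambda2, tol, max_sweeps):
    """Cyclical coordinate-descent sweeps on the Gram form (G = X'X,
    b = X'y, centred); updates ``beta`` and ``g_beta = G @ beta`` in place.
    Returns the sweep count, or -1 on non-convergence."""
    p = len(b)
    half_l1 = lambda1 / 2.0
    for sweeps in range(1, max_sweeps + 1):
        max_delta = 0.0
        for j in range(p):
            bj = beta[j]
            diag = G[j, j]
            rho = b[j] - g_beta[j] + diag * bj
            denom = diag + lambda2
            if denom < 1e-300:
                new = 0.0
            else:
                mag = abs(rho) - half_l1
                new = (np.sign(rho) * mag / denom) if mag > 0.0 else 0.0
            if new != bj:
                delta = new - bj
                for k in range(p):
                    g_beta[k] += G[k, j] * delta
                beta[j] = new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            return sweeps
    return -1


try:  # compile the inner loop when numba is available (pure-python fallback)
    from numba import njit as _njit

    _cd_gram_kernel = _njit(cache=True)(_cd_gram_kernel)
except ImportError:  # pragma: no cover
    pass


def _cd_gram(
    G: np.ndarray,
    b: np.ndarray,
    lambda1: float,
    lambda2: float,
    beta0: Optional[np.ndarray],
    tol: float,
    max_sweeps: int,
) -> tuple[np.ndarray, int]:
    """Solve the Gram-form naive elastic net by soft-thresholded cyclical
    coordinate descent:

        b_j <- S(b[j] - sum_{k != j} G[j, k] beta_k, lambda1 / 2)
               / (G_jj + lambda2)

    Returns (beta, sweeps used); raises on non-convergence."""
    G = np.ascontiguousarray(G, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    beta = (
        np.zeros(len(b)) if beta0 is None else np.asarray(beta0, float).copy()
    )
    g_beta = G @ beta
    sweeps = _cd_gram_kernel(
        G, b, beta, g_beta, float(lambda1), float(lambda2), float(tol),
        int(max_sweeps),
    )
    if sweeps < 0:
        raise ConvergenceError(
            f"elastic net did not converge in {max_sweeps} sweeps "
            f"(lambda1={lambda1}, lambda2={lambda2})"
        )
    return beta, int(sweeps)


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    lambda1: float,
    lambda2: float,
    standardize: bool = True,
    tol: float = 1e-9,
    max_sweeps: int = 10000,
    warm_start: Optional[np.ndarray] = None,
) -> FittedModel:
    """Naive elastic net by cyclical coordinate descent.

    Minimises ||y - b0 - X b||^2 + lambda2 ||b||^2 + lambda1 ||b||_1 with an
    unpenalized intercept; features standardized from the training data by
    default.  Coordinate updates use soft-thresholding
    S(z, t) = sign(z) max(|z|-t, 0); the objective is nonincreasing across
    sweeps and iteration stops when the largest coefficient change in a
    sweep falls below ``tol``.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if lambda1 < 0 or lambda2 < 0:
        raise ValidationError("penalties must be nonnegative")
    n, p = X.shape
    if n != y.shape[0]:
        raise ValidationError("X and y row counts differ")

    if standardize:
        Xs, x_mean, x_scale = _standardize_fit(X)
    else:
        Xs, x_mean, x_scale = X, None, None
    y_mean = y.mean()
    yc = y - y_mean  # intercept unpenalized: with centred X it is mean(y)

    beta, sweeps = _cd_gram(
        Xs.T @ Xs, Xs.T @ yc, lambda1, lambda2, warm_start, tol, max_sweeps
    )
    return FittedModel(
        family="elastic_net",
        intercept=float(y_mean),
        coef=beta,
        hyperparams={"lambda1": lambda1, "lambda2": lambda2},
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=float(y_mean),
        n_features=p,
        n_iter=sweeps,
        objective=elastic_net_objective(Xs, yc, 0.0, beta, lambda1, lambda2),
    )


def _inner_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    # local import to avoid a cycle with facebmi.cv
    from .cv import r_squared

    return r_squared(obs, pred)


def _inner_fold_indices(n: int, y: np.ndarray, k: int, repeats: int, seed: int):
    from .cv import stratified_folds

    plans = []
    for rep in range(repeats):
        rep_seed = int(
            np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31)
        )
        plans.append(stratified_folds(y, k=k, seed=rep_seed))
    return plans


def tune_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    inner_k: int = 10,
    inner_repeats: int = 5,
    seed: int = 0,
    tol: float = 1e-7,
) -> tuple[float, float]:
    """Grid-search (lambda1, lambda2) maximising mean inner-CV r^2.

    The inner cross-validation is a repeated stratified k-fold on the
    training data only; the pair with the highest mean r^2 across all inner
    folds and repeats wins (ties broken by grid order, which lists smaller
    penalties first).  Deterministic given ``seed``.
    """
    grid = [float(v) for v in lambda_grid]
    if not grid:
        raise ValidationError("empty lambda grid")
    if min(grid) < 0 or max(grid) > 1000:
        raise ValidationError("lambda grid must lie within [0, 1000]")
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n = len(y)
    k = min(inner_k, max(2, n // 2))
    plans = _inner_fold_indices(n, y, k, inner_repeats, seed)

    pairs = list(itertools.product(grid, grid))
    scores = np.zeros(len(pairs))
    counts = 0
    for plan in plans:
        for fold in range(plan.k):
            test = plan.assignments == fold
            train = ~test
            if test.sum() < 3 or train.sum() < 3:
                continue
            # standardize and form the Gram problem once per fold; the whole
            # lambda grid is then solved by warm-started coordinate descent
            Xs, x_mean, x_scale = _standardize_fit(X[train])
            ytr = y[train]
            yc = ytr - ytr.mean()
            G = Xs.T @ Xs
            bvec = Xs.T @ yc
            Xte_s = (X[test] - x_mean) / x_scale
            yte = y[test]
            warm = None
            for idx, (l1, l2) in enumerate(pairs):
                beta, _ = _cd_gram(G, bvec, l1, l2, warm, tol, 10000)
                warm = beta
                pred = ytr.mean() + Xte_s @ beta
                scores[idx] += _inner_r2(yte, pred)
            counts += 1
    if counts == 0:
        raise ValidationError("inner CV produced no usable folds")
    best = int(np.argmax(scores))
    return pairs[best]


def fit_svr_rbf(
    X: np.ndarray,
    y: np.ndarray,
    sigma: float,
    C: float,
    epsilon: float = 0.1,
) -> FittedModel:
    """Epsilon-SVR with kernel exp(-sigma ||u-v||^2), fitted on standardized
    features and outcome; predictions are de-standardized."""
    if sigma <= 0 or C <= 0 or epsilon < 0:
        raise ValidationError("require sigma > 0, C > 0, epsilon >= 0")
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    Xs, x_mean, x_scale = _standardize_fit(X)
    y_mean = y.mean()
    y_scale = y.std(ddof=0)
    if y_scale < 1e-12:
        y_scale = 1.0
    ys = (y - y_mean) / y_scale
    est = _SkSVR(kernel="rbf", gamma=sigma, C=C, epsilon=epsilon)
    est.fit(Xs, ys)
    return FittedModel(
        family="svr_rbf",
        hyperparams={"sigma": sigma, "C": C, "epsilon": epsilon},
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=float(y_mean),
        y_scale=float(y_scale),
        n_features=X.shape[1],
        estimator=est,
    )


def rbf_kernel(u: np.ndarray, v: np.ndarray, sigma: float) -> np.ndarray:
    """k(u, v) = exp(-sigma ||u - v||^2); k(u, u) = 1."""
    u = np.atleast_2d(np.asarray(u, float))
    v = np.atleast_2d(np.asarray(v, float))
    d2 = ((u[:, None, :] - v[None, :, :]) ** 2).sum(-1)
    return np.exp(-sigma * d2)


def tune_svr_rbf(
    X: np.ndarray,
    y: np.ndarray,
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    inner_k: int = 10,
    inner_repeats: int = 5,
    seed: int = 0,
    epsilon: float = 0.1,
) -> tuple[float, float]:
    """Grid-search (sigma, C) maximising mean inner-CV r^2 (same scheme as
    :func:`tune_elastic_net`)."""
    if not sigma_grid or not C_grid:
        raise ValidationError("empty SVR grid")
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n = len(y)
    k = min(inner_k, max(2, n // 2))
    plans = _inner_fold_indices(n, y, k, inner_repeats, seed)
    pairs = list(itertools.product([float(s) for s in sigma_grid],
                                   [float(c) for c in C_grid]))
    scores = np.zeros(len(pairs))
    counts = 0
    for plan in plans:
        for fold in range(plan.k):
            test = plan.assignments == fold
            train = ~test
            if test.sum() < 3 or train.sum() < 3:
                continue
            for idx, (s, c) in enumerate(pairs):
                m = fit_svr_rbf(X[train], y[train], s, c, epsilon=epsilon)
                scores[idx] += _inner_r2(y[test], predict(m, X[test]))
            counts += 1
    if counts == 0:
        raise ValidationError("inner CV produced no usable folds")
    best = int(np.argmax(scores))
    return pairs[best]


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Deterministic prediction applying stored standardization first."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.n_features and model.n_features:
        raise ValidationError(
            f"feature count {X.shape[1]} does not match training ({model.n_features})"
        )
    if model.family == "svr_rbf":
        Xs = (X - model.x_mean) / model.x_scale
        return model.estimator.predict(Xs) * model.y_scale + model.y_mean
    if model.x_mean is not None:
        X = (X - model.x_mean) / model.x_scale
    return model.intercept + X @ model.coef
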