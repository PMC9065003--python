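"""Salt-concentration regression on preprocessed Raman spectra.

The workhorse is an exact Gaussian-process regressor with a constant basis
(mean) function and a stationary kernel, the default being the rational
quadratic

    k_RQ(r) = sigma_f^2 * (1 + r^2 / (2 alpha l^2))^(-alpha),   r = |x - x'|,

a scale mixture of squared-exponential kernels that converges to one as
alpha -> infinity.  The constant basis coefficient beta multiplies H, an
n-by-1 vector of ones, and is profiled out by generalized least squares at
every hyperparameter evaluation; l, alpha, the signal amplitude sigma_f and
the noise level sigma_n maximize the exact log marginal likelihood via
multi-restart L-BFGS on log parameters with analytic gradients.

Because every kernel here is a function of the pairwise Euclidean distance
only, squared distances are computed once per fit and reused across all
hyperparameter evaluations.

Comparator models (ridge-regularized linear regression and a CART regression
tree), the 80/20 evaluation protocol, k-fold cross-validation,
leave-one-concentration-out and week inference by minimum residual live here
as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from sklearn.linear_model import RidgeCV
from sklearn.model_selection import KFold, train_test_split
from sklearn.tree import DecisionTreeRegressor

from .errors import FitError, InputError, ParameterError

__all__ = [
    "RQKernelParams",
    "GPRModel",
    "EvalReport",
    "SplitSpec",
    "KERNEL_TAGS",
    "rq_kernel",
    "kernel_matrix",
    "fit_gpr",
    "predict_gpr",
    "fit_baselines",
    "evaluate",
    "stratified_split",
    "cross_validate",
    "leave_one_concentration_out",
    "predict_week",
]

KERNEL_TAGS = ("rq", "squared_exponential", "matern52", "exponential")

_JITTER = 1e-10


@dataclass(frozen=True)
class RQKernelParams:
    """Rational-quadratic hyperparameters.

    length_scale l sets the input distance over which correlations decay;
    alpha is the dimensionless scale-mixture parameter; signal_sd sigma_f and
    noise_sd sigma_n are in output units (mM here).
    """

    length_scale: float
    alpha: float = 1.0
    signal_sd: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.length_scale <= 0 or self.alpha <= 0 or self.signal_sd <= 0 or self.noise_sd < 0:
            raise ParameterError(
                "need length_scale > 0, alpha > 0, signal_sd > 0, noise_sd >= 0; "
                f"got {self}"
            )


def rq_kernel(x: np.ndarray, x_prime: np.ndarray, params: RQKernelParams) -> float:
    """Rational-quadratic covariance between two input vectors."""
    x = np.asarray(x, dtype=float).ravel()
    x_prime = np.asarray(x_prime, dtype=float).ravel()
    if x.shape != x_prime.shape:
        raise InputError(f"dimension mismatch: {x.shape} vs {x_prime.shape}")
    r2 = float(np.sum((x - x_prime) ** 2))
    return float(
        params.signal_sd**2
        * (1.0 + r2 / (2.0 * params.alpha * params.length_scale**2)) ** (-params.alpha)
    )


def _corr(tag: str, r2: np.ndarray, l: float, alpha: float) -> np.ndarray:
    """Unit-amplitude stationary correlation as a function of squared distance."""
    if tag == "rq":
        return (1.0 + r2 / (2.0 * alpha * l**2)) ** (-alpha)
    if tag == "squared_exponential":
        return np.exp(-0.5 * r2 / l**2)
    r = np.sqrt(np.maximum(r2, 0.0))
    if tag == "matern52":
        u = np.sqrt(5.0) * r / l
        return (1.0 + u + u**2 / 3.0) * np.exp(-u)
    if tag == "exponential":
        return np.exp(-r / l)
    raise ParameterError(f"unknown kernel tag {tag!r}; choose from {KERNEL_TAGS}")


def _corr_grads(tag: str, r2: np.ndarray, l: float, alpha: float, C: np.ndarray):
    """d corr / d log(l) and d corr / d log(alpha) (None when alpha is unused)."""
    if tag == "rq":
        B = 1.0 + r2 / (2.0 * alpha * l**2)
        dl = B ** (-alpha - 1.0) * r2 / l**2
        dalpha = alpha * C * ((B - 1.0) / B - np.log(B))
        return dl, dalpha
    if tag == "squared_exponential":
        return C * r2 / l**2, None
    r = np.sqrt(np.maximum(r2, 0.0))
    if tag == "matern52":
        u = np.sqrt(5.0) * r / l
        # d/dlog l of (1+u+u^2/3) e^-u with du/dlog l = -u
        return np.exp(-u) * (u**2 / 3.0) * (1.0 + u), None
    if tag == "exponential":
        return C * r / l, None
    raise ParameterError(f"unknown kernel tag {tag!r}")


def kernel_matrix(
    X: np.ndarray, Y: np.ndarray, tag: str, l: float, alpha: float, signal_sd: float
) -> np.ndarray:
    """Cross-covariance matrix between two input sets."""
    r2 = cdist(np.atleast_2d(X), np.atleast_2d(Y), metric="sqeuclidean")
    return signal_sd**2 * _corr(tag, r2, l, alpha)


@dataclass
class GPRModel:
    """Trained exact GP: kernel tag + hyperparameters, profiled constant basis
    coefficient beta (mM), training data and cached Cholesky solve factors."""

    kernel_tag: str
    params: RQKernelParams
    beta: float
    X_train: np.ndarray
    y_train: np.ndarray
    alpha_vec: np.ndarray = field(repr=False)
    log_marginal_likelihood: float = np.nan
    seed: int | None = None
    tag: str = "gpr-rq"

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict_gpr(self, X_new)[0]


def _neg_lml_and_grad(
    theta: np.ndarray, r2: np.ndarray, y: np.ndarray, tag: str, noise_floor: float
) -> tuple[float, np.ndarray]:
    """Negative profiled log marginal likelihood and gradient in log parameters.

    theta = log(l, alpha, sigma_f, sigma_n).  beta is profiled by GLS at every
    evaluation; by the envelope theorem the gradient through beta vanishes.
    """
    l, alpha, sf, sn = np.exp(theta)
    sn = max(sn, noise_floor)
    n = y.size
    C = _corr(tag, r2, l, alpha)
    K = sf**2 * C
    K[np.diag_indices_from(K)] += sn**2 + _JITTER
    try:
        cho = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros_like(theta)
    ones = np.ones(n)
    Kinv_y = cho_solve(cho, y)
    Kinv_1 = cho_solve(cho, ones)
    beta = float(ones @ Kinv_y / (ones @ Kinv_1))
    resid = y - beta
    a = cho_solve(cho, resid)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    lml = -0.5 * float(resid @ a) - 0.5 * logdet - 0.5 * n * np.log(2.0 * np.pi)
    if not np.isfinite(lml):
        return 1e25, np.zeros_like(theta)

    Kinv = cho_solve(cho, np.eye(n))
    M = np.outer(a, a) - Kinv  # 0.5 * tr(M dK/dtheta) is dLML/dtheta
    dl, dalpha = _corr_grads(tag, r2, l, alpha, C)
    grad = np.zeros(4)
    grad[0] = 0.5 * np.sum(M * (sf**2 * dl))
    grad[1] = 0.5 * np.sum(M * (sf**2 * dalpha)) if dalpha is not None else 0.0
    grad[2] = 0.5 * np.sum(M * (2.0 * K - 2.0 * (sn**2 + _JITTER) * np.eye(n)))
    grad[3] = 0.5 * np.trace(M) * 2.0 * sn**2
    return -lml, -grad


def fit_gpr(
    X: np.ndarray,
    y: np.ndarray,
    kernel_tag: str = "rq",
    *,
    n_restarts: int = 3,
    seed: int = 0,
    noise_floor: float = 1e-8,
    max_train: int = 3000,
    maxiter: int = 200,
    fixed_params: RQKernelParams | None = None,
) -> GPRModel:
    """Fit an exact GP with constant basis by maximizing the marginal likelihood.

    Initialization: l = median pairwise training distance, alpha = 1,
    sigma_f = sd(y), sigma_n = sigma_f / 10, followed by ``n_restarts``
    restarts from log-normally jittered starting points (seeded).  Passing
    ``fixed_params`` skips optimization and conditions on those values.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n != y.size:
        raise InputError(f"{n} inputs but {y.size} targets")
    if n < 2:
        raise InputError("need at least 2 training points")
    if n > max_train:
        raise FitError(
            f"{n} training spectra exceed the exact-GP budget of {max_train}; "
            "subsample (stratified by concentration) or raise max_train"
        )
    if kernel_tag not in KERNEL_TAGS:
        raise ParameterError(f"unknown kernel tag {kernel_tag!r}; choose from {KERNEL_TAGS}")

    r2 = cdist(X, X, metric="sqeuclidean")

    if fixed_params is not None:
        params = fixed_params
        best_lml = None
    else:
        tri = r2[np.triu_indices(n, k=1)]
        l0 = float(np.sqrt(np.median(tri[tri > 0]))) if np.any(tri > 0) else 1.0
        sf0 = float(np.std(y)) or 1.0
        theta0 = np.log([l0, 1.0, sf0, max(sf0 / 10.0, noise_floor)])
        rng = np.random.default_rng(seed)
        starts = [theta0] + [theta0 + rng.normal(0.0, 0.5, size=4) for _ in range(n_restarts)]
        best = None
        for th in starts:
            res = minimize(
                _neg_lml_and_grad,
                th,
                args=(r2, y, kernel_tag, noise_floor),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter},
            )
            if res.fun < 1e24 and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise FitError("log marginal likelihood was non-finite at every restart")
        l, alpha, sf, sn = np.exp(best.x)
        params = RQKernelParams(l, alpha, sf, max(sn, noise_floor))
        best_lml = -float(best.fun)

    K = params.signal_sd**2 * _corr(kernel_tag, r2, params.length_scale, params.alpha)
    K[np.diag_indices_from(K)] += params.noise_sd**2 + _JITTER
    cho = cho_factor(K, lower=True)
    ones = np.ones(n)
    beta = float(ones @ cho_solve(cho, y) / (ones @ cho_solve(cho, ones)))
    alpha_vec = cho_solve(cho, y - beta)
    if best_lml is None:
        resid = y - beta
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        best_lml = float(-0.5 * resid @ alpha_vec - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi))
    return GPRModel(
        kernel_tag=kernel_tag,
        params=params,
        beta=beta,
        X_train=X,
        y_train=y,
        alpha_vec=alpha_vec,
        log_marginal_likelihood=best_lml,
        seed=seed,
        tag=f"gpr-{kernel_tag}",
    )


def predict_gpr(model: GPRModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean beta + k*^T K^-1 (y - beta H) and latent posterior sd."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise InputError(
            f"input dimension {X_new.shape[1]} != training dimension {model.X_train.shape[1]}"
        )
    p = model.params
    k_star = kernel_matrix(X_new, model.X_train, model.kernel_tag, p.length_scale, p.alpha, p.signal_sd)
    mean = model.beta + k_star @ model.alpha_vec

    K = kernel_matrix(
        model.X_train, model.X_train, model.kernel_tag, p.length_scale, p.alpha, p.signal_sd
    )
    K[np.diag_indices_from(K)] += p.noise_sd**2 + _JITTER
    cho = cho_factor(K, lower=True)
    v = cho_solve(cho, k_star.T)
    var = p.signal_sd**2 - np.einsum("ij,ji->i", k_star, v)
    return mean, np.sqrt(np.maximum(var, 0.0))


@dataclass(frozen=True)
class SplitSpec:
    """Train/test and cross-validation protocol: 80/20 split, 5 folds by default."""

    test_fraction: float = 0.2
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ParameterError(f"test_fraction must be in (0, 1), got {self.test_fraction}")
        if self.cv_folds < 2:
            raise ParameterError(f"cv_folds must be >= 2, got {self.cv_folds}")


@dataclass(frozen=True)
class EvalReport:
    """RMSE (mM), R^2, residuals (true - predicted) and per-true-concentration
    prediction medians for one model on one test set."""

    rmse: float
    r2: float | None
    residuals: np.ndarray
    per_concentration_medians: dict[float, float]
    model_tag: str = ""
    week: int | None = None


class RidgeLinearModel:
    """Ridge-regularized linear regression over the full spectral feature set.

    Plain least squares is ill-posed here (far more wavenumbers than spectra);
    the ridge path guarantees finite coefficients even for collinear features.
    """

    tag = "linear-ridge"

    def __init__(self, alphas: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0)):
        self._model = RidgeCV(alphas=alphas)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeLinearModel":
        self._model.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict(X)


class RegressionTreeModel:
    """CART regression tree with variance-reduction splits, depth-limited."""

    tag = "tree"

    def __init__(self, max_depth: int | None = 8, seed: int = 0):
        self._model = DecisionTreeRegressor(max_depth=max_depth, random_state=seed)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegressionTreeModel":
        self._model.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict(X)


def fit_baselines(X: np.ndarray, y: np.ndarray, seed: int = 0) -> dict[str, object]:
    """Fit the comparator models (ridge linear, regression tree)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size or y.size < 2:
        raise InputError("need matching X/y with at least 2 samples")
    models: dict[str, object] = {
        "linear-ridge": RidgeLinearModel().fit(X, y),
        "tree": RegressionTreeModel(seed=seed).fit(X, y),
    }
    return models


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray, week: int | None = None) -> EvalReport:
    """RMSE, R^2, residuals and per-concentration prediction medians."""
    y_test = np.asarray(y_test, dtype=float).ravel()
    if y_test.size == 0:
        raise InputError("empty test set")
    pred = np.asarray(model.predict(X_test), dtype=float).ravel()
    residuals = y_test - pred
    rmse = float(np.sqrt(np.mean(residuals**2)))
    ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero-variance test targets: R^2 is undefined", stacklevel=2)
        r2 = None
    else:
        r2 = float(1.0 - np.sum(residuals**2) / ss_tot)
    medians = {
        float(c): float(np.median(pred[y_test == c])) for c in np.unique(y_test)
    }
    return EvalReport(
        rmse=rmse,
        r2=r2,
        residuals=residuals,
        per_concentration_medians=medians,
        model_tag=getattr(model, "tag", type(model).__name__),
        week=week,
    )


def stratified_split(
    X: np.ndarray, y: np.ndarray, split: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """80/20-style split stratified by concentration level (each level lands in
    both halves)."""
    y = np.asarray(y, dtype=float).ravel()
    strata = y if np.unique(y).size < max(2, y.size // 4) else None
    return train_test_split(
        np.atleast_2d(X), y, test_size=split.test_fraction, random_state=split.seed, stratify=strata
    )


def cross_validate(
    X: np.ndarray, y: np.ndarray, model_factory, split: SplitSpec
) -> tuple[list[EvalReport], dict[str, float]]:
    """Seeded k-fold CV; returns per-fold reports plus mean/sd summary.

    ``model_factory`` is a zero-argument callable returning an unfitted model
    exposing fit/predict (e.g. ``lambda: RidgeLinearModel()`` or a wrapper
    around :func:`fit_gpr`).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size < split.cv_folds:
        raise InputError(f"{y.size} samples cannot fill {split.cv_folds} folds")
    folds = KFold(n_splits=split.cv_folds, shuffle=True, random_state=split.seed)
    reports: list[EvalReport] = []
    for train_idx, test_idx in folds.split(X):
        model = model_factory()
        model.fit(X[train_idx], y[train_idx])
        reports.append(evaluate(model, X[test_idx], y[test_idx]))
    rmses = np.array([r.rmse for r in reports])
    r2s = np.array([r.r2 for r in reports if r.r2 is not None], dtype=float)
    summary = {
        "rmse_mean": float(rmses.mean()),
        "rmse_sd": float(rmses.std(ddof=1)) if len(rmses) > 1 else 0.0,
        "r2_mean": float(r2s.mean()) if r2s.size else float("nan"),
        "r2_sd": float(r2s.std(ddof=1)) if r2s.size > 1 else 0.0,
    }
    return reports, summary


class GPRFactory:
    """fit/predict adapter so the GP plugs into the CV and baseline protocols."""

    def __init__(self, kernel_tag: str = "rq", seed: int = 0, **kwargs):
        self.kernel_tag = kernel_tag
        self.seed = seed
        self.kwargs = kwargs
        self.model: GPRModel | None = None
        self.tag = f"gpr-{kernel_tag}"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GPRFactory":
        self.model = fit_gpr(X, y, self.kernel_tag, seed=self.seed, **self.kwargs)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise InputError("predict before fit")
        return self.model.predict(X)


def leave_one_concentration_out(
    X: np.ndarray,
    y: np.ndarray,
    left_out: float,
    model_factory,
) -> tuple[EvalReport, float]:
    """Train on every concentration group except ``left_out``, predict that
    group, and report median(prediction) - left_out (mM)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    held = y == left_out
    if not held.any():
        raise InputError(f"concentration {left_out} mM not present in targets")
    if np.unique(y[~held]).size < 2:
        raise InputError("need at least 2 remaining concentration levels to train")
    model = model_factory()
    model.fit(X[~held], y[~held])
    with warnings.catch_warnings():
        # the held-out group is single-valued, so R^2 is undefined by design
        warnings.filterwarnings("ignore", message="zero-variance")
        report = evaluate(model, X[held], y[held])
    deviation = float(np.median(model.predict(X[held])) - left_out)
    return report, deviation


def predict_week(
    models: dict[int, object], X_unknown: np.ndarray, true_concentration: float
) -> tuple[int, dict[int, float]]:
    """Infer the growth week of a sample set by minimum |median prediction - truth|.

    Ties break toward the earlier week, deterministically.
    """
    if not models:
        raise InputError("empty week -> model map")
    X_unknown = np.atleast_2d(np.asarray(X_unknown, dtype=float))
    table = {
        int(week): float(abs(np.median(np.asarray(model.predict(X_unknown))) - true_concentration))
        for week, model in models.items()
    }
    best_week = min(sorted(table), key=lambda w: table[w])
    return best_week, table
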