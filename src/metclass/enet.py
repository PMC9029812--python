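r"""Weighted logistic elastic net with lambda selection by cross-validated
deviance.

The fitted criterion is

    min_{b0, b}  -(1/n) sum_i w_i [ y_i (b0 + x_i'b) - log(1 + e^{b0 + x_i'b}) ]
                 + lambda * sum_j pf_j [ (1-alpha) b_j^2 / 2 + alpha |b_j| ]

with observation weights w_i normalized to sum to n (inverse class
proportions by default, so each class carries equal total weight), mixing
parameter alpha in [0, 1] (0.5 by default: variable selection without a
hard cap on the number of selected variables), and optional per-feature
penalty multipliers pf_j (0 leaves a covariate such as age or sex
unpenalized).  The intercept is never penalized.  The solver is a
penalized-IRLS coordinate descent with warm starts along a descending
lambda path; solutions satisfy the KKT conditions of the criterion to the
requested tolerance.

lambda is chosen as the arg-min of mean held-out binomial deviance over
leave-one-out (or k-fold) cross-validation, with ties broken toward the
larger (sparser) lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import cd_logistic_path

__all__ = [
    "EnetModel", "ORRecord", "class_weights", "lambda_path", "fit_enet",
    "fit_enet_path", "enet_objective", "select_lambda", "kkt_residuals",
    "consensus_odds_ratios",
]


@dataclass
class EnetModel:
    """A fitted weighted logistic elastic net."""

    beta0: float
    beta: np.ndarray
    alpha: float
    lam: float
    weights: np.ndarray
    n: int
    p: int
    penalty_factor: np.ndarray | None = None

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.beta != 0.0)

    def decision_function(self, X) -> np.ndarray:
        return self.beta0 + np.asarray(X, dtype=float) @ self.beta

    def predict_proba(self, X) -> np.ndarray:
        eta = np.clip(self.decision_function(X), -30.0, 30.0)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class ORRecord:
    """Consensus odds ratio of one feature across the m imputation fits."""

    name: str
    odds_ratio: float
    low: float
    high: float
    retained_in_all: bool = True


def _check_Xy(X, y, weights):
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y dimensions disagree")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite inputs")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    if uniq.size < 2:
        raise ValueError("both classes must be present")
    if weights is None:
        weights = np.ones_like(y)
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.shape != y.shape or np.any(weights <= 0):
        raise ValueError("weights must be positive, one per observation")
    return X, y, weights


def class_weights(y) -> np.ndarray:
    """Inverse class-proportion weights, w_i = n / (2 * n_class(i)).

    The weights sum to n and each class's total weight is n/2, so the
    minority class is not swamped in the likelihood.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    n1 = float(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    w = np.where(y == 1.0, n / (2.0 * n1), n / (2.0 * n0))
    return w


def _base_fit(X, y, v, free_idx, max_iter=100, tol=1e-12):
    """Newton fit of the logistic model on unpenalized columns only."""
    n = y.size
    Z = np.column_stack([np.ones(n)] + [X[:, j] for j in free_idx])
    coef = np.zeros(Z.shape[1])
    for _ in range(max_iter):
        eta = np.clip(Z @ coef, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        g = Z.T @ (v * (y - p))
        W = v * p * (1 - p)
        H = (Z * W[:, None]).T @ Z + 1e-12 * np.eye(Z.shape[1])
        step = np.linalg.solve(H, g)
        coef += step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(Z @ coef, -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


def lambda_path(X, y, weights=None, alpha=0.5, n_lambda=100, ratio=1e-3,
                penalty_factor=None) -> np.ndarray:
    """Descending log-spaced lambda grid from lambda_max to lambda_max*ratio.

    lambda_max is the smallest penalty with an all-zero (penalized)
    solution: max_j |sum_i v_i x_ij (y_i - p_i)| / (alpha * pf_j), with
    p_i from the null model containing only the intercept and any
    unpenalized covariates.
    """
    X, y, weights = _check_Xy(X, y, weights)
    if alpha <= 0:
        raise ValueError("alpha must be positive for a lambda path; supply "
                         "an explicit grid when alpha = 0")
    p = X.shape[1]
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    v = weights / weights.sum()
    free = np.flatnonzero(pf == 0.0)
    if free.size:
        pnull = _base_fit(X, y, v, free)
    else:
        pnull = np.full(y.size, float(np.sum(v * y)))
    grad = X.T @ (v * (y - pnull))
    pen = pf > 0
    lam_max = float(np.max(np.abs(grad[pen]) / (alpha * pf[pen])))
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def fit_enet_path(X, y, weights=None, alpha=0.5, lambdas=None,
                  penalty_factor=None, tol=1e-9, max_outer=50, max_inner=1000):
    """Warm-started solutions along a descending lambda grid.

    Returns (betas [L, p], beta0s [L], lambdas).
    """
    X, y, weights = _check_Xy(X, y, weights)
    p = X.shape[1]
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    if lambdas is None:
        lambdas = lambda_path(X, y, weights, alpha, penalty_factor=pf)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be non-increasing")
    v = weights / weights.sum()
    Xt = np.ascontiguousarray(X.T)
    betas, beta0s = cd_logistic_path(
        Xt, y, v, float(alpha), lambdas, pf, float(tol), max_outer, max_inner
    )
    return betas, beta0s, lambdas


def fit_enet(X, y, weights=None, alpha=0.5, lam=None, penalty_factor=None,
             tol=1e-14, n_warm=15) -> EnetModel:
    """Fit the weighted logistic elastic net at a single lambda.

    Internally continues a short warm-start path from lambda_max down to
    ``lam`` for reliable convergence.  ``y`` must contain both classes.
    """
    X, y, weights = _check_Xy(X, y, weights)
    if lam is None:
        raise ValueError("lam is required")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    p = X.shape[1]
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    a = max(alpha, 1e-3)
    lam_max = lambda_path(X, y, weights, a, n_lambda=2, penalty_factor=pf)[0]
    if lam >= lam_max or lam == 0.0:
        grid = np.array([max(lam, 1e-12)])
        if lam == 0.0:
            grid = np.geomspace(lam_max, max(lam_max * 1e-4, 1e-12), n_warm)
            grid = np.append(grid, 0.0)
    else:
        grid = np.geomspace(lam_max, lam, n_warm)
        grid[-1] = lam
    betas, beta0s, _ = fit_enet_path(
        X, y, weights, alpha, grid, pf, tol=tol, max_outer=100
    )
    return EnetModel(
        beta0=float(beta0s[-1]), beta=betas[-1].copy(), alpha=float(alpha),
        lam=float(lam), weights=weights, n=X.shape[0], p=p,
        penalty_factor=pf,
    )


def enet_objective(model: EnetModel, X, y) -> float:
    """Evaluate the penalized criterion at the model's coefficients."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite inputs")
    w = model.weights
    v = w / w.sum()
    eta = model.beta0 + X @ model.beta
    nll = -float(np.sum(v * (y * eta - np.logaddexp(0.0, eta))))
    pf = (np.ones(model.p) if model.penalty_factor is None
          else model.penalty_factor)
    pen = model.lam * float(np.sum(pf * ((1 - model.alpha) * model.beta ** 2 / 2
                                         + model.alpha * np.abs(model.beta))))
    return nll + pen


def kkt_residuals(model: EnetModel, X, y) -> np.ndarray:
    """Per-feature KKT residuals of the criterion at the fitted solution.

    Active features: |grad_j + lam*(1-alpha)*pf_j*beta_j +
    lam*alpha*pf_j*sign(beta_j)|; inactive: max(0, |grad_j| -
    lam*alpha*pf_j).  The intercept residual is appended last.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    v = model.weights / model.weights.sum()
    p_hat = model.predict_proba(X)
    grad = -X.T @ (v * (y - p_hat))
    pf = (np.ones(model.p) if model.penalty_factor is None
          else model.penalty_factor)
    res = np.empty(model.p + 1)
    for j in range(model.p):
        bj = model.beta[j]
        if bj != 0.0:
            res[j] = abs(grad[j] + model.lam * (1 - model.alpha) * pf[j] * bj
                         + model.lam * model.alpha * pf[j] * np.sign(bj))
        else:
            res[j] = max(0.0, abs(grad[j]) - model.lam * model.alpha * pf[j])
    res[model.p] = abs(np.sum(v * (y - p_hat)))
    return res


def _binomial_deviance(y, p) -> np.ndarray:
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return -2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p))


@dataclass
class LambdaSelection:
    lam: float
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    index: int


def select_lambda(X, y, weights=None, alpha=0.5, cv="loo", n_lambda=100,
                  ratio=1e-3, penalty_factor=None, seed=0,
                  tol=1e-8) -> LambdaSelection:
    """Pick lambda minimizing cross-validated held-out binomial deviance.

    ``cv`` is "loo" for exact leave-one-out or an integer k for k-fold
    (stratified, shuffled with ``seed``).  Deviances are weighted by the
    observation weights.  Ties break toward the larger lambda.
    """
    X, y, weights = _check_Xy(X, y, weights)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 observations to select lambda")
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    lambdas = lambda_path(X, y, weights, alpha, n_lambda, ratio, pf)
    if cv == "loo":
        folds = np.arange(n)
    else:
        k = int(cv)
        rng = np.random.default_rng(seed)
        folds = np.empty(n, dtype=int)
        for cls in (0.0, 1.0):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            folds[idx] = np.arange(idx.size) % k
    dev_sum = np.zeros(lambdas.size)
    w_sum = 0.0
    for f in np.unique(folds):
        te = folds == f
        tr = ~te
        if np.unique(y[tr]).size < 2:
            warnings.warn("skipping CV fold with single-class training labels")
            continue
        betas, beta0s, _ = fit_enet_path(
            X[tr], y[tr], weights[tr], alpha, lambdas, pf, tol=tol,
            max_outer=25,
        )
        eta = np.clip(beta0s[None, :] + X[te] @ betas.T, -30, 30)  # (nte, L)
        prob = 1.0 / (1.0 + np.exp(-eta))
        dev = _binomial_deviance(y[te][:, None], prob)
        dev_sum += (weights[te][:, None] * dev).sum(axis=0)
        w_sum += weights[te].sum()
    if w_sum == 0:
        raise ValueError("no usable CV folds")
    mean_dev = dev_sum / w_sum
    idx = int(np.argmin(mean_dev))  # first occurrence = largest lambda
    return LambdaSelection(float(lambdas[idx]), lambdas, mean_dev, idx)


def consensus_odds_ratios(fits, feature_names, or_low=0.9, or_high=1.1):
    """Consensus odds ratios across the m imputation fits.

    A feature is reported only if its coefficient is nonzero in every fit
    and its consensus OR (exp of the mean coefficient, per 1-SD increase)
    lies outside [or_low, or_high].  The interval is exp(mean +- 2*SD)
    across fits; records are sorted by |log OR| descending.
    """
    if len(fits) == 0:
        raise ValueError("no fits supplied")
    B = np.vstack([f.beta for f in fits])  # (m, p)
    m, p = B.shape
    if len(feature_names) != p:
        raise ValueError("feature_names length mismatch")
    if m < 2:
        warnings.warn("fewer than 2 fits: reporting point ORs only")
    records = []
    for j in range(p):
        bj = B[:, j]
        if np.any(bj == 0.0):
            continue
        mean_b = float(bj.mean())
        orr = float(np.exp(mean_b))
        if or_low <= orr <= or_high:
            continue
        if m >= 2:
            sd = float(bj.std(ddof=1))
            low, high = float(np.exp(mean_b - 2 * sd)), float(np.exp(mean_b + 2 * sd))
        else:
            low = high = orr
        records.append(ORRecord(str(feature_names[j]), orr, low, high, True))
    records.sort(key=lambda r: abs(np.log(r.odds_ratio)), reverse=True)
    return records


def split_or_tables(records):
    """Split consensus ORs into positive (>1) and negative (<1) tables."""
    pos = [r for r in records if r.odds_ratio > 1.0]
    neg = [r for r in records if r.odds_ratio < 1.0]
    return pos, neg
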