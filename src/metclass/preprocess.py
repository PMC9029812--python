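"""Detrending, outlier masking, filtering, standardization, PCA.

The canonical preprocessing order for a training matrix is
``detrend -> standardize -> mad_mask -> filter_features`` with imputation
downstream; masks only ever grow until imputation.  Detrending regresses
each feature on run index, age, and sex with gradient-boosted trees so
nonlinear and discontinuous run-order drift is removed along with the
known age/sex associations; it never sees phenotype labels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb
from sklearn.decomposition import PCA

from .containers import FeatureMatrix

# small fixed hyperparameter grid searched per feature by k-fold CV; the
# lowest-capacity corner still carries a total shrinkage budget
# (rounds x learning rate) of 5, enough to represent strong drift
DEFAULT_GRID = tuple(
    {"max_depth": d, "n_rounds": r, "learning_rate": lr}
    for d in (2, 3) for r in (50, 200) for lr in (0.1, 0.3)
)


def mad_mask(matrix: FeatureMatrix, k: float = 3.0, scale: float = 1.0) -> FeatureMatrix:
    """Mask per-feature outliers beyond ``k`` median absolute deviations.

    Uses the unscaled MAD (no 1.4826 normal-consistency factor) by default;
    pass ``scale=1.4826`` for the consistent convention.  When the MAD of a
    feature is zero but the data are not constant, nothing is masked and a
    warning is issued (the threshold is degenerate).
    """
    out = matrix.copy()
    if not np.isfinite(k):
        return out
    for j in range(out.n_features):
        obs = out.mask[:, j]
        x = out.values[obs, j]
        if x.size < 3:
            continue
        med = np.median(x)
        mad = np.median(np.abs(x - med)) * scale
        if mad == 0.0:
            if np.ptp(x) > 0:
                warnings.warn(
                    f"feature {out.feature_ids[j]}: MAD is zero with "
                    "non-constant data; no outliers masked"
                )
            continue
        bad = np.abs(out.values[:, j] - med) > k * mad
        bad &= obs
        out.mask[bad, j] = False
    out.values = np.where(out.mask, out.values, np.nan)
    return out


def mad_bounds(matrix: FeatureMatrix, k: float = 3.0, scale: float = 1.0):
    """Per-feature (low, high) acceptance bounds implied by :func:`mad_mask`."""
    lo = np.full(matrix.n_features, -np.inf)
    hi = np.full(matrix.n_features, np.inf)
    for j in range(matrix.n_features):
        x = matrix.values[matrix.mask[:, j], j]
        if x.size < 3:
            continue
        med = np.median(x)
        mad = np.median(np.abs(x - med)) * scale
        if mad > 0 and np.isfinite(k):
            lo[j] = med - k * mad
            hi[j] = med + k * mad
    return lo, hi


def filter_features(matrix: FeatureMatrix, max_missing_frac: float = 0.5) -> FeatureMatrix:
    """Drop features with missing fraction strictly above the threshold.

    A feature missing in exactly half the subjects survives the default
    cut ("more than 50%" is the removal rule).
    """
    frac = matrix.missing_fraction(axis=0)
    keep = np.flatnonzero(frac <= max_missing_frac)
    if keep.size == 0:
        raise ValueError("missingness filter removed every feature")
    return matrix.select_features(keep)


@dataclass
class Scaler:
    """Per-feature centering/scaling constants fit on observed entries."""

    mean: np.ndarray
    std: np.ndarray  # sample SD (ddof=1)
    feature_ids: list[str]

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.std


def standardize(matrix: FeatureMatrix, return_scaler: bool = False):
    """Center and scale each feature to observed-entry mean 0, variance 1.

    Zero-variance features are dropped with a warning.  The fitted
    constants are returned (``return_scaler=True``) so held-out rows can be
    transformed with the training constants.
    """
    n, p = matrix.values.shape
    mean = np.zeros(p)
    std = np.zeros(p)
    for j in range(p):
        x = matrix.values[matrix.mask[:, j], j]
        if x.size >= 2:
            mean[j] = x.mean()
            std[j] = x.std(ddof=1)
        elif x.size == 1:
            mean[j] = x[0]
    keep = np.flatnonzero(std > 0)
    if keep.size < p:
        warnings.warn(f"dropping {p - keep.size} zero-variance feature(s)")
    sub = matrix.select_features(keep)
    mean, std = mean[keep], std[keep]
    out = sub.copy()
    out.values = np.where(out.mask, (out.values - mean) / std, np.nan)
    scaler = Scaler(mean, std, list(sub.feature_ids))
    return (out, scaler) if return_scaler else out


@dataclass
class DetrendModel:
    """Per-feature drift/covariate models (run index, age, sex -> abundance)."""

    boosters: list  # xgboost Booster, or ("mean", value) fallback
    params: list[dict]
    feature_ids: list[str]
    covariate_names: tuple = ("run_index", "age", "sex")

    def predict(self, covariates: np.ndarray) -> np.ndarray:
        """Fitted values at the given covariates, subjects x features."""
        n = covariates.shape[0]
        fitted = np.zeros((n, len(self.boosters)))
        dm = None
        for j, booster in enumerate(self.boosters):
            if isinstance(booster, tuple):
                fitted[:, j] = booster[1]
            else:
                if dm is None:
                    dm = xgb.DMatrix(covariates)
                fitted[:, j] = booster.predict(dm)
        return fitted

    def to_json(self, path) -> None:
        payload = {
            "version": 1,
            "covariates": list(self.covariate_names),
            "feature_ids": self.feature_ids,
            "params": self.params,
            "models": [
                {"kind": "mean", "value": b[1]} if isinstance(b, tuple)
                else {"kind": "xgboost",
                      "raw": b.save_raw("json").decode()}
                for b in self.boosters
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _cv_rmse(X, y, params: dict, folds: np.ndarray) -> float:
    err = 0.0
    for f in np.unique(folds):
        tr = folds != f
        te = ~tr
        booster = _fit_booster(X[tr], y[tr], params)
        pred = booster.predict(xgb.DMatrix(X[te]))
        err += float(np.sum((y[te] - pred) ** 2))
    return err


def _fit_booster(X, y, params: dict):
    dtrain = xgb.DMatrix(X, label=y)
    return xgb.train(
        {
            "max_depth": params["max_depth"],
            "eta": params["learning_rate"],
            "objective": "reg:squarederror",
            "tree_method": "exact",
            "nthread": 1,
            "base_score": float(np.mean(y)),
        },
        dtrain,
        num_boost_round=params["n_rounds"],
    )


def detrend(
    matrix: FeatureMatrix,
    covariates,
    cv_folds: int = 5,
    grid=DEFAULT_GRID,
    min_obs: int = 10,
    seed: int = 0,
) -> tuple[FeatureMatrix, DetrendModel]:
    """Remove run-order drift and age/sex trends feature by feature.

    ``covariates`` is an (n, 3) array-like of (run_index, age, sex01) per
    subject; sex is encoded F=0, M=1.  Hyperparameters are chosen per
    feature by ``cv_folds``-fold CV over a small fixed grid; features with
    fewer than ``min_obs`` observed values fall back to a mean-only
    detrend with a warning.  Residuals are computed only at observed
    entries and the mask is unchanged.
    """
    C = np.asarray(covariates, dtype=float)
    if C.shape[0] != matrix.n_subjects:
        raise ValueError("covariate rows do not match subjects")
    if np.isnan(C).any():
        raise ValueError("covariates must be complete")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    boosters, chosen = [], []
    for j in range(matrix.n_features):
        obs = matrix.mask[:, j]
        y = matrix.values[obs, j]
        if y.size < min_obs:
            warnings.warn(
                f"feature {matrix.feature_ids[j]}: <{min_obs} observed values;"
                " mean-only detrend"
            )
            mu = float(y.mean()) if y.size else 0.0
            boosters.append(("mean", mu))
            chosen.append({"fallback": "mean"})
            out.values[obs, j] = y - mu
            continue
        if np.ptp(y) == 0.0:
            boosters.append(("mean", float(y[0])))
            chosen.append({"fallback": "constant"})
            out.values[obs, j] = 0.0
            continue
        Xo = C[obs]
        folds = rng.permutation(y.size) % cv_folds
        best, best_err = None, np.inf
        for params in grid:
            err = _cv_rmse(Xo, y, params, folds)
            if err < best_err:
                best, best_err = params, err
        booster = _fit_booster(Xo, y, best)
        fitted = booster.predict(xgb.DMatrix(Xo))
        out.values[obs, j] = y - fitted
        boosters.append(booster)
        chosen.append(dict(best))
    out.values = np.where(out.mask, out.values, np.nan)
    model = DetrendModel(boosters, chosen, list(matrix.feature_ids))
    return out, model


def pca_project(matrix: FeatureMatrix, k: int = 2, fill: str = "error"):
    """Project onto the first ``k`` principal components (centered PCA).

    Requires a complete matrix; ``fill="mean"`` mean-fills missing entries
    first (the pre-imputation convention for a quick look at the data).
    Returns (scores, fraction of variance per PC).
    """
    X = matrix.values
    if not matrix.mask.all():
        if fill == "mean":
            col_mean = np.nanmean(X, axis=0)
            X = np.where(matrix.mask, X, col_mean[None, :])
        else:
            raise ValueError("matrix has missing entries; run after imputation "
                             "or pass fill='mean'")
    n, p = X.shape
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n, p)={min(n, p)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_.copy()
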