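"""Classification from presence/absence patterns.

When missingness is informative (for example phenotype-dependent
censoring of low-abundance metabolites), the binary pattern of which
features were detected can itself separate phenotypes.  This module
replaces abundances with 1 (present) / 0 (missing), runs the same
leave-one-out elastic-net machinery on the indicator matrix with age and
sex entering unpenalized, and provides per-feature univariate logistic
scans of missingness on phenotype with Benjamini-Hochberg correction.

Indicators are taken from the mask after MAD outlier masking but before
the 50%-missingness filter (profiles with extreme missingness are exactly
the ones whose presence patterns carry signal).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import enet as _enet
from .containers import FeatureMatrix
from .enrich import bh_adjust


@dataclass
class IndicatorMatrix:
    """Subjects x features binary (1 = observed) matrix; complete by
    construction."""

    values: np.ndarray
    subject_ids: list[str]
    feature_ids: list[str]
    dropped_constant: list[str]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def indicator_matrix(matrix: FeatureMatrix) -> IndicatorMatrix:
    """Presence/absence indicators from a raw (pre-imputation) mask.

    Constant columns (all-present or all-missing) carry no contrast and
    are dropped with a warning.
    """
    ind = matrix.mask.astype(float)
    keep = []
    dropped = []
    for j in range(matrix.n_features):
        if 0.0 < ind[:, j].mean() < 1.0:
            keep.append(j)
        else:
            dropped.append(matrix.feature_ids[j])
    if dropped:
        warnings.warn(f"dropped {len(dropped)} constant indicator column(s)")
    keep = np.asarray(keep, dtype=int)
    return IndicatorMatrix(
        ind[:, keep] if keep.size else np.empty((matrix.n_subjects, 0)),
        list(matrix.subject_ids),
        [matrix.feature_ids[j] for j in keep],
        dropped,
    )


def missingness_enet(indicators: IndicatorMatrix, labels, age, sex01,
                     alpha: float = 0.5, inner_cv=10, n_lambda: int = 100,
                     seed: int = 0):
    """LOO elastic net on missingness indicators plus unpenalized age/sex.

    Indicators are standardized like any feature (so the reported ORs are
    per standard-deviation increase of the indicator); age and sex carry a
    zero penalty factor and are therefore always in the model.  Returns
    (EvalResult, list of ORRecord from the full-data fit).
    """
    from .evaluate import _summarize, roc_auc  # local import avoids a cycle

    if indicators.n_features == 0:
        raise ValueError("indicator matrix is empty")
    y = np.asarray(labels, dtype=float).ravel()
    n = y.size
    base = np.column_stack([
        indicators.values,
        np.asarray(age, dtype=float),
        np.asarray(sex01, dtype=float),
    ])
    p_ind = indicators.n_features
    pf = np.ones(p_ind + 2)
    pf[-2:] = 0.0
    scores = np.empty((n, 1))
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xtr = base[tr]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (Xtr - mu) / sd
        xte = (base[i] - mu) / sd
        w = _enet.class_weights(y[tr])
        # per-fold inner-CV partition (see evaluate.loo_evaluate): a fixed
        # partition couples with the held-out class and biases the null
        fold_seed = (seed * 100003 + zlib.crc32(
            str(indicators.subject_ids[i]).encode())) % (2 ** 31)
        sel = _enet.select_lambda(Xs, y[tr], w, alpha, cv=inner_cv,
                                  n_lambda=n_lambda, penalty_factor=pf,
                                  seed=fold_seed)
        model = _enet.fit_enet(Xs, y[tr], w, alpha, sel.lam,
                               penalty_factor=pf, tol=1e-10)
        scores[i, 0] = model.predict_proba(xte[None, :])[0]
    result = _summarize(scores, y, indicators.subject_ids)

    # full-data fit for the OR table (single fit: indicators are complete,
    # so there is no imputation spread and the interval collapses)
    mu = base.mean(axis=0)
    sd = np.where(base.std(axis=0, ddof=1) > 0, base.std(axis=0, ddof=1), 1.0)
    Xs = (base - mu) / sd
    w = _enet.class_weights(y)
    sel = _enet.select_lambda(Xs, y, w, alpha, cv=inner_cv,
                              n_lambda=n_lambda, penalty_factor=pf, seed=seed)
    model = _enet.fit_enet(Xs, y, w, alpha, sel.lam, penalty_factor=pf,
                           tol=1e-10)
    names = list(indicators.feature_ids) + ["age", "sex_male"]
    ors = _enet.consensus_odds_ratios([model], names)
    # the unpenalized covariates always appear, whatever their OR
    reported = {r.name for r in ors}
    for covname in ("age", "sex_male"):
        if covname not in reported:
            j = names.index(covname)
            orr = float(np.exp(model.beta[j]))
            ors.append(_enet.ORRecord(covname, orr, orr, orr, True))
    return result, ors


def _logit_fit(X, y, ridge=0.0):
    """IRLS logistic fit returning (coef, standard errors, converged)."""
    n, q = X.shape
    Z = np.column_stack([np.ones(n), X])
    coef = np.zeros(q + 1)
    for _ in range(100):
        eta = np.clip(Z @ coef, -30, 30)
        p = 1 / (1 + np.exp(-eta))
        Wd = p * (1 - p)
        H = (Z * Wd[:, None]).T @ Z + ridge * np.eye(q + 1)
        g = Z.T @ (y - p) - ridge * coef
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return coef, np.full(q + 1, np.nan), False
        coef += step
        if np.max(np.abs(step)) < 1e-10:
            cov = np.linalg.inv(H)
            return coef, np.sqrt(np.diag(cov)), True
    return coef, np.full(q + 1, np.nan), False


def univariate_missingness_scan(indicators: IndicatorMatrix, labels,
                                covariates=None,
                                ridge_fallback: float = 1e-2) -> pd.DataFrame:
    """Per-feature logistic regression of the indicator on phenotype.

    The outcome is the presence indicator and the predictor the binary
    phenotype contrast (plus optional age/sex columns); q-values are
    Benjamini-Hochberg adjusted across testable features.  Features with
    separation are refit with a small ridge and flagged.
    """
    y_pheno = np.asarray(labels, dtype=float).ravel()
    C = None if covariates is None else np.asarray(covariates, dtype=float)
    rows = []
    for j in range(indicators.n_features):
        out = indicators.values[:, j]
        if out.min() == out.max():
            rows.append({"feature_id": indicators.feature_ids[j],
                         "coef": np.nan, "p": np.nan, "testable": False,
                         "flagged": False})
            continue
        X = y_pheno[:, None] if C is None else np.column_stack([y_pheno, C])
        coef, se, ok = _logit_fit(X, out)
        flagged = False
        if not ok or not np.isfinite(se[1]) or np.abs(coef[1]) > 15:
            coef, se, ok = _logit_fit(X, out, ridge=ridge_fallback)
            flagged = True
        z = coef[1] / se[1] if se[1] > 0 else np.nan
        from scipy.stats import norm
        p = 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"feature_id": indicators.feature_ids[j],
                     "coef": float(coef[1]), "p": float(p),
                     "testable": True, "flagged": flagged})
    df = pd.DataFrame(rows)
    q = np.full(len(df), np.nan)
    testable = df["testable"].to_numpy() & np.isfinite(df["p"].to_numpy())
    if testable.any():
        q[testable] = bh_adjust(df.loc[testable, "p"].to_numpy())
    df["q"] = q
    df["significant"] = df["q"] < 0.05
    return df
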