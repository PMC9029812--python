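"""Multiple imputation of missing abundances.

Missing entries are modeled as multivariate normal and imputed with an
EM-with-bootstrap scheme: each of the m copies bootstraps the training
rows, fits (mu, Sigma) by EM with a ridge prior toward the identity
(abundances are standardized upstream), and then draws the missing
entries of the original training rows from their conditional normal
distribution.  When the feature count exceeds ``block_threshold`` the
features are imputed in blocks against the leading principal components
of the complete-feature set (or of the mean-filled matrix when no feature
is complete), which keeps the covariance estimation problem well below
the sample size.

Imputation is always fit on training rows only; the pipeline never
imputes a held-out observation (see :func:`apply_to_newrow`), predicting
it instead through reduced-feature modeling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kernels import conditional_impute, em_mvn
from .containers import ContractError, FeatureMatrix

DEFAULTS = dict(
    m=5, ridge_frac=0.005, block_size=50, n_pcs=20, block_threshold=200,
    tol=1e-4, max_iter=200,
)


@dataclass
class ImputationSet:
    """m completed copies of a feature matrix from one imputation fit."""

    m: int
    completed: list  # list of (n, p) arrays
    fit_rows: list[str]
    feature_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        import pandas as pd
        for j, arr in enumerate(self.completed):
            pd.DataFrame(arr, index=self.fit_rows, columns=self.feature_ids) \
                .to_csv(outdir / f"imputation_{j+1}.csv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump({"m": self.m, "fit_rows": self.fit_rows,
                       "metadata": self.metadata}, fh)


def _pc_anchor(values, mask, n_pcs):
    """Complete anchor columns: PCs of complete features, or of the
    mean-filled matrix when too few features are complete."""
    n, p = values.shape
    n_pcs = min(n_pcs, max(n - 2, 1), p)
    complete = np.flatnonzero(mask.all(axis=0))
    if complete.size >= max(n_pcs, 5):
        Xc = values[:, complete]
        source = "complete-features"
    else:
        col_mean = np.where(mask, values, np.nan)
        mu = np.nanmean(col_mean, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        Xc = np.where(mask, values, mu[None, :])
        source = "mean-filled"
    Xc = Xc - Xc.mean(axis=0)
    # thin SVD; scores scaled to unit variance so they sit on the same
    # scale as the standardized features
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_pcs, int(np.sum(s > 1e-8)))
    if k == 0:
        return np.zeros((n, 0)), source
    scores = U[:, :k] * np.sqrt(n - 1)
    return scores, source


def _moment_init(X0, mask):
    cnt = np.maximum(mask.sum(axis=0), 1)
    mu0 = (X0 * mask).sum(axis=0) / cnt
    var0 = ((X0 - mu0) ** 2 * mask).sum(axis=0) / np.maximum(cnt - 1, 1)
    return mu0, np.diag(np.maximum(var0, 1e-3))


def _em_impute_once(values, mask, rng, ridge_frac, tol, max_iter,
                    init=None, add_noise=True):
    """One bootstrap-EM fit plus conditional draw for one feature block.

    ``init`` optionally warm-starts EM (e.g. from a base fit on the
    original rows); the fixed point sought is unchanged, only the number
    of iterations drops.
    """
    n, d = values.shape
    boot = rng.integers(0, n, size=n)
    X0 = np.where(mask, values, 0.0)
    Xb = X0[boot]
    obs_b = mask[boot]
    if init is None:
        mu0, sigma0 = _moment_init(Xb, obs_b)
    else:
        mu0, sigma0 = init[0].copy(), init[1].copy()
    ridge_n = ridge_frac * n
    mu, sigma, ll, n_iter, converged = em_mvn(
        Xb, obs_b, mu0, sigma0, float(ridge_n), float(tol), int(max_iter)
    )
    if not converged:
        warnings.warn("EM did not converge; falling back to conditional-mean "
                      "imputation for this copy")
        add_noise = False
    Z = rng.standard_normal((n, d))
    return conditional_impute(X0, mask, mu, sigma, Z, add_noise), n_iter, converged


def multiple_impute(matrix: FeatureMatrix, m: int = 5, seed: int = 0,
                    ridge_frac: float = 0.005, block_size: int = 50,
                    n_pcs: int = 20, block_threshold: int = 200,
                    tol: float = 1e-4, max_iter: int = 200) -> ImputationSet:
    """Produce m completed copies of ``matrix`` (fit on its rows only).

    Copy j uses seed + j so each copy is independently reproducible.
    Observed entries are identical across copies and equal to the input.
    """
    frac = matrix.missing_fraction(axis=0)
    if np.any(frac > 0.5):
        raise ValueError("features with >50% missingness must be filtered "
                         "before imputation")
    n, p = matrix.values.shape
    completed = []
    meta = dict(seed=seed, ridge_frac=ridge_frac, block_size=block_size,
                n_pcs=n_pcs, block_threshold=block_threshold, tol=tol,
                max_iter=max_iter, blocked=bool(p > block_threshold))
    if matrix.mask.all():
        completed = [matrix.values.copy() for _ in range(m)]
        return ImputationSet(m, completed, list(matrix.subject_ids),
                             list(matrix.feature_ids), meta)

    if p > block_threshold:
        anchor, source = _pc_anchor(matrix.values, matrix.mask, n_pcs)
        meta["pc_anchor"] = source
        blocks = [np.arange(s, min(s + block_size, p))
                  for s in range(0, p, block_size)]
    else:
        anchor = np.zeros((n, 0))
        blocks = [np.arange(p)]

    # copy j draws from its own generator seeded seed + j; blocks are
    # visited in a fixed order so each copy is independently reproducible
    rngs = [np.random.default_rng(seed + j) for j in range(m)]
    outs = [matrix.values.copy() for _ in range(m)]
    for blk in blocks:
        vb = np.concatenate([
            np.where(matrix.mask[:, blk], matrix.values[:, blk], 0.0),
            anchor,
        ], axis=1)
        mb = np.concatenate([
            matrix.mask[:, blk],
            np.ones((n, anchor.shape[1]), dtype=bool),
        ], axis=1)
        if mb.all():
            continue
        for j in range(m):
            filled, n_iter, conv = _em_impute_once(
                vb, mb, rngs[j], ridge_frac, tol, max_iter,
            )
            outs[j][:, blk] = filled[:, : blk.size]
    completed = [np.where(matrix.mask, matrix.values, o) for o in outs]
    return ImputationSet(m, completed, list(matrix.subject_ids),
                         list(matrix.feature_ids), meta)


def mean_impute(matrix: FeatureMatrix) -> np.ndarray:
    """Reference completion: fill each feature with its observed mean."""
    mu = np.nanmean(np.where(matrix.mask, matrix.values, np.nan), axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    return np.where(matrix.mask, matrix.values, mu[None, :])


def apply_to_newrow(*args, **kwargs):
    """Intentionally unsupported: held-out rows are never imputed.

    Prediction for a row with missing features goes through
    reduced-feature modeling (:func:`metclass.evaluate.reduced_feature_predict`)
    instead, so calling this is a pipeline contract violation.
    """
    raise ContractError(
        "imputing a held-out row is a contract violation; use "
        "reduced-feature prediction instead"
    )
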