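"""Leave-one-out evaluation with fold-internal imputation.

For every subject the full preprocessing-and-modeling chain is refit on
the remaining subjects: (optional) drift/covariate detrend, training-set
standardization, MAD outlier masking, the >50%-missingness filter, m-fold
multiple imputation, per-copy lambda selection and elastic-net fit, and a
reduced-feature prediction for the held-out subject.  Held-out rows are
never imputed: features the test subject is missing are either dropped
from a refit of the fold's model ("refit", the default) or have their
coefficients zeroed ("drop", equivalent to mean substitution after
standardization).

Imputation copy j is aligned across folds, so pooling the out-of-fold
scores of copy j over subjects gives ROC curve j; the summary AUC is the
arithmetic mean of the m per-copy AUCs.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import enet as _enet
from . import impute as _impute
from . import preprocess as _pre
from .containers import FeatureMatrix


@dataclass
class EvalConfig:
    """Stage parameters of one leave-one-out evaluation run."""

    alpha: float = 0.5
    m: int = 5
    inner_cv: int | str = 10        # k, or "loo" for exact inner LOO
    n_lambda: int = 100
    lambda_ratio: float = 1e-3
    reduced_strategy: str = "refit"  # or "drop"
    mad_k: float = 3.0
    max_missing_frac: float = 0.5
    detrend: bool = False
    detrend_cv_folds: int = 5
    impute_kwargs: dict = field(default_factory=dict)
    penalize_covariates: bool = True
    seed: int = 0


@dataclass
class EvalResult:
    """Per-subject out-of-fold scores and ROC/AUC summaries."""

    scores: np.ndarray          # (n, m) out-of-fold probabilities
    labels: np.ndarray          # (n,) binary
    subject_ids: list[str]
    auc_per_imputation: np.ndarray
    auc_mean: float
    roc_curves: list            # per copy: (fpr, tpr, thresholds)

    @property
    def m(self) -> int:
        return self.scores.shape[1]


def roc_auc(scores, labels):
    """ROC points and AUC via the rank (Mann-Whitney) formulation.

    Ties contribute 1/2 through midranks.  Returns ((fpr, tpr,
    thresholds), auc).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = float(labels.sum())
    n_neg = float(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return (fpr, tpr, thr), float(auc)


def _summarize(scores, labels, subject_ids) -> EvalResult:
    # quantize at the solver's resolution: fold models are converged to
    # ~1e-8, and e.g. an empty model's weighted-prior prediction is 0.5
    # up to sign-carrying rounding dust that differs by which class lost
    # its member — ranking that dust would manufacture AUC out of nothing
    scores = np.round(np.asarray(scores, dtype=float), 8)
    m = scores.shape[1]
    aucs = np.empty(m)
    curves = []
    for j in range(m):
        curve, aucs[j] = roc_auc(scores[:, j], labels)
        curves.append(curve)
    return EvalResult(scores, np.asarray(labels, float), list(subject_ids),
                      aucs, float(aucs.mean()), curves)


def reduced_feature_predict(model, X_train, y_train, test_row, observed,
                            strategy="refit"):
    """Predict a test row with missing features from a fitted fold model.

    ``observed`` is the boolean observed-feature indicator of the test row
    (in the fold's feature space).  "refit" refits the elastic net at the
    fold's lambda on the training data restricted to the observed
    features; "drop" zeroes the coefficients of unobserved features in the
    already-fit model.  With no observed features the weighted class prior
    is returned with a warning.
    """
    if strategy not in ("refit", "drop"):
        raise ValueError(f"unknown reduced-feature strategy {strategy!r}")
    observed = np.asarray(observed, dtype=bool)
    x = np.asarray(test_row, dtype=float)
    if observed.sum() == 0:
        warnings.warn("test row has no observed features; returning the "
                      "weighted class prior")
        v = model.weights / model.weights.sum()
        return float(np.sum(v * y_train))
    if observed.all():
        return float(model.predict_proba(x[None, :])[0])
    if strategy == "drop":
        xz = np.where(observed, x, 0.0)
        return float(model.predict_proba(xz[None, :])[0])
    cols = np.flatnonzero(observed)
    pf = None if model.penalty_factor is None else model.penalty_factor[cols]
    sub = _enet.fit_enet(X_train[:, cols], y_train, model.weights,
                         model.alpha, model.lam, penalty_factor=pf,
                         tol=1e-10)
    return float(sub.predict_proba(x[cols][None, :])[0])


def _prepare_fold(train: FeatureMatrix, test_vals, test_mask, cfg: EvalConfig):
    """Training-only preprocessing; returns processed train + aligned test row."""
    train_std, scaler = _pre.standardize(train, return_scaler=True)
    keep_ids = {f: i for i, f in enumerate(train.feature_ids)}
    kept = np.array([keep_ids[f] for f in train_std.feature_ids])
    test_vals = scaler.transform(test_vals[kept])
    test_mask = test_mask[kept]
    masked = _pre.mad_mask(train_std, k=cfg.mad_k)
    # test-row entries outside the training MAD bounds are treated as
    # missing too (outliers are processing noise wherever they occur)
    lo, hi = _pre.mad_bounds(train_std, k=cfg.mad_k)
    test_mask = test_mask & ~((test_vals < lo) | (test_vals > hi))
    filt = _pre.filter_features(masked, cfg.max_missing_frac)
    pos = {f: i for i, f in enumerate(masked.feature_ids)}
    idx = np.array([pos[f] for f in filt.feature_ids])
    return filt, test_vals[idx], test_mask[idx]


def loo_evaluate(matrix: FeatureMatrix, labels, config: EvalConfig | None = None,
                 covariates=None) -> EvalResult:
    """Outer leave-one-out evaluation of the full pipeline.

    ``labels`` is the binary contrast vector (0/1 per subject).  When
    ``config.detrend`` is set, ``covariates`` must be the (n, 3) array of
    (run_index, age, sex01) used to refit the per-feature drift models on
    each fold's training rows.
    """
    cfg = config or EvalConfig()
    y = np.asarray(labels, dtype=float).ravel()
    n = matrix.n_subjects
    if y.size != n:
        raise ValueError("labels length mismatch")
    if n < 20:
        raise ValueError("need at least 20 subjects for LOO evaluation")
    if min((y == 0).sum(), (y == 1).sum()) < 5:
        raise ValueError("each class needs at least 5 subjects")
    scores = np.full((n, cfg.m), np.nan)
    all_idx = np.arange(n)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    for i in range(n):
        tr_idx = all_idx[all_idx != i]
        # canonical (subject-id) training order plus a per-subject fold
        # seed make the scores invariant to how the input rows are shuffled
        tr_idx = tr_idx[np.argsort([matrix.subject_ids[t] for t in tr_idx],
                                   kind="stable")]
        y_tr = y[tr_idx]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"class vanished in fold {i}")
        train = matrix.select_subjects(tr_idx)
        test_vals = matrix.values[i].copy()
        test_mask = matrix.mask[i].copy()
        fold_seed = (cfg.seed * 100003
                     + zlib.crc32(matrix.subject_ids[i].encode())) % (2 ** 31)
        if cfg.detrend:
            if cov is None:
                raise ValueError("detrend=True requires covariates")
            train, dmodel = _pre.detrend(
                train, cov[tr_idx], cv_folds=cfg.detrend_cv_folds,
                seed=cfg.seed + 7919,
            )
            fitted = dmodel.predict(cov[i:i + 1])[0]
            test_vals = test_vals - fitted
        train_p, x_te, m_te = _prepare_fold(train, test_vals, test_mask, cfg)
        weights = _enet.class_weights(y_tr)
        iset = _impute.multiple_impute(
            train_p, m=cfg.m, seed=fold_seed, **cfg.impute_kwargs,
        )
        complete_train = train_p.mask.all()
        model_cache = None
        for j in range(cfg.m):
            if complete_train and model_cache is not None:
                model = model_cache
            else:
                Xj = iset.completed[j]
                # the inner-CV partition is re-drawn per outer fold: a
                # partition shared across folds couples with which class
                # lost its member and biases the null (leakage-like shift)
                sel = _enet.select_lambda(
                    Xj, y_tr, weights, cfg.alpha, cv=cfg.inner_cv,
                    n_lambda=cfg.n_lambda, ratio=cfg.lambda_ratio,
                    seed=fold_seed + j,
                )
                model = _enet.fit_enet(Xj, y_tr, weights, cfg.alpha, sel.lam,
                                       tol=1e-10)
                model._X_train = Xj  # kept for reduced-feature refits
                if complete_train:
                    model_cache = model
            scores[i, j] = reduced_feature_predict(
                model, model._X_train, y_tr,
                np.where(m_te, x_te, 0.0), m_te, cfg.reduced_strategy,
            )
    return _summarize(scores, y, matrix.subject_ids)


def exclusion_rerun(matrix: FeatureMatrix, labels, excluded_features,
                    config: EvalConfig | None = None,
                    covariates=None) -> EvalResult:
    """Re-run the LOO evaluation after removing a prior fit's support."""
    excluded = list(excluded_features)
    sub = matrix.drop_features(excluded) if excluded else matrix.copy()
    return loo_evaluate(sub, labels, config, covariates)


def low_missingness_rerun(matrix: FeatureMatrix, labels,
                          max_missing_frac: float = 0.01,
                          config: EvalConfig | None = None,
                          covariates=None) -> EvalResult:
    """Keep only near-complete features (<= max_missing_frac missing) and
    re-run the LOO evaluation, to check how much of the signal rides on
    informative missingness."""
    filt = _pre.filter_features(matrix, max_missing_frac)
    return loo_evaluate(filt, labels, config, covariates)


def full_data_fits(matrix: FeatureMatrix, labels, config: EvalConfig | None = None):
    """Fit one elastic net per imputation copy on the full data.

    Mirrors the consensus odds-ratio analysis: preprocess once on all
    subjects, impute m copies, select lambda and fit per copy.  Returns
    (models, feature_ids).
    """
    cfg = config or EvalConfig()
    y = np.asarray(labels, dtype=float).ravel()
    std, _ = _pre.standardize(matrix, return_scaler=True)
    masked = _pre.mad_mask(std, k=cfg.mad_k)
    filt = _pre.filter_features(masked, cfg.max_missing_frac)
    weights = _enet.class_weights(y)
    iset = _impute.multiple_impute(filt, m=cfg.m, seed=cfg.seed,
                                   **cfg.impute_kwargs)
    models = []
    for j in range(cfg.m):
        Xj = iset.completed[j]
        sel = _enet.select_lambda(Xj, y, weights, cfg.alpha, cv=cfg.inner_cv,
                                  n_lambda=cfg.n_lambda,
                                  ratio=cfg.lambda_ratio, seed=cfg.seed + j)
        models.append(_enet.fit_enet(Xj, y, weights, cfg.alpha, sel.lam,
                                     tol=1e-10))
    return models, list(filt.feature_ids)


def covariate_baseline(age, sex01, labels) -> EvalResult:
    """LOO unpenalized logistic regression on (age, sex) only.

    The reference model quantifying how much separation demographics
    alone provide.
    """
    age = np.asarray(age, dtype=float)
    sex01 = np.asarray(sex01, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    n = y.size
    X = np.column_stack([age, sex01])
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    scores = np.empty((n, 1))
    idx = np.arange(n)
    from sklearn.linear_model import LogisticRegression
    for i in range(n):
        tr = idx != i
        clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
        clf.fit(X[tr], y[tr])
        scores[i, 0] = clf.predict_proba(X[i:i + 1])[0, 1]
    return _summarize(scores, y, [f"S{i+1:04d}" for i in range(n)])


def precision_recall_points(scores, labels):
    """Precision-recall curve from pooled out-of-fold scores (no refit)."""
    from sklearn.metrics import precision_recall_curve
    prec, rec, thr = precision_recall_curve(labels, scores)
    return prec, rec, thr
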