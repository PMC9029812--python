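"""Univariate scans, FDR correction, pathway-tool export, and
overrepresentation analysis.

Each feature is separately regressed against disease status (feature as
predictor, phenotype as outcome) so correlated metabolites each get a
chance to appear in their pathways.  Untargeted results are exported in
the 4-column tab-separated dialect pathway-activity tools consume (m/z,
retention time, p-value, t-score), one file per ion mode; targeted
results feed a hypergeometric overrepresentation analysis against
curated metabolite sets (GMT-format text).  A built-in drug-mass list
supports excluding features within a mass tolerance of levodopa,
entacapone, and their metabolites before re-analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm


@dataclass
class UnivariateResult:
    feature_id: str
    t_value: float   # Wald z of the phenotype coefficient
    p: float
    q: float = np.nan
    mz: float = np.nan
    rt: float = np.nan
    ion_mode: str = ""


@dataclass
class MetaboliteSet:
    name: str
    members: frozenset
    source: str = ""


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * M / j, capped at 1, returned in the
    original order.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    M = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * M / np.arange(1, M + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(M)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _wald_logistic(x, y, ridge=0.0):
    """Univariate logistic y ~ x; returns (z, p, converged)."""
    n = x.size
    Z = np.column_stack([np.ones(n), x])
    coef = np.zeros(2)
    for _ in range(100):
        eta = np.clip(Z @ coef, -30, 30)
        pr = 1 / (1 + np.exp(-eta))
        W = pr * (1 - pr)
        H = (Z * W[:, None]).T @ Z + ridge * np.eye(2)
        g = Z.T @ (y - pr) - ridge * coef
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return np.nan, np.nan, False
        coef += step
        if np.max(np.abs(step)) < 1e-10:
            se = np.sqrt(np.diag(np.linalg.inv(H)))
            z = coef[1] / se[1]
            return float(z), float(2 * norm.sf(abs(z))), True
    return np.nan, np.nan, False


def univariate_scan(matrix, labels, annotations=None,
                    adjust_within=("profile", "ion_mode")) -> list[UnivariateResult]:
    """Per-feature logistic regressions of phenotype on abundance.

    ``matrix`` is a (standardized) FeatureMatrix; per-feature complete
    cases are used.  BH adjustment is applied separately within each
    (profile, ion mode) stratum when annotations are supplied, matching
    how ionization modes are analyzed separately downstream.
    """
    y = np.asarray(labels, dtype=float).ravel()
    ann = None
    if annotations is not None:
        ann = {a.feature_id: a for a in annotations}
    results = []
    for j, fid in enumerate(matrix.feature_ids):
        obs = matrix.mask[:, j]
        x = matrix.values[obs, j]
        yy = y[obs]
        if x.size < 8 or np.ptp(x) == 0 or np.unique(yy).size < 2:
            warnings.warn(f"feature {fid} untestable; excluded from scan")
            continue
        z, p, ok = _wald_logistic(x, yy)
        if not ok or not np.isfinite(p) or abs(z) > 50:
            z, p, ok = _wald_logistic(x, yy, ridge=1e-2)
        r = UnivariateResult(fid, z, p)
        if ann and fid in ann:
            r.mz, r.rt, r.ion_mode = ann[fid].mz, ann[fid].rt, ann[fid].ion_mode
        results.append(r)
    # BH within strata (profile x ion mode) when annotation is available
    if ann:
        strata = {}
        for idx, r in enumerate(results):
            key = (ann[r.feature_id].profile, r.ion_mode) \
                if r.feature_id in ann else ("", "")
            strata.setdefault(key, []).append(idx)
        for idxs in strata.values():
            q = bh_adjust([results[i].p for i in idxs])
            for i, qi in zip(idxs, q):
                results[i].q = float(qi)
    else:
        q = bh_adjust([r.p for r in results])
        for r, qi in zip(results, q):
            r.q = float(qi)
    return results


def write_mummichog_input(results, path, mode=None) -> Path:
    """Write the 4-column tab-separated pathway-tool input.

    Columns: m/z, retention_time, p-value, t-score.  ``mode`` filters to
    one ion mode; call once per mode to split pos/neg into separate files.
    """
    rows = [r for r in results if mode is None or r.ion_mode == mode]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("m/z\tretention_time\tp-value\tt-score\n")
        for r in rows:
            fh.write(f"{r.mz:.6g}\t{r.rt:.6g}\t{r.q:.6g}\t{r.t_value:.6g}\n")
    return path


def read_mummichog_input(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


_DRUG_FILE = "drug_masses.csv"


def builtin_drug_masses() -> pd.DataFrame:
    """Monoisotopic masses of levodopa, entacapone, and their metabolites."""
    with resources.files("metclass").joinpath("data", _DRUG_FILE).open() as fh:
        return pd.read_csv(fh)


def drug_mass_filter(annotations, drug_mz_list=None, tol: float = 1.0) -> list[str]:
    """Feature ids kept after removing those within ``tol`` m/z of a drug.

    The interval is closed: |mz - drug| <= tol is removed.  With no list
    supplied, the built-in levodopa/entacapone panel is used.
    """
    if drug_mz_list is None:
        drug_mz_list = builtin_drug_masses()["monoisotopic_mass"].tolist()
    drugs = np.asarray(list(drug_mz_list), dtype=float)
    kept = []
    for a in annotations:
        if not np.isfinite(a.mz):
            raise ValueError(f"feature {a.feature_id} has no m/z")
        if drugs.size and np.min(np.abs(a.mz - drugs)) <= tol:
            continue
        kept.append(a.feature_id)
    return kept


def hypergeometric_enrichment(significant, universe, sets,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Overrepresentation of ``significant`` within each metabolite set.

    p = P(X >= k) for X ~ Hypergeom(N=|universe|, K=|set & universe|,
    n=|significant|); BH-adjusted across sets.  Raw overlap fractions
    (k / K) are reported alongside.
    """
    sig = set(significant)
    uni = set(universe)
    if not sig <= uni:
        raise ValueError("significant list must be a subset of the universe")
    N = len(uni)
    n = len(sig)
    rows = []
    for s in sets:
        members = set(s.members) & uni
        K = len(members)
        k = len(members & sig)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append({"set": s.name, "overlap": k, "set_size": K,
                     "draw_size": n, "universe": N, "p": p,
                     "overlap_fraction": (k / K) if K else np.nan})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < alpha
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    return df


def read_gmt(path) -> list[MetaboliteSet]:
    """Parse GMT-format metabolite sets (name, description, members...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(MetaboliteSet(parts[0], frozenset(parts[2:]), parts[1]))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source or "na", *sorted(s.members)]) + "\n")
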