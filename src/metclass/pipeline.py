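"""End-to-end orchestration: configuration, manifests, full runs.

A run binds the stages together on synthetic or user-supplied data:
simulate (optional) -> preprocess -> leave-one-out evaluation per
contrast -> full-data consensus odds ratios -> missingness analyses ->
univariate scans and enrichment exports -> robustness re-runs.  Every
artifact is written under the output directory next to a manifest
recording the configuration hash, seeds, and package versions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import enet as _enet
from . import enrich as _enrich
from . import evaluate as _evaluate
from . import missingness as _missingness
from . import preprocess as _pre
from . import synthetic_data as _syn
from .containers import ConfigError, FeatureMatrix

_KNOWN_KEYS = {
    "contrast", "profile", "k_mad", "max_missing_frac", "m", "alpha",
    "inner_cv", "n_lambda", "reduced_strategy", "detrend", "seed",
    "simulate", "low_missingness_frac", "run_exclusion", "run_missingness",
    "run_univariate",
}


@dataclass
class PipelineConfig:
    """Validated stage parameters for one full run."""

    contrast: tuple[str, str] = ("PD", "Control")
    profile: str = "untargeted"
    k_mad: float = 3.0
    max_missing_frac: float = 0.5
    m: int = 5
    alpha: float = 0.5
    inner_cv: int | str = 10
    n_lambda: int = 100
    reduced_strategy: str = "refit"
    detrend: bool = False
    seed: int = 0
    simulate: dict | None = None
    low_missingness_frac: float = 0.01
    run_exclusion: bool = False
    run_missingness: bool = True
    run_univariate: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        return cls(**raw)

    def to_eval_config(self) -> _evaluate.EvalConfig:
        return _evaluate.EvalConfig(
            alpha=self.alpha, m=self.m, inner_cv=self.inner_cv,
            n_lambda=self.n_lambda, reduced_strategy=self.reduced_strategy,
            mad_k=self.k_mad, max_missing_frac=self.max_missing_frac,
            detrend=self.detrend, seed=self.seed,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _contrast_subset(cohort: pd.DataFrame, matrix: FeatureMatrix, contrast):
    pos, neg = contrast
    sel = cohort["phenotype"].isin([pos, neg]).to_numpy()
    idx = np.flatnonzero(sel)
    sub_cohort = cohort.iloc[idx].reset_index(drop=True)
    labels = (sub_cohort["phenotype"] == pos).astype(float).to_numpy()
    return sub_cohort, matrix.select_subjects(idx), labels


def _write_eval(outdir: Path, tag: str, result) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        result.scores,
        index=result.subject_ids,
        columns=[f"imputation_{j+1}" for j in range(result.m)],
    ).to_csv(outdir / f"{tag}_scores.csv")
    rows = []
    for j, (fpr, tpr, thr) in enumerate(result.roc_curves):
        for f, t in zip(fpr, tpr):
            rows.append({"imputation": j + 1, "fpr": f, "tpr": t})
    pd.DataFrame(rows).to_csv(outdir / f"{tag}_roc.csv", index=False)
    summary = {
        "auc_per_imputation": [float(a) for a in result.auc_per_imputation],
        "auc_mean": result.auc_mean,
    }
    with open(outdir / f"{tag}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def run_full(config: PipelineConfig, outdir, cohort=None, matrix=None,
             annotations=None) -> Path:
    """Execute the configured analysis graph and write a run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "seed": config.seed,
        "stages": [],
    }

    if cohort is None or matrix is None:
        sim = dict(config.simulate or {})
        sim.setdefault("profile", config.profile)
        sim.setdefault("seed", config.seed)
        gc = _syn.GeneratorConfig(**sim)
        cohort, matrix, annotations, _ = _syn.generate_study(gc)
        _syn.write_study(outdir / "simulated", cohort, matrix, annotations)
        manifest["stages"].append("simulate")

    balance = _syn.cohort_balance_tests(cohort)
    with open(outdir / "cohort_balance.json", "w") as fh:
        json.dump(balance, fh, indent=2)

    sub_cohort, sub_matrix, labels = _contrast_subset(cohort, matrix,
                                                      config.contrast)
    cov = np.column_stack([
        sub_cohort["run_index"].to_numpy(float),
        sub_cohort["age"].to_numpy(float),
        (sub_cohort["sex"] == "M").to_numpy(float),
    ])
    ecfg = config.to_eval_config()
    tag = f"{config.contrast[0]}_vs_{config.contrast[1]}"

    result = _evaluate.loo_evaluate(sub_matrix, labels, ecfg,
                                    covariates=cov if config.detrend else None)
    summary = _write_eval(outdir, tag, result)
    manifest["stages"].append("loo_evaluate")
    manifest["auc_mean"] = summary["auc_mean"]

    models, feat_ids = _evaluate.full_data_fits(sub_matrix, labels, ecfg)
    ors = _enet.consensus_odds_ratios(models, feat_ids)
    pd.DataFrame([{
        "feature": r.name, "odds_ratio": r.odds_ratio,
        "lower": r.low, "upper": r.high,
        "sign": "positive" if r.odds_ratio > 1 else "negative",
    } for r in ors]).to_csv(outdir / f"{tag}_consensus_or.csv", index=False)
    manifest["stages"].append("consensus_or")

    if config.run_missingness:
        std = _pre.standardize(sub_matrix)
        masked = _pre.mad_mask(std, k=config.k_mad)
        ind = _missingness.indicator_matrix(masked)
        if ind.n_features:
            mres, mors = _missingness.missingness_enet(
                ind, labels, sub_cohort["age"].to_numpy(float),
                (sub_cohort["sex"] == "M").to_numpy(float),
                alpha=config.alpha, inner_cv=config.inner_cv,
                n_lambda=config.n_lambda, seed=config.seed,
            )
            _write_eval(outdir, f"{tag}_missingness", mres)
            pd.DataFrame([{
                "feature": r.name, "odds_ratio": r.odds_ratio,
            } for r in mors]).to_csv(
                outdir / f"{tag}_missingness_or.csv", index=False)
            scan = _missingness.univariate_missingness_scan(
                ind, labels,
                covariates=np.column_stack([
                    sub_cohort["age"].to_numpy(float),
                    (sub_cohort["sex"] == "M").to_numpy(float),
                ]),
            )
            scan.to_csv(outdir / f"{tag}_missingness_scan.csv", index=False)
        manifest["stages"].append("missingness")

    if config.run_univariate:
        std = _pre.standardize(sub_matrix)
        uni = _enrich.univariate_scan(std, labels, annotations)
        pd.DataFrame([vars(r) for r in uni]).to_csv(
            outdir / f"{tag}_univariate.csv", index=False)
        if annotations is not None:
            for mode in ("pos", "neg"):
                _enrich.write_mummichog_input(
                    uni, outdir / f"{tag}_mummichog_{mode}.tsv", mode)
        manifest["stages"].append("univariate")

    if config.run_exclusion:
        support = set()
        for mdl in models:
            support |= {feat_ids[j] for j in mdl.support}
        excl = _evaluate.exclusion_rerun(sub_matrix, labels, sorted(support),
                                         ecfg)
        _write_eval(outdir, f"{tag}_exclusion", excl)
        manifest["stages"].append("exclusion_rerun")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
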