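"""Synthetic cohorts and LC-MS-like feature matrices.

This module emulates the statistical structure of a three-group CSF
metabolomics study (healthy controls, Alzheimer's disease, Parkinson's
disease): group sizes of 85/57/56 by default, phenotype-conditional age
distributions, a mild sex imbalance, assay batches filled round-robin
within phenotype strata, run-order instrument drift, sparse phenotype
effects on a minority of features, and missingness that may be completely
at random (MCAR), phenotype-dependent (MNAR-phenotype), or
abundance-dependent left-censoring (MNAR-abundance).

The generator's defaults reproduce the study-scale conditions (profile
widths of 6735 / 108 / 1070 features with roughly 16% / 3% / 81% of
entries missing for the untargeted, targeted, and lipid profiles); tests
and examples pass explicit smaller sizes.

Ground-truth signal labels are stored only in the returned
:class:`FeatureAnnotation` records; analysis modules never read them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError, FeatureMatrix, PHENOTYPES

# stable per-operation offsets added to config.seed so that, e.g., adding
# features never perturbs the cohort draw
_SEED_COHORT = 0
_SEED_PROFILE = 1
_SEED_MISSING = 2

# study-scale profile conditions: (n_features, per-phenotype missing rates)
# the rates average (weighted by the 85/57/56 group sizes) to the overall
# 16% / 3% / 81% missingness of the untargeted/targeted/lipid profiles,
# with the observed ordering Control > AD > PD
PROFILE_DEFAULTS = {
    "untargeted": (6735, (0.20, 0.16, 0.10)),
    "targeted": (108, (0.04, 0.03, 0.015)),
    "lipid": (1070, (0.85, 0.81, 0.75)),
}

# phenotype-conditional age (mean, sd) and female fractions from the cohort
# summary (Control 53.7+-20.3 with 41/85 F, AD 70.6+-9.8 with 29/57 F,
# PD 65+-10 with 17/56 F)
AGE_DEFAULTS = {"Control": (53.7, 20.3), "AD": (70.6, 9.8), "PD": (65.0, 10.0)}
FEMALE_FRACTIONS = {"Control": 41 / 85, "AD": 29 / 57, "PD": 17 / 56}


@dataclass
class GeneratorConfig:
    """Configuration for one synthetic study.

    ``effect_size`` is in standard-deviation units of the feature noise;
    ``missing_rates`` is either one probability (MCAR / MNAR-abundance) or
    one per phenotype in (Control, AD, PD) order.
    """

    n_per_group: tuple[int, int, int] = (85, 57, 56)
    profile: str = "untargeted"
    n_features: int | None = None
    n_signal_features: int = 10
    effect_size: float = 1.5
    age_effect_sd: float = 0.2
    sex_effect_sd: float = 0.2
    drift_amplitude: float = 0.0
    drift_form: str = "smooth"
    missing_mechanism: str = "MNAR-phenotype"
    missing_rates: float | tuple[float, float, float] | None = None
    signal_mode: str = "independent"  # or "latent" (redundant correlated signal)
    latent_primary_loading: float = 0.8
    latent_secondary_loading: float = 0.3
    n_secondary_features: int = 100
    age_bounds: tuple[float, float] = (20.0, 90.0)
    age_means: tuple[float, float, float] | None = None  # (Control, AD, PD)
    age_sds: tuple[float, float, float] | None = None
    batch_size: int = 28
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.profile not in PROFILE_DEFAULTS:
            raise ConfigError(f"unknown profile {self.profile!r}")
        if self.n_features is None:
            self.n_features = PROFILE_DEFAULTS[self.profile][0]
        if self.missing_rates is None:
            self.missing_rates = PROFILE_DEFAULTS[self.profile][1]
        if len(self.n_per_group) != 3 or any(n <= 0 for n in self.n_per_group):
            raise ConfigError("n_per_group must be three positive integers")
        if any(n < 2 for n in self.n_per_group):
            raise ConfigError("each phenotype group needs at least 2 subjects")
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")
        if self.n_signal_features > self.n_features:
            raise ConfigError("n_signal_features exceeds n_features")
        rates = np.atleast_1d(np.asarray(self.missing_rates, dtype=float))
        if np.any((rates < 0) | (rates > 1)):
            raise ConfigError("missing rates must lie in [0, 1]")
        if self.drift_form not in ("linear", "step", "smooth"):
            raise ConfigError(f"unknown drift form {self.drift_form!r}")
        if self.missing_mechanism not in (
            "MCAR", "MAR", "MNAR-phenotype", "MNAR-abundance"
        ):
            raise ConfigError(f"unknown mechanism {self.missing_mechanism!r}")

    def phenotype_rates(self) -> np.ndarray:
        rates = np.atleast_1d(np.asarray(self.missing_rates, dtype=float))
        if rates.size == 1:
            return np.repeat(rates, 3)
        if rates.size != 3:
            raise ConfigError("missing_rates must be scalar or length 3")
        return rates


@dataclass
class FeatureAnnotation:
    feature_id: str
    profile: str
    ion_mode: str
    mz: float
    rt: float
    name: str | None = None
    is_signal: bool = False  # generator ground truth; analysis never reads it


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic cohort as a subject metadata table.

    Ages are truncated normal within ``config.age_bounds`` per phenotype,
    sex is Bernoulli at the study female fractions, the global run order is
    a random permutation, and assay batches of ``batch_size`` are filled
    round-robin within phenotype strata so batch sizes differ by at most
    one.  LEDD (mg/day) and GBA-variant flags are drawn for PD only.
    """
    rng = np.random.default_rng(config.seed + _SEED_COHORT)
    n_total = int(sum(config.n_per_group))
    rows = []
    sid = 0
    for gi, (pheno, n) in enumerate(zip(PHENOTYPES, config.n_per_group)):
        mean, sd = AGE_DEFAULTS[pheno]
        if config.age_means is not None:
            mean = float(config.age_means[gi])
        if config.age_sds is not None:
            sd = float(config.age_sds[gi])
        lo, hi = config.age_bounds
        a, b = (lo - mean) / sd, (hi - mean) / sd
        ages = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        female = rng.random(n) < FEMALE_FRACTIONS[pheno]
        for k in range(n):
            sid += 1
            rows.append({
                "subject_id": f"S{sid:04d}",
                "phenotype": pheno,
                "age": float(ages[k]),
                "sex": "F" if female[k] else "M",
            })
    df = pd.DataFrame(rows)

    n_batches = max(1, int(np.ceil(n_total / config.batch_size)))
    # round-robin across batches, walking through subjects stratum by
    # stratum so each phenotype is spread evenly over batches
    df["batch"] = (np.arange(n_total) % n_batches) + 1

    df["run_index"] = rng.permutation(n_total) + 1

    is_pd = (df["phenotype"] == "PD").to_numpy()
    ledd = np.full(n_total, np.nan)
    ledd[is_pd] = np.clip(rng.normal(714.0, 536.0, is_pd.sum()), 0.0, None)
    df["ledd"] = ledd
    gba = np.full(n_total, np.nan, dtype=object)
    gba[is_pd] = rng.random(is_pd.sum()) < 8 / 56
    df["gba_variant"] = gba
    return df


def _drift_shape(run_frac: np.ndarray, form: str, rng) -> np.ndarray:
    """Unit-scale drift profile over normalized run order in [0, 1]."""
    if form == "linear":
        return 2.0 * (run_frac - 0.5)
    if form == "step":
        boundary = rng.uniform(0.25, 0.75)
        return np.where(run_frac < boundary, -1.0, 1.0)
    # smooth: sine with a random phase, ~1.5 cycles over the run
    phase = rng.uniform(0.0, 1.0)
    return np.sin(2.0 * np.pi * (1.5 * run_frac + phase))


def generate_profiles(
    cohort: pd.DataFrame, config: GeneratorConfig
) -> tuple[FeatureMatrix, list[FeatureAnnotation]]:
    """Generate a complete feature matrix plus annotations for one profile.

    Each feature is baseline + phenotype effect (signal features only)
    + age/sex trends + drift(run order) + Gaussian noise.  In "latent"
    signal mode the phenotype effect is carried by a subject-level latent
    factor: signal features load on it at ``latent_primary_loading`` and an
    additional ``n_secondary_features`` load weakly, emulating pathway-level
    leakage of a disease signature across many correlated metabolites.
    """
    if len(cohort) == 0:
        raise ConfigError("cohort is empty")
    rng = np.random.default_rng(config.seed + _SEED_PROFILE)
    n = len(cohort)
    p = config.n_features
    pheno = cohort["phenotype"].to_numpy()
    age = cohort["age"].to_numpy(dtype=float)
    sex01 = (cohort["sex"].to_numpy() == "M").astype(float)  # F=0, M=1
    run_frac = (cohort["run_index"].to_numpy(dtype=float) - 1) / max(n - 1, 1)

    values = rng.normal(0.0, config.noise_sd, size=(n, p))
    baseline = rng.normal(0.0, 1.0, size=p)
    values += baseline[None, :]

    # covariate trends: per-feature slopes on standardized age and sex
    age_std = (age - age.mean()) / (age.std() + 1e-12)
    age_slopes = rng.normal(0.0, config.age_effect_sd, size=p)
    sex_slopes = rng.normal(0.0, config.sex_effect_sd, size=p)
    values += np.outer(age_std, age_slopes) + np.outer(sex01 - sex01.mean(), sex_slopes)

    # sparse phenotype effects
    signal_idx = np.arange(config.n_signal_features)
    signs = {g: rng.choice([-1.0, 1.0], size=config.n_signal_features)
             for g in ("AD", "PD")}
    if config.signal_mode == "independent":
        for g in ("AD", "PD"):
            in_g = pheno == g
            if in_g.any():
                values[np.ix_(in_g, signal_idx)] += (
                    config.effect_size * signs[g][None, :]
                )
    elif config.signal_mode == "latent":
        # subject latent factor: unit noise plus a phenotype offset scaled so
        # a primary feature's marginal group contrast equals effect_size
        delta = config.effect_size / config.latent_primary_loading
        u = rng.normal(0.0, 1.0, size=n)
        for g in ("AD", "PD"):
            u[pheno == g] += delta * float(signs[g][0] if len(signs[g]) else 1.0)
        lp = config.latent_primary_loading
        ls = config.latent_secondary_loading
        values[:, signal_idx] *= np.sqrt(max(1.0 - lp ** 2, 0.0))
        values[:, signal_idx] += lp * u[:, None]
        n_sec = min(config.n_secondary_features, p - config.n_signal_features)
        sec_idx = np.arange(config.n_signal_features,
                            config.n_signal_features + n_sec)
        values[:, sec_idx] *= np.sqrt(max(1.0 - ls ** 2, 0.0))
        values[:, sec_idx] += ls * u[:, None]
    else:
        raise ConfigError(f"unknown signal_mode {config.signal_mode!r}")

    # instrument drift over run order, same amplitude for every feature with
    # a random per-feature sign (and per-feature step location / sine phase)
    if config.drift_amplitude != 0.0:
        drift_signs = rng.choice([-1.0, 1.0], size=p)
        for j in range(p):
            shape = _drift_shape(run_frac, config.drift_form, rng)
            values[:, j] += config.drift_amplitude * drift_signs[j] * shape

    annotations = []
    mz = rng.uniform(100.0, 2000.0, size=p)
    rt = rng.uniform(30.0, 4200.0, size=p)
    ion = rng.choice(["pos", "neg"], size=p)
    for j in range(p):
        annotations.append(FeatureAnnotation(
            feature_id=f"F{j+1:05d}", profile=config.profile,
            ion_mode=str(ion[j]), mz=float(mz[j]), rt=float(rt[j]),
            is_signal=bool(j < config.n_signal_features),
        ))
    fm = FeatureMatrix(values, np.ones_like(values, dtype=bool),
                       list(cohort["subject_id"]),
                       [a.feature_id for a in annotations])
    return fm, annotations


def inject_missingness(
    matrix: FeatureMatrix, cohort: pd.DataFrame, config: GeneratorConfig
) -> FeatureMatrix:
    """Mask entries of a complete matrix under the configured mechanism.

    MCAR masks uniformly; MAR masks at per-subject rates modulated by age
    (older subjects slightly more complete); MNAR-phenotype masks at
    per-phenotype rates; MNAR-abundance left-censors the lowest values of
    each feature.
    """
    if not matrix.mask.all():
        raise ValueError("inject_missingness expects a complete matrix")
    rates = config.phenotype_rates()
    rng = np.random.default_rng(config.seed + _SEED_MISSING)
    n, p = matrix.values.shape
    pheno = cohort["phenotype"].to_numpy()
    drop = np.zeros((n, p), dtype=bool)

    if config.missing_mechanism == "MCAR":
        rate = float(np.mean(rates))
        drop = rng.random((n, p)) < rate
    elif config.missing_mechanism == "MAR":
        # missingness depends on an observed covariate (age), not the value
        age = cohort["age"].to_numpy(dtype=float)
        z = (age - age.mean()) / (age.std() + 1e-12)
        base = float(np.mean(rates))
        row_rate = np.clip(base * (1.0 - 0.5 * np.tanh(z)), 0.0, 1.0)
        drop = rng.random((n, p)) < row_rate[:, None]
    elif config.missing_mechanism == "MNAR-phenotype":
        row_rate = np.array([rates[PHENOTYPES.index(g)] for g in pheno])
        drop = rng.random((n, p)) < row_rate[:, None]
    else:  # MNAR-abundance: left-censor the lowest values per feature
        rate = float(np.mean(rates))
        k = int(np.floor(rate * n))
        if k > 0:
            order = np.argsort(matrix.values, axis=0)
            for j in range(p):
                drop[order[:k, j], j] = True

    out = matrix.copy()
    out.mask = out.mask & ~drop
    out.values = np.where(out.mask, out.values, np.nan)
    return out


def generate_study(config: GeneratorConfig):
    """Convenience wrapper: cohort -> complete profiles -> missingness."""
    cohort = generate_cohort(config)
    complete, annotations = generate_profiles(cohort, config)
    observed = inject_missingness(complete, cohort, config)
    return cohort, observed, annotations, complete


def cohort_balance_tests(cohort: pd.DataFrame) -> dict:
    """Cohort balance diagnostics: sex x phenotype chi-squared and age ANOVA.

    Pearson chi-squared without continuity correction on the sex-by-phenotype
    contingency table, and a one-way ANOVA of age across phenotype groups.
    """
    groups = [g for g in PHENOTYPES if (cohort["phenotype"] == g).any()]
    if len(groups) < 2:
        raise ValueError("need at least two phenotype groups")
    if any((cohort["phenotype"] == g).sum() == 0 for g in groups):
        raise ValueError("phenotype group with zero subjects")
    table = pd.crosstab(cohort["sex"], cohort["phenotype"]).to_numpy()
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    ages = [cohort.loc[cohort["phenotype"] == g, "age"].to_numpy() for g in groups]
    f, p_age = stats.f_oneway(*ages)
    df1 = len(groups) - 1
    df2 = len(cohort) - len(groups)
    return {
        "chi2_sex_phenotype": (float(chi2), int(dof), float(p)),
        "anova_age_phenotype": (float(f), df1, df2, float(p_age)),
    }


def sex_phenotype_chi2(counts) -> tuple[float, int, float]:
    """Chi-squared test of independence on a sex x phenotype count table."""
    table = np.asarray(counts, dtype=float)
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def annotations_to_frame(annotations: list[FeatureAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_id": a.feature_id, "name": a.name, "profile": a.profile,
        "ion_mode": a.ion_mode, "mz": a.mz, "rt": a.rt, "is_signal": a.is_signal,
    } for a in annotations])


def write_study(outdir, cohort, matrix: FeatureMatrix, annotations) -> None:
    """Write subjects.csv, matrix.csv (blank = missing), annotations.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(outdir / "subjects.csv", index=False)
    matrix.to_csv(outdir / "matrix.csv")
    annotations_to_frame(annotations).to_csv(outdir / "annotations.csv", index=False)
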