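import numpy as np
import pytest

from metclass import synthetic_data as syn


@pytest.fixture(scope="session")
def small_study():
    """A small two-class-dominated study used across integration tests."""
    cfg = syn.GeneratorConfig(
        n_per_group=(30, 30, 2), n_features=80, n_signal_features=6,
        effect_size=1.5, missing_mechanism="MCAR", missing_rates=0.1,
        drift_amplitude=0.0, seed=7,
    )
    cohort, observed, annotations, complete = syn.generate_study(cfg)
    return dict(cfg=cfg, cohort=cohort, observed=observed,
                annotations=annotations, complete=complete)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def contrast_arrays(cohort, matrix, pos="AD", neg="Control"):
    sel = cohort["phenotype"].isin([pos, neg]).to_numpy()
    idx = np.flatnonzero(sel)
    labels = (cohort["phenotype"].to_numpy()[idx] == pos).astype(float)
    return matrix.select_subjects(idx), labels, cohort.iloc[idx].reset_index(drop=True)
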