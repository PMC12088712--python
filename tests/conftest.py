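import numpy as np
import pytest
from hypothesis import settings

from ecgtraj.cohort import CohortSpec, generate_cohort, spec_with_preset

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")

#: seed for the expensive trained-model fixtures (fixed once for the suite)
STUDY_SEED = 7


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten-patient moderate-effect cohort, in memory."""
    spec = CohortSpec(n_patients=10, visits_min=2, visits_max=3, rng_seed=5)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def clean_spec():
    """Noiseless spec (no additive noise, no baseline wander)."""
    return CohortSpec(noise_floor_mv=0.0, baseline_wander_mv=0.0, rng_seed=5)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A tiny cohort written to disk (manifest + ECG CSVs + ground truth)."""
    out = tmp_path_factory.mktemp("cohort")
    spec = spec_with_preset(
        CohortSpec(n_patients=4, visits_min=2, visits_max=3, record_seconds=4.0,
                   rng_seed=11), "moderate")
    data = generate_cohort(spec, out_dir=out)
    return out, data


# ---------------------------------------------------------------------------
# expensive trained-model fixtures (shared across behavioural tests)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def recovery_study():
    from ecgtraj import experiments
    return experiments.make_study_cohort(STUDY_SEED)


@pytest.fixture(scope="session")
def deht_recovery(recovery_study):
    from ecgtraj import experiments
    return experiments.run_deht_recovery(STUDY_SEED, study=recovery_study)


@pytest.fixture(scope="session")
def ebt_recovery(recovery_study):
    from ecgtraj import experiments
    return experiments.run_ebt_recovery(STUDY_SEED, study=recovery_study)


@pytest.fixture(scope="session")
def chance_floor(recovery_study):
    from ecgtraj import experiments
    return experiments.run_chance_floor(STUDY_SEED, study=recovery_study)
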