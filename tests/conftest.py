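import datetime as dt

import pytest

from twinliab import GompertzMortality, default_params, simulate_cohort

TRUTH = {"a2": 0.47, "c2": 0.21, "e2": 0.32}


@pytest.fixture(scope="session")
def paper_cohort():
    """Registry-scale cohort at the default (study-condition) parameters."""
    return simulate_cohort(default_params(n_pairs=45_000, seed=11))


@pytest.fixture(scope="session")
def paper_cohort_prevalent():
    """Same conditions with pre-window onsets emitted as visible cases."""
    return simulate_cohort(default_params(n_pairs=45_000, seed=13,
                                          emit_prevalent=True))


@pytest.fixture(scope="session")
def truth_50k():
    """50k-pair cohort with the latent truth attached."""
    params = default_params(n_pairs=50_000, seed=21)
    cohort, truth = simulate_cohort(params, return_truth=True)
    return cohort, truth, params


@pytest.fixture(scope="session")
def complete_cohort():
    """Death-free, censoring-free cohort observed to age ~105.

    Every individual's lifetime onset status is fully observed, so the raw
    case fraction equals the liability-scale lifetime prevalence.
    """
    params = default_params(
        n_pairs=20_000, seed=29,
        mortality=GompertzMortality(1e-12, 1e-12, 0.05),
        emigration_rate=0.0,
        birth_years=(1990, 1994),
        study_end=dt.date(2100, 1, 1),
    )
    return simulate_cohort(params), params
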