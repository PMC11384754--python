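import numpy as np
import pytest

from alleleprime.synthetic_trial import (
    Participant,
    TrialConfig,
    simulate_genotypes,
    simulate_trial_responses,
)


@pytest.fixture
def config():
    """Default study conditions with a small repertoire for fast tests."""
    return TrialConfig(seed=42, n_total_umis=5_000)


@pytest.fixture
def het_participant():
    return Participant(id="H01", dose_group="low", allele_1="*02", allele_2="*04")


@pytest.fixture
def homo02_participant():
    return Participant(id="H02", dose_group="high", allele_1="*02", allele_2="*02")


@pytest.fixture
def trial_responses_wk4():
    """One simulated trial's week-4 MBC response table."""
    cfg = TrialConfig(seed=7)
    participants = simulate_genotypes(cfg)
    return simulate_trial_responses(
        participants, cfg, timepoints=[("MBC", 4)]
    )
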