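import pytest

from batkit.gating import count_populations, default_gate_config
from batkit.scoring import condition_summaries, response_profile
from batkit.synthetic import (
    CONDITIONS, CohortConfig, sample_cohort, sample_seed_sequence,
    simulate_events,
)


@pytest.fixture(scope="session")
def gate_cfg():
    return default_gate_config()


@pytest.fixture(scope="session")
def small_cohort():
    """Five donors with reduced event depth for fast unit tests."""
    cfg = CohortConfig(n_donors=5, events_per_sample=20_000, seed=42)
    return cfg, sample_cohort(cfg)


def gated_counts(donor, cfg, seed, gate_cfg, n_events=None):
    """Simulate and gate all four conditions of one donor."""
    n = n_events or cfg.events_per_sample
    return {
        c: count_populations(
            simulate_events(donor, c, n,
                            sample_seed_sequence(seed, donor.donor_id, c), cfg),
            gate_cfg)
        for c in CONDITIONS
    }


def estimate_profile(donor, cfg, seed, gate_cfg, n_events=None):
    counts = gated_counts(donor, cfg, seed, gate_cfg, n_events)
    return response_profile(donor.donor_id, condition_summaries(counts))
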