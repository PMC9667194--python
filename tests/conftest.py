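from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from introseeker import SimConfig, make_dataset
from introseeker.alien_transcript_filter import presence_absence_filter, select_candidates

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: a small but fully structured configuration for fast end-to-end tests
TINY = dict(
    chrom_length=8_000,
    snp_per_chrom=60,
    probe_per_chrom=30,
    n_transcripts_per_chrom=6,
    transcript_len_max=900,
)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_config):
    """Full default-scale dataset for seed 1, shared across the suite."""
    return make_dataset(default_config)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return SimConfig(seed=1, **TINY)


@pytest.fixture(scope="session")
def ten_seed_runs():
    """Candidate-selection runs over seeds 1..10 at default configuration.

    Shared by the candidate-recovery and marker-specificity tests: for each
    seed, the dataset essentials, the expression-passing set, the candidate
    records and the truth labels.
    """
    runs = []
    for seed in range(1, 11):
        cfg = SimConfig(seed=seed)
        ds = make_dataset(cfg)
        tx = ds.transcripts
        expressed = presence_absence_filter(
            tx.fpkm, tx.sample_groups["line"], tx.sample_groups["parent"]
        )
        records, hits = select_candidates(tx.sequences, expressed, ds.panel, target_group=4)
        ds.panel._indexes.clear()  # free the k-mer indexes; sequences remain
        runs.append(
            {
                "seed": seed,
                "dataset": ds,
                "expressed": set(expressed),
                "records": records,
                "hits": hits,
                "truth": set(tx.donor_ids),
            }
        )
    return runs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
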