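"""Shared fixtures.

The forward-simulation replicate sets are session-scoped because they feed
several statistical checks (focal-window contrast, sweep localization); the
simulated study conditions are the divergence model's published parameters
rescaled by q = 31 (N' = 100), with 40 sampled haplotypes per population.
"""

from __future__ import annotations

import numpy as np
import pytest

from strainsweep.synthetic_data import (
    SimulationConfig,
    make_structured_fixture,
    simulate_divergence,
)

RESCALE_Q = 31
SIM_SEED = 20_240_101
N_SWEEP_REPS = 50
N_NEUTRAL_REPS = 50


@pytest.fixture(scope="session")
def sweep_config() -> SimulationConfig:
    return SimulationConfig(rescale_q=RESCALE_Q, seed=SIM_SEED)


@pytest.fixture(scope="session")
def sweep_sims(sweep_config):
    """50 replicates of the divergence model with selection."""
    return simulate_divergence(sweep_config, n_reps=N_SWEEP_REPS)


@pytest.fixture(scope="session")
def neutral_sims():
    """50 matched neutral replicates (no selection, focal site absent)."""
    cfg = SimulationConfig(rescale_q=RESCALE_Q, seed=SIM_SEED + 1000, sel=0.0)
    return simulate_divergence(cfg, n_reps=N_NEUTRAL_REPS)


@pytest.fixture(scope="session")
def structured_fixture():
    """Two groups at target F_ST 0.1 plus one planted F1 hybrid."""
    gm, meta = make_structured_fixture(
        n_per_group=20, n_variants=15_000, fst_target=0.1, n_hybrids=1, seed=7
    )
    return gm, meta


@pytest.fixture(scope="session")
def panmictic_fixture():
    gm, meta = make_structured_fixture(
        n_per_group=20, n_variants=4000, fst_target=0.0, n_hybrids=0, seed=11
    )
    return gm, meta


def distal_window_indices(windows, focal_pos: int, k: int = 10) -> np.ndarray:
    centers = (windows["start"].to_numpy() + windows["end"].to_numpy()) / 2.0
    return np.argsort(np.abs(centers - focal_pos))[-k:]
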