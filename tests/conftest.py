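"""Shared fixtures.

The session-scoped reference sets are built once at the simulation-study
conditions (n = 100 haplotypes, 150 kb at 1.5 cM/Mb, constant N = 10,000) with
desk-scale table sizes; the inference-level tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from sweepabc import (
    ABCConfig,
    Demography,
    PriorSpec,
    RecombinationMap,
    ReferenceSet,
    RegionSpec,
    SimulationConfig,
    SweepModelSpec,
    Trajectory,
    simulate_haplotypes,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def priors() -> PriorSpec:
    return PriorSpec()


@pytest.fixture(scope="session")
def abc_config() -> ABCConfig:
    return ABCConfig(n_accept=50)


@pytest.fixture(scope="session")
def refset95(study_config, priors) -> ReferenceSet:
    """Main reference set, conditioned on f_cur = 0.95."""
    return ReferenceSet.build(
        ("NT", "SDN", "SSV"), 0.95, priors, study_config, n_sims=1500, seed=1234
    )


@pytest.fixture(scope="session")
def refset50(study_config, priors) -> ReferenceSet:
    """Smaller companion set conditioned on f_cur = 0.5."""
    return ReferenceSet.build(
        ("NT", "SDN", "SSV"), 0.5, priors, study_config, n_sims=800, seed=4321
    )


@pytest.fixture()
def small_dem() -> Demography:
    return Demography.constant(500)


@pytest.fixture()
def pinned_traj() -> Trajectory:
    """Frequency pinned at 1: the single-background (plain coalescent) mode."""
    return Trajectory(freqs=np.ones(10), dt=1.0, t0=10.0)
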