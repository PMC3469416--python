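"""Small cross-test helpers."""

import numpy as np

from sweepabc import Demography, RecombinationMap, RegionSpec, Trajectory, simulate_haplotypes


def simulate_neutral_matrix(n=8, L=10_000.0, mu=5e-7, N=500.0, rate_cM_Mb=0.0, seed=0):
    """Plain-coalescent haplotypes via the pinned single-background mode."""
    dem = Demography.constant(N)
    traj = Trajectory(freqs=np.ones(5), dt=1.0, t0=5.0)
    region = RegionSpec(length_bp=L, selected_pos=L / 2, n=n, mu=mu)
    rmap = RecombinationMap.constant(rate_cM_Mb)
    return simulate_haplotypes(traj, region, rmap, dem, seed=seed, n_derived=n)
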