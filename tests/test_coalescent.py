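"""Structured-coalescent simulator: neutral oracles, sweep signatures,
focal-count allocation, perfect phylogeny without recombination."""

import math

import numpy as np
import pytest
from scipy import stats

from sweepabc import (
    Demography,
    RecombinationMap,
    RegionSpec,
    SweepModelSpec,
    Trajectory,
    sample_focal_counts,
    simulate_haplotypes,
    simulate_trajectory,
)
from helpers import simulate_neutral_matrix


def harmonic(n):
    return sum(1.0 / i for i in range(1, n))


class TestFocalCounts:
    def test_binomial_mean(self):
        rng = np.random.default_rng(0)
        ks = [sample_focal_counts(100, 0.5, rng)[0] for _ in range(10_000)]
        se = math.sqrt(100 * 0.25 / 10_000)
        assert abs(np.mean(ks) - 50) < 3 * se

    def test_n_two_always_one_one(self):
        rng = np.random.default_rng(1)
        for f in (0.01, 0.5, 0.99):
            assert sample_focal_counts(2, f, rng) == (1, 1)

    def test_matches_truncated_binomial_pmf(self):
        # chi-square against the enumerated truncated pmf
        n, f = 100, 0.95
        rng = np.random.default_rng(2)
        draws = np.array([sample_focal_counts(n, f, rng)[0] for _ in range(20_000)])
        ks = np.arange(1, n)
        pmf = stats.binom.pmf(ks, n, f)
        pmf /= pmf.sum()
        # pool tiny-expectation cells
        keep = pmf * len(draws) >= 5
        obs = np.array([(draws == k).sum() for k in ks])
        o = np.append(obs[keep], obs[~keep].sum())
        e = np.append(pmf[keep], pmf[~keep].sum()) * len(draws)
        chi2 = ((o - e) ** 2 / e).sum()
        assert stats.chi2.sf(chi2, len(o) - 1) > 0.01


class TestNeutralOracles:
    def test_mu_zero_gives_only_focal_column(self, small_dem):
        traj = Trajectory(freqs=np.ones(5), dt=1.0, t0=5.0)
        region = RegionSpec(length_bp=10_000, selected_pos=5_000, n=6, mu=0.0)
        h = simulate_haplotypes(
            traj, region, RecombinationMap.constant(1.5), small_dem, seed=0,
            n_derived=3,
        )
        assert h.n_sites == 1
        assert h.selected_index == 0
        assert h.focal_derived_count == 3

    def test_watterson_segregating_sites(self):
        # single-background mode vs Watterson's E[S] = theta * sum 1/i
        n, N, mu, L = 8, 500, 5e-7, 10_000.0
        theta = 4 * N * mu * L
        S = np.array(
            [simulate_neutral_matrix(n, L, mu, N, 0.0, seed=i).n_sites - 1
             for i in range(2000)]
        )
        expect = theta * harmonic(n)
        z = (S.mean() - expect) / (S.std() / math.sqrt(len(S)))
        assert abs(z) < 3.3

    def test_watterson_with_recombination(self):
        n, N, mu, L = 8, 500, 5e-7, 10_000.0
        theta = 4 * N * mu * L
        S = np.array(
            [simulate_neutral_matrix(n, L, mu, N, 150.0, seed=i).n_sites - 1
             for i in range(1500)]
        )
        expect = theta * harmonic(n)
        z = (S.mean() - expect) / (S.std() / math.sqrt(len(S)))
        assert abs(z) < 3.3

    def test_site_frequency_spectrum(self):
        # E[S_i] = theta / i: per-class z tests with Bonferroni at the 1% level
        n, N, mu, L = 8, 500, 5e-7, 10_000.0
        theta = 4 * N * mu * L
        reps = 2000
        counts = np.zeros((reps, n - 1))
        for r in range(reps):
            h = simulate_neutral_matrix(n, L, mu, N, 0.0, seed=10_000 + r)
            c = h.derived_counts
            c = np.delete(c, h.selected_index)
            for i in range(1, n):
                counts[r, i - 1] = (c == i).sum()
        mean = counts.mean(0)
        se = counts.std(0) / math.sqrt(reps)
        expect = theta / np.arange(1, n)
        z = (mean - expect) / se
        crit = stats.norm.isf(0.01 / (2 * (n - 1)))  # Bonferroni, two-sided 1%
        assert np.all(np.abs(z) < crit), z

    def test_mean_S_matches_msprime_oracle(self):
        # independent implementation: msprime under identical neutral settings
        msprime = pytest.importorskip("msprime")
        n, N, mu, L = 10, 500, 5e-7, 10_000.0
        ours = np.array(
            [simulate_neutral_matrix(n, L, mu, N, 60.0, seed=i).n_sites - 1
             for i in range(1200)]
        )
        # diploid sampling so the coalescent timescale is 2N, matching ours
        reps = msprime.sim_ancestry(
            samples=n // 2, ploidy=2, population_size=N, sequence_length=L,
            recombination_rate=60.0 * 1e-8, num_replicates=1200, random_seed=5,
        )
        theirs = []
        for ts in reps:
            mts = msprime.sim_mutations(
                ts, rate=mu, random_seed=len(theirs) + 1, discrete_genome=False
            )
            theirs.append(mts.num_sites)
        theirs = np.array(theirs)
        se = math.hypot(ours.std() / math.sqrt(len(ours)),
                        theirs.std() / math.sqrt(len(theirs)))
        assert abs(ours.mean() - theirs.mean()) < 3.3 * se


class TestStructure:
    def test_no_recombination_gives_perfect_phylogeny(self):
        # every pair of columns must be compatible with one tree
        # (four-gamete test passes everywhere)
        for seed in range(15):
            h = simulate_neutral_matrix(10, 5_000.0, 1e-6, 500, 0.0, seed=seed)
            A = h.alleles.astype(bool)
            S = A.shape[1]
            for i in range(S):
                for j in range(i + 1, S):
                    a, b = A[:, i], A[:, j]
                    gametes = {(1, 1) in zip(a, b), }
                    combos = set(zip(a.tolist(), b.tolist()))
                    assert len(combos) < 4, "four-gamete violation without recombination"

    def test_focal_count_respected_and_deterministic(self):
        dem = Demography.constant(2000)
        spec = SweepModelSpec(model="SDN", f_cur=0.8, s=0.05)
        traj = simulate_trajectory(spec, dem, seed=9)
        region = RegionSpec(length_bp=30_000, selected_pos=15_000, n=20, mu=1e-7)
        rmap = RecombinationMap.constant(1.5)
        h1 = simulate_haplotypes(traj, region, rmap, dem, seed=33)
        h2 = simulate_haplotypes(traj, region, rmap, dem, seed=33)
        assert h1 == h2
        assert 1 <= h1.focal_derived_count <= 19
        h3 = simulate_haplotypes(traj, region, rmap, dem, seed=33, n_derived=7)
        assert h3.focal_derived_count == 7

    def test_sweep_reduces_central_diversity_more_under_sdn_than_ssv(self):
        # hitch-hiking contrast: SDN at equal alpha digs a deeper, wider hole
        # than SSV (sweep from standing variation is weaker and narrower)
        dem = Demography.constant(10_000)
        region = RegionSpec(length_bp=150_000, selected_pos=75_000, n=50, mu=2.5e-8)
        rmap = RecombinationMap.constant(1.5)

        def pi_ratio(model, seed, **kw):
            spec = SweepModelSpec(model=model, f_cur=0.95, **kw)
            tr = simulate_trajectory(spec, dem, seed=seed)
            h = simulate_haplotypes(tr, region, rmap, dem, seed=seed + 1)
            d = np.abs(h.positions - 75_000)
            c = h.derived_counts.astype(float)
            c[h.selected_index] = 0  # focal column is conditioned on
            n = h.n
            pw = 2 * c * (n - c) / (n * (n - 1))
            central = pw[d <= 10_000].sum()
            far = pw[d > 50_000].sum()
            return central, far

        res = {}
        for model, kw in (("SDN", dict(s=0.025)), ("SSV", dict(s=0.025, f1=0.1))):
            cs, fs = zip(*(pi_ratio(model, 4_000 + 7 * i, **kw) for i in range(60)))
            res[model] = (np.mean(cs), np.mean(fs))
        assert res["SDN"][0] < res["SDN"][1], "SDN central diversity not reduced"
        assert res["SDN"][0] < res["SSV"][0], "SDN should dig deeper than SSV"

    def test_region_map_mismatch_rejected(self):
        with pytest.raises(ValueError):
            RegionSpec(length_bp=1000, selected_pos=2000, n=4, mu=1e-8)
        with pytest.raises(ValueError):
            RecombinationMap(breakpoints=(0.0, 5.0, 3.0), rates=(1.0, 1.0, 1.0))


class TestRecombinationMap:
    def test_cumulative_morgans(self):
        rmap = RecombinationMap(breakpoints=(0.0, 1000.0), rates=(1.0, 3.0))
        knots, cum = rmap.cumulative_arrays(2000.0)
        # 1 cM/Mb over 1 kb = 1e-5 Morgans; then 3 cM/Mb over 1 kb
        assert cum[-1] == pytest.approx(1e-5 + 3e-5)

    def test_hotspot_changes_breakpoint_density(self):
        # recombination events should concentrate in the hot interval
        dem = Demography.constant(1000)
        traj = Trajectory(freqs=np.ones(5), dt=1.0, t0=5.0)
        L = 40_000.0
        region = RegionSpec(length_bp=L, selected_pos=0.0, n=12, mu=2e-7)
        hot = RecombinationMap(breakpoints=(0.0, 20_000.0), rates=(0.0, 30.0))
        h = simulate_haplotypes(traj, region, hot, dem, seed=3, n_derived=12)
        assert h.n_sites > 5  # smoke: data came back
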