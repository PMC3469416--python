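"""Backward-diffusion trajectory simulator and allele-age formulas."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest, ks_2samp

from sweepabc import (
    Demography,
    PriorSpec,
    SweepModelSpec,
    expected_allele_age,
    simulate_trajectory,
)
from sweepabc.trajectory import TrajectoryError


def t0_sample(spec, dem, n, seed0, dt=None):
    return np.array(
        [simulate_trajectory(spec, dem, dt=dt, seed=seed0 + i).t0 for i in range(n)]
    )


class TestSpecValidation:
    def test_bounds(self):
        with pytest.raises(ValueError):
            SweepModelSpec(model="NT", f_cur=1.0)
        with pytest.raises(ValueError):
            SweepModelSpec(model="NT", f_cur=0.5, s=0.01)  # NT requires s = 0
        with pytest.raises(ValueError):
            SweepModelSpec(model="SSV", f_cur=0.5, s=0.01)  # missing f1
        with pytest.raises(ValueError):
            SweepModelSpec(model="SDN", f_cur=0.5, s=0.01, f1=0.1)  # stray f1

    def test_alpha(self):
        assert SweepModelSpec(model="SDN", f_cur=0.5, s=0.01).alpha(10_000) == 400.0

    def test_prior_support(self):
        rng = np.random.default_rng(0)
        pr = PriorSpec()
        for _ in range(200):
            spec, draws = pr.sample("SSV", 0.9, rng)
            assert 0.5e-8 <= draws["mu"] <= 6e-8
            assert -3 <= draws["log10_s"] <= -0.5
            assert 0 < spec.f1 <= 0.2


class TestTrajectories:
    def test_start_adjacent_to_boundary_absorbs_immediately(self):
        # a martingale started a hair above the absorbing boundary typically
        # crosses it within a few steps (occasional walks wander up first)
        dem = Demography.constant(1000)
        spec = SweepModelSpec(model="NT", f_cur=1.0 / 2000 + 1e-6)
        t0s = [simulate_trajectory(spec, dem, seed=s).t0 for s in range(20)]
        assert np.median(t0s) <= 5.0
        assert max(t0s) < 5000.0

    def test_frequencies_stay_in_unit_interval(self):
        dem = Demography.constant(500)
        for dt in (1.0, 0.5, 0.1):
            for seed in range(5):
                tr = simulate_trajectory(
                    SweepModelSpec(model="SDN", f_cur=0.9, s=0.05), dem, dt=dt, seed=seed
                )
                assert tr.freqs[0] == 0.9
                assert np.all((tr.freqs >= 0) & (tr.freqs <= 1))
                assert tr.freqs[-1] < 1.0 / (2 * 500)

    def test_sdn_sojourn_matches_diffusion_and_ode_oracles(self):
        # alpha = 4000: mean backward sojourn vs (a) the exact conditional
        # sojourn-time integral and (b) the deterministic logistic transit
        # (upper-bound approximation; diffusive boundary corrections are O(1/s))
        N, s = 10_000, 0.1
        dem = Demography.constant(N)
        t0s = t0_sample(SweepModelSpec(model="SDN", f_cur=0.95, s=s), dem, 500, 11_000)
        exact = expected_allele_age(0.95, N, s, generation_years=1.0)
        assert abs(t0s.mean() - exact) / exact < 0.05
        T_ode = quad(lambda x: 2.0 / (s * x * (1 - x)), 1 / (2 * N), 0.95)[0]
        assert abs(t0s.mean() - T_ode) / T_ode < 0.20

    def test_ssv_switch_time_and_neutral_tail(self):
        # every replicate records t1 with the path within one Euler step of f1,
        # and the pre-t1 (earlier-time) increments are drift-free
        N = 10_000
        dem = Demography.constant(N)
        spec = SweepModelSpec(model="SSV", f_cur=0.95, s=0.01, f1=0.05)  # alpha=400
        zs = []
        for seed in range(60):
            tr = simulate_trajectory(spec, dem, seed=seed)
            assert tr.t1 is not None and tr.t1 <= tr.t0
            i1 = int(round(tr.t1 / tr.dt))
            # one Euler step of drift+noise around f1
            step = abs(tr.freqs[i1] - tr.freqs[i1 - 1]) if i1 > 0 else 0.0
            assert tr.freqs[i1] <= 0.05 + 1e-12
            assert tr.freqs[i1] >= 0.05 - max(5 * math.sqrt(0.05 / (2 * N)), step)
            x = tr.freqs[i1:-1]
            inc = np.diff(tr.freqs[i1:])
            sd = np.sqrt(x * (1 - x) * tr.dt / (2 * N))
            ok = sd > 0
            zs.extend((inc[ok] / sd[ok]).tolist())
        zs = np.asarray(zs)
        # standardized neutral increments should be N(0,1): mean test at 1%
        z_mean = zs.mean() * math.sqrt(len(zs))
        assert abs(z_mean) < 2.58

    def test_ssv_with_fcur_below_f1_is_neutral_throughout(self):
        dem = Demography.constant(1000)
        tr = simulate_trajectory(
            SweepModelSpec(model="SSV", f_cur=0.05, s=0.1, f1=0.1), dem, seed=3
        )
        assert tr.t1 == 0.0

    def test_nesting_ssv_at_f1_one_over_2N_recovers_sdn(self):
        # the SSV model with f1 = 1/(2N) is the SDN model
        N = 10_000
        dem = Demography.constant(N)
        sdn = t0_sample(SweepModelSpec(model="SDN", f_cur=0.95, s=0.01), dem, 800, 1)
        ssv = t0_sample(
            SweepModelSpec(model="SSV", f_cur=0.95, s=0.01, f1=1.0 / (2 * N)),
            dem, 800, 50_001,
        )
        assert ks_2samp(sdn, ssv).pvalue > 0.01

    def test_neutral_t0_mean_matches_kimura_ohta(self):
        N, x = 2000, 0.5
        dem = Demography.constant(N)
        spec = SweepModelSpec(model="NT", f_cur=x)
        t0s = t0_sample(spec, dem, 3000, 7_000)
        expect = expected_allele_age(x, N, 0.0, generation_years=1.0)
        z = (t0s.mean() - expect) / (t0s.std() / math.sqrt(len(t0s)))
        assert abs(z) < 2.58  # two-sided 1% level

    def test_halving_dt_leaves_mean_within_mc_error(self):
        N, s = 10_000, 0.025
        dem = Demography.constant(N)
        spec = SweepModelSpec(model="SDN", f_cur=0.95, s=s)
        a = t0_sample(spec, dem, 400, 100, dt=1.0)
        b = t0_sample(spec, dem, 400, 200, dt=0.5)
        se = math.hypot(a.std() / 20, b.std() / 20)
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_horizon_failure_is_explicit(self):
        dem = Demography.constant(100_000)
        with pytest.raises(TrajectoryError, match="horizon"):
            simulate_trajectory(
                SweepModelSpec(model="NT", f_cur=0.5), dem, seed=0, max_horizon=50.0
            )

    def test_export(self, tmp_path):
        dem = Demography.constant(500)
        tr = simulate_trajectory(
            SweepModelSpec(model="SSV", f_cur=0.6, s=0.05, f1=0.1), dem, seed=5
        )
        p = tmp_path / "traj.tsv"
        tr.to_file(p)
        text = p.read_text()
        assert f"# t0={tr.t0:g}" in text
        assert "generation\tfrequency" in text


class TestAlleleAge:
    def test_neutral_age_lct_value(self):
        # x = 27%, N = 10,000, 25 y/gen: 484 ky before rounding
        age = expected_allele_age(0.27, 10_000, 0.0, 25.0)
        assert age == pytest.approx(484_274, rel=1e-3)

    def test_age_linear_in_N(self):
        a1 = expected_allele_age(0.27, 10_000, 0.0)
        a2 = expected_allele_age(0.27, 20_000, 0.0)
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_selected_age_matches_monte_carlo(self):
        # the simulator's t0 is the first passage below 1/(2N); by the strong
        # Markov property its expectation is the full mean loss time minus the
        # mean sub-threshold sojourn, both from the same closed form
        N, s, x = 10_000, 0.025, 0.27
        dem = Demography.constant(N)
        t0s = t0_sample(SweepModelSpec(model="SDN", f_cur=x, s=s), dem, 1500, 77_000)
        formula = expected_allele_age(x, N, s, generation_years=1.0)
        below = expected_allele_age(1.0 / (2 * N), N, s, generation_years=1.0)
        z = (t0s.mean() - (formula - below)) / (t0s.std() / math.sqrt(len(t0s)))
        assert abs(z) < 3.3

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            expected_allele_age(0.0, 1000, 0.0)
        with pytest.raises(ValueError):
            expected_allele_age(1.0, 1000, 0.0)
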