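"""Simulation studies: parameter recovery, model-choice power, calibration,
and robustness to misidentified focal sites and unmodelled bottlenecks.

Every experiment simulates datasets under known truths, runs the full
inference pipeline against a shared :class:`ReferenceSet`, and returns a tidy
DataFrame keyed by the scenario parameters, reproducible from its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .demography import Demography
from .inference import ABCConfig
from .pipeline import ReferenceSet, SimulationConfig, simulate_dataset
from .sumstats import RegionPartition, summary_vector
from .trajectory import PriorSpec, SweepModelSpec

logger = logging.getLogger("sweepabc")

__all__ = [
    "ScenarioGrid",
    "CalibrationReport",
    "power_series",
    "f1_psdn_correlation",
    "calibration",
    "calibration_report",
    "robustness_misid",
    "robustness_bottleneck",
    "parameter_recovery",
]

MU_FIXED = 2.5e-8  # the mutation rate used throughout the simulation studies


@dataclass(frozen=True)
class ScenarioGrid:
    """A set of model-choice scenarios: each cell is (truth, alpha, f1, f_cur)
    with ``replicates`` datasets per cell."""

    alphas: tuple[float, ...] = (0.0, 100.0, 200.0, 1000.0)
    f1s: tuple[float, ...] = (0.05,)
    f_curs: tuple[float, ...] = (0.95,)
    truths: tuple[str, ...] = ("NT", "SDN", "SSV")
    replicates: int = 100

    def __post_init__(self) -> None:
        if self.replicates < 10:
            raise ValueError("need at least 10 replicates per cell")

    def cells(self) -> list[dict]:
        out = []
        for f_cur in self.f_curs:
            for truth in self.truths:
                if truth == "NT":
                    out.append(dict(truth="NT", alpha=0.0, f1=math.nan, f_cur=f_cur))
                    continue
                for alpha in self.alphas:
                    if alpha <= 0:
                        continue
                    if truth == "SSV":
                        for f1 in self.f1s:
                            out.append(dict(truth="SSV", alpha=alpha, f1=f1, f_cur=f_cur))
                    else:
                        out.append(dict(truth="SDN", alpha=alpha, f1=math.nan, f_cur=f_cur))
        return out


def _truth_spec(truth: str, alpha: float, f1: float, f_cur: float, N0: float) -> SweepModelSpec:
    s = alpha / (4.0 * N0)
    if truth == "NT":
        return SweepModelSpec(model="NT", f_cur=f_cur)
    if truth == "SDN":
        return SweepModelSpec(model="SDN", f_cur=f_cur, s=s)
    return SweepModelSpec(model="SSV", f_cur=f_cur, s=s, f1=f1)


def _ensure_refsets(
    f_curs: Sequence[float],
    refsets: Optional[dict[float, ReferenceSet]],
    priors: PriorSpec,
    config: SimulationConfig,
    n_sims: int,
    seed: int,
) -> dict[float, ReferenceSet]:
    refsets = dict(refsets or {})
    for i, f_cur in enumerate(sorted(set(f_curs))):
        if f_cur not in refsets:
            logger.info("building reference set for f_cur=%.3g", f_cur)
            refsets[f_cur] = ReferenceSet.build(
                ("NT", "SDN", "SSV"), f_cur, priors, config,
                n_sims=n_sims, seed=seed + 1000 * i,
            )
    return refsets


def power_series(
    grid: ScenarioGrid,
    priors: PriorSpec = PriorSpec(),
    config: SimulationConfig = SimulationConfig(),
    n_sims: int = 20_000,
    abc: ABCConfig = ABCConfig(),
    seed: int = 0,
    refsets: Optional[dict[float, ReferenceSet]] = None,
    mu: float = MU_FIXED,
) -> pd.DataFrame:
    """Model posteriors and correct-assignment fractions over a scenario grid.

    Returns one row per replicate with the three model posteriors and whether
    the true model attained the maximum; reference tables are shared across
    cells with the same conditioning frequency.
    """
    refsets = _ensure_refsets(grid.f_curs, refsets, priors, config, n_sims, seed)
    N0 = config.dem.N0
    rows = []
    rng = np.random.SeedSequence(seed + 99)
    for ci, cell in enumerate(grid.cells()):
        rs = refsets[cell["f_cur"]]
        spec = _truth_spec(cell["truth"], cell["alpha"], cell["f1"], cell["f_cur"], N0)
        for rep in range(grid.replicates):
            dseed = int(rng.generate_state(1)[0] % (2**31 - 1))
            rng = rng.spawn(1)[0]
            try:
                hap, _ = simulate_dataset(spec, mu, config, dseed)
                res = rs.infer(hap, abc, seed=dseed)
            except Exception as e:  # cell marked incomplete, not fatal
                logger.warning("cell %d rep %d failed: %s", ci, rep, e)
                continue
            p = res.model_probabilities
            rows.append({
                **cell, "rep": rep,
                "pr_NT": p.get("NT", np.nan),
                "pr_SDN": p.get("SDN", np.nan),
                "pr_SSV": p.get("SSV", np.nan),
                "correct": res.best_model == cell["truth"],
            })
    return pd.DataFrame(rows)


def power_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per-cell quartiles/median of the true-model posterior and the fraction
    of replicates assigned to the true model."""
    rows = []
    for (truth, alpha, f1, f_cur), g in df.groupby(
        ["truth", "alpha", "f1", "f_cur"], dropna=False
    ):
        p = g[f"pr_{truth}"]
        rows.append({
            "truth": truth, "alpha": alpha, "f1": f1, "f_cur": f_cur,
            "n": len(g),
            "q25": p.quantile(0.25), "median": p.median(), "q75": p.quantile(0.75),
            "fraction_correct": g["correct"].mean(),
        })
    return pd.DataFrame(rows)


def f1_psdn_correlation(
    n_datasets: int,
    refset: ReferenceSet,
    abc: ABCConfig = ABCConfig(),
    seed: int = 0,
    mu: float = MU_FIXED,
) -> dict:
    """Correlation between the estimated initial frequency f1 and Pr(SDN)
    across SSV-truth datasets drawn from the prior.

    Returns the OLS R^2, the slope, and the per-dataset table.  Refuses to
    report R^2 with fewer than 30 completed datasets.
    """
    rng = np.random.default_rng(seed)
    cfg = refset.config
    rows = []
    for i in range(n_datasets):
        spec, draws = refset.priors.sample("SSV", refset.f_cur, rng)
        dseed = int(rng.integers(1, 2**31 - 1))
        try:
            hap, traj = simulate_dataset(spec, draws["mu"], cfg, dseed)
            res = refset.infer(hap, abc, seed=dseed)
        except Exception as e:
            logger.warning("dataset %d failed: %s", i, e)
            continue
        rows.append({
            "true_f1": spec.f1,
            "f1_mode": res.posteriors["SSV"]["f1"].mode,
            "pr_SDN": res.model_probabilities["SDN"],
        })
    df = pd.DataFrame(rows)
    if len(df) < 30:
        raise RuntimeError(f"only {len(df)} datasets completed; refusing to report R^2")
    r2, slope = ols_r2_slope(df["f1_mode"].to_numpy(), df["pr_SDN"].to_numpy())
    return {"r2": r2, "slope": slope, "table": df}


def ols_r2_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary-least-squares R^2 and slope of y on x (0, 0 when degenerate)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return 0.0, 0.0
    slope, _, r, *_ = stats.linregress(x, y)
    return float(r**2), float(slope)


@dataclass
class CalibrationReport:
    """Observed vs expected SSV fraction per log10 Bayes-factor bin."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    counts: np.ndarray
    observed_fraction: np.ndarray
    expected_fraction: np.ndarray
    flagged: np.ndarray  # outside binomial 99% bounds

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.bin_centers,
            "count": self.counts,
            "observed_ssv_fraction": self.observed_fraction,
            "expected_ssv_fraction": self.expected_fraction,
            "flagged": self.flagged,
        })


def calibration_report(
    log10_bf: np.ndarray, is_ssv: np.ndarray, bin_edges: Optional[np.ndarray] = None
) -> CalibrationReport:
    """Bin log10 Bayes factors (SSV over SDN) and compare the observed
    SSV-truth fraction per bin with the expectation 10^c / (1 + 10^c)."""
    log10_bf = np.asarray(log10_bf, dtype=float)
    is_ssv = np.asarray(is_ssv, dtype=bool)
    if bin_edges is None:
        bin_edges = np.arange(-2.25, 2.26, 0.5)
    lo, hi = bin_edges[0], bin_edges[-1]
    clipped = np.clip(log10_bf, lo + 1e-9, hi - 1e-9)
    idx = np.digitize(clipped, bin_edges) - 1
    nb = len(bin_edges) - 1
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    counts = np.zeros(nb, dtype=int)
    obs = np.full(nb, np.nan)
    flagged = np.zeros(nb, dtype=bool)
    expected = 10.0**centers / (1.0 + 10.0**centers)
    for b in range(nb):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b] == 0:
            continue
        # expected fraction at the actual BFs in the bin, not the bin center
        pbar = float(np.mean(10.0 ** log10_bf[sel] / (1 + 10.0 ** log10_bf[sel])))
        expected[b] = pbar
        obs[b] = is_ssv[sel].mean()
        k = is_ssv[sel].sum()
        lo_b, hi_b = stats.binom.interval(0.99, counts[b], pbar)
        flagged[b] = not (lo_b <= k <= hi_b)
    return CalibrationReport(
        bin_edges=bin_edges, bin_centers=centers, counts=counts,
        observed_fraction=obs, expected_fraction=expected, flagged=flagged,
    )


def calibration(
    n_datasets: int,
    refset: ReferenceSet,
    abc: ABCConfig = ABCConfig(),
    seed: int = 0,
    bin_edges: Optional[np.ndarray] = None,
) -> tuple[CalibrationReport, pd.DataFrame]:
    """Full-pipeline Bayes-factor calibration: datasets drawn half/half from
    the SSV and SDN priors, each pushed through model choice."""
    rng = np.random.default_rng(seed)
    cfg = refset.config
    rows = []
    for i in range(n_datasets):
        truth = "SSV" if rng.random() < 0.5 else "SDN"
        spec, draws = refset.priors.sample(truth, refset.f_cur, rng)
        dseed = int(rng.integers(1, 2**31 - 1))
        try:
            hap, _ = simulate_dataset(spec, draws["mu"], cfg, dseed)
            res = refset.infer(hap, abc, seed=dseed)
        except Exception as e:
            logger.warning("calibration dataset %d failed: %s", i, e)
            continue
        rows.append({
            "truth": truth,
            "true_f1": spec.f1 if truth == "SSV" else np.nan,
            "log10_bf": res.bayes_factor("SSV", "SDN"),
        })
    df = pd.DataFrame(rows)
    rep = calibration_report(
        df["log10_bf"].to_numpy(), (df["truth"] == "SSV").to_numpy(), bin_edges
    )
    return rep, df


def _misid_matrix(hap, offset_target: float, f_cur: float):
    """Re-anchor the matrix at the polymorphic site nearest the offset target
    (preferring sites with frequency close to the conditioning f_cur)."""
    from .coalescent import HaplotypeMatrix

    counts = hap.derived_counts
    n = hap.n
    freqs = counts / n
    usable = (counts >= 1) & (counts <= n - 1)
    usable[hap.selected_index] = False
    idxs = np.nonzero(usable)[0]
    if len(idxs) == 0:
        raise ValueError("no alternative site available")
    d = np.abs(hap.positions[idxs] - offset_target)
    close_freq = np.abs(freqs[idxs] - f_cur) <= 0.1
    pool = idxs[close_freq] if close_freq.any() else idxs
    dp = np.abs(hap.positions[pool] - offset_target)
    new_sel = int(pool[np.argmin(dp)])
    return HaplotypeMatrix(
        alleles=hap.alleles, positions=hap.positions,
        selected_index=new_sel, length_bp=hap.length_bp,
    )


def robustness_misid(
    offsets_bp: Sequence[float],
    refset: ReferenceSet,
    truths: Sequence[str] = ("SDN", "SSV"),
    alpha: float = 1000.0,
    f1: float = 0.1,
    replicates: int = 50,
    abc: ABCConfig = ABCConfig(),
    seed: int = 0,
    mu: float = MU_FIXED,
) -> pd.DataFrame:
    """Model choice when the summary statistics are anchored at a site offset
    from the truly selected one."""
    cfg = refset.config
    N0 = cfg.dem.N0
    for off in offsets_bp:
        if not 0 <= cfg.selected_pos + off < cfg.length_bp:
            raise ValueError(f"offset {off} bp falls outside the region")
    rng = np.random.default_rng(seed)
    rows = []
    for truth in truths:
        spec = _truth_spec(truth, alpha, f1, refset.f_cur, N0)
        for rep in range(replicates):
            dseed = int(rng.integers(1, 2**31 - 1))
            hap, _ = simulate_dataset(spec, mu, cfg, dseed)
            for off in offsets_bp:
                try:
                    if off == 0:
                        h2 = hap
                    else:
                        h2 = _misid_matrix(hap, cfg.selected_pos + off, refset.f_cur)
                    partition = RegionPartition(focal_pos=h2.selected_pos)
                    sv = summary_vector(h2, partition)
                    res = refset.infer(sv, abc, seed=dseed)
                except Exception as e:
                    logger.warning("misid rep failed: %s", e)
                    continue
                p = res.model_probabilities
                rows.append({
                    "truth": truth, "offset_bp": off, "rep": rep,
                    "pr_NT": p["NT"], "pr_SDN": p["SDN"], "pr_SSV": p["SSV"],
                })
    return pd.DataFrame(rows)


def robustness_bottleneck(
    strengths: Sequence[float],
    refset: ReferenceSet,
    truths: Sequence[str] = ("SSV",),
    alpha: float = 1000.0,
    f1: float = 0.1,
    replicates: int = 50,
    abc: ABCConfig = ABCConfig(),
    seed: int = 0,
    mu: float = MU_FIXED,
    bottleneck_start: float = 400.0,
    bottleneck_duration: float = 2000.0,
) -> pd.DataFrame:
    """Data simulated under a bottleneck (started 400 generations ago, lasting
    2,000 generations), analysed with constant-size reference tables.
    ``strength`` is the bottleneck size as a fraction of N0 (1 = none)."""
    cfg = refset.config
    N0 = cfg.dem.N0
    rng = np.random.default_rng(seed)
    rows = []
    for truth in truths:
        for strength in strengths:
            dem = Demography.bottleneck(
                N0, strength, start=bottleneck_start, duration=bottleneck_duration,
                generation_years=cfg.dem.generation_years,
            )
            sim_cfg = SimulationConfig(
                n=cfg.n, length_bp=cfg.length_bp, selected_pos=cfg.selected_pos,
                rmap=cfg.rmap, dem=dem, dt=cfg.dt, max_horizon=cfg.max_horizon,
            )
            spec = _truth_spec(truth, alpha, f1, refset.f_cur, N0)
            for rep in range(replicates):
                dseed = int(rng.integers(1, 2**31 - 1))
                try:
                    hap, _ = simulate_dataset(spec, mu, sim_cfg, dseed)
                    res = refset.infer(hap, abc, seed=dseed)
                except Exception as e:
                    logger.warning("bottleneck rep failed: %s", e)
                    continue
                p = res.model_probabilities
                best_sel = "SDN" if p["SDN"] >= p["SSV"] else "SSV"
                s_mode = 10.0 ** res.posteriors[best_sel]["log10_s"].mode
                rows.append({
                    "truth": truth, "strength": strength, "rep": rep,
                    "pr_NT": p["NT"], "pr_SDN": p["SDN"], "pr_SSV": p["SSV"],
                    "s_mode": s_mode,
                })
    return pd.DataFrame(rows)


def parameter_recovery(
    truth: SweepModelSpec,
    refset: ReferenceSet,
    replicates: int = 100,
    abc: ABCConfig = ABCConfig(),
    seed: int = 0,
    mu: float = MU_FIXED,
) -> dict:
    """Across-replicate averaged posteriors plus bias/RMSE of the mode for
    each parameter of the truth's model."""
    cfg = refset.config
    rng = np.random.default_rng(seed)
    model = truth.model
    grids = refset.grids(model)
    acc: dict[str, list[np.ndarray]] = {k: [] for k in grids}
    modes: dict[str, list[float]] = {k: [] for k in grids}
    for rep in range(replicates):
        dseed = int(rng.integers(1, 2**31 - 1))
        hap, _ = simulate_dataset(truth, mu, cfg, dseed)
        res = refset.infer(hap, abc, seed=dseed)
        for k, pd_ in res.posteriors[model].items():
            acc[k].append(pd_.density)
            modes[k].append(pd_.mode)
    out: dict[str, dict] = {}
    true_vals = {
        "mu": mu,
        "log10_s": math.log10(truth.s) if truth.s > 0 else math.nan,
        "f1": truth.f1 if truth.f1 is not None else math.nan,
    }
    for k in grids:
        dens = np.mean(np.array(acc[k]), axis=0)
        m = np.array(modes[k])
        entry = {
            "grid": grids[k], "mean_density": dens, "modes": m,
            "mode_mean": float(m.mean()),
        }
        if k in true_vals and np.isfinite(true_vals[k]):
            entry["true"] = true_vals[k]
            entry["bias"] = float(m.mean() - true_vals[k])
            entry["rmse"] = float(np.sqrt(np.mean((m - true_vals[k]) ** 2)))
        if k == "f1":
            # prior closeness: TV distance between the averaged posterior and
            # the flat prior on the grid
            g = grids[k]
            flat = np.full_like(g, 1.0 / (g[-1] - g[0]))
            z = np.trapezoid(dens, g)
            entry["tv_vs_prior"] = float(
                0.5 * np.trapezoid(np.abs(dens / z - flat), g)
            )
        out[k] = entry
    return out
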