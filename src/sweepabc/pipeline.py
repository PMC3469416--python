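"""Reference-table construction and the end-to-end inference pipeline.

A :class:`ReferenceSet` bundles, for one conditioning frequency ``f_cur``:
per-model reference tables (parameter draws, realized latent times, the 16 raw
statistics) and the transform pipeline fitted once on the pooled tables.  It
is the reusable, serializable object behind both the validation experiments
and observed-data inference.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coalescent import (
    CoalescentError,
    HaplotypeMatrix,
    RecombinationMap,
    RegionSpec,
    simulate_haplotypes,
)
from .demography import Demography
from .inference import ABCConfig, PosteriorResult, model_posterior
from .sumstats import STAT_NAMES, RegionPartition, SummaryVector, summary_vector
from .trajectory import (
    PriorSpec,
    SweepModelSpec,
    Trajectory,
    TrajectoryError,
    simulate_trajectory,
)
from .transform import TransformPipeline

logger = logging.getLogger("sweepabc")

__all__ = ["SimulationConfig", "ReferenceTable", "ReferenceSet", "build_reference_table"]


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, sample size and demography of the simulated datasets.

    Defaults are the simulation-study conditions: n = 100 haplotypes from a
    constant N = 10,000 population, a 150 kb region at 1.5 cM/Mb with the
    selected site at the centre.
    """

    n: int = 100
    length_bp: float = 150_000.0
    selected_pos: float = 75_000.0
    rmap: RecombinationMap = field(default_factory=lambda: RecombinationMap.constant(1.5))
    dem: Demography = field(default_factory=lambda: Demography.constant(10_000))
    dt: Optional[float] = None
    max_horizon: float = 2.0e6

    def region(self, mu: float) -> RegionSpec:
        return RegionSpec(
            length_bp=self.length_bp, selected_pos=self.selected_pos,
            n=self.n, mu=mu,
        )

    def partition(self) -> RegionPartition:
        return RegionPartition(focal_pos=self.selected_pos)


# parameters on their estimation scale, per model
MODEL_PARAMS = {
    "NT": ("mu",),
    "SDN": ("mu", "log10_s", "log10_t0"),
    "SSV": ("mu", "log10_s", "f1", "log10_t0", "log10_t1"),
}


def simulate_dataset(
    spec: SweepModelSpec,
    mu: float,
    config: SimulationConfig,
    seed: int,
    inference_dem: Optional[Demography] = None,
) -> tuple[HaplotypeMatrix, Trajectory]:
    """One dataset: trajectory then haplotypes.  ``inference_dem`` is unused
    here but mirrors the truth/inference split used in robustness studies."""
    ss = np.random.SeedSequence(seed)
    s_traj, s_hap = [int(x % (2**31 - 1)) for x in ss.generate_state(2)]
    traj = simulate_trajectory(
        spec, config.dem, dt=config.dt, seed=s_traj, max_horizon=config.max_horizon
    )
    hap = simulate_haplotypes(
        traj, config.region(mu), config.rmap, config.dem, seed=s_hap
    )
    return hap, traj


@dataclass
class ReferenceTable:
    """Per-model collection of parameter draws, latent times and raw
    statistics (one row per simulation)."""

    model: str
    f_cur: float
    table: pd.DataFrame  # param columns + t0 [+ t1] + the 16 stats
    n_sims: int
    seed: int
    n_failures: int = 0

    @property
    def stats(self) -> np.ndarray:
        return self.table[list(STAT_NAMES)].to_numpy(dtype=float)

    def theta(self, dt_floor: float = 1.0) -> tuple[np.ndarray, tuple[str, ...]]:
        """Parameter matrix on the estimation scale for the GLM."""
        names = MODEL_PARAMS[self.model]
        cols = []
        for nm in names:
            if nm == "mu":
                cols.append(self.table["mu"].to_numpy(float))
            elif nm == "log10_s":
                cols.append(self.table["log10_s"].to_numpy(float))
            elif nm == "f1":
                cols.append(self.table["f1"].to_numpy(float))
            elif nm == "log10_t0":
                cols.append(np.log10(np.maximum(self.table["t0"].to_numpy(float), dt_floor)))
            elif nm == "log10_t1":
                cols.append(np.log10(np.maximum(self.table["t1"].to_numpy(float), dt_floor)))
        return np.column_stack(cols), names

    def save(self, path: str | Path) -> None:
        import pyarrow as pa
        import pyarrow.parquet as pq

        t = pa.Table.from_pandas(self.table, preserve_index=False)
        meta = {
            b"sweepabc.model": self.model.encode(),
            b"sweepabc.f_cur": str(self.f_cur).encode(),
            b"sweepabc.n_sims": str(self.n_sims).encode(),
            b"sweepabc.seed": str(self.seed).encode(),
            b"sweepabc.n_failures": str(self.n_failures).encode(),
        }
        t = t.replace_schema_metadata({**(t.schema.metadata or {}), **meta})
        pq.write_table(t, path)

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceTable":
        import pyarrow.parquet as pq

        t = pq.read_table(path)
        md = t.schema.metadata or {}
        return cls(
            model=md[b"sweepabc.model"].decode(),
            f_cur=float(md[b"sweepabc.f_cur"].decode()),
            table=t.to_pandas(),
            n_sims=int(md[b"sweepabc.n_sims"].decode()),
            seed=int(md[b"sweepabc.seed"].decode()),
            n_failures=int(md[b"sweepabc.n_failures"].decode()),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_reference_table(
    model: str,
    f_cur: float,
    priors: PriorSpec,
    config: SimulationConfig,
    n_sims: int,
    seed: int,
    max_retries: int = 10,
    progress: bool = False,
) -> ReferenceTable:
    """Draw from the prior, simulate, summarize — ``n_sims`` times."""
    if model not in MODEL_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_sims)
    partition = config.partition()
    rows = []
    n_fail = 0
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        row = None
        for attempt in range(max_retries):
            try:
                spec, draws = priors.sample(model, f_cur, rng)
                dseed = int(rng.integers(1, 2**31 - 1))
                hap, traj = simulate_dataset(spec, draws["mu"], config, dseed)
                sv = summary_vector(hap, partition)
                row = {**draws, "t0": traj.t0,
                       **({"t1": traj.t1} if traj.t1 is not None else {}),
                       **sv.as_dict()}
                break
            except (TrajectoryError, CoalescentError) as e:
                n_fail += 1
                logger.debug("sim %d attempt %d failed: %s", i, attempt, e)
        if row is None:
            raise RuntimeError(
                f"simulation {i} failed {max_retries} times; giving up"
            )
        rows.append(row)
        if progress and (i + 1) % 500 == 0:
            logger.info("%s reference table: %d/%d", model, i + 1, n_sims)
    table = pd.DataFrame(rows)
    if n_fail:
        logger.info("%s reference table: %d retried failures", model, n_fail)
    return ReferenceTable(
        model=model, f_cur=f_cur, table=table, n_sims=n_sims, seed=seed,
        n_failures=n_fail,
    )


class ReferenceSet:
    """Reference tables for the candidate models plus the frozen transform."""

    def __init__(
        self,
        tables: dict[str, ReferenceTable],
        transform: TransformPipeline,
        config: SimulationConfig,
        priors: PriorSpec,
    ):
        self.tables = tables
        self.transform = transform
        self.config = config
        self.priors = priors
        self._components: dict[str, np.ndarray] = {}
        self._nn_thresholds: dict[tuple[str, float], float] = {}

    @property
    def f_cur(self) -> float:
        return next(iter(self.tables.values())).f_cur

    @property
    def models(self) -> tuple[str, ...]:
        return tuple(sorted(self.tables))

    @classmethod
    def build(
        cls,
        models: Sequence[str],
        f_cur: float,
        priors: PriorSpec,
        config: SimulationConfig,
        n_sims: int,
        seed: int,
        n_components: int = 5,
        progress: bool = False,
    ) -> "ReferenceSet":
        ss = np.random.SeedSequence(seed)
        seeds = [int(s % (2**31 - 1)) for s in ss.generate_state(len(models))]
        tables = {
            m: build_reference_table(
                m, f_cur, priors, config, n_sims, sd, progress=progress
            )
            for m, sd in zip(models, seeds)
        }
        pooled = np.vstack([t.stats for t in tables.values()])
        labels = np.concatenate(
            [[m] * len(t.table) for m, t in tables.items()]
        )
        tp = TransformPipeline().fit(pooled, labels, k=n_components)
        return cls(tables=tables, transform=tp, config=config, priors=priors)

    def components(self, model: str) -> np.ndarray:
        if model not in self._components:
            self._components[model] = self.transform.transform(self.tables[model].stats)
        return self._components[model]

    def observed_components(self, sv: SummaryVector | np.ndarray) -> np.ndarray:
        vals = sv.values if isinstance(sv, SummaryVector) else np.asarray(sv, float)
        return self.transform.transform(vals.reshape(1, -1))[0]

    def grids(self, model: str, grid_points: int = 101) -> dict[str, np.ndarray]:
        """Per-parameter posterior grids: prior support for mu/log10_s/f1,
        the accepted-range hull for the latent times (log scale)."""
        g: dict[str, np.ndarray] = {}
        theta, names = self.tables[model].theta()
        pr = self.priors
        for j, nm in enumerate(names):
            if nm == "mu":
                g[nm] = np.linspace(pr.mu_range[0], pr.mu_range[1], grid_points)
            elif nm == "log10_s":
                g[nm] = np.linspace(pr.log10_s_range[0], pr.log10_s_range[1], grid_points)
            elif nm == "f1":
                lo = max(pr.f1_range[0], 1e-4)
                g[nm] = np.linspace(lo, pr.f1_range[1], grid_points)
            else:  # latent times: span of the realized draws, padded 10%
                lo, hi = theta[:, j].min(), theta[:, j].max()
                pad = 0.1 * (hi - lo) + 1e-9
                g[nm] = np.linspace(lo - pad, hi + pad, grid_points)
        return g

    def infer(
        self,
        observed: SummaryVector | HaplotypeMatrix | np.ndarray,
        config: ABCConfig = ABCConfig(),
        seed: int | None = 0,
    ) -> PosteriorResult:
        """Model probabilities and adjusted posteriors for one observation."""
        if isinstance(observed, HaplotypeMatrix):
            observed = summary_vector(observed, self.config.partition())
        obs = self.observed_components(observed)
        tabs = {}
        thresholds = {}
        for m in self.models:
            theta, names = self.tables[m].theta()
            tabs[m] = (theta, self.components(m), names,
                       self.grids(m, config.grid_points))
            thresholds[m] = self._nn_threshold(m, config.poor_fit_quantile)
        return model_posterior(tabs, obs, config=config, seed=seed,
                               nn_thresholds=thresholds)

    def _nn_threshold(self, model: str, quantile: float) -> float:
        key = (model, quantile)
        if key not in self._nn_thresholds:
            from .inference import _poor_fit_threshold

            self._nn_thresholds[key] = _poor_fit_threshold(
                self.components(model), quantile, np.random.default_rng(0)
            )
        return self._nn_thresholds[key]

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for m, t in self.tables.items():
            t.save(d / f"ref_{m}.parquet")
        self.transform.save(d / "transform.json")
        meta = {
            "models": list(self.models),
            "f_cur": self.f_cur,
            "config": {
                "n": self.config.n,
                "length_bp": self.config.length_bp,
                "selected_pos": self.config.selected_pos,
                "rmap_breakpoints": list(self.config.rmap.breakpoints),
                "rmap_rates": list(self.config.rmap.rates),
                "dem_epochs": [list(e) for e in self.config.dem.epochs],
                "dt": self.config.dt,
                "max_horizon": self.config.max_horizon,
            },
            "priors": {
                "mu_range": list(self.priors.mu_range),
                "log10_s_range": list(self.priors.log10_s_range),
                "f1_range": list(self.priors.f1_range),
                "h_range": list(self.priors.h_range) if self.priors.h_range else None,
            },
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceSet":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        tables = {
            m: ReferenceTable.load(d / f"ref_{m}.parquet") for m in meta["models"]
        }
        cfg = meta["config"]
        config = SimulationConfig(
            n=cfg["n"], length_bp=cfg["length_bp"], selected_pos=cfg["selected_pos"],
            rmap=RecombinationMap(
                breakpoints=tuple(cfg["rmap_breakpoints"]), rates=tuple(cfg["rmap_rates"])
            ),
            dem=Demography(epochs=tuple(tuple(e) for e in cfg["dem_epochs"])),
            dt=cfg["dt"], max_horizon=cfg["max_horizon"],
        )
        pr = meta["priors"]
        priors = PriorSpec(
            mu_range=tuple(pr["mu_range"]),
            log10_s_range=tuple(pr["log10_s_range"]),
            f1_range=tuple(pr["f1_range"]),
            h_range=tuple(pr["h_range"]) if pr["h_range"] else None,
        )
        return cls(
            tables=tables,
            transform=TransformPipeline.load(d / "transform.json"),
            config=config,
            priors=priors,
        )
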