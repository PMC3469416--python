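"""Haplotype simulation for a recombining region conditional on a focal-site
trajectory (two-background structured coalescent, mbs-style)."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._coalcore import MASKW, sim_kernel
from .demography import Demography
from .trajectory import Trajectory

__all__ = [
    "RecombinationMap",
    "RegionSpec",
    "HaplotypeMatrix",
    "sample_focal_counts",
    "simulate_haplotypes",
    "CoalescentError",
]

MAX_SAMPLES = 64 * MASKW  # bitmask capacity of the kernel


class CoalescentError(RuntimeError):
    pass


@dataclass(frozen=True)
class RecombinationMap:
    """Piecewise-constant recombination map.

    ``breakpoints`` are 0-based interval start positions in bp (strictly
    increasing, first must be 0); ``rates`` the cM/Mb rate on each half-open
    interval ``[b_i, b_{i+1})``; the last interval extends indefinitely.
    """

    breakpoints: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints)
        rt = tuple(float(r) for r in self.rates)
        if len(bp) != len(rt) or len(bp) == 0:
            raise ValueError("breakpoints and rates must be same non-zero length")
        if bp[0] != 0:
            raise ValueError("first breakpoint must be 0")
        if any(b >= c for b, c in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(r < 0 for r in rt):
            raise ValueError("rates must be >= 0")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "rates", rt)

    @classmethod
    def constant(cls, rate_cM_Mb: float) -> "RecombinationMap":
        return cls(breakpoints=(0.0,), rates=(float(rate_cM_Mb),))

    def cumulative_arrays(self, length_bp: float) -> tuple[np.ndarray, np.ndarray]:
        """Knot positions (bp) and cumulative Morgans over ``[0, length_bp]``."""
        bps = [b for b in self.breakpoints if 0.0 < b < length_bp]
        knots = np.array([0.0] + bps + [float(length_bp)])
        cum = np.zeros_like(knots)
        for i in range(1, len(knots)):
            # rate on [knots[i-1], knots[i]) is the map rate at knots[i-1]
            j = np.searchsorted(self.breakpoints, knots[i - 1], side="right") - 1
            rate_m_per_bp = self.rates[j] * 1e-8  # cM/Mb -> Morgans/bp
            cum[i] = cum[i - 1] + rate_m_per_bp * (knots[i] - knots[i - 1])
        return knots, cum

    def total_morgans(self, length_bp: float) -> float:
        return float(self.cumulative_arrays(length_bp)[1][-1])


@dataclass(frozen=True)
class RegionSpec:
    """Simulated region geometry and mutation rate."""

    length_bp: float
    selected_pos: float
    n: int
    mu: float

    def __post_init__(self) -> None:
        if not 0 <= self.selected_pos < self.length_bp:
            raise ValueError("selected_pos must lie inside the region")
        if self.n < 2:
            raise ValueError("need at least two haplotypes")
        if self.n > MAX_SAMPLES:
            raise ValueError(f"sample size limited to {MAX_SAMPLES} haplotypes")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


class HaplotypeMatrix:
    """Phased binary haplotypes over a region (0 = ancestral, 1 = derived).

    ``alleles`` is an (n x S) uint8 matrix; ``positions`` the bp coordinate of
    each column (strictly increasing); ``selected_index`` the focal-site column
    (or -1 when absent).
    """

    def __init__(
        self,
        alleles: np.ndarray,
        positions: np.ndarray,
        selected_index: int,
        length_bp: Optional[float] = None,
    ):
        alleles = np.ascontiguousarray(alleles, dtype=np.uint8)
        positions = np.asarray(positions, dtype=np.float64)
        if alleles.ndim != 2 or alleles.shape[1] != len(positions):
            raise ValueError("alleles must be n x len(positions)")
        if len(positions) > 1 and np.any(np.diff(positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all((alleles == 0) | (alleles == 1)):
            raise ValueError("alleles must be 0/1")
        if selected_index >= len(positions):
            raise ValueError("selected_index out of range")
        self.alleles = alleles
        self.positions = positions
        self.selected_index = int(selected_index)
        self.length_bp = float(length_bp) if length_bp is not None else (
            float(positions[-1]) + 1.0 if len(positions) else 1.0
        )

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def derived_counts(self) -> np.ndarray:
        return self.alleles.sum(axis=0).astype(np.int64)

    @property
    def selected_pos(self) -> float:
        if self.selected_index < 0:
            raise ValueError("no focal column")
        return float(self.positions[self.selected_index])

    @property
    def focal_derived_count(self) -> int:
        return int(self.derived_counts[self.selected_index])

    def __eq__(self, other) -> bool:  # round-trip identity for tests
        return (
            isinstance(other, HaplotypeMatrix)
            and self.selected_index == other.selected_index
            and self.alleles.shape == other.alleles.shape
            and np.array_equal(self.alleles, other.alleles)
            and np.allclose(self.positions, other.positions, atol=1e-6)
        )


def sample_focal_counts(
    n: int, f_cur: float, seed: int | np.random.Generator | None = None
) -> tuple[int, int]:
    """Binomial(n, f_cur) focal-site sample allocation truncated to [1, n-1]."""
    if not 0.0 < f_cur < 1.0:
        raise ValueError("f_cur must be in (0,1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(10000):
        k = int(rng.binomial(n, f_cur))
        if 1 <= k <= n - 1:
            return k, n - k
    k = min(n - 1, max(1, int(round(n * f_cur))))  # pragma: no cover
    return k, n - k


def _decode_masks(masks: np.ndarray, n: int) -> np.ndarray:
    """(m x MASKW) uint64 bitmasks -> (n x m) uint8 allele matrix."""
    m = masks.shape[0]
    out = np.zeros((n, m), dtype=np.uint8)
    for i in range(n):
        w, b = divmod(i, 64)
        out[i] = ((masks[:, w] >> np.uint64(b)) & np.uint64(1)).astype(np.uint8)
    return out


def simulate_haplotypes(
    traj: Trajectory,
    region: RegionSpec,
    rmap: RecombinationMap,
    dem: Demography,
    seed: int | None = None,
    n_derived: Optional[int] = None,
    max_events: int = 2_000_000,
) -> HaplotypeMatrix:
    """Simulate a haplotype matrix conditional on the focal-site trajectory.

    The number of sampled derived haplotypes is drawn by
    :func:`sample_focal_counts` unless ``n_derived`` is given.
    """
    rng = np.random.default_rng(seed)
    if n_derived is None:
        n_der, n_anc = sample_focal_counts(region.n, traj.f_cur, rng)
    else:
        n_der = int(n_derived)
        n_anc = region.n - n_der
        if not (1 <= n_der <= region.n - 1) and not (
            n_der == region.n and n_anc == 0
        ):
            raise ValueError("n_derived must be in [1, n-1] (or n for pinned mode)")

    map_bp, map_M = rmap.cumulative_arrays(region.length_bp)
    ep_starts, ep_N = dem.as_arrays()
    n = region.n

    # expected segregating sites drive the buffer sizes
    theta = 4.0 * dem.N0 * region.mu * region.length_bp
    harm = sum(1.0 / i for i in range(1, n)) if n > 1 else 1.0
    exp_S = theta * harm
    rho_tot = 4.0 * dem.N0 * rmap.total_morgans(region.length_bp)
    max_seg = int(4096 + 64 * n + 32 * rho_tot)
    max_mut = int(2048 + 8 * exp_S)

    kseed = int(rng.integers(1, 2**31 - 1))
    for attempt in range(6):
        seg_l = np.empty(max_seg)
        seg_r = np.empty(max_seg)
        seg_mask = np.zeros((max_seg, MASKW), dtype=np.uint64)
        seg_birth = np.empty(max_seg)
        seg_next = np.empty(max_seg, dtype=np.int64)
        mut_pos = np.empty(max_mut)
        mut_mask = np.zeros((max_mut, MASKW), dtype=np.uint64)
        n_mut, status, events, t_end = sim_kernel(
            np.uint32(kseed), traj.freqs, traj.dt, ep_starts, ep_N,
            n_der, n_anc, float(region.length_bp), float(region.selected_pos),
            map_bp, map_M, region.mu,
            seg_l, seg_r, seg_mask, seg_birth, seg_next,
            mut_pos, mut_mask, max_events,
        )
        if status == 0:
            break
        if status in (1, 2):
            max_seg *= 2
        elif status == 3:
            max_mut *= 2
        else:
            raise CoalescentError(
                f"coalescent simulation failed (status {status}, events {events}); "
                "the numerical budget was exhausted before all lineages coalesced"
            )
    else:
        raise CoalescentError("coalescent buffers kept overflowing")

    pos = mut_pos[:n_mut]
    masks = mut_mask[:n_mut]
    # infinite-sites positions at 0.1 bp resolution, de-duplicated
    pos = np.round(pos, 1)
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    masks = masks[order]
    keep = np.ones(len(pos), dtype=bool)
    if len(pos) > 1:
        keep[1:] = np.diff(pos) > 0
    # make room for the focal column
    keep &= pos != round(region.selected_pos, 1)
    pos = pos[keep]
    masks = masks[keep]

    alleles = _decode_masks(masks, n)
    focal_col = np.zeros((n, 1), dtype=np.uint8)
    focal_col[:n_der, 0] = 1
    fpos = round(float(region.selected_pos), 1)
    ins = int(np.searchsorted(pos, fpos))
    alleles = np.concatenate([alleles[:, :ins], focal_col, alleles[:, ins:]], axis=1)
    positions = np.concatenate([pos[:ins], [fpos], pos[ins:]])
    return HaplotypeMatrix(
        alleles=alleles,
        positions=positions,
        selected_index=ins,
        length_bp=region.length_bp,
    )
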