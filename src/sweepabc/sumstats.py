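"""The 16-statistic summary of a haplotype region.

Four SFS statistics (Tajima's D, Fay & Wu's H, pi, S) are computed in three
concentric distance bands around the focal site — central (within 10 kb each
side), intermediate (10-50 kb) and faraway (> 50 kb) — plus extended haplotype
homozygosity (EHH) of the derived-allele carriers in 10/20/50 kb windows
centred on the focal site, and an (unstandardized) iHS.

Undefined statistics are reported as NaN, never as silent zeros.  The focal
column itself is excluded from the SFS statistics: it is conditioned on, not
random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .coalescent import HaplotypeMatrix

__all__ = [
    "RegionPartition",
    "SummaryVector",
    "STAT_NAMES",
    "pi_and_S",
    "tajimas_d",
    "fay_wu_h",
    "ehh",
    "ihs",
    "summary_vector",
]

STAT_NAMES = (
    "pi_central", "pi_intermediate", "pi_faraway",
    "S_central", "S_intermediate", "S_faraway",
    "D_central", "D_intermediate", "D_faraway",
    "H_central", "H_intermediate", "H_faraway",
    "EHH_10kb", "EHH_20kb", "EHH_50kb",
    "iHS",
)

REGIONS = ("central", "intermediate", "faraway")


@dataclass(frozen=True)
class RegionPartition:
    """Distance bands (bp from the focal site): central = [0, inner],
    intermediate = (inner, outer], faraway = (outer, inf).  The bands are
    disjoint and exhaustive so pi and S are additive across them."""

    focal_pos: float
    inner: float = 10_000.0
    outer: float = 50_000.0

    def __post_init__(self) -> None:
        if not 0 < self.inner < self.outer:
            raise ValueError("need 0 < inner < outer")

    def region_mask(self, positions: np.ndarray, region: str) -> np.ndarray:
        d = np.abs(np.asarray(positions, dtype=float) - self.focal_pos)
        if region == "central":
            return d <= self.inner
        if region == "intermediate":
            return (d > self.inner) & (d <= self.outer)
        if region == "faraway":
            return d > self.outer
        raise ValueError(f"unknown region {region!r}")


def _region_counts(h: HaplotypeMatrix, mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Derived counts of the polymorphic, non-focal columns in the region."""
    mask = np.asarray(mask, dtype=bool).copy()
    if h.selected_index >= 0:
        mask[h.selected_index] = False
    c = h.derived_counts[mask]
    poly = (c > 0) & (c < h.n)
    return c[poly], h.n


def pi_and_S(h: HaplotypeMatrix, mask: np.ndarray) -> tuple[float, int]:
    """Mean pairwise differences and segregating sites over the masked columns."""
    c, n = _region_counts(h, mask)
    S = int(len(c))
    pi = float((2.0 * c * (n - c) / (n * (n - 1))).sum())
    return pi, S


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(h: HaplotypeMatrix, mask: np.ndarray) -> float:
    c, n = _region_counts(h, mask)
    S = len(c)
    if S == 0 or n < 3:
        return math.nan
    pi = float((2.0 * c * (n - c) / (n * (n - 1))).sum())
    a1 = sum(1.0 / i for i in range(1, n))
    e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi - S / a1) / math.sqrt(var)


def fay_wu_h(h: HaplotypeMatrix, mask: np.ndarray) -> float:
    """theta_pi - theta_H; needs ancestral polarity (derived = 1)."""
    c, n = _region_counts(h, mask)
    if len(c) == 0:
        return math.nan
    theta_pi = float((2.0 * c * (n - c) / (n * (n - 1))).sum())
    theta_H = float((2.0 * c.astype(float) ** 2 / (n * (n - 1))).sum())
    return theta_pi - theta_H


@njit(cache=True)
def _refine_groups(codes: np.ndarray, col: np.ndarray) -> float:
    """Split haplotype groups by one more column (in place); returns the
    resulting homozygosity sum(k_g (k_g - 1)) / (K (K-1))."""
    K = codes.shape[0]
    for i in range(K):
        codes[i] = codes[i] * 2 + np.int64(col[i])
    order = np.argsort(codes)
    # compact relabel + pair count
    pairs = 0.0
    run = 1
    prev = codes[order[0]]
    label = 0
    codes[order[0]] = 0
    for ii in range(1, K):
        c = codes[order[ii]]
        if c == prev:
            run += 1
        else:
            pairs += run * (run - 1)
            run = 1
            label += 1
            prev = c
        codes[order[ii]] = label
    pairs += run * (run - 1)
    return pairs / (K * (K - 1))


def _homozygosity(rows: np.ndarray) -> float:
    """Probability two distinct random rows are identical."""
    K = rows.shape[0]
    if K < 2:
        return math.nan
    if rows.shape[1] == 0:
        return 1.0
    codes = np.zeros(K, dtype=np.int64)
    e = 1.0
    for j in range(rows.shape[1]):
        e = _refine_groups(codes, rows[:, j])
        if e == 0.0:
            break
    return e


def ehh(h: HaplotypeMatrix, scale_bp: float, core: int = 1) -> float:
    """EHH of the ``core``-allele carriers (1 = derived) in a window of total
    width ``scale_bp`` centred on the focal site."""
    if h.selected_index < 0:
        raise ValueError("haplotype matrix has no focal column")
    carriers = h.alleles[:, h.selected_index] == core
    if carriers.sum() < 2:
        return math.nan
    half = scale_bp / 2.0
    d = np.abs(h.positions - h.selected_pos)
    win = (d <= half)
    win[h.selected_index] = False
    return _homozygosity(h.alleles[np.ix_(carriers, win)])


def _ihh_one_side(rows: np.ndarray, dists: np.ndarray, threshold: float) -> tuple[float, bool]:
    """Area under the one-sided EHH decay curve (trapezoid over bp distance),
    integrating outward until EHH < threshold or the sites run out.
    Returns (area, truncated)."""
    K = rows.shape[0]
    order = np.argsort(dists, kind="stable")
    codes = np.zeros(K, dtype=np.int64)
    prev_d = 0.0
    prev_e = 1.0
    area = 0.0
    for j in order:
        e = _refine_groups(codes, rows[:, j])
        d = float(dists[j])
        area += 0.5 * (prev_e + e) * (d - prev_d)
        prev_d, prev_e = d, e
        if e < threshold:
            return area, False
    return area, True


def ihs(h: HaplotypeMatrix, threshold: float = 0.05) -> tuple[float, bool]:
    """Unstandardized iHS: ln(iHH_ancestral / iHH_derived), where iHH is the
    area under the EHH decay curve integrated outward (both directions) from
    the focal site until EHH < ``threshold`` or the region edge.

    Returns ``(value, truncated)``; ``truncated`` is set when either decay
    curve never dropped below the threshold before the region edge.  NaN when
    either allele has fewer than two carriers.
    """
    if h.selected_index < 0:
        raise ValueError("haplotype matrix has no focal column")
    focal_alleles = h.alleles[:, h.selected_index]
    truncated = False
    ihh = {}
    for core in (0, 1):
        carriers = focal_alleles == core
        if carriers.sum() < 2:
            return math.nan, False
        rows = h.alleles[carriers]
        areas = 0.0
        for side in ("left", "right"):
            if side == "left":
                sel = h.positions < h.selected_pos
                dists = h.selected_pos - h.positions[sel]
            else:
                sel = h.positions > h.selected_pos
                dists = h.positions[sel] - h.selected_pos
            a, trunc = _ihh_one_side(rows[:, sel], dists, threshold)
            areas += a
            truncated |= trunc
        ihh[core] = areas
    if ihh[1] <= 0 or ihh[0] <= 0:
        return math.nan, truncated
    return float(np.log(ihh[0] / ihh[1])), truncated


@dataclass
class SummaryVector:
    """The 16 named statistics; undefined entries are NaN."""

    values: np.ndarray
    ihs_truncated: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(STAT_NAMES),):
            raise ValueError(f"expected {len(STAT_NAMES)} values")

    def __getitem__(self, name: str) -> float:
        return float(self.values[STAT_NAMES.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(STAT_NAMES, map(float, self.values)))

    def to_tsv(self, header: bool = True) -> str:
        lines = []
        if header:
            lines.append("\t".join(STAT_NAMES))
        lines.append("\t".join(f"{v:.10g}" for v in self.values))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "SummaryVector":
        lines = [l for l in text.strip().splitlines() if l.strip()]
        if len(lines) == 2 and not lines[0].lstrip("-").replace(".", "").replace(
            "\t", ""
        ).replace("e", "").replace("+", "").isdigit():
            names = lines[0].split("\t")
            vals = dict(zip(names, (float(v) for v in lines[1].split("\t"))))
            return cls(values=np.array([vals[n] for n in STAT_NAMES]))
        return cls(values=np.array([float(v) for v in lines[-1].split("\t")]))


def summary_vector(
    h: HaplotypeMatrix, partition: Optional[RegionPartition] = None
) -> SummaryVector:
    """Assemble all 16 statistics for one region."""
    if partition is None:
        partition = RegionPartition(focal_pos=h.selected_pos)
    vals = np.full(len(STAT_NAMES), np.nan)
    for ri, region in enumerate(REGIONS):
        mask = partition.region_mask(h.positions, region)
        pi, S = pi_and_S(h, mask)
        vals[STAT_NAMES.index(f"pi_{region}")] = pi
        vals[STAT_NAMES.index(f"S_{region}")] = S
        vals[STAT_NAMES.index(f"D_{region}")] = tajimas_d(h, mask)
        vals[STAT_NAMES.index(f"H_{region}")] = fay_wu_h(h, mask)
    for scale in (10_000, 20_000, 50_000):
        vals[STAT_NAMES.index(f"EHH_{scale//1000}kb")] = ehh(h, scale)
    ihs_val, trunc = ihs(h)
    vals[STAT_NAMES.index("iHS")] = ihs_val
    return SummaryVector(values=vals, ihs_truncated=trunc)
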