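"""Observed-data ingestion and fixture generation.

Reads phased biallelic VCF regions with ancestral-allele polarization (INFO/AA
tag or a two-column position->base table), HapMap-format recombination maps,
and writes small self-contained fixture datasets (VCF + map + expected
statistics) generated by the simulator so the observed-data path is testable
offline end to end.

Coordinates are 0-based half-open internally; 1-based only in VCF records.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .coalescent import HaplotypeMatrix, RecombinationMap, RegionSpec, simulate_haplotypes
from .demography import Demography
from .sumstats import RegionPartition, summary_vector
from .trajectory import SweepModelSpec, simulate_trajectory

logger = logging.getLogger("sweepabc")

__all__ = [
    "ObservedRegion",
    "read_vcf_region",
    "read_recmap",
    "write_vcf",
    "write_recmap",
    "make_fixtures",
]


@dataclass
class ObservedRegion:
    """Phased, polarized haplotypes for one genomic interval, plus the focal
    site and everything inference needs."""

    haplotypes: HaplotypeMatrix
    f_cur: float
    rmap: Optional[RecombinationMap] = None
    population: str = ""
    metadata: dict = field(default_factory=dict)
    n_dropped: int = 0

    @property
    def focal_pos(self) -> float:
        return self.haplotypes.selected_pos


def _load_ancestral_table(path: str | Path) -> dict[int, str]:
    table: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos, base = line.split()[:2]
        table[int(pos)] = base.upper()
    return table


def read_vcf_region(
    path: str | Path,
    interval: tuple[str, int, int],
    focal_pos: int,
    ancestral: str | Path = "AA",
    population: str = "",
) -> ObservedRegion:
    """Build an :class:`ObservedRegion` from a phased biallelic VCF.

    Parameters
    ----------
    interval
        ``(chrom, start, end)``, 0-based half-open in genome coordinates.
    focal_pos
        0-based genome coordinate of the putatively selected site; must be a
        record in the VCF.
    ancestral
        ``"AA"`` to use the INFO/AA tag, otherwise the path of a two-column
        ``position  ancestral_base`` table (positions 1-based, as in VCF).

    Sites that are multiallelic, non-SNP, unpolarizable, or carry missing
    alleles are dropped and counted.
    """
    from cyvcf2 import VCF

    chrom, start, end = interval
    use_tag = str(ancestral) == "AA"
    anc_table = None if use_tag else _load_ancestral_table(ancestral)

    vcf = VCF(str(path))
    cols: list[np.ndarray] = []
    positions: list[int] = []
    n_dropped = 0
    indexed = any(
        Path(str(path) + ext).exists() for ext in (".tbi", ".csi")
    )
    if indexed:
        it = vcf(f"{chrom}:{start + 1}-{end}")
    else:  # plain-text VCF: scan and filter
        it = (v for v in vcf if v.CHROM == chrom and start <= v.POS - 1 < end)
    for v in it:
        pos0 = v.POS - 1
        if not (start <= pos0 < end):
            continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        if use_tag:
            aa = v.INFO.get("AA")
            aa = aa.upper() if isinstance(aa, str) else None
        else:
            aa = anc_table.get(v.POS)
        if aa not in (v.REF.upper(), v.ALT[0].upper()):
            n_dropped += 1
            continue
        gts = v.genotypes  # [[a0, a1, phased], ...]
        hap = []
        ok = True
        for g in gts:
            alleles, phased = g[:-1], g[-1]
            if any(a < 0 for a in alleles):
                ok = False  # missing allele
                break
            if len(alleles) > 1 and not phased:
                raise ValueError(
                    f"unphased genotype at {v.CHROM}:{v.POS}; phased data required"
                )
            hap.extend(alleles)
        if not ok:
            n_dropped += 1
            continue
        col = np.array(hap, dtype=np.uint8)
        if aa == v.ALT[0].upper():
            col = (1 - col).astype(np.uint8)  # derived allele is REF
        cols.append(col)
        positions.append(pos0)
    vcf.close()

    if not cols:
        raise ValueError("no usable biallelic phased SNPs in interval")
    alleles = np.column_stack(cols)
    pos_rel = np.array(positions, dtype=float) - start
    focal_rel = float(focal_pos - start)
    hit = np.nonzero(pos_rel == focal_rel)[0]
    if len(hit) == 0:
        raise ValueError(f"focal site at position {focal_pos} absent from the VCF region")
    sel = int(hit[0])
    h = HaplotypeMatrix(
        alleles=alleles, positions=pos_rel, selected_index=sel,
        length_bp=float(end - start),
    )
    f_cur = h.focal_derived_count / h.n
    logger.info("VCF region: %d sites kept, %d dropped", h.n_sites, n_dropped)
    return ObservedRegion(
        haplotypes=h, f_cur=f_cur, population=population,
        metadata={"interval": list(interval), "source": str(path)},
        n_dropped=n_dropped,
    )


def read_recmap(
    path: str | Path, region_start: int = 0, region_length: Optional[float] = None
) -> RecombinationMap:
    """Read a HapMap-format recombination map
    (``Position(bp)  Rate(cM/Mb)  Map(cM)`` after an optional chromosome
    column; header line present).

    The returned map is in region-local coordinates (``region_start`` maps to
    0); positions outside the file's range take the nearest given rate.
    """
    rows: list[tuple[int, float]] = []
    lines = Path(path).read_text().splitlines()
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        # skip a leading chromosome column if present
        if parts and not parts[0].lstrip("+-").replace(".", "").isdigit():
            parts = parts[1:]
        try:
            pos = int(float(parts[0]))
            rate = float(parts[1])
        except (ValueError, IndexError):
            if not rows:
                continue  # header
            raise ValueError(f"line {ln}: malformed recombination-map line: {raw!r}")
        if rows and pos <= rows[-1][0]:
            raise ValueError(f"line {ln}: non-monotone position {pos}")
        rows.append((pos, rate))
    if not rows:
        raise ValueError("recombination map file has no data rows")
    breakpoints = [0.0]
    rates = [rows[0][1]]  # nearest rate extends left of the first knot
    for pos, rate in rows:
        rel = float(pos - region_start)
        if rel <= 0:
            rates[0] = rate  # last knot at/before region start sets the base rate
            continue
        if region_length is not None and rel >= region_length:
            break
        breakpoints.append(rel)
        rates.append(rate)
    return RecombinationMap(breakpoints=tuple(breakpoints), rates=tuple(rates))


def write_recmap(rmap: RecombinationMap, path: str | Path, length_bp: float) -> None:
    """HapMap-format export of a region-local map."""
    knots, cum = rmap.cumulative_arrays(length_bp)
    lines = ["Position(bp)\tRate(cM/Mb)\tMap(cM)"]
    for i, b in enumerate(rmap.breakpoints):
        cm = float(np.interp(b, knots, cum)) * 100.0
        lines.append(f"{int(b)}\t{rmap.rates[i]:g}\t{cm:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_vcf(
    h: HaplotypeMatrix,
    path: str | Path,
    chrom: str = "1",
    start: int = 0,
    sample_prefix: str = "S",
) -> None:
    """Write a haplotype matrix as a phased diploid VCF (fixture export).

    Haplotypes 2i and 2i+1 become sample i; the ancestral allele is written in
    the INFO/AA tag.  Positions are rounded to whole bp (deduplicated by
    nudging) since VCF coordinates are integral.
    """
    if h.n % 2 != 0:
        raise ValueError("need an even number of haplotypes for diploid VCF")
    n_ind = h.n // 2
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"##contig=<ID={chrom}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"{sample_prefix}{i}" for i in range(n_ind)),
    ]
    used = set()
    for j in range(h.n_sites):
        pos1 = int(round(h.positions[j])) + start + 1
        while pos1 in used:
            pos1 += 1
        used.add(pos1)
        gts = "\t".join(
            f"{h.alleles[2 * i, j]}|{h.alleles[2 * i + 1, j]}" for i in range(n_ind)
        )
        vid = "focal" if j == h.selected_index else "."
        lines.append(f"{chrom}\t{pos1}\t{vid}\tA\tC\t.\tPASS\tAA=A\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def make_fixtures(
    outdir: str | Path,
    seed: int = 0,
    n: int = 20,
    length_bp: float = 40_000.0,
    f_cur: float = 0.8,
    s: float = 0.05,
    mu: float = 2.5e-8,
    N: float = 2_000.0,
    model: str = "SDN",
    f1: Optional[float] = None,
) -> dict:
    """Simulate a small dataset and write VCF + recombination map + expected
    statistics, so the observed-data path can be exercised offline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dem = Demography.constant(N)
    spec = SweepModelSpec(
        model=model, f_cur=f_cur, s=s if model != "NT" else 0.0,
        f1=f1 if model == "SSV" else None,
    )
    rng = np.random.default_rng(seed)
    rmap = RecombinationMap.constant(1.5)
    traj = simulate_trajectory(spec, dem, seed=int(rng.integers(1, 2**31 - 1)))
    region = RegionSpec(length_bp=length_bp, selected_pos=length_bp / 2, n=n, mu=mu)
    h = simulate_haplotypes(traj, region, rmap, dem, seed=int(rng.integers(1, 2**31 - 1)))
    # snap positions to unique whole bp so the VCF round-trips exactly
    pos = []
    last = -1
    for p in h.positions:
        q = max(int(round(p)), last + 1)
        pos.append(q)
        last = q
    h = HaplotypeMatrix(
        alleles=h.alleles, positions=np.array(pos, dtype=float),
        selected_index=h.selected_index, length_bp=h.length_bp,
    )
    write_vcf(h, outdir / "region.vcf")
    write_recmap(rmap, outdir / "recmap.txt", length_bp)
    partition = RegionPartition(focal_pos=h.selected_pos)
    sv = summary_vector(h, partition)
    (outdir / "expected_stats.tsv").write_text(sv.to_tsv())
    meta = {
        "seed": seed, "n": n, "length_bp": length_bp, "f_cur": f_cur,
        "model": model, "s": spec.s, "f1": f1, "mu": mu, "N": N,
        "focal_pos_0based": int(round(h.selected_pos)),
        "focal_derived_count": h.focal_derived_count,
        "t0": traj.t0, "t1": traj.t1,
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    return meta
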