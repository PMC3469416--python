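"""Hudson ms-format text interchange for haplotype matrices.

One block per matrix::

    //
    # sweepabc length_bp=<L> focal_index=<k>
    segsites: <S>
    positions: <p1> <p2> ...
    0110...
    1010...

Positions are written as fractions of the region length with enough digits to
round-trip 0.1 bp resolution; the focal column index and region length ride in
the comment line.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import TextIO

import numpy as np

from .coalescent import HaplotypeMatrix

__all__ = ["write_ms", "read_ms"]


class MsParseError(ValueError):
    pass


def write_ms(h: HaplotypeMatrix, sink: str | Path | TextIO) -> None:
    out: TextIO
    close = False
    if isinstance(sink, (str, Path)):
        out = open(sink, "w")
        close = True
    else:
        out = sink
    try:
        out.write("//\n")
        out.write(
            f"# sweepabc length_bp={h.length_bp:.10g} focal_index={h.selected_index}\n"
        )
        out.write(f"segsites: {h.n_sites}\n")
        if h.n_sites:
            rel = h.positions / h.length_bp
            out.write("positions: " + " ".join(f"{p:.12f}" for p in rel) + "\n")
            for row in h.alleles:
                out.write("".join("1" if a else "0" for a in row) + "\n")
        out.write("\n")
    finally:
        if close:
            out.close()


def read_ms(source: str | Path | TextIO) -> HaplotypeMatrix:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = text.splitlines()
    length_bp = None
    focal_index = -1
    segsites = None
    positions: np.ndarray | None = None
    rows: list[str] = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("//"):
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("length_bp="):
                    length_bp = float(tok.split("=", 1)[1])
                elif tok.startswith("focal_index="):
                    focal_index = int(tok.split("=", 1)[1])
            continue
        if line.startswith("segsites:"):
            try:
                segsites = int(line.split(":", 1)[1])
            except ValueError:
                raise MsParseError(f"line {ln}: malformed segsites line: {raw!r}")
            continue
        if line.startswith("positions:"):
            try:
                positions = np.array([float(x) for x in line.split(":", 1)[1].split()])
            except ValueError:
                raise MsParseError(f"line {ln}: malformed positions line: {raw!r}")
            if segsites is not None and len(positions) != segsites:
                raise MsParseError(
                    f"line {ln}: {len(positions)} positions but segsites: {segsites}"
                )
            continue
        if set(line) <= {"0", "1"}:
            rows.append(line)
            continue
        raise MsParseError(f"line {ln}: unrecognized content: {raw!r}")
    if segsites is None:
        raise MsParseError("no segsites line found")
    if segsites == 0:
        n = max(len(rows), 1)
        return HaplotypeMatrix(
            alleles=np.zeros((n, 0), dtype=np.uint8),
            positions=np.array([]),
            selected_index=-1,
            length_bp=length_bp,
        )
    if positions is None:
        raise MsParseError("no positions line found")
    if not rows:
        raise MsParseError("no haplotype rows found")
    if any(len(r) != segsites for r in rows):
        raise MsParseError("haplotype row length does not match segsites")
    alleles = np.array([[int(c) for c in r] for r in rows], dtype=np.uint8)
    L = length_bp if length_bp is not None else 1.0
    return HaplotypeMatrix(
        alleles=alleles,
        positions=positions * L,
        selected_index=focal_index,
        length_bp=L,
    )
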