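"""Piecewise-constant demographic histories.

Time runs backward from the present in generations. A :class:`Demography` is an
ordered list of epochs ``(start_time, N)``: the population has diploid size ``N``
from ``start_time`` (generations before present) until the start of the next
epoch; the last epoch extends to infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["Demography"]


@dataclass(frozen=True)
class Demography:
    """Piecewise-constant population-size history.

    Parameters
    ----------
    epochs
        Ordered ``(start_generation, diploid_N)`` pairs. The first epoch must
        start at time 0; start times strictly increasing; all N >= 2.
    generation_years
        Years per generation, used only when reporting times in years.
    """

    epochs: tuple[tuple[float, float], ...]
    generation_years: float = 25.0

    def __post_init__(self) -> None:
        if len(self.epochs) == 0:
            raise ValueError("Demography needs at least one epoch")
        starts = [e[0] for e in self.epochs]
        sizes = [e[1] for e in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(n < 2 for n in sizes):
            raise ValueError("all population sizes must be >= 2")
        object.__setattr__(self, "epochs", tuple((float(a), float(n)) for a, n in self.epochs))

    @classmethod
    def constant(cls, N: float, generation_years: float = 25.0) -> "Demography":
        return cls(epochs=((0.0, float(N)),), generation_years=generation_years)

    @classmethod
    def bottleneck(
        cls,
        N0: float,
        strength: float,
        start: float = 400.0,
        duration: float = 2000.0,
        generation_years: float = 25.0,
    ) -> "Demography":
        """Bottleneck of given strength (N_bottleneck = strength * N0) starting
        ``start`` generations ago and lasting ``duration`` generations."""
        if not 0 < strength:
            raise ValueError("strength must be positive")
        if strength == 1.0:
            return cls.constant(N0, generation_years)
        return cls(
            epochs=((0.0, N0), (start, max(2.0, strength * N0)), (start + duration, N0)),
            generation_years=generation_years,
        )

    @property
    def N0(self) -> float:
        """Present-day (epoch-0) diploid size."""
        return self.epochs[0][1]

    def size_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """Diploid size at time ``t`` generations before present."""
        starts = np.array([e[0] for e in self.epochs])
        sizes = np.array([e[1] for e in self.epochs])
        idx = np.searchsorted(starts, np.asarray(t, dtype=float), side="right") - 1
        out = sizes[idx]
        return float(out) if np.isscalar(t) else out

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        starts = np.array([e[0] for e in self.epochs], dtype=np.float64)
        sizes = np.array([e[1] for e in self.epochs], dtype=np.float64)
        return starts, sizes

    # -- plain-text interchange ("start_generation  diploid_N") ---------------

    @classmethod
    def from_file(cls, path: str | Path, generation_years: float = 25.0) -> "Demography":
        """Read a two-column table ``start_generation diploid_N``.

        A header line and '#' comments are allowed.
        """
        epochs: list[tuple[float, float]] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                epochs.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if epochs:
                    raise ValueError(f"malformed demography line: {line!r}")
                continue  # header line
        return cls(epochs=tuple(epochs), generation_years=generation_years)

    def to_file(self, path: str | Path) -> None:
        lines = ["start_generation\tdiploid_N"]
        lines += [f"{a:g}\t{n:g}" for a, n in self.epochs]
        Path(path).write_text("\n".join(lines) + "\n")
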