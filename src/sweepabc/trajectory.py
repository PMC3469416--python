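"""Backward-in-time allele-frequency trajectories of a focal allele.

The focal allele is observed at frequency ``f_cur`` today.  Its history is
simulated backward in time with an Euler scheme on the Wright-Fisher diffusion
run in reverse: per generation the frequency moves by ``-M(x) dt`` plus noise
of variance ``x(1-x)/(2N(t)) dt``, where the drift

    M(x) = s x (1-x) [h + (1-2h) x]

is the standard diffusion drift for genotype fitnesses 1, 1+hs, 1+s
(``h = 0.5`` is the additive/codominant model with fitnesses 1, 1+s/2, 1+s).
Backward in time, selection pushes the frequency *down*, so selected paths
absorb quickly at the origin of the allele.

Model variants
--------------
NT   no selection; the backward path is a driftless martingale.
SDN  selection acts over the whole backward path (allele beneficial since its
     origin).
SSV  selection acts until the backward path first reaches ``f1``; before that
     (i.e., earlier in real time) the allele drifted neutrally.  ``t1`` records
     the selection-onset time.

Paths are conditioned on the allele having arisen by mutation (eventual
absorption at frequency 0 backward in time) by rejection: an unconditioned
backward path that reaches fixation (``x >= 1 - 1/(2N)``) is discarded and
restarted, which yields exactly the law of the path conditioned on loss.

``expected_allele_age`` provides the matching closed-form/diffusion
expectations: the Kimura-Ohta ``-4N x ln(x) / (1-x)`` generations for a neutral
allele, and for a selected allele the mean absorption time at 0 of the forward
diffusion conditioned on loss (the time-reversal of the origin process),
evaluated by numerical integration of the conditioned sojourn-time densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from numba import njit
from scipy.integrate import quad

from .demography import Demography

__all__ = [
    "SweepModelSpec",
    "PriorSpec",
    "Trajectory",
    "simulate_trajectory",
    "expected_allele_age",
]

_MODELS = ("NT", "SDN", "SSV")


@dataclass(frozen=True)
class SweepModelSpec:
    """Focal-allele model: which selection scenario and with what parameters.

    ``s`` is the selection coefficient per generation of the derived homozygote
    (fitnesses 1, 1+hs, 1+s); ``f1`` is the frequency at selection onset (SSV
    only); ``f_cur`` the known present-day derived frequency.
    """

    model: str
    f_cur: float
    s: float = 0.0
    h: float = 0.5
    f1: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {self.model!r}")
        if not 0.0 < self.f_cur < 1.0:
            raise ValueError(f"f_cur must be in (0,1), got {self.f_cur}")
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must be in [0,1]")
        if self.model == "NT" and self.s != 0:
            raise ValueError("NT model requires s = 0")
        if self.model == "SSV":
            if self.f1 is None or not 0.0 < self.f1 < 1.0:
                raise ValueError("SSV model requires f1 in (0,1)")
        elif self.f1 is not None:
            raise ValueError(f"f1 is only meaningful under SSV, not {self.model}")

    def alpha(self, N0: float) -> float:
        """Population-scaled selection coefficient alpha = 4 N0 s."""
        return 4.0 * N0 * self.s


@dataclass(frozen=True)
class PriorSpec:
    """Uniform priors on the per-model parameters.

    Defaults: mu ~ U(0.5e-8, 6e-8) per bp per generation,
    log10(s) ~ U(-3, -0.5), f1 ~ U(0, 0.2], optionally h ~ U(0, 1).
    """

    mu_range: tuple[float, float] = (0.5e-8, 6e-8)
    log10_s_range: tuple[float, float] = (-3.0, -0.5)
    f1_range: tuple[float, float] = (0.0, 0.2)
    h_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        for name in ("mu_range", "log10_s_range", "f1_range"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} must be a finite increasing pair")

    def sample(self, model: str, f_cur: float, rng: np.random.Generator) -> tuple[SweepModelSpec, dict]:
        """Draw one parameter set; returns the spec and the raw draws."""
        mu = rng.uniform(*self.mu_range)
        draws = {"mu": mu}
        if model == "NT":
            spec = SweepModelSpec(model="NT", f_cur=f_cur)
        else:
            log10_s = rng.uniform(*self.log10_s_range)
            s = 10.0 ** log10_s
            draws["log10_s"] = log10_s
            h = 0.5
            if self.h_range is not None:
                h = rng.uniform(*self.h_range)
                draws["h"] = h
            if model == "SSV":
                lo, hi = self.f1_range
                # uniform on (lo, hi]: draw in [lo, hi) and reflect the open end
                f1 = hi - rng.uniform(0.0, hi - lo)
                draws["f1"] = f1
                spec = SweepModelSpec(model="SSV", f_cur=f_cur, s=s, h=h, f1=f1)
            else:
                spec = SweepModelSpec(model="SDN", f_cur=f_cur, s=s, h=h)
        return spec, draws


@dataclass
class Trajectory:
    """A sampled backward allele-frequency path on a uniform time grid.

    ``freqs[i]`` is the frequency at ``i * dt`` generations before present;
    ``freqs[0] = f_cur``.  ``t0`` is the allele origin (absorption below
    ``1/(2N(t))``); ``t1`` the selection-onset time (SSV only).
    """

    freqs: np.ndarray
    dt: float
    t0: float
    t1: Optional[float] = None
    seed: Optional[int] = None
    rejections: int = 0

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.freqs)) * self.dt

    @property
    def f_cur(self) -> float:
        return float(self.freqs[0])

    def to_file(self, path: str | Path) -> None:
        """Tab-separated ``generation  frequency`` with a metadata header block."""
        lines = [f"# t0={self.t0:g}"]
        if self.t1 is not None:
            lines.append(f"# t1={self.t1:g}")
        if self.seed is not None:
            lines.append(f"# seed={self.seed}")
        lines.append("generation\tfrequency")
        t = self.times
        lines += [f"{t[i]:g}\t{self.freqs[i]:.8g}" for i in range(len(self.freqs))]
        Path(path).write_text("\n".join(lines) + "\n")


class TrajectoryError(RuntimeError):
    """Raised when a backward path fails to absorb within the horizon."""


@njit(cache=True)
def _traj_kernel(f_cur, s, h, f1, use_sel, use_switch, ep_starts, ep_N,
                 dt, max_steps, seed, out):  # pragma: no cover - jitted
    """Euler simulation of the backward path.  Returns
    (n_steps, t1_idx, rejections, status); status 1 = horizon exceeded."""
    np.random.seed(seed)
    n_ep = len(ep_starts)
    rejections = 0
    for _attempt in range(100000):
        x = f_cur
        sel_on = use_sel
        if use_switch and f_cur <= f1:
            sel_on = False
        t1_idx = 0 if (use_switch and not sel_on) else -1
        ep = 0
        i = 0
        rejected = False
        while True:
            t = i * dt
            while ep + 1 < n_ep and ep_starts[ep + 1] <= t:
                ep += 1
            N = ep_N[ep]
            lo = 1.0 / (2.0 * N)
            out[i] = x
            if x < lo:
                return i, t1_idx, rejections, 0
            if x >= 1.0 - lo:
                rejected = True
                rejections += 1
                break
            if sel_on and x <= f1:
                sel_on = False
                t1_idx = i
            if i + 1 >= max_steps:
                return i, t1_idx, rejections, 1
            drift = 0.0
            if sel_on:
                drift = s * x * (1.0 - x) * (h + (1.0 - 2.0 * h) * x)
            sd = math.sqrt(x * (1.0 - x) * dt / (2.0 * N))
            x = x - drift * dt + sd * np.random.standard_normal()
            if x < 0.0:
                x = 0.0
            elif x > 1.0:
                rejected = True
                rejections += 1
                break
            i += 1
        if not rejected:
            break
    return 0, -1, rejections, 2


def default_dt(dem: Demography) -> float:
    """Euler step: ``min(1, N_min/1000)`` generations."""
    n_min = min(n for _, n in dem.epochs)
    return min(1.0, n_min / 1000.0)


def simulate_trajectory(
    spec: SweepModelSpec,
    dem: Demography,
    dt: Optional[float] = None,
    seed: int | None = None,
    max_horizon: float = 2.0e6,
) -> Trajectory:
    """Sample one backward trajectory conditioned on the present frequency.

    Parameters
    ----------
    spec, dem
        Model parameters and demographic history.
    dt
        Euler step in generations; defaults to ``min(1, N_min/1000)``.
    max_horizon
        Maximum backward time in generations before giving up.
    """
    if dt is None:
        dt = default_dt(dem)
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_min = min(n for _, n in dem.epochs)
    if spec.f_cur >= 1.0 - 1.0 / (2.0 * n_min):
        raise ValueError("f_cur is at or above the fixation boundary for this demography")
    max_steps = int(max_horizon / dt) + 2
    out = np.empty(max_steps, dtype=np.float64)
    ep_starts, ep_N = dem.as_arrays()
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31 - 1))
    use_sel = spec.model in ("SDN", "SSV")
    use_switch = spec.model == "SSV"
    f1 = spec.f1 if spec.f1 is not None else 0.0
    n_steps, t1_idx, rejections, status = _traj_kernel(
        spec.f_cur, spec.s, spec.h, f1, use_sel, use_switch,
        ep_starts, ep_N, dt, max_steps, np.uint32(seed % (2**31 - 1)), out,
    )
    if status == 1:
        raise TrajectoryError(
            f"backward path did not absorb within the horizon of {max_horizon:g} generations"
        )
    if status == 2:
        raise TrajectoryError("rejection sampling failed to produce a path absorbed at loss")
    freqs = out[: n_steps + 1].copy()
    t1 = t1_idx * dt if (use_switch and t1_idx >= 0) else (0.0 if use_switch else None)
    return Trajectory(
        freqs=freqs, dt=dt, t0=n_steps * dt, t1=t1, seed=seed, rejections=rejections
    )


def expected_allele_age(
    x: float,
    N: float,
    s: float,
    generation_years: float = 25.0,
) -> float:
    """Expected age (in years) of a derived allele currently at frequency ``x``.

    For ``s = 0`` this is the Kimura-Ohta neutral expectation
    ``-4 N x ln(x) / (1 - x)`` generations.  For ``s > 0`` (additive selection,
    fitnesses 1, 1+s/2, 1+s) the age equals the mean time to loss of the
    forward diffusion started at ``x`` conditioned on loss -- the time reversal
    of the origination process -- computed by integrating the conditioned
    sojourn-time density over frequency space.
    """
    if not 0.0 < x < 1.0:
        raise ValueError("x must be strictly inside (0,1)")
    if N < 2:
        raise ValueError("N must be >= 2")
    if s < 0:
        raise ValueError("s must be >= 0")
    if s == 0.0:
        gens = -4.0 * N * x * math.log(x) / (1.0 - x)
        return gens * generation_years

    beta = 2.0 * N * s  # scale exponent: psi(y) = exp(-beta y)

    def S(y: float) -> float:  # scale measure integral, ∫_0^y psi
        return -math.expm1(-beta * y) / beta

    def R(y: float) -> float:  # (S(1)-S(y)) / psi(y), computed stably
        return -math.expm1(-beta * (1.0 - y)) / beta

    S1 = S(1.0)

    def left(xi: float) -> float:  # sojourn density (conditioned on loss), xi < x
        return 4.0 * N * S(xi) * R(xi) / (S1 * xi * (1.0 - xi))

    Sx = S(x)
    Rx = R(x)

    def right(xi: float) -> float:  # xi > x
        return (
            4.0 * N * (Sx / S1) * R(xi) ** 2
            * math.exp(beta * (x - xi)) / (Rx * xi * (1.0 - xi))
        )

    t_left, _ = quad(left, 0.0, x, limit=200)
    t_right, _ = quad(right, x, 1.0, limit=200)
    return (t_left + t_right) * generation_years
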