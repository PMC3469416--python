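"""Model/Results surface for sweep-mode inference.

:class:`SweepInference` is the user-facing model object: it holds one observed
region (or its summary statistics), the candidate sweep models with their
priors, and the simulation settings.  ``fit()`` builds (or reuses) the
reference tables, runs rejection + GLM adjustment, and returns a
:class:`SweepInferenceResults` carrying model probabilities, parameter
posteriors with 95% HPD intervals, and a printable summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .coalescent import HaplotypeMatrix
from .inference import ABCConfig, PosteriorDensity, PosteriorResult
from .io import ObservedRegion
from .pipeline import ReferenceSet, SimulationConfig
from .sumstats import SummaryVector, summary_vector
from .trajectory import PriorSpec

__all__ = ["SweepInference", "SweepInferenceResults"]


class SweepInference:
    """ABC model choice between NT / SDN / SSV for one focal site.

    Parameters
    ----------
    observed
        An :class:`ObservedRegion`, a :class:`HaplotypeMatrix` with its focal
        column set, or a precomputed :class:`SummaryVector`.
    f_cur
        Present-day derived frequency at the focal site; inferred from the
        data when an observed region / matrix is given.
    models, priors, config
        Candidate models, parameter priors, and simulation settings for the
        reference tables.
    n_sims
        Reference simulations per model (when no prebuilt reference is given).
    reference
        A prebuilt :class:`ReferenceSet` to reuse (its conditioning f_cur must
        match).
    """

    def __init__(
        self,
        observed: ObservedRegion | HaplotypeMatrix | SummaryVector,
        f_cur: Optional[float] = None,
        models: Sequence[str] = ("NT", "SDN", "SSV"),
        priors: PriorSpec = PriorSpec(),
        config: SimulationConfig = SimulationConfig(),
        n_sims: int = 20_000,
        abc: ABCConfig = ABCConfig(),
        reference: Optional[ReferenceSet] = None,
    ):
        if isinstance(observed, ObservedRegion):
            self.data = observed.haplotypes
            f_cur = observed.f_cur if f_cur is None else f_cur
        else:
            self.data = observed
        if isinstance(self.data, HaplotypeMatrix) and f_cur is None:
            f_cur = self.data.focal_derived_count / self.data.n
        if f_cur is None:
            raise ValueError("f_cur is required when only summary statistics are given")
        if not 0 < f_cur < 1:
            raise ValueError("f_cur must be in (0,1)")
        self.f_cur = float(f_cur)
        self.models = tuple(models)
        self.priors = priors
        self.config = config
        self.n_sims = n_sims
        self.abc = abc
        self.reference = reference

    @classmethod
    def from_reference(
        cls,
        observed: ObservedRegion | HaplotypeMatrix | SummaryVector,
        reference: ReferenceSet,
        abc: ABCConfig = ABCConfig(),
    ) -> "SweepInference":
        return cls(
            observed,
            f_cur=reference.f_cur,
            models=reference.models,
            priors=reference.priors,
            config=reference.config,
            abc=abc,
            reference=reference,
        )

    def fit(self, seed: int = 0, progress: bool = False) -> "SweepInferenceResults":
        ref = self.reference
        if ref is None:
            ref = ReferenceSet.build(
                self.models, self.f_cur, self.priors, self.config,
                n_sims=self.n_sims, seed=seed, progress=progress,
            )
            self.reference = ref
        if isinstance(self.data, HaplotypeMatrix):
            sv = summary_vector(self.data, ref.config.partition())
        else:
            sv = self.data
        raw = ref.infer(sv, self.abc, seed=seed)
        return SweepInferenceResults(model=self, result=raw, reference=ref, observed=sv)


@dataclass
class SweepInferenceResults:
    """Fitted results: model probabilities and adjusted parameter posteriors."""

    model: SweepInference
    result: PosteriorResult
    reference: ReferenceSet
    observed: SummaryVector

    @property
    def model_probabilities(self) -> dict[str, float]:
        return self.result.model_probabilities

    @property
    def best_model(self) -> str:
        return self.result.best_model

    @property
    def poor_fit(self) -> bool:
        return self.result.poor_fit

    def posterior(self, model: str, param: str) -> PosteriorDensity:
        return self.result.posteriors[model][param]

    def bayes_factor(self, m1: str, m2: str) -> float:
        return self.result.bayes_factor(m1, m2)

    def estimates(self, model: str) -> dict[str, dict[str, float]]:
        """Mode and 95% HPD per parameter, on natural scales (s as a plain
        coefficient, times in years).  Intervals on log-scale parameters are
        the transformed HPD hulls."""
        gy = self.reference.config.dem.generation_years
        out: dict[str, dict[str, float]] = {}
        for name, pd_ in self.result.posteriors[model].items():
            if name.startswith("log10_t"):
                key = name.replace("log10_", "") + "_years"
                tr = lambda v: 10.0**v * gy
            elif name == "log10_s":
                key = "s"
                tr = lambda v: 10.0**v
            else:
                key = name
                tr = lambda v: v
            out[key] = {
                "mode": tr(pd_.mode),
                "hpd_low": tr(pd_.hpd_low),
                "hpd_high": tr(pd_.hpd_high),
            }
        return out

    def alpha_mode(self, model: str = "SDN") -> float:
        """Posterior mode of alpha = 4 N0 s under a selection model."""
        N0 = self.reference.config.dem.N0
        return 4.0 * N0 * 10.0 ** self.result.posteriors[model]["log10_s"].mode

    def summary(self) -> str:
        lines = []
        lines.append("Sweep-mode ABC inference")
        lines.append("=" * 60)
        lines.append(f"f_cur = {self.model.f_cur:.3f}   "
                     f"models: {', '.join(self.reference.models)}")
        if self.poor_fit:
            lines.append("WARNING: none of the candidate models fits the data well")
        lines.append("-" * 60)
        lines.append("Model probabilities:")
        for m, p in sorted(self.model_probabilities.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {m:4s}  {p:8.4f}")
        for m in self.reference.models:
            if m == "NT":
                continue
            est = self.estimates(m)
            lines.append("-" * 60)
            lines.append(f"{m} parameter estimates (mode [95% HPD]):")
            for k, e in est.items():
                lines.append(
                    f"  {k:10s} {e['mode']:#.4g}  [{e['hpd_low']:#.4g}, {e['hpd_high']:#.4g}]"
                )
        lines.append("=" * 60)
        return "\n".join(lines)
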