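# sweepabc

**Did this allele sweep from standing variation, from a new mutation, or is
it just drift?** `sweepabc` answers that question for a single focal site
whose position and present-day derived frequency are known, using Approximate
Bayesian Computation over three models:

- **SDN** — sweep from a *de novo* mutation: the allele was beneficial
  (fitnesses 1, 1+s/2, 1+s) from the moment it arose;
- **SSV** — sweep from *standing variation*: the allele drifted neutrally
  until it reached a frequency f1, when selection began (so SSV with
  f1 = 1/2N *is* SDN: the models are nested);
- **NT** — neutral drift, still conditioned on the allele having reached its
  observed frequency f_cur.

The package simulates data trajectory-first: a backward Euler scheme on the
time-reversed Wright–Fisher diffusion draws the focal allele's frequency path
(with t0 = allele origin and, for SSV, t1 = selection onset), and a
two-background structured coalescent generates haplotypes for the
surrounding region conditional on that path, with recombination from a
HapMap-style map and piecewise-constant demography. Each dataset is reduced
to 16 summary statistics — Tajima's D, Fay & Wu's H, π and S in three
distance bands around the focal site, EHH at 10/20/50 kb, and iHS — which are
Box-Cox linearized and compressed to five PLS-DA components. Rejection ABC
retains the simulations closest to the observed components, a
Leuenberger–Wegmann GLM adjustment turns them into parameter posteriors
(s, μ, f1, and the allele ages t0/t1), and marginal densities give model
probabilities. Closed-form allele-age expectations (Kimura–Ohta for s = 0,
conditioned sojourn-time integrals for s > 0) are included.

Intended users: population geneticists with a candidate selected site (from
a scan or functional evidence) who want to classify the sweep mode and date
the allele, and methodologists studying when SSV and SDN are separable at
all.

## Worked example

Simulate one dataset under a known truth (SDN, α = 4Ns = 400, μ = 2.5e-8,
f_cur = 0.95, n = 100 haplotypes over 150 kb, N = 10,000), then infer the
sweep mode from it:

```python
from sweepabc import (ABCConfig, PriorSpec, ReferenceSet, SimulationConfig,
                      SweepInference, SweepModelSpec)
from sweepabc.pipeline import simulate_dataset

config = SimulationConfig()          # n=100, 150 kb, 1.5 cM/Mb, N=10,000
reference = ReferenceSet.build(("NT", "SDN", "SSV"), f_cur=0.95,
                               priors=PriorSpec(), config=config,
                               n_sims=2000, seed=42)       # ~2 min

truth = SweepModelSpec(model="SDN", f_cur=0.95, s=0.01)    # alpha = 400
data, trajectory = simulate_dataset(truth, 2.5e-8, config, seed=2028)

fit = SweepInference.from_reference(data, reference,
                                    abc=ABCConfig(n_accept=60)).fit(seed=0)
print(fit.summary())
```

which prints:

```
Sweep-mode ABC inference
============================================================
f_cur = 0.950   models: NT, SDN, SSV
------------------------------------------------------------
Model probabilities:
  SDN     0.6816
  SSV     0.3184
  NT      0.0000
------------------------------------------------------------
SDN parameter estimates (mode [95% HPD]):
  mu         2.700e-08  [2.095e-08, 3.470e-08]
  s          0.01259  [0.005309, 0.03548]
  t0_years   3.540e+04  [1.455e+04, 7.998e+04]
...
```

Reading it: neutrality is rejected outright (Pr(NT) ≈ 0); the de novo model
is favoured 0.68 : 0.32 over standing variation — a single replicate
separates the two sweep models only partially, as expected. The
selection-coefficient mode 0.0126 (α ≈ 503) and the allele-age mode of
~35 ky bracket the generating values (s = 0.01, true origin 42.2 ky for this
replicate) within their 95% HPD intervals. Averaging the posterior mode
over replicates recovers α = 400 closely (see below).

The same pipeline runs from the shell:

```bash
sweepabc build-ref --f-cur 0.95 --n-sims 20000 --seed 1 --out refs/
sweepabc simulate-data --model SDN --f-cur 0.95 --s 0.01 --seed 7 --out obs.ms
sweepabc infer --obs obs.ms --refs refs/ --out result.json
sweepabc validate calibration --refs refs/ --n 500 --out calib.tsv
```

Observed data enter through `read_vcf_region` (phased biallelic VCF with
INFO/AA or a position→ancestral-base table) and `read_recmap`
(HapMap-format recombination map); `sweepabc fixtures` writes a small fully
simulated VCF + map + statistics directory so that path is testable offline.

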