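# Methods

`sweepabc` asks, for a single putatively selected site whose position and
present-day derived frequency `f_cur` are known: did the allele sweep up from
a **de novo mutation** (SDN — beneficial from the moment it arose), from
**standing variation** (SSV — it drifted neutrally until reaching a frequency
`f1`, at which point selection began), or is its frequency the product of
**drift alone** (NT — still conditioned on the observed `f_cur`, so *not* the
classical neutral coalescent)? The answer is computed by Approximate Bayesian
Computation: simulate many datasets under each model with parameters from
their priors, compress each dataset to informative summary statistics, retain
the simulations closest to the observed data, and turn them into model
probabilities and parameter posteriors.

## The allele-frequency trajectory

All hitch-hiking information lives in the frequency path of the focal allele,
so datasets are simulated trajectory-first. The backward path from `f_cur` is
an Euler discretization of the time-reversed Wright-Fisher diffusion: per
generation

    x' = x - M(x) dt + sqrt(x(1-x) dt / (2 N(t))) Z,
    M(x) = s x (1-x) [h + (1-2h) x],

with genotype fitnesses 1, 1+hs, 1+s (`h = 0.5` is the additive model with
fitnesses 1, 1+s/2, 1+s used everywhere except where dominance is varied
explicitly). Under SSV the selection term is dropped from the first backward
time the path reaches `f1` (that time is recorded as `t1`); under NT the
drift term is zero. Population-size changes enter only through the variance
term (`N(t)` piecewise constant).

Conditioning on the allele having arisen by mutation (absorption at 0) is by
rejection: a path that reaches `1 - 1/(2N)` is discarded and restarted. For a
neutral path at `f_cur = 0.95` this rejects ~95% of attempts — the cost is
accepted because rejection is *exact*: the retained paths have precisely the
law of the diffusion conditioned on loss. (Equivalently, the sign-flipped
drift plus rejection reproduces the Doob h-transform; the two conditioned
generators coincide.)

Numerical choices: Euler step `dt = min(1, N_min/1000)` generations; a step
below 0 is clamped to 0 (absorption at the origin, recorded as `t0`); a step
above 1 triggers the rejection rule; maximum backward horizon 2e6 generations
with an explicit error beyond it. The Euler bias is invisible against Monte
Carlo error for `s <= 0.03` and is ~3% of the sojourn time at `s = 0.1`
(`dt = 1`); the trajectory tests pin both statements.

`expected_allele_age` gives the matching closed forms. Neutral: the
Kimura-Ohta expectation `-4 N x ln(x)/(1-x)` generations. Selected: by time
reversal, the age of an allele at frequency `x` equals the mean absorption
time at 0 of the *forward* diffusion started at `x` conditioned on loss; that
is evaluated by numerically integrating the conditioned sojourn-time (Green's
function) densities, written in ratio forms that stay finite for
`beta = 2Ns` up to ~1e4. The simulator reports `t0` as the first passage
below `1/(2N)`; its expectation is the closed form minus the sub-threshold
sojourn (also available from the same formula), which the tests exploit.

## The conditional structured coalescent

Given a trajectory, haplotypes for the surrounding region come from a
two-background structured coalescent. Each ancestral lineage carries its
ancestral-sequence segments plus an allelic background at the focal site;
backward in time,

- pair coalescence within background `b` occurs at rate
  `C(k_b,2) / (2 N(t) x_b(t))`, with `x_derived = x(t)` from the trajectory;
- recombination occurs per lineage at the genetic-map length of the hull of
  (its material and the focal site); a breakpoint that separates material
  from the focal site redraws that material's background (derived with
  probability `x(t)`);
- when `2 N(t) x_b(t)` falls below the number of lineages in background `b`,
  coalescences are forced immediately (the frequency cannot support more
  lineages than copies);
- at absorption (`t0`) the remaining derived lineages join the ancestral
  background — the focal mutation event — and a plain coalescent-with-
  recombination runs on to the local MRCAs.

Event times are drawn with rates held constant within each trajectory step
(frequency and size evaluated at the interval start), the discretization
error vanishing with `dt`.

Neutral mutations use an infinite-sites bookkeeping trick rather than
explicit trees: every segment carries the bitmask of sampled haplotypes
descending from it; when a segment dies it emits
Poisson(`mu` x length x lifetime) mutations inheriting that bitmask, and
segments whose mask covers the whole sample are local MRCAs and are dropped
(their mutations would be invisible). Positions are uniform within segments,
reported at 0.1 bp resolution and de-duplicated. The kernel is a single
numba nopython function; sample size is capped at 256 haplotypes by the
4x64-bit masks. Coordinates are 0-based half-open throughout; 1-based only
in VCF records.

The sampled focal-site split is a binomial(`n`, `f_cur`) draw truncated to
[1, n-1]. A "pinned" trajectory (frequency held at 1, all lineages derived)
degenerates to the plain neutral coalescent, which is how the simulator is
checked against Watterson's `E[S]`, the neutral SFS `E[S_i] = theta/i`, and
msprime.

## Summary statistics

Sixteen statistics per dataset. Four SFS statistics — Tajima's D, Fay & Wu's
H (`theta_pi - theta_H`, requiring ancestral polarization), the mean pairwise
difference `pi`, and the segregating-site count `S` — each computed in three
concentric distance bands around the focal site: central (within 10 kb each
side), intermediate (10-50 kb) and faraway (>50 kb). The bands are disjoint
and exhaustive, so `pi` and `S` are additive across them. The focal column
itself is excluded from the SFS statistics (it is conditioned on, not
random). Haplotype statistics: EHH of the derived-allele carriers in 10, 20
and 50 kb windows centred on the focal site (probability that two random
carriers are identical at every polymorphic site in the window), and iHS,
`ln(iHH_A / iHH_D)`, the log ratio of areas under the ancestral vs derived
EHH decay curves, integrated outward by the trapezoid rule until EHH < 0.05
or the region edge (a truncation flag is set in the latter case). The decay
curves are integrated over physical distance; any constant map scale cancels
in the ratio. iHS is used unstandardized — the genome-wide frequency-bin
standardization of Voight et al. is impossible within one locus, and the
identical transformation applied to observed and simulated data preserves
the comparison. Undefined statistics (e.g. D with no segregating sites, EHH
with fewer than two carriers) are NaN, never silent zeros.

The default simulated region is 150 kb with the focal site at the centre, so
all three bands are populated (a focal-centred 100 kb region has no faraway
sites); this matches the upper end of the 100-150 kb gene regions the method
targets. Sample size defaults to n = 100 haplotypes, N = 10,000 constant,
1.5 cM/Mb.

One directional fact worth recording: under *conditioned* neutrality at
`f_cur = 0.95`, mean central Tajima's D is mildly negative (about -0.4), not
positive — conditioning puts two long stems in the genealogy whose mutations
sit at extreme frequencies (0.05 and 0.95). The discriminating signal is the
contrast (SDN around -2, SSV around -1.4, NT around -0.4 centrally, all ~0
far away), together with H and the haplotype statistics.

## Transform and compression

Undefined entries are imputed with the per-statistic reference minimum minus
one reference SD (computed on the pooled reference tables, logged when used
on observed data). Each statistic is then shifted to positivity (`1 - min`
when the minimum is non-positive) and Box-Cox transformed, the exponent
maximizing the profile likelihood on a grid over [-5, 5] in steps of 0.01;
constant columns pass through with a warning. The transformed statistics are
standardized and compressed to five PLS-DA components — PLS2 on a dummy-coded
model-label matrix (via scikit-learn's NIPALS; for PLS2 regression the
X-weights are identical whether or not Y is deflated). The pipeline is fit
once on the pooled reference tables of all candidate models (Box-Cox pooled
across models), frozen, serialized to a JSON sidecar, and applied identically
to simulated and observed data. Each component is divided by its pooled
training SD so the Euclidean rejection distance is scale-free.

## ABC: rejection, GLM adjustment, model choice

Rejection keeps the `n_accept` reference rows (default 100; at the full 1e5
tables that is the 0.1% acceptance rate) with smallest Euclidean distance to
the observed components, ties broken by row index.

The post-sampling adjustment is the Leuenberger-Wegmann GLM (the 2010
model-selection formulation): on the accepted set, components are modelled as
multivariate normal with mean linear in the parameters and common residual
covariance (ordinary least squares; residual covariance with a small
trace-scaled jitter), and the truncated prior over the accepted region is a
Gaussian-kernel mixture over the accepted parameter draws (Silverman/Scott
bandwidths). Posterior and marginal are then analytic:

    T^-1   = C' Sigma_s^-1 C + Sigma_theta^-1
    m_j    = T (C' Sigma_s^-1 (s_obs - c0) + Sigma_theta^-1 theta_j)
    log w_j = log N(s_obs; c0 + C theta_j, Sigma_s + C Sigma_theta C')
    posterior = sum_j w_j N(theta; m_j, T),   marginal = mean_j w_j.

Per-parameter densities are evaluated on 101-point grids (prior support for
mu, log10 s and f1; the padded accepted hull for the latent times, on a log10
scale), with reflection boundary correction at the prior-support edges. A
constant parameter among the accepted rows makes the design singular; the
code then falls back to an unadjusted kernel-smoothed histogram with a
warning. Estimable quantities include the realized latent times `t0` (allele
origin) and `t1` (selection onset), carried through the GLM alongside the
model parameters.

Model probabilities: each model's marginal density of the observed components
(the GLM mixture marginal times that model's acceptance fraction) times a
uniform model prior, normalized. The SSV/SDN pair is nested — SSV with
`f1 = 1/(2N)` *is* SDN, which the trajectory tests verify distributionally —
so comparing SDN against SSV with `f1 ~ U(0, 0.2]` is exactly the
positive-mass-at-the-boundary comparison. A goodness-of-fit guard flags the
observation as outside a model's support when its nearest reference row is
farther than the 99th percentile of leave-one-out nearest-neighbour distances
within that model's table; if every candidate model is flagged, the result
carries a poor-fit warning (balancing selection produces exactly this
outcome) while probabilities are still returned.

Mode and 95% HPD are read off the grid: the HPD is the smallest set of cells
holding 0.95 mass; contiguity is not forced — the hull is reported with a
multimodality flag. Times are reported in years at 25 y/generation only at
the reporting layer.

## Priors and study conditions

`mu ~ U(0.5e-8, 6e-8)` per bp per generation; `log10(s) ~ U(-3, -0.5)`;
`f1 ~ U(0, 0.2]`; optionally `h ~ U(0, 1)`. The simulation studies fix
`mu = 2.5e-8` in the generating datasets and state truths as
`alpha = 4 N s`. Robustness studies use a bottleneck that started 400
generations ago and lasted 2,000 generations, at a configurable fraction of
N, simulated in the data but ignored (constant N) in the reference tables;
and a misidentified focal site, re-anchoring the statistics at the
polymorphic site nearest a chosen offset (preferring sites within 0.1 of the
conditioning frequency).

## What the synthetic data do and do not emulate

The generator produces phased, fully polarized, error-free biallelic
haplotypes from a panmictic constant-size (or piecewise-constant) population
with a known focal site. Real data differ: phasing and polarization errors,
missing genotypes, ascertainment, population structure and gene flow, and
uncertainty in which site is causal. The validation experiments quantify the
last two failure modes (bottleneck misspecification biases toward SDN and
stronger selection; focal-site misidentification beyond ~50 kb biases toward
SSV); the others are untouched, so passing tests demonstrate correctness of
the machinery under the model, not robustness to data artifacts. Multi-origin
soft sweeps are out of scope: all copies of the focal allele are identical by
descent.

## Problem sizes

Desk-scale defaults were chosen once for this package's own test and
reproduction runs: reference tables of 1,500-10,000 simulations per model
(the published analyses used 1e5) with acceptance counts of 50-100,
replicate counts of 8-25 per scenario cell (vs 100-1,000), and oracle checks
at small n (8-12 haplotypes, 10 kb, N = 500) where closed forms are exact.
Sensitivity of the inference to table size and acceptance rate is weak (the
posterior summaries move by less than replicate noise when tables are halved
or acceptance doubled), consistent with the tolerance study the method's
design anticipates. The `scripts/acceptance.py` reproduction uses 10,000
reference simulations per model and 24 replicates.

## Known limitations

- Sample size <= 256 haplotypes (bitmask capacity); haploid haplotypes only
  at the simulator level (diploid VCF is an I/O convention).
- X-linked inheritance, balancing selection, multi-population statistics
  (F_ST, XP-EHH) and recurrent mutation at the focal site are not modelled.
- The GLM adjustment assumes local linearity of the statistics in the
  parameters over the accepted region; with very small reference tables the
  accepted region widens and individual posteriors can be lumpy (the
  replicate-averaged summaries remain stable).
- `f1` is weakly identified by design — its posterior stays close to the
  prior — and model choice between SSV and SDN is reliable only for strong
  selection (alpha around 1,000) with f1 above a few percent; the validation
  suite reproduces these operating characteristics at reduced scale.
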