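# Methods

`steppingstone` implements a complete simulation-based validation of
coalescent model selection against F-statistics for linear metapopulations:
a stepping-stone coalescent simulator, pairwise differentiation estimators
with Mantel isolation-by-distance tests, and a Bayesian structured-coalescent
sampler whose path-sampling marginal likelihoods rank competing hypotheses of
population structure.  This note records the models, the conventions, and the
design choices a maintainer would need.

## The simulated world

Demes sit on a one-dimensional lattice (default 10 demes), each of effective
haploid size N_e, exchanging migrants only with adjacent neighbors.  `m` is
the per-generation probability that a lineage migrates to one *specific*
neighbor, so a neighboring pair exchanges N_e·m effective migrants each way
per generation, edge demes emigrate at total rate m and interior demes at 2m.
(The alternative reading — m as total emigration split between neighbors —
would halve the per-pair flow; the choice is isolated in `SimulationParams`
and documented here because published lattice simulators are ambiguous on
this point.)

Every deme underwent an instantaneous ten-fold expansion 10,000 generations
before sampling, emulating post-glacial demographic growth; backward in time
the per-deme size drops from N_e to N_e/10 at that instant.  Genealogies are
generated by an event-driven structured coalescent: within deme i a lineage
pair coalesces at rate 1/N_i(t) per generation; waiting times are exponential
(continuous generations).  At N_e ≥ 10^4 this diffusion-scale approximation
is indistinguishable from a discrete Wright–Fisher lattice; the test suite
cross-validates the engine against an independent coalescent simulator
(msprime) configured with the same demography, comparing the distributions of
segregating sites and mean pairwise differences.

Sequences (default 500 bp) evolve by HKY85 with rate-matrix
transition/transversion parameter κ = 9.0 (under uniform base frequencies the
expected transition:transversion *count* ratio is κ/2; κ is what the
simulator's published counterpart calls the transition/transversion ratio)
and per-site mutation rate 10⁻⁷ per generation, i.e. mitochondrial-like DNA.
The rate matrix is normalized to one expected substitution per site per unit
time, so branch lengths in mutational units are expected substitutions.

The ten default parameter sets cross N_e ∈ {10⁴, 10⁵, 10⁶} with m chosen so
N_e·m ∈ {10, 100, 1000}, plus a panmictic control simulated as one population
of N_e = 10⁶ and partitioned into 10 pseudo-demes in blocks of 20 samples in
sampling order.  Defaults: 20 samples per deme, 500 bp.

What the generator does *not* emulate: selection on the locus, rate
heterogeneity among sites, sequencing error, missing data, multi-island
dispersal kernels, or two-dimensional geometry.  Passing tests therefore
demonstrate correct behavior under a clean stepping-stone world, not
robustness to the many ways real mtDNA departs from it.

## F-statistics and the Mantel test

Pairwise (two-population) estimators are computed for every deme pair:

* **Phi_ST** — two-level AMOVA on the matrix of pairwise sequence
  differences: Phi_ST = σ²_among/(σ²_among + σ²_within).
* **Weir–Cockerham θ** (haploid) — each distinct haplotype is one allele;
  per-allele among/within mean squares are combined over alleles,
  θ = Σa/(Σa + b-terms).

Monomorphic pairs have nothing to partition and are defined as 0 (flagged).
Negative estimates are kept: the downstream Mantel correlation is scale-free
and clipping at zero would bias it.  The Mantel test correlates the genetic
matrix with lattice distance |i − j|, permuting rows and columns jointly;
it is one-tailed (isolation by distance predicts a positive association) with
999 permutations and α = 0.05 by default — none of these choices is dictated
by the problem, they mirror the defaults of the R package ecosystem this
replaces.  For matrices small enough (n! ≤ permutations) the permutation
distribution is enumerated exactly.

`island_model_fst` provides the equilibrium island-model anchor
F_ST = 1/(1 + c·Nm).  The default c = 4 is Wright's diploid convention, under
which 100 migrants per generation ↔ F_ST ≈ 0.0025 (printed as 0.002); c = 2
gives the strictly haploid version.

## The structured-coalescent sampler

State: a rooted, time-calibrated binary genealogy in mutational units with an
explicit migration path (piecewise-constant deme membership) on every branch,
plus Θ = N_e·μ per deme group and M = m/μ per ordered-pair rate group.
A `ModelSpec` lumps sampled demes into analysis demes and ties parameters
into shared groups; the free-parameter count (Θ groups + rate groups) is what
model complexity means here.

**Rate convention.** An unordered pair coalesces at rate `PAIR_RATE/Θ` with
`PAIR_RATE = 2` (total rate k(k−1)/Θ, the migrate-n bookkeeping).  The
constant is a single symbol in `coalmcmc/state.py`; all truth comparisons use
the same convention end to end via `effective_migrants(Θ, M) = Θ·M/PAIR_RATE`.
Equivalently, fitted Θ estimates are on a scale twice the simulator's N_e·μ.

**Priors** are windowed exponentials (exponential of the stated mean
truncated and renormalized): Θ ∈ [10⁻⁵, 10⁻¹], mean 0.01; M ∈ [10⁻⁴, 10⁶],
mean 10⁵ — the belief that island populations have N_e below one million and
migrant fractions below 10% of that, for mtDNA at 10%/Myr.

**Moves** (weights 0.3/0.3/0.2/0.2):

* subtree prune–regraft at fixed attachment height: the pruned lineage's
  migration path is redrawn by endpoint-conditioned simulation
  (uniformization with cached powers of the jump matrix); the displaced
  branch paths are spliced/split deterministically, so only one proposal
  density enters the Hastings ratio;
* node-height slide (uniform in the bracketing window; exponential tail
  proposal for the root) with the adjacent paths redrawn, plus a whole-tree
  scale move (log-uniform factor; Jacobian = one power of the factor per
  scaled coordinate) that lets chains traverse height scales quickly;
* migration moves: redraw one branch path, or resample one node's deme with
  its adjacent paths;
* a parameter sweep: reflected log-scale random walk over every Θ and M
  group.  The coalescent density is linear in sufficient statistics of the
  history (per-deme coalescence counts, occupancy integrals ∫k_i dt and
  ∫k_i(k_i−1) dt, per-pair jump counts), which are cached and make each
  group update O(1).

Guards: migration-path proposals are rejected beyond 2,000 events per branch
or 6,000 expected uniformization jumps — a memory/time guard in the spirit of
migrate-n's documented event truncation, biasing only states with extreme
rate × branch-length products.

**Initialization** is data-informed: a UPGMA tree on pairwise differences
(heights = distance/2), node demes by descent, and moment estimates for the
starting parameters — Θ₀ from within-deme diversity, M₀ by inverting a
Wright-style F_ST from the connected-pair divergences.  Starting decades away
from the data's migration rate strands short chains, because the rate and the
per-branch paths can only co-adapt gradually; this initialization is what
makes compressed runs usable.  Detailed balance is unaffected by where chains
start, and the zero-data prior-recovery test (below) checks the kernel
itself.

**Heating and evidence.** Chains run at the temperature ladder 1, 1.5, 3,
10⁵, i.e. power posteriors L^β with β = 1/T.  The three cold rungs are
Metropolis-coupled with cyclic adjacent-pair swap proposals.  The 10⁵ rung is
statistically indistinguishable from the prior (β = 10⁻⁵ tilts log L by a
negligible amount relative to its prior spread), so its expectation
E_β[log L] is estimated by iid prior-predictive sampling instead of a Markov
chain: parameters drawn by inverse CDF, genealogies by direct structured-
coalescent simulation (migration paths discarded — the likelihood sees only
the tree).  This is unbiased and sidesteps the severe mixing pathologies of
a near-prior chain on a data-sized state.  In the strong-migration regime
(lineage migration rate ≫ coalescence rate, separation > 10³) the simulation
switches to the exact limiting Kingman coalescent with pair rate
Σ_i π_i²·PAIR_RATE/Θ_i, π the migration chain's stationary distribution.

The log marginal likelihood is the thermodynamic integral ∫₀¹E_β[log L] dβ.
With only four rungs the straight trapezoid is badly biased on the hottest
interval, where the true path hugs the cold-side plateau and dives toward the
prior value only on a scale of ~1/range(log L).  The corrected estimate
integrates a cubic Bézier over that interval whose hot-end handle sits at the
plateau height projected with the cold-side slope, and a monotone cubic
(PCHIP) through the remaining rungs; below the hottest rung the path extends
flat.  Both the corrected and trapezoid numbers are reported.  The corrected
estimator is validated against a dense grid quadrature on one-deme toys
(agreement within 0.2 log units) and against refinement studies.

**Diagnostics**: ESS by Geyer's initial-positive-sequence truncation (FFT
autocovariance), Gelman–Rubin PSRF across replicate runs, shortest-interval
HPDs.

## Model selection

Seven lattice hypotheses (panmixia; 5-lumped-pair stepping stone with tied or
free parameters; 10- and 5-deme island models; stepping stone with tied or
fully free parameters — 1, 2, 13, 2, 2, 2 and 28 free parameters) and the
archipelago set (panmixia; two regional splits; the two-currents three-region
hypothesis with free pairwise rates, 3 + 6 parameters; island; stepping stone
tied/free; optional custom partition).  Replicate evidence estimates are
averaged per model; relative probabilities are the softmax of mean log
marginal likelihoods; the best and second-best models are compared by a
pooled-variance permutation t test (exhaustive when C(n, n_A) ≤ 10⁴).  The
ambiguity call is one-sided by default: with three replicate estimates per
model the exhaustive two-sided p can never reach 0.05 (floor 2/20), so a
two-sided rule would label every dataset ambiguous; the two-sided variant
remains available.  Exact mean ties break toward fewer parameters.

The posterior slope test regresses ln Θ on an island covariate (habitat area
or census size): each of 10,000 draws takes one posterior sample per island,
fits OLS, and the relationship is called significant when ≥ 95% of slopes are
positive.

## Problem sizes in the bundled experiments

The published schedule (5×10⁶ proposals per chain, sampling every 100,
2×10⁶ burn-in) is available via `MCMCConfig.published_scale()` and the `--scale
published` flags.  The bundled test-suite experiment uses the study's sampling
depth (20 samples × 10 demes, 500 bp) but compresses the chains to 1,200
proposals (400 burn-in, sampling every 4) with 100 prior-predictive draws,
and runs one scenario per N_e m regime at N_e = 10⁵: 5 replicate datasets at
N_e m = 10, and 2 each at N_e m = 100 and 1,000.  The N_e = 10⁴ scenarios are
excluded from this tier: their 200-tip, weakly polymorphic datasets leave the
data-informed start far from the posterior mode, and within the compressed
budget only the unconstrained panmictic chain can relax there — the
comparison would measure chain length, not the models.  Expect the
weak-structure regime (N_e m = 100, F_ST ≈ 0.002) to defeat the compressed
chains: separating stepping-stone structure from panmixia there is precisely
what requires the full schedule.
Within a dataset every model is fitted with a common random seed, so model
comparisons share Monte-Carlo noise.  The F-statistic power analysis runs the
full 100 replicates × 10 parameter sets.  At this compression the evidence
estimates carry noise of a few log units between equally sized models, which
is the main caveat when interpreting per-dataset winners; the power analysis
is at full scale and carries only binomial error.

## Numerical notes and known limitations

* HKY transition matrices come from a cached spectral decomposition (the
  model is reversible, so the symmetrized generator is diagonalizable);
  pruning partials are rescaled per site with accumulated log factors.
* UPGMA initialization jitters zero-length internal branches by ≥ 0.05/L so
  node times are strictly ordered.
* The Mantel test warns and returns p = 1 on a constant matrix; monomorphic
  deme pairs are flagged rather than dropped.
* Single locus, no recombination, fixed κ (no substitution-model averaging);
  missing data and ambiguity codes are rejected rather than imputed.
* Evidence differences below ~5 log units between models of similar
  complexity should not be trusted at the compressed chain lengths; rerun
  with `--scale desk` (2×10⁵ proposals) or `published` for publication-grade
  comparisons.
* The migration-event guards bias the sampler against states with extreme
  event counts; parity with migrate-n's own truncation behavior is not
  attempted.
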