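# Methods

This note documents the probabilistic models, the sampler, the numerical
choices, and the validation designs implemented in `mscoal`, together with
the design decisions taken where more than one reasonable convention exists.

## Conventions

**Time axis.** All trees are height trees: extant tips at height 0, heights
increasing into the past. Trees are strictly binary; polytomies are
rejected at parse time. Node ids are stable across MCMC proposals, so
per-branch quantities (population sizes, rates, rate categories) keyed by
the child node id survive topology rearrangements.

**Population sizes.** `N_b` is stored as the haploid-equivalent size that
enters the coalescence rate directly: `j` lineages coalesce at rate
`C(j,2)/N_b`, and a branch of duration `tau` spans `tau/N_b` coalescent
units. With diploid effective size `Ne`, `N_b = 2*Ne`, so `tau/N_b`
equals the conventional `tau/(2*Ne)`. Keeping a single internal convention
with explicit converters avoids factor-of-two errors between the haploid
sizes used in simulation and the diploid `Ne` used in summaries. A
per-locus ploidy multiplier (default 1) rescales the effective size of a
locus; the gamma sufficient statistic absorbs the factor so pooling across
loci remains valid.

## Model components

### MSC coalescent density and analytical integration

Per species branch `b`, the sufficient statistics are the coalescence
count `n_b` and the integrated intensity `gamma_b = sum_j C(j,2) dt_j`
over lineage-count intervals, pooled across loci. The density is
`prod_b N_b^{-n_b} exp(-gamma_b/N_b)`. Under `N_b ~ InvGamma(alpha, beta)`
the per-branch marginal has the conjugate closed form

    beta^alpha Gamma(alpha+n_b) / (Gamma(alpha) (beta+gamma_b)^(alpha+n_b)),

which the test suite verifies against adaptive quadrature on random states
(relative tolerance 1e-6). The default fixes `alpha = 3` (prior cv exactly
1) and estimates only the mean `mu = beta/2`; when the mean is estimated
its hyperprior is a `1/x` density truncated to a configurable range
(default `[1e-8, 10]`) — a choice made here because no standard reference
pins it; it is proper and scale-neutral within the range. In the explicit
("mcmc") mode, sizes are sampled with a Gamma(shape 2, mean `mu`) prior.

### Species-tree prior

The birth–death prior is the reconstructed process conditioned on the
number of extant tips, with the origin time carrying an improper uniform
prior (equivalently: the process observed at a stationary time with `n`
species extant). With `lambda > mu`, `r = lambda - mu`,
`p1(t) = r^2 e^{-rt}/(lambda - mu e^{-rt})^2` and
`Q(x) = r e^{-rx} / (lambda (lambda - mu e^{-rx}))`, the joint density over
the labeled topology and internal heights `x_1 > ... > x_{n-1}` is

    2^{n-1}/(n-1)! * lambda * Q(x_1) * prod_i lambda * p1(x_i),

which reduces to `const * lambda^{n-1} e^{-lambda L}` (`L` = total branch
length) in the Yule case and makes the implied topology law uniform over
ranked labeled trees. The same law drives the simulator by exact
inversion: in CDF space the oldest speciation time is Beta(n-1, 2) and the
remaining times are i.i.d. uniform below it, so simulator and MCMC prior
agree by construction — a property the prior-sampling equivalence tests
rely on. Parameterization is by net diversification `d = lambda - mu` and
extinction fraction `f = mu/lambda`; `f = 0` gives Yule. When estimated,
`d` has a truncated `1/x` hyperprior and `f` a uniform prior on `[0, 1)`.

### Clocks

Relaxed-clock rate distributions (log-normal with real-space mean 1, i.e.
log-mean `-sigma^2/2`, or unit-mean exponential) are discretized into
quantile midpoints at probabilities `(i+0.5)/n_bins`, renormalized to mean
exactly 1; every branch carries a uniform-prior category index. The bin
count defaults to the number of branches (the prior-correctness protocol
uses 100). Renormalization (rather than raw quantiles) is this package's
choice; it makes the mean-1 contract exact at every bin count.

The species-tree relaxed clock assigns each species branch a relative rate
`R_b` (root fixed at 1, configurable); a gene branch's rate is
`r = sum_segments(c*L*R)/l` over its embedding segments, so `r*l` equals
the expected substitutions exactly (tested as an identity). Gene-tree
relaxed clocks draw a category per gene branch; the strict clock sets all
rates to the locus rate `c`.

Per-locus rates `c_i` carry a lognormal(real-space mean 1, sigma 0.6)
prior. Two identifiability devices are available: the default constrains
the arithmetic mean of the locus rates to 1 and moves rate mass between
locus pairs; the unconstrained mode samples each `c_i` freely (plus a
counter-scaling move along the rate–time ridge). The unconstrained mode is
what the calibration tests use, because there the generative law and the
prior can be made to match exactly.

### Phylogenetic likelihood

Felsenstein pruning over compressed site patterns, reversible JC/HKY/GTR
models normalized to one expected substitution per unit rate x time, and
discrete-gamma among-site rate variation with equal-weight categories
whose rates are analytic within-bin means (BEAST convention), renormalized
to mean 1. Gaps, `N` and IUPAC ambiguity codes become partial-state tip
vectors. Per-pattern rescaling guards against underflow; transition
matrices for all branches and categories are computed in one batched
eigendecomposition call. Branch rates and durations enter only through
their product (tested).

**Concatenation mode** scores every locus directly on the species tree and
drops the coalescent density — the shared-tree model that concatenated
analyses assume. This is how the package reproduces
concatenation-vs-coalescent comparisons inside one codebase.

## Operators

Default mix (weights in `operators.default_operators`, tuned once on the
synthetic fixtures): joint and single-tree scales, uniform node-height
slides, root-offset scales, naive rooted NNI ("narrow exchange") and
height-preserving SPR with incompatibility auto-rejection, Wilson–Balding
on gene trees, rate-category resample/swap moves, and hyperparameter
scales. Scale kernels draw `s` uniformly on `[lam, 1/lam]` with Hastings
ratio `s^(dim-2)`.

Coordinated kernels:

* **CoordinatedUniform** picks a non-root internal species node `S`,
  selects per gene tree the "connected component" of nodes whose
  descendant individuals overlap both children of `S` and fall entirely
  inside `S` (a purely topological criterion, hence symmetric), computes
  the height window `(D, U)` within which shifting `S` plus the component
  changes no topology, and draws the new height uniformly. The analytic
  bounds are validated against a grid-scan oracle.
* **CoordinatedExponential** treats the species root the same way; the new
  root offset `x'` above the bound `D` is exponential with rate `lambda`,
  independent of the current `x`, so the log Hastings ratio is
  `lambda*(x'-x)`. During burn-in `lambda` is retuned every 100 proposals
  to `ln 2 / mean(x)` (median at the running posterior mean of `x`) and
  frozen afterwards (diminishing adaptation).
* **CoordinatedExchange** proposes a species NNI (restriction of the
  target edge to the uncle) or a height-preserving SPR (uniform target
  among branches crossing the pruned node's height; NNI and SPR outcome
  sets are disjoint so the kind probabilities cancel), then rebuilds the
  gene trees: every gene coalescence whose height lies in the affected
  window — between the attachment height and the merge node of the old and
  new attachment paths — is erased, along with every lineage link crossing
  the window top; events are re-paired bottom-up at their original heights
  among lineages co-resident in a species branch of the proposed tree, and
  the dangling lineages are re-matched to the upper structure within their
  species branch. Cutting *all* crossing links (not only broken ones) is
  what makes the move reversible; the Hastings ratio is the log-ratio of
  forward choice probabilities and the replayed probability of rebuilding
  the original configuration, with the within-branch matching factorials
  cancelling. The default NNI:SPR weight is 2:1.

Naive topology operators remain in the default mix (coordinated topology
moves are opt-in), mirroring the recommended production configuration; the
prior-correctness protocol enables everything.

Invalid proposals (incompatibility, empty choice sets) auto-reject via an
explicit validity flag rather than a `-inf` likelihood, keeping acceptance
bookkeeping clean.

## MCMC bookkeeping

The state caches per-locus branch rates and likelihoods; operators
invalidate exactly the loci they touch, and the cached posterior is
checked against a fresh recomputation periodically (and in tests, every
few steps). Chains are bit-reproducible for a fixed seed. Traces record
the posterior, likelihood, prior, coalescent term, tree prior, net
diversification, extinction fraction, population-size mean and
species-tree height; trees are logged as annotated newick. ESS uses
Geyer's initial-positive-sequence estimator. The convergence protocol
discards 12.5% burn-in (ceiling rounding), and doubles the chain — halving
the sampling rate so the stored sample count stays constant — until every
monitored statistic (those that actually vary under the run configuration)
reaches the ESS threshold, up to a doubling cap that is reported rather
than raised.

### Configuration schema (YAML)

```yaml
model:        # ModelSettings fields, e.g.
  popsize_mode: integrated        # or mcmc
  popsize_alpha: 3.0
  clock_kind: strict              # strict | st_ucln | st_uced | gt_ucln | gt_uced
  clock_sigma: 0.3
data:         # omit for prior-only sampling
  loci: [path1.fasta, path2.fasta]
  mapping: mapping.tsv            # haplotype<TAB>species
  schema: fasta                   # or nexus
subst: {kind: HKY, kappa: 3.0, gamma_shape: 0.2, gamma_categories: 4}
init: {diversification: 70.0, extinction_fraction: 0.3, popsize_mean: 0.002}
n_species: 5                      # prior-only runs
samples_per_species: 1
chain_length: 100000
sample_interval: 100
operators: {coordinated_topology: false, naive_topology: true,
            coordinated_heights: true}
out_prefix: chain
```

Substitution-model parameters (kappa, gamma shape, base frequencies) are
fixed per run rather than estimated; the validation designs all use the
generating values, and rate-parameter estimation is orthogonal to the
coalescent machinery this package is about.

## Simulators and validation designs

The generator is first-class code: conditioned birth–death species trees
(exact inversion, uniform ranked topologies built by uniform pairwise
merging), per-branch sizes from gamma or inverse-gamma, per-branch rates
from the continuous or discretized mean-1 distributions (optionally
renormalized to mean exactly 1 over non-root branches; the root rate is
1), MSC gene trees by per-branch exponential coalescence, and sequence
evolution site-by-site with per-site gamma categories. Three presets
encode the validation designs:

* `prior_test` — 5 species, 1 haplotype each, birth 200 / death 100,
  inverse-gamma(3, 0.004) sizes, species rates from a discretized
  (100-bin) lognormal, two loci with clock rates 0.5 and 2.0. Used for the
  sampling-from-the-prior equivalence checks. The lognormal sd is 0.3
  (matching the inference default; the design itself fixes only "mean 1").
* `simstudy` — 21 species, 2 haplotypes each, birth 100 / death 30,
  gamma(2, 0.002) sizes, renormalized lognormal(0.3) species rates,
  lognormal(0.6) locus rates, HKY kappa 3 with 4-category gamma(0.2)
  sites, 600 nt, 26 loci. Its mean branch length is about 3 coalescent
  units (the reported scale of the design this emulates); reduced
  versions drive the recovery and coverage tests.
* `spils` — fixed pectinate topology ((((A,B),C),D),E), Yule rate 10,
  inverse-gamma(3, 0.2) sizes (heavy incomplete lineage sorting by
  design), strict-clock JC sequences, 1000 nt, 100 loci, one haplotype
  per species. Reduced versions drive the rate-bias direction check.

Fixture layout per replicate: `loci/locus_###.fasta`,
`truth/{species.nwk, gene_###.nwk, rates.tsv}`, `mapping.tsv`. The `scale`
knob shrinks only the number of loci, never the distributions.

**What the simulators do not emulate:** recombination within loci,
migration or hybridization, serially sampled tips, sequencing error, and
alignment uncertainty. Passing tests therefore demonstrate correctness of
the inference machinery under the model, not robustness of the model to
real-data violations.

## Problem sizes used by the test suite

The distributional protocols run at desk scale, chosen so the whole suite
stays comfortably runnable on a laptop core: prior equivalence with ~20k
retained MCMC samples against 20k direct simulations; operator-specific
chains of 1e5–4e5 steps; the coalescent-unit summary over 30 replicates;
the rate-bias direction check with 8 replicates x 20 loci x 400 nt and
sign tests pooled over the A and B branches; parameter-recovery coverage
over 20 repetitions of a 3-species, 3-locus design. Distribution
comparisons thin chains heavily (effectively independent draws) because
KS and chi-square tests assume independent samples.

## Numerical choices and degenerate inputs

* Compatibility checks use a relative tolerance of 1e-13 at height
  boundaries; embeddings raise on genuinely incompatible inputs.
* Transition matrices come from the symmetrized eigendecomposition; rows
  are clipped at 0 and renormalized to guard round-off at extreme
  distances.
* The pruning likelihood returns `-inf` (never raises) when a site
  likelihood underflows to 0 even after rescaling, so MH treats such
  states as zero-probability.
* Ties: MCC ties break lexicographically on the sorted clade strings; HPD
  ties break toward the lower endpoint; burn-in row counts round up.
* Constant trace series report ESS 0 with a warning (a stuck chain should
  look stuck, not converged).
* `hpd_interval` refuses fewer than 20 samples; `rate_regression` refuses
  fewer than 3 pairs or zero-variance truth.

## Known limitations

* Single-threaded; likelihoods are vectorized over patterns and
  categories but loci are scored sequentially.
* No BEAGLE-style likelihood acceleration and no checkpoint files; the
  convergence protocol doubles in-process.
* The coordinated SPR rebuild erases all window events, which is simple
  and provably reversible but churns more of the gene trees than a
  minimal rebuild would; its acceptance rate drops on data-rich loci,
  where the naive moves and height operators carry the mixing.
* At strongly reduced per-locus information, posterior-mean species-branch
  rates under the coalescent drift upward by roughly 0.1 when the truth is
  a strict clock, although a matched-prior calibration on the same
  geometry is centered (the sampler itself is unbiased); the effect is a
  small-sample interplay between rate-time confounding and the rate prior
  and fades as loci lengthen. The rate-bias direction check runs at a
  scale where the qualitative contrast is clean.
* Only nucleotide models (JC/HKY/GTR); no codon or amino-acid models, no
  invariant-sites category, no partitioned models within a locus.
* Species networks, migration and serially sampled tips are out of scope.
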