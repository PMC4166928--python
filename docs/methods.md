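# Methods

This note records the models implemented in `mitoclock`, the defaults and
why they were chosen, the numerical choices, and what the synthetic-data
based validation does and does not establish.

## Serial coalescent simulation

Genealogies of heterochronously sampled tips are drawn from the serial
(heterochronous) coalescent. With `t` measured in years before present and
increasing into the past, the effective population size is
Ne(t) = N₀·exp(−g·t); while `k` lineages are active, the coalescence
intensity is k(k−1)/2 ÷ (Ne(t)·τ) per year, with τ the generation time.
Tips join the active set at their sampling ages. Waiting times are drawn
exactly by time rescaling: a unit exponential is inverted through the
cumulative intensity Λ(t), which is analytic for exponential growth — no
discretization anywhere. When g·t would overflow the exponential (a
pathological combination of growth rate and tip age) the simulator raises
a diagnostic error rather than returning a distorted tree.

Defaults: N₀ = 10,000 (an effective female population size conventional
for human mtDNA), g = 2.5 × 10⁻⁵ per year (visible growth over the last
~100 ky without collapsing the ancient part of the tree), τ = 25 years (a
conventional human value; it only ever appears multiplied by N₀, since
all rates are per year). These defaults produce panels whose modern-tip
TMRCAs fall around 10⁵ years, the right order for human mtDNA.

## Sequence evolution

Partitions follow the K = 4 scheme used for the mitochondrial molecule —
PC1+PC2, PC3, HVS1+HVS2, rRNA+tRNA — with unlinked substitution models and
rates, and a topology shared across partitions. Default per-partition
rates (subs/site/year): 0.756 × 10⁻⁸, 3.323 × 10⁻⁸, 31.434 × 10⁻⁸ and
1.007 × 10⁻⁸ respectively; whole-molecule analyses use 2.143 × 10⁻⁸.
The default substitution model is HKY with κ = 22 and base frequencies
(0.309, 0.313, 0.131, 0.247), i.e. the strong transition bias and A/C-rich
composition characteristic of the mtDNA light strand. Rate variation
across sites uses the discrete-gamma construction with category rates
equal to conditional means on equal-probability slices (4 categories by
default), optionally with a proportion of invariant sites; site-category
assignments are drawn once per site and held fixed across the tree
(standard rates-across-sites).

Rate matrices are normalized to one expected substitution per site per
unit distance and exponentiated through the π-symmetrized
eigendecomposition, which is exact and stable for every reversible model
here; row sums are verified to 10⁻⁹.

## Postmortem damage (PMD)

Deamination converts C→T and G→A in ancient templates. Generatively, each
C or G of an ancient tip of age `a` is flipped independently with
probability q = 1 − exp(−δ·a); modern tips are untouched. The rate δ has
units of damage events per site per year; the fitted value for real
ancient mtDNA is of order 10⁻⁹, which for the oldest anatomically modern
sample (39,464 years) translates to less than one expected damaged site
per genome — the arithmetic `expected_damaged_sites` reproduces.

In the likelihood, the same convention appears as modified tip partials:
with q as above, an observed T assigns weight q to a true C (and an
observed A weight q to a true G), while C/G observations keep their
one-hot vector. Keeping the undamaged-emission weight at 1 (rather than
1 − q) treats damage as able to create, never destroy, the observed T/A;
the probability-normalized alternative would differ only at second order
in q for realistic δ, and the chosen form is the exact matched inverse of
the generative simulator, so simulation and inference form a coherent
pair. Damage applies to all C/G sites, not only transition-prone ones —
the simulator and the likelihood share this convention.

## Damage QC

A damaged sequence carries an excess of private variants that look like
deamination. A column is a singleton for sequence *i* when, ignoring rows
with N or a gap, exactly one row (*i*) differs from the single state shared
by all the others; columns with three or more states are discarded.
Deamination-consistent means the focal base is T against a C background or
A against a G background. The expected deamination-consistent fraction
under no damage is estimated from the pooled singleton spectrum of the
modern sequences rather than set to a theoretical constant, because the
mutation spectrum itself is asymmetric (transitions dominate); each
ancient sequence is then tested with a two-sided exact binomial test, and
flagged only for a Bonferroni-significant *excess*. A pooled variant of
the test supports the negative control (undamaged ancient sequences
should match the modern spectrum). GC-content differences between sample
classes use Welch's t-test on per-sequence GC fractions, gaps and Ns
excluded; degenerate classes are reported as not testable.

Power note: with δ = 5 × 10⁻⁷ the expected number of damaged sites on a
16.6-kb genome ranges from ~9 (2.5-ka tip) to ~150 (40-ka tip). Validation
panels therefore inject damage into tips from the older half of the
ancient age range, where the damage signal is unambiguous at the
family-wise 5% level; for very young tips the same δ produces too few
events for a singleton test to see, which is a property of the test, not
of the implementation.

## Likelihood engine

Felsenstein pruning over compressed site patterns with per-pattern
scaling (each internal node's partials renormalized by their maximum,
log-scales accumulated), so 300-tip trees stay in range. Gamma categories
are summed with their weights at the root. Branch substitution lengths
are rate × duration × branch-multiplier; the strict clock fixes all
multipliers at 1, UCLN gives each branch an independent lognormal
multiplier with real-space mean 1 and log-space standard deviation
`ucld_stdev` (the clock-likeness diagnostic). The per-node update loop is
JIT-compiled with numba when available, with an equivalent numpy path
otherwise. Partials are cached per node and only ancestors of a changed
edge are recomputed during MCMC.

## Priors and calibration

- **Tip priors**: normal(age, radiocarbon SE), truncated at zero by
  rejection in the move; a plain number fixes a point age (no density
  term).
- **Node priors**: normal(mean, 0.2 × mean) on the age of the MRCA of a
  named tip set, applied softly (to the MRCA of the current topology,
  monophyletic or not).
- **Root prior**: offset lognormal with offset 5 My, real-space mean 6 My
  and 97.5% quantile 7.5 My. Three published constraints (minimum, mean,
  95% interval) over-determine the two-parameter family, so the mean and
  the upper quantile are honored exactly (σ solved by Brent's method to
  10⁻¹⁰, the smaller root taken — the larger one concentrates all mass at
  the offset) and the implied lower quantile follows.
- **Flat bounds**: rates uniform on (10⁻¹⁰, 10⁻⁵) subs/site/year. A
  uniform node-age window of (0.0645, 50) My is available and is applied
  to the root by default. Applying the 64.5-ky lower bound to *every*
  internal node would contradict any serial tree whose recent coalescences
  are younger than the oldest tip, so the all-nodes variant is opt-in
  (`bound_all_internal_nodes=True`).
- **Nuisance priors**: N₀ log-uniform on (10, 10⁸) — scale-free, so the
  tree height is calibrated by the data, not the prior; growth rate
  exponential with mean 10⁻⁴/year when sampled; δ log-uniform on
  (10⁻¹⁵, 10⁻⁶); `ucld_stdev` exponential with mean 1/3.

The date-randomization machinery deliberately runs with the growth rate
fixed at zero and only the scale-free N₀ sampled: an informative prior on
g pins the coalescent timescale and thereby fakes a rate calibration even
after the tip dates are shuffled, which would mask exactly the loss of
signal the test is designed to detect.

## MCMC

Metropolis–Hastings with: uniform node-age slides within parent/children
bounds, a scale move on the root branch, Gaussian moves on
interval-calibrated tip ages, scale moves on rates, N₀, δ and
`ucld_stdev`, reflected-normal moves on g, per-branch multiplier scales
under UCLN, an occasional independence draw of each rate from its flat
prior, and a joint "updown" move that scales rates up while scaling all
internal node ages (and, coherently, N₀ and g) down — the move that
crosses the rate–height ridge, without which tip-dated posteriors mix an
order of magnitude slower. A narrow subtree-exchange topology move exists
but is off by default: the comparisons this package implements concern
rates and ages on a fixed topology (cross-comparisons explicitly require
it), and desk-scale validation supplies the known simulated topology or
the serial-UPGMA heuristic tree. Proposal widths adapt toward ~25%
acceptance during burn-in only, and runs are bit-reproducible given a
seed. Multiple chains are pooled after per-chain burn-in; any parameter
with pooled ESS < 200 flags the run as unconverged.

Desk-scale defaults are deliberate: recovery analyses use 40-tip, 4-kb
panels with 120k steps (20% burn-in, thinning 50), which yields rate ESS
of ~50–100 and stable 95% HPDs; the date-randomization analyses use
30k-step chains on 5-kb panels. These sizes are the package's validation
profile; analyses of real 350-genome panels would scale the same code to
longer chains.

ESS uses the initial-positive-sequence truncation of the autocorrelation
sum, capped at n; HPD intervals are the shortest contiguous window
containing ⌈0.95·n⌉ sorted samples, ties resolved to the lowest start.

## Marginal likelihoods

Path sampling integrates E_β[log L] over a Beta(0.3, 1)-quantile ladder of
32 power posteriors by the trapezoidal rule; stepping-stone sums
log-mean importance ratios between adjacent rungs on the same samples.
Both carry delta-method Monte-Carlo errors and warn on rungs whose
log-likelihood ESS is poor. The generic interface takes any sampler of
log-likelihood values at a given β, so the conjugate-model validation and
the phylogenetic adapter use identical estimator code.

## What the synthetic validation shows — and what it does not

The generator reproduces the statistical structure the analysis assumes:
heterochronous coalescent genealogies, partitioned rates, dating error,
deamination. Passing tests therefore establish internal correctness
(simulation → inference round trips, oracle equivalence, calibrated
priors), not real-data performance. Real ancient mtDNA additionally has
alignment error, reference bias, contamination, strand-specific damage
profiles and fragment-end effects, none of which are modelled; the QC
screen sees only genotype-level deamination excess, not read-level damage
curves. Rate estimates on real panels also depend on choices held fixed
here (alignment, partition search, haplogroup structure).

## Known limitations

- Logistic growth and clade-specific demographic priors are not
  implemented; one demographic prior applies tree-wide.
- UCLN uses continuous per-branch rate parameters (lognormal prior,
  mean-one multipliers) rather than a discretized-category
  implementation; with few branches the two differ slightly in prior
  geometry.
- The topology move set (narrow exchange) is sufficient for perturbation
  around a good starting tree, not for global tree search.
- The singleton screen needs enough damage events per sequence
  (δ·age·L ≳ 20) for useful per-sequence power; below that only the
  pooled test is informative.
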