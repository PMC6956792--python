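# Methods

## Model and procedure

`ppcoal` performs posterior predictive simulation for SNP-based
species-tree inference under the multispecies coalescent (MSC). The
fitted model is represented by a posterior sample of rooted,
(near-)ultrametric species trees plus a trace log of per-sample
likelihoods. The check draws species trees from that posterior,
simulates one replicate SNP dataset per tree under the MSC, and
compares summary statistics of the observed data (data-based checks)
or of re-inferences on the replicates (inference-based checks) against
the predictive distribution. Systematic discrepancy indicates that the
data were not generated by the model the inference assumed — the
canonical culprit for SNP data being gene flow between lineages.

### Coalescent simulator

The simulator is a native structured coalescent inside the species
tree. Conventions:

* **Time** is in generations before present; tips are at time 0. For
  posterior trees whose branch lengths carry multiplicative noise (and
  are therefore not exactly ultrametric), internal-node ages are taken
  as the maximum distance to a descendant tip, which guarantees ages
  increase rootward.
* **Ploidy.** `Ne` is a diploid effective size: a lineage pair in a
  population coalesces at rate `1/(2Ne)` per generation, so the
  expected TMRCA of two haploid samples in one population is `2Ne`
  generations. A split time quoted as "5N" means `5 × Ne` generations.
  Branch lengths supplied in coalescent units are converted by
  multiplying by `2Ne`.
* **Migration** (the MSC+m violation model) is symmetric secondary
  contact between two extant species: forward in time, `m` migrants
  per generation each way; backward in time each lineage in either
  population jumps to the other at rate `m/(2Ne)` while the contact
  window `[0, start_time]` is open. The window closes early if either
  species merges into its ancestor, and a window older than the pair's
  common ancestor is rejected as inconsistent. The event loop is an
  exact Gillespie walk with piecewise-constant rates, stopping and
  re-drawing at every speciation time and window boundary.
* **SNP ascertainment.** Each locus is an independent genealogy
  carrying exactly one mutation on an edge drawn with probability
  proportional to edge length. Since no edge of a binary-rooted
  genealogy subtends the full sample, every locus is polymorphic by
  construction — matching datasets specified as "k SNPs". The
  metadata mutation rate is carried through to writers but does not
  affect genotypes under this conditioning. There is no recombination
  within loci, no linkage between loci, and no multiallelic sites.
* **Reproducibility.** Each locus uses a counter-derived child stream
  of the master seed, so the same seed reproduces a matrix exactly and
  increasing `n_snps` appends loci without reshuffling earlier ones.

The simulator was validated against closed forms (mean TMRCA `2Ne` for
two haploids; mean total length `4Ne(1 + 1/2)` for three) and against
an independent coalescent implementation (msprime) on a two-population
split-with-migration model; the independent simulator is a test oracle
only, never a dependency of the pipeline.

### Summary statistics

* **Hudson `F_ST`**, per locus
  `N = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)`,
  `D = p1(1−p2) + p2(1−p1)`, combined across loci as `ΣN/ΣD` (ratio of
  sums). `N` equals between-minus-within heterozygosity with unbiased
  small-sample corrections, so per-pair values can be negative; they
  are reported as computed, never clamped, because clamping would bias
  the tail counts of the predictive comparison. Loci monomorphic
  within a pooled pair are uninformative for that pair and excluded.
  The estimator requires ≥ 2 haploids per species. A Weir–Cockerham
  alternative was considered and not implemented: only one estimator
  is exercised by the checks, and Hudson's is the sample-size-robust
  default for this kind of data.
* **`F_ST` mean (FSTA) and range (FSTR)** are taken over defined
  species pairs (range = max − min). Whether "range" should run over
  pairs or over loci is a genuinely open reading; over pairs was
  chosen and is what the outlier test also operates on.
* **Tree distances.** RF is the bipartition symmetric difference on
  the unrooted view, normalized by its maximum `2(n−3)` to lie in
  [0, 1]. KF is the unnormalized branch-score distance; the procedure
  only ever compares KF values on a common tip set, so scale cancels
  and no normalization is imposed (the branch-score distance is
  unbounded, so no bounded form is claimed). Both are computed through
  dendropy and cross-checked in the tests by brute-force bipartition
  enumeration.
* **Likelihood summaries** use the sample standard deviation (n−1).

### Decision rules

* **Two-tailed posterior predictive p-value**
  `p = min(1, 2·min(#above, #below)/N)`; exact ties count in neither
  tail, and an all-ties comparison returns p = 1 (no evidence of
  discrepancy). Violation when `p < alpha` (default 0.05).
* **`F_ST` outlier test**: per species pair, the mean of
  (empirical − predictive) over predictive datasets; outliers are
  points beyond the Tukey fences (hinges ± 1.5·IQR), with hinges
  computed by the five-number-summary convention of R's
  `boxplot.stats`. Any outlier is a violation and names the suspect
  pair. The fences are computed across pairs (not across datasets per
  pair — the other reading of an ambiguous procedure).
* **Tree-distance check**: a null distribution of distances between
  random distinct posterior-tree pairs (default 1000 pairs, drawn with
  replacement over pairs, members forced distinct) yields a threshold
  at its 95% quantile; per predictive dataset, 100 random trees of its
  re-analysis are compared to the source posterior tree; pooled over
  datasets, p is the fraction exceeding the threshold and violation is
  `p > alpha` (large predictive-to-source distances mean misfit).
  Pooling across datasets, rather than averaging per-dataset
  p-values, was chosen as the cleaner estimator of the same fraction.
* One predictive dataset per sampled posterior tree; uniform posterior
  subsampling uses the stride `round(i·(N−1)/(n−1))`, random
  subsampling is without replacement. Posteriors below 100 trees
  trigger a warning. Burn-in removal (ceil rule) is exposed for raw
  logs and defaults to 0.

## Synthetic posteriors

Inference on SNP data is external and expensive; all tests and the
harness emulate its output with a synthetic posterior: each sample is
the center tree, optionally hit by one random NNI move (probability
`topology_jitter`; edges incident to the root are avoided because a
swap there can leave the unrooted topology unchanged) and with every
branch length multiplied by mean-one lognormal noise of coefficient of
variation `length_jitter_cv`; trace likelihoods are i.i.d. normal.
This reproduces the right interfaces and controlled amounts of
posterior spread, but not MCMC autocorrelation, correlated
branch-length errors, or the systematic response of real inference to
misfit. Consequently the harness validates the checking machinery
(calibration, power direction, bookkeeping), not the full-pipeline
behaviour of any particular inference program.

## Simulation-study harness

The reference design mirrors the benchmark setting: 6 species on a
symmetric topology (cherries at 5N, third species at 10N, root at
20N), `Ne = 100,000`, 2 haploids per species, and for the violation
model a uniformly drawn species pair exchanging `m ~ U(0.5, 5)`
migrants/generation since 2.5N generations ago. Desk-scale defaults —
200 SNPs, 20 posterior trees, 20 predictive datasets, 10 replicates
per model — keep a run in minutes; these sizes are the package's
working defaults, while statistic definitions and decision rules are
size-free. Confusion matrices use the positive class "violation called
on an MSC+m dataset"; MCC returns 0 when a denominator factor is zero
(the convention consistent with degenerate always-one-answer
classifiers). The gene-flow trend is summarized by the Spearman rank
correlation between `m` and the p-value, with 0 returned for constant
input.

## Numerical choices and degenerate inputs

* Quantiles of the tree-distance null use numpy's default linear
  interpolation; hinge quartiles for the outlier fences use the Tukey
  convention (these two serve different procedures and intentionally
  differ).
* `two_tailed_ppp` on an empty predictive list, `F_ST` on a species
  with one haploid, tree comparisons on mismatched tip sets, and
  single-row trace logs all raise informative errors rather than
  returning sentinel values.
* Species pairs with no informative loci are reported NaN, excluded
  from mean/range/outlier computations, and error only when every
  pair is undefined.
* Seeds: every stochastic entry point takes a seed; internal
  per-replicate and per-locus streams are derived via
  `SeedSequence(entropy, spawn_key)` and reduced below 2³¹ where an
  integer seed is required.

## Known limitations

* `Ne` is constant across branches unless explicitly overridden per
  clade; no continuous-time `Ne` trajectories.
* Migration is symmetric and limited to tip-species pairs during one
  contact window; no ancestral-lineage migration, no more than one
  simultaneous pair per scenario draw.
* The SNAPP-style XML is a minimal compatible dialect defined by its
  own round-trip, not a byte-faithful BEAST2 template.
* Empirical matrices with missing data are accepted by the readers
  only insofar as missing codes are excluded upstream; the simulator
  itself never emits missing genotypes.
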