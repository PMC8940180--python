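# Methods

## The chronospace model

A dating analysis with fixed topology yields posterior samples of
chronograms: rooted ultrametric trees over one tip set, branch lengths
in Myr, tips extant at age 0. Each internal node is identified by its
clade key (the set of tip labels below it), so node ages can be matched
across samples and across analyses. A study that repeats the analysis
over the levels of several methodological factors produces a labeled
cloud of points in node-age space — the chronospace — with one row per
sampled chronogram and one column per internal node.

Node ages are extracted as the mean root-to-tip distance below each node
rather than a single path, which absorbs the rounding noise typical of
published tree files; a tree whose root-to-tip paths deviate from their
mean by more than a relative tolerance (default 1e-4 of the root age) is
rejected (or kept with a warning in lenient mode). Default sample
handling mirrors common MCMC practice: discard the leading 25% of each
run, thin to every 2nd tree, and cap at 200 trees per run by seeded
uniform subsampling, giving 400 chronograms for a two-run analysis.
Serially sampled (non-extant) tips are not supported.

## Between-group PCA and factor impact

For a factor with g levels, bgPCA eigendecomposes the covariance of the
g level mean vectors. Three numerical conventions matter and are fixed
here:

- **Unweighted levels.** Level means count equally and the data are
  centered on the grand mean *of level means*, so unbalanced designs do
  not tilt the axes. The covariance uses denominator g; this scale
  cancels in every reported ratio.
- **Rank and orientation.** Eigenvalues below 1e-12 × the leading one
  are treated as zero, so at most g−1 (and possibly fewer) axes are
  returned; identical level means yield zero axes. Each axis is flipped
  so its largest-magnitude loading is positive, making outputs
  deterministic.
- **Variance explained.** Per axis: the sample variance (ddof = 1) of
  all projected scores divided by the total variance of the age matrix
  (sum of per-column sample variances). Because ddof-1 variances ignore
  any centering constant, the choice of centering vector cannot change
  this ratio — which resolves, rather than begs, the question of which
  centered total to use. The statistic is translation-invariant per
  column and invariant under global rescaling of ages.

Per-node sensitivity (`node_shifts`) is the largest absolute difference
between level mean ages, sorted descending with ties broken by canonical
clade order (ascending clade size, then lexicographic tip list) and
flagged above a threshold (default 20 Myr). Consensus age ranges
summarize run-level *median* ages by their min/max across runs — medians
because that is the convention for reporting dated consensus trees.
Factors are analyzed one at a time; no interaction terms.

bgPCA is known to separate even randomly labeled groups. The
permutation baseline recomputes the total variance explained under label
shuffles that preserve level sizes and reports the observed value's
percentile. Under a true null the observed labeling is exchangeable
with the shuffles, so that percentile is uniform — the correct
calibration check is therefore "the observed value is not an outlier of
the null" (we use the Tukey fence rule, quartiles ± 1.5 IQR), not
containment in the interquartile range, which a null effect would fail
half the time by construction.

All internal nodes enter the chronospace by default, outgroup nodes
included (deep nodes are often the sensitive ones); `restrict_to`
confines the matrix to any clade subset.

## Posterior summaries

HPD intervals are computed exactly on the empirical sample: the shortest
window of ⌈mass·n⌉ consecutive order statistics, earliest window on
ties, no kernel smoothing. Medians use the midpoint convention. For
multimodal samples the HPD need not contain the median; it always
contains at least the stated mass. Interval probabilities are inclusive
fractions of samples inside [t_young, t_old]. Posteriors from different
settings can be merged with equal per-analysis weight; unequal set sizes
are first down-sampled evenly (deterministically) to the smallest size.
LTT curves step at each distinct internal-node age, merging coincident
ages, and close at the tip count at age 0; polytomies contribute
(children − 1) lineages per step.

## Gene properties and subsampling

Seven per-locus properties are computed after pruning outgroups (and any
taxa without data): mean bootstrap over internal branches that carry a
support value; RF similarity 1 − |A△B|/(|A|+|B|) over non-trivial
bipartition sets restricted to shared taxa (polytomies — e.g. a
deliberately collapsed contentious node in the reference — are handled
natively); rate = total tree length / terminals; root-to-tip variance on
the midpoint-rooted gene tree (gene trees arrive unrooted once outgroups
are pruned); saturation as the zero-intercept regression slope of
uncorrected amino-acid p-distances on patristic distances; RCFV
compositional heterogeneity; and occupancy as the fraction of reference
terminals with data. The 20-state amino-acid alphabet is assumed, all
other symbols treated as missing. Loci with fewer than four usable taxa
are skipped with a warning.

The usefulness axis is found by PCA on the correlation matrix of the
z-standardized table: the highest-variance component on which the two
signal loadings share one sign and the three bias loadings the opposite
sign, oriented so usefulness increases. If no component shows the
contrast, an error asks for a manual override rather than guessing. The
property set and the signal/bias column lists are arguments, so
properties can be swapped without code changes.

Selection schemes: usefulness, signal (RF similarity), occupancy
(descending), random (seeded), and clock-like — smallest root-to-tip
variance among loci whose rate lies within one sample standard deviation
of the mean rate. The filter exists because minimum-variance selection
alone favors near-constant loci that carry almost no dating information;
disabling it (`rate_filter_sd=None`) recovers the plain minimum-variance
ranking. All ties break on locus id, so selections are deterministic.

## Delta dissection

Per-site log-likelihoods of the same alignment under two candidate
topologies (natural log; same data and model, so no rescaling) are
summed within loci: δ(locus) = Σ lnL(T1) − lnL(T2), positive supporting
T1, antisymmetric under swapping, and summing to the total lnL
difference over a full partition. Partition files use the common 1-based
inclusive convention and are converted to half-open offsets internally.
The trend statistic averages δ over the top-k loci of a usefulness
ranking for k in multiples of a step (default 20) and fits a
second-degree polynomial by least squares. Cumulative top-k is the
default reading ("the most useful 20, 40, …"); disjoint blocks are
available via `mode="blocks"`.

## Synthetic data

The generator produces data with exactly the structure the analyses
assume, which is what the tests exercise.

- **Trees:** seeded pure-birth (Yule) simulation; after the last split
  the process runs one further waiting time so no internal node sits at
  age 0, and node times are rescaled to the nominal root age (default
  500 Myr, 60 tips).
- **Posterior jitter:** per sample, the root age is log-normal (default
  log-sd 0.01) around the true root age; every other internal node age
  is drawn top-down as a Beta fraction of its parent's realized age,
  with the Beta mean at the node's true relative position. Samples are
  therefore ultrametric with parent ≥ child *by construction* — no
  rejection sampling, which would bias ages near constraints. The Beta
  concentration is set per node so the marginal age sd is ≈ 5 Myr by
  default (a fixed concentration can be supplied instead); zero noise
  reproduces the true ages exactly.
- **Factor effects:** a shift δ (default +30 Myr on the 10 non-root
  clades with most headroom below their parents) is added to the true
  age of target clades for matching factor levels, clamped to the
  feasible interval; a clamp that realizes less than half the nominal
  shift warns.
- **Design:** the default factorial is 5 loci schemes × 2 substitution
  models × 2 clocks × 2 priors × 2 runs = 80 sets of 200 samples.
  Per-row seeds are content hashes of (master seed, levels, run), so
  extending the design never changes existing rows; everything is
  byte-reproducible under a master seed.
- **Loci:** gene trees are the species tree after k seeded NNI moves
  with log-normal branch noise, supports decreasing in k; alignments
  evolve under a uniform-exchange 20-state process with log-normal
  per-locus rates (default 0.002 subs/site/Myr) and optional taxon
  dropout.

What the generator does *not* emulate: extinction and fossilized
birth-death processes, rate autocorrelation along branches, realistic
amino-acid exchangeabilities, among-site rate variation, topological
uncertainty within a posterior, and between-run convergence failures.
Passing tests therefore demonstrate that the estimators recover known
structure under the stated noise model, not that any empirical dataset's
ages are correct.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full default design
(16 000 chronograms × 59 nodes) — generation and one full factor-impact
analysis take well under a second — and repeat it over 100 seeds for the
recovery and calibration checks. Effect recovery uses the injected
+30 Myr shift and expects the clock factor first in ≥95/100 seeds; null
calibration expects the observed value inside the permutation Tukey
fences in ≥90/100 seeds (60 permutations per seed). Key tolerances:
bgPCA agrees with a brute-force eigen implementation to 1e-8; Newick
round-trips preserve ages to 1e-9 Myr (12 fixed decimals per branch
length); HPD endpoints on 10 000 normal draws match the analytic
interval to 2%; δ sums conserve the total lnL difference to 1e-9.

## Known limitations

Chronospaces require a shared fixed topology across all analyses;
tip-dated or topologically variable posteriors are out of scope. bgPCA
quantifies linear mean separation only — a factor that changes posterior
*variance* without moving means will show near-zero impact. The
saturation slope assumes enough comparable sites per taxon pair;
extremely gappy loci yield noisy slopes. The CLI's `report` command
covers the chronospace branch of the workflow; gene subsampling and δ
dissection are separate subcommands.
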