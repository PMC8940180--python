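# chronospace

Sensitivity analysis of Bayesian divergence-time estimates.

Time-calibrating a phylogeny forces a string of methodological choices —
relaxed-clock model, substitution model, node-age prior, which loci to
sample — and inferred node ages can move by tens of millions of years
depending on them. This package represents each posterior chronogram as
a point in a **chronospace**: a multidimensional space in which every
axis is the age of one internal node of a fixed topology. Between-group
PCA of that space isolates and quantifies the effect of each choice on
divergence times. It is aimed at phylogeneticists running factorial
dating studies (e.g. PhyloBayes/MCMCtree analyses repeated across
settings) who want to know *which* decisions actually matter.

## The method

Let `X` be the n × p matrix of node ages (n posterior chronograms from
all analyses, p internal nodes, Myr), and let a factor (say, the clock
model) partition the rows into g levels. Between-group PCA (bgPCA):

1. compute the level mean vectors m₁,…,m_g (unweighted) and their grand
   mean m̄;
2. eigendecompose the covariance of the level means,
   B = (1/g) Σₐ (mₐ − m̄)(mₐ − m̄)ᵀ, keeping the ≤ g−1 axes with
   non-negligible eigenvalues;
3. project all centered samples onto those axes.

The **impact** of the factor is the fraction of the total age variance
carried by the projections: Σⱼ Var(X·vⱼ) / Σₖ Var(X·ₖ) (sample
variances, denominator n−1). Per-node sensitivity is reported as the
largest absolute difference between level mean ages, flagged above a
threshold (default 20 Myr). Because bgPCA separates even arbitrary
groupings to some degree, a label-permutation baseline calibrates the
observed value against chance.

Around this core the package implements the full workflow:

- **`chronospace.trees`** — Newick/NEXUS posterior samples → burn-in,
  thinning, per-run caps, ultrametricity validation, node ages keyed by
  clades, and the samples × nodes matrix;
- **`chronospace.summary`** — medians, exact empirical 95% HPD
  intervals (shortest window over the sorted draws), posterior
  probabilities of named time intervals, lineage-through-time curves;
- **`chronospace.genes`** — seven per-locus properties (mean bootstrap,
  RF similarity to a species tree, rate, root-to-tip variance,
  saturation slope, RCFV, occupancy), the PCA "usefulness" axis along
  which signal rises while bias falls, and five locus-sampling schemes
  (usefulness / signal / clock-like with a one-sd rate filter /
  occupancy / random);
- **`chronospace.likelihoods`** — gene-wise δ = Σ site lnL(T1) − lnL(T2)
  between two candidate topologies, and its trend over datasets of the
  top-k most useful loci (multiples of 20, quadratic fit);
- **`chronospace.simulate`** — seeded synthetic studies: pure-birth
  trees, posterior-like chronogram sets with factor-specific age shifts
  (valid by construction), factorial designs, synthetic loci.

## Worked example

`examples/01_chronospace_impact.py` simulates a 40-setting × 2-run
factorial study (200 posterior chronograms each, 60-tip tree) in which
only the clock model truly shifts ages (+30 Myr on 10 clades), then
ranks the factors:

```
chronospace: 16000 chronograms x 59 node ages

     factor  n_levels  n_axes  variance_explained_pct
      clock         2       1               43.280814
loci_scheme         5       4               20.254882
subst_model         2       1                6.685144
      prior         2       1                4.993938

nodes whose mean age shifts by >20 Myr between clocks: 10 of 59

observed clock variance explained: 43.3%
permutation null (label shuffles): median 16.8%, observed percentile 100
```

The clock factor — the only one with a real effect — explains twice as
much node-age variance as any null factor, exactly the 10 clades
carrying the injected shift are flagged, and the permutation baseline
confirms the separation far exceeds what bgPCA produces on shuffled
labels. The other example scripts walk through posterior summaries and
LTT curves (`02`), locus ranking and subsampling (`03`), and δ-score
dissection of conflicting signal (`04`).

A thin CLI mirrors the library (`chronospace simulate | build | bgpca |
impact | shifts | summarize | ltt | geneprops | select | delta |
report`); every command logs its effective configuration and input
hashes and writes deterministic TSV/JSON/SVG artifacts.

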