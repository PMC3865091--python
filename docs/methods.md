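# Methods

This note documents the statistical models, the numerical choices, and the
assumptions behind `comodnet`, in the order the pipeline runs them.

## Study design and traits

The reference design has three groups of 7 samples: ethanol-naive, air-exposed
two-bottle-choice drinkers (Air-2BC) and vapor-exposed dependent drinkers
(CIE-2BC). The *escalation of consumption* (EoC) trait codes the groups
0 / 1 / 2 and is used as a plain numeric vector in Pearson correlations — the
coding itself asserts an ordered, roughly equally spaced escalation, and no
ordinal-regression machinery is layered on top. Drinking amounts (g/kg,
average of the final 5-day session) are carried as a second quantitative
trait; the simulator draws them as `eoc + N(0, 0.3)` rescaled by 1.75 g/kg per
EoC unit (dependent mice in limited-access two-bottle-choice paradigms drink
roughly 2.5–4 g/kg), clipped at zero, with naive animals fixed at exactly 0.
This keeps drinking strongly but not perfectly correlated with the EoC code.

## Synthetic paired omics

The generator reproduces the statistical structure the analysis assumes, not
the biology of any particular array:

* Per module *m*, a latent factor over samples is drawn as
  `f_m = c·z(eoc) + sqrt(1 − c²)·N(0,1)`, standardized, so its population
  correlation with the EoC trait is the chosen `trait_corr` c. Member features
  are `loading·f_m + N(0, noise_sd)`; background features are pure noise.
* Each miRNA feature is printed as `n_replicates` spots (default 4) sharing
  the feature signal with independent `N(0, 0.3)` measurement noise; a
  fraction `flag_rate` (default 2%) of spot×sample entries is flagged
  uniformly at random. Per-feature baselines uniform on 6–12 log2 units are
  added and values exponentiated to mimic raw intensities. Proteins mimic
  standardized gel-spot log abundances: log2 scale, one measurement per spot.
* A repression link of strength s replaces the protein module's factor by
  `−s·f_miRNA + sqrt(1 − s²)·N(0,1)` (standardized), so the *factor-level*
  cross-omic correlation is exactly −s. The literal alternative — scaling the
  negated factor by s — would leave the correlation at −1 for every s > 0
  after standardization and make the strength parameter meaningless, so the
  mixture construction is used. Feature-level links replace a single protein
  feature's signal the same way.
* The target-prediction table carries one row per repression link
  (representative member features stand in for module-level links) plus
  random decoys; the PPI table contains the complete within-module edge sets
  (confidence uniform on 0.4–1) plus random cross edges at a configurable
  density (confidence uniform on 0–1). Planted rows carry an `is_planted`
  marker so recovery is measurable downstream.

Defaults (8 miRNA modules × 25 features + 300 background over 21 samples,
loading 0.8, noise sd 0.6; 6 protein modules × 20 + 130 background; module
trait correlations of magnitude 0.6–0.7 with two neutral modules) are chosen
to match the scale at which the reference analysis operates while staying
desk-sized; the full ~1,000-miRNA / ~1,250-spot shape is reachable through
the configuration. What the generator does *not* emulate: scanner/image
artifacts, dye bias, batch structure, heteroscedastic intensity-dependent
noise, realistic miRNA sequence identities, or indirect (transcription-factor
mediated) cross-omic coupling. Passing tests therefore demonstrate that the
pipeline recovers the structure it models — block-modular coexpression with
trait-correlated factors and linear repression — not that it is robust to
every artifact of real arrays.

## Preprocessing

Order of operations: between-array quantile normalization of raw intensities →
zero-weighting of flagged spots (a fully flagged spot row is dropped) →
per-feature median over the unflagged replicates → log2. Medians are taken on
the intensity scale, before the log transform, and there is no background
correction stage. Tie handling in quantile normalization assigns tied values
the mean of the reference values at their tied ranks; the "sorted columns
identical" identity is exact only in the absence of ties. The weighting of
flagged spots is binary (0/1). A feature whose replicates are all flagged in
a sample becomes missing; features missing in more than 25% of samples
(configurable) are dropped before correlation-based stages, and surviving
missing values are handled by pairwise-complete Pearson correlation.

## Moderated differential expression

The group-means model gives per-feature means and the pooled within-group
variance s² with df `d = N − k`. The hierarchical model `s² ~ s0²·F(d, d0)`
is fitted by matching the first two moments of log s²:

    E[log s²]  = log s0² + ψ(d/2) − log(d/2) − ψ(d0/2) + log(d0/2)
    Var[log s²] = ψ′(d/2) + ψ′(d0/2)

with ψ, ψ′ the digamma and trigamma functions. The trigamma equation is
inverted by Newton iteration (tolerance 1e-8); when the empirical variance of
log s² does not exceed its sampling expectation ψ′(d/2), the prior is
degenerate (d0 = ∞, full shrinkage to s0²). Contrasts use
`s̃² = (d0·s0² + d·s²)/(d0 + d)` and a two-sided t with d0 + d df; p-values
are clamped at the smallest positive double. With d0 = 0 the statistic
reduces to the classical pooled t — exactly so when the model is fitted on the
two compared groups (with three groups the pooled variance borrows the third
group's df, which is the standard behaviour of a group-means fit). BH
adjustment is implemented natively with the canonical `m·p/rank` step-up
arithmetic so it agrees bitwise with the textbook definition.

Directional summaries count a feature as up at fold change > 1.05 and
p < 0.05, and down at fold change < 1/1.05 (the reciprocal convention,
symmetric on the log scale); percentages are taken over all detected
features, raw p is used (q is reported alongside), and the prevalent
direction is the strict count majority.

## Signed coexpression networks

Similarity is `S = (1 + r)/2` on Pearson correlations (zero-variance features
excluded with a warning), adjacency `a = S^β` with the diagonal zeroed for
connectivity computations. The scale-free fit index bins connectivities into
10 equal-count (quantile) bins, estimates the frequency per unit connectivity
(bin frequency / bin width — an equal-count histogram density), and reports
the R² of the log–log regression signed by the negated slope, so positive
values mean decreasing degree distributions. Degenerate inputs (constant k,
fewer than 3 usable bins) score 0. The soft power is the lowest candidate in
1..20 with signed R² > 0.8; if none qualifies the argmax is selected and the
report flagged. The equal-count density estimator is used deliberately: on
block-modular data the degree distribution is bimodal and a fixed-width
binning saturates well below the 0.8 criterion for every β, whereas the
quantile binning resolves the decay and lets the stated selection rule
operate.

TOM uses the standard signed-network form given in the README with diagonal
1; clustering runs average linkage (UPGMA, via scipy) on `d = 1 − TOM`. The
alternative `d = 1 − a` is available behind the `dissimilarity` config switch
for comparison, but 1 − TOM is the default since the named procedure clusters
the topological-overlap dissimilarity.

### Dynamic tree cut

On TOM-dissimilarity dendrograms a static cut at the nominal height (0.995)
is vacuous — nearly every merge sits below it — while single-merge gap
criteria fail in the other direction: straggler module members chain onto
branches in increments of ~0.002–0.01, so no individual merge exhibits a
large gap. The implemented variant therefore cuts at an *adaptive core
height* derived from the tree's own height distribution,

    tau = h5 + c(deepSplit)·(cutHeight − h5),

where h5 is the 5th percentile of merge heights and c maps the deep-split
preset 0–4 to {static, 0.91, 0.82, 0.73, 0.64}. Components of the merges
below τ with at least `min_module_size` leaves are the modules; everything
else is unassigned (gray, label 0), and labels are renumbered 1..K by
descending size with the conventional colour palette (turquoise, blue, brown,
…; gray reserved for 0). Tight branches (planted or real modules) merge well
below τ and surface whole; structureless data produce chained dendrograms
whose sub-τ components stay below any reasonable minimum size, so noise-only
input comes out almost entirely gray. Higher presets lower τ and split
loosely joined branches into more, smaller modules. On the default synthetic
design this cut recovers the planted partition with adjusted Rand index
0.86–0.96 across seeds.

### Eigengenes, significance, traits

The module eigengene is the first right singular vector of the standardized
member × sample submatrix — unit norm across samples, oriented so its
correlation with the members' mean profile is nonnegative — with variance
explained = first squared singular value over the total. A single-member
module degenerates to that feature's standardized profile. Correlation tests
use `t = r·sqrt((n−2)/(1−r²))` with n − 2 df throughout (eigengene–trait,
feature significance, cross-omic). Feature-significance tables rank by |GS|
descending (dense ranks); whether signed or absolute GS should order such
tables is a presentation choice, and absolute ordering is used so strong
negative correlates surface.

## Cross-omic integration

The bidirectional step selects trait features of each omic at p ≤ 0.05,
|GS| ≥ 0.5, truncated to the top 20 by |GS| (mirroring the usual top-20
display; all three thresholds configurable), and correlates them against the
other omic's eigengenes alongside EoC and drinking. The anti-correlation
report screens module pairs at cor(ME_A, ME_B) < 0 with |r| ≥ 0.5 and ranks
by |r(ME_A, EoC)| + |r(ME_B, EoC)|, attaching the most negatively correlated
protein members as feature-level support. Because trait-correlated modules of
the two omics share the EoC driver, modules with opposite trait signs are
anti-correlated even without a planted link; the ranking deliberately does
not try to separate direct repression from trait-mediated coupling — that
distinction is not identifiable from correlation alone.

## Integrative network

Evidence filters follow the source operators exactly: miRNA DE p < 0.06
(cortex) / p < 0.05 (midbrain), protein DE p ≤ 0.2, coexpression |r| ≥ 0.5
with p ≤ 0.01 (cortex) / p < 0.05 (midbrain), PPI confidence ≥ 0.15. The
graph is undirected for all metrics (target-edge direction is kept as an
attribute); betweenness is normalized to pair fractions, closeness is
computed within each connected component without cross-component rescaling,
and eccentricity ranks ascending (smaller = more central) in the hub
aggregate, which is the unweighted mean of per-metric dense ranks with
lexicographic tie-breaks. The five metrics cover the centrality, clustering
and bottleneck families commonly used for this kind of scoring.

## Problem sizes, determinism, limitations

The default problem sizes (500 miRNA features / 250 protein spots over 21
samples, 20-seed recovery studies, 2,000-feature null calibrations) were
chosen so the whole suite and the acceptance script each run in well under
two minutes on one CPU; all stages scale to the full array sizes through the
configuration. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configurations reproduce byte-identical
TSV outputs, and the run manifest records the config hash, seed, input
checksums and package version. Known limitations: no covariates or array
weights in the linear model, no block-wise decomposition for very large
feature sets, no consensus/multi-set module analysis or module-preservation
statistics, no hybrid (PAM-like) tree-cut reassignment, and no live
annotation-service queries — target and PPI tables are plain TSV inputs.
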