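# comodnet

Integrative miRNA–protein coexpression network analysis for small paired-omics
studies.

`comodnet` is built for the situation where the *same* biological samples have
been profiled twice — e.g. miRNA microarrays and 2D-gel proteomics from the
brains of mice in a three-group chronic-ethanol drinking design (naive,
non-dependent drinkers, vapor-exposed dependent drinkers) — and the question is
not which single molecules move, but which *groups* of coexpressed molecules
track the phenotype, and whether miRNA modules repress protein modules. It is a
library first (importable API plus `examples/`), with a thin `comodnet` CLI for
running the pipeline end to end.

## What it computes

**Moderated differential expression.** After between-array quantile
normalization, removal of flagged spots and a median over the four replicate
spots per miRNA, a group-means linear model is fitted on log2 data. Per-feature
variances s² (df *d*) are shrunk toward an empirical-Bayes prior (d₀, s₀²)
estimated by log-scale moment matching (digamma/trigamma inversion), giving the
moderated t statistic

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d),
    t = log₂FC / (s̃·√(1/n₁ + 1/n₂)),   df = d₀ + d,

with Benjamini–Hochberg FDR control and directional (up/down) summaries at a
5% fold-change pivot.

**Signed weighted coexpression modules.** Pearson correlations map to the
signed similarity S(i,j) = (1 + cor(xᵢ,xⱼ))/2; the soft power β is the lowest
value in 1..20 whose weighted network a(i,j) = S(i,j)^β has an approximately
scale-free degree distribution (signed fit index R² > 0.8). The topological
overlap matrix

    TOM(i,j) = (Σᵤ a(i,u)·a(u,j) + a(i,j)) / (min(kᵢ,kⱼ) + 1 − a(i,j))

is clustered by average linkage on 1 − TOM, and a dynamic tree cut (cut height
0.995, deep split 2, minimum module size 5) labels the module branches; module
eigengenes (first principal components) summarize each module.

**Bidirectional cross-omic integration.** Eigengenes of each omic are
correlated with the ordinal escalation-of-consumption trait (0/1/2), drinking
amounts, and the top trait-correlated features of the *other* omic; negatively
correlated, trait-relevant module pairs are ranked as candidate
miRNA-repression relationships.

**Integrative network.** Region-specific evidence filters (cortex: miRNA
p < 0.06, protein p ≤ 0.2; coexpression |r| ≥ 0.5 with p ≤ 0.01) combine
differential expression, coexpression, miRNA→gene target predictions and
PPIs (confidence ≥ 0.15) into one typed graph scored with degree, betweenness,
closeness, clustering and eccentricity; hubs are ranked by mean per-metric
rank.

**Synthetic paired-omics generator.** Every stage is testable without
downloads: the generator plants block-modular correlation structure
(module latent factors with chosen trait correlations), replicate spots with
flags, and miRNA→protein repression links with matching target/PPI tables.

## Worked example

```bash
python examples/03_coexpression_modules.py
```

```
soft power beta = 15, signed R^2 = 0.819
module sizes: {1: 26, 2: 26, 3: 25, 4: 24, 5: 24, 6: 23, 7: 22, 8: 21} (+ 309 gray)
module eigengene vs EoC trait (r near +-0.6-0.7 marks trait-relevant modules):
module trait      r     p
   ME1   eoc  0.609 0.003
   ME2   eoc -0.719 0.000
   ME3   eoc -0.732 0.000
   ME4   eoc  0.783 0.000
   ME5   eoc -0.810 0.000
   ME6   eoc -0.094 0.685
   ME7   eoc  0.205 0.374
   ME8   eoc  0.654 0.001
```

The generator planted 8 modules of 25 features (six with trait correlations of
magnitude 0.6–0.7, two neutral) among 300 noise features; the pipeline selects
β = 15 as the lowest power reaching scale-free fit R² ≥ 0.8, recovers all
eight modules at sizes 21–26, leaves the noise gray, and the eigengene–trait
correlations separate the six trait-relevant modules (|r| ≈ 0.6–0.8,
p ≤ 0.003) from the two neutral ones. The other examples walk through
differential expression, cross-omic anti-correlation and network hub scoring;
`examples/06_full_pipeline.py` (or `comodnet all --seed 42 --out out/`) runs
everything and writes per-stage TSVs plus a run manifest.

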