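# Methods

## Model and assumptions

`modelmatch` compares differential-expression (DE) results, never raw data.
Each dataset enters as one record per gene: a direction of change and a
p-value from whatever DE engine produced it (edgeR, limma, DESeq2, ...). The
package assumes those p-values are honestly computed two-sided DE p-values;
it makes no distributional assumption beyond that, because every downstream
statistic depends only on the *ranking* induced by the signed significance
`s_g = -log10(p_g) * sign(Δ_g)` and on set overlaps of top-ranked genes.

The congruence score treats the two gene signatures being compared as draws
from their shared measured universe. Its null model is the hypergeometric
one: if the model's top-K up genes were a uniform random K-subset of the
shared universe, the overlap with the reference's top-K up genes would be
hypergeometric. Each quadrant is tested one-sided for over-enrichment only;
the subtraction of the discordant quadrants (B, C) supplies the penalty
direction, and a two-sided test would double-count that evidence. Quadrant
tests use the *post-restriction* set sizes (the signature lengths after
intersection with the shared universe), not the nominal K, so datasets with
fewer than K significant genes per side remain comparable.

Tail p-values are evaluated in log space (`scipy.stats.hypergeom.logsf`) and
floored at 1e-320 before the -log10 transform, capping any single quadrant's
contribution at 320 and keeping scores finite. The exactness of the tail is
verified against an independent enumeration oracle (exact binomial-coefficient
sums) over every parameter combination with N ≤ 30.

## Key parameters

| parameter | default | units | why |
|-----------|---------|-------|-----|
| `K` (signature size) | 1000 | genes/side | large enough to reflect reproducible biology rather than the extreme tail; fixed so every dataset pair is compared on equal footing |
| `p_floor` | 1e-300 | p-value | p printed as 0 must not produce an infinite rank statistic |
| `min_present` (portrait) | majority of inputs | datasets | a consensus gene should be measured by most studies before it can vote |
| RRHO `step` | N/100 | ranks | ~100×100 grids give figure-scale resolution at negligible cost |
| `min_fraction_present` (embedding) | 0.5 | fraction | mirrors the portrait's majority rule for the gene panel |

Ties in rankings break by ascending gene symbol; ranking ties in model tables
break by dataset id. Both choices are arbitrary but deterministic across
platforms, which matters more than the specific rule.

## Portrait construction

The portrait treats each input dataset equally: per gene,

    consensus_score = (support_up - support_down) / n_present
                      * mean(|s| over datasets measuring the gene)

The vote margin captures directional consistency; the mean magnitude keeps
strongly regulated genes ahead of marginal ones at equal consistency. A pure
vote count is available by ignoring the magnitude factor, but the weighted
form is the default because unweighted votes produce massive ties at small
dataset counts. Genes with a tied vote get consensus sign 0 and are excluded
when the portrait is converted back to a DE table for scoring. The
reconstructed table materializes `p = 10^(-|consensus_score|)` so the signed
significance round-trips exactly.

Duplicate symbols after harmonization collapse to the record with the
largest |s|: the most significant probe or transcript represents the gene;
averaging would dilute exactly the rank extremes the signatures depend on.

## RRHO grids

At each pair of rank cutoffs (i, j) the overlap x of the two top lists is
compared with its expectation ij/N. Over-enriched cells store
`-log10 P(X ≥ x)` (positive), under-enriched cells `+log10 P(X ≤ x)`
(negative), so concordant dataset pairs light up the main diagonal and
reversed pairs the anti-diagonal. The grid's quantitative anchors are
properties, not pixels: it is transpose-symmetric in its arguments, its
(K, K) corner reproduces the congruence module's up-up quadrant tail on the
same inputs, and negating one dataset maps cell (i, j) to the negated value
at (N−i, j). Rendering (`plot_grid`) is a deliberately thin layer over the
exported matrix.

## Synthetic data: what it emulates and what it does not

The generator plants a signed effect vector (a fraction of genes shifted by
`effect_size` noise-SD units, signs balanced) and derives each dataset by a
three-way per-gene choice: keep the planted effect with probability ρ
(congruence), flip its sign with probability δ (discordance), silence it
otherwise. Unplanted genes are always null, so ρ = δ = 0 yields an honest
global-null dataset. Observations are two groups of `n_per_group` normal
samples compared by Welch's t-test; the pipeline consumes only (direction,
p), so a count-based RNA-seq simulation would add machinery without changing
any contract being tested.

Defaults are chosen to resemble a typical bulk DE study: 20,000 genes
(protein-coding transcriptome scale), 10% of genes perturbed at 1 SD, 6
samples per group, unit noise. One master seed drives everything;
per-dataset seeds derive at fixed offsets so streams are independent but
reproducible.

What the generator does **not** emulate: gene-gene correlation, batch and
platform effects, region/sex covariate structure, heavy-tailed or dependent
noise, and symbol-mapping noise across species. Passing recovery tests
therefore show that the statistics behave correctly under their own
assumptions — clean directional signal plus independent noise — not that any
particular biological ranking is right. On real data the scores inherit
whatever biases the upstream DE analyses carry.

## Problem sizes used in the self-checks

The oracle comparison enumerates all ~87,000 hypergeometric parameter
combinations with N ≤ 30. Null calibration uses 200 replicate dataset pairs
at 2,000 genes, K = 200. Ranking recovery uses a 7-model library
(ρ ∈ {0.9, 0.7, 0.5, 0.3, 0.1}, a null, and a δ = 0.9 discordant model) at
5,000 genes with a portrait from 5 datasets. Portrait recovery uses 5
datasets at the default 20,000 genes and checks sign concordance with the
planted truth among the 500 strongest consensus genes. These sizes exercise
every code path at full statistical strength while keeping the whole suite
fast enough to run on every commit.

## Known limitations

* Symbol harmonization is uppercasing plus an optional user-supplied alias
  table; there is no ortholog inference, so genes without a shared symbol
  across species silently drop out of the shared universe.
* The score is not calibrated across pairs with very different shared-universe
  sizes; rankings against a common reference (the intended use) are safe, but
  comparing scores across different references should be done with care.
* The expected-vs-observed sign rule in RRHO cells puts exact-expectation
  cells on the over-enrichment branch; at interior cells with integer ij/N
  the mirror property holds only approximately.
* `embed_2d` coordinates are a visualization; every quantitative statement
  should use the correlation-distance matrix it returns alongside.
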