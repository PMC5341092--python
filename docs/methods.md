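# Methods

## The analysis in one paragraph

Each gene in a testis-expressed protein set carries a category label
derived from mouse knockout phenotypes — prepubertal lethality, male
sub-/infertility, or nonessential — together with four quantitative
covariates: pairwise human–mouse dN/dS (plus its components dN and dS),
PPI node degree, tissue-specificity τ, and GO-slim multifunctionality.
The analysis asks two questions: how the covariates relate to each other
across the whole set (zero-order and partial rank correlations), and how
they differ among the three essentiality categories (Kruskal–Wallis with
pairwise Mann–Whitney post-hocs, category-composition tests for X-linkage
and immunity involvement, and bootstrap confidence intervals for
category medians).

## Classification rules

Alleles enter classification only if they are targeted ("Targeted" allele
type), are annotated "Null/knockout", affect a single gene, and were
observed homozygous — or hemizygous for X-linked genes in male mice.
Lethality evidence is any Mammalian Phenotype (MP) term inside the
`preweaning lethality` (MP:0010770) or `lethality at weaning`
(MP:0008569) subtrees, or one of four broader survival terms
(MP:0011400, MP:0010831, MP:0008770, MP:0010769) accompanied by a
curation flag confirming sub-Mendelian prepubertal death. Sub-/infertility
evidence is `male infertility` (MP:0001925) or `reduced male fertility`
(MP:0001922), or any configured additional male-reproductive root
accompanied by a confirming curation flag. Genes with both kinds of
evidence — counting any male-reproductive phenotype including decreased
litter size, across alleles — are excluded as doubly essential. Remaining
exclusions fire in a fixed precedence order (double essentiality >
unclear-or-fertile > litter-size-only > requires-extra-manipulation >
special case); the order is a determinism choice, since the narrative
exclusion protocol it encodes does not specify one. Terms flagged
female-specific never create sub-/infertility evidence but do not
themselves exclude a gene. Manual literature verification cannot be
recomputed, so it enters the pipeline as curation flags on input rows.

## Covariates

* **τ** is computed on raw FPKM over the 24 analysis tissues (the three
  female-specific tissues ovary/placenta/uterus are dropped first; a
  27-tissue mode and a log2(FPKM+1) option exist for sensitivity
  analyses). All-zero profiles have undefined τ (x_max = 0) and are
  excluded rather than assigned 0.
* **Node degree** comes from a cleaned simple undirected graph: deleted
  accessions removed with their edges, renamed ones replaced, products of
  non-protein-coding genes dropped unless rescued by an HGNC
  protein-coding flag, unreviewed accessions merged into a reviewed
  accession of the same gene (edges inherited), duplicate edges and
  self-interactions collapsed. A gene linked to several accessions gets
  the one of highest degree; equal-degree ties break to the
  lexicographically smallest accession (a determinism choice).
  Accessions mapping to multiple genes stay in the graph — they still
  contribute to neighbours' degrees — but are not selectable at gene
  level.
* **Multifunctionality** is the size of the union of minimal-cover
  GO-slim biological-process ancestors over a protein's BP annotations
  (is_a and part_of edges only, the classic map2slim convention;
  regulates is not traversed). The root BP term is ignored when its
  evidence code is ND. The immunity flag is reachability of
  `immune system process` (GO:0002376) from any BP annotation.

## Statistics

All procedures are implemented from first principles; scipy contributes
only the reference distributions (t, χ², normal).

* Spearman ρ is the Pearson correlation of average ranks; two-tailed p
  from t = ρ√((n−2)/(1−ρ²)) on n−2 df.
* Partial Spearman correlation comes from the inverse of the Pearson
  correlation matrix of ranks, ρ_xy·z = −Ω_xy/√(Ω_xx Ω_yy), with p from a
  t distribution on n−2−k df.
* Kruskal–Wallis H uses the tie correction H′ = H/(1 − ΣT/(N³−N)),
  T = t³−t per tie group; p from χ² on g−1 df.
* Mann–Whitney U is exact (dynamic-programming enumeration of the null
  distribution of U) when n_a·n_b ≤ 400 and the data are untied, else a
  tie-corrected normal approximation with continuity correction; the mode
  is overridable. The exact and approximate paths agree to |Δp| < 0.01 by
  n = 20 per group.
* Pearson χ² has no Yates correction. Fisher's exact test uses the
  probability-mass two-sided rule; for 2×3 tables it is the
  Freeman–Halton extension (full enumeration of tables with the observed
  margins). The test is chosen automatically: exact whenever any expected
  cell count is below 5.
* Holm's step-down adjustment takes an explicit family size m that may
  exceed the number of p-values passed, supporting families inflated by
  alternative-definition recalculations. Default families: the three
  zero-order plus three partial correlations involving dN/dS form one
  family of six; the remaining zero-order correlations a family of three;
  post-hoc tests a family of three per variable.
* Median confidence intervals use the percentile bootstrap with
  nearest-rank endpoints, default B = 100,000 resamples, drawn from a
  counter-based Philox generator for bit-reproducibility. Percentile
  (rather than BCa) is the minimal reading of "bootstrap CI" and is the
  documented default.

Empirical null calibration: over 2,000 null replicates, the size of the
Spearman, partial Spearman, Kruskal–Wallis, Mann–Whitney (approximate)
and χ² tests at α = 0.05 lies within [0.04, 0.06]. Fisher's exact test is
deliberately conservative on discrete tables — its attainable size is
below the nominal level — so the suite asserts validity (size ≤ nominal)
rather than a two-sided band for it.

## Synthetic-data generator

The generator draws a latent Gaussian vector per gene. Target Spearman
correlations among (dN/dS, degree, multifunctionality, τ) are converted
to latent Pearson correlations by r = 2·sin(πρ_s/6) (exact for the
bivariate normal copula), with projection to the nearest
positive-definite correlation matrix if an inconsistent target is
supplied (the projection is recorded). Category structure enters as
additive location shifts on the latent scale before the marginal
transform. Because a mixture of shifted components adds between-group
covariance, the within-category correlation matrix is compensated —
W = σσ′∘R_target − B, where B is the shift covariance — so the *global*
sample Spearman matrix converges to the target (verified to ±0.03 at
n = 10,000; within ±0.08 at the default n = 965).

Default study conditions: 965 genes split 57/502/406
(sub-/infertility / lethality / nonessential); target correlations
(dN/dS,degree) = −0.229, (dN/dS,multifun) = −0.134, (dN/dS,τ) = 0.088,
(degree,multifun) = 0.398, (degree,τ) = −0.304, (multifun,τ) = −0.082;
per-category X-linkage proportions 5/57, 8/502, 27/406 and immunity
proportions 11/57, 140/502, 130/406 (realized as exact per-category
counts with random membership). Latent shifts (sub-/infertility,
lethality, nonessential, in within-category SD units): dN/dS
(+0.45, −0.18, +0.16); degree (−0.35, +0.28, −0.25); multifunctionality
(−0.25, +0.20, −0.20); τ (+0.70, −0.26, +0.22); dS (−0.35, −0.10, +0.22).
These produce the canonical median orderings — sub-/infertility highest
in dN/dS and τ, lethality highest in degree and multifunctionality and
lowest in dN/dS and τ — at magnitudes giving strongly significant
Kruskal–Wallis results at n = 965 while keeping the global correlation
distortion small.

Marginals are not dictated by any data source and are chosen as
realistic families, all overridable: dN/dS ~ Beta(1.6, 14) (support
(0,1), median ≈ 0.085 — all values below 1, i.e. purifying selection
throughout); degree ⌈lognormal(σ=1, scale=8)⌉ (heavy-tailed counts ≥ 1);
multifunctionality 1 + NegBin(4, 0.4) capped at the 40-term toy slim
pool; τ ~ Beta(2.2, 1.5) (testis-biased, right-shifted); dS ~
Gamma(4, 0.13); dN is derived as dN/dS × dS. dS has no target
cross-correlation and is compensated to be uncorrelated with the other
latents within categories.

Fixture emission inverts each downstream computation so the round trip
is exact: the FPKM matrix uses one-dominant-tissue profiles
(peak 100, baseline 100·(1−τ), so recomputed τ equals ground truth to
float precision); the GAF file annotates each gene with children of
exactly `multifunctionality` distinct slim terms (one inside the immunity
subtree when the immunity flag is set); the edge list realizes the
ground-truth degree sequence by Havel–Hakimi construction (non-graphical
sequences are repaired by ±1 adjustments, recorded in the manifest and
written back to the ground truth); the phenotype-allele table cycles
through the evidence variants of each category, including hemizygous
alleles for X-linked genes and decoy non-targeted alleles the filter must
drop. The toy MP and GO ontologies are small synthetic trees bundled with
the fixtures (written by code, labelled synthetic in their headers).

## What the simulation does and does not show

Passing round-trip and calibration tests demonstrates that the pipeline's
bookkeeping, classification logic, and statistical machinery are correct
and deterministic, and that the generator reproduces the intended
correlation and location structure. It does not demonstrate anything
about real interactomes or expression atlases: the synthetic network is
a degree-sequence construction without biological topology (no
clustering, no community structure), expression profiles have a single
dominant tissue rather than realistic co-expression, the global copula
is assumed to hold within categories (real within-category structure is
unreported), and dS saturation is not simulated. Conclusions about real
data require the real inputs.

## Numerical choices and degenerate inputs

Zero-variance rank vectors make correlations undefined (error). A
singular rank-correlation matrix (e.g. exactly duplicated variables)
makes the partial correlation undefined (error). Kruskal–Wallis on
all-identical pooled values is an error; two identical groups give H = 0.
All-zero expression rows are excluded from τ with a ledger entry. Fisher
enumeration compares point probabilities with a 1e−9 relative tolerance
to absorb floating-point noise in the ≤-observed rule. Exclusion-ledger
counts balance the gene universe exactly (asserted at run time);
duplicate-id collapses are recorded as non-balancing notes. Report TSVs
are written with a fixed float format, making same-seed reruns
byte-identical.

## Problem sizes used in the test suite

Unit and acceptance tests run the default 965-gene study once per
session, a 10,000-gene draw for the convergence check, 2,000-replicate
null calibrations, and 200 small (90-gene) null studies for the
generator's type-I check; bootstrap tests use B between 500 and 100,000.
These sizes keep the full suite at well under a minute while leaving
every statistical check adequately powered.

## Known limitations

* The pairwise post-hoc χ²/Fisher choice is made per pairwise table, so
  a variable can mix test types across pairs (as composition tables do
  when one category is small).
* The exact Mann–Whitney path requires untied data; heavily tied count
  variables always take the approximate path regardless of sample size.
* The Freeman–Halton implementation enumerates 2×C tables only — enough
  for three-category composition tests; wider tables would need a
  network-algorithm implementation.
* The classifier encodes literature curation as input flags; it cannot
  detect miscurated flags, only apply them consistently.
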