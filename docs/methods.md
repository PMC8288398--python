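# Methods

This note records the models, defaults and design decisions behind
`isletage`, in the order the pipeline runs them. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Synthetic data model

Counts are drawn from a gamma-Poisson (negative-binomial) hierarchy on a
genes × cells grid. The mean of gene *g* in cell *c* is assembled
multiplicatively and then renormalized per cell so that expected totals
follow the cell's library size:

    rate(g, c) = π_g · T(g, type_c) · D(g, donor_c) · A(g, c) · H(g, c) · N(g, c)
    mean(g, c) = L_c · rate(g, c) / Σ_g rate(g, c)
    count(g, c) ~ NB(mean(g, c), θ_g / λ_c)

with the following components (all log-scale parameters are **log2**):

- **π_g, baseline abundance** — log-normal, σ = 1.6 (natural-log scale of
  the draw); genes named by the configuration (hormones, chaperones,
  markers, program genes) are assigned to fixed abundance classes
  (`baseline_boost`, spread 0.25) so that, e.g., hormone share of the
  transcriptome does not swing by an order of magnitude between seeds.
  Hormones (GCG/INS/SST/PPY) carry boost 200 and a 2⁵ within-type marker
  enrichment, making the own-hormone a dominant transcript as in real
  islet cells; program and noise-coupled genes carry boost 10 (chaperone-like
  abundance — a program planted in dropout-dominated genes would be
  unrecoverable by any method and would not emulate the study, whose aging
  DEGs are well-detected genes).
- **T, cell-type profile** — besides the named markers, every gene gets a
  per-type log-normal factor with log2 sd 0.5 (`type_profile_sd`): real
  endocrine types differ genome-wide (hundreds of marker genes per type),
  not only at canonical hormones. Without this, donor structure
  out-modularizes type structure in graph clustering, contradicting the
  observed behaviour of islet data where types dominate.
- **D, donor batch effect** — per-donor per-gene log-normal factor, log2 sd
  0.1 by default (0.2 in the aging-axis stress scenario), shared by all of
  a donor's cells. This is what the aging-axis procedure must disentangle
  from age.
- **A, aging program** — old donors' cells of a type get 2^log2FC per
  program gene; programs can be restricted to one sex. Default: a
  100-gene β program (50 up at +1 including HSP90B1/HSPA5/CALR/PDIA*/
  DNAJB*/CDKN1A/CDKN2A, 50 down at −1) and an 80-gene α program (±1).
- **λ_c, dispersion inflation** — old cells of flagged types draw
  λ = 1 + (mult − 1)·G, G ~ Gamma(shape 1, mean 1), so inflation is
  heterogeneous across cells with the configured mean (default 1.5 in α
  and β only). The NB size is divided by λ.
- **N, noise coupling** — designated genes' means are multiplied by
  λ^strength (default strength 3), and those genes get a tight NB size
  (θ = 8): genes that track a latent stress factor closely are necessarily
  low-dispersion around it, like the ER chaperones that correlate with
  transcriptional noise in aged β-cells. Because λ > 1 only in old cells,
  coupled genes are genuinely age-upregulated; their expected log2FC,
  log2 E[λ^s], is recorded in the truth tables.
- **H, hub regulator** — a per-cell log-normal latent activity u multiplies
  the hub gene (HSPA5) and its 30 targets (u^strength), creating the
  co-expression a network method must recover. Targets exclude other
  TF-list genes so the hub is the only regulator sharing the latent.
- **L_c, library size** — log-normal, mean 10⁵, σ = 0.35. Together with
  the abundance spread this calibrates the design target of ≈4 389 genes
  detected per cell at 6 000 genes total.

Default design: 8 young + 8 old donors (4 F / 4 M each), 5 575 cells at
proportions α 0.50 / β 0.20 / δ 0.15 / PP 0.15 (true proportions are not
published; configurable). Determinism: one `numpy` Generator seeded from
the (config, seed) pair drives every draw.

What the generator does **not** emulate: read-level artifacts (FASTQ,
UMI collisions), doublets, ambient RNA, ERCC spike-ins, low-rank
(correlated-across-genes) batch effects, and cross-type compositional
coupling beyond per-cell renormalization. Passing recovery tests on this
model therefore demonstrates correctness of the statistics under a
realistic count law, not robustness to every artifact of real data.

## Quality control and normalization

Cells below `min_genes` = 1 000 detected genes or `min_counts` = 10 000
UMIs are dropped (the study's exact thresholds are not published; both are
configurable and logged, and every decision is listed per cell in the QC
report). Genes are never filtered implicitly. Normalization scales each
cell to 10⁵ counts and applies log2(x+1); all downstream log2FCs are
differences of these values.

## Cell typing

PCA (50 components, randomized solver, seeded) → symmetric 15-NN graph →
Leiden modularity optimization at resolution 0.1. Greedy agglomerative
modularity (Clauset–Newman–Moore) was evaluated first and produced poor
partitions on graphs whose neighbourhoods are 95% type-pure, so the Leiden
optimizer is used; the low resolution targets major-population granularity
— the endocrine types — because finer within-type structure (donor blocks,
aging states) is the business of later stages, not of typing. Clusters are
annotated by z-scoring each canonical marker's mean expression across
clusters (removing hormone scale differences) and assigning the top-scoring
type; a top-vs-second margin below 0.25 leaves a cluster "unassigned".
Marker discovery is one-vs-rest two-sided Wilcoxon on log-normalized values
with BH correction (log2FC ≥ 0.5, FDR ≤ 0.05, expressed in ≥ 25% of the
type).

## Transcriptional noise

For one cell type, genes expressed in ≥ 10% of its cells are kept; the
centroid is the mean log-normalized profile per (type, age group); a cell's
noise is its Euclidean distance to its own group centroid divided by
√(n genes). Centroids are per age group *on purpose*: a mean aging shift
(DEGs) must not masquerade as noise — the statistic isolates dispersion
around the group mean. The metric is pluggable (`1 − Pearson` to the
centroid as the alternative). Old vs young is a Welch two-tailed t-test on
per-cell noise. Noise-correlated genes use Pearson r across the type's
cells with a positive-only rule (r > 0.6, BH-FDR < 0.05); noise-rank bins
are display-level only.

The Welch test treats cells as independent; donor batch effects induce
within-donor correlation that the test ignores. The null calibration
(uniform p over 200 no-inflation replicates) is therefore run at
`donor_effect_sd` = 0 — with strong donor effects the cell-level test is
anticonservative, a known limitation shared with the per-cell tests of the
field.

## Aging axis

Within one type, the per-cell mean log-expression and detected-gene count
are regressed out of every gene, with the covariates centered **within
donors** first. Rationale: these "complexity" covariates form the dominant
global PC of scRNA-seq data, and an aging program genuinely shifts them
(a 100-gene program changes detected counts), so uncentered regression
would delete unbalanced programs while no regression lets the age contrast
rotate into the global mode. Donor-centering removes only within-donor
complexity variance and leaves every between-donor contrast — age programs
and single-donor batch shifts alike — for the consistency filter to judge.

PCA (10 components, genes centered) follows. For each component up to
`max_pc` = 10: orient so old cells score higher, compute the cell-level
old-vs-young AUC, and require *donor consistency* — every donor's median
score on its age group's side of the midpoint between the group medians.
Donor medians are the evidence unit because age is constant within a donor.
The consistent component with the highest AUC is the aging axis; if none is
consistent the type is reported "not discriminated" (the expected outcome
for δ/PP cells and for no-aging data). Midpoint thresholding then assigns
old-donor cells above the threshold "old-like" and young-donor cells below
it "young-like" (never across donor age, by construction); DEGs between the
states use Wilcoxon + BH on the *unregressed* values with |log2FC| ≥ 0.5,
FDR ≤ 0.05. The direct all-old-vs-all-young contrast is computed with the
same test as a cross-check, and sex stratification reruns the whole
procedure per sex.

The automated PC search (instead of manual inspection) and the strict
all-donor consistency rule are this package's choices; softer consistency
criteria are conceivable but less auditable.

## Gene-set statistics

Set scores are per-cell means of log-normalized expression over the set's
genes present in the matrix, compared between groups by Welch t-test.
Fold-change matrices report per-type old/young log2FC masked to genes
called differential in ≥ 1 type with the DEG defaults. Overlap enrichment
is the upper-tail hypergeometric. GSEA is pre-ranked with weight = |score|
and a **gene-permutation** null (random same-size sets), NES = ES divided
by the mean |null ES| of the same sign, with BH q across the tested sets —
gene permutation is chosen over phenotype permutation for determinism and
desk-scale speed, and is a documented divergence from the original GSEA;
NES values are not comparable across implementations. All curated lists
(UPR branches, ERAD, GenAge/SASP-style, TF lists) are user inputs; the
repository ships only small illustrative sets over simulated gene names.

## Ligand–receptor test

Score = arithmetic mean of (mean ligand in sender, mean receptor in
receiver) on log-normalized values; combinations where either gene is
expressed in < 10% of the relevant type are reported untested with the
reason. The null shuffles cell-type labels across cells (sizes preserved;
one shared shuffle per iteration for all pairs), and
p = (1 + #{null ≥ obs}) / (n_perm + 1), so the attainable floor is
1/(n_perm+1). This is the dot-plot statistic convention of
permutation-based interaction tools.

## Regulatory network

Edge weight = |Spearman correlation| between regulator and target
log-normalized expression over the analyzed cells (monotone-invariant,
deterministic; constant genes get weight 0); edges above the 0.90 weight
quantile of all candidate pairs are retained; hubs rank by out-degree, ties
by total weight then lexically. Regulators default to the DEG set
intersected with a user TF list. Rank correlation is used instead of a
tree-ensemble importance for determinism and speed; no equivalence to any
specific published network tool is claimed — recovery of planted hubs on
synthetic truth is the contract.

## Problem sizes and numerical choices

Recovery checks run at the full design scale (5 575 cells, 6 000 genes;
10 replicates for the noise pattern). Calibration nulls use reduced sizes
chosen to estimate the relevant rate precisely: 200 replicates of a
240-cell/400-gene no-structure dataset for noise-p uniformity, 100
replicates of a 320-cell/600-gene dataset with donor effects for the
axis type-I rate, and a 480-cell null with 63 pairs × 16 ordered type
pairs (≈1 000 combinations, 500 permutations) for the interaction test.
The aging-axis recovery scenario runs at 3 000 genes: with iid per-gene
donor noise the planted-direction cosine is information-bounded by the
ratio of planted mass (100 genes at |log2FC| 1) to accumulated donor noise,
and 3 000 genes is the scale at which the planted direction is cleanly
identifiable while donor confounding is still strong (donor sd 0.2 there).

Ties in Wilcoxon use the tie-corrected normal approximation; undefined
statistics (constant genes) are assigned p = 1 rather than NaN; BH is
implemented once (statsmodels) and reused everywhere; permutation p-values
use add-one estimators and never report 0. All stochastic steps take
explicit seeds, and the pipeline fans a single run seed out to per-stage
seeds through a fixed counter scheme.

## Known limitations

- There is no single canonical definition of per-cell transcriptional
  noise in the literature (gene subset, distance and normalization all
  vary); ours is a declared, pluggable choice with the standard intent of
  measuring dispersion around the group mean.
- Cell-level tests (noise Welch, Wilcoxon DEG) ignore within-donor
  correlation; donor-level aggregation enters only through the axis
  consistency rule.
- Published DEG counts, specific PC indices (PC9/PC4) and p-values from the
  monkey dataset are not reproducible here — the raw data have no public
  accession — so all guarantees are property-based on synthetic truth.
- GSEA's gene-permutation null is liberal for correlated gene sets
  relative to phenotype permutation.
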