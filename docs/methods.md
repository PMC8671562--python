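# Methods

`synotreg` implements the computational stages of a paired single-cell
transcriptome + TCR (5' scRNA/V(D)J) analysis of regulatory T cells sampled
from two tissue compartments — peripheral blood (PB) and synovial fluid (SF)
— together with a truth-labelled synthetic-data generator that makes every
stage testable without access to patient data.  Upstream steps (alignment
and UMI quantification, normalization-based integration, dimensionality
reduction and clustering) are out of scope; cluster labels are treated as
input metadata.

## Cell-level quality control

Per-cell metrics are computed on the raw UMI matrix: mitochondrial fraction
(UMIs of `MT-`-prefixed genes over total UMIs; 0 for an empty cell), number
of expressed genes (count > 0), total UMIs, CD3 positivity (any transcript
of CD3E/CD3D/CD3G), and the number of distinct productive TCR chains per
locus (duplicate contigs of one chain collapse; they are assembly
redundancy, not extra chains).

Default removal rules (memory-Treg preset): mitochondrial fraction > 0.10,
expressed genes < 250 or > 4000, total UMIs > 25,000, no CD3 transcript,
or a TCR multiplet (> 1 beta chain or > 2 alpha chains).  A second preset
for the psoriatic-arthritis validation dataset uses gene bounds 500/3500,
skips the CD3 gate (those libraries were sorted on CD3 protein) and removes
CD4/CD8 co-expressing cells, where "CD8" means CD8A or CD8B at the
transcript level.  All removal conditions are strict inequalities, so cells
exactly at a boundary (250 genes, 10.0% mitochondrial, 25,000 UMIs) are
kept.  Removed cells are attributed to the first rule they fail in a fixed
order (mito, low genes, high genes, high UMI, CD3, TCR multiplet, CD4/CD8,
CD14), so per-rule counts plus kept cells always total the input.  An
optional direct rule removes CD14-positive cells in place of the original
clustering-based monocyte purge.  The mitochondrial fraction is computed on
the raw matrix, before any gene filtering.

## Hashtag demultiplexing

Cells are classified singlet / doublet / negative from hashtag-oligo (HTO)
counts.  For each tag a background negative binomial (mean/size
parameterisation; variance = mu + mu^2/size) is fitted by the method of
moments — mu = sample mean, size = mu^2/(s^2 − mu), with a Poisson fallback
(size = infinity) when the sample variance does not exceed the mean — and
the tag-positive threshold is the 99th quantile of that distribution,
computed by direct summation of the probability mass function.  A cell is
positive for a tag when its count strictly exceeds the threshold; ties at
the threshold are negative.

Background cells are selected by k-means with k = n_tags + 1 on
CLR-transformed counts (ln(c+1) centred per cell across tags; plain log
counts when there is a single tag): for each tag, the cluster with the
lowest mean count for that tag serves as background.  The lowest cluster is
signal-free by construction; using the complement of the highest cluster
instead leaves inter-tag doublets in the background, which inflates the
fitted variance and the threshold by an order of magnitude.  When
clustering degenerates (fewer than 20 background cells) the fallback is the
cells at or below the tag's 90th count percentile.  The moment fit refuses
to run on fewer than 20 background cells and advises a manual threshold.

## Clonotype calling and compartment enrichment

Cells sharing identical CDR3 nucleotide sequences for both the alpha and
beta chains belong to one clonotype; the clone key is the sorted distinct
alpha CDR3s joined with the sorted distinct beta CDR3s.  Cells lacking a
productive beta or alpha chain are excluded (the definition keys on both
chains; keying on beta alone would merge unrelated cells).  Two modes:
`clonality_table` retains multi-beta droplets, each distinct chain multiset
forming its own clone; `joint_gex`, used whenever expression and clonality
are analysed on the same cells, excludes multiplets (> 1 beta or > 2 alpha)
before keying.  Calling is invariant to contig order.

A clone is eligible for the enrichment test when it has at least
`min_cells = 3` members in either compartment (max(n_PB, n_SF) >= 3; a
total-size rule is available as a switch).  For each eligible clone the
2x2 table [[n_SF, total_SF − n_SF], [n_PB, total_PB − n_PB]] is tested,
where the totals are all clonotyped cells per compartment — the proportion
being compared is only defined over cells with a called clonotype.  The
two-sided Fisher's exact p sums the hypergeometric point probabilities of
all tables with the observed margins whose probability does not exceed the
observed one by more than a 1e-7 relative tolerance (the point-probability
rule, matching R's convention); degenerate margins give p = 1.
Benjamini–Hochberg step-up adjustment runs across eligible clones only, and
a clone is significant at adjusted p <= 0.05.  Per-clone descriptive
outputs include the odds ratio, the enriched compartment (larger clone
fraction), the distribution of members over transcriptional clusters with
descriptive hypergeometric over/under-representation p-values (reported,
never thresholded), and a CD4/CD8 lineage call by majority vote over
members (CD8-like when normalized CD8A + CD8B exceeds CD4; ties abstain,
tied votes give "unassigned").

## Expression statistics

Normalization scales each cell to `scale_total = 10,000` counts and applies
natural log1p; zeros map to zeros and the result is invariant to per-cell
depth.  Setting `scale_total` to the cell total reproduces raw log(UMI+1).

Differential expression between two disjoint groups (each >= 3 cells) uses
the Wilcoxon rank-sum test on normalized values with average ranks for
ties.  Genes are tested only when detected in at least `min_pct = 0.10` of
either group.  With both groups of 8 cells or fewer the p-value is exact —
full enumeration of all C(n1+n2, n1) group labelings, two-sided by
deviation of the rank sum from its null mean — otherwise a normal
approximation with tie-corrected variance and no continuity correction.
The fold change is the Seurat-style natural-log ratio
ln(mean(expm1(x_A)) + 1) − ln(mean(expm1(x_B)) + 1).  Bonferroni
multiplies by the total number of genes in the matrix (not only tested
genes; switchable via `m_total`).  The reporting filter keeps
|logFC| strictly greater than 0.25, flags significance at adjusted
p < 0.05, and can drop TCR variable-segment genes (TRAV/TRBV/TRAJ/TRBJ
prefixes), which are clone identity rather than biology in
clonotype-vs-clonotype comparisons.  The negative-binomial GLM variant some
toolkits offer is deliberately not implemented; the rank-sum test is the
one used for every reported comparison.

Module scores use expression-matched controls: all genes are ranked by mean
normalized expression and split into `n_bins = 24` equal-count bins; for
each module gene, `n_ctrl = 100` control genes are drawn with replacement
from its bin using a caller-supplied seed; the per-cell score is the mean
over module genes minus the mean over all control draws.  A random gene set
therefore scores ~0 in expectation regardless of expression level.  The
per-dataset mean score under an exchangeable null is unbiased but carries
sampling noise from the finite module and bin width (roughly ±0.05 for a
25-gene module over 24 bins on ~800 genes).

Cluster-by-compartment composition is compared with the two-proportion
pooled z-test, no continuity correction, two-sided, uncorrected for
multiplicity (one test per cluster, mirroring a per-figure annotation);
z^2 equals the 1-df chi-square statistic of the same table.  Pairwise
co-expression uses average-rank Spearman correlation; a zero-variance gene
has undefined rho and is reported missing.

## Synthetic data

The generator emulates the statistical structure the analysis assumes —
not transcriptome realism (no batch effects, dropout curves, or V(D)J
grammar):

- **Expression**: gamma-Poisson (negative binomial, dispersion `size = 2`)
  counts with per-gene baseline means drawn log-normal (median 1, log-sd 1)
  and per-cell depth factors log-normal (log-sd 0.25); 13 mitochondrial
  genes named with the `MT-` prefix; CD3E/CD3D/CD3G means high enough that
  genuine T cells pass the CD3 gate; a CD8 lineage fraction (default 10%)
  with CD8A/CD8B high and CD4 low.  Each cell belongs to one of
  `n_clusters = 10` clusters; each cluster's marker genes (10 per cluster)
  are elevated `marker_fold = 4`; one designated cluster carries a
  25-gene module elevated `module_fold = 2` for scoring experiments.
- **Repertoire**: every cell carries one productive alpha and beta chain
  with random in-frame CDR3 nucleotide strings (10–20 sense codons, 30–60
  nt, no stops; uniform over codons — enrichment statistics depend only on
  string identity).  Background cells are singleton clones.
  `n_expanded_clones = 10` planted clones have sizes
  2 + Geometric(p = 1/(mean − 2)) — geometric-shaped with support >= 3
  and exact mean `expanded_size_mean = 20`; a group smaller than three
  cells is not an expansion under the analysis' own eligibility rule —
  and each member lands in SF with probability `sf_bias = 0.9`.  A 10%
  dual-alpha rate and a 5% non-productive extra-contig rate exercise the
  chain-collapsing rules.
- **Hashing**: 2 hashtags (the study hashed the sorted Treg population with
  a single TotalSeq tag pooled into the lane; two tags emulate hashed
  Tregs plus a second hashed population), negative-binomial counts with
  signal mean 200 and background mean 4 (50x) at size 10; 5% doublets
  receive signal on two tags.
- **Controlled QC violations** (off by default): per-rule rates plant
  high-mito, low/high-gene-count, high-UMI and multi-beta cells, with the
  truth table recording every flag.

All randomness derives from one seed through fixed named substreams
(genes / cells / expression / TCR / HTO / QC), so adding a component never
perturbs the draws of another, and identical configs produce byte-identical
output files.  Null replicates require `sf_bias = 0.5` and use seeds
base + r.  Infeasible configurations (expansions exceeding compartment
pools, high-gene violations without enough genes) raise configuration
errors rather than degrading silently.

What passing on these data does and does not show: the tests demonstrate
correctness of the statistics and the operating characteristics (error
control, power, classification accuracy) under negative-binomial expression
and memoryless clone-size tails; they do not certify behaviour under
ambient contamination, batch structure, or real repertoire grammar.

## Pipeline

Stage order follows the study: expression QC (mito / gene / UMI bounds) →
hashtag demultiplexing (keep singlets) → CD3 gate and TCR-multiplet
exclusion → clonotyping → enrichment → normalization and SF-vs-PB
differential expression → module scoring → per-cluster composition tests.
Every output table carries the seed and a config hash (computed over the
analysis-relevant configuration, excluding the output directory) in a
comment header; the JSON manifest records per-stage in/out cell counts so
the QC funnel is auditable on any dataset.  Identical config + seed yields
a byte-identical bundle.

## Validation experiment sizes

The validation suite (`synotreg.validation`, exercised by the test suite
and by `scripts/acceptance.py`) uses: every 2x2 table with grand total
<= 40 against exact integer enumeration; 1000 random p-vectors (lengths
1–500) against a reference step-up loop; 100 random small-group datasets
against full labeling enumeration plus 100 datasets at 50 cells/group
against the exact rank-sum null; 200 null repertoire replicates
(~2,700 cells, ~100 eligible clones each) for false-discovery control; 50
seeds of the planted-expansion design (~2,300 cells) for recovery; 20
seeds of 1,000-cell hashing experiments for demultiplexing accuracy; 50
elevated plus 20 null module-scoring datasets (1,000 cells, 800 genes);
and two full pipeline runs for bundle determinism.  These sizes keep each
study to seconds-to-minutes on one CPU while leaving Monte-Carlo error
well below the margins being tested.

## Known limitations

- Clones are compared within one dataset; cross-patient clone sharing and
  repertoire-diversity summaries are out of scope.
- The enrichment test conditions on clonotyped cells; if clonotyping rates
  differed systematically between compartments the totals would shift.
- Under the planted-expansion defaults (geometric sizes, mean 20, bias
  0.9, ~1,150 cells per compartment) small clones are intrinsically
  undetectable: an all-SF clone of five or fewer cells cannot reach
  two-sided Fisher p <= 0.05 against balanced totals, so measured recovery
  of planted clones plateaus near 3/4 — a property of the design, not of
  the implementation (detection is ~1.0 for sizes >= 15).
- The demultiplexer assumes at least one signal-free k-means cluster per
  tag; extreme doublet rates or fewer than ~20 background cells trigger
  the percentile fallback or a manual-threshold error.
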