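# Methods

`glioprog` re-implements, as a tested library, the computational procedures
used to stratify Parkinson's disease (PD) donors into mutually exclusive
glial multicellular programs from single-nucleus RNA-seq and imaging
spatial transcriptomics: nucleus quality control, compositional statistics,
gene-signature scoring, tiered differential-expression overlap, spatial
autocorrelation, and donor classification. Because no public count matrices
accompany the study design this package targets, every procedure is
exercised end-to-end on a synthetic cohort generator that reproduces the
statistical structure the procedures assume. This note documents the
models, the defaults and why they were chosen, and what the synthetic
results do and do not establish.

## Synthetic cohort model

The generator (`glioprog.synthetic`) draws donors nested in three program
groups — UPR-high, Reactive, and Homeostatic — with ten donors per group by
default. Each donor's subpopulation composition is drawn from a Dirichlet
distribution centred on its group's mean composition row with concentration
300. Ten glial subpopulations are modelled across four cell classes:
astrocytes (A0, AR1, AR2, SVZC), microglia (MH, MH-HSP, M1),
oligodendroglia (MOL, PDAO) and OPCs. UPR-high donors are dominated by AR1
astrocytes, MH-HSP microglia and PDAO oligodendroglia (which therefore
covary across donors); Reactive donors by AR2 astrocytes and M1 microglia;
Homeostatic donors keep both program blocks at 1% absolute abundance. The
default composition rows place the planted astrocyte and microglia program
fractions far from the 10% classification boundary on both sides (about 52%
AR1-of-astrocytes in UPR-high donors versus about 2% in Homeostatic
donors), matching the near-total within-donor program dominance the donor
stratification model assumes; the concentration of 300 keeps donor-to-donor
scatter within a group small relative to that margin. Each donor
contributes 1,000 cells split across the two striatal regions (putamen,
caudate nucleus), a realistic per-donor snRNA-seq yield at this panel size.

Expression is negative-binomial: cell means are library size (log-normal
around 2,500 UMIs) times a subpopulation profile on the simplex, with
variance mu + 0.3 mu^2 (a single shared dispersion — downstream rank tests
assume nothing richer). Profiles share a log-normal background over 600
genes; each subpopulation's 20 marker genes are enriched 2^2-fold
(graded subtype-state markers), and each cell class's 20 class markers are
enriched 2^5-fold, reflecting that canonical class markers (GFAP- or
CSF1R-like) are near-exclusive while subtype states are graded shifts. Five
percent of each cell's expected counts is redistributed to the donor-pooled
profile (ambient contamination), and a flagged mitochondrial gene block
receives 5% of each profile's mass. Doublets are exact parent-pair count
sums, heterotypic when the parents' classes differ. Braak Lewy-body stages
are drawn per donor from group-specific distributions (Homeostatic donors
early-stage controls, the PD groups spanning stages 2–6), and the UPR-high
group is male-only by default, mirroring the sex skew the stratification
analysis accounts for.

Spatial samples are uniform random point fields in a 3 mm square with
geometrically laid-out domains at the observed tissue fractions — gray
matter (~72%), vertical white-matter bands (~19%), scattered vascular cells
(~5%) and a ventricle strip (~3%). Spatially variable genes are Poisson
with rate 6 inside a few 350-µm patches and 0.2 outside; the remaining
panel genes are position-independent Poisson.

What the generator does *not* emulate: real striatal expression profiles,
batch effects beyond the donor random effect, UMAP geometry, segmentation
error, or spatially structured ambient contamination. Tests passing on this
cohort therefore establish that the implementations are correct and
well-calibrated under their stated assumptions, not that the biological
conclusions transfer to any particular real dataset.

## Quality control

Four layers, applied per sample in order (membership is intersection-stable,
so the order affects only the attribution of removals):

1. **Fixed thresholds** — keep 500 ≤ UMIs ≤ 250,000, 1,200 ≤ detected
   genes ≤ 15,000 (bounds inclusive), mitochondrial fraction ≤ 10%.
2. **Polynomial outliers** — detected genes are regressed on log10(UMIs)
   with a degree-2 least-squares fit; cells deviating by more than 2,000
   genes are removed. The residual is taken on the linear gene-count scale
   (the threshold's units make no sense on the log scale).
3. **Consensus doublet voting** — any per-sample scorer mapping (counts,
   iteration seed) to boolean flags is run 100 times with derived seeds;
   cells flagged in strictly more than 10% of runs are removed. The
   built-in reference scorer simulates parent-pair-sum doublets, embeds
   observed and simulated cells in log1p CP10K space through a seeded
   Gaussian random projection, scores cells by the simulated-neighbour
   fraction among 20 nearest neighbours and flags the top 5%. It is a
   minimal stand-in that exercises the consensus machinery; production
   doublet callers plug into the same interface.
4. **Heterotypic doublets** — per cell class, the mean log-normalised
   marker expression is fit with a two-component Gaussian mixture (EM,
   k-means initialisation, seeded); the class threshold is the lower
   component's mean plus four of its standard deviations, and cells
   exceeding the threshold for two or more classes are removed. Mixtures
   are fit per sample; components with weight below 1% are skipped with a
   warning, and EM non-convergence is an error naming the class.

## Compositional statistics

Per-sample subpopulation counts c_ij (sample i, subpopulation j) are
transformed with the centred log-ratio using a pseudocount of 1:
clr_ij = ln((c_ij + 1) / g_i), where g_i is the geometric mean of the
sample's (c + 1) values. Rows sum to zero by construction; the pseudocount
breaks exact scale invariance, which holds only for pseudocount 0 on
positive rows (tested). Condition contrasts use the two-sided Mann-Whitney
U test per subpopulation — exact enumeration for untied groups of at most
20 samples, otherwise the tie-corrected normal approximation — with
Benjamini-Hochberg adjustment across subpopulations reported alongside raw
p-values. Braak-stage profiles average subject-level CLR within stage,
masking stage cells backed by fewer than two subjects, with optional
per-subpopulation z-scoring across stages. Abundance correlations are
pairwise-complete Pearson; pathology correlations are Spearman rank
correlations between CLR abundance and Lewy-body density per region, after
excluding donors contributing fewer than 50 nuclei in that region. The two
regions are always separate strata and never pooled into one sample.

## Donor stratification

The astrocyte rule is hierarchical with strict thresholds: after removing
ventricle-specific SVZCs from the denominator, a sample is UPR-high when
AR1 exceeds 10% of astrocytes, else Reactive when AR2 exceeds 10%, else
Homeostatic. The four-way microglia rule labels a donor Reactive (>10% M1),
UPR-high (>10% UPR-like), Homeostatic (neither above 10%) or Mixed (both
above 10%); equality at the boundary always falls to the lower branch. In
the pipeline the microglial fractions come from annotated subpopulation
counts over all of a donor's microglia, because that is what the published
rule thresholds; the per-cell signature-labeling route (score two
signatures, z-scale, argmax with a 0.5-z margin) is provided and tested as
an alternative for datasets without subpopulation annotations, but its
false-label rate on majority-class cells (~10% on synthetic microglia) is
too high to drive donor fractions, which is why it is not the pipeline
default. The mixed rate (share of Mixed donors) quantifies mutual
exclusivity, and cross-region consistency reports each donor's modal label
and agreement fraction, with ties broken toward non-Homeostatic labels and
then lexicographically.

Sample-level structure is summarised by a divergence matrix over per-cell
latent coordinates (the pipeline supplies 10 PCA components): for each
ordered sample pair the Kullback-Leibler divergence is estimated with the
Wang-Kulkarni-Verdu k-nearest-neighbour estimator at k = 6 — the dimension
times the mean log ratio of cross- to within-sample k-th neighbour radii
plus log(m/(n−1)) — then symmetrised and clipped at zero. Samples under the
minimum cell count (500 for real-scale data; 100 in the synthetic
pipeline, whose donor-region samples hold ~500 cells) are dropped. A
generic average-linkage agglomerative grouping over the matrix stands in
for graph community detection, which is out of scope.

## Signature scoring

Module scores follow the expression-matched control scheme: genes are
ranked by dataset-wide mean expression (ties broken by gene identifier so
results are invariant to column order) and cut into 25 equal-size bins; for
each set gene, 50 control genes are drawn seeded from its bin, and the
score is the mean log-normalised expression of the set minus that of the
pooled control set. A set that exhausts its bins (e.g. the full gene
universe) scores exactly zero with a warning. One-versus-rest enrichment
uses the Wilcoxon rank-sum test per group with BH adjustment across groups;
since module scores can be negative, the reported log2 fold change is
computed after shifting all means by the global minimum plus 1e-9, and the
shift is recorded in the output (the fold-change convention for scores is
not standardised; the shift makes ours explicit and order-preserving).
Dot-plot summaries report, per gene and group, the expressing fraction and
the mean expression both over all cells and over expressing cells only —
both variants are emitted because conventions differ.

## Differential expression and overlap logic

Per-gene two-group contrasts use the two-sided Wilcoxon rank-sum test with
tie correction (exact enumeration when both groups have at most eight
cells), log2 fold change of de-logged group means with epsilon 1e-9 (the
dominant single-cell convention), and the expressing fraction `pts` in the
test group. Significant DEGs satisfy adjusted p < 0.05, pts > 0.1 and
|LFC| ≥ 0.25, and partition into Tier 1 (|LFC| ≥ 2.0), Tier 2 ([1.0, 2.0)),
Tier 3 ([0.5, 1.0)) and Tier 4 ([0.25, 0.5)). Donor-group contrasts test
UPR-high or Reactive donors' cells against Homeostatic donors' cells with
the reciprocal PD-associated group excluded entirely, keeping the reference
pure.

Overlap analyses first drop clone-derived and non-coding identifiers (AC,
AL, AP or AF followed by a digit, or any LINC prefix; case-sensitive, so
ACTB and ALDH1L1 survive). The dual-threshold rule builds the candidate
universe from genes passing a strict threshold (|LFC| ≥ 1.0, adjusted
p < 0.05) in at least one comparison and admits a universe gene into
another comparison when it passes the relaxed threshold there (|LFC| ≥ 0.5
for the three-way Venn, ≥ 0.25 across cell types) with the same LFC sign;
genes whose strict occurrences disagree in sign are excluded and reported.
Venn regions partition the universe; UpSet-style intersections are emitted
for every non-empty pattern with a flag marking those containing strictly
more than 10 genes.

## Spatial autocorrelation

Connectivity is the Delaunay triangulation of cell centroids (degenerate
configurations error with a jitter-flag hint; the jitter is at most
0.01 µm). Moran's I uses binary adjacency row-standardised by default — the
weighting is configurable because published analyses rarely state it — and
significance is a one-sided (greater) permutation test with
p = (1 + #{I_perm ≥ I_obs}) / (1 + 100), whose floor 1/101 avoids zero
p-values; positive autocorrelation is the target alternative since the goal
is detecting spatially variable genes. Per-sample analysis restricts to the
gray-matter domain, skips samples with fewer than 50 observations, and
aggregates gene-level I and p as unweighted means across retained samples
with a top-k summary per condition.

## Numerical and scale choices

All randomness flows from explicit seeds through `numpy` `SeedSequence`
spawning, so same-seed runs are byte-identical, and every tabular output
carries a metadata header with the version, seed and a parameter hash. The
default pipeline configuration runs the full synthetic study — 30 donors ×
1,000 cells × 600 genes, two 5,000-cell spatial samples, 100 Moran
permutations — in about three minutes on one CPU; its QC thresholds are
rescaled to the 600-gene panel (minimum 150 detected genes) and the
consensus voting runs 40 iterations at that scale, while the
`QCThresholds` dataclass defaults keep the real-data values (1,200 genes,
100 iterations). Acceptance-level checks run the consensus calibration at
the full 100 iterations. The kNN-divergence estimator is known to be
biased low for large shifts; only its ordering and its null behaviour are
relied upon. Known limitations: no ambient-RNA correction, no
mixed-effects or pseudobulk DE, no isometric log-ratio alternatives, and
domain labels for spatial samples are inputs, not inferred.
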