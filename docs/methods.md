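# Methods

`tcrpersist` analyzes longitudinal paired-chain single-cell TCR/RNA data
from allogeneic hematopoietic stem-cell transplantation (alloHSCT): it
follows donor T-cell clones from the graft into the recipient, derives
the transcriptional signature of the clones that persist, and asks
whether those cells could have been identified in the donor already.
This note documents the models, the synthetic cohort the test-bed runs
on, the numerical choices, and the limits of what the tests show.

## Clonotype model

A clonotype is strictly paired: a cell enters the repertoire only when a
productive TRA *and* a productive TRB chain were recovered, and the key
concatenates V gene and CDR3 nucleotide sequence per chain
(`TRAV…_cdr3nt|TRBV…_cdr3nt`). Per cell and locus the highest-UMI chain
is selected; UMI ties resolve to the lexicographically smallest CDR3 so
calls are deterministic. The key is configurable in principle (J gene,
amino-acid CDR3), but the V + CDR3nt "strict" convention is the default
because it is the common choice for paired-chain data; single-chain
cells are never merged into paired clonotypes and are reported as
unassigned. Repertoire frequencies are normalized over cells with a
paired assignment — repertoire statistics describe the sampled
repertoire, not all sequenced cells.

## Persistence

A clonotype *persists* when it appears in ≥1 donor sample (pre/post
G-CSF mobilization) and ≥1 recipient sample (day +90/+180) of the same
donor-recipient pair. This is pure set logic — no abundance threshold —
so it is monotone under added samples, and precision/recall against a
planted truth are exactly 1 for clones sampled on both sides.
Persistence is never computed across pairs; unrelated repertoires share
essentially no paired clonotypes, and a cross-pair overlap screen is
emitted for QC only. Expansion/contraction is summarized as
log2(recipient mean frequency / donor mean frequency) with a
pseudo-frequency of 0.5/total for absences; the bin labels
Rare/Small/Medium/Large/Hyperexpanded use the conventional cut-offs
(1e-4, 1e-3, 1e-2, 1e-1) on half-open intervals.

## Diversity and overlap

Diversity is the inverse Simpson index D = 1/Σp², the effective number
of equally abundant clones; it is reported per sample and pooled per
role, since both readings of "donor vs recipient diversity" are useful.
Overlap is the Morisita index in its bounded frequency-based
(Morisita–Horn) form

    C = 2 Σxᵢyᵢ / ((Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y),

the form commercial and academic repertoire toolchains compute; the
classical count-based estimator (which can exceed 1) is available via
`form="classical"`.

## Pseudobulk differential expression

The persistence signature is derived replicate-aware: counts of all
CD8TEM cells of one sample and persistence stratum are summed into a
pseudobulk profile, and genes are tested persisting-vs-other with pair
identity as a fixed-effect covariate (the design is paired within
donor-recipient pairs). Per gene the model is a negative-binomial
log-linear GLM with median-of-ratios size factors as offsets.

Dispersion and testing needed care at this design size (32 columns, 22
parameters with 4 pairs; or 40/22 with 20 pairs in the calibration
suite):

* a **pooled NB dispersion** is estimated by solving the Pearson χ²
  estimating equation Σ(y−μ̂)²/(μ̂+αμ̂²) = n_genes·(m−k) with means from
  per-gene Poisson fits (the df correction removes most of the
  fitted-mean shrinkage bias);
* each gene additionally carries a **quasi-dispersion** φ (Pearson
  statistic of its NB fit divided by residual df), moderated across
  genes by an empirical-Bayes squeeze (trigamma method-of-moments prior,
  as in limma); the moderated φ scales the Wald standard error;
* the Wald statistic is referred to a **t distribution on the residual
  df** rather than a normal — at ~18 residual df the normal reference is
  visibly anticonservative.

Plain gene-wise moment dispersions with a normal Wald reference gave a
type-I error of ~0.10–0.42 at nominal 0.05 in null simulations; the
design above sits at ~0.055–0.065 on 2,000 null genes with 20 pairs,
inside three binomial standard errors. Gene-wise moment dispersions are
still reported in the DE table for diagnostics; the dispersion floor is
1e-8 and genes with fewer than 10 total counts are excluded. Adjustment
is Benjamini–Hochberg; the signature is the genes with adjusted p < 0.01
and |log2FC| > 0.5, ordered by adjusted p. Exact equality with any
specific external DE tool is not claimed.

## Cytotoxicity and effectorness scores

The cytotoxicity score projects log2-CPM profiles onto the first
principal component of a cytotoxicity reference panel (12 genes: PRF1,
GZMB, GZMA, GZMH, GNLY, NKG7, KLRD1, KLRG1, FCGR3A, CTSW, CST7,
FGFBP2). Reference profiles are centered/scaled per gene; the loading is
unit-norm and oriented so NK reference profiles score above naive ones;
query genes missing from the panel are imputed at the reference mean
(zero after centering). Library normalization is always computed over
the full count table before subsetting to the panel — normalizing within
the panel distorts the scale badly. The packaged reference is synthetic
(sorted-population profiles generated from the same cell-type program
used by the simulator, labeled as such); a user-supplied gene × profile
table is accepted in its place. One component is retained by default.

The effectorness score is a deliberately simple pseudotime: CD8 cells
are log-normalized (counts per 10k, log1p), centered per sample as a
batch proxy, reduced by PCA, and ranked along PC1 with the naive-CD8
centroid anchored at the low end, min-max scaled to [0, 1]. This is a
rank approximation to graph-based trajectory pseudotime; it preserves
ordering (naive < TCM < TEM) but not path geometry.

## In-silico enrichment

Donor CD4/CD8 T-cells with a paired clonotype are labeled by whether
their clone persists, and classifiers (L2 logistic regression on
standardized features; random forest with √p features per split and
inverse-prevalence class weights) are trained on four feature panels:
ADT surface antigens (10, pass-through when provided — not simulated),
literature cytotoxicity genes (12), CD8TEM markers (50), and the derived
persistence signature (54). The figure of merit is the **enrichment
factor**: precision among predicted-persisting divided by baseline
prevalence.

Two evaluation schemes: (1) "10-fold cross-validation with a 75:25
split" is internally ambiguous (ten disjoint folds imply 90:10); it is
implemented as 10 independent stratified random 75:25 splits, honoring
both the repeat count and the ratio. (2) Leave-one-donor-out: train on
all donors but one, evaluate on the held-out donor — the stringent test
of transfer to an unseen individual. Predicted-positive rule: class
probability ≥ 0.5 / majority vote. Feature importance for forests is
permutation importance (mean precision drop over 10 shuffles per
feature, on a ≤2,000-row subsample to bound runtime); logistic models
report absolute standardized coefficients instead, flagged in the
output.

The random-forest tree count is 500 in `ClassifierSpec` defaults; the
pipeline runs 200 (and the acceptance checks 100–200), where medians are
already stable — factors change by well under 5% beyond ~100 trees on
these panel sizes.

## Synthetic cohort

The generator emulates the study design: 4 donor-recipient pairs × 4
timepoints × 2,500 cells per sample (~1,900 T-cells each; the study
reports ~2,500 T-cells per sample, an order-of-magnitude anchor).
Components:

* **Clones.** 600 T clones per pair, apportioned across six T subsets by
  the cell-type mix; within a subset, clone weights follow a Zipf
  rank-frequency law r^(−1/(a−1)) with clone-size exponent a = 2, so a
  few clones dominate. A size-biased 10% of donor CD8TEM clones is
  marked persisting — expanded clones are the ones sampled on both sides
  — and reappears in the recipient with weight × 5 (`persist_expansion`).
  All other recipient clones are novel with a flatter exponent (2.5):
  reconstituting clones are many and small compared to the expanded
  persisting effectors. Pairs share no clonotype keys.
* **Composition.** Baseline mix: 75% T (CD8 TEM 0.19, CD8 TCM 0.08, CD8
  Naive 0.11, CD4 TEM 0.08, CD4 TCM 0.12, CD4 Naive 0.17), plus NK/B/Mono.
  Recipients double the CD8 TEM share (renormalized), reflecting
  effector expansion after transplant. These choices put the persisting
  cell fraction among donor T-cells at ~10–12%, inside the study's 6–19%
  band, and make recipient diversity reliably lower than donor
  diversity.
* **Chains.** Per clone, unique (V gene, CDR3nt) TRA and TRB with CDR3
  lengths 30–45 nt (multiples of 3, no stop codons). Capture is
  imperfect: 12% alpha and 6% beta dropout per cell, 4% secondary
  lower-UMI alpha chains. Only cells with both chains enter the
  repertoire, mirroring real paired-chain loss.
* **Counts.** 1,000 genes; negative binomial with variance μ + 0.3μ²,
  mean library 2,500. Log2 mean offsets encode a cytotoxicity program
  graded along the naive→effector axis (NK highest), CD8TEM markers,
  naive markers, lineage markers, and — only in cells of persisting
  clones — the 54 signature genes at +0.8 log2 (NKG7, GZMH, ADGRG1,
  KLRD1, FCGR3A first, synthetic names after). Per-sample depth factors
  are lognormal (σ = 0.1).
* **QC fields.** pct-mito and label-transfer scores are drawn with ~2%
  planted failures each; detected-gene counts come from the realized
  count vectors.
* **Determinism.** One master seed; per-sample streams are derived by
  hashing (pair, timepoint), so a sample can be regenerated
  independently and reruns are byte-identical.

What the simulator does *not* model: V(D)J recombination biology, ADT
counts, doublets, ambient RNA, batch effects beyond depth scaling,
cell-type misannotation, or clonal drift between the two samples of one
role. Passing the recovery tests therefore shows the pipeline's logic
and inference are correct under a faithful-but-clean data model; it does
not certify performance against annotation noise or batch structure in
real data.

## Problem sizes in tests and acceptance

The unit suite runs on small cohorts (2 pairs × ~400–600 cells); the
acceptance layer uses the full default cohort (40,000 cells), 10 seeded
cohorts for the diversity direction, a 2,000-gene/20-pair null for DE
calibration, 20 label permutations for the enrichment null, and
100–200-tree forests for the enrichment recovery checks. The
effect-size dose-response sweep runs 4-pair cohorts at 1,000 cells per
sample and 500 genes, five seeds per effect level. These sizes
keep the whole suite within a coffee break on one CPU while leaving
every statistical margin comfortable.

## Known limitations

* The DE test is calibrated for the simulated NB world; strong
  mean-dispersion trends in real data would call for a trended prior
  rather than a single pooled dispersion.
* The effectorness score is a PC1 rank, not a trajectory method; on data
  with branching differentiation it can fold branches onto one axis.
* The cytotoxicity reference shipped is synthetic; scores are
  comparable within a run, not across references.
* Persistence is presence/absence logic; with very shallow sampling it
  undercounts persisting clones (the generator logs planted persisting
  clones missed by sampling as `undersampled`).
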