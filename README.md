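# tcrpersist

Clonal tracking of donor T-cell clonotypes through allogeneic
hematopoietic stem-cell transplantation (alloHSCT).

After alloHSCT, a recipient's T-cell compartment is rebuilt from the
graft. Which donor clones survive the transfer, what do they look like
transcriptionally, and could they have been identified — and enriched —
in the graft beforehand? `tcrpersist` answers these questions for
longitudinal paired-chain scTCR/RNA-seq cohorts (donor sampled pre/post
G-CSF mobilization, recipient at day +90 and +180):

* **Clonotyping** — strict paired-αβ keys (`TRAV_cdr3nt|TRBV_cdr3nt`),
  highest-UMI chain per locus, per-sample repertoire tables and
  expansion bins.
* **Persistence tracking** — a clonotype persists iff it appears in ≥1
  donor and ≥1 recipient sample of the same pair; top-clone
  trajectories, persisting share of the most abundant recipient clones,
  phenotype attribution.
* **Repertoire statistics** — inverse Simpson diversity D = 1/Σpᵢ²,
  Morisita–Horn overlap
  C = 2Σxᵢyᵢ / ((Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y), cell-type composition.
* **Persistence signature** — pseudobulk (summed counts per sample ×
  cell type × stratum) negative-binomial GLM with pair identity as
  covariate, quasi-likelihood moderated Wald-t tests, BH adjustment;
  signature = adj. p < 0.01 and |log2FC| > 0.5. Cytotoxicity scoring by
  projection onto a reference PCA; effectorness as PC1-rank pseudotime.
* **In-silico enrichment** — logistic-regression and random-forest
  classifiers over four feature panels (ADT / cytotoxicity genes /
  CD8TEM markers / persistence signature); enrichment factor =
  precision among predicted-persisting ÷ baseline prevalence, evaluated
  by repeated stratified 75:25 splits and leave-one-donor-out.
* **Synthetic cohorts** — a first-class generator planting ground truth
  (clone sizes, persisting clones, signature genes) in the study's
  design: 4 pairs × 4 timepoints × 2,500 cells.

File formats are the 10x-adjacent plain-text dialects:
`filtered_contig_annotations.csv`, MatrixMarket counts with
features/barcodes sidecars, and a tab-separated cell-metadata table.

## Worked example

```python
from tcrpersist.synthetic import SimConfig, simulate_cohort
from tcrpersist.io_model import qc_filter_cells
from tcrpersist.clonotyping import call_clonotypes, build_repertoire_table
from tcrpersist.tracking import call_persistence, persisting_share_of_top
from tcrpersist.repertoire_stats import pooled_diversity

cohort, truth = simulate_cohort(SimConfig(seed=1))
kept, removed = qc_filter_cells(cohort.cells)
assignment = call_clonotypes(cohort.chains, kept)
table = build_repertoire_table(assignment, cohort.samples)

pair_a = table.restrict_to_pair(cohort.samples, "A")
call = call_persistence(pair_a, cohort.samples)
samples_a = [s for s in cohort.samples if s.pair_id == "A"]
donor = [s.sample_id for s in samples_a if s.role == "donor"]
rec = [s.sample_id for s in samples_a if s.role == "recipient"]

print(f"cells kept after QC:      {len(kept)}")
print(f"paired-chain T cells:     {len(assignment.assigned)}")
print(f"pair A persisting clones: {len(call.persisting_keys)}")
print(f"pair A donor diversity:   {pooled_diversity(table, donor):.1f}")
print(f"pair A recipient div.:    {pooled_diversity(table, rec):.1f}")
print(f"pair A share of top 10:   {persisting_share_of_top(pair_a, call, samples_a, 10):.2f}")
```

prints

```
cells kept after QC:      38000
paired-chain T cells:     24206
pair A persisting clones: 14
pair A donor diversity:   94.2
pair A recipient div.:    53.0
pair A share of top 10:   0.60
```

Reading: of 40,000 simulated cells, 38,000 pass QC and 24,206 carry both
TCR chains; 14 of pair A's clonotypes are seen on both sides of the
transplant; the recipient repertoire has collapsed to roughly half the
donor's effective clone number; and 6 of the 10 most abundant recipient
clonotypes are persisting donor clones.

The same pipeline runs from the shell, one stage or end to end:

```
tcrpersist all --seed 1 --outdir runs/demo
```

which writes per-stage TSV artifacts (persistence calls, trajectories,
diversity/overlap tables, DE results, signature gene list, scores,
enrichment results), JSON manifests, and a summary `report.json` —
byte-identical across reruns with the same seed.

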