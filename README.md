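# methcompart

Inference of A/B chromatin compartments from DNA-methylation microarray
data, detection of tumour-specific compartment changes, and integrated
scoring of transcription factors that drive aberrant gene expression —
as a tested, reusable pipeline in which every stage can be exercised on
synthetic data with planted ground truth.

## The problem

Genomes are spatially organised into two mutually exclusive compartments:
**A** (open, accessible, transcriptionally active) and **B** (closed).
Compartment membership can be inferred without Hi-C, from long-range
correlation structure in CpG methylation beta values: probe-level betas
are binned into 100-kb windows, the window-by-window Pearson correlation
matrix is computed across samples per chromosome, and each window's entry
in the normalised first eigenvector of that matrix, *e*<sub>w</sub>, gives
a signed "closed-ness" score (positive = closed, negative = open,
|*e*<sub>w</sub>| = call confidence).

Comparing compartment profiles between a tumour cohort and a normal-tissue
cohort yields **tumour-specific open (TSO)** windows (open in tumour,
closed in normal) and **tumour-specific closed (TSC)** windows.  TFs whose
ChIP-seq binding sites cluster in TSO regions and whose target genes are
systematically overexpressed in tumours are candidate transcriptional
drivers.  Binding enrichment uses the width-ratio statistic

```
F = [ width(peaks ∩ TSO) / width(peaks \ TSO) ] / [ width(TSO) / width(¬TSO) ]
```

with a chi-squared goodness-of-fit test on peak counts and
Benjamini–Hochberg adjustment across studies.  Target genes are genes
with a peak within 1 kb of their TSS; their expression shift is tested by
empirical-Bayes moderated *t*-statistics (per-gene variances shrunk toward
a prior (d₀, s₀²) fitted by moment-matching with trigamma inversion)
followed by a competitive Wilcoxon mean-rank gene-set test.  The two lines
of evidence combine into the integrated driver score

```
S = log10(F) · (−log10 p)
```

Activator candidates require F > 1.5 and p < 10⁻⁴; repressor candidates
require significant depletion from TSO, significant enrichment in TSC and
systematic target down-regulation.

## Worked example

The package ships a synthetic-data generator whose default desk-scale
scenario (2 chromosomes × 100 windows of 100 kb, 50 samples per cohort,
5 probes per window, 20 TFs of which 3 are planted activator drivers and
1 a planted repressor, 2000 genes) runs the full pipeline in about one
second:

```
$ methcompart pipeline --simulate --seed 1 --outdir run1
TSO 5  TSC 5  activators ['tf09', 'tf04', 'tf05']  repressors ['tf17']
```

The run directory contains the per-window compartment profiles,
differential window sets, the per-study enrichment table, target sets,
moderated-t table, gene-set test table, driver scores and a provenance
block.  The planted activators (tf09, tf04, tf05 in this seed) occupy the
top three integrated scores:

```
$ head -4 run1/driver_scores.tsv | cut -f1-8
study_id	tf	F_tso	log10F_tso	p_up	neg_log10_p_up	score	F_tsc
tf09_simulated	tf09	4.69204	0.671362	4.05775e-16	15.3917	10.3334	0.92783
tf04_simulated	tf04	4.39167	0.64263	1.21573e-13	12.9152	8.29967	1.17167
tf05_simulated	tf05	4.38413	0.641883	4.01036e-10	9.39682	6.03166	0.969911
```

Reading the first row: tf09's binding sites are 4.7-fold enriched in
tumour-specific open chromatin, its target genes are overexpressed in the
tumour group at p ≈ 4×10⁻¹⁶, and the product of the two log-scale
evidence terms gives the integrated score S ≈ 10.3.  The planted
repressor tf17 shows the mirror pattern (depleted from TSO, enriched in
TSC, targets down-regulated) and is flagged by `select_repressors`.

The same steps are available as library functions
(`infer_compartments`, `compare_profiles`, `fold_enrichment`,
`moderated_t`, `gene_set_rank_test`, `integrated_score`, …) and as
individual subcommands (`simulate`, `infer`, `diffcomp`, `tfenrich`,
`validate`), all operating on plain TSV/BED/bedGraph files.

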