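# Methods

## Compartment inference

Probe-level beta values (optionally filtered against user-supplied
SNP-overlapping or CpG-island probe lists) are averaged into fixed
windows (default 100 kb; median available by configuration).  Windows
without probes are *missing*, never zero, and missingness propagates as
NA through every downstream set operation.  Per chromosome, the
window × window Pearson correlation matrix is computed across samples
(pairwise-complete; windows with fewer than 3 paired observations or
zero variance are dropped with a warning) and its leading eigenvector is
taken.  Profiles never span chromosomes.

**Sample centering.**  Before the correlation is computed, each sample's
mean binned value (over its non-missing windows) is subtracted.  Global
per-sample methylation level is a nuisance — it tracks tumour purity,
array batch and global hypomethylation — and removing it turns the
compartment signal into a within-sample contrast: windows of one
compartment co-vary positively with each other and negatively with the
other compartment, so the two compartments load on the leading
eigenvector with opposite signs.  Without this step, two compartments
whose fluctuations are uncorrelated in absolute terms produce a
correlation matrix with two positive diagonal blocks, and the leading
eigenvector concentrates on a single compartment instead of contrasting
the two; sign-based calling then fails on roughly half the genome.
Centering can be disabled (`center_samples=False`) for data that is
already level-normalised.

**Eigenvector numerics.**  Dense symmetric eigendecomposition
(`scipy.linalg.eigh`, subset of one) up to 2000 windows per chromosome;
above that, power iteration with a trace shift (tolerance 1e-10, at most
10,000 iterations).  A tie between equal leading eigenvalues is broken
by whichever eigenvector is computed first.  The vector is normalised to
max |e| = 1 per chromosome; the leading eigenvalue's share of the trace
is recorded per chromosome as a quality indicator.

**Orientation.**  The eigenvector's sign is arbitrary, so it is oriented
against a covariate — by default the per-window mean methylation — such
that their Pearson correlation is positive.  Under the generator's
convention (closed windows more methylated) this makes positive scores =
closed.  The covariate and direction are configurable because the
biological direction on real open-sea probes is tissue dependent; the
orientation rule is validated against planted truth in the recovery
tests and is idempotent.  The orientation covariate and normalisation
rule are stored in the profile and checked for equality before two
profiles are compared.

**Confidence.**  |e_w| is the call confidence.  Two thresholds are in
common use — 0.1 (the default here, the one used for the differential
analysis) and 0.01 — and both are exposed; windows below the threshold
in either cohort are excluded from the differential sets.

## Differential compartments

TSO = {w : e_tumour < −θ and e_normal > +θ}; TSC symmetric.  θ applies
to both cohorts.  The *strict* subset additionally requires
|e_tumour − e_normal| ≥ 0.2 (both profiles must use the same
normalisation; enforced via provenance).  Descriptive statistics:
call concordance and eigen-score correlation over windows confident in
both cohorts; per-chromosome observed/expected aberrant-window ratios
where the expectation is proportional to each chromosome's share of
*eligible* (confident-in-both) windows so heavily-NA chromosomes are not
penalised; and a split-half robustness run in which the tumour cohort is
split into two random halves and the identical procedure is applied
between them — a null comparison that should produce far fewer windows
than tumour-vs-normal.

## TF enrichment

F is a ratio of merged base-pair widths (peaks are clipped to the genome
and merged first, so replicate overlap never double-counts).  No
pseudocounts: F = 0 and F = ∞ are reported honestly and flagged out of
log-scale summaries.  The chi-squared test assigns each peak by its
midpoint (keeping peaks as independent units; a width-based variant is
available by configuration) and compares the two cells against the
target's genomic share with a 1-df goodness-of-fit statistic; an
expected cell below 1 sets an unreliability flag.  Multiplicity is
handled by Benjamini–Hochberg (via `statsmodels`).  Enrichment widths
are computed over the whole tiled genome by default, with an
eligible-windows-only mode for sensitivity analysis.  Robustness
summaries: pairwise Jaccard of per-study overlapped-window sets (two
studies overlapping nothing are identical, J = 1, flag by convention),
Spearman correlation between per-study log2 F toward TSO and toward TSC,
and a sweep over confidence cutoffs and window-selection rules that
reports the Spearman correlation matrix of the per-study log2 F profiles
across settings.

## Expression

Targets: a gene is a target of a study if any peak base pair is within
1 kb (inclusive) of its TSS; distance is 0 when the TSS is inside a
peak.  The robustness grid {1, 2, 5, 10} kb is built in; the default is
1 kb, always recorded in provenance.  Strand is used only to locate the
TSS.

Moderated t: ordinary two-sample pooled-variance statistics per gene;
the prior (d₀, s₀²) is fitted by matching the first two moments of
log s² to the scaled-F sampling law, with the trigamma inverted by
Newton's method (tolerance 1e-8); genes with zero variance are excluded
from the fit, and a non-positive excess variance yields d₀ = ∞ (full
shrinkage).  t̃ = b / √(s̃²(1/n₁+1/n₂)) with s̃² = (d₀s₀² + d·s²)/(d₀+d)
and d₀+d degrees of freedom (normal when infinite).  The implementation
is checked against `limma::eBayes` (R 4.3.3 / limma 3.58.1) on a frozen
fixture, agreeing to ~1e-12.  Expression input is log-scale; use
log2(count+1) for count data.

Gene-set test: competitive mean-rank (Wilcoxon) test of the target set
within the genome-wide moderated-t ordering; ties get average ranks;
"up" means shifted toward overexpression in tumour.  Exact subset
enumeration when C(N, m) ≤ 10⁵, otherwise the normal approximation
z = (R̄ − (N+1)/2)/√((N−m)(N+1)/(12m)) — verified against an exact
dynamic-programming tail at N = 50, m = 5 to within 0.02.

## Driver scoring

S = log10(F)·(−log10 p); undefined (flagged) when F is 0 or infinite,
in which case candidacy is decided by rule inspection only.  Activators:
F_TSO > 1.5 and p_up < 10⁻⁴, minus a configurable exclusion list of
RNA-polymerase study names (a polymerase "enrichment" would only reflect
active transcription).  The expression threshold is implemented as
p < 10⁻⁴ — smaller p = stronger overexpression — which is the direction
consistent with the construction of the test.  Repressors: F_TSO < 1 and
F_TSC > 1, both with BH-adjusted chi-squared p < 0.05 (a default, since
"significant" is otherwise unquantified), plus p_down < 10⁻⁴.

## Synthetic data

The generator plants a complete ground truth and emits the same file
formats the real pipeline reads, so synthetic and real runs share one
code path.

* **Compartments:** alternating blocks (default 5 windows) per
  chromosome; a balanced random subset of blocks is flipped in the
  tumour (default flip fraction 0.05 → ~10 of 200 windows, half TSO,
  half TSC).
* **Methylation:** on the logit scale, window signal =
  logit(μ_compartment) + a_{s,c} + ε, with per-sample per-compartment
  factors a ~ N(0, τ²) (τ = 0.5) shared across that compartment's
  windows, window noise ε ~ N(0, σ²) (σ = 0.2), probe noise
  N(0, η²) (η = 0.05) added on the beta scale and clamped to [0, 1].
  Defaults μ_open = 0.35, μ_closed = 0.65 (closed more methylated).
  The implied within-compartment inter-window correlation is
  τ²/(τ²+σ²) ≈ 0.862; the two compartment factors are independent, so
  raw cross-compartment correlation is ≈ 0 — the anticorrelation the
  eigenvector uses appears after the inference's per-sample centering.
  Probe positions are uniform within windows and fixed by the scenario
  seed (one array design shared by both cohorts).
* **Peaks:** midpoints sampled with per-bp weight ρ inside a chosen
  window set and 1 elsewhere (expected in-target fraction
  ρW_T/(ρW_T+W_rest)).  Activator drivers use ρ = 4 toward the TSO
  truth; the repressor uses ρ = 4 toward TSC **and** weight 1/ρ in TSO —
  without active depletion a uniform-elsewhere repressor would be only
  marginally depleted from TSO and the depletion side of the
  repressor rule would be untestable.  Each study also gets one peak at
  each of its target genes' TSSs (50 targets/TF) so TSS-proximity
  mapping recovers the planted sets; 2000 background peaks of 500 bp.
* **Expression:** y = b_g + δ_g·1[tumour] + N(0, 1), baseline
  b_g ~ N(8, 1); δ_g = +2 for activator targets, −2 for repressor
  targets, 0 otherwise.  Activator-driver target TSSs are placed inside
  TSO-truth windows (drivers bind the chromatin that opened around
  their targets), repressor targets inside TSC.
* **Tracks:** per-window accessibility values around compartment means
  (open 10 vs closed 2, sd 1, floored at 0); acetylation-like peaks
  enriched (ρ = 8) in open windows; summit-bearing repressive-mark peaks
  enriched in closed windows.

Default scenario: 2 chromosomes × 100 windows × 100 kb, 50 samples per
cohort, 5 probes per window, 20 TFs (3 activators + 1 repressor planted),
2000 genes.  These sizes run the complete pipeline in roughly a second,
so the recovery experiments replicate over 10–20 seeds in well under a
minute each.

**What passing recovery tests does and does not show.**  The generator
reproduces the *correlation geometry* the method assumes — block
structure, two-group flips, enrichment-weighted binding, shifted
targets — but not probe chemistry (type I/II design, SNP artefacts),
cell-type mixtures, purity gradients, copy-number-driven methylation
shifts, or realistic peak-width/TSS-distance distributions.  Recovery at
the planted effect sizes demonstrates correctness of the machinery, not
sensitivity on real cohorts.

## Numerical and degenerate-input choices

0-based half-open coordinates everywhere; truncated terminal windows
keep their residual width in all width-normalised statistics; empty
interval collections intersect to (0, 0); an empty peak set or an empty
target set is an error for F; both-empty Jaccard sets give J = 1 with a
flag; a gene set disjoint from the universe is skipped with a flag; the
rank test refuses m = 0 and m = N; p-values are floored at the smallest
positive double.  All generators are pure functions of (parameters,
seed).
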