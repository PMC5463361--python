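"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the statistical structure the analysis assumes:

* two-cohort methylation matrices whose windows carry block-structured
  compartment signal on the logit scale (shared per-sample compartment
  factors give long-range within-compartment correlation; betas stay in
  [0, 1]);
* ChIP-seq peak sets whose midpoints are enriched toward chosen window
  sets, with driver TFs additionally anchored at their target genes' TSSs;
* two-group expression with planted shifts in driver target genes; and
* accessibility/histone-mark style tracks keyed to the tumour compartments.

Every generator is a pure function of its parameters and seed.  The
default desk-scale scenario — 2 chromosomes x 100 windows of 100 kb,
50 samples per cohort, 5 probes per window, 20 TFs of which 3 are planted
activator drivers and 1 a planted repressor, 2000 genes — runs the full
pipeline in seconds.

Convention: closed-compartment windows have the HIGHER mean beta, so the
eigenvector orientation against mean methylation is well defined in
recovery tests.  This is configurable because the biological direction on
real open-sea probes is tissue dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_genomics import (
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    WindowSet,
    write_bed,
    write_bedgraph,
    write_layout,
)
from .compartments import CALL_CLOSED, CALL_OPEN, MethylationMatrix
from .expression import ExpressionMatrix, GeneAnnotation, NORMAL, TUMOUR

ACTIVATOR = "activator"
REPRESSOR = "repressor"


def _rng(seed: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriverSpec:
    tf: str
    direction: str            # "activator" | "repressor"
    rho: float                # per-bp binding enrichment toward flipped windows
    delta: float              # target-gene log-expression shift (sign applied)


@dataclass(frozen=True)
class SimulationTruth:
    """Planted ground truth shared by all generators of one scenario."""

    layout: GenomeLayout
    normal_calls: tuple[str, ...]
    tumour_calls: tuple[str, ...]
    tso: WindowSet            # open in tumour, closed in normal
    tsc: WindowSet
    tfs: tuple[str, ...]
    drivers: tuple[DriverSpec, ...]
    targets: Mapping[str, frozenset[str]]   # tf -> target gene ids
    gene_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        flipped = {i for i, (a, b) in enumerate(zip(self.normal_calls, self.tumour_calls))
                   if a != b}
        if flipped != (self.tso.members | self.tsc.members):
            raise ValueError("flipped windows inconsistent with TSO/TSC truth")
        for spec in self.drivers:
            if spec.rho < 1:
                raise ValueError("driver binding enrichment must be >= 1")
            missing = self.targets.get(spec.tf, frozenset()) - set(self.gene_ids)
            if missing:
                raise ValueError(f"driver {spec.tf} targets unknown genes")

    def driver_for(self, tf: str) -> DriverSpec | None:
        for spec in self.drivers:
            if spec.tf == tf:
                return spec
        return None


def generate_truth(layout: GenomeLayout, *,
                   block_length: int = 5,
                   flip_fraction: float = 0.05,
                   n_tfs: int = 20,
                   n_activators: int = 3,
                   n_repressors: int = 1,
                   rho: float = 4.0,
                   delta: float = 2.0,
                   n_genes: int = 2000,
                   targets_per_tf: int = 50,
                   seed: int = 0) -> SimulationTruth:
    """Plant compartment calls, tumour flips, driver TFs and target sets.

    Normal-cohort calls form contiguous alternating blocks of
    ``block_length`` windows per chromosome (closed first).  A random
    subset of blocks — balanced between the two directions — is flipped in
    the tumour so that roughly ``flip_fraction`` of windows change
    compartment.  Driver TFs are drawn from the TF panel; each TF gets a
    target-gene set (driver sets mutually disjoint).
    """
    if not 0 <= flip_fraction <= 0.5:
        raise ValueError("flip_fraction must lie in [0, 0.5]")
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    if n_activators + n_repressors > n_tfs:
        raise ValueError("more drivers than TFs")
    rng = _rng(seed, 0)

    normal = []
    blocks: list[list[int]] = []          # window indices per block
    for chrom in layout.chromosomes:
        off = layout.chrom_offset(chrom)
        n = layout.n_windows_chrom(chrom)
        for b0 in range(0, n, block_length):
            idx = list(range(off + b0, off + min(b0 + block_length, n)))
            call = CALL_CLOSED if (b0 // block_length) % 2 == 0 else CALL_OPEN
            normal.extend([call] * len(idx))
            blocks.append(idx)

    n_windows = layout.n_windows
    target_flips = round(flip_fraction * n_windows)
    closed_blocks = [b for b in blocks if normal[b[0]] == CALL_CLOSED]
    open_blocks = [b for b in blocks if normal[b[0]] == CALL_OPEN]
    rng.shuffle(closed_blocks)
    rng.shuffle(open_blocks)
    tumour = list(normal)
    tso_members: set[int] = set()
    tsc_members: set[int] = set()
    flipped = 0
    # alternate directions so both TSO and TSC are populated
    while flipped < target_flips and (closed_blocks or open_blocks):
        if (len(tso_members) <= len(tsc_members) and closed_blocks) or not open_blocks:
            block = closed_blocks.pop()
            for w in block:
                tumour[w] = CALL_OPEN
            tso_members.update(block)
        else:
            block = open_blocks.pop()
            for w in block:
                tumour[w] = CALL_CLOSED
            tsc_members.update(block)
        flipped += len(block)

    gene_ids = tuple(f"gene{i:05d}" for i in range(n_genes))
    tfs = tuple(f"tf{i:02d}" for i in range(n_tfs))
    driver_idx = rng.choice(n_tfs, size=n_activators + n_repressors, replace=False)
    drivers = tuple(
        DriverSpec(tf=tfs[i], direction=ACTIVATOR if k < n_activators else REPRESSOR,
                   rho=rho, delta=delta)
        for k, i in enumerate(driver_idx)
    )
    # driver target sets are mutually disjoint; other TFs draw freely
    pool = rng.permutation(n_genes)
    targets: dict[str, frozenset[str]] = {}
    used = 0
    for spec in drivers:
        picked = pool[used:used + targets_per_tf]
        used += targets_per_tf
        targets[spec.tf] = frozenset(gene_ids[i] for i in picked)
    for tf in tfs:
        if tf not in targets:
            picked = rng.choice(n_genes, size=targets_per_tf, replace=False)
            targets[tf] = frozenset(gene_ids[i] for i in picked)

    return SimulationTruth(
        layout=layout, normal_calls=tuple(normal), tumour_calls=tuple(tumour),
        tso=WindowSet(layout, frozenset(tso_members)),
        tsc=WindowSet(layout, frozenset(tsc_members)),
        tfs=tfs, drivers=drivers, targets=targets, gene_ids=gene_ids, seed=seed,
    )


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def generate_methylation(truth: SimulationTruth,
                         cohort: Literal["normal", "tumour"],
                         n_samples: int = 50, *,
                         probes_per_window: int = 5,
                         mu_open: float = 0.35,
                         mu_closed: float = 0.65,
                         tau: float = 0.5,
                         sigma: float = 0.2,
                         eta: float = 0.05,
                         seed: int = 0) -> MethylationMatrix:
    """Compartment-structured beta matrix for one cohort.

    Per sample s and compartment c a latent factor a_{s,c} ~ N(0, tau^2)
    is shared by every window of that compartment; the window signal is
    x_{w,s} = logit(mu_{c(w)}) + a_{s,c(w)} + eps_{w,s}, eps ~ N(0, sigma^2),
    and each probe reports clamp01(logistic(x) + N(0, eta^2)).  The two
    compartment factors are independent, so raw inter-window correlation is
    ~tau^2/(tau^2+sigma^2) within a compartment and ~0 across compartments.
    Probe positions are uniform within their window and shared between
    cohorts (they derive from the truth's seed, like a fixed array design).
    """
    if n_samples < 3:
        raise ValueError("need >= 3 samples for correlation estimation")
    if probes_per_window < 1:
        raise ValueError("probes_per_window must be >= 1")
    if not (0 < mu_open < 1 and 0 < mu_closed < 1):
        raise ValueError("compartment mean betas must lie in (0, 1)")
    if cohort == TUMOUR:
        calls = truth.tumour_calls
    elif cohort == NORMAL:
        calls = truth.normal_calls
    else:
        raise ValueError(f"unknown cohort {cohort!r}")
    layout = truth.layout
    n_windows = layout.n_windows

    # probe placement: fixed by the scenario, identical across cohorts
    design_rng = _rng(truth.seed, 1)
    probe_ids, chroms, positions, window_of_probe = [], [], [], []
    for w in range(n_windows):
        b = layout.window_bounds(w)
        pos = np.sort(design_rng.integers(b.start, b.end, size=probes_per_window))
        for k, p in enumerate(pos):
            probe_ids.append(f"cg_{b.chrom}_{w:05d}_{k}")
            chroms.append(b.chrom)
            positions.append(int(p))
            window_of_probe.append(w)

    rng = _rng(seed, 2)
    mu = np.where(np.array(calls) == CALL_OPEN, logit(mu_open), logit(mu_closed))
    is_open = np.array([c == CALL_OPEN for c in calls])
    a_open = rng.normal(0.0, tau, size=n_samples)
    a_closed = rng.normal(0.0, tau, size=n_samples)
    factor = np.where(is_open[:, None], a_open[None, :], a_closed[None, :])
    eps = rng.normal(0.0, sigma, size=(n_windows, n_samples))
    x = mu[:, None] + factor + eps                     # windows x samples
    probe_signal = expit(x[np.array(window_of_probe)])
    betas = probe_signal + rng.normal(0.0, eta, size=probe_signal.shape)
    betas = np.clip(betas, 0.0, 1.0)
    sample_ids = tuple(f"{cohort[:3]}{i:03d}" for i in range(n_samples))
    return MethylationMatrix(
        probe_ids=tuple(probe_ids), chroms=tuple(chroms),
        positions=tuple(positions), betas=betas,
        sample_ids=sample_ids, cohort=cohort,
    )


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def generate_peaks(truth: SimulationTruth, tf: str, n_peaks: int,
                   peak_width: int, target_windows: WindowSet, rho: float, *,
                   avoid_windows: WindowSet | None = None,
                   avoid_weight: float = 1.0,
                   with_summits: bool = False,
                   study_id: str | None = None,
                   cell_line: str = "simulated",
                   seed: int = 0) -> PeakSet:
    """Peaks whose midpoints carry per-bp weight ``rho`` inside the target
    windows and 1 elsewhere (optionally ``avoid_weight`` in a depleted
    set), so the expected fraction of midpoints landing in the target is
    rho * W_T / (rho * W_T + W_rest).  Peaks are clipped to chromosome
    bounds.
    """
    if n_peaks <= 0:
        raise ValueError("n_peaks must be positive")
    if rho < 0:
        raise ValueError("rho must be >= 0")
    layout = truth.layout
    if peak_width >= layout.window_size:
        raise ValueError("peak width must be smaller than the window size")
    rng = _rng(seed, 3)
    widths = layout.window_widths().astype(float)
    weights = np.ones(layout.n_windows)
    weights[list(target_windows.members)] = rho
    if avoid_windows is not None:
        weights[list(avoid_windows.members)] = avoid_weight
    probs = weights * widths
    probs /= probs.sum()
    windows = rng.choice(layout.n_windows, size=n_peaks, p=probs)
    half = peak_width // 2
    intervals = []
    for w in windows:
        b = layout.window_bounds(int(w))
        mid = int(rng.integers(b.start, b.end))
        length = layout.chrom_length(b.chrom)
        start = max(0, mid - half)
        end = min(length, mid + (peak_width - half))
        summit = mid if with_summits else None
        intervals.append(GenomicInterval(b.chrom, start, end, summit=summit))
    return PeakSet(study_id=study_id or f"{tf}_{cell_line}", tf=tf,
                   cell_line=cell_line, intervals=tuple(intervals))


def generate_study_peaks(truth: SimulationTruth, annotation: GeneAnnotation,
                         tf: str, *, n_background: int = 2000,
                         peak_width: int = 500, seed: int = 0) -> PeakSet:
    """Full ChIP-seq study for one TF: background peaks (driver-weighted
    toward the flipped compartments) plus one peak at each target gene's
    TSS so that TSS-proximity mapping recovers the planted target set.

    Activator drivers are enriched toward the tumour-specific open
    windows; the repressor pattern is enriched toward tumour-specific
    closed windows and depleted (weight 1/rho) from tumour-specific open
    ones; non-driver TFs bind uniformly.
    """
    spec = truth.driver_for(tf)
    if spec is None:
        background = generate_peaks(
            truth, tf, n_background, peak_width,
            WindowSet(truth.layout, frozenset()), 1.0, seed=seed)
    elif spec.direction == ACTIVATOR:
        background = generate_peaks(
            truth, tf, n_background, peak_width, truth.tso, spec.rho, seed=seed)
    else:
        background = generate_peaks(
            truth, tf, n_background, peak_width, truth.tsc, spec.rho,
            avoid_windows=truth.tso, avoid_weight=1.0 / spec.rho, seed=seed)
    ann = annotation.to_frame()
    half = peak_width // 2
    tss_peaks = []
    for gid in sorted(truth.targets.get(tf, frozenset())):
        row = ann.loc[gid]
        length = truth.layout.chrom_length(row["chrom"])
        start = max(0, int(row["tss"]) - half)
        end = min(length, int(row["tss"]) + (peak_width - half))
        tss_peaks.append(GenomicInterval(row["chrom"], start, end))
    return PeakSet(study_id=background.study_id, tf=tf,
                   cell_line=background.cell_line,
                   intervals=background.intervals + tuple(tss_peaks))


# ---------------------------------------------------------------------------
# Annotation and expression
# ---------------------------------------------------------------------------

def generate_annotation_and_expression(truth: SimulationTruth, *,
                                       n_tumour: int = 50,
                                       n_normal: int = 50,
                                       baseline_mean: float = 8.0,
                                       baseline_sd: float = 1.0,
                                       sigma_e: float = 1.0,
                                       seed: int = 0,
                                       ) -> tuple[GeneAnnotation, ExpressionMatrix]:
    """Gene TSS annotation plus a two-group log-expression matrix.

    Driver target genes get TSSs inside the corresponding flipped windows
    (activator targets in tumour-specific open windows, repressor targets
    in tumour-specific closed ones) — drivers bind the chromatin that
    opened or closed around their targets — and carry a planted shift:
    y_{g,s} = b_g + delta_g * 1[s tumour] + N(0, sigma_e^2) with
    delta_g = +delta for activator targets, -delta for repressor targets,
    0 otherwise.
    """
    layout = truth.layout
    rng = _rng(seed, 4)
    n_genes = len(truth.gene_ids)

    special_windows: dict[str, WindowSet] = {}
    delta_sign: dict[str, float] = {}
    for spec in truth.drivers:
        ws = truth.tso if spec.direction == ACTIVATOR else truth.tsc
        sgn = 1.0 if spec.direction == ACTIVATOR else -1.0
        for gid in truth.targets[spec.tf]:
            special_windows[gid] = ws
            delta_sign[gid] = sgn * spec.delta

    chroms, tss, strands = [], [], []
    genome = layout.genome_size
    offsets = np.cumsum([0] + list(layout.lengths))
    for gid in truth.gene_ids:
        ws = special_windows.get(gid)
        if ws is not None and len(ws) > 0:
            w = int(rng.choice(sorted(ws.members)))
            b = layout.window_bounds(w)
            pos = int(rng.integers(b.start, b.end))
            chrom = b.chrom
        else:
            g = int(rng.integers(0, genome))
            ci = int(np.searchsorted(offsets, g, side="right") - 1)
            chrom = layout.chromosomes[ci]
            pos = g - int(offsets[ci])
        chroms.append(chrom)
        tss.append(pos)
        strands.append("+" if rng.random() < 0.5 else "-")
    annotation = GeneAnnotation(truth.gene_ids, tuple(chroms), tuple(tss), tuple(strands))

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    delta = np.array([delta_sign.get(g, 0.0) for g in truth.gene_ids])
    sample_ids = [f"tum{i:03d}" for i in range(n_tumour)] + \
                 [f"nor{i:03d}" for i in range(n_normal)]
    groups = {s: (TUMOUR if s.startswith("tum") else NORMAL) for s in sample_ids}
    is_tum = np.array([groups[s] == TUMOUR for s in sample_ids], dtype=float)
    noise = rng.normal(0.0, sigma_e, size=(n_genes, len(sample_ids)))
    y = baseline[:, None] + delta[:, None] * is_tum[None, :] + noise
    values = pd.DataFrame(y, index=list(truth.gene_ids), columns=sample_ids)
    values.index.name = "gene_id"
    return annotation, ExpressionMatrix(values=values, groups=groups)


# ---------------------------------------------------------------------------
# Orthogonal-evidence tracks
# ---------------------------------------------------------------------------

def generate_tracks(truth: SimulationTruth, *,
                    open_mean: float = 10.0,
                    closed_mean: float = 2.0,
                    signal_sd: float = 1.0,
                    n_acetyl_peaks: int = 1000,
                    n_repressive_peaks: int = 500,
                    enrichment: float = 8.0,
                    seed: int = 0,
                    ) -> tuple[list[GenomicInterval], PeakSet, PeakSet]:
    """Accessibility-like bedGraph, an acetylation-like peak set enriched
    in open windows, and a summit-bearing repressive-mark peak set
    enriched in closed windows, all keyed to the tumour compartments.
    """
    if open_mean <= closed_mean:
        raise ValueError("accessibility-like tracks need open mean > closed mean")
    layout = truth.layout
    rng = _rng(seed, 5)
    track = []
    for w in range(layout.n_windows):
        b = layout.window_bounds(w)
        mean = open_mean if truth.tumour_calls[w] == CALL_OPEN else closed_mean
        value = max(0.0, rng.normal(mean, signal_sd)) if signal_sd > 0 else mean
        track.append(GenomicInterval(b.chrom, b.start, b.end, value=value))
    open_windows = WindowSet(layout, frozenset(
        w for w, c in enumerate(truth.tumour_calls) if c == CALL_OPEN))
    closed_windows = open_windows.complement()
    acetyl = generate_peaks(truth, "H3K27ac", n_acetyl_peaks, 2000,
                            open_windows, enrichment, cell_line="simulated",
                            study_id="H3K27ac_sim", seed=seed + 101)
    repressive = generate_peaks(truth, "H3K27me3", n_repressive_peaks, 1000,
                                closed_windows, enrichment, with_summits=True,
                                cell_line="simulated", study_id="H3K27me3_sim",
                                seed=seed + 202)
    return track, acetyl, repressive


# ---------------------------------------------------------------------------
# Scenario bundle and writers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    truth: SimulationTruth
    meth_tumour: MethylationMatrix
    meth_normal: MethylationMatrix
    studies: tuple[PeakSet, ...]
    annotation: GeneAnnotation
    expression: ExpressionMatrix
    track: tuple[GenomicInterval, ...]
    acetyl_peaks: PeakSet
    summit_peaks: PeakSet


def default_layout(n_chromosomes: int = 2, windows_per_chrom: int = 100,
                   window_size: int = 100_000) -> GenomeLayout:
    return GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(n_chromosomes)),
        tuple(windows_per_chrom * window_size for _ in range(n_chromosomes)),
        window_size=window_size,
    )


def simulate_scenario(seed: int = 0, *, layout: GenomeLayout | None = None,
                      n_samples: int = 50, n_tfs: int = 20,
                      n_genes: int = 2000, **truth_kwargs) -> Scenario:
    """Generate the complete default scenario from one seed."""
    layout = layout or default_layout()
    truth = generate_truth(layout, n_tfs=n_tfs, n_genes=n_genes,
                           seed=seed, **truth_kwargs)
    meth_t = generate_methylation(truth, TUMOUR, n_samples, seed=seed * 7 + 1)
    meth_n = generate_methylation(truth, NORMAL, n_samples, seed=seed * 7 + 2)
    annotation, expr = generate_annotation_and_expression(
        truth, n_tumour=n_samples, n_normal=n_samples, seed=seed * 7 + 3)
    studies = tuple(
        generate_study_peaks(truth, annotation, tf, seed=seed * 7 + 10 + k)
        for k, tf in enumerate(truth.tfs)
    )
    track, acetyl, repressive = generate_tracks(truth, seed=seed * 7 + 4)
    return Scenario(truth=truth, meth_tumour=meth_t, meth_normal=meth_n,
                    studies=studies, annotation=annotation, expression=expr,
                    track=tuple(track), acetyl_peaks=acetyl,
                    summit_peaks=repressive)


def write_scenario(scenario: Scenario, outdir: str | Path) -> None:
    """Write a scenario in the same flat-file formats the real pipeline
    reads, so synthetic and real runs share one code path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = scenario.truth.layout
    write_layout(layout, outdir / "genome.tsv")
    scenario.meth_tumour.to_frame().to_csv(outdir / "meth_tumour.tsv", sep="\t")
    scenario.meth_normal.to_frame().to_csv(outdir / "meth_normal.tsv", sep="\t")
    scenario.annotation.to_frame().to_csv(outdir / "genes.tsv", sep="\t")
    scenario.expression.values.to_csv(outdir / "expression.tsv", sep="\t")
    pd.Series(dict(scenario.expression.groups), name="group") \
        .rename_axis("sample_id").to_csv(outdir / "groups.tsv", sep="\t")
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for study in scenario.studies:
        write_bed(study, peak_dir / f"{study.study_id}.bed")
    write_bedgraph(scenario.track, outdir / "dnase.bedgraph")
    write_bed(scenario.acetyl_peaks, outdir / "h3k27ac.bed")
    write_bed(scenario.summit_peaks, outdir / "h3k27me3.bed", summits=True)
    truth = scenario.truth
    pd.DataFrame({
        "window": range(layout.n_windows),
        "normal_call": truth.normal_calls,
        "tumour_call": truth.tumour_calls,
    }).to_csv(outdir / "truth_calls.tsv", sep="\t", index=False)
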