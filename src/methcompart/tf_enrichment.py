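"""Enrichment of ChIP-seq peak sets in differential compartment windows.

The central statistic is the width-ratio fold enrichment

    F = [ width(peaks ∩ target) / width(peaks \\ target) ]
        / [ width(target) / width(¬target) ]

computed over merged peak base pairs, together with a one-degree-of-freedom
chi-squared goodness-of-fit test on peak counts (midpoint assignment by
default; base-pair widths by config), Benjamini-Hochberg adjustment across
studies, and the robustness summaries: pairwise Jaccard of overlapped
window sets, the open-vs-closed enrichment correlation, and a sweep of the
confidence cutoff.

No pseudocounts are applied to F: a peak set with no target overlap gets
F = 0, and one entirely inside the target gets F = +inf with a flag;
log-scale summaries report NaN for both and mark the row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_genomics import GenomeLayout, PeakSet, WindowSet, intersect_width
from .compartments import CompartmentProfile
from .differential import compare_profiles


@dataclass(frozen=True)
class EnrichmentResult:
    study_id: str
    tf: str
    fold_enrichment: float          # F; 0, finite, or +inf
    chi2: float
    p_value: float
    adj_p_value: float | None       # filled in after BH across studies
    n_peaks: int
    bp_inside: int
    bp_outside: int
    expected_unreliable: bool = False   # an expected chi-squared cell < 1

    @property
    def log2_f(self) -> float:
        return math.log2(self.fold_enrichment) \
            if 0 < self.fold_enrichment < math.inf else float("nan")

    @property
    def log10_f(self) -> float:
        return math.log10(self.fold_enrichment) \
            if 0 < self.fold_enrichment < math.inf else float("nan")


def fold_enrichment(peaks: PeakSet, target: WindowSet, layout: GenomeLayout) -> float:
    """Width-ratio fold enrichment of a peak set toward a window set.

    Peaks are clipped to the layout and merged before widths are taken, so
    F is well defined under overlapping replicate peaks.  F = 0 when no
    peak base pair overlaps the target; +inf when all of them do.
    """
    if peaks.n_peaks == 0:
        raise ValueError("empty peak set")
    w_target = target.width()
    if w_target == 0:
        raise ValueError("target window set has zero width")
    w_comp = layout.genome_size - w_target
    if w_comp == 0:
        raise ValueError("target covers the whole genome")
    inside, outside = intersect_width(peaks.clipped(layout).intervals, target)
    if inside == 0:
        return 0.0
    if outside == 0:
        return math.inf
    return (inside / outside) / (w_target / w_comp)


def chi2_peak_test(peaks: PeakSet, target: WindowSet, layout: GenomeLayout,
                   assignment: Literal["midpoint", "width"] = "midpoint",
                   ) -> tuple[float, float, tuple[float, float], tuple[float, float], bool]:
    """Goodness-of-fit test of the peak distribution against the target's
    genomic share.

    With ``assignment="midpoint"`` (default) each peak is one observation
    assigned inside/outside by its midpoint, keeping peaks as independent
    units.  With ``"width"`` the observed cells are merged base-pair
    widths.  Returns (chi2, p, observed, expected, unreliable_flag); the
    flag is set when an expected cell is below 1.
    """
    if peaks.n_peaks == 0:
        raise ValueError("empty peak set")
    clipped = peaks.clipped(layout)
    q = target.width() / layout.genome_size
    if assignment == "midpoint":
        inside = 0
        for chrom, mid in clipped.midpoints():
            w = layout.window_index(chrom, mid)
            if w in target:
                inside += 1
        total = clipped.n_peaks
    elif assignment == "width":
        inside, outside = intersect_width(clipped.intervals, target)
        total = inside + outside
    else:
        raise ValueError(f"unknown assignment {assignment!r}")
    observed = (float(inside), float(total - inside))
    expected = (total * q, total * (1 - q))
    unreliable = min(expected) < 1
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected) if e > 0)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p, observed, expected, unreliable


def adjust_pvalues(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich_studies(studies: Iterable[PeakSet], target: WindowSet,
                   layout: GenomeLayout,
                   assignment: Literal["midpoint", "width"] = "midpoint",
                   ) -> list[EnrichmentResult]:
    """F, chi-squared and BH-adjusted p for each study against one target set."""
    results = []
    for peaks in studies:
        f = fold_enrichment(peaks, target, layout)
        chi2, p, (obs_in, _), _, unreliable = chi2_peak_test(
            peaks, target, layout, assignment)
        inside, outside = intersect_width(peaks.clipped(layout).intervals, target)
        results.append(EnrichmentResult(
            study_id=peaks.study_id, tf=peaks.tf, fold_enrichment=f,
            chi2=chi2, p_value=p, adj_p_value=None, n_peaks=peaks.n_peaks,
            bp_inside=inside, bp_outside=outside,
            expected_unreliable=unreliable))
    adj = adjust_pvalues([r.p_value for r in results])
    return [EnrichmentResult(**{**r.__dict__, "adj_p_value": a})
            for r, a in zip(results, adj)]


def overlapped_windows(peaks: PeakSet, target: WindowSet,
                       layout: GenomeLayout) -> frozenset[int]:
    """Target windows overlapped by at least one peak base pair."""
    hit: set[int] = set()
    for iv in peaks.clipped(layout).merged():
        off = layout.chrom_offset(iv.chrom)
        first = iv.start // layout.window_size
        last = (iv.end - 1) // layout.window_size
        for k in range(first, last + 1):
            w = off + k
            if w in target:
                hit.add(w)
    return frozenset(hit)


def pairwise_jaccard(studies: Sequence[PeakSet], target: WindowSet,
                     layout: GenomeLayout) -> pd.DataFrame:
    """Jaccard index between each pair of studies' overlapped-window sets.

    Two studies that both overlap no target window at all are given J = 1
    (their overlapped sets are identical, albeit empty).
    """
    sets = [overlapped_windows(p, target, layout) for p in studies]
    ids = [p.study_id for p in studies]
    n = len(sets)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = sets[i] | sets[j]
            mat[i, j] = mat[j, i] = (len(sets[i] & sets[j]) / len(union)) if union else 1.0
    return pd.DataFrame(mat, index=ids, columns=ids)


def enrichment_correlation(open_results: Sequence[EnrichmentResult],
                           closed_results: Sequence[EnrichmentResult],
                           ) -> tuple[float, float]:
    """Spearman rank correlation between per-study log fold enrichments to
    the open-specific and closed-specific window sets, paired by study id.
    Studies whose F is 0 or infinite on either side are excluded (their log
    is undefined).
    """
    closed_by_id = {r.study_id: r for r in closed_results}
    xs, ys = [], []
    for r in open_results:
        other = closed_by_id.get(r.study_id)
        if other is None:
            continue
        if np.isfinite(r.log2_f) and np.isfinite(other.log2_f):
            xs.append(r.log2_f)
            ys.append(other.log2_f)
    if len(xs) < 3:
        raise ValueError("fewer than 3 comparable study pairs")
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p)


def threshold_sweep(tumour: CompartmentProfile, normal: CompartmentProfile,
                    studies: Sequence[PeakSet], layout: GenomeLayout,
                    thetas: Sequence[float],
                    include_concordant: bool = True,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute per-study log2 F under a grid of confidence cutoffs and
    window-selection rules.

    Settings are "tso@theta" for each theta (tumour-open / normal-closed)
    and, when ``include_concordant`` is true, "bothopen@theta"
    (open in both cohorts) — the latter shares the open-in-tumour property
    but not the compartment *change*, so its enrichment profile should
    decorrelate from the TSO-based ones.  Returns (per-study log2 F table,
    Spearman correlation matrix between setting columns).  A setting whose
    window set is empty is kept as a column of NaN with a flag in the
    column name, never silently dropped.
    """
    if len(thetas) == 0:
        raise ValueError("theta grid is empty")
    columns: dict[str, list[float]] = {}

    def add_column(name: str, values: list[float]) -> None:
        # repeated grid entries stay as distinct columns
        base, k = name, 1
        while name in columns:
            k += 1
            name = f"{base}#{k}"
        columns[name] = values

    for theta in thetas:
        et, en = tumour.scores, normal.scores
        ok = np.isfinite(et) & np.isfinite(en)
        selections = {
            f"tso@{theta:g}": np.flatnonzero(ok & (et < -theta) & (en > theta)),
        }
        if include_concordant:
            selections[f"bothopen@{theta:g}"] = np.flatnonzero(
                ok & (et < -theta) & (en < -theta))
        for name, idx in selections.items():
            if len(idx) == 0:
                add_column(name + "!empty", [float("nan")] * len(studies))
                continue
            target = WindowSet(layout, frozenset(idx.tolist()))
            fs = [fold_enrichment(p, target, layout) for p in studies]
            add_column(name, [math.log2(f) if 0 < f < math.inf else float("nan")
                              for f in fs])
    table = pd.DataFrame(columns, index=[p.study_id for p in studies])
    valid = [c for c in table.columns if not c.endswith("!empty")]
    corr = table[valid].corr(method="spearman")
    return table, corr


def results_to_frame(open_results: Sequence[EnrichmentResult],
                     closed_results: Sequence[EnrichmentResult] | None = None,
                     ) -> pd.DataFrame:
    """One row per study: TF, F and log2 F with chi-squared p and adjusted p
    for the open-specific set, and the same for the closed-specific set
    when given (mirrors the layout of a per-study enrichment table).
    """
    rows = []
    closed_by_id = {r.study_id: r for r in (closed_results or [])}
    for r in open_results:
        row = {
            "study_id": r.study_id, "tf": r.tf, "n_peaks": r.n_peaks,
            "F_tso": r.fold_enrichment, "log2F_tso": r.log2_f,
            "p_tso": r.p_value, "p_adj_tso": r.adj_p_value,
        }
        c = closed_by_id.get(r.study_id)
        if c is not None:
            row.update({"F_tsc": c.fold_enrichment, "log2F_tsc": c.log2_f,
                        "p_tsc": c.p_value, "p_adj_tsc": c.adj_p_value})
        rows.append(row)
    return pd.DataFrame(rows)
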