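"""Orthogonal-evidence checks for compartment calls.

Per-window statistics from independent assays — accessibility signal
sums, active-mark peak coverage, repressive-mark summit overlap — are
compared between the open and closed compartment groups; copy-number
state distributions and pathway over-representation guard against the
differential windows being driven by aneuploidy or trivial gene content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_genomics import GenomeLayout, GenomicInterval, PeakSet, WindowSet, merge_intervals
from .compartments import CALL_CLOSED, CALL_OPEN, CompartmentProfile
from .expression import GeneAnnotation


@dataclass(frozen=True)
class WindowStatistic:
    """One value per window plus a tag saying what kind of statistic it is."""

    layout: GenomeLayout
    values: np.ndarray
    kind: str    # "signal_sum" | "signal_mean" | "coverage" | "summit" | ...

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.layout.n_windows,):
            raise ValueError("one value per window required")
        if self.kind == "coverage" and ((values < 0) | (values > 1)).any():
            raise ValueError("coverage proportions must lie in [0, 1]")
        object.__setattr__(self, "values", values)


def _split_at_windows(iv: GenomicInterval, layout: GenomeLayout):
    """Yield (window index, overlap bp) pieces of an interval."""
    off = layout.chrom_offset(iv.chrom)
    w = layout.window_size
    first, last = iv.start // w, (iv.end - 1) // w
    for k in range(first, last + 1):
        lo = max(iv.start, k * w)
        hi = min(iv.end, (k + 1) * w, layout.chrom_length(iv.chrom))
        if lo < hi:
            yield off + k, hi - lo


def window_signal_sum(track: Iterable[GenomicInterval],
                      layout: GenomeLayout) -> WindowStatistic:
    """Per-window integral of a valued track: sum of value x overlap bp.

    An interval spanning a window boundary contributes proportionally to
    each side, so the total over all windows equals the per-bp integral of
    the track exactly.
    """
    sums = np.zeros(layout.n_windows)
    for iv in track:
        if iv.value is None or not np.isfinite(iv.value):
            raise ValueError(f"track interval without finite value: {iv}")
        if iv.chrom not in layout.chromosomes:
            continue
        for w, bp in _split_at_windows(iv, layout):
            sums[w] += iv.value * bp
    return WindowStatistic(layout, sums, "signal_sum")


def window_signal_mean(track: Iterable[GenomicInterval],
                       layout: GenomeLayout) -> WindowStatistic:
    """Per-window average per-bp signal (the sum divided by window width)."""
    sums = window_signal_sum(track, layout)
    return WindowStatistic(layout, sums.values / layout.window_widths(), "signal_mean")


def window_peak_coverage(peaks: PeakSet, layout: GenomeLayout) -> WindowStatistic:
    """Proportion of each window covered by (merged) peak base pairs."""
    covered = np.zeros(layout.n_windows)
    for iv in peaks.clipped(layout).merged():
        for w, bp in _split_at_windows(iv, layout):
            covered[w] += bp
    return WindowStatistic(layout, covered / layout.window_widths(), "coverage")


def window_summit_overlap(peaks: PeakSet, layout: GenomeLayout) -> WindowStatistic:
    """Indicator per window: does at least one peak summit fall inside it?"""
    flags = np.zeros(layout.n_windows)
    for iv in peaks.clipped(layout).intervals:
        if iv.summit is None:
            raise ValueError(
                f"peak {iv.chrom}:{iv.start}-{iv.end} has no summit coordinate")
        flags[layout.window_index(iv.chrom, iv.summit)] = 1.0
    return WindowStatistic(layout, flags, "summit")


def compare_by_compartment(stat: WindowStatistic, profile: CompartmentProfile,
                           *, t_variant: Literal["pooled", "welch"] = "pooled",
                           ) -> dict:
    """Compare a window statistic between open- and closed-called windows.

    Returns medians per group and their difference, a two-sample t-test
    p-value (pooled by default, Welch by config), and — for indicator
    statistics — the proportion positive per group.  NA-called windows are
    excluded.
    """
    calls = np.array(profile.calls)
    open_vals = stat.values[calls == CALL_OPEN]
    closed_vals = stat.values[calls == CALL_CLOSED]
    if len(open_vals) < 2 or len(closed_vals) < 2:
        raise ValueError("need >= 2 windows in each compartment group")
    t, p = stats.ttest_ind(open_vals, closed_vals,
                           equal_var=(t_variant == "pooled"))
    return {
        "median_open": float(np.median(open_vals)),
        "median_closed": float(np.median(closed_vals)),
        "median_difference": float(np.median(open_vals) - np.median(closed_vals)),
        "t": float(t),
        "p_value": float(p),
        "proportion_positive_open": float((open_vals > 0).mean()),
        "proportion_positive_closed": float((closed_vals > 0).mean()),
        "n_open": int(len(open_vals)),
        "n_closed": int(len(closed_vals)),
    }


def copy_number_distribution(states: pd.DataFrame, annotation: GeneAnnotation,
                             windows_of_interest: WindowSet,
                             *, mapping: Literal["tss", "span"] = "tss",
                             ) -> pd.DataFrame:
    """Copy-number state proportions inside vs outside a window set.

    ``states`` is a gene x sample integer matrix of thresholded calls in
    {-2..2}.  Genes are mapped to windows by TSS (default).  For each
    group, (gene, sample) pairs are counted per state and normalised to
    proportions summing to 1.
    """
    layout = windows_of_interest.layout
    ann = annotation.to_frame()
    genes_in, genes_out = [], []
    for gid in states.index:
        if gid not in ann.index:
            continue
        row = ann.loc[gid]
        if row["chrom"] not in layout.chromosomes:
            continue
        w = layout.window_index(row["chrom"], int(row["tss"]))
        (genes_in if w in windows_of_interest else genes_out).append(gid)
    if not genes_in or not genes_out:
        raise ValueError("a gene group is empty; cannot form distributions")
    out = {}
    for name, genes in (("inside", genes_in), ("outside", genes_out)):
        vals = states.loc[genes].to_numpy().ravel()
        counts = pd.Series(vals).value_counts().sort_index()
        out[name] = counts / counts.sum()
    return pd.DataFrame(out).fillna(0.0).rename_axis("state")


def geneset_overrepresentation(selected: Iterable[str], universe: Iterable[str],
                               gene_sets: Mapping[str, Iterable[str]],
                               ) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a selection.

    Sets are intersected with the universe first; a set disjoint from the
    universe is kept as a flagged row with no test.  P-values are
    upper-tail hypergeometric (at least the observed overlap), adjusted by
    Benjamini-Hochberg across the tested sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    n_univ, n_sel = len(universe), len(selected)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        if not members:
            rows.append((name, 0, 0, np.nan, True))
            continue
        k = len(members & selected)
        # P(X >= k), X ~ Hypergeom(N=n_univ, K=len(members), n=n_sel)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_sel))
        rows.append((name, len(members), k, p, False))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_value",
                                     "skipped"]).set_index("set")
    tested = ~df["skipped"]
    adj = pd.Series(np.nan, index=df.index)
    if tested.any():
        from .tf_enrichment import adjust_pvalues
        adj[tested] = adjust_pvalues(df.loc[tested, "p_value"].tolist())
    df["adj_p_value"] = adj
    return df


def genes_in_windows(annotation: GeneAnnotation, windows: WindowSet) -> set[str]:
    """Gene ids whose TSS falls in a window set."""
    layout = windows.layout
    out = set()
    for gid, chrom, tss in zip(annotation.gene_ids, annotation.chroms, annotation.tss):
        if chrom in layout.chromosomes:
            if layout.window_index(chrom, tss) in windows:
                out.add(gid)
    return out
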