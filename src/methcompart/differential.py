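"""Tumour-vs-normal comparison of compartment profiles.

Produces tumour-specific open (TSO: open in tumour, closed in normal) and
tumour-specific closed (TSC) window sets, the concordance summaries, the
per-chromosome enrichment of aberrant windows, and the split-half
robustness check in which a cohort is split into two random halves and the
same differential procedure is run between them (a null comparison that
should yield far fewer windows than tumour-vs-normal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .core_genomics import GenomeLayout, WindowSet
from .compartments import (
    CALL_NA,
    CompartmentProfile,
    MethylationMatrix,
    bin_methylation,
    call_compartments,
    compartment_eigenvector,
)


@dataclass(frozen=True)
class DifferentialCompartments:
    """TSO/TSC window sets with the thresholds that produced them.

    ``delta_scores`` is the per-window eigenvector change
    e_tumour - e_normal (NaN where either profile is missing).
    """

    tso: WindowSet
    tsc: WindowSet
    theta: float
    delta_scores: np.ndarray
    strict: bool = False
    delta_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.tso.members & self.tsc.members:
            raise ValueError("TSO and TSC overlap")

    @property
    def aberrant(self) -> WindowSet:
        return WindowSet(self.tso.layout, self.tso.members | self.tsc.members)


def _check_layouts(tumour: CompartmentProfile, normal: CompartmentProfile) -> GenomeLayout:
    if tumour.layout != normal.layout:
        raise ValueError("profiles computed on different layouts")
    if tumour.normalization != normal.normalization:
        raise ValueError("profiles use different normalization rules")
    return tumour.layout


def compare_profiles(tumour: CompartmentProfile, normal: CompartmentProfile,
                     theta: float = 0.1) -> DifferentialCompartments:
    """Windows confidently open in tumour and closed in normal (TSO), and
    vice versa (TSC).  The confidence threshold is applied symmetrically:
    a window must exceed theta in *both* cohorts to be a member.
    """
    layout = _check_layouts(tumour, normal)
    et, en = tumour.scores, normal.scores
    ok = np.isfinite(et) & np.isfinite(en)
    tso = np.flatnonzero(ok & (et < -theta) & (en > theta))
    tsc = np.flatnonzero(ok & (et > theta) & (en < -theta))
    delta = np.where(ok, et - en, np.nan)
    return DifferentialCompartments(
        tso=WindowSet(layout, frozenset(tso.tolist())),
        tsc=WindowSet(layout, frozenset(tsc.tolist())),
        theta=theta,
        delta_scores=delta,
    )


def strict_subset(diff: DifferentialCompartments,
                  delta_threshold: float = 0.2) -> DifferentialCompartments:
    """Restrict to windows whose eigenvector also changed by at least
    ``delta_threshold`` in absolute value (the sign change is already
    guaranteed by membership).
    """
    keep_tso = frozenset(w for w in diff.tso.members
                         if abs(diff.delta_scores[w]) >= delta_threshold)
    keep_tsc = frozenset(w for w in diff.tsc.members
                         if abs(diff.delta_scores[w]) >= delta_threshold)
    layout = diff.tso.layout
    return DifferentialCompartments(
        tso=WindowSet(layout, keep_tso),
        tsc=WindowSet(layout, keep_tsc),
        theta=diff.theta,
        delta_scores=diff.delta_scores,
        strict=True,
        delta_threshold=delta_threshold,
    )


def concordance(tumour: CompartmentProfile, normal: CompartmentProfile,
                theta: float = 0.1) -> tuple[float, float, int]:
    """(fraction of confident windows with the same call, Pearson r of the
    eigen scores over windows non-missing in both, number excluded as
    low-confidence).
    """
    _check_layouts(tumour, normal)
    et, en = tumour.scores, normal.scores
    finite = np.isfinite(et) & np.isfinite(en)
    if finite.sum() < 2:
        raise ValueError("fewer than 2 shared windows: correlation undefined")
    confident = finite & (np.abs(et) >= theta) & (np.abs(en) >= theta)
    n_excluded = int(finite.sum() - confident.sum())
    same = np.sign(et[confident]) == np.sign(en[confident])
    agreement = float(same.mean()) if confident.any() else float("nan")
    r = float(np.corrcoef(et[finite], en[finite])[0, 1])
    return agreement, r, n_excluded


def chromosome_enrichment(diff: DifferentialCompartments,
                          tumour: CompartmentProfile,
                          normal: CompartmentProfile) -> pd.DataFrame:
    """Observed vs expected aberrant windows per chromosome.

    Expected counts are proportional to each chromosome's share of
    *eligible* windows (confident in both cohorts at the theta used for the
    comparison), so chromosomes with many missing or low-confidence windows
    are not penalised.  Observed and expected counts both sum to the total
    number of aberrant windows.
    """
    layout = diff.tso.layout
    theta = diff.theta
    et, en = tumour.scores, normal.scores
    eligible = (np.isfinite(et) & np.isfinite(en)
                & (np.abs(et) > theta) & (np.abs(en) > theta))
    chroms = layout.window_chroms()
    aberrant = np.zeros(layout.n_windows, dtype=bool)
    aberrant[list(diff.aberrant.members)] = True
    total_aberrant = aberrant.sum()
    total_eligible = eligible.sum()
    rows = []
    for chrom in layout.chromosomes:
        on_chrom = chroms == chrom
        obs = int((aberrant & on_chrom).sum())
        n_elig = int((eligible & on_chrom).sum())
        exp = total_aberrant * n_elig / total_eligible if total_eligible else 0.0
        ratio = obs / exp if exp > 0 else 0.0
        rows.append((chrom, n_elig, obs, exp, ratio))
    return pd.DataFrame(rows, columns=["chrom", "eligible", "observed",
                                       "expected", "ratio"])


def split_half_robustness(meth: MethylationMatrix, layout: GenomeLayout,
                          n_per_subset: int, *, theta: float = 0.1,
                          reference: DifferentialCompartments | None = None,
                          seed: int = 0,
                          aggregator: Literal["mean", "median"] = "mean",
                          ) -> tuple[int, frozenset[int]]:
    """Differential windows between two random disjoint sample subsets.

    Runs bin -> eigenvector -> call -> compare on the two subsets with the
    same thresholds as the reference tumour-vs-normal comparison.  Returns
    the count of differential windows and the overlap with the reference
    differential set (empty set if no reference given).  A cohort with no
    substructure should yield far fewer windows than a genuine
    tumour-vs-normal run.
    """
    if 2 * n_per_subset > meth.n_samples:
        raise ValueError("cohort too small for two disjoint subsets")
    rng = np.random.default_rng(seed)
    order = rng.permutation(meth.n_samples)
    idx_a, idx_b = order[:n_per_subset], order[n_per_subset:2 * n_per_subset]

    def run(idx: np.ndarray) -> CompartmentProfile:
        sub = MethylationMatrix(
            probe_ids=meth.probe_ids, chroms=meth.chroms, positions=meth.positions,
            betas=meth.betas[:, idx],
            sample_ids=tuple(meth.sample_ids[i] for i in idx),
            cohort=meth.cohort,
        )
        binned = bin_methylation(sub, layout, aggregator=aggregator)
        return call_compartments(compartment_eigenvector(binned), theta)

    diff = compare_profiles(run(idx_a), run(idx_b), theta)
    members = diff.aberrant.members
    shared = members & reference.aberrant.members if reference is not None else frozenset()
    return len(members), shared


def write_differential(diff: DifferentialCompartments, path) -> None:
    layout = diff.tso.layout
    rows = []
    for w in sorted(diff.tso.members | diff.tsc.members):
        b = layout.window_bounds(w)
        kind = "TSO" if w in diff.tso.members else "TSC"
        rows.append((b.chrom, b.start, b.end, w, kind, diff.delta_scores[w]))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "window", "set", "delta_e"]) \
        .to_csv(path, sep="\t", index=False, float_format="%.6g")
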