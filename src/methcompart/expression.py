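"""Target-gene assignment, moderated t-statistics and gene-set rank tests.

Genes are assigned as targets of a ChIP-seq study when a peak lies within
a distance cutoff of their TSS (default 1 kb, inclusive).  Differential
expression between tumour and normal uses the empirical-Bayes moderated
two-sample t: per-gene pooled variances s_g^2 with d_g residual degrees of
freedom are shrunk toward a prior (d0, s0^2) fitted by moment-matching the
log variances to a scaled-F sampling law,

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g),
    t~_g   = b_g / sqrt(s~_g^2 (1/n1 + 1/n2)),   df = d0 + d_g.

Target sets are then tested for a systematic shift in the ranking of the
per-gene statistics (a competitive Wilcoxon mean-rank test), with exact
subset enumeration on small problems and a normal approximation otherwise.

Expression values are expected on a log scale; for count inputs use
log2(count + 1) upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_genomics import GenomeLayout, PeakSet

TUMOUR = "tumour"
NORMAL = "normal"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """Gene TSS coordinates.  Strand is used only to locate the TSS."""

    gene_ids: tuple[str, ...]
    chroms: tuple[str, ...]
    tss: tuple[int, ...]
    strands: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        n = len(self.gene_ids)
        if not (len(self.chroms) == len(self.tss) == len(self.strands) == n):
            raise ValueError("annotation arrays differ in length")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids, "chrom": self.chroms,
            "tss": self.tss, "strand": self.strands,
        }).set_index("gene_id")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneAnnotation":
        return cls(tuple(df.index.astype(str)), tuple(df["chrom"].astype(str)),
                   tuple(df["tss"].astype(int)), tuple(df["strand"].astype(str)))


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample log-scale expression with tumour/normal group labels."""

    values: pd.DataFrame                 # genes x samples
    groups: Mapping[str, str]            # sample id -> "tumour" | "normal"

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")
        counts = pd.Series([self.groups[s] for s in self.values.columns]).value_counts()
        for g in (TUMOUR, NORMAL):
            if counts.get(g, 0) < 2:
                raise ValueError(f"need >= 2 samples in group {g!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass(frozen=True)
class ModeratedStats:
    """Per-gene moderated t results and the fitted prior."""

    table: pd.DataFrame       # index gene_id; lfc, s2, df, s2_post, t, p_value
    prior_df: float           # d0, possibly inf
    prior_var: float          # s0^2


@dataclass(frozen=True)
class GeneSetTestResult:
    study_id: str
    m: int                    # target genes in universe
    n_universe: int
    mean_rank: float
    z: float
    p_value: float
    alternative: str          # "up" | "down"
    exact: bool = False


# ---------------------------------------------------------------------------
# Target mapping
# ---------------------------------------------------------------------------

def map_targets(peaks: PeakSet, annotation: GeneAnnotation,
                cutoff: int = 1000) -> set[str]:
    """Genes with a peak base pair within ``cutoff`` bp of their TSS
    (inclusive boundary; distance 0 when the TSS lies inside a peak).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(annotation) == 0:
        raise ValueError("empty gene annotation")
    merged = peaks.merged()
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in merged}:
        ivs = [iv for iv in merged if iv.chrom == chrom]
        by_chrom[chrom] = (np.array([iv.start for iv in ivs]),
                           np.array([iv.end for iv in ivs]))
    targets: set[str] = set()
    for gid, chrom, tss in zip(annotation.gene_ids, annotation.chroms, annotation.tss):
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        j = np.searchsorted(starts, tss, side="right")
        dist = math.inf
        if j > 0:
            # nearest peak at or left of the TSS; last covered bp is end-1
            dist = max(0, tss - (ends[j - 1] - 1))
        if j < len(starts):
            dist = min(dist, starts[j] - tss)
        if dist <= cutoff:
            targets.add(gid)
    return targets


def target_cutoff_grid(peaks: PeakSet, annotation: GeneAnnotation,
                       cutoffs: Sequence[int] = (1000, 2000, 5000, 10000),
                       ) -> dict[int, set[str]]:
    """Target sets across the standard robustness grid of TSS cutoffs."""
    return {c: map_targets(peaks, annotation, c) for c in cutoffs}


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton's method."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        deriv = float(special.polygamma(2, x))
        step = (tri - y) / deriv
        x -= step
        if x <= 0:
            x = 1e-8
        if abs(step) < tol * max(x, 1.0):
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of (d0, s0^2) from sample variances.

    Under the model s_g^2 | sigma_g^2 ~ sigma_g^2 chi^2_d / d with
    sigma_g^2 ~ s0^2 d0 / chi^2_{d0}, the log variances have
    E[log s^2] = log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2)
    and Var[log s^2] = psi'(d/2) + psi'(d0/2).  Inverting the trigamma
    gives d0; an excess variance <= 0 yields d0 = +inf (no gene-level
    variance heterogeneity beyond sampling noise).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need >= 2 positive variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2) + math.log(df / 2)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2))
    if evar <= 0:
        return math.inf, math.exp(emean)
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = math.exp(emean + float(special.digamma(d0 / 2)) - math.log(d0 / 2))
    return d0, s0_sq


def moderated_t(expr: ExpressionMatrix, *,
                prior_df: float | None = None) -> ModeratedStats:
    """Empirical-Bayes moderated two-sample t, tumour vs normal.

    The log fold change b_g is mean(tumour) - mean(normal).  ``prior_df``
    overrides the fitted d0 (0 recovers the ordinary pooled t; inf shrinks
    every variance fully to s0^2).
    """
    tum = expr.values[expr.group_columns(TUMOUR)].to_numpy()
    nor = expr.values[expr.group_columns(NORMAL)].to_numpy()
    n1, n2 = tum.shape[1], nor.shape[1]
    d = n1 + n2 - 2
    if d <= 0:
        raise ValueError("zero residual degrees of freedom")
    lfc = tum.mean(axis=1) - nor.mean(axis=1)
    ss = tum.var(axis=1, ddof=1) * (n1 - 1) + nor.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d

    if len(lfc) < 10:
        import warnings
        warnings.warn("fewer than 10 genes: variance-prior fit is unreliable")
    try:
        d0, s0_sq = fit_variance_prior(s2, d)
    except ValueError:
        if prior_df is None:
            raise
        d0, s0_sq = prior_df, float(np.mean(s2))  # prior forced; plain pooled prior var
    if prior_df is not None:
        d0 = prior_df
    if d0 == 0:
        s2_post = s2.copy()
    elif math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)

    scale = 1.0 / n1 + 1.0 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2_post * scale)
    df_total = d0 + d
    if math.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df=df_total)
    table = pd.DataFrame({
        "lfc": lfc, "s2": s2, "df": float(d), "s2_post": s2_post,
        "t": t, "p_value": p,
    }, index=expr.values.index)
    return ModeratedStats(table=table, prior_df=d0, prior_var=s0_sq)


# ---------------------------------------------------------------------------
# Gene-set rank test
# ---------------------------------------------------------------------------

EXACT_LIMIT = 100_000


def gene_set_rank_test(statistics: pd.Series, targets: Iterable[str],
                       alternative: Literal["up", "down"] = "up",
                       study_id: str = "") -> GeneSetTestResult:
    """Competitive mean-rank test of a target gene set.

    Tests the null that target-gene ranks are uniformly scattered through
    the genome-wide ordering of ``statistics``.  "up" asks whether targets
    sit toward the overexpressed end (large statistics); "down" the
    opposite.  Rank ties get average ranks.  When C(N, m) <= 10^5 the
    p-value is computed by exhaustive subset enumeration; otherwise a
    normal approximation with

        z = (mean_rank - (N+1)/2) / sqrt((N-m)(N+1)/(12 m))

    is used.
    """
    statistics = statistics.astype(float)
    targets = set(targets)
    unknown = targets - set(statistics.index)
    if unknown:
        raise ValueError(f"targets outside universe: {sorted(unknown)[:5]}")
    n = len(statistics)
    m = len(targets)
    if m == 0 or m == n:
        raise ValueError("target set must be a proper non-empty subset")
    values = statistics.to_numpy()
    if alternative == "down":
        values = -values
    elif alternative != "up":
        raise ValueError(f"unknown alternative {alternative!r}")
    ranks = stats.rankdata(values)          # ascending: largest stat = rank N
    is_target = statistics.index.isin(targets)
    obs_sum = float(ranks[is_target].sum())
    mean_rank = obs_sum / m

    if math.comb(n, m) <= EXACT_LIMIT:
        count = sum(1 for combo in combinations(ranks, m)
                    if sum(combo) >= obs_sum - 1e-9)
        p = count / math.comb(n, m)
        exact = True
    else:
        p = None
        exact = False
    sd = math.sqrt((n - m) * (n + 1) / (12.0 * m))
    z = (mean_rank - (n + 1) / 2.0) / sd
    if p is None:
        p = float(stats.norm.sf(z))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    # report the mean rank on the original ("up") orientation
    if alternative == "down":
        mean_rank = (n + 1) - mean_rank
    return GeneSetTestResult(study_id=study_id, m=m, n_universe=n,
                             mean_rank=mean_rank, z=z, p_value=p,
                             alternative=alternative, exact=exact)


def test_target_sets(stats_table: ModeratedStats,
                     targets_by_study: Mapping[str, Iterable[str]],
                     alternative: Literal["up", "down"] = "up",
                     ranking: str = "t") -> list[GeneSetTestResult]:
    """Rank-sum test for each study's target set against the moderated-t
    ranking (genes ranked by the moderated t by default).
    """
    series = stats_table.table[ranking]
    out = []
    for study_id, targets in targets_by_study.items():
        targets = set(targets) & set(series.index)
        if not targets:
            continue
        out.append(gene_set_rank_test(series, targets, alternative, study_id=study_id))
    return out
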