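"""Open/closed chromatin compartment inference from methylation arrays.

The method bins probe-level beta values into fixed genomic windows,
computes the window-by-window Pearson correlation matrix across samples
per chromosome, and takes the leading eigenvector of that matrix.  The
eigenvector is normalised to max |e| = 1 and sign-oriented against a
covariate (by default the per-window mean methylation) so that windows
with higher methylation receive positive scores.  Positive score = closed
compartment, negative = open; |e| is the confidence of the call.

Binned values are mean-centred within each sample before the correlation
is computed.  This removes global per-sample methylation level — a
nuisance that varies with purity and batch — and turns the compartment
signal into a contrast, so that the two compartments load on the leading
eigenvector with opposite signs even when their fluctuations are
uncorrelated in absolute terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import linalg

from .core_genomics import GenomeLayout, GenomicInterval

#: e > +theta -> closed, e < -theta -> open, otherwise NA.
CALL_CLOSED = "closed"
CALL_OPEN = "open"
CALL_NA = "NA"

DEFAULT_CONFIDENCE = 0.1  # figure-legend definition; 0.01 available by config


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethylationMatrix:
    """Probe-level beta values (probes x samples) with genomic coordinates."""

    probe_ids: tuple[str, ...]
    chroms: tuple[str, ...]
    positions: tuple[int, ...]
    betas: np.ndarray           # probes x samples, values in [0, 1]
    sample_ids: tuple[str, ...]
    cohort: str = ""

    def __post_init__(self) -> None:
        betas = np.asarray(self.betas, dtype=float)
        n_probes = len(self.probe_ids)
        if betas.shape != (n_probes, len(self.sample_ids)):
            raise ValueError("betas shape does not match probe/sample ids")
        if len(self.chroms) != n_probes or len(self.positions) != n_probes:
            raise ValueError("coordinate arrays do not match probe ids")
        if betas.size and (np.nanmin(betas) < 0 or np.nanmax(betas) > 1):
            raise ValueError("beta values must lie in [0, 1]")
        object.__setattr__(self, "betas", betas)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.betas, index=list(self.probe_ids),
                          columns=list(self.sample_ids))
        df.insert(0, "chrom", list(self.chroms))
        df.insert(1, "pos", list(self.positions))
        df.index.name = "probe_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cohort: str = "") -> "MethylationMatrix":
        samples = [c for c in df.columns if c not in ("chrom", "pos")]
        return cls(
            probe_ids=tuple(df.index.astype(str)),
            chroms=tuple(df["chrom"].astype(str)),
            positions=tuple(df["pos"].astype(int)),
            betas=df[samples].to_numpy(dtype=float),
            sample_ids=tuple(samples),
            cohort=cohort,
        )


@dataclass(frozen=True)
class BinnedMethylation:
    """Window x sample aggregated betas; windows without probes are NaN."""

    layout: GenomeLayout
    values: np.ndarray          # n_windows x n_samples, NaN = missing
    probe_counts: np.ndarray    # n_windows
    sample_ids: tuple[str, ...]
    cohort: str = ""

    @property
    def missing(self) -> np.ndarray:
        return self.probe_counts == 0


@dataclass(frozen=True)
class CompartmentProfile:
    """Per-window eigenvector scores and open/closed calls.

    ``scores`` is the normalised leading eigenvector (max |e| = 1 per
    chromosome, NaN for missing windows); ``calls`` holds "open" /
    "closed" / "NA"; confidence is |e|.  ``eigenvalue_share`` maps each
    chromosome to the leading eigenvalue's share of the trace, and
    provenance records the orientation covariate and normalisation so two
    profiles can only be compared when computed the same way.
    """

    layout: GenomeLayout
    scores: np.ndarray
    calls: tuple[str, ...]
    eigenvalue_share: dict[str, float]
    orientation_covariate: str = "mean_methylation"
    normalization: str = "max_abs"
    cohort: str = ""

    @property
    def confidence(self) -> np.ndarray:
        return np.abs(self.scores)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.layout.n_windows):
            w = self.layout.window_bounds(i)
            rows.append((w.chrom, w.start, w.end, self.scores[i],
                         self.calls[i], abs(self.scores[i])))
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "eigen_score", "call", "confidence"])


# ---------------------------------------------------------------------------
# Probe filtering and binning
# ---------------------------------------------------------------------------

def filter_probes(meth: MethylationMatrix,
                  exclude_ids: Iterable[str] = (),
                  exclude_regions: Iterable[GenomicInterval] = ()) -> MethylationMatrix:
    """Remove probes by id (e.g. SNP-overlapping) or by genomic region
    (e.g. promoter CpG islands), preserving probe order.
    """
    exclude_ids = set(exclude_ids)
    regions = list(exclude_regions)
    keep = []
    for i, pid in enumerate(meth.probe_ids):
        if pid in exclude_ids:
            continue
        pos, chrom = meth.positions[i], meth.chroms[i]
        if any(r.chrom == chrom and r.start <= pos < r.end for r in regions):
            continue
        keep.append(i)
    if not keep:
        raise ValueError("all probes removed by filtering")
    idx = np.array(keep)
    return replace(
        meth,
        probe_ids=tuple(meth.probe_ids[i] for i in keep),
        chroms=tuple(meth.chroms[i] for i in keep),
        positions=tuple(meth.positions[i] for i in keep),
        betas=meth.betas[idx],
    )


def bin_methylation(meth: MethylationMatrix, layout: GenomeLayout,
                    aggregator: Literal["mean", "median"] = "mean") -> BinnedMethylation:
    """Aggregate probe betas to windows (mean by default; median by config).

    Windows with no probes become NaN, not zero, and are excluded from the
    correlation downstream.
    """
    n_win = layout.n_windows
    counts = np.zeros(n_win, dtype=int)
    buckets: dict[int, list[int]] = {}
    for i, (chrom, pos) in enumerate(zip(meth.chroms, meth.positions)):
        if chrom not in layout.chromosomes:
            continue
        w = layout.window_index(chrom, pos)
        buckets.setdefault(w, []).append(i)
    values = np.full((n_win, meth.n_samples), np.nan)
    agg = np.nanmean if aggregator == "mean" else np.nanmedian
    for w, rows in buckets.items():
        values[w] = agg(meth.betas[rows], axis=0)
        counts[w] = len(rows)
    return BinnedMethylation(layout=layout, values=values, probe_counts=counts,
                             sample_ids=meth.sample_ids, cohort=meth.cohort)


# ---------------------------------------------------------------------------
# Eigenvector machinery
# ---------------------------------------------------------------------------

DENSE_EIG_LIMIT = 2000
POWER_TOL = 1e-10
POWER_MAXITER = 10_000


def leading_eigenvector(mat: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenvector and eigenvalue of a symmetric matrix.

    Dense symmetric eigendecomposition up to ``DENSE_EIG_LIMIT`` rows;
    power iteration (with a trace shift to ensure the largest eigenvalue
    dominates in magnitude) above.  A tie between equal leading
    eigenvalues is broken by whichever eigenvector the routine computes
    first.  The sign of the returned vector is arbitrary.
    """
    mat = np.asarray(mat, dtype=float)
    n = mat.shape[0]
    if mat.shape != (n, n):
        raise ValueError("matrix must be square")
    if n <= DENSE_EIG_LIMIT:
        w, v = linalg.eigh(mat, subset_by_index=[n - 1, n - 1])
        return v[:, 0], float(w[0])
    # power iteration on mat + shift*I so the algebraically-largest
    # eigenvalue is also largest in magnitude
    shift = float(np.abs(mat).sum(axis=1).max())
    rng = np.random.default_rng(0)
    vec = rng.standard_normal(n)
    vec /= np.linalg.norm(vec)
    for _ in range(POWER_MAXITER):
        nxt = mat @ vec + shift * vec
        nrm = np.linalg.norm(nxt)
        if nrm == 0:
            break
        nxt /= nrm
        if min(np.linalg.norm(nxt - vec), np.linalg.norm(nxt + vec)) < POWER_TOL:
            vec = nxt
            break
        vec = nxt
    eigval = float(vec @ (mat @ vec))
    return vec, eigval


def _orient(scores: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Flip sign so the Pearson correlation with the covariate is positive.

    Idempotent: orienting an oriented vector is a no-op.  Zero correlation
    leaves the sign unchanged.
    """
    ok = np.isfinite(scores) & np.isfinite(covariate)
    if ok.sum() >= 2 and np.std(scores[ok]) > 0 and np.std(covariate[ok]) > 0:
        r = np.corrcoef(scores[ok], covariate[ok])[0, 1]
        if r < 0:
            return -scores
    return scores


def compartment_eigenvector(binned: BinnedMethylation,
                            chromosomes: Iterable[str] | None = None,
                            *,
                            center_samples: bool = True,
                            min_pairs: int = 3) -> CompartmentProfile:
    """Infer compartment scores per chromosome from binned methylation.

    Per chromosome: Pearson correlation matrix of windows across samples
    (pairwise-complete; windows with fewer than ``min_pairs`` paired
    observations, no probes, or zero variance are dropped as missing),
    leading eigenvector, normalised to max |e| = 1, sign-oriented so that
    e correlates positively with per-window mean methylation.  Profiles
    never span chromosomes.
    """
    layout = binned.layout
    if chromosomes is None:
        chromosomes = layout.chromosomes
    scores = np.full(layout.n_windows, np.nan)
    shares: dict[str, float] = {}
    values = binned.values
    if center_samples:
        # remove each sample's global level over non-missing windows
        values = values - np.nanmean(values, axis=0, keepdims=True)
    covariate_all = np.nanmean(binned.values, axis=1)  # raw mean methylation

    for chrom in chromosomes:
        off = layout.chrom_offset(chrom)
        n = layout.n_windows_chrom(chrom)
        idx = np.arange(off, off + n)
        sub = values[idx]
        usable = ~np.all(np.isnan(sub), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sds = np.nanstd(sub, axis=1)
        zero_var = usable & (sds == 0)
        if zero_var.any():
            warnings.warn(f"{chrom}: {int(zero_var.sum())} constant window(s) set to missing")
        usable &= sds > 0
        n_obs = np.sum(~np.isnan(sub), axis=1)
        usable &= n_obs >= min_pairs
        if usable.sum() < 3:
            warnings.warn(f"{chrom}: fewer than 3 usable windows, no profile")
            continue
        frame = pd.DataFrame(sub[usable].T)  # samples x windows
        corr = frame.corr(min_periods=min_pairs).to_numpy()
        np.fill_diagonal(corr, 1.0)
        corr[np.isnan(corr)] = 0.0  # pairwise-incomplete cells
        vec, eigval = leading_eigenvector(corr)
        shares[chrom] = float(eigval / np.trace(corr))
        e = np.full(n, np.nan)
        e[usable] = vec
        maxabs = np.nanmax(np.abs(e))
        if maxabs > 0:
            e = e / maxabs
        e = _orient(e, covariate_all[idx])
        scores[idx] = e

    calls = tuple(
        CALL_NA if not np.isfinite(s) else (CALL_CLOSED if s > 0 else CALL_OPEN)
        for s in scores
    )
    return CompartmentProfile(layout=layout, scores=scores, calls=calls,
                              eigenvalue_share=shares, cohort=binned.cohort)


def call_compartments(profile: CompartmentProfile,
                      theta: float = DEFAULT_CONFIDENCE) -> CompartmentProfile:
    """Set windows with confidence |e| < theta to NA; keep sign calls above."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    calls = []
    for s in profile.scores:
        if not np.isfinite(s) or abs(s) < theta:
            calls.append(CALL_NA)
        else:
            calls.append(CALL_CLOSED if s > 0 else CALL_OPEN)
    return replace(profile, calls=tuple(calls))


def infer_compartments(meth: MethylationMatrix, layout: GenomeLayout,
                       theta: float = DEFAULT_CONFIDENCE,
                       aggregator: Literal["mean", "median"] = "mean") -> CompartmentProfile:
    """Convenience: bin -> eigenvector -> threshold calls."""
    binned = bin_methylation(meth, layout, aggregator=aggregator)
    profile = compartment_eigenvector(binned)
    return call_compartments(profile, theta)


def write_profile(profile: CompartmentProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_profile(path, layout: GenomeLayout, cohort: str = "") -> CompartmentProfile:
    df = pd.read_csv(path, sep="\t")
    if len(df) != layout.n_windows:
        raise ValueError("profile row count does not match layout windows")
    return CompartmentProfile(
        layout=layout,
        scores=df["eigen_score"].to_numpy(dtype=float),
        calls=tuple(df["call"].astype(str)),
        eigenvalue_share={},
        cohort=cohort,
    )
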