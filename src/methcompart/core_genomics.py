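"""Genome layout, window tiling, interval arithmetic and flat-file readers.

All coordinates are 0-based half-open (BED convention) everywhere in the
package.  A genome is modelled as an ordered list of chromosomes tiled into
fixed-width windows (default 100 kb); the final window of each chromosome is
truncated at the chromosome end and keeps its true residual width in every
width-normalised statistic.

Strand is ignored for peaks and windows: chromatin compartments are
strandless.  Gene strand is only ever used to locate a TSS coordinate
(see :mod:`methcompart.expression`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_WINDOW_SIZE = 100_000


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, optionally carrying a track value or a
    peak summit position (absolute coordinate, must lie within the interval).
    """

    chrom: str
    start: int
    end: int
    value: float | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths, tiled into consecutive windows.

    Windows are indexed globally: chromosome order first, then tile order
    within the chromosome.  The last tile of a chromosome is truncated at
    the chromosome end.
    """

    chromosomes: tuple[str, ...]
    lengths: tuple[int, ...]
    window_size: int = DEFAULT_WINDOW_SIZE

    def __post_init__(self) -> None:
        if len(self.chromosomes) != len(self.lengths):
            raise ValueError("chromosomes and lengths differ in length")
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        object.__setattr__(self, "lengths", tuple(int(l) for l in self.lengths))

    # -- window bookkeeping -------------------------------------------------

    def n_windows_chrom(self, chrom: str) -> int:
        length = self.chrom_length(chrom)
        return -(-length // self.window_size)  # ceil div

    @property
    def n_windows(self) -> int:
        return sum(self.n_windows_chrom(c) for c in self.chromosomes)

    @property
    def genome_size(self) -> int:
        return sum(self.lengths)

    def chrom_length(self, chrom: str) -> int:
        try:
            return self.lengths[self.chromosomes.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def chrom_offset(self, chrom: str) -> int:
        """Global index of the first window of ``chrom``."""
        i = self.chromosomes.index(chrom)
        return sum(self.n_windows_chrom(c) for c in self.chromosomes[:i])

    def window_index(self, chrom: str, pos: int) -> int:
        """Global window index containing position ``pos`` on ``chrom``."""
        if not 0 <= pos < self.chrom_length(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        return self.chrom_offset(chrom) + pos // self.window_size

    def window_bounds(self, index: int) -> GenomicInterval:
        """Window interval for a global window index."""
        if index < 0:
            raise IndexError(index)
        for chrom in self.chromosomes:
            n = self.n_windows_chrom(chrom)
            if index < n:
                start = index * self.window_size
                end = min(start + self.window_size, self.chrom_length(chrom))
                return GenomicInterval(chrom, start, end)
            index -= n
        raise IndexError("window index out of range")

    def window_widths(self) -> np.ndarray:
        """Width of every window in global index order (residual last tiles)."""
        widths = []
        for chrom, length in zip(self.chromosomes, self.lengths):
            n = self.n_windows_chrom(chrom)
            w = np.full(n, self.window_size, dtype=np.int64)
            w[-1] = length - (n - 1) * self.window_size
            widths.append(w)
        return np.concatenate(widths)

    def window_chroms(self) -> np.ndarray:
        """Chromosome name of every window in global index order."""
        return np.concatenate([
            np.repeat(c, self.n_windows_chrom(c)) for c in self.chromosomes
        ])


def tile_windows(layout: GenomeLayout) -> list[GenomicInterval]:
    """Tile every chromosome into consecutive ``window_size`` intervals.

    The global window index is the position in the returned list.
    """
    out: list[GenomicInterval] = []
    for chrom, length in zip(layout.chromosomes, layout.lengths):
        for start in range(0, length, layout.window_size):
            out.append(GenomicInterval(chrom, start, min(start + layout.window_size, length)))
    return out


@dataclass(frozen=True)
class WindowSet:
    """A set of global window indices of a :class:`GenomeLayout`."""

    layout: GenomeLayout
    members: frozenset[int]

    def __post_init__(self) -> None:
        members = frozenset(int(m) for m in self.members)
        n = self.layout.n_windows
        if any(m < 0 or m >= n for m in members):
            raise ValueError("window index outside layout")
        object.__setattr__(self, "members", members)

    def width(self) -> int:
        """Total base pairs covered (truncated terminal tiles use residual width)."""
        widths = self.layout.window_widths()
        return int(widths[sorted(self.members)].sum()) if self.members else 0

    def complement(self) -> "WindowSet":
        return WindowSet(self.layout, frozenset(range(self.layout.n_windows)) - self.members)

    def intervals(self) -> list[GenomicInterval]:
        """Member windows as (merged, sorted) genomic intervals."""
        return merge_intervals(self.layout.window_bounds(i) for i in sorted(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, idx: int) -> bool:
        return idx in self.members


@dataclass(frozen=True)
class PeakSet:
    """ChIP-seq peak intervals from one study (one TF in one cell line).

    Intervals need not be sorted or disjoint on input; they are
    canonicalised (sorted, clipped, merged) on demand by the width
    computations, so replicate peak overlap never double-counts base pairs.
    """

    study_id: str
    tf: str
    cell_line: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))

    @property
    def n_peaks(self) -> int:
        return len(self.intervals)

    def clipped(self, layout: GenomeLayout) -> "PeakSet":
        """Drop or clip intervals to layout bounds."""
        kept = []
        for iv in self.intervals:
            if iv.chrom not in layout.chromosomes:
                continue
            length = layout.chrom_length(iv.chrom)
            if iv.start >= length:
                continue
            if iv.end > length:
                iv = replace(iv, end=length,
                             summit=iv.summit if iv.summit is not None and iv.summit < length else None)
            kept.append(iv)
        return replace(self, intervals=tuple(kept))

    def merged(self) -> list[GenomicInterval]:
        return merge_intervals(self.intervals)

    def total_width(self) -> int:
        return sum(iv.width for iv in self.merged())

    def midpoints(self) -> list[tuple[str, int]]:
        return [(iv.chrom, (iv.start + iv.end) // 2) for iv in self.intervals]


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort intervals and merge overlapping or adjacent ones per chromosome.

    Values and summits are dropped: the result is a plain disjoint cover.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or adjacency
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def _overlap_width(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> int:
    """Total bp of intersection of two *disjoint sorted* interval lists."""
    total = 0
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs_b in by_chrom_b.items():
        ivs_a = [iv for iv in a if iv.chrom == chrom]
        i = j = 0
        while i < len(ivs_a) and j < len(ivs_b):
            lo = max(ivs_a[i].start, ivs_b[j].start)
            hi = min(ivs_a[i].end, ivs_b[j].end)
            if lo < hi:
                total += hi - lo
            if ivs_a[i].end < ivs_b[j].end:
                i += 1
            else:
                j += 1
    return total


def intersect_width(intervals: Iterable[GenomicInterval],
                    windows: WindowSet) -> tuple[int, int]:
    """Base pairs of ``intervals`` inside and outside a window set.

    Intervals are merged first so overlapping replicate peaks never
    double-count; ``inside + outside`` equals the merged total width.
    Returns ``(0, 0)`` for an empty collection.
    """
    merged = merge_intervals(intervals)
    if not merged:
        return 0, 0
    total = sum(iv.width for iv in merged)
    inside = _overlap_width(merged, windows.intervals())
    return inside, total - inside


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, *, study_id: str = "", tf: str = "",
             cell_line: str = "", layout: GenomeLayout | None = None,
             strict: bool = False, summit_offset_column: int | None = None) -> PeakSet:
    """Read a BED3+/narrowPeak file into a :class:`PeakSet`.

    BED is 0-based half-open with at least three columns.  If
    ``summit_offset_column`` is given (1-based column number, 10 for
    narrowPeak), that column is read as the summit offset from the peak
    start; an offset of -1 means "no summit".

    With a ``layout``, out-of-bounds intervals are clipped with a warning,
    or rejected when ``strict`` is true.  Malformed lines raise with their
    line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            summit = None
            if summit_offset_column is not None and len(fields) >= summit_offset_column:
                off = int(fields[summit_offset_column - 1])
                if off >= 0:
                    summit = start + off
            if layout is not None:
                if chrom not in layout.chromosomes:
                    if strict:
                        raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom}")
                    warnings.warn(f"{path}: line {lineno}: unknown chromosome {chrom}, skipped")
                    continue
                length = layout.chrom_length(chrom)
                if end > length or start < 0:
                    if strict:
                        raise ValueError(f"{path}: line {lineno}: interval outside {chrom}")
                    warnings.warn(f"{path}: line {lineno}: clipped to {chrom} bounds")
                    start, end = max(start, 0), min(end, length)
                    if start >= end:
                        continue
                    if summit is not None and not (start <= summit < end):
                        summit = None
            intervals.append(GenomicInterval(chrom, start, end, summit=summit))
    return PeakSet(study_id=study_id, tf=tf, cell_line=cell_line, intervals=tuple(intervals))


def write_bed(peaks: PeakSet, path: str | Path, *, summits: bool = False) -> None:
    """Write a PeakSet as BED3, or with narrowPeak-style summit offsets."""
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            if summits:
                off = -1 if iv.summit is None else iv.summit - iv.start
                name = f"{peaks.tf}_peak"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\t0\t-1\t-1\t{off}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedgraph(path: str | Path) -> list[GenomicInterval]:
    """Read a 4-column bedGraph into valued intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: bedGraph needs 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: malformed bedGraph record") from None
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            out.append(GenomicInterval(fields[0], start, end, value=value))
    return out


def write_bedgraph(track: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in track:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.value:g}\n")


def read_layout(path: str | Path, window_size: int = DEFAULT_WINDOW_SIZE) -> GenomeLayout:
    """Read a two-column (chrom, length) TSV into a GenomeLayout."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return GenomeLayout(tuple(df["chrom"].astype(str)), tuple(df["length"].astype(int)),
                        window_size=window_size)


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in zip(layout.chromosomes, layout.lengths):
            fh.write(f"{chrom}\t{length}\n")


def read_table(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    """Generic TSV matrix: header row of sample ids, first column feature id."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT needs >= 3 columns")
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets
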