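import numpy as np
import pytest

from methcompart import (
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    WindowSet,
)
from methcompart.drivers import PipelineConfig, run_pipeline
from methcompart.synthetic import simulate_scenario


@pytest.fixture
def tiny_layout():
    """One 1-kb chromosome in ten 100-bp windows."""
    return GenomeLayout(("chr1",), (1000,), window_size=100)


@pytest.fixture
def two_chrom_layout():
    return GenomeLayout(("chr1", "chr2"), (300_000, 150_000), window_size=100_000)


@pytest.fixture(scope="session")
def scenario1():
    """Default desk-scale scenario, seed 1 (shared across tests)."""
    return simulate_scenario(1)


@pytest.fixture(scope="session")
def pipeline_result1():
    return run_pipeline(PipelineConfig(simulate=True, seed=1))


def random_intervals(rng, layout, n, max_width=None):
    """Random (possibly overlapping) intervals on a small genome."""
    out = []
    for _ in range(n):
        chrom = rng.choice(layout.chromosomes)
        length = layout.chrom_length(chrom)
        width = int(rng.integers(1, max_width or max(2, length // 3)))
        start = int(rng.integers(0, max(1, length - width)))
        out.append(GenomicInterval(chrom, start, start + width))
    return out


def bp_membership_count(intervals, windows: WindowSet):
    """Brute-force per-base-pair oracle for interval/window overlap.

    Counts each genomic base pair covered by >= 1 interval exactly once,
    split by whether the base pair lies in a member window.
    """
    layout = windows.layout
    member_bp = set()
    for w in windows.members:
        b = layout.window_bounds(w)
        member_bp.update((b.chrom, p) for p in range(b.start, b.end))
    covered = set()
    for iv in intervals:
        covered.update((iv.chrom, p) for p in range(iv.start, iv.end))
    inside = sum(1 for bp in covered if bp in member_bp)
    return inside, len(covered) - inside
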