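import math

import numpy as np
import pytest

from methcompart import (
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    WindowSet,
    adjust_pvalues,
    chi2_peak_test,
    enrichment_correlation,
    fold_enrichment,
    pairwise_jaccard,
    threshold_sweep,
)
from methcompart.tf_enrichment import EnrichmentResult, enrich_studies
from conftest import bp_membership_count, random_intervals


def peak_set(intervals, study="s", tf="TF"):
    return PeakSet(study, tf, "cell", tuple(intervals))


@pytest.fixture
def genome_1kb():
    # 1000-bp genome in 100-bp windows; target = first two windows (200 bp)
    layout = GenomeLayout(("chr1",), (1000,), window_size=100)
    target = WindowSet(layout, frozenset({0, 1}))
    return layout, target


class TestFoldEnrichment:
    def test_balanced_split_gives_width_ratio(self, genome_1kb):
        layout, target = genome_1kb
        peaks = peak_set([GenomicInterval("chr1", 0, 50),
                          GenomicInterval("chr1", 500, 550)])
        # (50/50) / (200/800) = 4
        assert fold_enrichment(peaks, target, layout) == pytest.approx(4.0)

    def test_genome_wide_peak_is_unenriched(self, genome_1kb):
        layout, target = genome_1kb
        peaks = peak_set([GenomicInterval("chr1", 0, 1000)])
        assert fold_enrichment(peaks, target, layout) == pytest.approx(1.0)

    def test_no_overlap_gives_zero(self, genome_1kb):
        layout, target = genome_1kb
        peaks = peak_set([GenomicInterval("chr1", 500, 600)])
        assert fold_enrichment(peaks, target, layout) == 0.0

    def test_fully_contained_gives_infinity(self, genome_1kb):
        layout, target = genome_1kb
        peaks = peak_set([GenomicInterval("chr1", 10, 60)])
        assert fold_enrichment(peaks, target, layout) == math.inf

    def test_empty_peaks_and_empty_target_rejected(self, genome_1kb):
        layout, target = genome_1kb
        with pytest.raises(ValueError):
            fold_enrichment(peak_set([]), target, layout)
        with pytest.raises(ValueError):
            fold_enrichment(peak_set([GenomicInterval("chr1", 0, 10)]),
                            WindowSet(layout, frozenset()), layout)

    def test_matches_per_bp_oracle_on_random_instances(self):
        layout = GenomeLayout(("chrA", "chrB"), (600, 500), window_size=100)
        rng = np.random.default_rng(13)
        for _ in range(100):
            ivs = random_intervals(rng, layout, int(rng.integers(1, 6)))
            k = int(rng.integers(1, layout.n_windows))
            members = frozenset(int(i) for i in
                                rng.choice(layout.n_windows, size=k, replace=False))
            target = WindowSet(layout, members)
            inside, outside = bp_membership_count(ivs, target)
            w_t = target.width()
            w_c = layout.genome_size - w_t
            if w_c == 0:
                continue
            if inside == 0:
                expected = 0.0
            elif outside == 0:
                expected = math.inf
            else:
                expected = (inside / outside) / (w_t / w_c)
            assert fold_enrichment(peak_set(ivs), target, layout) == \
                pytest.approx(expected)

    def test_invariant_under_uniform_coordinate_scaling(self, genome_1kb):
        layout, target = genome_1kb
        peaks = peak_set([GenomicInterval("chr1", 30, 170),
                          GenomicInterval("chr1", 640, 810)])
        f1 = fold_enrichment(peaks, target, layout)
        scale = 7
        layout2 = GenomeLayout(("chr1",), (1000 * scale,), window_size=100 * scale)
        target2 = WindowSet(layout2, target.members)
        peaks2 = peak_set([GenomicInterval("chr1", 30 * scale, 170 * scale),
                           GenomicInterval("chr1", 640 * scale, 810 * scale)])
        assert fold_enrichment(peaks2, target2, layout2) == pytest.approx(f1)

    def test_enrichment_to_target_implies_depletion_from_complement(self):
        layout = GenomeLayout(("chr1",), (1000,), window_size=100)
        rng = np.random.default_rng(14)
        for _ in range(20):
            ivs = random_intervals(rng, layout, 4)
            members = frozenset(int(i) for i in rng.choice(10, size=4, replace=False))
            target = WindowSet(layout, members)
            f_t = fold_enrichment(peak_set(ivs), target, layout)
            f_c = fold_enrichment(peak_set(ivs), target.complement(), layout)
            if math.isfinite(f_t) and f_t > 1:
                assert f_c < 1


class TestChi2:
    def test_derived_example(self, genome_1kb):
        layout, target = genome_1kb
        # 10 peaks, 6 midpoints inside a 20% target: E=(2,8), chi2=10
        ivs = [GenomicInterval("chr1", 10 * i, 10 * i + 4) for i in range(6)] + \
              [GenomicInterval("chr1", 500 + 20 * i, 504 + 20 * i) for i in range(4)]
        chi2, p, obs, exp, unreliable = chi2_peak_test(peak_set(ivs), target, layout)
        assert obs == (6.0, 4.0) and exp == (2.0, 8.0)
        assert chi2 == pytest.approx(10.0)
        assert p == pytest.approx(0.001565, rel=1e-3)

    def test_proportional_observed_gives_null(self, genome_1kb):
        layout, target = genome_1kb
        ivs = [GenomicInterval("chr1", 10, 14), GenomicInterval("chr1", 110, 114)] + \
              [GenomicInterval("chr1", 300 + 50 * i, 304 + 50 * i) for i in range(8)]
        chi2, p, _, _, _ = chi2_peak_test(peak_set(ivs), target, layout)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_all_inside(self, genome_1kb):
        layout, target = genome_1kb
        ivs = [GenomicInterval("chr1", 10 * i, 10 * i + 4) for i in range(10)]
        chi2, _, _, _, _ = chi2_peak_test(peak_set(ivs), target, layout)
        assert chi2 == pytest.approx(40.0)

    def test_small_expected_cell_flagged(self):
        layout = GenomeLayout(("chr1",), (1000,), window_size=100)
        target = WindowSet(layout, frozenset({0}))  # q = 0.1
        ivs = [GenomicInterval("chr1", 500, 504)] * 2
        *_, unreliable = chi2_peak_test(peak_set(ivs), target, layout)
        assert unreliable  # expected inside cell = 0.2 < 1

    def test_width_assignment_variant(self, genome_1kb):
        layout, target = genome_1kb
        ivs = [GenomicInterval("chr1", 150, 250)]  # 50 bp in, 50 bp out
        chi2, _, obs, exp, _ = chi2_peak_test(peak_set(ivs), target, layout,
                                              assignment="width")
        assert obs == (50.0, 50.0)
        assert exp == (20.0, 80.0)


class TestBH:
    def test_hand_computed_step_up(self):
        assert adjust_pvalues([0.01, 0.04, 0.03]) == \
            pytest.approx([0.03, 0.04, 0.04])

    def test_degenerate_and_single(self):
        assert adjust_pvalues([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert adjust_pvalues([0.37]) == pytest.approx([0.37])

    def test_adjusted_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(size=50)
        adj = np.array(adjust_pvalues(list(p)))
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])


class TestJaccard:
    def test_set_arithmetic(self, genome_1kb):
        layout, _ = genome_1kb
        target = WindowSet(layout, frozenset({1, 2, 3}))
        a = peak_set([GenomicInterval("chr1", 110, 120),
                      GenomicInterval("chr1", 210, 220)], study="a")
        b = peak_set([GenomicInterval("chr1", 210, 220),
                      GenomicInterval("chr1", 310, 320)], study="b")
        mat = pairwise_jaccard([a, b], target, layout)
        assert mat.loc["a", "b"] == pytest.approx(1 / 3)
        assert mat.loc["a", "a"] == 1.0

    def test_disjoint_sets_and_empty_sets(self, genome_1kb):
        layout, _ = genome_1kb
        target = WindowSet(layout, frozenset({1, 2}))
        a = peak_set([GenomicInterval("chr1", 110, 120)], study="a")
        b = peak_set([GenomicInterval("chr1", 210, 220)], study="b")
        c = peak_set([GenomicInterval("chr1", 910, 920)], study="c")  # no overlap
        d = peak_set([GenomicInterval("chr1", 930, 940)], study="d")  # no overlap
        mat = pairwise_jaccard([a, b, c, d], target, layout)
        assert mat.loc["a", "b"] == 0.0
        assert mat.loc["c", "d"] == 1.0  # both empty: identical by convention


class TestEnrichmentCorrelation:
    def make_results(self, fs, study_prefix="s"):
        return [EnrichmentResult(f"{study_prefix}{i}", f"tf{i}", f, 0.0, 1.0,
                                 None, 10, 0, 0) for i, f in enumerate(fs)]

    def test_identical_vectors_give_rho_one(self):
        fs = [0.5, 1.2, 2.0, 3.5, 4.0]
        rho, _ = enrichment_correlation(self.make_results(fs), self.make_results(fs))
        assert rho == pytest.approx(1.0)

    def test_reversed_ranking_gives_rho_minus_one(self):
        fs = [0.5, 1.2, 2.0, 3.5, 4.0]
        rho, _ = enrichment_correlation(self.make_results(fs),
                                        self.make_results(fs[::-1]))
        assert rho == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            enrichment_correlation(self.make_results([1.0, 2.0]),
                                   self.make_results([1.0, 2.0]))

    def test_planted_drivers_give_negative_open_closed_correlation(
            self, pipeline_result1):
        rho, _ = enrichment_correlation(pipeline_result1.open_results,
                                        pipeline_result1.closed_results)
        assert rho < 0


class TestThresholdSweep:
    def test_duplicate_settings_correlate_perfectly(self, scenario1,
                                                    pipeline_result1):
        layout = scenario1.truth.layout
        table, corr = threshold_sweep(pipeline_result1.tumour_profile,
                                      pipeline_result1.normal_profile,
                                      scenario1.studies[:8], layout,
                                      thetas=[0.1, 0.1],
                                      include_concordant=False)
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_tso_settings_mutually_more_similar_than_to_bothopen(
            self, scenario1, pipeline_result1):
        layout = scenario1.truth.layout
        table, corr = threshold_sweep(pipeline_result1.tumour_profile,
                                      pipeline_result1.normal_profile,
                                      list(scenario1.studies), layout,
                                      thetas=[0.05, 0.1, 0.2])
        tso_cols = [c for c in corr.columns if c.startswith("tso")]
        both_cols = [c for c in corr.columns if c.startswith("bothopen")]
        within = corr.loc[tso_cols, tso_cols].to_numpy()
        within_mean = within[np.triu_indices_from(within, k=1)].mean()
        across_mean = corr.loc[tso_cols, both_cols].to_numpy().mean()
        assert within_mean > across_mean

    def test_empty_grid_rejected(self, pipeline_result1, scenario1):
        with pytest.raises(ValueError):
            threshold_sweep(pipeline_result1.tumour_profile,
                            pipeline_result1.normal_profile,
                            list(scenario1.studies), scenario1.truth.layout,
                            thetas=[])

    def test_empty_selection_flagged_not_dropped(self, scenario1,
                                                 pipeline_result1):
        layout = scenario1.truth.layout
        table, _ = threshold_sweep(pipeline_result1.tumour_profile,
                                   pipeline_result1.normal_profile,
                                   scenario1.studies[:3], layout,
                                   thetas=[2.0], include_concordant=False)
        assert any(c.endswith("!empty") for c in table.columns)
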