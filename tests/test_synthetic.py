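import numpy as np
import pytest

from methcompart import GenomeLayout, WindowSet
from methcompart.compartments import CALL_OPEN, CALL_CLOSED, bin_methylation
from methcompart.synthetic import (
    default_layout,
    generate_annotation_and_expression,
    generate_methylation,
    generate_peaks,
    generate_tracks,
    generate_truth,
    simulate_scenario,
)


@pytest.fixture(scope="module")
def layout():
    return default_layout()  # 2 chromosomes x 100 windows of 100 kb


class TestTruth:
    def test_zero_flip_fraction_leaves_tumour_identical(self, layout):
        truth = generate_truth(layout, flip_fraction=0.0, seed=3)
        assert truth.tumour_calls == truth.normal_calls
        assert len(truth.tso) == len(truth.tsc) == 0

    def test_flip_fraction_bookkeeping(self, layout):
        truth = generate_truth(layout, flip_fraction=0.05, seed=3)
        flipped = truth.tso.members | truth.tsc.members
        # 5% of 200 windows, up to block-size rounding
        assert abs(len(flipped) - 10) <= 5
        for w in truth.tso.members:
            assert truth.normal_calls[w] == CALL_CLOSED
            assert truth.tumour_calls[w] == CALL_OPEN
        for w in truth.tsc.members:
            assert truth.normal_calls[w] == CALL_OPEN
            assert truth.tumour_calls[w] == CALL_CLOSED

    def test_same_seed_reproduces_truth(self, layout):
        assert generate_truth(layout, seed=11) == generate_truth(layout, seed=11)

    def test_blocks_are_contiguous_and_alternating(self, layout):
        truth = generate_truth(layout, block_length=5, flip_fraction=0.0, seed=0)
        calls = truth.normal_calls[:100]
        for b in range(20):
            block = set(calls[5 * b:5 * (b + 1)])
            assert len(block) == 1
        assert calls[0] == CALL_CLOSED and calls[5] == CALL_OPEN

    def test_flip_fraction_out_of_range(self, layout):
        with pytest.raises(ValueError):
            generate_truth(layout, flip_fraction=0.6)


class TestMethylation:
    def test_noise_free_limit_recovers_compartment_means(self, layout):
        truth = generate_truth(layout, seed=5)
        meth = generate_methylation(truth, "normal", n_samples=3,
                                    probes_per_window=1, tau=0.0, sigma=0.0,
                                    eta=0.0, seed=5)
        binned = bin_methylation(meth, layout)
        for w, call in enumerate(truth.normal_calls):
            expected = 0.35 if call == CALL_OPEN else 0.65
            assert binned.values[w] == pytest.approx(expected, abs=1e-12)

    def test_within_compartment_intraclass_correlation(self, layout):
        # tau=0.5, sigma=0.2 -> expected inter-window correlation within a
        # compartment = tau^2/(tau^2+sigma^2) = 0.25/0.29 ~ 0.862
        truth = generate_truth(layout, flip_fraction=0.0, seed=5)
        meth = generate_methylation(truth, "normal", n_samples=100, tau=0.5,
                                    sigma=0.2, eta=0.0, seed=5)
        binned = bin_methylation(meth, layout)
        # undo the beta-scale squash: correlation is defined on the logit scale
        from scipy.special import logit
        x = logit(np.clip(binned.values, 1e-6, 1 - 1e-6))
        closed = [w for w, c in enumerate(truth.normal_calls) if c == CALL_CLOSED]
        corr = np.corrcoef(x[closed])
        off_diag = corr[np.triu_indices_from(corr, k=1)]
        # Monte-Carlo tolerance: ~3 standard errors at n=100 samples
        assert off_diag.mean() == pytest.approx(0.25 / 0.29, abs=0.04)

    def test_cross_compartment_factors_anticorrelate_after_sample_centering(self, layout):
        # raw compartment factors are independent; once each sample's global
        # level is removed (as the inference does) the compartments become
        # mirror contrasts of each other
        truth = generate_truth(layout, flip_fraction=0.0, seed=5)
        meth = generate_methylation(truth, "normal", n_samples=100, tau=0.5,
                                    sigma=0.2, eta=0.0, seed=5)
        binned = bin_methylation(meth, layout)
        from scipy.special import logit
        x = logit(np.clip(binned.values, 1e-6, 1 - 1e-6))
        open_w = [w for w, c in enumerate(truth.normal_calls) if c == CALL_OPEN]
        closed_w = [w for w, c in enumerate(truth.normal_calls) if c == CALL_CLOSED]
        raw_cross = np.corrcoef(x)[np.ix_(open_w, closed_w)]
        # the mean cross correlation tracks the sampled correlation of the
        # two latent factors, whose sd at n=100 samples is ~1/sqrt(100);
        # 3 Monte-Carlo standard errors of that shared draw
        assert abs(raw_cross.mean()) < 0.3
        centred = x - x.mean(axis=0, keepdims=True)
        cross = np.corrcoef(centred)[np.ix_(open_w, closed_w)]
        assert cross.mean() < -0.5

    def test_same_seed_identical_matrix(self, layout):
        truth = generate_truth(layout, seed=5)
        a = generate_methylation(truth, "tumour", n_samples=5, seed=9)
        b = generate_methylation(truth, "tumour", n_samples=5, seed=9)
        assert np.array_equal(a.betas, b.betas)
        assert a.positions == b.positions

    def test_probe_positions_shared_between_cohorts(self, layout):
        truth = generate_truth(layout, seed=5)
        t = generate_methylation(truth, "tumour", n_samples=3, seed=1)
        n = generate_methylation(truth, "normal", n_samples=3, seed=2)
        assert t.positions == n.positions and t.probe_ids == n.probe_ids


class TestPeaks:
    def test_uniform_sampling_at_rho_one(self, layout):
        truth = generate_truth(layout, seed=5)
        target = WindowSet(layout, frozenset(range(40)))  # 20% of genome
        peaks = generate_peaks(truth, "tfx", 2000, 500, target, 1.0, seed=5)
        frac = np.mean([layout.window_index(c, m) in target
                        for c, m in peaks.midpoints()])
        assert frac == pytest.approx(0.2, abs=0.03)

    def test_extreme_rho_puts_all_midpoints_in_target(self, layout):
        truth = generate_truth(layout, seed=5)
        target = WindowSet(layout, frozenset(range(40)))
        peaks = generate_peaks(truth, "tfx", 500, 500, target, 1e9, seed=5)
        assert all(layout.window_index(c, m) in target
                   for c, m in peaks.midpoints())

    def test_weighted_sampling_expectation(self, layout):
        # rho=4 on 20% of the genome: expected midpoint fraction
        # 4*0.2/(4*0.2+0.8) = 0.5, within binomial error at n=2000
        truth = generate_truth(layout, seed=5)
        target = WindowSet(layout, frozenset(range(40)))
        peaks = generate_peaks(truth, "tfx", 2000, 500, target, 4.0, seed=5)
        frac = np.mean([layout.window_index(c, m) in target
                        for c, m in peaks.midpoints()])
        assert frac == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 2000))

    def test_invalid_parameters(self, layout):
        truth = generate_truth(layout, seed=5)
        target = WindowSet(layout, frozenset({0}))
        with pytest.raises(ValueError):
            generate_peaks(truth, "tfx", 0, 500, target, 1.0)
        with pytest.raises(ValueError):
            generate_peaks(truth, "tfx", 10, 200_000, target, 1.0)


class TestAnnotationAndExpression:
    def test_null_deltas_centre_t_statistics_at_zero(self, layout):
        from methcompart.expression import moderated_t
        truth = generate_truth(layout, n_activators=0, n_repressors=0,
                               n_genes=500, seed=5)
        _, expr = generate_annotation_and_expression(truth, n_tumour=20,
                                                     n_normal=20, seed=5)
        t = moderated_t(expr).table["t"]
        assert abs(t.mean()) < 0.1
        assert np.mean(np.abs(t) > 2) < 0.1

    def test_planted_shift_matches_two_sample_t_expectation(self, layout):
        # delta=2, sigma_e=1, n=50/50 -> E[t] ~ 2/sqrt(2/50) = 10
        truth = generate_truth(layout, n_genes=500, seed=5)
        _, expr = generate_annotation_and_expression(truth, n_tumour=50,
                                                     n_normal=50, seed=5)
        from methcompart.expression import moderated_t
        t = moderated_t(expr).table["t"]
        up_targets = set()
        for spec in truth.drivers:
            if spec.direction == "activator":
                up_targets |= truth.targets[spec.tf]
        observed = t.loc[sorted(up_targets)].mean()
        assert observed == pytest.approx(10.0, abs=1.5)

    def test_driver_targets_placed_in_flipped_windows(self, layout):
        truth = generate_truth(layout, n_genes=500, seed=5)
        ann, _ = generate_annotation_and_expression(truth, seed=5)
        frame = ann.to_frame()
        for spec in truth.drivers:
            windows = truth.tso if spec.direction == "activator" else truth.tsc
            for gid in truth.targets[spec.tf]:
                row = frame.loc[gid]
                assert layout.window_index(row["chrom"], row["tss"]) in windows

    def test_same_seed_identical_outputs(self, layout):
        truth = generate_truth(layout, n_genes=200, seed=5)
        a = generate_annotation_and_expression(truth, seed=4)
        b = generate_annotation_and_expression(truth, seed=4)
        assert a[0] == b[0]
        assert a[1].values.equals(b[1].values)


class TestTracks:
    def test_zero_closed_mean_and_zero_noise_gives_zero_closed_signal(self, layout):
        from methcompart.validation import window_signal_sum
        truth = generate_truth(layout, seed=5)
        track, _, _ = generate_tracks(truth, open_mean=10.0, closed_mean=0.0,
                                      signal_sd=0.0, seed=5)
        sums = window_signal_sum(track, layout)
        closed = [w for w, c in enumerate(truth.tumour_calls) if c == CALL_CLOSED]
        assert np.all(sums.values[closed] == 0)

    def test_open_windows_have_higher_median_signal(self, layout):
        from methcompart.validation import window_signal_sum
        truth = generate_truth(layout, seed=5)
        track, _, _ = generate_tracks(truth, seed=5)
        sums = window_signal_sum(track, layout)
        open_w = [w for w, c in enumerate(truth.tumour_calls) if c == CALL_OPEN]
        closed = [w for w, c in enumerate(truth.tumour_calls) if c == CALL_CLOSED]
        assert np.median(sums.values[open_w]) > np.median(sums.values[closed])

    def test_summits_enriched_in_closed_windows(self, layout):
        from methcompart.validation import window_summit_overlap
        truth = generate_truth(layout, seed=5)
        _, _, repressive = generate_tracks(truth, seed=5)
        flags = window_summit_overlap(repressive, layout)
        open_w = [w for w, c in enumerate(truth.tumour_calls) if c == CALL_OPEN]
        closed = [w for w, c in enumerate(truth.tumour_calls) if c == CALL_CLOSED]
        assert flags.values[closed].mean() > flags.values[open_w].mean()


def test_scenario_is_pure_function_of_seed():
    a, b = simulate_scenario(3), simulate_scenario(3)
    assert a.truth == b.truth
    assert np.array_equal(a.meth_tumour.betas, b.meth_tumour.betas)
    assert a.studies[0].intervals == b.studies[0].intervals
    assert a.expression.values.equals(b.expression.values)
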