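"""Decay fitting: peak finding, tail/reconvolution fits, χ², τ_m arithmetic."""

import numpy as np
import pytest

from flimfret import (
    DecayGroundTruth,
    DecayHistogram,
    FitConfig,
    IrfModel,
    amplitude_weighted_mean_lifetime,
    expected_decay,
    find_peak,
    reconvolution_fit,
    reduced_chi_squared,
    simulate_decay_histogram,
    tail_fit,
)

from .oracles import grid_search_biexp, profiled_deviance, tail_window


def _hist(counts, dt=50.0 / 1024.0):
    counts = np.asarray(counts)
    if counts.size < 16:
        counts = np.concatenate([counts, np.zeros(16 - counts.size)])
    return DecayHistogram(counts=counts, channel_width=dt)


class TestFindPeak:
    def test_maximum_channel(self):
        assert find_peak(_hist([0, 1, 5, 3, 1])) == 2

    def test_tie_broken_by_earliest(self):
        assert find_peak(_hist([0, 4, 4, 1])) == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            find_peak(_hist(np.zeros(32)))

    def test_simulated_peak_near_irf_center(self, acq):
        irf = IrfModel(center=2.0, fwhm=0.1)
        truth = DecayGroundTruth(components=((1.0, 2.44),))
        h = simulate_decay_histogram(truth, irf, 1e6, acq, seed=4)
        center_channel = int(2.0 / acq.channel_width)
        # the convolved decay peaks slightly after the IRF center (EMG mode)
        assert 0 <= find_peak(h) - center_channel <= 4


class TestAmplitudeWeightedMean:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((1.0, 2.44, 0.0, 1.0), 2.44),
            ((0.5, 1.0, 0.5, 3.0), 2.0),
            ((0.3, 1.2, 0.7, 2.8), 2.32),
        ],
    )
    def test_arithmetic(self, args, expected):
        assert amplitude_weighted_mean_lifetime(*args) == pytest.approx(expected)

    def test_unnormalized_amplitudes_rejected_not_renormalized(self):
        with pytest.raises(ValueError, match="sum to 1"):
            amplitude_weighted_mean_lifetime(0.6, 1.0, 0.6, 3.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            amplitude_weighted_mean_lifetime(-0.1, 1.0, 1.1, 3.0)


class TestReducedChiSquared:
    def test_perfect_model_is_zero(self):
        y = np.arange(10.0) + 1
        assert reduced_chi_squared(y, y, 2) == 0.0

    def test_correct_model_near_one(self, rng):
        # Poisson data around the true model: χ²ν concentrates near 1
        model = np.full(1000, 100.0)
        obs = rng.poisson(model)
        assert 0.9 <= reduced_chi_squared(obs, model, 4) <= 1.1

    def test_gross_misfit_far_above_threshold(self, rng):
        model = np.full(600, 50.0)
        obs = rng.poisson(2 * model)
        assert reduced_chi_squared(obs, model, 4) > 10

    def test_nonpositive_dof_rejected(self):
        with pytest.raises(ValueError):
            reduced_chi_squared(np.ones(4), np.ones(4), 4)


class TestTailFit:
    def test_noise_free_monoexponential_is_exact(self, acq):
        tau = 2.5
        t = np.arange(acq.n_channels) * acq.channel_width
        counts = 5e4 * acq.channel_width / tau * np.exp(-t / tau)
        res = tail_fit(_hist(counts, acq.channel_width), FitConfig(model_order=1))
        assert res.converged
        assert res.tau_mean == pytest.approx(tau, abs=1e-6)
        assert res.chi2_reduced < 1e-10

    def test_biexponential_recovery_matches_grid_oracle(self, acq):
        # equal pre-exponential amplitudes at τ = 1 and 3 ns correspond to
        # photon fractions 0.25 / 0.75
        truth = DecayGroundTruth(components=((0.25, 1.0), (0.75, 3.0)))
        irf = IrfModel(center=2.0, fwhm=0.05)
        h = simulate_decay_histogram(truth, irf, 1e6, acq, seed=8)
        res = tail_fit(h)
        assert res.converged
        assert res.chi2_reduced < 1.1
        assert res.tau_fast == pytest.approx(1.0, rel=0.05)
        assert res.tau_slow == pytest.approx(3.0, rel=0.05)

        t, y, _ = tail_window(h.counts, acq.channel_width)
        grid_obj, grid_tf, grid_ts, _ = grid_search_biexp(
            t, y, np.arange(0.90, 1.101, 0.01), np.arange(2.80, 3.201, 0.01)
        )
        assert res.tau_fast == pytest.approx(grid_tf, abs=0.011)
        assert res.tau_slow == pytest.approx(grid_ts, abs=0.011)
        fit_obj = profiled_deviance(t, y, res.tau_fast, res.tau_slow, res.a_fast)
        assert fit_obj <= grid_obj * (1 + 1e-6)

    def test_optimizer_beats_coarse_grid_on_noise_free_data(self, small_acq):
        truth = DecayGroundTruth(components=((0.4, 0.8), (0.6, 2.6)))
        irf = IrfModel(center=2.0, fwhm=0.05)
        y_clean = expected_decay(truth, irf, 2e5, small_acq)
        h = _hist(y_clean, small_acq.channel_width)
        res = tail_fit(h)
        t, y, _ = tail_window(h.counts, small_acq.channel_width)
        grid_obj, *_ = grid_search_biexp(
            t, y, np.arange(0.2, 3.01, 0.1), np.arange(0.2, 4.01, 0.1)
        )
        fit_obj = profiled_deviance(t, y, res.tau_fast, res.tau_slow, res.a_fast)
        # noise-free: both objectives are ~0; compare with an absolute floor
        assert fit_obj <= grid_obj + 1e-6

    def test_monoexponential_data_biexponential_model_keeps_tau_mean(self, acq, irf):
        # components are unidentifiable but τ_m must survive
        truth = DecayGroundTruth(components=((1.0, 2.44),))
        h = simulate_decay_histogram(truth, irf, 1e6, acq, seed=12)
        res = tail_fit(h, FitConfig(model_order=2))
        assert res.tau_mean == pytest.approx(2.44, rel=0.01)

    def test_insufficient_photons_flagged_not_raised(self, acq, irf):
        truth = DecayGroundTruth(components=((1.0, 2.44),))
        h = simulate_decay_histogram(truth, irf, 100, acq, seed=1)
        res = tail_fit(h, FitConfig(min_photons=400))
        assert not res.converged
        assert np.isnan(res.tau_mean)

    def test_amplitudes_normalized_and_components_ordered(self, acq, irf, rng):
        truth = DecayGroundTruth(components=((0.4, 1.2), (0.6, 2.8)))
        for _ in range(5):
            h = simulate_decay_histogram(truth, irf, 3e4, acq, seed=rng)
            res = tail_fit(h)
            assert res.a_fast + res.a_slow == 1.0
            assert res.tau_fast <= res.tau_slow
            assert res.tau_fast <= res.tau_mean <= res.tau_slow

    def test_precision_scales_with_photon_count(self, acq, irf, rng):
        # SD of recovered τ_m must fall as counts rise 10³ -> 10⁴ -> 10⁵
        truth = DecayGroundTruth(components=((1.0, 2.44),))
        sds = []
        for n in (1e3, 1e4, 1e5):
            taus = [
                tail_fit(
                    simulate_decay_histogram(truth, irf, n, acq, seed=rng),
                    FitConfig(min_photons=200),
                ).tau_mean
                for _ in range(40)
            ]
            sds.append(np.std(taus))
        assert sds[0] > sds[1] > sds[2]


class TestReconvolutionFit:
    def test_delta_irf_agrees_with_tail_fit(self, acq):
        irf = IrfModel(center=2.0, fwhm=2e-7)
        truth = DecayGroundTruth(components=((1.0, 2.44),))
        h = simulate_decay_histogram(truth, irf, 3e5, acq, seed=3)
        res_tail = tail_fit(h)
        res_recv = reconvolution_fit(h, irf, repetition_period=acq.repetition_period)
        assert res_recv.tau_mean == pytest.approx(res_tail.tau_mean, rel=0.02)

    def test_recovers_donor_lifetime_through_wide_irf(self, acq):
        irf = IrfModel(center=2.0, fwhm=0.3)
        truth = DecayGroundTruth(components=((1.0, 2.44),))
        h = simulate_decay_histogram(truth, irf, 1e6, acq, seed=5)
        res = reconvolution_fit(h, irf, repetition_period=acq.repetition_period)
        assert res.converged
        assert res.tau_mean == pytest.approx(2.44, rel=0.02)

    def test_mismatched_irf_degrades_fit(self, acq):
        irf_true = IrfModel(center=2.0, fwhm=0.3)
        truth = DecayGroundTruth(components=((1.0, 2.44),))
        h = simulate_decay_histogram(truth, irf_true, 1e6, acq, seed=6)
        good = reconvolution_fit(h, irf_true, repetition_period=acq.repetition_period)
        bad = reconvolution_fit(
            h, IrfModel(center=2.0, fwhm=0.6), repetition_period=acq.repetition_period
        )
        assert bad.chi2_reduced > good.chi2_reduced
        assert bad.chi2_reduced > tail_fit(h).chi2_reduced
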