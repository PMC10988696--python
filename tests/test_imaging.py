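"""Lifetime images: binning, ROI aggregation, per-pixel fits, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flimfret import (
    AcquisitionConfig,
    CellPhantom,
    DecayGroundTruth,
    FitConfig,
    LifetimeImage,
    PixelHistogramStack,
    aggregate_roi_decay,
    bin_pixels,
    fit_lifetime_image,
    render_lifetime_map,
    simulate_flim_image,
    tail_fit,
)
from flimfret.imaging import LIFETIME_COLORMAP


def _random_stack(rng, shape=(4, 4), n_channels=64):
    acq = AcquisitionConfig(
        n_channels=n_channels, channel_width=50.0 / n_channels,
        image_shape=shape, seed=0,
    )
    counts = rng.integers(0, 50, size=(*shape, n_channels)).astype(np.uint32)
    return PixelHistogramStack(counts=counts, acquisition=acq)


def _uniform_phantom(shape, tau, photons, label="cell", bg=0.005):
    truth = DecayGroundTruth(components=((1.0, tau),), background_fraction=bg)
    return CellPhantom(
        label=label, mask=np.ones(shape, dtype=bool),
        photons_per_pixel=photons, truth=truth,
    )


class TestBinPixels:
    def test_photons_conserved_and_shape_halved(self, rng):
        stack = _random_stack(rng, shape=(4, 4))
        binned = bin_pixels(stack, 2)
        assert binned.shape == (2, 2)
        assert binned.total_counts == stack.total_counts
        # each output histogram is the channel-wise sum of its 2x2 block
        expect = stack.counts[:2, :2].sum(axis=(0, 1))
        assert np.array_equal(binned.counts[0, 0], expect)

    def test_factor_one_is_identity(self, rng):
        stack = _random_stack(rng)
        assert bin_pixels(stack, 1) is stack

    def test_odd_edges_keep_partial_blocks(self, rng):
        stack = _random_stack(rng, shape=(5, 5))
        binned = bin_pixels(stack, 2)
        assert binned.shape == (3, 3)
        assert binned.total_counts == stack.total_counts
        assert np.array_equal(binned.counts[2, 2], stack.counts[4, 4])

    @given(
        rows=st.integers(1, 7), cols=st.integers(1, 7), factor=st.integers(1, 4),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_conservation_property(self, rows, cols, factor, seed):
        rng = np.random.default_rng(seed)
        stack = _random_stack(rng, shape=(rows, cols), n_channels=32)
        binned = bin_pixels(stack, factor)
        assert binned.total_counts == stack.total_counts
        assert binned.shape == (-(-rows // factor), -(-cols // factor))

    def test_invalid_factor_rejected(self, rng):
        with pytest.raises(ValueError):
            bin_pixels(_random_stack(rng), 0)


class TestAggregateRoi:
    def test_whole_image_mask_equals_full_sum(self, rng):
        stack = _random_stack(rng)
        roi = aggregate_roi_decay(stack, np.ones((4, 4), dtype=bool))
        assert np.array_equal(roi.counts, stack.counts.sum(axis=(0, 1)))

    def test_disjoint_masks_are_additive(self, rng):
        stack = _random_stack(rng)
        a = np.zeros((4, 4), dtype=bool); a[:2] = True
        b = np.zeros((4, 4), dtype=bool); b[2:] = True
        ra = aggregate_roi_decay(stack, a).counts
        rb = aggregate_roi_decay(stack, b).counts
        rab = aggregate_roi_decay(stack, a | b).counts
        assert np.array_equal(rab, ra + rb)

    def test_single_pixel_mask_returns_that_histogram(self, rng):
        stack = _random_stack(rng)
        m = np.zeros((4, 4), dtype=bool); m[1, 3] = True
        roi = aggregate_roi_decay(stack, m)
        assert np.array_equal(roi.counts, stack.counts[1, 3])

    def test_empty_or_misshapen_mask_rejected(self, rng):
        stack = _random_stack(rng)
        with pytest.raises(ValueError, match="empty"):
            aggregate_roi_decay(stack, np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError, match="shape"):
            aggregate_roi_decay(stack, np.ones((3, 3), dtype=bool))


class TestFitLifetimeImage:
    def test_uniform_phantom_recovers_lifetime(self, irf):
        acq = AcquisitionConfig(image_shape=(4, 4), seed=7)
        ph = _uniform_phantom((4, 4), 2.44, 4e3)
        stack = simulate_flim_image([ph], irf, acq)
        img = fit_lifetime_image(stack, FitConfig(min_photons=400))
        assert img.valid.all()
        assert np.nanmean(img.tau_mean) == pytest.approx(2.44, abs=0.05)

    def test_background_only_region_fully_masked(self, irf):
        acq = AcquisitionConfig(image_shape=(3, 3), seed=1)
        stack = simulate_flim_image([], irf, acq, background_photons_per_pixel=50.0)
        img = fit_lifetime_image(stack, FitConfig(min_photons=400))
        assert not img.valid.any()
        assert np.isnan(img.tau_mean).all()

    def test_two_phantoms_resolved_as_separate_plateaus(self, irf):
        acq = AcquisitionConfig(image_shape=(4, 8), seed=5)
        donor = np.zeros((4, 8), dtype=bool); donor[:, :4] = True
        fusion = np.zeros((4, 8), dtype=bool); fusion[:, 4:] = True
        phs = [
            CellPhantom(label="donor", mask=donor, photons_per_pixel=4e3,
                        truth=DecayGroundTruth(components=((1.0, 2.44),),
                                               background_fraction=0.005)),
            CellPhantom(label="fusion", mask=fusion, photons_per_pixel=4e3,
                        truth=DecayGroundTruth(components=((1.0, 1.84),),
                                               background_fraction=0.005)),
        ]
        stack = simulate_flim_image(phs, irf, acq)
        img = fit_lifetime_image(stack, FitConfig(min_photons=400))
        td, tf = img.tau_mean[:, :4].ravel(), img.tau_mean[:, 4:].ravel()
        pooled_sd = np.sqrt((td.std() ** 2 + tf.std() ** 2) / 2)
        assert (td.mean() - tf.mean()) > 5 * pooled_sd

    def test_roi_fit_matches_mean_of_pixel_fits(self, irf):
        acq = AcquisitionConfig(image_shape=(3, 3), seed=9)
        ph = _uniform_phantom((3, 3), 2.2, 5e3)
        stack = simulate_flim_image([ph], irf, acq)
        img = fit_lifetime_image(stack, FitConfig(min_photons=400))
        roi_tau = tail_fit(aggregate_roi_decay(stack, ph.mask)).tau_mean
        assert roi_tau == pytest.approx(np.nanmean(img.tau_mean), rel=0.02)


class TestRenderLifetimeMap:
    def _image(self, taus):
        taus = np.asarray(taus, dtype=float)
        valid = np.isfinite(taus)
        return LifetimeImage(tau_mean=taus, chi2=np.zeros_like(taus), valid=valid)

    def test_scale_endpoints_are_pure_blue_and_red(self):
        rgb = render_lifetime_map(self._image([[1.70, 2.60]]))
        assert tuple(rgb[0, 0]) == (0, 0, 255)
        assert tuple(rgb[0, 1]) == (255, 0, 0)

    def test_out_of_range_lifetimes_clamp_to_endpoints(self):
        rgb = render_lifetime_map(self._image([[0.5, 5.0]]))
        assert tuple(rgb[0, 0]) == (0, 0, 255)
        assert tuple(rgb[0, 1]) == (255, 0, 0)

    def test_midpoint_maps_to_colormap_center(self):
        # 2.15 ns sits exactly halfway on the 1.70-2.60 scale: the pure
        # green centre of the blue-to-red colormap (within one LUT step)
        rgb = render_lifetime_map(self._image([[2.15]]))
        expected = np.asarray(LIFETIME_COLORMAP(0.5, bytes=True)[:3], dtype=int)
        assert np.abs(rgb[0, 0].astype(int) - expected).max() <= 2
        assert rgb[0, 0][1] == 255

    def test_invalid_pixels_are_black_and_rendering_is_pure(self):
        img = self._image([[2.0, float("nan")]])
        r1 = render_lifetime_map(img)
        r2 = render_lifetime_map(img)
        assert tuple(r1[0, 1]) == (0, 0, 0)
        assert r1.tobytes() == r2.tobytes()

    def test_inverted_scale_rejected(self):
        with pytest.raises(ValueError):
            render_lifetime_map(self._image([[2.0]]), t_min=2.6, t_max=1.7)
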