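"""Generator tests: footprints, spike trains, AP kernel, movie rendering."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import optimize

from voltpipe.movie import compute_dff
from voltpipe.simulate import (
    GroundTruth,
    SimConfig,
    ap_kernel_value,
    count_overlapping_pairs,
    make_footprints,
    preset,
    render_ap_kernel,
    render_dff,
    render_movie,
    simulate_cohort,
    simulate_fov,
    simulate_spike_train,
)
from voltpipe.events import detect_bursts
from voltpipe.waveforms import compute_fwhm

from conftest import small_config


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------


class TestFootprints:
    def test_single_neuron_has_nonempty_mask(self):
        gt = make_footprints(1, (64, 64), 0.0, seed=1)
        assert gt.n_neurons == 1
        assert gt.masks[0].sum() > 0

    def test_disjoint_when_overlap_zero(self):
        gt = make_footprints(2, (64, 64), 0.0, seed=1)
        assert not np.any(gt.masks[0] & gt.masks[1])

    def test_twelve_neurons_fit_standard_fov(self):
        # a full field of view holds a dozen somas
        gt = make_footprints(12, (150, 200), 0.0, seed=0)
        assert gt.n_neurons == 12
        assert all(gt.masks[i].any() for i in range(12))
        assert count_overlapping_pairs(gt.masks) == 0

    def test_requested_overlap_produces_overlapping_pairs(self):
        gt = make_footprints(6, (100, 100), overlap_fraction=0.2, seed=3)
        target = round(0.2 * 6 * 5 / 2)
        assert count_overlapping_pairs(gt.masks) >= target

    def test_deterministic_given_seed(self):
        a = make_footprints(5, (80, 80), 0.0, seed=9)
        b = make_footprints(5, (80, 80), 0.0, seed=9)
        np.testing.assert_array_equal(a.footprints, b.footprints)

    def test_overcrowded_fov_raises_density_error(self):
        with pytest.raises(RuntimeError, match="dense"):
            make_footprints(40, (40, 40), 0.0, seed=0, max_tries=50)

    def test_footprints_nonnegative_and_smooth_peak(self):
        gt = make_footprints(3, (64, 64), 0.0, seed=2)
        assert gt.footprints.min() >= 0
        assert np.allclose(gt.footprints.max(axis=(1, 2)), 1.0, atol=0.01)


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------


class TestSpikeTrains:
    def test_zero_rate_gives_empty_train(self):
        assert simulate_spike_train(0.0, "poisson", 180.0, seed=0).size == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_spike_train(-1.0, "poisson", 10.0)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            simulate_spike_train(1.0, "ratchet", 10.0)

    def test_thinned_poisson_rate_matches_dead_time_formula(self):
        # absolute refractory period τ thins a Poisson process of rate λ
        # to an output rate λ/(1 + λτ)
        lam, tau, dur = 1.0, 0.005, 10_000.0
        st = simulate_spike_train(lam, "poisson", dur, refractory_ms=5.0, seed=7)
        expected = lam / (1.0 + lam * tau)
        se = math.sqrt(expected * dur) / dur
        assert abs(st.size / dur - expected) < 3 * se

    def test_strictly_increasing_within_duration(self):
        st = simulate_spike_train(5.0, "poisson", 60.0, refractory_ms=5.0, seed=3)
        assert np.all(np.diff(st) > 0)
        assert st[0] >= 0 and st[-1] < 60.0

    def test_refractory_enforced(self):
        st = simulate_spike_train(50.0, "poisson", 30.0, refractory_ms=10.0, seed=1)
        assert np.all(np.diff(st) >= 0.010 - 1e-12)

    def test_burst_pattern_recovered_by_burst_detector(self):
        # noiseless ground truth: the classifier should see ~ the
        # configured number of burst onsets (6/min over 10 min)
        onset_rate = 6.0 / 60.0
        st = simulate_spike_train(
            2.0, "bursting", 600.0, refractory_ms=5.0, seed=5,
            burst_onset_rate=onset_rate, burst_fraction=1.0,
        )
        n_bursts = len(detect_bursts(st))
        expected = onset_rate * 600.0
        assert abs(n_bursts - expected) < 4 * math.sqrt(expected)

    def test_synchronized_pattern_shares_onsets(self):
        onsets = np.array([1.0, 5.0, 9.0])
        rngs = [np.random.default_rng(i) for i in range(2)]
        trains = [
            simulate_spike_train(
                1.0, "synchronized-bursting", 12.0, rng=r,
                burst_onsets=onsets, participation=1.0,
            )
            for r in rngs
        ]
        for tr in trains:
            for onset in onsets:
                assert np.any(np.abs(tr - onset) < 1e-9)


# ---------------------------------------------------------------------------
# AP kernel
# ---------------------------------------------------------------------------


class TestAPKernel:
    def test_peak_amplitude_and_fwhm_definitional(self):
        t_ms, k = render_ap_kernel(10.0, 10.0, 500.0)
        assert k.max() == pytest.approx(10.0)
        # continuous-time FWHM via dense resampling
        dense_t = np.arange(-50, 200, 0.01)
        dense = ap_kernel_value(dense_t, 10.0, 10.0)
        above = dense_t[dense >= 5.0]
        assert (above[-1] - above[0]) == pytest.approx(10.0, abs=0.1)

    def test_gaussian_kernel_closed_form_fwhm(self):
        sigma = 5.0
        fwhm = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma  # 11.77 ms
        dense_t = np.arange(-40, 40, 0.01)
        dense = ap_kernel_value(dense_t, fwhm, 10.0, shape="gaussian")
        above = dense_t[dense >= 5.0]
        assert (above[-1] - above[0]) == pytest.approx(11.77, abs=0.05)

    def test_rendered_spike_fwhm_measured_by_analyzer(self):
        # a noiseless rendered AP measured by the waveform analyzer
        # returns the configured width up to interpolation error
        tt = (np.arange(151) - 75) * 2.0  # 300 ms window at 500 Hz
        seg = ap_kernel_value(tt, 14.8, 10.0)
        measured = compute_fwhm(seg, 500.0)
        assert measured == pytest.approx(14.8, rel=0.02)

    def test_rise_fraction_quarter_of_fwhm(self):
        dense_t = np.arange(-50.0, 200.0, 0.005)
        dense = ap_kernel_value(dense_t, 20.0, 10.0)
        above = dense_t[dense >= 5.0]
        left, right = above[0], above[-1]
        peak_t = dense_t[np.argmax(dense)]
        assert (peak_t - left) / (right - left) == pytest.approx(0.25, abs=0.01)

    def test_undersampled_fwhm_warns(self):
        with pytest.warns(UserWarning, match="frame period"):
            render_ap_kernel(1.0, 10.0, 500.0)

    def test_invalid_fwhm_rejected(self):
        with pytest.raises(ValueError):
            render_ap_kernel(0.0, 10.0, 500.0)


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------


def _empty_ground_truth(h, w):
    return GroundTruth(
        footprints=np.zeros((0, h, w), dtype=np.float32),
        masks=np.zeros((0, h, w), dtype=bool),
        centers=np.zeros((0, 2)),
        radii=np.zeros(0),
        spike_times=[],
        plateau_intervals=[],
        kernel_params=[],
        dff_traces=[],
    )


class TestRenderMovie:
    def test_no_neurons_no_noise_gives_flat_background(self):
        cfg = small_config(n_neurons=0, shot_noise=False, background_counts=120.0)
        gt = _empty_ground_truth(*cfg.fov_shape)
        gt.config = cfg
        movie = render_movie(gt, cfg)
        assert np.all(movie.frames == 120)

    def test_single_spike_trace_inverts_to_kernel(self):
        # analytic inversion of the rendering equation: with no noise, no
        # background and no bleaching, ΔF/F₀ over the exact mask equals
        # the generating trace up to 16-bit quantization
        cfg = small_config(
            n_neurons=1, shot_noise=False, background_counts=0.0, duration=20.0,
            seed=4,
        )
        gt = make_footprints(1, cfg.fov_shape, 0.0, cfg.seed, cfg.soma_radius_px)
        t = np.arange(int(cfg.duration * cfg.frame_rate)) / cfg.frame_rate
        dff = ap_kernel_value((t - 10.0) * 1000.0, 14.8, 10.0)
        gt.spike_times = [np.array([10.0])]
        gt.plateau_intervals = [[]]
        gt.kernel_params = [(14.8, 10.0)]
        gt.dff_traces = [dff]
        gt.firing_rates = np.array([0.05])
        movie = render_movie(gt, cfg)
        mask = gt.masks[0]
        raw = movie.frames[:, mask].mean(axis=1)
        rec = compute_dff(raw, cfg.frame_rate, baseline_method="global_percentile")
        assert np.max(np.abs(rec.values - dff)) < 0.2  # percent ΔF/F₀

    def test_bleach_time_constant_recovered_by_exponential_fit(self):
        cfg = small_config(
            n_neurons=1, firing_rate=0.0, shot_noise=False, bleach_tau=60.0,
            duration=60.0,
        )
        movie, gt = simulate_fov(cfg)
        y = movie.frames.mean(axis=(1, 2)).astype(float)
        t = movie.times
        popt, _ = optimize.curve_fit(
            lambda t, a, tau, c: a * np.exp(-t / tau) + c, t, y,
            p0=(y[0] - y[-1], 30.0, y[-1]),
        )
        assert popt[1] == pytest.approx(60.0, abs=5.0)

    def test_overflow_error_suggests_lower_baseline(self):
        cfg = small_config(baseline_counts=80_000.0, shot_noise=False)
        with pytest.raises(ValueError, match="baseline"):
            simulate_fov(cfg)

    def test_bit_identical_given_seed(self):
        cfg = small_config(seed=8, duration=5.0)
        a, _ = simulate_fov(cfg)
        b, _ = simulate_fov(cfg)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_adding_neuron_preserves_existing_spike_trains(self):
        # per-neuron seed streams: neuron k's spikes do not depend on how
        # many neurons come after it
        cfg3 = small_config(n_neurons=3, seed=6, duration=10.0)
        cfg4 = small_config(n_neurons=4, seed=6, duration=10.0)
        gt3 = render_dff(
            make_footprints(3, cfg3.fov_shape, 0.0, 6, cfg3.soma_radius_px), cfg3
        )
        gt4 = render_dff(
            make_footprints(4, cfg4.fov_shape, 0.0, 6, cfg4.soma_radius_px), cfg4
        )
        for i in range(3):
            np.testing.assert_array_equal(gt3.spike_times[i], gt4.spike_times[i])

    def test_conservation_noise_free_round_trip(self, rng):
        # render→extract round trip over the exact mask, no noise/bleach
        cfg = small_config(
            n_neurons=2, shot_noise=False, background_counts=0.0, duration=15.0,
            seed=11,
        )
        movie, gt = simulate_fov(cfg)
        for i in range(2):
            raw = movie.frames[:, gt.masks[i]].mean(axis=1)
            rec = compute_dff(raw, cfg.frame_rate, baseline_method="global_percentile")
            # sliding baseline settles after the first window
            assert np.max(np.abs(rec.values - gt.dff_traces[i])) < 0.25


# ---------------------------------------------------------------------------
# presets and cohorts
# ---------------------------------------------------------------------------


class TestPresets:
    def test_reported_cohort_parameters(self):
        assert preset("WT4").firing_rate[0] == pytest.approx(1.03)
        assert preset("WT4").ap_fwhm == pytest.approx(14.8)
        assert preset("WT4").n_neurons == 24
        assert preset("WT83").firing_rate[0] == pytest.approx(0.23)
        assert preset("WT83").n_neurons == 41
        assert preset("WT156").n_neurons == 36
        assert preset("WT156").firing_pattern == "bursting"
        assert preset("primary").ap_fwhm[0] == pytest.approx(10.1)
        assert preset("primary").ap_fwhm[1] == pytest.approx(7.14)
        assert preset("primary").firing_pattern == "synchronized-bursting"

    def test_all_presets_run_at_500hz_for_180s(self):
        for name in ("WT4", "WT156", "WT83", "primary"):
            cfg = preset(name)
            assert cfg.frame_rate == 500.0
            assert cfg.duration == 180.0
            assert cfg.fov_shape == (150, 200)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            preset("WT0")

    def test_scale_shrinks_fov_and_preserves_photon_budget(self):
        full = preset("WT4")
        quarter = preset("WT4", scale=0.25)
        assert quarter.fov_shape == (38, 50)
        assert quarter.baseline_counts == pytest.approx(full.baseline_counts * 16)

    def test_cohort_splits_into_fovs_of_at_most_twelve(self):
        cfg = dataclasses.replace(
            small_config(seed=2, duration=5.0), n_neurons=7, neurons_per_fov=3
        )
        movies = simulate_cohort(cfg)
        assert [gt.n_neurons for _, gt in movies] == [3, 3, 1]

    def test_lognormal_parameter_draws_match_requested_moments(self):
        from voltpipe.simulate import _draw_lognormal

        r = np.random.default_rng(0)
        draws = _draw_lognormal(10.1, 7.14, 200_000, r, floor=2.0)
        assert draws.min() >= 2.0
        assert draws.mean() == pytest.approx(10.1, rel=0.02)
        assert draws.std() == pytest.approx(7.14, rel=0.05)


class TestConfigValidation:
    def test_invalid_frame_rate(self):
        with pytest.raises(ValueError):
            SimConfig(frame_rate=50.0)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            SimConfig(duration=0.0)

    def test_undersampled_ap_warns(self):
        with pytest.warns(UserWarning, match="undersampled"):
            SimConfig(ap_fwhm=3.0, frame_rate=500.0)
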