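"""Analysis operators: PSTHs, RSI, biphasic index, receptive fields, correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from irsretina import analysis, synth
from irsretina.analysis import (
    PSTHMatrix,
    biphasic_index,
    center_distance,
    compute_rsi,
    darkening_score,
    fit_rf,
    peak_latency,
    psth,
    separate_sta,
    spike_correlation,
    sta,
)
from irsretina.circuit import CircuitParams, bipolar_filter


class TestPSTH:
    def test_ten_trials_one_spike_each(self):
        trials = [np.array([15.0])] * 10
        prof = psth(trials, bin_ms=10.0, duration_ms=50.0)
        expect = np.zeros(5)
        expect[1] = 100.0
        np.testing.assert_allclose(prof, expect)

    def test_no_spikes_all_zero(self):
        prof = psth([np.array([])] * 3, bin_ms=10.0, duration_ms=100.0)
        assert np.all(prof == 0.0)

    def test_event_alignment(self):
        # one spike 15 ms after each of 4 events
        events = np.array([100.0, 300.0, 700.0, 1500.0])
        spikes = events + 15.0
        prof = psth(spikes, events, bin_ms=10.0, duration_ms=50.0)
        assert prof[1] == pytest.approx(100.0)

    def test_homogeneous_poisson_is_flat(self):
        rate = np.full(2000, 100.0)
        trials = synth.poisson_spikes(rate, n_trials=200, seed=0, dt=1.0)
        prof = psth(trials, bin_ms=100.0, duration_ms=2000.0)
        np.testing.assert_allclose(prof, 100.0, rtol=0.1)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            psth(np.array([1.0]), events=np.array([]))


class TestPeakLatency:
    def test_symmetric_triple_peaks_at_center(self):
        prof = np.array([0.0, 40.0, 50.0, 40.0, 0.0])
        res = peak_latency(prof, bin_ms=10.0, t_start=80.0)
        assert res["latency"] == pytest.approx(105.0)
        assert res["peak_rate"] == 50.0

    def test_asymmetric_triple_matches_polyfit_vertex(self):
        prof = np.array([0.0, 40.0, 50.0, 48.0, 0.0])
        res = peak_latency(prof, bin_ms=10.0, t_start=80.0)
        centers = 80.0 + (np.arange(5) + 0.5) * 10.0
        coef = np.polyfit(centers[1:4], prof[1:4], 2)
        assert res["latency"] == pytest.approx(-coef[1] / (2 * coef[0]))

    def test_single_nonzero_bin(self):
        res = peak_latency(np.array([0.0, 30.0, 0.0]), bin_ms=10.0)
        assert res["latency"] == pytest.approx(15.0)

    def test_edge_maximum_flagged(self):
        res = peak_latency(np.array([50.0, 40.0, 0.0]), bin_ms=10.0)
        assert res["edge"] and res["latency"] == pytest.approx(5.0)

    def test_all_zero_profile_flagged(self):
        res = peak_latency(np.zeros(5))
        assert res["undefined"] and np.isnan(res["latency"])


def _matrix_from_pairs(rec_profiles, chg_profiles, bin_ms=10.0, t_start=0.0):
    """Assemble a 4-position PSTHMatrix from recurrence/change profiles."""
    profiles = {}
    for i in range(1, 5):
        profiles[(i, i)] = np.asarray(rec_profiles[i - 1], dtype=float)
        chg_start = (i - 1 + 2) % 4 + 1
        profiles[(chg_start, i)] = np.asarray(chg_profiles[i - 1], dtype=float)
    return PSTHMatrix(profiles=profiles, bin=bin_ms, t_start=t_start, n_positions=4)


def _step_profile(n_bins, step_bin, height, baseline=0.0):
    p = np.full(n_bins, baseline)
    p[step_bin:] += height
    return p


class TestComputeRSI:
    def test_pure_recurrence_gives_one(self):
        rec = [_step_profile(40, 20, 4.0)] * 4
        chg = [np.zeros(40)] * 4
        m = _matrix_from_pairs(rec, chg)
        res = compute_rsi(m, fixation_onset=100.0, rate_screen=None)
        np.testing.assert_allclose(res.d_rec, 4.0)
        np.testing.assert_allclose(res.d_change, 0.0)
        assert res.rsi == pytest.approx(1.0)

    def test_equal_derivatives_give_zero(self):
        rec = [_step_profile(40, 20, 3.0)] * 4
        m = _matrix_from_pairs(rec, rec)
        assert compute_rsi(m, 100.0, rate_screen=None).rsi == pytest.approx(0.0)

    def test_three_to_one_ratio_gives_half(self):
        rec = [_step_profile(40, 20, 3.0)] * 4
        chg = [_step_profile(40, 20, 1.0)] * 4
        m = _matrix_from_pairs(rec, chg)
        assert compute_rsi(m, 100.0, rate_screen=None).rsi == pytest.approx(0.5)

    def test_model_matrix_is_irs(self, std_matrix):
        res = compute_rsi(std_matrix, fixation_onset=100.0, rate_screen=None)
        assert res.rsi >= 0.5 and res.is_irs

    def test_degenerate_terms_neutral_and_flagged(self):
        rec = [np.zeros(40)] * 4
        m = _matrix_from_pairs(rec, rec)
        res = compute_rsi(m, 100.0, rate_screen=None)
        assert res.rsi == 0.0 and res.degenerate_terms.all()

    def test_window_outside_profile_rejected(self):
        m = _matrix_from_pairs([np.zeros(10)] * 4, [np.zeros(10)] * 4)
        with pytest.raises(ValueError, match="window"):
            compute_rsi(m, fixation_onset=500.0, rate_screen=None)

    def test_rate_screen_gates_classification(self):
        rec = [_step_profile(40, 20, 30.0)] * 4  # peak 30 Hz < 50 Hz screen
        chg = [np.zeros(40)] * 4
        m = _matrix_from_pairs(rec, chg)
        res = compute_rsi(m, 100.0, rate_screen=50.0)
        assert res.rsi == 1.0 and not res.passed_rate_screen and not res.is_irs


@st.composite
def _psth_profiles(draw):
    arr = hnp.arrays(
        dtype=np.float64,
        shape=(8, 36),
        elements=st.floats(0.0, 200.0, allow_nan=False),
    )
    return draw(arr)


class TestRSIProperties:
    """Invariances of the derivative-based index, against a brute-force scan."""

    @staticmethod
    def _oracle_max_derivative(profile, bin_ms, t_start, lo, hi):
        best = -np.inf
        for k in range(1, profile.size):
            edge = t_start + k * bin_ms
            if lo <= edge < hi:
                best = max(best, profile[k] - profile[k - 1])
        return best

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(profiles=_psth_profiles())
    def test_window_maxima_match_bruteforce_and_invariances(self, profiles):
        rec, chg = profiles[:4], profiles[4:]
        m = _matrix_from_pairs(rec, chg)
        res = compute_rsi(m, fixation_onset=100.0, rate_screen=None)
        for i in range(4):
            assert res.d_rec[i] == pytest.approx(
                self._oracle_max_derivative(rec[i], 10.0, 0.0, 150.0, 300.0)
            )
        # invariance to a constant baseline added to every PSTH
        m_shift = _matrix_from_pairs(rec + 17.0, chg + 17.0)
        assert compute_rsi(m_shift, 100.0, rate_screen=None).rsi == pytest.approx(
            res.rsi, abs=1e-9
        )
        # invariance to a positive rate rescaling
        m_scale = _matrix_from_pairs(rec * 3.5, chg * 3.5)
        assert compute_rsi(m_scale, 100.0, rate_screen=None).rsi == pytest.approx(
            res.rsi, abs=1e-9
        )


class TestBiphasicIndex:
    def test_constructed_lobes(self):
        t = np.linspace(0, 1, 500)
        f = -np.exp(-(((t - 0.2) / 0.05) ** 2)) + 0.66 * np.exp(
            -(((t - 0.5) / 0.08) ** 2)
        )
        assert biphasic_index(f) == pytest.approx(0.66, abs=1e-3)

    def test_monophasic_is_zero(self):
        t = np.linspace(0, 1, 200)
        assert biphasic_index(np.exp(-(((t - 0.3) / 0.1) ** 2))) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            biphasic_index(np.zeros(10))

    def test_bipolar_filter_against_dense_extremum_search(self, params):
        """Filter index equals a brute-force lobe search on a 10x finer grid."""
        from dataclasses import replace

        f = bipolar_filter(params)
        fine = bipolar_filter(replace(params, dt=params.dt / 10.0))
        g = fine.samples
        first, second = g[np.argmin(g)], g[np.argmax(g)]  # neg lobe precedes pos
        assert np.argmin(g) < np.argmax(g)
        oracle = abs(second) / abs(first)
        assert biphasic_index(f) == pytest.approx(oracle, rel=1e-3)
        assert 0.0 < biphasic_index(f) < np.inf


class TestSTA:
    def test_single_spike_returns_that_segment(self):
        rng = np.random.default_rng(0)
        frames = rng.choice([-1.0, 1.0], size=(100, 4, 4))
        spikes = np.array([1500.0])  # frame 75 at 50 Hz
        avg, skipped = sta(spikes, frames, 50.0, window_ms=700.0)
        assert skipped == 0
        np.testing.assert_array_equal(avg, frames[75 - np.arange(35)])

    def test_stimulus_independent_spikes_average_out(self):
        rng = np.random.default_rng(1)
        frames = rng.choice([-1.0, 1.0], size=(20000, 3, 3))
        spikes = np.sort(rng.uniform(15000.0, 399000.0, size=8000))
        avg, _ = sta(spikes, frames, 50.0)
        assert np.abs(avg).max() < 5.0 / np.sqrt(8000)

    def test_early_spikes_skipped_and_counted(self):
        frames = np.ones((100, 2, 2))
        avg, skipped = sta(np.array([100.0, 1500.0]), frames, 50.0)
        assert skipped == 1

    def test_temporal_filter_recovery_from_ln_cell(self):
        """STA temporal component correlates >0.9 with the generating filter."""
        stim = synth.WhiteNoiseStimulus(nx=10, ny=10, duration_s=400.0, seed=2)
        frames = synth.generate_frames(stim)
        frame_ms = 1000.0 / stim.update_hz
        t = np.arange(0.0, 120.0, frame_ms)
        kernel = (t / 40.0) * np.exp(1.0 - t / 40.0)
        kernel /= np.linalg.norm(kernel)
        spikes = synth.ln_whitenoise_spikes(
            stim, frames, (300.0, 300.0), 90.0, temporal_filter=kernel, seed=3
        )[:5000]
        avg, _ = sta(spikes, frames, stim.update_hz)
        _, temporal = separate_sta(avg, polarity="off")
        # STA lag k is the stimulus k frames before the spike, so it aligns
        # with kernel index k directly; the Off cell carries the kernel with
        # flipped sign
        recovered = temporal[: kernel.size]
        r = np.corrcoef(recovered, -kernel)[0, 1]
        assert r > 0.9


class TestSeparateSTA:
    def test_rank_one_reconstruction_exact(self):
        temporal = np.array([0.0, -1.0, -0.3, 0.4, 0.1])
        spatial = np.outer(np.hanning(6), np.hanning(6))
        sta_arr = temporal[:, None, None] * spatial[None, :, :]
        s_map, t_filt = separate_sta(sta_arr, polarity="off")
        recon = t_filt[:, None, None] * s_map[None, :, :]
        np.testing.assert_allclose(recon, sta_arr, atol=1e-12)

    def test_noisy_rank_one_recovery(self):
        rng = np.random.default_rng(4)
        temporal = np.sin(np.linspace(0, np.pi, 20)) * -1.0
        spatial = np.outer(np.hanning(8), np.hanning(8))
        sta_arr = temporal[:, None, None] * spatial[None, :, :]
        noisy = sta_arr + rng.normal(0, 0.02, sta_arr.shape)
        s_map, _ = separate_sta(noisy, polarity="off")
        flat = spatial.ravel() / np.linalg.norm(spatial)
        assert abs(np.corrcoef(s_map.ravel(), flat)[0, 1]) > 0.99

    def test_off_polarity_sign_convention(self):
        temporal = np.array([0.0, 1.0, 0.5])  # wrong-sign input
        spatial = np.ones((3, 3))
        _, t_filt = separate_sta(temporal[:, None, None] * spatial, polarity="off")
        assert t_filt[np.argmax(np.abs(t_filt))] < 0

    def test_zero_sta_rejected(self):
        with pytest.raises(ValueError):
            separate_sta(np.zeros((5, 3, 3)))


class TestFitRF:
    @staticmethod
    def _gaussian_map(center, sigma, n=24, px=15.0):
        xs = (np.arange(n) + 0.5) * px
        xx, yy = np.meshgrid(xs, xs)
        return np.exp(-(((xx - center[0]) ** 2 + (yy - center[1]) ** 2) / (2 * sigma**2)))

    def test_isotropic_sigma_gives_closed_form_diameter(self):
        fit = fit_rf(self._gaussian_map((180.0, 180.0), 91.7), pixel_size=15.0)
        assert fit.diameter == pytest.approx(2 * 1.5 * 91.7, rel=1e-3)

    def test_center_recovered_within_half_pixel(self):
        fit = fit_rf(self._gaussian_map((187.0, 164.0), 60.0), pixel_size=15.0)
        assert abs(fit.center[0] - 187.0) < 7.5 and abs(fit.center[1] - 164.0) < 7.5

    def test_center_distance_helper(self):
        a = fit_rf(self._gaussian_map((150.0, 180.0), 60.0), pixel_size=15.0)
        b = fit_rf(self._gaussian_map((250.0, 180.0), 60.0), pixel_size=15.0)
        assert center_distance(a, b) == pytest.approx(100.0, abs=1.0)

    def test_negative_peak_map_fitted_after_flip(self):
        fit = fit_rf(-self._gaussian_map((180.0, 180.0), 75.0), pixel_size=15.0)
        assert fit.converged and fit.diameter == pytest.approx(2 * 1.5 * 75.0, rel=1e-3)


class TestSpikeCorrelation:
    def test_identical_trains_peak_at_zero(self):
        rng = np.random.default_rng(5)
        train = np.sort(rng.uniform(0, 60000, 2000))
        h = spike_correlation(train, train)
        assert h.peak_lag == 0.0 and h.peak > 0.5

    def test_shifted_train_peaks_at_shift(self):
        rng = np.random.default_rng(6)
        train = np.sort(rng.uniform(0, 60000, 2000))
        h = spike_correlation(train, train + 5.0)
        assert h.peak_lag == pytest.approx(5.0)

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(7)
        a = np.sort(rng.uniform(0, 200000, 4000))
        b = np.sort(rng.uniform(0, 200000, 4000))
        h = spike_correlation(a, b)
        assert abs(h.peak) < 0.01

    def test_probabilities_bounded(self):
        rng = np.random.default_rng(8)
        a = np.sort(rng.uniform(0, 10000, 500))
        b = np.sort(rng.uniform(0, 10000, 800))
        h = spike_correlation(a, b)
        assert np.all(h.probability >= 0.0) and np.all(h.probability <= 1.0)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            spike_correlation(np.array([]), np.array([1.0]))


class TestDarkeningScore:
    def _rf(self, center=(300.0, 300.0)):
        return analysis.RFFit(center=center, sigmas=(60.0, 60.0), orientation=0.0)

    def test_uniform_image_scores_zero(self):
        img = np.full((40, 40), 1.0)
        assert darkening_score(img, img.copy(), self._rf(), "fixation_onset") == 0.0

    def test_darker_than_blur_scores_positive(self):
        from irsretina.stimulus import blur_image

        img = np.full((40, 40), 1.0)
        img[15:25, 15:25] = 0.4  # dark patch under the RF center
        blurred = blur_image(img, 300.0, 15.0)
        score = darkening_score(img, blurred, self._rf(), "fixation_onset")
        assert score > 0.0

    def test_transition_onset_flips_contrast_sign(self):
        img = np.full((40, 40), 1.0)
        img[15:25, 15:25] = 1.6  # bright patch: darkening at transition onset
        from irsretina.stimulus import blur_image

        blurred = blur_image(img, 300.0, 15.0)
        fix = darkening_score(img, blurred, self._rf(), "fixation_onset")
        trans = darkening_score(img, blurred, self._rf(), "transition_onset")
        assert trans > fix

    def test_rf_outside_image_rejected(self):
        img = np.ones((20, 20))
        with pytest.raises(ValueError, match="outside"):
            darkening_score(img, img, self._rf(center=(900.0, 900.0)), "fixation_onset")

    def test_planted_monotone_relation_yields_positive_r(self):
        """Images whose darkening drives peak size give positive R for all cells."""
        from irsretina.analysis import darkening_peak_correlation
        from irsretina.stimulus import blur_image

        rng = np.random.default_rng(9)
        scores, peaks = {}, {}
        for cell in range(6):
            rf = self._rf()
            cell_scores = []
            for pos in range(4):
                img = np.full((40, 40), 1.0)
                depth = 0.1 + 0.2 * pos + rng.uniform(0, 0.02)
                img[15:25, 15:25] = 1.0 - depth
                blurred = blur_image(img, 300.0, 15.0)
                cell_scores.append(darkening_score(img, blurred, rf, "fixation_onset"))
            scores[f"c{cell}"] = cell_scores
            # peak size grows monotonically with the planted darkening
            peaks[f"c{cell}"] = [s * 2.0 + rng.uniform(0, 0.1) for s in cell_scores]
        res = darkening_peak_correlation(scores, peaks)
        assert all(r > 0 for r in res["r"].values())
        assert res["pvalue"] < 0.05
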