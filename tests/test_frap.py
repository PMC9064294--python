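"""FRAP protocols: bleach detection, normalization, averaging, fitting."""

import math

import numpy as np
import pytest

from edequant.frap import (FrapTrace, NormalizedTrace, AveragedTrace,
                           average_aligned_traces, detect_bleach_frame,
                           extract_patch_traces, fit_recovery,
                           normalize_condensate_trace, normalize_patch_trace,
                           qc_exclude_moving, read_traces_csv,
                           refit_recovery_csv,
                           select_patch_events_by_reference)
from edequant.simulate import (FrapParams, frap_model,
                               simulate_frap_experiment)

LN2 = math.log(2.0)


def _model_trace(mobile=0.63, tau=22.0, depth=0.8, t_bleach=10.0,
                 dt=1.0, duration=130.0):
    """Exact normalized model curve as a NormalizedTrace."""
    t = np.arange(0.0, duration, dt)
    value = np.where(t >= t_bleach,
                     frap_model(np.maximum(t - t_bleach, 0.0), mobile, tau),
                     1.0)
    return NormalizedTrace(time_rel=t - t_bleach, value=value)


class TestDetectBleach:
    def test_constructed_step(self):
        tr = FrapTrace(time=np.arange(6.0),
                       roi_mean=np.array([10, 10, 10, 2, 3, 4.0]))
        assert detect_bleach_frame(tr) == 3

    def test_flat_trace_has_no_event(self):
        tr = FrapTrace(time=np.arange(6.0), roi_mean=np.full(6, 5.0))
        with pytest.raises(ValueError, match="no bleach event"):
            detect_bleach_frame(tr)

    def test_simulated_detection_accuracy(self):
        # over many noisy draws the detected frame is within +-1 of truth
        rng = np.random.default_rng(11)
        params = FrapParams(0.63, 22.0, 0.8, 10.0)
        traces, _ = simulate_frap_experiment(params, 0.05, 1000, rng)
        true_index = traces[0].bleach_index
        hits = sum(abs(detect_bleach_frame(tr) - true_index) <= 1
                   for tr in traces)
        assert hits >= 990


class TestNormalization:
    def _trace(self, noise_sd=0.0, cell_bleach=0.01, seed=0):
        rng = np.random.default_rng(seed)
        params = FrapParams(0.63, 22.0, 0.8, 10.0)
        traces, _ = simulate_frap_experiment(params, noise_sd, 1, rng,
                                             cell_bleach_rate=cell_bleach)
        tr = traces[0]
        tr.bleach_index = detect_bleach_frame(tr)
        return tr

    def test_symbolic_construction_recovers_model(self):
        # raw trace built with acquisition bleaching; after the ratio
        # correction and double normalization the model curve reappears
        tr = self._trace()
        norm = normalize_condensate_trace(tr)
        post = norm.time_rel >= 0
        expected = frap_model(norm.time_rel[post], 0.63, 22.0)
        assert np.allclose(norm.value[post], expected, atol=1e-6)

    def test_anchors_zero_and_one_by_construction(self):
        tr = self._trace(noise_sd=0.05, seed=3)
        norm = normalize_condensate_trace(tr)
        assert norm.value[tr.bleach_index] == pytest.approx(0.0, abs=1e-12)
        pre = (norm.time_rel < 0) & (norm.time_rel >= -5.0)
        assert norm.value[pre].mean() == pytest.approx(1.0, abs=1e-9)

    def test_full_recovery_approaches_one(self):
        rng = np.random.default_rng(5)
        params = FrapParams(1.0, 5.0, 0.8, 10.0)
        traces, _ = simulate_frap_experiment(params, 0.0, 1, rng)
        tr = traces[0]
        tr.bleach_index = detect_bleach_frame(tr)
        norm = normalize_condensate_trace(tr)
        assert norm.value[-1] == pytest.approx(1.0, abs=1e-3)

    def test_affine_invariance_of_normalization(self):
        tr = self._trace(noise_sd=0.05, seed=9)
        norm1 = normalize_condensate_trace(tr)
        tr2 = FrapTrace(time=tr.time, roi_mean=3.0 * tr.roi_mean + 40.0,
                        cell_mean=3.0 * tr.cell_mean + 40.0,
                        bg_mean=3.0 * tr.bg_mean + 40.0,
                        bleach_index=tr.bleach_index)
        norm2 = normalize_condensate_trace(tr2)
        assert np.allclose(norm1.value, norm2.value, atol=1e-9)

    def test_degenerate_cell_signal_rejected(self):
        tr = self._trace()
        tr.cell_mean = tr.bg_mean.copy()
        with pytest.raises(ValueError, match="degenerate"):
            normalize_condensate_trace(tr)

    def test_short_prebleach_window_rejected(self):
        tr = self._trace()
        short = FrapTrace(time=tr.time[8:], roi_mean=tr.roi_mean[8:],
                          cell_mean=tr.cell_mean[8:], bg_mean=tr.bg_mean[8:],
                          bleach_index=tr.bleach_index - 8)
        with pytest.raises(ValueError, match="window"):
            normalize_condensate_trace(short)


class TestAveraging:
    def test_identical_traces_average_to_themselves(self):
        tr = _model_trace()
        avg = average_aligned_traces([tr, tr, tr])
        assert np.allclose(avg.value, np.interp(avg.time_rel, tr.time_rel,
                                                tr.value), atol=1e-12)
        assert avg.n_traces == 3

    def test_symmetric_pair_averages_to_one(self):
        tr = _model_trace()
        mirror = NormalizedTrace(time_rel=tr.time_rel, value=2.0 - tr.value)
        avg = average_aligned_traces([tr, mirror])
        assert np.allclose(avg.value, 1.0, atol=1e-12)

    def test_unequal_lengths_match_manual_mean(self):
        # hand-computed oracle on the overlap grid
        a = NormalizedTrace(time_rel=np.array([0.0, 1, 2, 3]),
                            value=np.array([0.0, 1, 2, 3]))
        b = NormalizedTrace(time_rel=np.array([0.0, 1, 2]),
                            value=np.array([2.0, 3, 4]))
        avg = average_aligned_traces([a, b], min_coverage=0.9)
        assert np.allclose(avg.time_rel, [0, 1, 2])
        assert np.allclose(avg.value, [1.0, 2.0, 3.0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no traces"):
            average_aligned_traces([])


class TestQc:
    def _trace(self, trace_id):
        t = np.arange(0.0, 30.0)
        return FrapTrace(time=t, roi_mean=np.full(30, 10.0),
                         trace_id=trace_id)

    def test_stationary_kept_drifting_excluded(self):
        traces = [self._trace("still"), self._trace("mover")]
        tracks = {"still": np.zeros((30, 2)),
                  "mover": np.column_stack([np.linspace(0, 1.0, 30),
                                            np.zeros(30)])}
        kept = qc_exclude_moving(traces, tracks, max_displacement_um=0.3)
        assert [tr.trace_id for tr in kept] == ["still"]

    def test_known_movers_recovered_exactly(self):
        rng = np.random.default_rng(2)
        ids = [f"t{i}" for i in range(20)]
        movers = set(rng.choice(ids, size=7, replace=False))
        traces = [self._trace(i) for i in ids]
        tracks = {}
        for i in ids:
            drift = 0.8 if i in movers else 0.05
            tracks[i] = np.column_stack([np.linspace(0, drift, 30),
                                         np.zeros(30)])
        kept = {tr.trace_id for tr in
                qc_exclude_moving(traces, tracks, 0.3)}
        assert kept == set(ids) - movers

    def test_missing_track_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="no centroid track"):
            kept = qc_exclude_moving([self._trace("lost")], {}, 0.3)
        assert kept == []


class TestFitRecovery:
    @pytest.mark.parametrize("mobile,tau", [(0.63, 22.0), (0.91, 7.8)])
    def test_noiseless_round_trip_exact(self, mobile, tau):
        fit = fit_recovery(_model_trace(mobile, tau))
        assert fit.mobile_fraction == pytest.approx(mobile, abs=1e-6)
        assert fit.half_time_s == pytest.approx(tau, abs=1e-6)

    def test_rate_half_time_identity(self):
        fit = fit_recovery(_model_trace(0.63, 22.0))
        assert fit.rate * fit.half_time_s == pytest.approx(LN2, abs=1e-12)

    def test_refit_of_fitted_curve_is_fixed_point(self):
        fit = fit_recovery(_model_trace(0.5, 15.0))
        refit = fit_recovery(_model_trace(fit.mobile_fraction,
                                          fit.half_time_s))
        assert refit.mobile_fraction == pytest.approx(fit.mobile_fraction,
                                                      abs=1e-9)
        assert refit.half_time_s == pytest.approx(fit.half_time_s, abs=1e-6)

    def test_matches_brute_force_grid_search(self):
        # independent oracle: dense grid search over (M, tau) minimising SSE
        rng = np.random.default_rng(21)
        params = FrapParams(0.63, 22.0, 0.8, 10.0)
        traces, _ = simulate_frap_experiment(params, 0.05, 36, rng)
        normalized = []
        for tr in traces:
            tr.bleach_index = detect_bleach_frame(tr)
            normalized.append(normalize_condensate_trace(tr))
        avg = average_aligned_traces(normalized)
        fit = fit_recovery(avg)
        post = avg.time_rel >= 0
        t, v = avg.time_rel[post], avg.value[post]
        grid_m = np.linspace(0.5, 0.8, 601)
        grid_tau = np.linspace(10.0, 35.0, 1001)
        sse = ((v[None, None, :]
                - grid_m[:, None, None]
                * (1 - np.exp(-LN2 * t[None, None, :]
                              / grid_tau[None, :, None]))) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.mobile_fraction == pytest.approx(grid_m[i], rel=0.01)
        assert fit.half_time_s == pytest.approx(grid_tau[j], rel=0.01)

    def test_ensemble_fits_are_unbiased(self):
        # median over replicate ensembles close to generating parameters
        params = FrapParams(0.63, 22.0, 0.8, 10.0)
        fits_m, fits_tau = [], []
        for i in range(60):
            rng = np.random.default_rng(1000 + i)
            traces, _ = simulate_frap_experiment(params, 0.05, 36, rng)
            normalized = []
            for tr in traces:
                tr.bleach_index = detect_bleach_frame(tr)
                normalized.append(normalize_condensate_trace(tr))
            fit = fit_recovery(average_aligned_traces(normalized))
            fits_m.append(fit.mobile_fraction)
            fits_tau.append(fit.half_time_s)
        assert abs(np.median(fits_m) / 0.63 - 1) < 0.03
        assert abs(np.median(fits_tau) / 22.0 - 1) < 0.03

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="post-bleach"):
            fit_recovery(NormalizedTrace(time_rel=np.array([-1.0, 0, 1]),
                                         value=np.array([1.0, 0, 0.1])))


class TestPatchTraces:
    def test_uniform_disk_gives_constant_trace(self):
        stack = np.full((4, 21, 21), 7.0)
        (tr,) = extract_patch_traces(stack, [(10.0, 10.0)],
                                     frame_interval=1.0)
        assert np.allclose(tr.roi_mean, 7.0)

    def test_three_pixel_circle_has_29_pixels(self):
        # exhaustive enumeration oracle for the center-distance rule
        count = sum(1 for dy in range(-4, 5) for dx in range(-4, 5)
                    if dy * dy + dx * dx <= 9)
        assert count == 29
        stack = np.zeros((1, 21, 21))
        ys, xs = np.mgrid[0:21, 0:21]
        inside = (ys - 10) ** 2 + (xs - 10) ** 2 <= 9
        stack[0][inside] = 1.0
        (tr,) = extract_patch_traces(stack, [(10, 10)], frame_interval=1.0)
        assert tr.roi_mean[0] == pytest.approx(1.0)
        assert inside.sum() == 29

    def test_trace_proportional_to_amplitude(self):
        from edequant.simulate import simulate_frap_patch_movies
        rng = np.random.default_rng(4)
        params = FrapParams(0.91, 7.8, 0.8, 10.0)
        movies, _ = simulate_frap_patch_movies(params, 0.0, 1, rng)
        stack, centroid = movies[0]
        (tr,) = extract_patch_traces(stack, [centroid], frame_interval=0.5)
        floor = 1.0 - params.bleach_depth
        post = tr.time >= params.bleach_time_s
        expected = floor + params.bleach_depth * frap_model(
            tr.time[post] - params.bleach_time_s, 0.91, 7.8)
        ratio = tr.roi_mean[post] / tr.roi_mean[0]
        assert np.allclose(ratio, expected, atol=1e-9)

    def test_edge_centroid_excluded_by_default(self):
        stack = np.zeros((2, 21, 21))
        traces = extract_patch_traces(stack, [(1.0, 10.0)],
                                      frame_interval=1.0)
        assert traces == []

    def test_patch_normalization_round_trip(self):
        from edequant.simulate import simulate_frap_patch_movies
        rng = np.random.default_rng(4)
        movies, _ = simulate_frap_patch_movies(
            FrapParams(0.91, 7.8, 0.8, 10.0), 0.0, 1, rng)
        stack, centroid = movies[0]
        (tr,) = extract_patch_traces(stack, [centroid], frame_interval=0.5)
        tr.bleach_index = detect_bleach_frame(tr)
        norm = normalize_patch_trace(tr)
        post = norm.time_rel >= 0
        assert np.allclose(norm.value[post],
                           frap_model(norm.time_rel[post], 0.91, 7.8),
                           atol=1e-9)


class TestReferenceSelection:
    def _pair(self, peak_s, trace_id, bleach_index=10):
        t = np.arange(0.0, 120.0)
        green = FrapTrace(time=t, roi_mean=np.where(t < 10, 10.0, 3.0),
                          bleach_index=bleach_index, trace_id=trace_id)
        red_curve = np.exp(-0.5 * ((t - (10.0 + peak_s)) / 5.0) ** 2)
        red = FrapTrace(time=t, roi_mean=red_curve, trace_id=trace_id)
        return green, red

    def test_early_peak_excluded_late_peak_included(self):
        g1, r1 = self._pair(30.0, "early")
        g2, r2 = self._pair(61.0, "late")
        kept = select_patch_events_by_reference([g1, g2], [r1, r2])
        assert [tr.trace_id for tr in kept] == ["late"]

    def test_known_cohort_selected_exactly(self):
        rng = np.random.default_rng(8)
        delays = rng.uniform(10.0, 110.0, size=30)
        greens, reds = [], []
        for i, d in enumerate(delays):
            g, r = self._pair(float(d), f"ev{i}")
            greens.append(g)
            reds.append(r)
        kept = {tr.trace_id for tr in
                select_patch_events_by_reference(greens, reds, 60.0)}
        expected = {f"ev{i}" for i, d in enumerate(delays) if d >= 60.0}
        assert kept == expected

    def test_unpaired_trace_warned_and_dropped(self):
        g, _ = self._pair(90.0, "lonely")
        with pytest.warns(UserWarning, match="no reference"):
            kept = select_patch_events_by_reference([g], [])
        assert kept == []


class TestCsvRoundTrip:
    def test_traces_csv_round_trip(self, tmp_path):
        import pandas as pd
        rng = np.random.default_rng(1)
        traces, _ = simulate_frap_experiment(FrapParams(), 0.05, 3, rng)
        rows = []
        for tr in traces:
            for k in range(len(tr)):
                rows.append({"time_s": tr.time[k], "roi": tr.roi_mean[k],
                             "cell": tr.cell_mean[k], "bg": tr.bg_mean[k],
                             "trace_id": tr.trace_id})
        path = tmp_path / "traces.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        back = read_traces_csv(path)
        assert len(back) == 3
        orig = {tr.trace_id: tr for tr in traces}
        for tr in back:
            assert np.allclose(tr.roi_mean, orig[tr.trace_id].roi_mean)

    def test_refit_recovery_csv(self, tmp_path):
        import pandas as pd
        tr = _model_trace(0.63, 22.0)
        path = tmp_path / "recovery.csv"
        pd.DataFrame({"time_s": tr.time_rel, "value": tr.value}).to_csv(
            path, index=False)
        fit = refit_recovery_csv(path)
        assert fit.mobile_fraction == pytest.approx(0.63, abs=1e-6)
        assert fit.half_time_s == pytest.approx(22.0, abs=1e-6)

    def test_refit_missing_file_guidance(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="source-data"):
            refit_recovery_csv(tmp_path / "absent.csv")
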