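"""Spot detection, optimal-assignment tracking, density, condition summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from edequant.patches import (CellRecord, Spot, compare_conditions,
                              detect_spots, detection_scores, link_tracks,
                              match_points, patch_density, total_linking_cost,
                              track_lifetimes)


def _spot(frame, y, x, intensity=1.0):
    return Spot(frame=frame, y=float(y), x=float(x), intensity=intensity)


class TestDetectSpots:
    def test_blank_image_yields_nothing(self):
        assert detect_spots(np.zeros((64, 64))) == []

    def test_single_spot_detected_and_localized(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = 50.0 * np.exp(-((yy - 30.4) ** 2 + (xx - 21.7) ** 2)
                            / (2 * 1.3 ** 2))
        rng = np.random.default_rng(0)
        img = np.maximum(img + rng.normal(0, 2.0, img.shape), 0)
        spots = detect_spots(img)
        assert len(spots) == 1
        assert math.hypot(spots[0].y - 30.4, spots[0].x - 21.7) < 0.5

    def test_field_recall_precision_at_snr5(self):
        # small version of the parameter-recovery surface: see the
        # acceptance tests for the full study
        from edequant.preprocess import rolling_ball_background
        from edequant.simulate import SimulationConfig, simulate_movie
        nm = nt = nd = 0
        sq = 0.0
        for i in range(6):
            cfg = SimulationConfig(image_shape=(200, 200), n_cells=3,
                                   patch_amplitude_cv=0.0, rng_seed=50 + i)
            stack, truth = simulate_movie(cfg)
            img, _ = rolling_ball_background(stack[0], 10)
            det = np.array([[s.y, s.x] for s in detect_spots(img)]
                           ).reshape(-1, 2)
            tru = np.array([e.projected_position_px
                            for e in truth.live_patches(0.0)]).reshape(-1, 2)
            sc = detection_scores(det, tru, 2.0)
            nm += sc["n_matched"]
            nt += sc["n_true"]
            nd += sc["n_detected"]
            sq += sc["rmse_px"] ** 2 * sc["n_matched"]
        assert nm / nt >= 0.95
        assert nm / nd >= 0.95
        assert math.sqrt(sq / nm) <= 0.5


class TestDensity:
    def test_arithmetic_identity(self):
        rec = CellRecord(cell_id=1, projected_area_um2=12.57, patch_count=25)
        assert patch_density(rec) == pytest.approx(25 / 50.27, rel=1e-3)
        assert rec.surface_area_um2 == pytest.approx(4 * 12.57)

    def test_zero_patches_zero_density(self):
        rec = CellRecord(cell_id=1, projected_area_um2=10.0, patch_count=0)
        assert patch_density(rec) == 0.0

    def test_budding_cell_rejected(self):
        rec = CellRecord(cell_id=1, projected_area_um2=10.0, patch_count=5,
                         is_budding=True)
        with pytest.raises(ValueError, match="budding"):
            patch_density(rec)

    def test_zero_area_rejected(self):
        rec = CellRecord(cell_id=1, projected_area_um2=0.0, patch_count=5)
        with pytest.raises(ValueError, match="area"):
            patch_density(rec)

    def test_density_linear_in_birth_rate(self):
        # doubling the birth rate doubles the estimated density
        from edequant.preprocess import rolling_ball_background
        from edequant.pipeline import _mask_from_layout
        from edequant.patches import make_cell_records
        from edequant.simulate import SimulationConfig, simulate_movie

        def measure(rate, seeds):
            count, surface = 0, 0.0
            for s in seeds:
                cfg = SimulationConfig(image_shape=(256, 256), n_cells=4,
                                       patch_birth_rate=rate,
                                       patch_amplitude_cv=0.0, rng_seed=s)
                stack, truth = simulate_movie(cfg)
                img, _ = rolling_ball_background(stack[0], 10)
                mask = _mask_from_layout(truth, img.shape, cfg.pixel_size)
                spots = detect_spots(img, cell_mask=mask.labels)
                for rec in make_cell_records(mask, spots):
                    count += rec.patch_count
                    surface += rec.surface_area_um2
            return count / surface

        d1 = measure(4e-4, range(300, 320))
        d2 = measure(8e-4, range(400, 420))
        assert d2 / d1 == pytest.approx(2.0, rel=0.2)


def brute_force_frame_links(pts_a, pts_b, max_disp):
    """Enumeration oracle: over all one-to-one matchings under the distance
    gate, maximise the number of links, then minimise total distance."""
    n1, n2 = len(pts_a), len(pts_b)
    feasible = [(i, j, math.dist(pts_a[i], pts_b[j]))
                for i in range(n1) for j in range(n2)
                if math.dist(pts_a[i], pts_b[j]) <= max_disp]
    best = (0, 0.0, [])
    for k in range(len(feasible), -1, -1):
        found = None
        for combo in itertools.combinations(feasible, k):
            rows = [c[0] for c in combo]
            cols = [c[1] for c in combo]
            if len(set(rows)) < k or len(set(cols)) < k:
                continue
            cost = sum(c[2] for c in combo)
            if found is None or cost < found[1]:
                found = (k, cost, combo)
        if found:
            best = found
            break
    return best[0], best[1]


class TestLinkTracks:
    def test_stationary_spot_single_track(self):
        spots = [_spot(f, 10, 10) for f in range(10)]
        tracks = link_tracks(spots, 2.0, 0)
        assert len(tracks) == 1
        assert len(tracks[0].spots) == 10

    def test_distant_spots_stay_separate(self):
        spots = [_spot(0, 10, 10), _spot(0, 30, 30),
                 _spot(1, 10, 10), _spot(1, 30, 30)]
        tracks = link_tracks(spots, 5.0, 0)
        assert len(tracks) == 2

    def test_matches_exhaustive_optimal_assignment(self):
        # random small instances: <= 4 spots/frame over <= 6 frames
        rng = np.random.default_rng(17)
        for trial in range(25):
            n_frames = int(rng.integers(2, 7))
            spots = []
            frames = []
            for f in range(n_frames):
                pts = rng.uniform(0, 20, size=(int(rng.integers(0, 5)), 2))
                frames.append(pts)
                spots.extend(_spot(f, y, x) for y, x in pts)
            tracks = link_tracks(spots, 3.0, 0)
            n_links, cost = total_linking_cost(tracks)
            exp_links, exp_cost = 0, 0.0
            for a, b in itertools.pairwise(frames):
                k, c = brute_force_frame_links(a.tolist(), b.tolist(), 3.0)
                exp_links += k
                exp_cost += c
            assert n_links == exp_links
            assert cost == pytest.approx(exp_cost, abs=1e-9)

    def test_permutation_invariance_within_frames(self):
        rng = np.random.default_rng(3)
        spots = [_spot(f, *rng.uniform(0, 30, 2)) for f in range(5)
                 for _ in range(4)]
        tracks_a = link_tracks(list(spots), 2.5, 1)
        rng.shuffle(spots)
        tracks_b = link_tracks(spots, 2.5, 1)
        sig_a = sorted((t.start_frame, t.end_frame,
                        round(t.spots[0].y, 9)) for t in tracks_a)
        sig_b = sorted((t.start_frame, t.end_frame,
                        round(t.spots[0].y, 9)) for t in tracks_b)
        assert sig_a == sig_b

    def test_gap_bridging(self):
        spots = [_spot(0, 10, 10), _spot(1, 10.2, 10),
                 _spot(3, 10.4, 10), _spot(4, 10.6, 10)]
        tracks = link_tracks(spots, 2.0, 1)
        assert len(tracks) == 1
        assert tracks[0].n_frames_spanned == 5


class TestLifetimes:
    def test_arithmetic(self):
        spots = [_spot(f, 5, 5) for f in range(10, 40)]
        tracks = link_tracks(spots, 1.0, 0)
        # crop censor flags: the only track spans frames 10..39
        tracks[0].censored_start = tracks[0].censored_end = False
        life = track_lifetimes(tracks, 2.0)
        assert life.tolist() == [60.0]

    def test_censored_tracks_excluded_by_default(self):
        spots = [_spot(f, 5, 5) for f in range(10)]
        tracks = link_tracks(spots, 1.0, 0)
        assert tracks[0].censored_start and tracks[0].censored_end
        assert track_lifetimes(tracks, 2.0).size == 0
        assert track_lifetimes(tracks, 2.0, censor_policy="keep").size == 1

    def test_simulated_lifetime_mean_recovered(self):
        # movie-level closed loop lives in the acceptance tests; here the
        # tracker is fed exact detections to isolate the lifetime estimator
        rng = np.random.default_rng(6)
        from edequant.simulate import Cell, sample_patch_events
        # duration >> mean lifetime keeps the censoring-exclusion bias
        # (for exponential: (mT - 2m^2) / (T - m) vs m) well under 2%
        cell = Cell(1, (500.0, 500.0), 2.0)
        duration, dt = 6000.0, 2.0
        events = sample_patch_events(cell, 0.01, "exponential", duration,
                                     rng, lifetime_mean=90.0,
                                     pixel_size=0.1)
        spots = []
        n_frames = int(duration / dt)
        for f in range(n_frames):
            t = f * dt
            for i, e in enumerate(events):
                if e.alive_at(t):
                    # separate events spatially so linking is unambiguous
                    spots.append(_spot(f, 3.0 * i, 0.0))
        tracks = link_tracks(spots, 1.0, 0)
        life = track_lifetimes(tracks, dt)
        assert life.mean() == pytest.approx(90.0, rel=0.05)


class TestCompareConditions:
    def test_identical_conditions_zero_change(self):
        df = pd.DataFrame({"condition": ["a"] * 4 + ["b"] * 4,
                           "replicate": [0, 0, 1, 1] * 2,
                           "value": [3.0, 5.0, 4.0, 6.0] * 2})
        out = {s.condition: s for s in compare_conditions(df, "a")}
        assert out["b"].percent_change_vs_reference == pytest.approx(0.0)

    def test_replicate_mean_arithmetic(self):
        df = pd.DataFrame({
            "condition": ["mut"] * 2 + ["ref"] * 2,
            "replicate": [0, 1, 0, 1],
            "value": [2.0, 4.0, 4.0, 8.0]})
        out = {s.condition: s for s in compare_conditions(df, "ref")}
        assert out["mut"].grand_mean == pytest.approx(3.0)
        assert out["ref"].grand_mean == pytest.approx(6.0)
        assert out["mut"].percent_change_vs_reference == pytest.approx(50.0)

    def test_agrees_with_naive_recomputation(self):
        rng = np.random.default_rng(12)
        rows = []
        for cond in ("x", "y", "z"):
            for rep in range(3):
                for _ in range(rng.integers(5, 15)):
                    rows.append({"condition": cond, "replicate": rep,
                                 "value": float(rng.uniform(1, 10))})
        df = pd.DataFrame(rows)
        out = {s.condition: s for s in compare_conditions(df, "x")}
        for cond in ("x", "y", "z"):
            rep_means = [df[(df.condition == cond) & (df.replicate == r)]
                         ["value"].mean() for r in range(3)]
            grand = float(np.mean(rep_means))
            assert out[cond].grand_mean == pytest.approx(grand)
            assert out[cond].sd_of_replicate_means == pytest.approx(
                float(np.std(rep_means, ddof=1)))
            assert out[cond].percent_change_vs_reference == pytest.approx(
                (1 - grand / out["x"].grand_mean) * 100)

    def test_missing_reference_rejected(self):
        df = pd.DataFrame({"condition": ["a"], "replicate": [0],
                           "value": [1.0]})
        with pytest.raises(ValueError, match="reference"):
            compare_conditions(df, "nope")


class TestMatching:
    def test_one_to_one_matching_is_optimal(self):
        detected = np.array([[0.0, 0.0], [0.0, 1.0]])
        truth = np.array([[0.0, 0.6]])
        matches = match_points(detected, truth, 2.0)
        assert len(matches) == 1
        # the closer detection wins
        assert matches[0] == (1, 0)

    def test_scores_on_perfect_detections(self):
        pts = np.random.default_rng(0).uniform(0, 50, size=(20, 2))
        sc = detection_scores(pts, pts, 1.0)
        assert sc["recall"] == 1.0 and sc["precision"] == 1.0
        assert sc["rmse_px"] == 0.0
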