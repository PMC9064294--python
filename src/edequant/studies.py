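"""Closed-loop simulation studies: generate with known truth, measure, compare.

Each function runs one complete analysis on synthetic data whose generating
parameters are known, returning both the estimate and the truth. These are
the workhorses behind the numbered analysis scripts, the test suite and the
reproduction script; every estimate is produced by the same code path a user
would run on real images (render -> background-subtract -> detect/extract ->
normalize/track -> fit/summarise).

Problem sizes default to what gives each estimator comfortable statistical
resolution (documented in the methods note) while staying quick on one CPU.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .cellquant import (bright_structure_mask, coloc_fraction,
                        cytosolic_intensity, total_cell_intensity)
from .frap import (FrapFit, average_aligned_traces, detect_bleach_frame,
                   extract_patch_traces, fit_recovery,
                   normalize_condensate_trace, normalize_patch_trace)
from .patches import (compare_conditions, detect_spots, detection_scores,
                      link_tracks, make_cell_records, track_lifetimes)
from .pipeline import _mask_from_layout
from .preprocess import rolling_ball_background
from .simulate import (FrapParams, SimulationConfig,
                       simulate_expression_series, simulate_frap_experiment,
                       simulate_frap_patch_movies, simulate_movie,
                       simulate_two_channel_movie)

__all__ = [
    "CONDENSATE_FRAP", "PATCH_FRAP",
    "condensate_frap_study", "patch_frap_study",
    "patch_detection_study", "patch_lifetime_study",
    "condition_comparison_study", "buffering_study", "coloc_study",
]

# reference FRAP parameters for the two structure classes: condensates
# recover with tau_half = 22 s and 63% mobile fraction; native endocytic
# sites with tau_half = 7.8 s and 91% mobile fraction
CONDENSATE_FRAP = FrapParams(mobile_fraction=0.63, half_time_s=22.0,
                             bleach_depth=0.8, bleach_time_s=10.0)
PATCH_FRAP = FrapParams(mobile_fraction=0.91, half_time_s=7.8,
                        bleach_depth=0.8, bleach_time_s=10.0)


def condensate_frap_study(seed: int,
                          params: FrapParams = CONDENSATE_FRAP,
                          n_traces: int = 36,
                          noise_sd: float = 0.05) -> FrapFit:
    """Condensate-protocol closed loop.

    Simulate raw three-ROI traces (whole-cell acquisition bleaching and a
    constant background channel included), then run the full protocol:
    bleach detection, background/bleach correction with double
    normalization, alignment and averaging, single-exponential fit.
    """
    rng = np.random.default_rng([seed, 1])
    traces, _ = simulate_frap_experiment(params, noise_sd, n_traces, rng)
    normalized = []
    for tr in traces:
        tr.bleach_index = detect_bleach_frame(tr)
        normalized.append(normalize_condensate_trace(tr))
    return fit_recovery(average_aligned_traces(normalized))


def patch_frap_study(seed: int,
                     params: FrapParams = PATCH_FRAP,
                     n_traces: int = 14,
                     noise_sd: float = 0.05) -> FrapFit:
    """Endocytic-site (TIRF) protocol closed loop.

    Render one single-patch movie per event, extract the 3-pixel circular
    ROI trace around the patch centroid, apply the raw 0-1 normalization
    (no further corrections, per the protocol), average and fit.
    """
    rng = np.random.default_rng([seed, 2])
    movies, _ = simulate_frap_patch_movies(params, noise_sd, n_traces, rng)
    normalized = []
    for stack, centroid in movies:
        tr = extract_patch_traces(stack, [centroid], frame_interval=0.5)[0]
        tr.bleach_index = detect_bleach_frame(tr)
        normalized.append(normalize_patch_trace(tr))
    return fit_recovery(average_aligned_traces(normalized))


def _snapshot_config(seed: int, **overrides) -> SimulationConfig:
    defaults = dict(image_shape=(256, 256), n_cells=4, n_frames=1,
                    rng_seed=seed)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def patch_detection_study(seed: int,
                          n_fields: int = 60,
                          birth_rate: float = 5e-4,
                          amplitude_cv: float = 0.0,
                          match_radius_px: float = 2.0) -> dict:
    """Detection and density recovery on steady-state snapshots.

    Renders ``n_fields`` independent fields of spherical cells with membrane
    patches at steady state, runs rolling-ball subtraction and spot
    detection, and scores detections against the ground-truth positions of
    every patch alive at the imaged time. Fixed patch amplitude
    (``amplitude_cv = 0``) realises the configured signal-to-noise exactly.
    Returns density estimate vs truth and pooled recall/precision/RMSE.
    """
    total_count = 0
    total_surface = 0.0
    n_matched = n_true = n_det = 0
    sq_err: list[float] = []
    for i in range(n_fields):
        cfg = _snapshot_config(int(np.random.default_rng([seed, 3, i])
                                   .integers(2 ** 31)),
                               patch_birth_rate=birth_rate,
                               patch_amplitude_cv=amplitude_cv)
        stack, truth = simulate_movie(cfg)
        img, _ = rolling_ball_background(stack[0], 10)
        mask = _mask_from_layout(truth, img.shape, cfg.pixel_size)
        spots = detect_spots(img, cell_mask=mask.labels)
        for rec in make_cell_records(mask, spots):
            total_count += rec.patch_count
            total_surface += rec.surface_area_um2
        live = truth.live_patches(0.0)
        det = np.array([[s.y, s.x] for s in spots]).reshape(-1, 2)
        tru = np.array([e.projected_position_px for e in live]).reshape(-1, 2)
        sc = detection_scores(det, tru, match_radius_px)
        n_matched += sc["n_matched"]
        n_true += sc["n_true"]
        n_det += sc["n_detected"]
        if np.isfinite(sc["rmse_px"]):
            sq_err.append(sc["rmse_px"] ** 2 * sc["n_matched"])
    density_true = birth_rate * 90.0  # steady state: birth rate x mean lifetime
    return {
        "density_est_per_um2": total_count / total_surface,
        "density_true_per_um2": density_true,
        "recall": n_matched / n_true,
        "precision": n_matched / n_det,
        "rmse_px": math.sqrt(sum(sq_err) / n_matched),
        "n_true": n_true,
    }


def patch_lifetime_study(seed: int,
                         n_fields: int = 6,
                         duration_s: float = 1800.0,
                         frame_interval: float = 2.0) -> dict:
    """Lifetime recovery from full movies: detect, link, exclude censored.

    Gamma-distributed lifetimes (shape 4, mean 90 s) on movies an order of
    magnitude longer than the mean lifetime, so the censoring loss is small;
    several independent fields give the mean-lifetime estimate a sampling
    error well inside the band the estimator is judged against.
    """
    n_frames = int(duration_s / frame_interval)
    lifetimes = []
    true_lifetimes = []
    for i in range(n_fields):
        cfg = _snapshot_config(int(np.random.default_rng([seed, 4, i])
                                   .integers(2 ** 31)),
                               image_shape=(200, 200), n_cells=3,
                               n_frames=n_frames,
                               frame_interval=frame_interval,
                               patch_amplitude_cv=0.0)
        stack, truth = simulate_movie(cfg)
        all_spots = []
        for f in range(n_frames):
            # flat background: per-frame median subtraction is exact here and
            # far cheaper than morphological background estimation per frame
            frame = np.maximum(stack[f] - np.median(stack[f]), 0.0)
            all_spots.extend(detect_spots(frame, frame=f))
        # the displacement gate must absorb the apparent centroid jump when
        # two patches transiently come within the PSF scale (the merged
        # detection sits between them), and the gap must cover the frames a
        # patch spends hidden inside such a merge; 3 px / 2 frames removes
        # the track-fragmentation bias these episodes otherwise cause
        tracks = link_tracks(all_spots, max_displacement_px=3.0,
                             max_gap_frames=2)
        lifetimes.extend(track_lifetimes(tracks, frame_interval,
                                         min_frames=3))
        true_lifetimes.extend(
            e.lifetime for e in truth.patch_events
            if not (e.truncated_start or e.truncated_end)
            and 0 <= e.birth_time and e.death_time < duration_s)
    return {
        "mean_lifetime_est_s": float(np.mean(lifetimes)),
        "mean_lifetime_config_s": 90.0,
        "n_tracks": len(lifetimes),
    }


def condition_comparison_study(seed: int,
                               programmed_reduction: float = 0.46,
                               n_replicates: int = 3,
                               fields_per_replicate: int = 40,
                               reference_birth_rate: float = 5e-4) -> dict:
    """Two simulated strains with a programmed density reduction.

    The mutant's patch birth rate is scaled by (1 - reduction); per-cell
    densities are measured through the full detection pipeline, summarised
    by replicate means, and compared with the replicate-mean convention.
    """
    rows = []
    rates = {"wildtype": reference_birth_rate,
             "mutant": reference_birth_rate * (1.0 - programmed_reduction)}
    for ci, (cond, rate) in enumerate(rates.items()):
        for rep in range(n_replicates):
            for i in range(fields_per_replicate):
                sub = np.random.default_rng([seed, 5, ci, rep, i])
                cfg = _snapshot_config(int(sub.integers(2 ** 31)),
                                       patch_birth_rate=rate,
                                       patch_amplitude_cv=0.0)
                stack, truth = simulate_movie(cfg)
                img, _ = rolling_ball_background(stack[0], 10)
                mask = _mask_from_layout(truth, img.shape, cfg.pixel_size)
                spots = detect_spots(img, cell_mask=mask.labels)
                for rec in make_cell_records(mask, spots):
                    rows.append({"condition": cond, "replicate": rep,
                                 "value": rec.density_per_um2})
    summaries = compare_conditions(pd.DataFrame(rows), reference="wildtype")
    by_name = {s.condition: s for s in summaries}
    return {
        "percent_reduction_est": by_name["mutant"].percent_change_vs_reference,
        "percent_reduction_true": programmed_reduction * 100.0,
        "summaries": summaries,
    }


def buffering_study(seed: int,
                    levels=(10, 20, 30, 40, 50, 70, 100, 140),
                    saturation: float = 50.0,
                    cells_per_level: int = 3) -> dict:
    """Concentration buffering: cytosolic vs cellular intensity series.

    Above the saturation level the excess protein is deposited in
    condensates; the measured cytosolic mean should stay flat while the
    cellular mean keeps rising.
    """
    rng = np.random.default_rng([seed, 6])
    cfg = SimulationConfig(image_shape=(96, 96), cell_radius_um=(2.0, 2.0),
                           rng_seed=seed)
    cyt = np.zeros(len(levels))
    cellular = np.zeros(len(levels))
    for rep in range(cells_per_level):
        imgs, truths = simulate_expression_series(levels, saturation, cfg, rng)
        for i, (img, truth) in enumerate(zip(imgs, truths)):
            mask = _mask_from_layout(truth, img.shape, cfg.pixel_size)
            sub = img - cfg.background_level
            cellular[i] += total_cell_intensity(sub, mask.labels) / cells_per_level
            excl = bright_structure_mask(sub, mask.labels)
            cyt[i] += cytosolic_intensity(
                sub, mask.labels, excl, n_boxes=10, exclusion_margin_px=6,
                rng=np.random.default_rng([seed, 7, rep])) / cells_per_level
    saturated = cyt[np.asarray(levels, dtype=float) >= saturation]
    return {
        "levels": np.asarray(levels, dtype=float),
        "cytosolic_mean": cyt,
        "cellular_mean": cellular,
        "saturated_flatness": float(np.ptp(saturated) / saturated.mean()),
        "cellular_monotonic": bool(np.all(np.diff(cellular) > 0)),
    }


def coloc_study(seed: int,
                programmed_fraction: float = 0.4,
                n_fields: int = 15,
                max_distance_um: float = 0.25) -> dict:
    """Colocalized-fraction recovery from rendered two-channel images.

    Objects are detected independently in each channel and a green object
    counts as colocalized when a red centroid lies within
    ``max_distance_um``. Also reports the realised ground-truth fraction of
    the Bernoulli partner draws.
    """
    greens = []
    reds = []
    truth_partnered = []
    for i in range(n_fields):
        sub = np.random.default_rng([seed, 8, i])
        cfg = SimulationConfig(image_shape=(256, 256), n_cells=4,
                               condensates_per_cell=3,
                               condensate_amplitude=400.0,
                               rng_seed=int(sub.integers(2 ** 31)))
        g, r, truth = simulate_two_channel_movie(
            cfg, programmed_fraction, np.random.default_rng([seed, 9, i]))
        truth_partnered.extend(t["partnered"] for t in truth.coloc_table)
        for stack, store in ((g, greens), (r, reds)):
            img, _ = rolling_ball_background(stack[0], 10)
            pts = np.array([[s.y, s.x] for s in
                            detect_spots(img, min_separation_px=4)])
            store.append(pts.reshape(-1, 2) * cfg.pixel_size)
        # keep channel pairs aligned per field by offsetting coordinates
        offset = i * 1000.0
        greens[-1] = greens[-1] + offset
        reds[-1] = reds[-1] + offset
    result = coloc_fraction(np.vstack(greens), np.vstack(reds),
                            max_distance_um)
    result["programmed_fraction"] = programmed_fraction
    result["truth_fraction"] = float(np.mean(truth_partnered))
    return result
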