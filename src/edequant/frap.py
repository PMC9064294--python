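"""FRAP analysis: both acquisition protocols and the single-exponential fit.

Two protocols are implemented, mirroring how condensates and native
endocytic sites are measured:

* **Condensate protocol** — three ROIs per event (background, whole cell,
  bleached structure). The ROI trace is background-subtracted and divided by
  the background-subtracted whole-cell trace (which removes acquisition
  photobleaching), then double-normalized: 0 at the first post-bleach sample,
  1 at the mean of the 5 s pre-bleach window. Events whose structure moved
  during acquisition are excluded. Individual normalized curves are aligned
  to bleach time, averaged, and the average is fitted.

* **Endocytic-site (TIRF) protocol** — single-patch traces are extracted as
  the mean over a 3-pixel-radius circle around the patch centroid from
  background-subtracted movies; no further corrections are applied before
  the same 0-1 normalization. Events are kept only when the reference
  (actin-reporter) channel peaks well after the bleach, which guards against
  sites that were already disassembling.

The recovery model is value(t) = M * (1 - exp(-ln2 * t / t_half)) with mobile
fraction M and half-time t_half; the rate k = ln2 / t_half.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import frap_model

LN2 = math.log(2.0)

__all__ = [
    "FrapTrace",
    "NormalizedTrace",
    "AveragedTrace",
    "FrapFit",
    "detect_bleach_frame",
    "normalize_condensate_trace",
    "normalize_patch_trace",
    "average_aligned_traces",
    "qc_exclude_moving",
    "fit_recovery",
    "extract_patch_traces",
    "select_patch_events_by_reference",
    "read_traces_csv",
    "write_fits_csv",
    "refit_recovery_csv",
]


@dataclass
class FrapTrace:
    """Raw ROI time series for one FRAP event.

    ``cell_mean`` and ``bg_mean`` are present for the condensate protocol and
    None for the endocytic-site protocol. ``bleach_index`` is the index of
    the first post-bleach sample (None until detected).
    """

    time: np.ndarray
    roi_mean: np.ndarray
    cell_mean: np.ndarray | None = None
    bg_mean: np.ndarray | None = None
    bleach_index: int | None = None
    trace_id: str = ""
    edge_flagged: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.roi_mean = np.asarray(self.roi_mean, dtype=float)
        if self.time.ndim != 1 or self.time.size != self.roi_mean.size:
            raise ValueError("time and roi_mean must be 1D of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in ("cell_mean", "bg_mean"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != self.time.size:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)
        if self.bleach_index is not None:
            if not (0 < self.bleach_index < self.time.size):
                raise ValueError("bleach_index out of range")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class NormalizedTrace:
    """Double-normalized recovery: 0 at first post-bleach sample, pre-bleach
    mean 1; time_rel is seconds relative to the bleach."""

    time_rel: np.ndarray
    value: np.ndarray
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.time_rel = np.asarray(self.time_rel, dtype=float)
        self.value = np.asarray(self.value, dtype=float)


@dataclass
class AveragedTrace(NormalizedTrace):
    sd: np.ndarray = field(default_factory=lambda: np.array([]))
    n_per_point: np.ndarray = field(default_factory=lambda: np.array([]))
    n_traces: int = 0


@dataclass
class FrapFit:
    """Fitted single-exponential recovery."""

    mobile_fraction: float
    half_time_s: float
    residual_sse: float = float("nan")
    n_traces_averaged: int = 0

    def __post_init__(self) -> None:
        if self.half_time_s <= 0:
            raise ValueError("half_time_s must be positive")

    @property
    def rate(self) -> float:
        """Recovery rate k = ln2 / t_half (s^-1)."""
        return LN2 / self.half_time_s

    def predict(self, t):
        return frap_model(t, self.mobile_fraction, self.half_time_s)


# --------------------------------------------------------------------------
# bleach detection and normalization
# --------------------------------------------------------------------------

def detect_bleach_frame(trace: FrapTrace, min_drop_fraction: float = 0.2
                        ) -> int:
    """Index of the first post-bleach sample.

    Finds the largest single-step fractional drop of the ROI signal; raises
    if no step exceeds ``min_drop_fraction``.
    """
    roi = trace.roi_mean
    if roi.size < 3:
        raise ValueError("need at least 3 samples to detect a bleach")
    prev = roi[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        drops = np.where(prev > 0, (prev - roi[1:]) / prev, 0.0)
    best = int(np.argmax(drops))
    if drops[best] < min_drop_fraction:
        raise ValueError("no bleach event detected: largest drop "
                         f"{drops[best]:.3f} < {min_drop_fraction}")
    return best + 1


def _double_normalize(time: np.ndarray, series: np.ndarray,
                      bleach_index: int, prebleach_window_s: float,
                      trace_id: str) -> NormalizedTrace:
    t_bleach = time[bleach_index]
    pre = (time < t_bleach) & (time >= t_bleach - prebleach_window_s)
    window_span = t_bleach - time[time < t_bleach].min() if np.any(time < t_bleach) else 0.0
    if not np.any(pre) or window_span < prebleach_window_s - 1e-9:
        raise ValueError(
            f"pre-bleach window shorter than {prebleach_window_s} s")
    f_pre = float(series[pre].mean())
    f0 = float(series[bleach_index])
    denom = f_pre - f0
    if denom <= 0:
        raise ValueError("degenerate normalization: pre-bleach mean does not "
                         "exceed the first post-bleach sample")
    value = (series - f0) / denom
    return NormalizedTrace(time_rel=time - t_bleach, value=value,
                           trace_id=trace_id)


def normalize_condensate_trace(trace: FrapTrace,
                               prebleach_window_s: float = 5.0
                               ) -> NormalizedTrace:
    """Condensate-protocol normalization.

    F_corr(t) = (roi - bg) / (cell - bg) removes background and acquisition
    photobleaching (the whole-cell signal decays with the same illumination
    the ROI sees); the corrected trace is then rescaled to 0 at the first
    post-bleach sample and 1 at the pre-bleach mean. Invariant to affine
    rescaling (gain/offset) of the raw camera signal.
    """
    if trace.cell_mean is None or trace.bg_mean is None:
        raise ValueError("condensate protocol requires cell_mean and bg_mean")
    if trace.bleach_index is None:
        raise ValueError("bleach_index not set; run detect_bleach_frame first")
    denom = trace.cell_mean - trace.bg_mean
    if np.any(denom <= 0):
        raise ValueError("degenerate correction: cell signal does not exceed "
                         "background everywhere")
    f_corr = (trace.roi_mean - trace.bg_mean) / denom
    return _double_normalize(trace.time, f_corr, trace.bleach_index,
                             prebleach_window_s, trace.trace_id)


def normalize_patch_trace(trace: FrapTrace,
                          prebleach_window_s: float = 5.0) -> NormalizedTrace:
    """Endocytic-site protocol: 0-1 normalization applied directly to the ROI
    means of a background-subtracted movie; no further corrections."""
    if trace.bleach_index is None:
        raise ValueError("bleach_index not set; run detect_bleach_frame first")
    return _double_normalize(trace.time, trace.roi_mean, trace.bleach_index,
                             prebleach_window_s, trace.trace_id)


# --------------------------------------------------------------------------
# alignment, averaging, QC
# --------------------------------------------------------------------------

def average_aligned_traces(traces: list[NormalizedTrace],
                           min_coverage: float = 0.5) -> AveragedTrace:
    """Pointwise mean of bleach-aligned normalized traces.

    Traces are linearly interpolated onto a common grid (step = median frame
    interval across traces, anchored at t_rel = 0); grid points covered by
    fewer than ``min_coverage`` of the traces are dropped. Returns the mean
    with per-point SD and coverage counts.
    """
    if not traces:
        raise ValueError("no traces to average")
    dts = [float(np.median(np.diff(tr.time_rel))) for tr in traces]
    dt = float(np.median(dts))
    t_lo = min(float(tr.time_rel.min()) for tr in traces)
    t_hi = max(float(tr.time_rel.max()) for tr in traces)
    grid = dt * np.arange(math.ceil(t_lo / dt - 1e-9),
                          math.floor(t_hi / dt + 1e-9) + 1)
    n = len(traces)
    values = np.full((n, grid.size), np.nan)
    for i, tr in enumerate(traces):
        inside = (grid >= tr.time_rel.min() - 1e-9) & \
                 (grid <= tr.time_rel.max() + 1e-9)
        values[i, inside] = np.interp(grid[inside], tr.time_rel, tr.value)
    coverage = np.sum(~np.isnan(values), axis=0)
    min_n = max(1, math.ceil(min_coverage * n))
    keep = coverage >= min_n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values[:, keep], axis=0)
        sd = np.nanstd(values[:, keep], axis=0, ddof=1) if n > 1 \
            else np.zeros(int(keep.sum()))
    return AveragedTrace(time_rel=grid[keep], value=mean, sd=sd,
                         n_per_point=coverage[keep], n_traces=n)


def qc_exclude_moving(traces: list[FrapTrace],
                      centroid_tracks: dict[str, np.ndarray],
                      max_displacement_um: float,
                      max_prebleach_cv: float | None = None
                      ) -> list[FrapTrace]:
    """Drop events whose structure moved during acquisition.

    ``centroid_tracks`` maps trace_id to an (n, 2) array of (y, x) centroid
    positions in µm; a trace is kept when the net displacement from first to
    last position is within ``max_displacement_um``. Axial movement is not
    observable in 2D, so an optional pre-bleach intensity-stability check
    (coefficient of variation <= ``max_prebleach_cv``) stands in for it.
    Traces with no track are excluded with a warning.
    """
    kept = []
    for tr in traces:
        track = centroid_tracks.get(tr.trace_id)
        if track is None:
            warnings.warn(f"trace {tr.trace_id!r} has no centroid track; "
                          "excluded")
            continue
        track = np.asarray(track, dtype=float)
        disp = float(np.hypot(*(track[-1] - track[0])))
        if disp > max_displacement_um:
            continue
        if max_prebleach_cv is not None and tr.bleach_index is not None:
            pre = tr.roi_mean[:tr.bleach_index]
            if pre.size >= 2 and pre.mean() > 0:
                if pre.std(ddof=0) / pre.mean() > max_prebleach_cv:
                    continue
        kept.append(tr)
    return kept


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def fit_recovery(averaged_trace: NormalizedTrace) -> FrapFit:
    """Least-squares single-exponential fit of the post-bleach recovery.

    Fits value(t) = M * (1 - exp(-ln2 * t / t_half)) to samples with
    t_rel >= 0. Initialization: M0 is the mean of the last 10% of samples;
    t_half,0 comes from a log-linear fit of the residual amplitude
    (M0 - value). Bounds: M in [0, 1.5] (values above 1 can occur for
    endocytic sites where ongoing maturation adds signal), t_half in
    (0, 10 * t_max].
    """
    post = averaged_trace.time_rel >= 0
    t = averaged_trace.time_rel[post]
    v = averaged_trace.value[post]
    if t.size < 5:
        raise ValueError("need at least 5 post-bleach samples to fit")
    t_max = float(t.max())
    n_tail = max(3, int(math.ceil(0.1 * t.size)))
    m0 = float(np.clip(np.mean(v[-n_tail:]), 1e-3, 1.5))
    resid = m0 - v
    pos = resid > 1e-9
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(resid[pos]), 1)[0]
        tau0 = LN2 / max(-slope, LN2 / (10.0 * t_max))
    else:
        tau0 = 0.25 * t_max
    tau0 = float(np.clip(tau0, 1e-6, 10.0 * t_max))
    try:
        popt, _ = curve_fit(frap_model, t, v, p0=(m0, tau0),
                            bounds=([0.0, 1e-9], [1.5, 10.0 * t_max]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"recovery fit failed to converge (init M0={m0:.3g}, "
            f"tau0={tau0:.3g} s): {exc}") from exc
    m_fit, tau_fit = float(popt[0]), float(popt[1])
    sse = float(np.sum((v - frap_model(t, m_fit, tau_fit)) ** 2))
    n_traces = getattr(averaged_trace, "n_traces", 1)
    return FrapFit(mobile_fraction=m_fit, half_time_s=tau_fit,
                   residual_sse=sse, n_traces_averaged=n_traces)


# --------------------------------------------------------------------------
# TIRF patch-trace extraction and reference-channel selection
# --------------------------------------------------------------------------

def circle_pixels(center_yx: tuple[float, float], radius_px: float,
                  shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Indices of pixels whose centers lie within radius_px of the centroid."""
    cy, cx = center_yx
    y0 = max(int(math.floor(cy - radius_px)), 0)
    y1 = min(int(math.ceil(cy + radius_px)), shape[0] - 1)
    x0 = max(int(math.floor(cx - radius_px)), 0)
    x1 = min(int(math.ceil(cx + radius_px)), shape[1] - 1)
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2
    return yy[inside], xx[inside]


def extract_patch_traces(stack, centroids, radius_px: float = 3.0,
                         frame_interval: float | None = None,
                         include_edge: bool = False) -> list[FrapTrace]:
    """Per-frame mean over a small circular ROI at each patch centroid.

    ``stack`` is an ImageStack or a (T, Y, X) array (assumed already
    background-subtracted per the TIRF protocol). Centroids within
    ``radius_px`` of the image edge are flagged and excluded unless
    ``include_edge`` is set.
    """
    from .preprocess import ImageStack
    if isinstance(stack, ImageStack):
        data = stack.data
        if frame_interval is None:
            frame_interval = stack.frame_interval
    else:
        data = np.asarray(stack, dtype=float)
    if data.ndim != 3:
        raise ValueError("extract_patch_traces expects a (T, Y, X) movie")
    if frame_interval is None or frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    ny, nx = data.shape[1:]
    times = np.arange(data.shape[0]) * frame_interval
    traces = []
    for i, (cy, cx) in enumerate(centroids):
        at_edge = (cy < radius_px or cy > ny - 1 - radius_px
                   or cx < radius_px or cx > nx - 1 - radius_px)
        if at_edge and not include_edge:
            continue
        ys, xs = circle_pixels((cy, cx), radius_px, (ny, nx))
        roi = data[:, ys, xs].mean(axis=1)
        traces.append(FrapTrace(time=times, roi_mean=roi,
                                trace_id=f"patch-{i:03d}",
                                edge_flagged=at_edge))
    return traces


def select_patch_events_by_reference(traces_green: list[FrapTrace],
                                     traces_red: list[FrapTrace],
                                     min_peak_delay_s: float = 60.0
                                     ) -> list[FrapTrace]:
    """Keep green events whose reference (red) channel peaks at least
    ``min_peak_delay_s`` after the bleach.

    The reference reporter marks the end of the endocytic event; requiring a
    late peak excludes sites already disassembling when bleached. Pairing is
    by trace_id; unpaired green traces are excluded with a warning.
    """
    red_by_id = {tr.trace_id: tr for tr in traces_red}
    kept = []
    for green in traces_green:
        red = red_by_id.get(green.trace_id)
        if red is None:
            warnings.warn(f"no reference trace for {green.trace_id!r}; "
                          "excluded")
            continue
        if green.bleach_index is None:
            raise ValueError("green trace has no bleach_index")
        t_bleach = green.time[green.bleach_index]
        t_peak = red.time[int(np.argmax(red.roi_mean))]
        if t_peak - t_bleach >= min_peak_delay_s:
            kept.append(green)
    return kept


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

def read_traces_csv(path) -> list[FrapTrace]:
    """Read raw FRAP traces from CSV (columns: time_s, roi, cell, bg,
    trace_id; cell and bg optional)."""
    df = pd.read_csv(path)
    required = {"time_s", "roi", "trace_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for tid, group in df.groupby("trace_id", sort=True):
        group = group.sort_values("time_s")
        traces.append(FrapTrace(
            time=group["time_s"].to_numpy(),
            roi_mean=group["roi"].to_numpy(),
            cell_mean=group["cell"].to_numpy() if "cell" in group else None,
            bg_mean=group["bg"].to_numpy() if "bg" in group else None,
            trace_id=str(tid)))
    return traces


def write_fits_csv(fits: list[FrapFit], path, labels: list[str] | None = None
                   ) -> pd.DataFrame:
    """Write one CSV row per fit (mobile fraction, half-time, rate, SSE, n)."""
    rows = []
    for i, f in enumerate(fits):
        rows.append({
            "label": labels[i] if labels else f"fit-{i:02d}",
            "mobile_fraction": f.mobile_fraction,
            "half_time_s": f.half_time_s,
            "rate_per_s": f.rate,
            "residual_sse": f.residual_sse,
            "n_traces_averaged": f.n_traces_averaged,
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def refit_recovery_csv(path, time_column: str = "time_s",
                       value_column: str = "value") -> FrapFit:
    """Refit a published averaged-recovery table.

    Expects a CSV with a time column (seconds relative to bleach) and a
    normalized recovery column; fits the single-exponential model to the
    t >= 0 samples. Raises FileNotFoundError with guidance when the table is
    absent (supplementary source-data files must be downloaded separately
    and placed under data/source_data/).
    """
    import os
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"{path} not found: download the published source-data table and "
            "place it at this path to refit the original recovery curve")
    df = pd.read_csv(path)
    for col in (time_column, value_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not in {path}")
    trace = NormalizedTrace(time_rel=df[time_column].to_numpy(),
                            value=df[value_column].to_numpy())
    return fit_recovery(trace)
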