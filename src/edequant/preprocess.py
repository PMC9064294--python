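"""Image corrections applied before every measurement.

Rolling-ball background subtraction, mono-exponential photobleaching
correction of movies, threshold-based cell masking from a reference channel,
and maximum-intensity projection. Coordinate convention throughout the
package: 0-based pixel indices, pixel centers at integer coordinates,
row-major (y, x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from skimage import filters, measure, restoration
from scipy import ndimage

__all__ = [
    "ImageStack",
    "CellMask",
    "rolling_ball_background",
    "correct_movie_bleaching",
    "segment_cells",
    "max_project",
]


@dataclass
class ImageStack:
    """Intensity stack with physical metadata.

    ``data`` is (T, Y, X) for movies or (Y, X) for single frames; values are
    arbitrary camera units (AU), nonnegative.
    """

    data: np.ndarray
    pixel_size: float            # µm per pixel
    frame_interval: float = 0.0  # s; 0 for single images / z-stacks
    z_step: float | None = None  # µm, when the leading axis is z
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError("data must be 2D (Y, X) or 3D (T/Z, Y, X)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval < 0:
            raise ValueError("frame_interval must be >= 0")

    @property
    def n_frames(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.data if self.data.ndim == 2 else self.data[i]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class CellMask:
    """Labelled cell mask; label 0 is background."""

    labels: np.ndarray
    pixel_size: float
    projected_area_um2: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not self.projected_area_um2:
            px_area = self.pixel_size ** 2
            ids, counts = np.unique(self.labels, return_counts=True)
            self.projected_area_um2 = {
                int(i): float(c) * px_area for i, c in zip(ids, counts) if i > 0}

    @property
    def n_cells(self) -> int:
        return len(self.projected_area_um2)

    def cell_ids(self) -> list[int]:
        return sorted(self.projected_area_um2)


def rolling_ball_background(image: np.ndarray, radius_px: float
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and subtract a smooth background with the rolling-ball method.

    A ball of the given radius is rolled under the intensity surface; the
    surface it traces is the background. Returns (corrected, background) with
    the corrected image floored at 0. Diffraction-limited spots much smaller
    than the ball radius pass through with their integrated intensity
    essentially preserved.
    """
    image = np.asarray(image, dtype=float)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if radius_px >= min(image.shape[-2:]):
        raise ValueError("rolling-ball radius larger than the image")
    if image.ndim == 2:
        background = restoration.rolling_ball(image, radius=radius_px)
        return np.maximum(image - background, 0.0), background
    if image.ndim == 3:
        corrected = np.empty_like(image)
        background = np.empty_like(image)
        for i in range(image.shape[0]):
            background[i] = restoration.rolling_ball(image[i], radius=radius_px)
            corrected[i] = np.maximum(image[i] - background[i], 0.0)
        return corrected, background
    raise ValueError("image must be 2D or 3D")


def correct_movie_bleaching(stack: ImageStack,
                            mask: np.ndarray | None = None
                            ) -> ImageStack:
    """Divide out global photobleaching fitted as a mono-exponential decay.

    Frame means (within ``mask`` when given, whole frames otherwise) are
    fitted to a * exp(-k t); each frame is divided by its fitted relative
    decay exp(-k t), so corrected frame means are flat in expectation and the
    first frame is preserved. A non-positive fitted rate means there is no
    decay to correct; the input is returned unchanged with a warning.
    """
    data = stack.data
    if data.ndim != 3 or data.shape[0] < 5:
        raise ValueError("bleach correction needs a movie of >= 5 frames")
    if mask is not None:
        m = np.asarray(mask) > 0
        means = np.array([data[f][m].mean() for f in range(data.shape[0])])
    else:
        means = data.mean(axis=(1, 2))
    t = stack.times()
    if stack.frame_interval <= 0:
        t = np.arange(data.shape[0], dtype=float)

    def model(tt, a, k):
        return a * np.exp(-k * tt)

    k0 = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        logm = np.log(np.maximum(means, 1e-12))
        slope = np.polyfit(t, logm, 1)[0]
        k0 = max(-slope, 1e-6)
    try:
        popt, _ = curve_fit(model, t, means, p0=(means[0], k0), maxfev=10000)
    except RuntimeError:
        warnings.warn("bleach fit did not converge; returning input unchanged")
        return stack
    a_fit, k_fit = popt
    if not np.isfinite(k_fit) or k_fit <= 0:
        warnings.warn("no photobleaching decay detected (k <= 0); "
                      "identity correction applied")
        return stack
    decay = np.exp(-k_fit * t)
    corrected = data / decay[:, None, None]
    return ImageStack(data=corrected, pixel_size=stack.pixel_size,
                      frame_interval=stack.frame_interval,
                      z_step=stack.z_step, channel_name=stack.channel_name)


def segment_cells(reference_image: np.ndarray,
                  pixel_size: float,
                  min_area_um2: float = 3.0,
                  smooth_sigma: float = 2.0) -> CellMask:
    """Threshold-based cell masking from a reference channel.

    Gaussian smooth, Otsu threshold, fill holes, label, drop objects below
    ``min_area_um2``. The threshold is data-derived, so the mask is invariant
    to a positive rescaling of the image. An empty or flat image yields an
    empty mask rather than an error.
    """
    img = np.asarray(reference_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_cells expects a single 2D image")
    empty = CellMask(labels=np.zeros(img.shape, dtype=np.int32),
                     pixel_size=pixel_size)
    if img.size == 0 or np.ptp(img) == 0:
        return empty
    smoothed = ndimage.gaussian_filter(img, smooth_sigma)
    if np.ptp(smoothed) == 0:
        return empty
    thresh = filters.threshold_otsu(smoothed)
    binary = smoothed > thresh
    binary = ndimage.binary_fill_holes(binary)
    min_px = max(int(round(min_area_um2 / pixel_size ** 2)), 1)
    labels = measure.label(binary)
    # drop objects below the area floor, then relabel contiguously
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = set(ids[counts >= min_px])
    cleaned = np.where(np.isin(labels, list(keep)), labels, 0)
    labels = measure.label(cleaned > 0).astype(np.int32)
    return CellMask(labels=labels, pixel_size=pixel_size)


def max_project(stack: ImageStack | np.ndarray, axis: int = 0) -> np.ndarray:
    """Per-pixel maximum-intensity projection along the named axis."""
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if data.ndim == 2:
        return data.copy()
    if not (-data.ndim <= axis < data.ndim):
        raise ValueError(f"stack has no axis {axis}")
    return data.max(axis=axis)
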