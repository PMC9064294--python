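"""Per-cell intensity measurements, condensate classification, colocalization.

The concentration-buffering readout compares two per-cell quantities: the
mean pixel intensity over the whole masked cell (*cellular*), which tracks
total expression, and the mean over small cytosolic regions chosen away from
bright structures and vacuoles (*cytosolic*), which tracks the free
cytosolic pool. When a protein phase-separates above a critical
concentration, the cytosolic mean saturates while the cellular mean keeps
rising — condensates absorb the excess.

Condensate identification uses the fact that condensates are much brighter
than normal endocytic patches: an object qualifies when its integrated
intensity exceeds a multiple of the dataset's median patch intensity, or its
diameter exceeds a size threshold. Cells are classified as diffuse (no
membrane objects), patches (discrete objects), or networks (connected object
area above a fraction of the cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import binomtest

__all__ = [
    "IntensityRecord",
    "CellPhenotype",
    "cytosolic_intensity",
    "total_cell_intensity",
    "classify_condensates",
    "fraction_cells_with_phenotype",
    "coloc_fraction",
    "roi_time_trace",
    "detect_vacuoles",
    "bright_structure_mask",
]

LOCALIZATION_CLASSES = ("diffuse", "patches", "networks")


@dataclass
class IntensityRecord:
    cell_id: int
    cytosolic_mean: float
    cellular_mean: float
    replicate_id: str = ""
    condition: str = ""


@dataclass
class CellPhenotype:
    cell_id: int
    has_condensate: bool
    n_condensates: int
    localization_class: str = "patches"

    def __post_init__(self) -> None:
        if self.localization_class not in LOCALIZATION_CLASSES:
            raise ValueError(
                f"localization_class must be one of {LOCALIZATION_CLASSES}")
        if self.has_condensate != (self.n_condensates > 0):
            raise ValueError("has_condensate inconsistent with n_condensates")


# --------------------------------------------------------------------------
# intensity measurements
# --------------------------------------------------------------------------

def detect_vacuoles(image: np.ndarray, cell_mask: np.ndarray,
                    pixel_size: float,
                    intensity_factor: float = 0.5,
                    min_area_um2: float = 0.5) -> np.ndarray:
    """Detect vacuoles as large dark intracellular regions.

    Pixels inside the cell darker than ``intensity_factor`` times the
    within-cell median, in connected patches of at least ``min_area_um2``.
    """
    img = np.asarray(image, dtype=float)
    inside = np.asarray(cell_mask) > 0
    if not inside.any():
        return np.zeros(img.shape, dtype=bool)
    med = float(np.median(img[inside]))
    dark = inside & (img < intensity_factor * med)
    labels, _ = ndimage.label(dark)
    min_px = int(round(min_area_um2 / pixel_size ** 2))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, labels.max() + 1))
    keep = np.isin(labels, 1 + np.flatnonzero(sizes >= min_px))
    return keep


def bright_structure_mask(image: np.ndarray, cell_mask: np.ndarray,
                          smooth_sigma: float = 2.0,
                          offset: float = 10.0) -> np.ndarray:
    """Mask of bright structures (condensates, clusters) inside the cell.

    The image is smoothed so single-pixel shot noise does not trigger the
    rule; pixels exceeding the within-cell median by ``offset`` are flagged.
    Combine with :func:`detect_vacuoles` to build the exclusion mask for
    cytosolic sampling.
    """
    img = ndimage.gaussian_filter(np.asarray(image, dtype=float), smooth_sigma)
    inside = np.asarray(cell_mask) > 0
    if not inside.any():
        return np.zeros(img.shape, dtype=bool)
    med = float(np.median(img[inside]))
    return inside & (img > med + offset)


def cytosolic_intensity(image: np.ndarray,
                        cell_mask: np.ndarray,
                        exclusion_mask: np.ndarray | None = None,
                        box_px: int = 5,
                        n_boxes: int = 5,
                        exclusion_margin_px: int = 3,
                        rng: np.random.Generator | None = None) -> float:
    """Mean of small cytosolic box regions away from bright structures.

    Samples up to ``n_boxes`` non-overlapping ``box_px`` x ``box_px`` squares
    fully inside the cell mask and at least ``exclusion_margin_px`` from any
    excluded pixel (condensates, vacuoles), and returns the mean of the box
    means. Deterministic for a given ``rng``. Raises when no admissible box
    exists for the cell.
    """
    img = np.asarray(image, dtype=float)
    inside = np.asarray(cell_mask) > 0
    if exclusion_mask is not None:
        excl = ndimage.binary_dilation(
            np.asarray(exclusion_mask) > 0,
            iterations=exclusion_margin_px)
        admissible_px = inside & ~excl
    else:
        admissible_px = inside
    # a box anchored at (y, x) is admissible iff every pixel of it is
    ok = ndimage.minimum_filter(admissible_px.astype(np.uint8),
                                size=box_px,
                                mode="constant", cval=0)
    half = box_px // 2
    centers = np.argwhere(ok > 0)
    if centers.size == 0:
        raise ValueError("no admissible cytosolic box in this cell")
    if rng is None:
        rng = np.random.default_rng(0)
    order = rng.permutation(len(centers))
    chosen: list[tuple[int, int]] = []
    box_means: list[float] = []
    for idx in order:
        cy, cx = map(int, centers[idx])
        if any(abs(cy - oy) < box_px and abs(cx - ox) < box_px
               for oy, ox in chosen):
            continue
        box = img[cy - half:cy + half + 1, cx - half:cx + half + 1]
        chosen.append((cy, cx))
        box_means.append(float(box.mean()))
        if len(chosen) >= n_boxes:
            break
    return float(np.mean(box_means))


def total_cell_intensity(image_or_stack: np.ndarray,
                         cell_mask: np.ndarray) -> float:
    """Mean pixel value within the masked cell (over the whole volume when a
    stack is given). Input is assumed background-subtracted."""
    data = np.asarray(image_or_stack, dtype=float)
    mask = np.asarray(cell_mask) > 0
    if not mask.any():
        raise ValueError("empty cell mask")
    if data.ndim == 2:
        return float(data[mask].mean())
    if data.ndim == 3:
        return float(data[:, mask].mean())
    raise ValueError("expected a 2D image or 3D stack")


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def classify_condensates(objects: pd.DataFrame,
                         intensity_ratio_threshold: float = 5.0,
                         size_threshold_um: float = 0.3,
                         network_area_fraction: float = 0.10,
                         all_cell_ids: list[int] | None = None
                         ) -> list[CellPhenotype]:
    """Classify cells by their bright-object content.

    ``objects`` has one row per detected object with columns: cell_id,
    intensity (integrated), diameter_um, and optionally area_fraction (the
    connected-object area as a fraction of the cell area, per cell). An
    object is a condensate when its intensity is at least
    ``intensity_ratio_threshold`` times the dataset median (condensates are
    much brighter than normal patches) or its diameter is at least
    ``size_threshold_um``. Cells with no objects are diffuse; cells whose
    connected object area fraction exceeds ``network_area_fraction`` are
    networks; all others are patches.
    """
    required = {"cell_id", "intensity", "diameter_um"}
    missing = required - set(objects.columns)
    if missing:
        raise ValueError(f"objects table missing columns: {sorted(missing)}")
    if len(objects) == 0:
        raise ValueError("empty object table: dataset median is undefined")
    median_intensity = float(objects["intensity"].median())
    if median_intensity <= 0:
        raise ValueError("non-positive median object intensity")
    is_condensate = (
        (objects["intensity"] >= intensity_ratio_threshold * median_intensity)
        | (objects["diameter_um"] >= size_threshold_um))
    out = []
    seen = set()
    for cid, group in objects.groupby("cell_id", sort=True):
        seen.add(int(cid))
        n_cond = int(is_condensate[group.index].sum())
        if ("area_fraction" in group
                and float(group["area_fraction"].max()) > network_area_fraction):
            cls = "networks"
        else:
            cls = "patches"
        out.append(CellPhenotype(cell_id=int(cid),
                                 has_condensate=n_cond > 0,
                                 n_condensates=n_cond,
                                 localization_class=cls))
    # cells with no detected membrane objects at all are diffuse
    for cid in (all_cell_ids or []):
        if int(cid) not in seen:
            out.append(CellPhenotype(cell_id=int(cid), has_condensate=False,
                                     n_condensates=0,
                                     localization_class="diffuse"))
    out.sort(key=lambda p: p.cell_id)
    return out


def fraction_cells_with_phenotype(phenotypes: pd.DataFrame,
                                  flag_column: str = "positive"
                                  ) -> pd.DataFrame:
    """Fraction of positive cells per condition: per-replicate fractions,
    then mean ± SD across replicates.

    ``phenotypes`` has one row per cell with columns condition, replicate and
    a boolean ``flag_column``. Empty replicates are dropped with a warning.
    """
    import warnings
    required = {"condition", "replicate", flag_column}
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for cond, group in phenotypes.groupby("condition", sort=True):
        fracs = []
        for rep, sub in group.groupby("replicate", sort=True):
            if len(sub) == 0:
                warnings.warn(f"empty replicate {rep!r} in {cond!r}; skipped")
                continue
            fracs.append(float(sub[flag_column].mean()))
        rows.append({
            "condition": cond,
            "n_replicates": len(fracs),
            "fraction_mean": float(np.mean(fracs)),
            "fraction_sd": float(np.std(fracs, ddof=1)) if len(fracs) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# colocalization
# --------------------------------------------------------------------------

def coloc_fraction(green_centroids_um: np.ndarray,
                   red_centroids_um: np.ndarray,
                   max_distance_um: float = 0.25,
                   confidence: float = 0.99) -> dict[str, float]:
    """Fraction of green objects with a red punctum within reach.

    A green object colocalizes when any red centroid lies within
    ``max_distance_um``. Returns the fraction with a binomial confidence
    interval (Clopper-Pearson).
    """
    green = np.asarray(green_centroids_um, dtype=float).reshape(-1, 2)
    red = np.asarray(red_centroids_um, dtype=float).reshape(-1, 2)
    if len(green) == 0:
        raise ValueError("no green objects: colocalized fraction undefined")
    if len(red) == 0:
        hits = 0
    else:
        d = np.hypot(green[:, None, 0] - red[None, :, 0],
                     green[:, None, 1] - red[None, :, 1])
        hits = int(np.sum(d.min(axis=1) <= max_distance_um))
    n = len(green)
    ci = binomtest(hits, n).proportion_ci(confidence_level=confidence,
                                          method="exact")
    return {"fraction": hits / n, "n_green": n, "n_colocalized": hits,
            "ci_low": float(ci.low), "ci_high": float(ci.high)}


# --------------------------------------------------------------------------
# ROI time traces
# --------------------------------------------------------------------------

def roi_time_trace(stack: np.ndarray,
                   roi: tuple[int, int, int, int],
                   background_roi: tuple[int, int, int, int] | None = None
                   ) -> np.ndarray:
    """Per-frame mean inside a rectangular ROI, minus the per-frame mean of a
    background ROI when given. ROIs are (y, x, height, width) in pixels."""
    data = np.asarray(stack, dtype=float)
    if data.ndim == 2:
        data = data[None]
    ny, nx = data.shape[1:]

    def crop(r):
        y, x, h, w = r
        if y < 0 or x < 0 or h <= 0 or w <= 0 or y + h > ny or x + w > nx:
            raise ValueError(f"ROI {r} outside the {ny}x{nx} image")
        return data[:, y:y + h, x:x + w].mean(axis=(1, 2))

    trace = crop(roi)
    if background_roi is not None:
        trace = trace - crop(background_roi)
    return trace
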