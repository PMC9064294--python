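"""Ground-truthed synthetic fluorescence microscopy for yeast endocytosis.

Everything downstream of raw images in this package — FRAP normalisation and
fitting, patch detection/tracking, density and lifetime estimation, intensity
buffering and colocalization measurements — is validated against movies
generated here, where the true event log is known exactly.

The physical picture: roughly spherical yeast cells (radius ~2-3 µm) sit on a
coverslip and are imaged in widefield or TIRF. Diffraction-limited endocytic
patches are born on the plasma membrane as a homogeneous Poisson process on
the sphere surface, live for a stochastic lifetime (order 1-2 minutes), and
are rendered as isotropic Gaussians at their projected position. A few much
brighter, larger, long-lived condensates may also be present. The detector
model is the standard camera chain: global exponential photobleaching, then
Poisson shot noise, then additive Gaussian read noise, clipped at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

LN2 = math.log(2.0)

__all__ = [
    "SimulationConfig",
    "FrapParams",
    "Cell",
    "PatchEvent",
    "Condensate",
    "GroundTruth",
    "frap_model",
    "make_cell_layout",
    "sample_patch_events",
    "render_frame",
    "render_movie",
    "render_reference_image",
    "simulate_movie",
    "simulate_frap_experiment",
    "simulate_frap_patch_movies",
    "simulate_two_channel_movie",
]


# --------------------------------------------------------------------------
# configuration and ground-truth records
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of a synthetic movie.

    All physical quantities carry explicit units; pixel quantities are
    converted through ``pixel_size``. ``rng_seed`` fixes every random choice:
    the same config renders byte-identical stacks and truth tables.
    """

    image_shape: tuple[int, int] = (128, 128)   # (ny, nx) pixels
    pixel_size: float = 0.1                     # µm per pixel
    frame_interval: float = 2.0                 # s
    n_frames: int = 1
    n_cells: int = 1
    cell_radius_um: tuple[float, float] = (2.0, 2.5)   # sampled uniformly
    patch_birth_rate: float = 5e-4              # events µm⁻² s⁻¹ of membrane
    patch_lifetime_mean: float = 90.0           # s
    patch_lifetime_dist: str = "gamma"          # fixed | exponential | gamma
    patch_lifetime_shape: float = 4.0           # gamma shape parameter
    patch_amplitude: float = 50.0               # AU, peak above background
    patch_amplitude_cv: float = 0.2             # lognormal spread
    psf_sigma: float = 1.3                      # px, isotropic Gaussian PSF
    condensate_radius_um: float = 0.5
    condensate_amplitude: float = 500.0
    condensates_per_cell: int = 0
    cytosol_level: float = 0.0                  # AU, uniform fill inside cell
    background_level: float = 100.0             # AU, camera offset + medium
    bleach_rate: float = 0.0                    # s⁻¹, global photobleaching
    shot_noise: bool = True
    read_noise_sd: float = 2.0                  # AU
    tirf: bool = False                          # render near hemisphere only
    far_attenuation: float = 1.0                # dimming of far-hemisphere spots
    rng_seed: int = 0

    def validate(self) -> list[str]:
        """Return a list of violation messages (empty when valid)."""
        errors: list[str] = []
        if len(self.image_shape) != 2 or any(s < 8 for s in self.image_shape):
            errors.append("image_shape must be (ny, nx) with ny, nx >= 8")
        for name in ("pixel_size", "frame_interval", "patch_lifetime_mean",
                     "psf_sigma"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        for name in ("patch_birth_rate", "patch_amplitude", "patch_amplitude_cv",
                     "condensate_radius_um", "condensate_amplitude",
                     "cytosol_level", "background_level", "bleach_rate",
                     "read_noise_sd", "far_attenuation"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be nonnegative")
        if self.n_frames < 1:
            errors.append("n_frames must be >= 1")
        if self.n_cells < 0:
            errors.append("n_cells must be >= 0")
        lo, hi = self.cell_radius_um
        if not (0 < lo <= hi):
            errors.append("cell_radius_um must satisfy 0 < min <= max")
        if self.patch_lifetime_dist not in ("fixed", "exponential", "gamma"):
            errors.append(
                f"unknown patch_lifetime_dist {self.patch_lifetime_dist!r}")
        if self.patch_lifetime_shape <= 0:
            errors.append("patch_lifetime_shape must be positive")
        # the largest allowed cell must fit inside the field
        max_r_px = hi / self.pixel_size
        if self.n_cells > 0 and 2 * max_r_px >= min(self.image_shape):
            errors.append("image_shape too small for cell_radius_um")
        return errors

    def validated(self) -> "SimulationConfig":
        errors = self.validate()
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))
        return self


@dataclass
class FrapParams:
    """Single-exponential FRAP ground truth.

    The normalized recovery follows value(t) = M * (1 - exp(-ln2 * t / t_half))
    for t >= 0 after the bleach, with value 0 immediately post-bleach and 1 as
    the pre-bleach reference level. ``bleach_depth`` is the fractional drop of
    the corrected signal at the bleach (0.8 means the ROI falls to 20% of its
    pre-bleach level).
    """

    mobile_fraction: float = 0.63
    half_time_s: float = 22.0
    bleach_depth: float = 0.8
    bleach_time_s: float = 10.0

    def validate(self) -> None:
        if self.mobile_fraction < 0:
            raise ValueError("mobile_fraction must be >= 0")
        if self.half_time_s <= 0:
            raise ValueError("half_time_s must be positive")
        if not (0 < self.bleach_depth <= 1):
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.bleach_time_s < 0:
            raise ValueError("bleach_time_s must be >= 0")


@dataclass
class Cell:
    cell_id: int
    center_px: tuple[float, float]   # (y, x)
    radius_um: float

    def radius_px(self, pixel_size: float) -> float:
        return self.radius_um / pixel_size


@dataclass
class PatchEvent:
    """One endocytic site: born on the membrane, dies after its lifetime.

    ``membrane_position_um`` is (x, y, z) relative to the cell center, on the
    sphere of the cell radius; z > 0 is the far hemisphere (away from the
    coverslip). ``projected_position_px`` is the (y, x) image position.
    """

    cell_id: int
    birth_time: float
    death_time: float
    membrane_position_um: tuple[float, float, float]
    projected_position_px: tuple[float, float]
    amplitude: float
    truncated_start: bool = False
    truncated_end: bool = False

    @property
    def lifetime(self) -> float:
        return self.death_time - self.birth_time

    def alive_at(self, t: float) -> bool:
        return self.birth_time <= t < self.death_time


@dataclass
class Condensate:
    cell_id: int
    position_px: tuple[float, float]
    radius_um: float
    amplitude: float
    z_sign: float = -1.0   # near hemisphere by default


@dataclass
class GroundTruth:
    """Event log of a simulation; every rendered object has one record."""

    cells: list[Cell] = field(default_factory=list)
    patch_events: list[PatchEvent] = field(default_factory=list)
    condensates: list[Condensate] = field(default_factory=list)
    frap: FrapParams | None = None
    coloc_table: list[dict] | None = None   # two-channel partner records

    def live_patches(self, t: float) -> list[PatchEvent]:
        return [e for e in self.patch_events if e.alive_at(t)]


# --------------------------------------------------------------------------
# model curve
# --------------------------------------------------------------------------

def frap_model(t, mobile_fraction: float, half_time_s: float):
    """Normalized single-exponential recovery M*(1 - exp(-ln2 * t / t_half))."""
    t = np.asarray(t, dtype=float)
    return mobile_fraction * (1.0 - np.exp(-LN2 * t / half_time_s))


# --------------------------------------------------------------------------
# layout and event sampling
# --------------------------------------------------------------------------

def make_cell_layout(config: SimulationConfig,
                     rng: np.random.Generator,
                     max_tries: int = 2000) -> list[Cell]:
    """Place non-overlapping spherical cells fully inside the field of view.

    Rejection sampling with a retry budget; raises RuntimeError if the
    requested cells cannot be placed.
    """
    config.validated()
    ny, nx = config.image_shape
    cells: list[Cell] = []
    tries = 0
    while len(cells) < config.n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {config.n_cells} cells in "
                f"{config.image_shape} after {max_tries} tries")
        tries += 1
        r_um = rng.uniform(*config.cell_radius_um)
        r_px = r_um / config.pixel_size
        if 2 * r_px >= min(ny, nx):
            continue
        cy = rng.uniform(r_px, ny - 1 - r_px)
        cx = rng.uniform(r_px, nx - 1 - r_px)
        ok = True
        for other in cells:
            o_px = other.radius_px(config.pixel_size)
            d = math.hypot(cy - other.center_px[0], cx - other.center_px[1])
            if d <= r_px + o_px:
                ok = False
                break
        if ok:
            cells.append(Cell(cell_id=len(cells) + 1,
                              center_px=(cy, cx), radius_um=r_um))
    return cells


def _sample_lifetimes(n: int, dist: str, mean: float, shape: float,
                      rng: np.random.Generator) -> np.ndarray:
    if dist == "fixed":
        return np.full(n, mean)
    if dist == "exponential":
        return rng.exponential(mean, size=n)
    if dist == "gamma":
        return rng.gamma(shape, mean / shape, size=n)
    raise ValueError(f"unknown lifetime distribution {dist!r}")


def sample_patch_events(cell: Cell,
                        birth_rate: float,
                        lifetime_dist: str,
                        duration: float,
                        rng: np.random.Generator,
                        *,
                        lifetime_mean: float = 90.0,
                        lifetime_shape: float = 4.0,
                        amplitude: float = 50.0,
                        amplitude_cv: float = 0.0,
                        pixel_size: float = 0.1,
                        t_start: float = 0.0) -> list[PatchEvent]:
    """Sample membrane patch events for one cell.

    Births are a homogeneous Poisson process on the sphere surface
    (S = 4*pi*r^2) over [t_start, t_start + duration); positions are uniform
    on the sphere; lifetimes are i.i.d. from the configured distribution.
    Events still alive at t_start + duration are kept and flagged truncated.
    Setting ``t_start`` negative provides burn-in so the live-patch count is
    at steady state by t = 0.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    surface = 4.0 * math.pi * cell.radius_um ** 2
    n = rng.poisson(birth_rate * surface * duration)
    births = np.sort(rng.uniform(t_start, t_start + duration, size=n))
    lifetimes = _sample_lifetimes(n, lifetime_dist, lifetime_mean,
                                  lifetime_shape, rng)
    # uniform on the sphere: z uniform in [-r, r], azimuth uniform
    z = rng.uniform(-cell.radius_um, cell.radius_um, size=n)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    rho = np.sqrt(np.maximum(cell.radius_um ** 2 - z ** 2, 0.0))
    x = rho * np.cos(phi)
    y = rho * np.sin(phi)
    if amplitude_cv > 0:
        sigma_log = math.sqrt(math.log(1.0 + amplitude_cv ** 2))
        amps = amplitude * rng.lognormal(-0.5 * sigma_log ** 2, sigma_log,
                                         size=n)
    else:
        amps = np.full(n, amplitude)
    t_end = t_start + duration
    events = []
    for i in range(n):
        death = births[i] + lifetimes[i]
        events.append(PatchEvent(
            cell_id=cell.cell_id,
            birth_time=float(births[i]),
            death_time=float(death),
            membrane_position_um=(float(x[i]), float(y[i]), float(z[i])),
            projected_position_px=(
                cell.center_px[0] + y[i] / pixel_size,
                cell.center_px[1] + x[i] / pixel_size),
            amplitude=float(amps[i]),
            truncated_start=births[i] < 0.0,
            truncated_end=death > t_end,
        ))
    return events


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _add_gaussian(frame: np.ndarray, y: float, x: float,
                  amplitude: float, sigma: float) -> None:
    """Add an isotropic Gaussian peak in place, on a local window."""
    ny, nx = frame.shape
    half = max(3, int(math.ceil(4.0 * sigma)))
    y0, y1 = int(math.floor(y)) - half, int(math.floor(y)) + half + 1
    x0, x1 = int(math.floor(x)) - half, int(math.floor(x)) + half + 1
    y0c, y1c = max(y0, 0), min(y1, ny)
    x0c, x1c = max(x0, 0), min(x1, nx)
    if y0c >= y1c or x0c >= x1c:
        return
    yy = np.arange(y0c, y1c, dtype=float)[:, None] - y
    xx = np.arange(x0c, x1c, dtype=float)[None, :] - x
    frame[y0c:y1c, x0c:x1c] += amplitude * np.exp(
        -(yy ** 2 + xx ** 2) / (2.0 * sigma ** 2))


def _cytosol_image(config: SimulationConfig, cells: list[Cell]) -> np.ndarray:
    ny, nx = config.image_shape
    img = np.zeros((ny, nx), dtype=float)
    if config.cytosol_level <= 0:
        return img
    yy, xx = np.mgrid[0:ny, 0:nx]
    for cell in cells:
        r_px = cell.radius_px(config.pixel_size)
        inside = ((yy - cell.center_px[0]) ** 2
                  + (xx - cell.center_px[1]) ** 2) <= r_px ** 2
        img[inside] += config.cytosol_level
    return img


def _condensate_sigma_px(radius_um: float, config: SimulationConfig) -> float:
    # apparent width: object radius convolved with the PSF
    r_px = radius_um / config.pixel_size
    return math.sqrt(config.psf_sigma ** 2 + (r_px / 2.0) ** 2)


def _visible_amplitude(event: PatchEvent, config: SimulationConfig) -> float:
    z = event.membrane_position_um[2]
    if z > 0:   # far hemisphere
        if config.tirf:
            return 0.0
        return event.amplitude * config.far_attenuation
    return event.amplitude


def render_frame(t: float, cells: list[Cell], events: list[PatchEvent],
                 condensates: list[Condensate],
                 config: SimulationConfig) -> np.ndarray:
    """Noiseless, unbleached frame at time t (background + all live objects)."""
    ny, nx = config.image_shape
    frame = np.full((ny, nx), config.background_level, dtype=float)
    frame += _cytosol_image(config, cells)
    for ev in events:
        if not ev.alive_at(t):
            continue
        amp = _visible_amplitude(ev, config)
        if amp <= 0:
            continue
        _add_gaussian(frame, ev.projected_position_px[0],
                      ev.projected_position_px[1], amp, config.psf_sigma)
    for cond in condensates:
        _add_gaussian(frame, cond.position_px[0], cond.position_px[1],
                      cond.amplitude,
                      _condensate_sigma_px(cond.radius_um, config))
    return frame


def _apply_noise(frame: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    out = frame
    if config.shot_noise:
        out = rng.poisson(np.maximum(out, 0.0)).astype(float)
    if config.read_noise_sd > 0:
        out = out + rng.normal(0.0, config.read_noise_sd, size=out.shape)
    return np.maximum(out, 0.0)


def _place_condensates(cells: list[Cell], config: SimulationConfig,
                       rng: np.random.Generator) -> list[Condensate]:
    out = []
    for cell in cells:
        for _ in range(config.condensates_per_cell):
            # on the membrane, near hemisphere, away from the projected rim
            z_frac = rng.uniform(0.5, 0.95)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            rho_um = cell.radius_um * math.sqrt(1.0 - z_frac ** 2)
            out.append(Condensate(
                cell_id=cell.cell_id,
                position_px=(
                    cell.center_px[0] + rho_um * math.sin(phi) / config.pixel_size,
                    cell.center_px[1] + rho_um * math.cos(phi) / config.pixel_size),
                radius_um=config.condensate_radius_um,
                amplitude=config.condensate_amplitude))
    return out


def render_movie(layout: list[Cell],
                 events: list[PatchEvent],
                 config: SimulationConfig,
                 rng: np.random.Generator,
                 *,
                 condensates: list[Condensate] | None = None,
                 frame_times: np.ndarray | None = None,
                 ) -> tuple["np.ndarray", GroundTruth]:
    """Render a T x Y x X movie with the camera noise chain.

    Each frame is the noiseless scene scaled by exp(-bleach_rate * t), then
    Poisson shot noise (if enabled), then Gaussian read noise, clipped at 0.
    Returns the stack and the GroundTruth event log.
    """
    config.validated()
    if frame_times is None:
        frame_times = np.arange(config.n_frames) * config.frame_interval
    frame_times = np.asarray(frame_times, dtype=float)
    if condensates is None:
        condensates = _place_condensates(layout, config, rng)
    stack = np.empty((len(frame_times), *config.image_shape), dtype=float)
    for f, t in enumerate(frame_times):
        frame = render_frame(t, layout, events, condensates, config)
        frame = frame * math.exp(-config.bleach_rate * t)
        stack[f] = _apply_noise(frame, config, rng)
    truth = GroundTruth(cells=list(layout), patch_events=list(events),
                        condensates=list(condensates))
    return stack, truth


def render_reference_image(layout: list[Cell], config: SimulationConfig,
                           rng: np.random.Generator,
                           cytosol_level: float = 50.0) -> np.ndarray:
    """Single reference-channel frame: cytosol-filled cells, no patches.

    Emulates a cytosolic/membrane marker channel used only for cell masking.
    """
    ref_cfg = replace(config, cytosol_level=cytosol_level)
    frame = np.full(config.image_shape, config.background_level, dtype=float)
    frame += _cytosol_image(ref_cfg, layout)
    return _apply_noise(frame, config, rng)


# --------------------------------------------------------------------------
# FRAP simulation
# --------------------------------------------------------------------------

def _frap_corrected_curve(times: np.ndarray, params: FrapParams) -> np.ndarray:
    """Ideal corrected (bleach-normalised) ROI signal: 1 pre-bleach, drop to
    (1 - depth), then recovery toward 1 - depth * (1 - M)."""
    floor = 1.0 - params.bleach_depth
    curve = np.ones_like(times, dtype=float)
    post = times >= params.bleach_time_s
    curve[post] = floor + params.bleach_depth * frap_model(
        times[post] - params.bleach_time_s,
        params.mobile_fraction, params.half_time_s)
    return curve


def simulate_frap_experiment(frap_params: FrapParams,
                             noise_sd: float,
                             n_traces: int,
                             rng: np.random.Generator,
                             *,
                             frame_interval: float = 1.0,
                             duration_s: float = 130.0,
                             cell_bleach_rate: float = 0.004,
                             cell_level: float = 1000.0,
                             bg_level: float = 100.0,
                             ):
    """Simulate condensate-protocol FRAP traces in raw camera units.

    The ideal corrected curve (pre-bleach plateau 1, instantaneous drop by
    ``bleach_depth``, single-exponential recovery with mobile fraction M and
    half-time t_half) is mapped back to raw units through a whole-cell
    acquisition-bleaching channel cell(t) = cell_level * exp(-k t) and a
    constant background channel:

        roi(t) = bg + (cell(t) - bg) * (curve(t) + eps_t),  eps ~ N(0, noise_sd)

    so ``noise_sd`` is the noise amplitude on the corrected (normalized)
    scale. Returns (traces, GroundTruth); traces are FrapTrace objects from
    :mod:`edequant.frap`.
    """
    from .frap import FrapTrace   # local import to avoid a cycle

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    frap_params.validate()
    if frap_params.bleach_time_s >= duration_s:
        raise ValueError("bleach_time_s must fall inside the trace")
    times = np.arange(0.0, duration_s, frame_interval)
    bleach_index = int(np.searchsorted(times, frap_params.bleach_time_s))
    ideal = _frap_corrected_curve(times, frap_params)
    traces = []
    for i in range(n_traces):
        eps = rng.normal(0.0, noise_sd, size=times.size) if noise_sd > 0 else 0.0
        cell = cell_level * np.exp(-cell_bleach_rate * times)
        bg = np.full_like(times, bg_level)
        roi = bg + (cell - bg) * (ideal + eps)
        traces.append(FrapTrace(time=times.copy(), roi_mean=roi,
                                cell_mean=cell, bg_mean=bg,
                                bleach_index=bleach_index,
                                trace_id=f"sim-{i:03d}"))
    truth = GroundTruth(frap=frap_params)
    return traces, truth


def simulate_frap_patch_movies(frap_params: FrapParams,
                               noise_sd: float,
                               n_traces: int,
                               rng: np.random.Generator,
                               *,
                               frame_interval: float = 0.5,
                               duration_s: float = 70.0,
                               field_px: int = 25,
                               amplitude: float = 200.0,
                               psf_sigma: float = 1.3,
                               bg_level: float = 0.0,
                               roi_radius_px: int = 3,
                               ):
    """Simulate endocytic-site (TIRF protocol) FRAP as rendered movies.

    Each movie holds one diffraction-limited patch at the field center whose
    amplitude follows the ideal FRAP curve; ``noise_sd`` is calibrated to the
    0-1 normalized scale of the 3-px circular ROI mean, and realised as
    Gaussian pixel noise. Background-subtracted input is assumed by the
    protocol, so ``bg_level`` defaults to 0. Returns
    (list of (stack, centroid_yx), GroundTruth).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    frap_params.validate()
    times = np.arange(0.0, duration_s, frame_interval)
    ideal = _frap_corrected_curve(times, frap_params)
    center = (field_px // 2, field_px // 2)

    # ROI gain: mean over the 29-pixel disc of a unit-amplitude Gaussian
    yy, xx = np.mgrid[0:field_px, 0:field_px]
    disc = ((yy - center[0]) ** 2 + (xx - center[1]) ** 2) <= roi_radius_px ** 2
    unit = np.exp(-(((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
                    / (2.0 * psf_sigma ** 2)))
    roi_gain = float(unit[disc].mean())
    n_roi_px = int(disc.sum())
    # pixel noise sd that yields `noise_sd` on the normalized ROI scale
    pixel_sd = (noise_sd * frap_params.bleach_depth * amplitude * roi_gain
                * math.sqrt(n_roi_px))

    movies = []
    for _ in range(n_traces):
        stack = np.empty((times.size, field_px, field_px), dtype=float)
        for f, t in enumerate(times):
            frame = np.full((field_px, field_px), bg_level, dtype=float)
            _add_gaussian(frame, center[0], center[1],
                          amplitude * ideal[f], psf_sigma)
            if pixel_sd > 0:
                frame += rng.normal(0.0, pixel_sd, size=frame.shape)
            stack[f] = frame
        movies.append((stack, center))
    truth = GroundTruth(frap=frap_params)
    return movies, truth


def simulate_expression_series(levels,
                               saturation: float,
                               config: SimulationConfig,
                               rng: np.random.Generator,
                               n_condensates: int = 2,
                               ):
    """Cells over an expression series with a saturating cytosolic pool.

    For each total expression level E (AU per cytosolic pixel equivalent),
    one cell is rendered whose cytosol sits at min(E, saturation) while the
    excess (E - saturation) is deposited into a few bright condensates whose
    integrated intensity accounts exactly for the excess — the intensity
    bookkeeping of concentration buffering by phase separation. Returns
    (list of images, list of GroundTruth).
    """
    images, truths = [], []
    for level in levels:
        cfg = replace(config, n_cells=1,
                      cytosol_level=min(float(level), saturation),
                      condensates_per_cell=0)
        layout = make_cell_layout(cfg, rng)
        cell = layout[0]
        conds: list[Condensate] = []
        excess = max(float(level) - saturation, 0.0)
        if excess > 0:
            area_px = math.pi * cell.radius_px(cfg.pixel_size) ** 2
            sigma_c = _condensate_sigma_px(cfg.condensate_radius_um, cfg)
            amp = excess * area_px / n_condensates / (2.0 * math.pi * sigma_c ** 2)
            for _ in range(n_condensates):
                ang = rng.uniform(0.0, 2.0 * math.pi)
                rho = cell.radius_px(cfg.pixel_size) * 0.5 * math.sqrt(rng.uniform(0, 1))
                conds.append(Condensate(
                    cell_id=cell.cell_id,
                    position_px=(cell.center_px[0] + rho * math.sin(ang),
                                 cell.center_px[1] + rho * math.cos(ang)),
                    radius_um=cfg.condensate_radius_um,
                    amplitude=amp))
        stack, truth = render_movie(layout, [], cfg, rng, condensates=conds,
                                    frame_times=np.array([0.0]))
        images.append(stack[0])
        truths.append(truth)
    return images, truths


def simulate_movie(config: SimulationConfig,
                   *,
                   burn_in_s: float | None = None,
                   frame_times: np.ndarray | None = None,
                   ):
    """End-to-end convenience: layout, patch events, rendered movie.

    All randomness derives from ``config.rng_seed``, so a fixed config is
    bit-reproducible. ``burn_in_s`` extends event sampling before t = 0 so
    the live-patch count is at steady state from the first frame (default:
    5 mean lifetimes when the birth rate is nonzero).
    """
    config.validated()
    rng = np.random.default_rng(config.rng_seed)
    layout = make_cell_layout(config, rng)
    if burn_in_s is None:
        burn_in_s = 5.0 * config.patch_lifetime_mean if config.patch_birth_rate > 0 else 0.0
    duration = (config.n_frames - 1) * config.frame_interval + config.frame_interval
    if frame_times is not None:
        duration = float(np.max(frame_times)) + config.frame_interval
    events: list[PatchEvent] = []
    for cell in layout:
        events.extend(sample_patch_events(
            cell, config.patch_birth_rate, config.patch_lifetime_dist,
            duration + burn_in_s, rng,
            lifetime_mean=config.patch_lifetime_mean,
            lifetime_shape=config.patch_lifetime_shape,
            amplitude=config.patch_amplitude,
            amplitude_cv=config.patch_amplitude_cv,
            pixel_size=config.pixel_size,
            t_start=-burn_in_s))
    stack, truth = render_movie(layout, events, config, rng,
                                frame_times=frame_times)
    return stack, truth


# --------------------------------------------------------------------------
# two-channel colocalization simulation
# --------------------------------------------------------------------------

def simulate_two_channel_movie(config: SimulationConfig,
                               coloc_fraction: float,
                               rng: np.random.Generator,
                               *,
                               offset_um: float = 0.1,
                               n_red_independent_per_cell: int = 2,
                               ):
    """Render paired green/red frames with a programmed colocalized fraction.

    Each green condensate receives a red partner punctum (within
    ``offset_um`` of its centroid) with probability ``coloc_fraction``; the
    remaining red puncta are placed independently on the cell. Returns
    (green_stack, red_stack, GroundTruth) where the truth table records which
    green objects have a deliberate partner.
    """
    if not (0.0 <= coloc_fraction <= 1.0):
        raise ValueError("coloc_fraction must be in [0, 1]")
    config.validated()
    layout = make_cell_layout(config, rng)
    greens = _place_condensates(layout, config, rng)
    cell_by_id = {c.cell_id: c for c in layout}

    reds: list[Condensate] = []
    table: list[dict] = []
    for gi, g in enumerate(greens):
        partnered = bool(rng.random() < coloc_fraction)
        if partnered:
            ang = rng.uniform(0, 2 * math.pi)
            d_px = rng.uniform(0, offset_um) / config.pixel_size
            reds.append(Condensate(
                cell_id=g.cell_id,
                position_px=(g.position_px[0] + d_px * math.sin(ang),
                             g.position_px[1] + d_px * math.cos(ang)),
                radius_um=config.condensate_radius_um,
                amplitude=config.condensate_amplitude))
        table.append({"green_index": gi, "cell_id": g.cell_id,
                      "partnered": partnered})
    for cell in layout:
        for _ in range(n_red_independent_per_cell):
            ang = rng.uniform(0, 2 * math.pi)
            rho = cell.radius_px(config.pixel_size) * math.sqrt(rng.uniform(0, 0.8))
            reds.append(Condensate(
                cell_id=cell.cell_id,
                position_px=(cell.center_px[0] + rho * math.sin(ang),
                             cell.center_px[1] + rho * math.cos(ang)),
                radius_um=config.condensate_radius_um,
                amplitude=config.condensate_amplitude))

    green_stack, _ = render_movie(layout, [], config, rng, condensates=greens,
                                  frame_times=np.array([0.0]))
    red_stack, _ = render_movie(layout, [], config, rng, condensates=reds,
                                frame_times=np.array([0.0]))
    truth = GroundTruth(cells=layout, condensates=greens, coloc_table=table)
    truth.red_condensates = reds   # type: ignore[attr-defined]
    return green_stack, red_stack, truth
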