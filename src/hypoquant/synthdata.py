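"""Synthetic imaging inputs with known ground truth.

Every pipeline stage in this package is verified by parameter recovery on
synthetic data emulating the three assay types it quantifies:

* two-channel confocal series of a cell-wall lattice carrying a ratiometric
  pH sensor (pH-insensitive reference channel, pH-quenched sense channel),
  with a step-like apoplastic acidification at a configurable onset time;
* single-channel scanner-like silhouettes of a hypocotyl segment whose
  length is constant through a lag phase and then grows linearly;
* luminescence time courses with a delayed saturating rise, and bending
  rod series for gravitropic angle measurement.

The sense-channel brightness follows the single-site protonation sigmoid

    B(pH) = 1 / (1 + 10**(pKa - pH)),

so lower pH always yields a lower (noiseless) sense/reference ratio.  Each
generator returns its output together with a :class:`GroundTruth` record;
analysis code never reads the ground truth — only tests compare against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .series import ImageSeries, Trace

__all__ = [
    "PHSeriesConfig",
    "GrowthSeriesConfig",
    "GroundTruth",
    "quench_fraction",
    "ph_schedule",
    "wall_lattice",
    "render_rod",
    "generate_ph_series",
    "generate_flank_zstack",
    "generate_elongation_series",
    "generate_luminescence_trace",
    "luminescence_stack",
    "generate_bending_series",
    "inject_drift",
]


def _require(cond: bool, fieldname: str, message: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {message}")


def quench_fraction(ph: np.ndarray | float, pka: float) -> np.ndarray | float:
    """Relative sense-channel brightness B(pH) = 1 / (1 + 10**(pKa - pH)).

    Strictly increasing in pH; equals 0.5 at pH == pKa.
    """
    return 1.0 / (1.0 + 10.0 ** (pka - np.asarray(ph, dtype=float)))


@dataclass
class GroundTruth:
    """Latent variables of a synthetic dataset, for test-time comparison only.

    Which fields are populated depends on the generator.  Analysis modules
    must never read this object; it exists so tests can close the loop
    between generated truth and recovered estimates.
    """

    true_onset_min: float | None = None
    ph_series: np.ndarray | None = None          # per-frame uniform pH
    ph_map_series: np.ndarray | None = None      # (T, H, W) per-pixel pH
    wall_mask: np.ndarray | None = None          # (H, W) lattice support
    true_length_series: np.ndarray | None = None  # (T,) px, noiseless
    true_angle_series_deg: np.ndarray | None = None
    clean_trace: np.ndarray | None = None        # noiseless trace values
    drift_px: np.ndarray | None = None           # (T, 2) injected (dx, dy)


# ---------------------------------------------------------------------------
# Ratiometric pH series
# ---------------------------------------------------------------------------

@dataclass
class PHSeriesConfig:
    """Parameters of the two-channel ratiometric pH series generator.

    Defaults reproduce the study conditions of the acidification assay: a
    ~1 h confocal time-lapse at 5-min sampling, acidification starting
    20 min after treatment and developing over tens of minutes
    (``tau_min`` = 30), and a sensor with apparent pKa 6.0 reporting a
    drop from pH 6.4 to pH 5.4.
    """

    image_height_px: int = 128
    image_width_px: int = 128
    wall_spacing_px: int = 16
    wall_width_px: int = 2
    ref_wall_intensity: float = 200.0
    background_intensity: float = 20.0
    noise_sd: float = 10.0
    pka: float = 6.0
    ph_initial: float = 6.4
    ph_final: float = 5.4
    onset_min: float = 20.0
    tau_min: float = 30.0
    n_frames: int = 13
    time_step_min: float = 5.0
    t_start_min: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.image_height_px >= 8, "image_height_px", "must be >= 8")
        _require(self.image_width_px >= 8, "image_width_px", "must be >= 8")
        _require(self.wall_spacing_px >= 2, "wall_spacing_px", "must be >= 2")
        _require(
            1 <= self.wall_width_px < self.wall_spacing_px,
            "wall_width_px",
            "must be >= 1 and smaller than wall_spacing_px",
        )
        _require(self.ref_wall_intensity > 0, "ref_wall_intensity", "must be > 0")
        _require(self.background_intensity >= 0, "background_intensity", "must be >= 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.ph_final <= self.ph_initial, "ph_final",
                 "acidification requires ph_final <= ph_initial")
        _require(self.tau_min > 0, "tau_min", "must be > 0")
        _require(self.n_frames >= 1, "n_frames", "must be >= 1")
        _require(self.time_step_min > 0, "time_step_min", "must be > 0")
        span = self.n_frames * self.time_step_min
        _require(0 <= self.onset_min < self.t_start_min + span, "onset_min",
                 "must fall within the acquisition window")


def ph_schedule(times_min: np.ndarray, config: PHSeriesConfig) -> np.ndarray:
    """Uniform apoplastic pH at each frame time.

    Constant at ``ph_initial`` before onset, then an exponential approach
    to ``ph_final`` with time constant ``tau_min``.
    """
    t = np.asarray(times_min, dtype=float)
    dt = np.maximum(t - config.onset_min, 0.0)
    ph = config.ph_final + (config.ph_initial - config.ph_final) * np.exp(
        -dt / config.tau_min
    )
    return np.where(t < config.onset_min, config.ph_initial, ph)


def wall_lattice(config: PHSeriesConfig) -> np.ndarray:
    """Boolean (H, W) support of the rectangular cell-wall lattice.

    Line positions are spaced ``wall_spacing_px`` on average with a small
    deterministic per-line jitter (seeded by ``config.seed``): real cell
    files are irregular, and a perfectly periodic lattice would make
    translation registration ambiguous up to the lattice period.
    """
    rng = np.random.default_rng(config.seed + 982451653 % (2**31))
    h, w = config.image_height_px, config.image_width_px
    jitter_max = max((config.wall_spacing_px - config.wall_width_px) // 3, 0)

    def line_support(extent: int) -> np.ndarray:
        out = np.zeros(extent, dtype=bool)
        pos = 0
        while pos < extent:
            out[pos:pos + config.wall_width_px] = True
            step = config.wall_spacing_px + int(
                rng.integers(-jitter_max, jitter_max + 1)
            )
            pos += max(step, config.wall_width_px + 1)
        return out

    yy = line_support(h)
    xx = line_support(w)
    return yy[:, None] | xx[None, :]


def _render_ph_frames(
    config: PHSeriesConfig,
    ph_map: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render (T, 2, H, W) ref+sense frames from a per-pixel pH map."""
    wall = wall_lattice(config)
    t = ph_map.shape[0]
    ref = np.where(wall, config.ref_wall_intensity, config.background_intensity)
    ref = np.broadcast_to(ref, (t,) + wall.shape).astype(float)
    bright = quench_fraction(ph_map, config.pka)
    sense = np.where(
        wall, config.ref_wall_intensity * bright, config.background_intensity
    )
    frames = np.stack([ref, np.asarray(sense, dtype=float)], axis=1)
    if config.noise_sd > 0:
        frames = frames + rng.normal(0.0, config.noise_sd, size=frames.shape)
    return np.clip(frames, 0.0, None)


def generate_ph_series(config: PHSeriesConfig) -> tuple[ImageSeries, GroundTruth]:
    """Two-channel (reference, sense) confocal-like series with a pH drop.

    The reference channel is pH-independent (``ref_wall_intensity`` at wall
    pixels); the sense channel is quenched at low pH
    (``ref_wall_intensity * B(pH)``).  Gaussian noise is added per pixel,
    channel and frame, then clipped at zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = config.t_start_min + config.time_step_min * np.arange(config.n_frames)
    ph = ph_schedule(times, config)
    ph_map = np.broadcast_to(
        ph[:, None, None],
        (config.n_frames, config.image_height_px, config.image_width_px),
    ).copy()
    frames = _render_ph_frames(config, ph_map, rng)
    series = ImageSeries(
        frames,
        channel_labels=("RFP", "GFP"),
        ref_channel="RFP",
        sense_channel="GFP",
        time_step_min=config.time_step_min,
        t_start_min=config.t_start_min,
    )
    truth = GroundTruth(
        true_onset_min=config.onset_min,
        ph_series=ph,
        ph_map_series=ph_map,
        wall_mask=wall_lattice(config),
    )
    return series, truth


def generate_flank_zstack(
    config: PHSeriesConfig,
    ph_upper: float,
    ph_lower: float,
    n_slices: int = 8,
) -> tuple[ImageSeries, GroundTruth]:
    """One-timepoint z-stack whose upper and lower halves differ in pH.

    Emulates a bending hypocotyl whose lower flank is more acidic than the
    upper flank; the stack axis plays the role of z-sections, one per
    "frame" of the returned series.
    """
    config.validate()
    _require(n_slices >= 1, "n_slices", "must be >= 1")
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height_px, config.image_width_px
    ph_map = np.full((n_slices, h, w), float(ph_upper))
    ph_map[:, h // 2:, :] = float(ph_lower)
    frames = _render_ph_frames(config, ph_map, rng)
    series = ImageSeries(
        frames,
        channel_labels=("RFP", "GFP"),
        ref_channel="RFP",
        sense_channel="GFP",
        time_step_min=1.0,
    )
    truth = GroundTruth(ph_map_series=ph_map, wall_mask=wall_lattice(config))
    return series, truth


# ---------------------------------------------------------------------------
# Elongation series
# ---------------------------------------------------------------------------

@dataclass
class GrowthSeriesConfig:
    """Parameters of the scanner-like segment elongation generator.

    Defaults reproduce the elongation assay conditions: a ~2 mm segment
    scanned every 5 min for ~2 h, static through a 20-min lag phase and
    then elongating at 30 %/h.  ``px_per_mm`` defaults to the resolution
    of a 2400 DPI flatbed scan (~94.5 px/mm).
    """

    initial_length_px: float = 200.0
    rod_width_px: float = 12.0
    onset_min: float = 20.0
    growth_rate_pct_per_hr: float = 30.0
    length_noise_sd_px: float = 1.0
    angle_jitter_deg: float = 1.0
    orientation_deg: float = 90.0
    image_height_px: int = 384
    image_width_px: int = 384
    rod_intensity: float = 200.0
    background_intensity: float = 10.0
    px_per_mm: float = 94.5
    n_frames: int = 25
    time_step_min: float = 5.0
    t_start_min: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.initial_length_px > 0, "initial_length_px", "must be > 0")
        _require(self.rod_width_px >= 3, "rod_width_px", "must be >= 3")
        _require(self.onset_min >= 0, "onset_min", "must be >= 0")
        _require(self.length_noise_sd_px >= 0, "length_noise_sd_px", "must be >= 0")
        _require(self.angle_jitter_deg >= 0, "angle_jitter_deg", "must be >= 0")
        _require(self.px_per_mm > 0, "px_per_mm", "must be > 0")
        _require(self.n_frames >= 1, "n_frames", "must be >= 1")
        _require(self.time_step_min > 0, "time_step_min", "must be > 0")
        _require(self.rod_intensity > self.background_intensity,
                 "rod_intensity", "must exceed background_intensity")
        final = self.true_length(self.t_start_min
                                 + self.time_step_min * (self.n_frames - 1))
        margin = self.rod_width_px + 6 * self.length_noise_sd_px + 4
        _require(
            final + margin <= min(self.image_height_px, self.image_width_px),
            "initial_length_px",
            "rod at final length would exceed the frame bounds",
        )

    def true_length(self, t_min: np.ndarray | float) -> np.ndarray | float:
        """Noiseless segment length L(t): flat lag, then linear growth."""
        t = np.asarray(t_min, dtype=float)
        growth = self.growth_rate_pct_per_hr / 100.0 / 60.0  # fraction per min
        length = self.initial_length_px * (
            1.0 + growth * np.maximum(t - self.onset_min, 0.0)
        )
        return length if length.ndim else float(length)


def render_rod(
    shape: tuple[int, int],
    center_xy: tuple[float, float],
    length_px: float,
    width_px: float,
    angle_deg: float,
) -> np.ndarray:
    """Boolean mask of a capsule-shaped rod (tip-to-tip length ``length_px``).

    The capsule's semicircular end caps make its maximum caliper equal to
    its length regardless of width.  ``angle_deg`` follows the package
    convention: 0 = horizontal, +90 = vertical-up, with image y downward.
    """
    h, w = shape
    cx, cy = center_xy
    half = max(length_px - width_px, 0.0) / 2.0
    a = math.radians(angle_deg)
    ux, uy = math.cos(a), -math.sin(a)  # y axis points down
    yy, xx = np.mgrid[0:h, 0:w]
    # distance from each pixel centre to the capsule's axis segment
    px = xx - cx
    py = yy - cy
    proj = np.clip(px * ux + py * uy, -half, half)
    d2 = (px - proj * ux) ** 2 + (py - proj * uy) ** 2
    return d2 <= (width_px / 2.0) ** 2


def generate_elongation_series(
    config: GrowthSeriesConfig,
) -> tuple[ImageSeries, GroundTruth]:
    """Single-channel series of a bright segment silhouette on dark background.

    The rendered rod length is the true length plus per-frame Gaussian
    jitter (``length_noise_sd_px``); its orientation wobbles by
    ``angle_jitter_deg`` around the nominal pose.  Ground truth carries the
    noiseless length series and the true onset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = config.t_start_min + config.time_step_min * np.arange(config.n_frames)
    true_len = np.asarray(config.true_length(times))
    shape = (config.image_height_px, config.image_width_px)
    center = (config.image_width_px / 2.0, config.image_height_px / 2.0)
    frames = np.empty((config.n_frames,) + shape)
    for i in range(config.n_frames):
        length = true_len[i] + rng.normal(0.0, config.length_noise_sd_px)
        length = max(length, config.rod_width_px + 1.0)
        angle = config.orientation_deg + rng.normal(0.0, config.angle_jitter_deg)
        rod = render_rod(shape, center, length, config.rod_width_px, angle)
        frames[i] = np.where(rod, config.rod_intensity, config.background_intensity)
    series = ImageSeries(
        frames,
        channel_labels=("scan",),
        pixel_size_um=1000.0 / config.px_per_mm,
        time_step_min=config.time_step_min,
        t_start_min=config.t_start_min,
    )
    truth = GroundTruth(
        true_onset_min=config.onset_min, true_length_series=true_len
    )
    return series, truth


# ---------------------------------------------------------------------------
# Luminescence traces
# ---------------------------------------------------------------------------

def generate_luminescence_trace(
    baseline: float = 100.0,
    amplitude: float = 300.0,
    onset_min: float = 20.0,
    rise_tau_min: float = 60.0,
    n_frames: int = 13,
    time_step_min: float = 5.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[Trace, GroundTruth]:
    """Reporter time course: flat baseline, then a saturating rise.

    The noiseless trace equals ``baseline`` for t < onset and
    ``baseline + amplitude * (1 - exp(-(t - onset)/rise_tau))`` afterwards,
    so it is continuous at the breakpoint.
    """
    _require(amplitude >= 0, "amplitude", "must be >= 0")
    _require(rise_tau_min > 0, "rise_tau_min", "must be > 0")
    _require(noise_sd >= 0, "noise_sd", "must be >= 0")
    _require(n_frames >= 2, "n_frames", "must be >= 2")
    rng = np.random.default_rng(seed)
    t = time_step_min * np.arange(n_frames)
    clean = baseline + amplitude * -np.expm1(
        -np.maximum(t - onset_min, 0.0) / rise_tau_min
    )
    value = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    trace = Trace(t, value, value_kind="luminescence")
    return trace, GroundTruth(true_onset_min=onset_min, clean_trace=clean)


def luminescence_stack(
    trace: Trace, shape: tuple[int, int] = (64, 64), background: float = 0.0
) -> ImageSeries:
    """Image stack whose every in-frame pixel carries the trace value.

    Convenience for exercising ROI trace extraction end to end.
    """
    h, w = shape
    frames = np.maximum(trace.value, 0.0)[:, None, None] * np.ones((1, h, w))
    frames = np.maximum(frames, background)
    return ImageSeries(
        frames,
        channel_labels=("LUC",),
        time_step_min=float(np.diff(trace.time_min).mean()),
        t_start_min=float(trace.time_min[0]),
    )


# ---------------------------------------------------------------------------
# Gravitropic bending
# ---------------------------------------------------------------------------

def generate_bending_series(
    start_angle_deg: float = 0.0,
    final_angle_deg: float = 90.0,
    rate_deg_per_hr: float = 45.0,
    n_frames: int = 13,
    time_step_min: float = 30.0,
    seed: int = 0,
    rod_length_px: float = 100.0,
    rod_width_px: float = 9.0,
    image_size_px: int = 256,
) -> tuple[ImageSeries, GroundTruth]:
    """Rod-mask series rotating from the start angle toward the final angle.

    The rod pivots about its basal end at ``rate_deg_per_hr`` and saturates
    at ``final_angle_deg`` (0 = horizontal, +90 = vertical-up).
    """
    for name, val in (("start_angle_deg", start_angle_deg),
                      ("final_angle_deg", final_angle_deg)):
        _require(-180.0 <= val <= 180.0, name, "must lie in [-180, 180]")
    _require(rate_deg_per_hr >= 0, "rate_deg_per_hr", "must be >= 0")
    _require(n_frames >= 1, "n_frames", "must be >= 1")
    del seed  # trajectory is deterministic; kept for interface symmetry
    t = time_step_min * np.arange(n_frames)
    travel = rate_deg_per_hr * t / 60.0
    span = final_angle_deg - start_angle_deg
    angles = start_angle_deg + np.sign(span) * np.minimum(travel, abs(span))
    base = (image_size_px / 2.0, image_size_px - 24.0)  # (x, y), y down
    shape = (image_size_px, image_size_px)
    frames = np.empty((n_frames,) + shape)
    for i, ang in enumerate(angles):
        a = math.radians(ang)
        cx = base[0] + rod_length_px / 2.0 * math.cos(a)
        cy = base[1] - rod_length_px / 2.0 * math.sin(a)
        rod = render_rod(shape, (cx, cy), rod_length_px, rod_width_px, ang)
        frames[i] = rod.astype(float)
    series = ImageSeries(
        frames, channel_labels=("mask",), time_step_min=time_step_min
    )
    return series, GroundTruth(true_angle_series_deg=angles)


# ---------------------------------------------------------------------------
# Drift injection
# ---------------------------------------------------------------------------

def inject_drift(
    series: ImageSeries, step_sd_px: float = 2.0, seed: int = 0
) -> tuple[ImageSeries, np.ndarray]:
    """Apply an integer random-walk drift to every frame (circularly).

    Frame t is rolled by the cumulative shift ``drift[t] = (dx, dy)``
    relative to frame 0 (positive dx moves content rightward, positive dy
    downward).  Circular rolling keeps translation estimation exact, which
    is what the registration round-trip tests rely on.  Returns the drifted
    series and the (T, 2) integer drift log.
    """
    _require(step_sd_px >= 0, "step_sd_px", "must be >= 0")
    rng = np.random.default_rng(seed)
    steps = np.round(
        rng.normal(0.0, step_sd_px, size=(series.n_frames, 2))
    ).astype(int)
    steps[0] = 0
    drift = np.cumsum(steps, axis=0)
    data = series.data.copy()
    for t in range(series.n_frames):
        dx, dy = drift[t]
        data[t] = np.roll(data[t], shift=(dy, dx), axis=(-2, -1))
    return series.with_data(data), drift
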