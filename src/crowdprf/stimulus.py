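"""Time-resolved binary stimulus apertures and the behavioural trial schedule.

Three fMRI paradigms are modelled on a common visual-field raster:

* a drifting high-contrast bar (pRF mapping),
* a combined rotating-wedge / expanding-contracting-ring run (retinotopy),
* a block-design localizer placing the crowding stimulus patch at the
  trained location (6.5 deg eccentricity, 25 deg clockwise from the upper
  vertical meridian).

Apertures are binary masks: luminance, flicker and gamma correction are not
modelled (contrast is metadata only).  The behavioural schedule produces
balanced 4AFC crowding-trial tables using the method of constant stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when stimulus timing or counts do not fit together."""


DEFAULT_SPACINGS = (0.75, 1.25, 1.75, 2.25, 2.75, 3.25)
GAP_DIRECTIONS = ("up", "down", "left", "right")


def _as_fraction(seconds: float) -> Fraction:
    return Fraction(seconds).limit_denominator(10_000)


@dataclass(frozen=True)
class FieldRaster:
    """Square pixel raster over the central visual field.

    x increases rightward, y upward, origin at fixation.  ``n_pixels`` must
    be odd so one pixel centre sits exactly at (0, 0).
    """

    half_width: float = 9.0
    n_pixels: int = 101

    def __post_init__(self) -> None:
        if self.n_pixels < 3 or self.n_pixels % 2 == 0:
            raise ConfigurationError("n_pixels must be odd and >= 3")
        if self.half_width <= 0:
            raise ConfigurationError("half_width must be positive")

    @property
    def pixel_size(self) -> float:
        return 2.0 * self.half_width / (self.n_pixels - 1)

    @property
    def coords(self) -> np.ndarray:
        return np.linspace(-self.half_width, self.half_width, self.n_pixels)

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xx, yy) pixel-centre coordinates in degrees."""
        c = self.coords
        return np.meshgrid(c, c)


@dataclass
class ApertureMovie:
    """Time-ordered binary masks on a :class:`FieldRaster`."""

    frames: np.ndarray  # (n_frames, n_pixels, n_pixels), values in {0, 1}
    frame_duration: float
    tr: float
    raster: FieldRaster
    paradigm: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        uniq = np.unique(self.frames)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ConfigurationError("aperture frames must be binary")
        total = _as_fraction(self.frame_duration) * self.n_frames
        if (total / _as_fraction(self.tr)).denominator != 1:
            raise ConfigurationError(
                f"run duration {float(total)} s is not a multiple of tr={self.tr} s"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_duration

    @property
    def n_trs(self) -> int:
        return int(round(self.duration / self.tr))

    def frame_matrix(self) -> np.ndarray:
        """Frames flattened to (n_frames, n_pixels**2), float (cached)."""
        fm = self.meta.get("_frame_matrix")
        if fm is None or fm.shape[0] != self.n_frames:
            fm = self.frames.reshape(self.n_frames, -1).astype(float)
            self.meta["_frame_matrix"] = fm
        return fm


def bar_aperture_run(
    raster: FieldRaster = FieldRaster(),
    bar_width_fraction: float = 0.25,
    directions: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0),
    step_duration: float = 2.0,
    tr: float = 2.0,
    n_steps: int = 16,
) -> ApertureMovie:
    """One pRF-mapping run of drifting-bar apertures.

    Each of the eight motion directions contributes one sweep of ``n_steps``
    frames; the bar traverses the field perpendicular to its orientation and
    the motion direction reverses at the sweep midpoint (the second half
    retraces the first half's positions in reverse).  Cardinal bars span the
    full raster; diagonal bars are truncated at the midline along their own
    length and therefore cover only half of the screen.

    Parameters
    ----------
    bar_width_fraction : fraction of ``raster.half_width`` giving bar width
        (default 1/4 of the 9 deg stimulus radius, i.e. 2.25 deg).
    """
    if not (0 < bar_width_fraction <= 1):
        raise ConfigurationError("bar_width_fraction must lie in (0, 1]")
    if n_steps < 2 or n_steps % 2:
        raise ConfigurationError("n_steps must be an even integer >= 2")
    sweep = _as_fraction(step_duration) * n_steps
    if (sweep / _as_fraction(tr)).denominator != 1:
        raise ConfigurationError("sweep duration must be a multiple of tr")

    hw = raster.half_width
    width = bar_width_fraction * hw
    xx, yy = raster.grid()

    half = n_steps // 2
    forward = np.linspace(-hw, hw, half)
    positions = np.concatenate([forward, forward[::-1]])

    frames = []
    for angle in directions:
        theta = np.deg2rad(angle)
        ux, uy = np.cos(theta), np.sin(theta)          # motion direction
        proj_motion = xx * ux + yy * uy
        proj_length = -xx * uy + yy * ux               # along the bar
        diagonal = (angle % 90.0) != 0.0
        for pos in positions:
            mask = np.abs(proj_motion - pos) <= width / 2.0
            if diagonal:
                mask &= proj_length >= 0.0
            frames.append(mask)
    movie = ApertureMovie(
        frames=np.stack(frames).astype(np.uint8),
        frame_duration=step_duration,
        tr=tr,
        raster=raster,
        paradigm="bar",
        meta={
            "directions": list(directions),
            "n_steps": n_steps,
            "bar_width": width,
            "positions": positions.tolist(),
        },
    )
    return movie


@dataclass
class RetinotopyRun:
    """Combined wedge+ring run with separable component movies."""

    combined: ApertureMovie
    wedge: ApertureMovie
    ring: ApertureMovie
    wedge_period: float
    ring_period: float
    wedge_start_deg: float
    wedge_step_deg: float
    ecc_range: tuple[float, float]

    @property
    def n_wedge_cycles(self) -> int:
        return int(round(self.combined.duration / self.wedge_period))

    @property
    def n_ring_cycles(self) -> int:
        return int(round(self.combined.duration / self.ring_period))


def wedge_ring_run(
    raster: FieldRaster = FieldRaster(),
    wedge_width_deg: float = 45.0,
    wedge_step_deg: float = 22.5,
    ring_width_deg: float = 1.5,
    ecc_range: tuple[float, float] = (0.2, 9.0),
    step_duration: float = 3.0,
    tr: float = 1.5,
    n_wedge_cycles: int = 6,
    n_ring_cycles: int = 8,
    wedge_start_deg: float = 90.0,
) -> RetinotopyRun:
    """Combined rotating-wedge / ring run.

    The wedge (45 deg of polar angle) steps clockwise through 16 positions of
    22.5 deg, one full rotation in 48 s; the ring (1.5 deg wide, 0.2–9 deg)
    completes an expansion-plus-contraction cycle in 12 steps (36 s).  The
    asynchronous cycle counts (6 wedge vs 8 ring cycles) make the two
    components separable by frequency over the common 288 s run.
    """
    n_wedge_steps = int(round(360.0 / wedge_step_deg))
    if not np.isclose(n_wedge_steps * wedge_step_deg, 360.0):
        raise ConfigurationError("wedge_step_deg must divide 360")
    wedge_period = n_wedge_steps * step_duration
    n_ring_steps = 12
    ring_period = n_ring_steps * step_duration
    if not np.isclose(n_wedge_cycles * wedge_period, n_ring_cycles * ring_period):
        raise ConfigurationError(
            "wedge and ring cycles do not reach a common run length: "
            f"{n_wedge_cycles}x{wedge_period}s vs {n_ring_cycles}x{ring_period}s"
        )
    duration = n_wedge_cycles * wedge_period
    n_frames = int(round(duration / step_duration))

    xx, yy = raster.grid()
    ecc = np.hypot(xx, yy)
    ang = np.rad2deg(np.arctan2(yy, xx))
    lo, hi = ecc_range

    wedge_frames = np.zeros((n_frames, raster.n_pixels, raster.n_pixels), np.uint8)
    ring_frames = np.zeros_like(wedge_frames)
    half_cycle = n_ring_steps // 2
    for k in range(n_frames):
        wk = k % n_wedge_steps
        centre = wedge_start_deg - wedge_step_deg * wk  # clockwise rotation
        delta = (ang - centre + 180.0) % 360.0 - 180.0
        wedge_frames[k] = (
            (np.abs(delta) <= wedge_width_deg / 2.0) & (ecc >= lo) & (ecc <= hi)
        )
        rk = k % n_ring_steps
        j = rk if rk < half_cycle else (n_ring_steps - 1 - rk)  # fold contraction
        centre_ecc = lo + (hi - lo) * (j + 0.5) / half_cycle
        ring_frames[k] = (
            (np.abs(ecc - centre_ecc) <= ring_width_deg / 2.0) & (ecc >= lo) & (ecc <= hi)
        )

    kwargs = dict(frame_duration=step_duration, tr=tr, raster=raster)
    wedge = ApertureMovie(wedge_frames, paradigm="wedge", **kwargs)
    ring = ApertureMovie(ring_frames, paradigm="ring", **kwargs)
    combined = ApertureMovie(
        (wedge_frames | ring_frames).astype(np.uint8), paradigm="wedge_ring", **kwargs
    )
    return RetinotopyRun(
        combined=combined,
        wedge=wedge,
        ring=ring,
        wedge_period=wedge_period,
        ring_period=ring_period,
        wedge_start_deg=wedge_start_deg,
        wedge_step_deg=wedge_step_deg,
        ecc_range=ecc_range,
    )


def crowding_patch_center(ecc: float = 6.5, polar_deg: float = 65.0) -> tuple[float, float]:
    """Centre of the trained stimulus patch in (x, y) degrees.

    Default: 6.5 deg eccentricity, 25 deg clockwise from the vertical
    meridian, i.e. polar angle 65 deg CCW from the right horizontal.
    """
    theta = np.deg2rad(polar_deg)
    return float(ecc * np.cos(theta)), float(ecc * np.sin(theta))


def localizer_blocks(
    n_cycles: int = 8,
    block_duration: float = 16.0,
    tr: float = 2.0,
    raster: FieldRaster = FieldRaster(),
    center_ecc: float = 6.5,
    center_polar_deg: float = 65.0,
    element_size: float = 0.75,
    flanker_gap: float = 0.95,
) -> tuple[np.ndarray, ApertureMovie]:
    """Block-design localizer: boxcar regressor plus stimulus aperture.

    Each cycle is one fixation block (0) followed by one stimulation block
    (1), 16 s each.  The aperture places a Landolt-C-plus-flankers patch
    (0.75 deg elements, flankers at 0.95 deg centre-to-centre along the
    radial axis) at the trained upper-right location.
    """
    if n_cycles < 1:
        raise ConfigurationError("n_cycles must be >= 1")
    per_block = _as_fraction(block_duration) / _as_fraction(tr)
    if per_block.denominator != 1:
        raise ConfigurationError("block_duration must be a multiple of tr")
    per_block = int(per_block)
    design = np.tile(np.r_[np.zeros(per_block), np.ones(per_block)], n_cycles)

    cx, cy = crowding_patch_center(center_ecc, center_polar_deg)
    radial = np.array([cx, cy]) / np.hypot(cx, cy)
    xx, yy = raster.grid()
    mask = np.zeros((raster.n_pixels, raster.n_pixels), bool)
    for offset in (-flanker_gap, 0.0, flanker_gap):
        ex, ey = cx + offset * radial[0], cy + offset * radial[1]
        mask |= np.hypot(xx - ex, yy - ey) <= element_size / 2.0
    frames = design[:, None, None].astype(np.uint8) * mask.astype(np.uint8)
    movie = ApertureMovie(
        frames,
        frame_duration=tr,
        tr=tr,
        raster=raster,
        paradigm="localizer",
        meta={"center": (cx, cy), "design": design.tolist()},
    )
    return design, movie


def trial_schedule(
    subject: str = "s01",
    spacings: tuple[float, ...] = DEFAULT_SPACINGS,
    gap_directions: tuple[str, ...] = GAP_DIRECTIONS,
    trials_per_subblock: int = 432,
    subblocks_per_block: int = 2,
    blocks_per_day: int = 2,
    n_days: int = 4,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Balanced 4AFC crowding-trial schedule (no responses).

    Within every sub-block each spacing x gap-direction cell appears equally
    often (432 trials = 6 spacings x 4 gaps x 18 repetitions by default);
    trial order is randomized by ``seed``.  Each training block presents one
    flanker configuration, so a day's two blocks cover radial and tangential
    (block order randomized per day), and one configuration accumulates
    2 x 432 = 864 trials per block.
    """
    n_cells = len(spacings) * len(gap_directions)
    if trials_per_subblock % n_cells:
        raise ConfigurationError(
            f"{trials_per_subblock} trials cannot be balanced over {n_cells} cells"
        )
    reps = trials_per_subblock // n_cells
    rng = np.random.default_rng(seed)
    base = pd.DataFrame(
        [(s, g) for s in spacings for g in gap_directions for _ in range(reps)],
        columns=["spacing", "gap_direction"],
    )
    rows = []
    for day in range(1, n_days + 1):
        orients = ["radial", "tangential"][: blocks_per_day]
        order = rng.permutation(len(orients))
        for block, oi in enumerate(order, start=1):
            for sub in range(1, subblocks_per_block + 1):
                t = base.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(
                    drop=True
                )
                t.insert(0, "subject", subject)
                t.insert(1, "day", day)
                t.insert(2, "block", block)
                t.insert(3, "sub_block", sub)
                t.insert(4, "flanker_orientation", orients[oi])
                rows.append(t)
    out = pd.concat(rows, ignore_index=True)
    out["response"] = pd.NA
    out["correct"] = pd.NA
    return out


def weber_contrast(stimulus_luminance: float, background_luminance: float) -> float:
    """|L_stim - L_bg| / L_bg (dimensionless)."""
    return abs(stimulus_luminance - background_luminance) / background_luminance
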