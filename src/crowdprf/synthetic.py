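"""Synthetic ground-truth data with the statistical structure the analysis
assumes: Gaussian-pRF voxel time courses, simulated crowding observers, and
retinotopic grid maps with a known field-sign boundary.

Every generator is a pure function of (configuration, seed).  Defaults
emulate the study conditions: pRF size growing linearly with eccentricity
(V1-like ROIs ~0.9-1.0 deg, V2-like ~1.1-1.5 deg over 0.5-9 deg), a trained
region (tROI) within 1.5 deg of the trained locus at 6.5 deg eccentricity
in the upper-right field, a configurable post-training pRF-size reduction
(default 21%) concentrated in designated ROIs, and observers whose critical
spacing shrinks day by day (radial larger than tangential; day-1 group
means 2.39/1.54 deg, day-4 means 1.60/1.26 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hemodynamics import HRFSpec, convolve_bold_many
from .psychophysics import DEFAULT_LAPSE, GUESS_4AFC
from .stimulus import (
    ApertureMovie,
    DEFAULT_SPACINGS,
    GAP_DIRECTIONS,
    crowding_patch_center,
    trial_schedule,
)

TRAINED_LOCUS = crowding_patch_center()  # (2.747, 5.891) deg

# size-eccentricity line (intercept deg, slope deg/deg) per ROI class
DEFAULT_SIZE_ECC = {
    "dV1": (0.80, 0.025),
    "vV1": (0.80, 0.025),
    "dV2": (1.00, 0.055),
    "vV2": (1.00, 0.055),
    "tROI": (1.00, 0.055),
}
# polar-angle range (deg CCW from right horizontal) per ROI; ventral cortex
# represents the upper field, dorsal the lower field
DEFAULT_POLAR_RANGES = {
    "dV1": (-80.0, -10.0),
    "dV2": (-80.0, -10.0),
    "vV1": (10.0, 80.0),
    "vV2": (10.0, 80.0),
}

# day-by-day group-mean critical spacings (degrees); days 2-3 interpolate
# between the printed day-1 and day-4 group means
DEFAULT_CS_MEANS = {
    "radial": (2.39, 2.05, 1.80, 1.60),
    "tangential": (1.54, 1.44, 1.34, 1.26),
}


@dataclass(frozen=True)
class NoiseSpec:
    model: str = "white"       # "white" | "ar1"
    sd_ratio: float = 0.5      # noise SD relative to the voxel's signal SD
    ar_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_ratio < 0:
            raise ValueError("sd_ratio must be >= 0")
        if not (-1 < self.ar_coef < 1):
            raise ValueError("ar_coef must lie in (-1, 1)")
        if self.model not in ("white", "ar1"):
            raise ValueError("noise model must be 'white' or 'ar1'")


@dataclass
class SimulatedVoxels:
    pre: np.ndarray                      # (n_voxels, n_trs)
    post: np.ndarray
    truth: pd.DataFrame                  # per-voxel ground truth
    movie: ApertureMovie = field(repr=False, default=None)


def _noise(rng: np.random.Generator, spec: NoiseSpec, sd: np.ndarray,
           shape: tuple[int, int]) -> np.ndarray:
    eps = rng.standard_normal(shape) * sd[:, None]
    if spec.model == "ar1" and spec.ar_coef != 0.0:
        phi = spec.ar_coef
        for t in range(1, shape[1]):
            eps[:, t] += phi * eps[:, t - 1]
        eps *= np.sqrt(1.0 - phi**2)  # keep the marginal SD
    return eps


def gen_voxel_dataset(
    movie: ApertureMovie,
    hrf: HRFSpec,
    n_per_roi: dict[str, int] | None = None,
    ecc_range: tuple[float, float] = (0.5, 9.0),
    size_ecc: dict[str, tuple[float, float]] | None = None,
    effect_by_roi: dict[str, float] | None = None,
    noise: NoiseSpec = NoiseSpec(),
    ecc_shift_by_roi: dict[str, float] | None = None,
    troi_center: tuple[float, float] = TRAINED_LOCUS,
    troi_radius: float = 1.5,
    sigma_jitter: float = 0.05,
    n_runs: int = 4,
    seed: int | None = 0,
) -> SimulatedVoxels:
    """Pre/post voxel-by-time BOLD matrices with stored ground truth.

    True pRF sizes follow sigma = intercept + slope * ecc (plus a small
    seeded jitter); post-session sigma is pre-session sigma scaled by
    (1 - effect) in the ROIs named by ``effect_by_roi`` (default: 21% in
    tROI).  ``ecc_shift_by_roi`` optionally moves post-session centres
    toward fixation by the given amount in degrees (default off).  Noise SD
    is set per voxel relative to its noiseless signal SD; the returned
    series is the average of ``n_runs`` identical repetitions of the run
    (the mapping protocol acquires the bar run four times per session and
    averages them), so the averaged noise SD is sd_ratio / sqrt(n_runs)
    times the signal SD.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n_per_roi = {"tROI": 40} if n_per_roi is None else n_per_roi
    size_ecc = DEFAULT_SIZE_ECC if size_ecc is None else size_ecc
    effect_by_roi = {"tROI": 0.21} if effect_by_roi is None else effect_by_roi
    ecc_shift_by_roi = ecc_shift_by_roi or {}
    lo, hi = ecc_range
    if hi > movie.raster.half_width:
        raise ValueError("ecc_range exceeds the stimulus aperture radius")

    rng = np.random.default_rng(seed)
    rows = []
    for roi, count in n_per_roi.items():
        intercept, slope = size_ecc[roi]
        for _ in range(count):
            if roi == "tROI":
                r = troi_radius * np.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * np.pi)
                x0 = troi_center[0] + r * np.cos(ang)
                y0 = troi_center[1] + r * np.sin(ang)
            else:
                ecc = rng.uniform(lo, hi)
                p_lo, p_hi = DEFAULT_POLAR_RANGES[roi]
                pol = np.deg2rad(rng.uniform(p_lo, p_hi))
                x0, y0 = ecc * np.cos(pol), ecc * np.sin(pol)
            ecc_v = float(np.hypot(x0, y0))
            sigma = max(
                intercept + slope * ecc_v + rng.normal(0.0, sigma_jitter), 0.1
            )
            effect = effect_by_roi.get(roi, 0.0)
            if not (0 <= effect < 1):
                raise ValueError("effect must lie in [0, 1)")
            shift = ecc_shift_by_roi.get(roi, 0.0)
            scale_post = max(ecc_v - shift, 0.1) / ecc_v if shift else 1.0
            rows.append(
                {
                    "roi": roi,
                    "x0_pre": x0, "y0_pre": y0, "sigma_pre": sigma,
                    "x0_post": x0 * scale_post, "y0_post": y0 * scale_post,
                    "sigma_post": sigma * (1.0 - effect),
                    "beta": rng.uniform(0.8, 1.2),
                    "baseline": rng.normal(100.0, 10.0),
                }
            )
    truth = pd.DataFrame(rows)
    truth.insert(0, "voxel", np.arange(len(truth)))
    truth["ecc_pre"] = np.hypot(truth.x0_pre, truth.y0_pre)
    truth["ecc_post"] = np.hypot(truth.x0_post, truth.y0_post)

    from .prf import predict_many  # deferred to avoid an import cycle

    out = {}
    for session in ("pre", "post"):
        params = truth[[f"x0_{session}", f"y0_{session}", f"sigma_{session}"]].to_numpy()
        bold = predict_many(params, movie, hrf)
        signal = truth["beta"].to_numpy()[:, None] * bold
        sd = signal.std(axis=1) * noise.sd_ratio / np.sqrt(n_runs)
        eps = _noise(rng, noise, sd, signal.shape)
        out[session] = truth["baseline"].to_numpy()[:, None] + signal + eps
    return SimulatedVoxels(pre=out["pre"], post=out["post"], truth=truth, movie=movie)


def _weibull_threshold(cs: float, slope: float, guess: float, lapse: float,
                       criterion: float = 0.68) -> float:
    """Weibull scale theta placing the criterion exactly at ``cs``."""
    f = (criterion - guess) / (1.0 - guess - lapse)
    return cs / (-np.log(1.0 - f)) ** (1.0 / slope)


def gen_trial_dataset(
    n_subjects: int = 15,
    cs_means: dict[str, tuple[float, ...]] | None = None,
    subject_sd: float = 0.2,
    cell_jitter: float = 0.05,
    slope: float = 3.0,
    guess: float = GUESS_4AFC,
    lapse: float = DEFAULT_LAPSE,
    spacings: tuple[float, ...] = DEFAULT_SPACINGS,
    trials_per_subblock: int = 432,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulated 4AFC crowding observers over the 4-day schedule.

    Each subject carries one lognormal proficiency factor (SD
    ``subject_sd`` on the log scale) applied to the day-by-orientation
    group-mean critical spacings, plus a small per-cell jitter.  Responses
    are Bernoulli draws from the Weibull psychometric whose 68% point sits
    at the subject's true critical spacing; wrong answers spread uniformly
    over the three incorrect gap directions.

    Returns (trials, truth) where truth holds each subject's true critical
    spacing per day and orientation.
    """
    cs_means = DEFAULT_CS_MEANS if cs_means is None else cs_means
    n_days = len(next(iter(cs_means.values())))
    rng = np.random.default_rng(seed)
    trials_all, truth_rows = [], []
    for si in range(n_subjects):
        subject = f"s{si + 1:02d}"
        factor = float(np.exp(rng.normal(0.0, subject_sd)))
        sched = trial_schedule(
            subject=subject,
            spacings=spacings,
            trials_per_subblock=trials_per_subblock,
            n_days=n_days,
            seed=int(rng.integers(2**31)),
        )
        cs_true = {}
        for orient, means in cs_means.items():
            for day, mean in enumerate(means, start=1):
                cs = mean * factor * float(np.exp(rng.normal(0.0, cell_jitter)))
                cs_true[(orient, day)] = cs
                truth_rows.append(
                    {"subject": subject, "day": day,
                     "flanker_orientation": orient, "cs_true": cs}
                )
        theta = {
            key: _weibull_threshold(cs, slope, guess, lapse)
            for key, cs in cs_true.items()
        }
        s = sched["spacing"].to_numpy(float)
        keys = list(zip(sched["flanker_orientation"], sched["day"]))
        th = np.array([theta[k] for k in keys])
        p = guess + (1.0 - guess - lapse) * (1.0 - np.exp(-((s / th) ** slope)))
        correct = rng.uniform(size=len(sched)) < p
        gaps = sched["gap_direction"].to_numpy()
        wrong = np.array([
            GAP_DIRECTIONS[rng.choice([i for i in range(4) if GAP_DIRECTIONS[i] != g])]
            for g in gaps[~correct]
        ], dtype=object) if (~correct).any() else np.array([], dtype=object)
        resp = gaps.astype(object).copy()
        resp[~correct] = wrong
        sched["response"] = resp
        sched["correct"] = correct
        trials_all.append(sched)
    trials = pd.concat(trials_all, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def gen_retinotopy_grid(
    n_rows: int = 24,
    n_cols: int = 20,
    boundary_row: int | None = None,
    polar_span: tuple[float, float] = (0.0, 90.0),
    ecc_span: tuple[float, float] = (0.5, 9.0),
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two-region cortical grid with mirrored polar progressions.

    The polar-angle map rises from ``polar_span[0]`` to ``polar_span[1]``
    over rows 0..boundary_row and then falls back symmetrically (a mirror
    reversal, as at the V1/V2 border); eccentricity increases smoothly
    along columns in both regions.  Returns (polar, ecc, truth) with the
    ground-truth boundary row in ``truth``.
    """
    boundary_row = n_rows // 2 if boundary_row is None else boundary_row
    if not (1 <= boundary_row <= n_rows - 2):
        raise ValueError("boundary_row must be interior to the grid")
    rng = np.random.default_rng(seed)
    p0, p1 = polar_span
    rows = np.arange(n_rows, dtype=float)
    up = p0 + (p1 - p0) * rows / boundary_row
    down = p1 - (p1 - p0) * (rows - boundary_row) / (n_rows - 1 - boundary_row)
    polar_profile = np.where(rows <= boundary_row, up, down)
    polar = np.tile(polar_profile[:, None], (1, n_cols))
    e0, e1 = ecc_span
    ecc = np.tile(np.linspace(e0, e1, n_cols)[None, :], (n_rows, 1))
    if noise_sd > 0:
        polar = polar + rng.normal(0, noise_sd, polar.shape)
        ecc = ecc + rng.normal(0, noise_sd, ecc.shape)
    return polar, ecc, {"boundary_row": boundary_row}
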