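"""Phase-encoded retinotopy and visual field sign on a cortical grid.

A combined wedge+ring run drives each voxel periodically at two distinct
frequencies (6 wedge cycles and 8 ring cycles per run), so the polar-angle
and eccentricity responses separate cleanly in the discrete Fourier
spectrum.  The response phase at each stimulus frequency, after
compensating the hemodynamic delay, is inverted through the stimulus
schedule to recover the preferred polar angle (wedge) or eccentricity
(ring).

The visual field sign at each node of a 2D cortical grid is the sign of the
Jacobian determinant of the (polar angle, eccentricity) mapping, computed by
central differences: mirror-image representations (e.g. V1) and non-mirror
representations (e.g. V2) carry opposite signs, so the sign flips at area
borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_HRF_DELAY = 4.75  # seconds; canonical kernel peak delta + alpha*tau
DEFAULT_COHERENCE_THRESHOLD = 0.3


@dataclass
class PhaseMapResult:
    """Per-voxel phase (radians, (-pi, pi]) and coherence at one frequency."""

    phase: np.ndarray
    coherence: np.ndarray
    n_cycles: int


def fourier_phase(ts: np.ndarray, n_cycles: int) -> PhaseMapResult:
    """Phase and coherence at ``n_cycles`` cycles per run.

    Coherence is the Fourier amplitude at the target frequency divided by
    the root-sum-square amplitude over all nonzero frequencies (1 for a pure
    sinusoid at the target frequency, near 0 for white noise).  Accepts a
    single series or a (n_voxels, n_samples) matrix.
    """
    ts = np.asarray(ts, float)
    one = ts.ndim == 1
    ts = np.atleast_2d(ts)
    n = ts.shape[1]
    if not (1 <= n_cycles < n / 2):
        raise ValueError("n_cycles must satisfy 1 <= n_cycles < n_samples/2")
    spec = np.fft.rfft(ts, axis=1)
    amp = np.abs(spec[:, 1:])  # exclude DC
    total = np.sqrt((amp**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(total > 0, np.abs(spec[:, n_cycles]) / total, 0.0)
    phase = np.angle(spec[:, n_cycles])
    if one:
        return PhaseMapResult(phase[0], coherence[0], n_cycles)
    return PhaseMapResult(phase, coherence, n_cycles)


def _peak_time(phase: np.ndarray, period: float, hrf_delay: float) -> np.ndarray:
    """Response-peak time within one stimulus cycle, delay-compensated.

    For x(t) ~ cos(2*pi*t/period - phi) the DFT phase is -phi and the peak
    sits at t = phi*period/(2*pi); subtracting the hemodynamic delay gives
    the neural event time (mod period).
    """
    t_peak = (-np.asarray(phase) / (2.0 * np.pi)) * period
    return (t_peak - hrf_delay) % period


def wedge_angle_from_phase(
    phase: np.ndarray,
    period: float = 48.0,
    wedge_start_deg: float = 90.0,
    hrf_delay: float = DEFAULT_HRF_DELAY,
) -> np.ndarray:
    """Polar angle (deg CCW from right horizontal, (-180, 180]) of the wedge
    position driving the response; the wedge rotates clockwise from
    ``wedge_start_deg``."""
    t = _peak_time(phase, period, hrf_delay)
    ang = wedge_start_deg - 360.0 * t / period
    return (np.asarray(ang) + 180.0) % 360.0 - 180.0


def ring_ecc_from_phase(
    phase: np.ndarray,
    period: float = 36.0,
    ecc_range: tuple[float, float] = (0.2, 9.0),
    hrf_delay: float = DEFAULT_HRF_DELAY,
) -> np.ndarray:
    """Eccentricity of the ring position driving the response.

    The schedule is inverted through the expansion half-cycle; peak times
    landing in the contraction half are folded back onto it (the two halves
    traverse the same eccentricities in mirrored order).
    """
    t = _peak_time(phase, period, hrf_delay)
    t = np.where(t > period / 2.0, period - t, t)
    lo, hi = ecc_range
    return np.clip(lo + (hi - lo) * (2.0 * t / period), lo, hi)


def threshold_coherence(
    result: PhaseMapResult, min_coherence: float = DEFAULT_COHERENCE_THRESHOLD
) -> np.ndarray:
    """Boolean mask of voxels whose coherence reaches the threshold."""
    return np.asarray(result.coherence) >= min_coherence


def field_sign_map(polar: np.ndarray, ecc: np.ndarray) -> np.ndarray:
    """Visual field sign per grid node: +1, -1, or NaN.

    ``polar`` and ``ecc`` are 2D maps (same rectangular lattice, uniform
    spacing; NaN marks missing nodes).  The sign is that of the determinant
    of the Jacobian of (polar, ecc) with respect to grid coordinates,
    estimated by central differences; border nodes and nodes with any
    missing 4-neighbour are NaN.  The sign is invariant to adding constants
    to either map and to uniform positive rescaling.
    """
    polar = np.asarray(polar, float)
    ecc = np.asarray(ecc, float)
    if polar.shape != ecc.shape or polar.ndim != 2:
        raise ValueError("polar and ecc must be 2D maps of equal shape")
    if min(polar.shape) < 3:
        raise ValueError("grid must be at least 3x3")
    out = np.full(polar.shape, np.nan)
    dp_di = (polar[2:, 1:-1] - polar[:-2, 1:-1]) / 2.0
    dp_dj = (polar[1:-1, 2:] - polar[1:-1, :-2]) / 2.0
    de_di = (ecc[2:, 1:-1] - ecc[:-2, 1:-1]) / 2.0
    de_dj = (ecc[1:-1, 2:] - ecc[1:-1, :-2]) / 2.0
    # Jacobian in (x, y) grid coordinates: x along columns (j), y along rows
    det = dp_dj * de_di - dp_di * de_dj
    interior = np.sign(det)
    interior[det == 0] = np.nan
    out[1:-1, 1:-1] = interior
    return out
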