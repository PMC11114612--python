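"""Hemodynamic response kernel and neural-to-BOLD convolution.

The impulse response is a gamma-variate,

    h(t) = ((t - delta)/tau)**alpha * exp(-(t - delta)/tau)   for t >= delta,
    h(t) = 0                                                  otherwise,

with onset delay ``delta`` (default 2.25 s), dispersion ``tau`` (1.25 s) and
shape exponent ``alpha`` (2), so the kernel peaks at delta + alpha*tau =
4.75 s.  The same canonical kernel serves the localizer GLM and the pRF
forward model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np


@dataclass(frozen=True)
class HRFSpec:
    delta: float = 2.25
    tau: float = 1.25
    alpha: float = 2.0
    dt: float = 0.1
    duration: float = 32.0
    normalization: str = "peak_one"  # or "unit_sum"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.normalization not in ("peak_one", "unit_sum"):
            raise ValueError("normalization must be 'peak_one' or 'unit_sum'")

    @property
    def peak_time(self) -> float:
        return self.delta + self.alpha * self.tau


def hrf_kernel(spec: HRFSpec) -> np.ndarray:
    """Sampled kernel on t = 0, dt, 2*dt, ... < duration."""
    n = int(round(spec.duration / spec.dt))
    if not math.isclose(n * spec.dt, spec.duration, rel_tol=1e-9):
        raise ValueError("dt must divide the kernel support")
    t = np.arange(n) * spec.dt
    s = np.maximum(t - spec.delta, 0.0) / spec.tau
    h = s**spec.alpha * np.exp(-s)
    h[t < spec.delta] = 0.0
    if spec.normalization == "peak_one":
        h /= h.max()
    else:
        h /= h.sum()
    return h


def _fine_dt(frame_duration: float, tr: float, target: float) -> float:
    """Largest common subdivision of frame and TR timing no coarser than target."""
    g = Fraction(frame_duration).limit_denominator(10_000)
    step = Fraction(
        math.gcd(g.numerator * Fraction(tr).limit_denominator(10_000).denominator,
                 Fraction(tr).limit_denominator(10_000).numerator * g.denominator),
        g.denominator * Fraction(tr).limit_denominator(10_000).denominator,
    )
    k = max(1, math.ceil(step / Fraction(target).limit_denominator(10_000)))
    return float(step / k)


def convolve_bold(
    neural: np.ndarray,
    spec: HRFSpec,
    tr: float,
    frame_duration: float | None = None,
) -> np.ndarray:
    """Causal convolution of a neural series with the HRF, sampled at TR.

    ``neural`` is sampled at frame resolution (``frame_duration`` defaults to
    ``tr``).  The series is held piecewise-constant on a fine grid dividing
    both frame and TR timing, convolved with the kernel sampled on that grid
    (scaled by the grid step so amplitudes approximate the continuous
    integral), zero-padded before run onset and truncated at run end, then
    read out at TR midpoints.  Output length = run duration / tr.
    """
    arr = np.asarray(neural, float)
    if arr.size == 0:
        raise ValueError("neural series is empty")
    if arr.ndim == 1:
        return convolve_bold_many(arr[None, :], spec, tr, frame_duration)[0]
    return convolve_bold_many(arr, spec, tr, frame_duration)


def convolve_bold_many(
    neural: np.ndarray, spec: HRFSpec, tr: float, frame_duration: float | None = None
) -> np.ndarray:
    """Vectorized :func:`convolve_bold` over rows of a (n_series, n_frames) array."""
    neural = np.asarray(neural, float)
    if neural.ndim != 2:
        raise ValueError("expected a 2D array of series")
    fd = tr if frame_duration is None else frame_duration
    dt = _fine_dt(fd, tr, spec.dt)
    up = int(round(fd / dt))
    fine = np.repeat(neural, up, axis=1)
    kernel = hrf_kernel(replace(spec, dt=dt)) * dt
    n_fine = fine.shape[1]
    from scipy.signal import fftconvolve

    conv = fftconvolve(fine, kernel[None, :], axes=1)[:, :n_fine]
    duration = neural.shape[1] * fd
    n_out = int(round(duration / tr))
    idx = np.minimum((np.floor(((np.arange(n_out) + 0.5) * tr) / dt)).astype(int), n_fine - 1)
    return conv[:, idx]
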