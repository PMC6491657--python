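"""Observation-model utilities.

Proportional (constant-CV) noise injection, automatic wavelet denoising,
shape-preserving sparse-to-dense interpolation and decimating resampling.
These emulate an assay whose error standard deviation scales with the
concentration, followed by the standard pre-processing applied before
parameter estimation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import PchipInterpolator

from .timeseries import TimeSeries

__all__ = [
    "NoiseSpec",
    "add_proportional_noise",
    "wavelet_denoise",
    "densify",
    "resample",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Proportional observation noise: value * (1 + cv * z), z ~ N(0, 1).

    ``cv`` is the dimensionless error fraction (0.2 for 20%); ``seed`` feeds a
    numpy default_rng generator so every draw is reproducible.
    """

    cv: float
    seed: int

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


def add_proportional_noise(series: TimeSeries, spec: NoiseSpec) -> TimeSeries:
    """Perturb each value multiplicatively with i.i.d. seeded Gaussian noise.

    Negative outputs are kept — clipping would bias high-noise scenarios —
    and downstream consumers must tolerate them.
    """
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(len(series))
    return TimeSeries(series.times, series.values * (1.0 + spec.cv * z))


def wavelet_denoise(
    series: TimeSeries, level: int, wavelet: str = "sym8"
) -> TimeSeries:
    """Automatic wavelet denoising by soft-thresholding detail coefficients.

    Decomposes with a symlet basis (order 8 by default, symmetric signal
    extension), applies the universal threshold ``sqrt(2 ln N) * sigma_j`` to
    each detail level up to ``level``, with the noise scale ``sigma_j``
    estimated per level from the median absolute deviation of that level's
    coefficients, then reconstructs and crops to the input length.  A shallow
    ``level`` preserves more geometric detail of the trajectory; deeper levels
    smooth more aggressively.
    """
    if level < 1:
        raise ValueError("level must be at least 1")
    series.sampling_interval()  # validates uniform sampling
    x = series.values
    n = x.size
    if n < 2 ** level:
        raise ValueError(f"series of length {n} too short for level {level}")
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if level > max_level:
        raise ValueError(
            f"level {level} too deep for length {n} with wavelet {wavelet} "
            f"(max {max_level})"
        )
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    thresholded = [coeffs[0]]
    for detail in coeffs[1:]:
        sigma = np.median(np.abs(detail)) / 0.6745
        thr = sigma * math.sqrt(2.0 * math.log(n))
        if thr > 0:
            detail = pywt.threshold(detail, thr, mode="soft")
        thresholded.append(detail)
    rec = pywt.waverec(thresholded, wavelet, mode="symmetric")
    return TimeSeries(series.times, rec[:n])


def densify(
    series: TimeSeries, target_interval: float, times=None
) -> TimeSeries:
    """Interpolate onto a finer uniform grid with a monotone cubic Hermite.

    Shape-preserving (pchip) interpolation: no overshoot between knots, exact
    reproduction of knot values where grids coincide.  The output grid spans
    the original range; explicit ``times`` outside it raise a range error.
    """
    if len(series) < 2:
        raise ValueError("need at least two points to densify")
    if times is None:
        if not target_interval > 0:
            raise ValueError("target_interval must be positive")
        t0 = float(series.times[0])
        n = int(math.floor(series.span / target_interval + 1e-9))
        times = t0 + np.arange(n + 1) * target_interval
    else:
        times = np.asarray(times, dtype=float)
        if times.min() < series.times[0] - 1e-9 or times.max() > series.times[-1] + 1e-9:
            raise ValueError("requested times extrapolate beyond the series range")
    interp = PchipInterpolator(series.times, series.values)
    return TimeSeries(times, interp(times))


def resample(series: TimeSeries, interval: float) -> TimeSeries:
    """Decimate a uniform series, keeping every (interval/source)-th sample."""
    h = series.sampling_interval()
    ratio = interval / h
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"interval {interval} is not a positive multiple of the source interval {h}"
        )
    step = int(round(ratio))
    return TimeSeries(series.times[::step], series.values[::step])
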