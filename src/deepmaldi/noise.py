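"""High-frequency noise estimation and SNR-based peak detection.

Noise is defined as fluctuation with wavelength much smaller than the
peak width.  It is isolated by subtracting a Savitzky-Golay smoothed
spectrum from the original and estimated robustly from the interquartile
spread of the residual in a relative-width m/z window:

    sigma_hat = (P50 - P25) / (sqrt(2) * erfinv(0.5)) ~ (P50 - P25) / 0.6745

For N(mu, sigma^2) residuals this reproduces sigma exactly while being
insensitive to outliers (real peaks leaking into the residual).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from functools import lru_cache

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import find_peaks
from scipy.special import erfinv

__all__ = [
    "ERFINV_HALF",
    "NOISE_DIVISOR",
    "NoiseProfile",
    "Peak",
    "smooth_sg",
    "estimate_noise",
    "noise_profile",
    "detect_peaks",
    "peak_density",
    "estimate_peak_width",
]

#: erfinv(1/2), the quantile constant behind the robust width-to-sigma map.
ERFINV_HALF = float(erfinv(0.5))
#: (P50 - P25) of N(0, 1): sqrt(2) * erfinv(0.5) ~ 0.6745.
NOISE_DIVISOR = float(np.sqrt(2.0) * erfinv(0.5))

SG_WINDOW_DEFAULT = 29
SG_ORDER_DEFAULT = 8
MIN_WINDOW_POINTS = 50


@dataclass(frozen=True)
class Peak:
    """A detected peak: apex position/intensity, local SNR, optional FWHM."""

    apex_mz: float
    apex_intensity: float
    snr: float
    fwhm: float | None = None


@dataclass(frozen=True)
class NoiseProfile:
    """Robust noise sigma estimated at a set of evaluation m/z points."""

    eval_mz: np.ndarray = field(repr=False)
    sigma: np.ndarray = field(repr=False)
    rel_width: float = 0.08

    def __post_init__(self) -> None:
        mz = np.asarray(self.eval_mz, dtype=np.float64)
        s = np.asarray(self.sigma, dtype=np.float64)
        if mz.shape != s.shape:
            raise ValueError("eval_mz and sigma must have equal shape")
        if np.any(s < 0):
            raise ValueError("noise sigma must be >= 0")
        object.__setattr__(self, "eval_mz", mz)
        object.__setattr__(self, "sigma", s)

    def interp(self, mz) -> np.ndarray:
        """Linear-in-m/z interpolation of sigma (edge values extended)."""
        return np.interp(np.asarray(mz, dtype=np.float64), self.eval_mz, self.sigma)


def smooth_sg(spectrum, window_length: int = SG_WINDOW_DEFAULT,
              poly_order: int = SG_ORDER_DEFAULT) -> np.ndarray:
    """Savitzky-Golay smoothing of the intensity vector.

    Accepts a spectrum object (``.intensities``) or a bare array and
    returns an array of the same length.  The local-polynomial kernel is
    built on abscissae scaled to [-1, 1], which keeps the least-squares
    solve well conditioned at high order: the filter reproduces
    polynomials up to degree ``poly_order`` to machine precision.  Edges
    are handled by refitting the edge window's polynomial and evaluating
    it at the uncovered positions.
    """
    y = np.asarray(getattr(spectrum, "intensities", spectrum), dtype=np.float64)
    if window_length % 2 == 0 or window_length < 3:
        raise ValueError("window_length must be odd and >= 3")
    if poly_order >= window_length:
        raise ValueError("poly_order must be smaller than window_length")
    if y.size < window_length:
        raise ValueError("input shorter than the smoothing window")
    kernel = _sg_kernel(window_length, poly_order)
    out = np.convolve(y, kernel, mode="same")  # kernel is symmetric
    half = window_length // 2
    t = (np.arange(window_length) - half) / half
    basis = np.vander(t, poly_order + 1, increasing=True)
    head_coef, *_ = np.linalg.lstsq(basis, y[:window_length], rcond=None)
    out[:half] = basis[:half] @ head_coef
    tail_coef, *_ = np.linalg.lstsq(basis, y[-window_length:], rcond=None)
    out[-half:] = basis[-half:] @ tail_coef
    return out


@lru_cache(maxsize=8)
def _sg_kernel(window_length: int, poly_order: int) -> np.ndarray:
    """Center-evaluation smoothing kernel from a scaled local-polynomial fit."""
    half = window_length // 2
    t = (np.arange(window_length) - half) / max(half, 1)
    basis = np.vander(t, poly_order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(basis, np.eye(window_length), rcond=None)
    return coef[0]


def noise_window(at_mz: float, rel_width: float = 0.08) -> tuple[float, float]:
    """The m/z window of relative width ``rel_width`` centred at ``at_mz``."""
    half = 0.5 * rel_width * at_mz
    return at_mz - half, at_mz + half


def _window_residuals(grid, residual: np.ndarray, at_mz: float, rel_width: float) -> np.ndarray:
    lo, hi = noise_window(at_mz, rel_width)
    sl = grid.window_slice(lo, hi)
    vals = residual[sl]
    if vals.size == 0:
        raise ValueError(f"noise window [{lo:.1f}, {hi:.1f}] Da contains no grid points")
    if vals.size < MIN_WINDOW_POINTS:
        raise ValueError(
            f"noise window [{lo:.1f}, {hi:.1f}] Da has only {vals.size} grid points "
            f"(minimum {MIN_WINDOW_POINTS})"
        )
    return vals


def estimate_noise(spectrum, at_mz: float, rel_width: float = 0.08,
                   residual: np.ndarray | None = None) -> float:
    """Robust noise sigma at ``at_mz`` from the smoothing residual.

    ``residual`` may be passed to reuse one smoothing pass across many
    evaluation points.  A negative raw estimate (possible only through
    percentile inversion on pathological residuals) clamps to 0 with a
    warning.
    """
    if residual is None:
        residual = spectrum.intensities - smooth_sg(spectrum)
    vals = _window_residuals(spectrum.grid, residual, at_mz, rel_width)
    p25, p50 = np.percentile(vals, [25.0, 50.0])  # linear interpolation convention
    sigma = (p50 - p25) / NOISE_DIVISOR
    if sigma < 0:
        warnings.warn(f"negative noise estimate {sigma:.3g} at {at_mz} Da clamped to 0")
        sigma = 0.0
    return float(sigma)


def noise_profile(spectrum, eval_points, rel_width: float = 0.08) -> NoiseProfile:
    """Estimate noise at each of ``eval_points``, sharing one smoothing pass."""
    eval_points = np.asarray(eval_points, dtype=np.float64)
    residual = spectrum.intensities - smooth_sg(spectrum)
    sigma = np.array([
        estimate_noise(spectrum, mz, rel_width, residual=residual) for mz in eval_points
    ])
    return NoiseProfile(eval_mz=eval_points, sigma=sigma, rel_width=rel_width)


def detect_peaks(spectrum, profile: NoiseProfile, snr_cutoff: float,
                 min_separation: int = 3) -> list[Peak]:
    """Local maxima of the smoothed spectrum with SNR >= ``snr_cutoff``.

    SNR is apex intensity over the interpolated local noise sigma, so
    the spectrum should be background-subtracted.  Two guards reject
    artifacts of the smoothing itself: a maximum must rise at least
    ``snr_cutoff`` sigma above its saddle (topographic prominence, vs
    noise wiggles riding on the flank of an intense neighbour), and its
    prominence must exceed twice the local smoothing lack-of-fit (the
    max |residual| within one smoothing window), which suppresses the
    small ringing sidelobes the polynomial filter leaves beside very
    sharp peaks.  ``min_separation`` is the minimum apex distance in
    grid steps (default 3).  Returns peaks sorted by m/z.
    """
    if snr_cutoff <= 0:
        raise ValueError("snr_cutoff must be positive")
    smoothed = smooth_sg(spectrum)
    residual = np.abs(spectrum.intensities - smoothed)
    local_err = maximum_filter1d(residual, size=SG_WINDOW_DEFAULT)
    idx, props = find_peaks(smoothed, distance=max(1, int(min_separation)),
                            prominence=0.0)
    if idx.size == 0:
        return []
    mz = spectrum.grid.mz[idx]
    intensity = smoothed[idx]
    sigma = profile.interp(mz)
    snr = np.divide(intensity, sigma, out=np.full(idx.shape, np.inf), where=sigma > 0)
    prominent = props["prominences"] >= np.maximum(snr_cutoff * sigma, 2.0 * local_err[idx])
    keep = (snr >= snr_cutoff) & prominent
    return [
        Peak(apex_mz=float(m), apex_intensity=float(a), snr=float(s))
        for m, a, s in zip(mz[keep], intensity[keep], snr[keep])
    ]


def peak_density(peaks, mz_range: tuple[float, float] = (3200.0, 30000.0),
                 n_bins: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram of peak apex positions.

    Returns (counts, bin_edges); counts sum to the number of peaks whose
    apex lies within ``mz_range``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = mz_range
    if not hi > lo:
        raise ValueError("empty m/z range")
    apexes = np.array([p.apex_mz for p in peaks], dtype=np.float64)
    counts, edges = np.histogram(apexes, bins=n_bins, range=(lo, hi))
    return counts, edges


def estimate_peak_width(spectrum, peaks, top_k: int) -> list[Peak]:
    """FWHM of the ``top_k`` most intense peaks by half-maximum crossings.

    Crossings are located on the smoothed spectrum by linear
    interpolation.  A peak whose half-maximum level is not reached on
    some side before the signal rises again (overlap with a neighbour)
    gets ``fwhm=None`` - flagged unreliable rather than guessed.  A peak
    whose crossing search runs off the grid edge raises.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    smoothed = smooth_sg(spectrum)
    mz = spectrum.grid.mz
    ranked = sorted(peaks, key=lambda p: p.apex_intensity, reverse=True)[:top_k]
    out: list[Peak] = []
    for pk in ranked:
        i = int(np.argmin(np.abs(mz - pk.apex_mz)))
        half = smoothed[i] / 2.0
        left = _half_crossing(mz, smoothed, i, half, step=-1)
        right = _half_crossing(mz, smoothed, i, half, step=+1)
        fwhm = None
        if left is not None and right is not None:
            fwhm = float(right - left)
        out.append(Peak(pk.apex_mz, pk.apex_intensity, pk.snr, fwhm=fwhm))
    return out


def _half_crossing(mz, y, apex_idx: int, half: float, step: int) -> float | None:
    """Walk from the apex until y drops through ``half``; None if y rises first."""
    i = apex_idx
    while True:
        j = i + step
        if j < 0 or j >= y.size:
            raise ValueError(
                f"peak at {mz[apex_idx]:.1f} Da truncated at the grid edge before "
                "reaching half maximum"
            )
        if y[j] <= half:
            # linear interpolation between j and i
            frac = (y[i] - half) / (y[i] - y[j])
            return float(mz[i] + frac * (mz[j] - mz[i]))
        if y[j] > y[i]:
            return None  # rising again: overlapping neighbour
        i = j
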