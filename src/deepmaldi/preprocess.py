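"""Raw-spectrum alignment, random-subset averaging, convex-hull background
subtraction, windowed normalization, and feature integration.

The processing order is fixed: align raw spectra to internal calibration
points, average a randomly selected fixed number of them, subtract the
lower-convex-hull background, re-align the averages, normalize over the
union of three mass windows, and integrate features between their m/z
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import MzGrid
from .io import FeatureDefinition, RawSpectrum
from .noise import detect_peaks, noise_profile

__all__ = [
    "NORMALIZATION_WINDOWS",
    "CalibrationSet",
    "AverageSpectrum",
    "Excluded",
    "default_match_tol",
    "detect_calibration_points",
    "align_raw_spectrum",
    "average_spectra",
    "lower_hull_baseline",
    "subtract_background",
    "realign_average",
    "normalize",
    "integrate_features",
    "process_average",
]

#: Mass windows (Da) whose union defines the normalization integral.
NORMALIZATION_WINDOWS = ((6100.0, 7500.0), (8500.0, 10700.0), (13300.0, 16400.0))

CALIBRATION_SNR_DEFAULT = 3.0
PRESENCE_FRACTION_DEFAULT = 0.5
MIN_MATCH_FRACTION_DEFAULT = 0.6


def default_match_tol(mz: float) -> float:
    """Peak-to-calibration matching tolerance: max(1 Da, 300 ppm of m/z)."""
    return max(1.0, 300.0e-6 * mz)


@dataclass(frozen=True)
class CalibrationSet:
    """Internal calibration m/z points plus the selection thresholds used."""

    points: np.ndarray = field(repr=False)
    snr_threshold: float = CALIBRATION_SNR_DEFAULT
    presence_fraction: float = PRESENCE_FRACTION_DEFAULT

    def __post_init__(self) -> None:
        pts = np.sort(np.asarray(self.points, dtype=np.float64))
        if pts.size < 2:
            raise ValueError("a calibration set needs at least 2 points (affine fit)")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return int(self.points.size)


@dataclass(frozen=True)
class Excluded:
    """A spectrum that could not be aligned; kept with its reason, never dropped."""

    spectrum: RawSpectrum
    reason: str
    n_matched: int
    n_calibration: int


@dataclass
class AverageSpectrum:
    """Pointwise mean of n aligned raw spectra.

    ``n_shots`` is 800 x the number of raw spectra averaged; the
    processing flags only ever go False -> True (a background cannot be
    un-subtracted).
    """

    grid: MzGrid
    intensities: np.ndarray = field(repr=False)
    n_shots: int = 800
    provenance: tuple = ()
    background_subtracted: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=np.float64)
        if y.shape != (len(self.grid),):
            raise ValueError("intensity vector length does not match grid length")
        self.intensities = y

    @property
    def n_raw(self) -> int:
        return len(self.provenance)


# ---------------------------------------------------------------------------
# calibration and alignment


def _background_free(spectrum) -> np.ndarray:
    return spectrum.intensities - lower_hull_baseline(spectrum.grid.mz, spectrum.intensities)


def _detect_apexes(spectrum, snr_threshold: float, n_noise_points: int = 8) -> np.ndarray:
    """Apex m/z of peaks above ``snr_threshold`` after hull-background removal."""
    flat = type("S", (), {})()
    flat.grid = spectrum.grid
    flat.intensities = _background_free(spectrum)
    eval_points = np.linspace(spectrum.grid.start * 1.05, spectrum.grid.stop * 0.95,
                              n_noise_points)
    prof = noise_profile(flat, eval_points)
    peaks = detect_peaks(flat, prof, snr_cutoff=snr_threshold)
    return np.array([p.apex_mz for p in peaks], dtype=np.float64)


def detect_calibration_points(
    pool: list[RawSpectrum],
    snr_threshold: float = CALIBRATION_SNR_DEFAULT,
    presence_fraction: float = PRESENCE_FRACTION_DEFAULT,
    match_tol=default_match_tol,
) -> CalibrationSet:
    """Select internal calibration points present in the majority of a pool.

    Peaks are detected per spectrum at ``snr_threshold``, apexes are
    clustered across spectra within ``match_tol`` of their m/z, and
    clusters detected in more than ``presence_fraction`` of the pool are
    reported at their median apex position.
    """
    if not pool:
        raise ValueError("raw-spectrum pool is empty")
    records = []  # (apex_mz, spectrum_index)
    for si, spec in enumerate(pool):
        for mz in _detect_apexes(spec, snr_threshold):
            records.append((mz, si))
    records.sort()
    clusters: list[list[tuple[float, int]]] = []
    for mz, si in records:
        if clusters and mz - clusters[-1][-1][0] <= match_tol(mz):
            clusters[-1].append((mz, si))
        else:
            clusters.append([(mz, si)])
    points = []
    need = presence_fraction * len(pool)
    for cl in clusters:
        n_spectra = len({si for _, si in cl})
        if n_spectra > need:
            points.append(float(np.median([mz for mz, _ in cl])))
    if len(points) < 2:
        raise ValueError(
            f"only {len(points)} calibration points found (need >= 2); "
            "lower the SNR threshold or check the pool"
        )
    return CalibrationSet(np.array(points), snr_threshold, presence_fraction)


def _affine_fit(observed: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """Least-squares fit reference ~ a*observed + b."""
    if np.ptp(observed) == 0:
        raise ValueError("degenerate alignment fit: all matched peaks at one m/z")
    a, b = np.polyfit(observed, reference, 1)
    return float(a), float(b)


def _warp_resample(grid: MzGrid, intensities: np.ndarray, a: float, b: float) -> np.ndarray:
    """Intensities of the corrected spectrum x_true = a*x_obs + b on ``grid``."""
    return np.interp((grid.mz - b) / a, grid.mz, intensities)


def align_raw_spectrum(
    raw: RawSpectrum,
    calset: CalibrationSet,
    match_tol=default_match_tol,
    min_match_fraction: float = MIN_MATCH_FRACTION_DEFAULT,
) -> RawSpectrum | Excluded:
    """Affine m/z recalibration of one raw spectrum against a calibration set.

    Detected peaks are matched to calibration points within
    ``match_tol``; if at least ``min_match_fraction`` of calibration
    points find a match, the least-squares affine correction is applied
    and the spectrum linearly resampled onto the common grid.  Otherwise
    an :class:`Excluded` record is returned.
    """
    apexes = _detect_apexes(raw, calset.snr_threshold)
    matched_obs, matched_ref = [], []
    for ref in calset.points:
        if apexes.size == 0:
            break
        j = int(np.argmin(np.abs(apexes - ref)))
        if abs(apexes[j] - ref) <= match_tol(ref):
            matched_obs.append(apexes[j])
            matched_ref.append(ref)
    frac = len(matched_obs) / len(calset)
    if frac < min_match_fraction:
        return Excluded(
            spectrum=raw,
            reason=f"matched {len(matched_obs)}/{len(calset)} calibration points "
                   f"(fraction {frac:.2f} < {min_match_fraction})",
            n_matched=len(matched_obs),
            n_calibration=len(calset),
        )
    a, b = _affine_fit(np.array(matched_obs), np.array(matched_ref))
    corrected = _warp_resample(raw.grid, raw.intensities, a, b)
    return raw.copy(intensities=corrected, aligned=True)


def average_spectra(pool: list[RawSpectrum], n_raw: int, seed: int) -> AverageSpectrum:
    """Average ``n_raw`` aligned raw spectra selected randomly without replacement."""
    if n_raw < 1:
        raise ValueError("n_raw must be >= 1")
    if n_raw > len(pool):
        raise ValueError(f"n_raw={n_raw} exceeds pool size {len(pool)}")
    for i, spec in enumerate(pool):
        if not spec.aligned:
            raise ValueError(f"pool member {i} is not aligned")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(len(pool), size=n_raw, replace=False))
    stack = np.mean([pool[i].intensities for i in chosen], axis=0)
    shots = int(sum(pool[i].shots for i in chosen))
    prov = tuple(pool[i].spot_id if pool[i].spot_id is not None else int(i) for i in chosen)
    return AverageSpectrum(grid=pool[0].grid, intensities=stack, n_shots=shots,
                           provenance=prov)


# ---------------------------------------------------------------------------
# background, normalization, features


def lower_hull_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Background estimate: the lower convex hull of the (x, y) point set.

    Computed by a monotone-chain scan over the x-sorted points; collinear
    points are kept as hull vertices so that an exactly affine spectrum
    reproduces itself.  Returned as the hull evaluated at every x by
    linear interpolation between vertices.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (x[a] - x[o]) * (y[i] - y[o]) - (y[a] - y[o]) * (x[i] - x[o])
            if cross < 0:  # clockwise turn: middle vertex lies above the chord
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x, x[hull], y[hull])


def subtract_background(spectrum: AverageSpectrum) -> AverageSpectrum:
    """Subtract the convex-hull background; output is >= 0 everywhere."""
    if spectrum.background_subtracted:
        raise ValueError("background already subtracted")
    baseline = lower_hull_baseline(spectrum.grid.mz, spectrum.intensities)
    residual = np.maximum(spectrum.intensities - baseline, 0.0)
    return replace(spectrum, intensities=residual, background_subtracted=True)


def realign_average(
    avg: AverageSpectrum,
    calset: CalibrationSet,
    match_tol=default_match_tol,
    min_match_fraction: float = MIN_MATCH_FRACTION_DEFAULT,
) -> AverageSpectrum | Excluded:
    """Re-align an average using peaks common to all averages.

    Same affine code path as raw-spectrum alignment; the calibration set
    is typically built from the averages themselves with
    :func:`detect_calibration_points`.
    """
    apexes = _detect_apexes(avg, calset.snr_threshold)
    matched_obs, matched_ref = [], []
    for ref in calset.points:
        if apexes.size == 0:
            break
        j = int(np.argmin(np.abs(apexes - ref)))
        if abs(apexes[j] - ref) <= match_tol(ref):
            matched_obs.append(apexes[j])
            matched_ref.append(ref)
    frac = len(matched_obs) / len(calset)
    if frac < min_match_fraction:
        return Excluded(spectrum=avg, reason="average could not be re-aligned",
                        n_matched=len(matched_obs), n_calibration=len(calset))
    a, b = _affine_fit(np.array(matched_obs), np.array(matched_ref))
    corrected = _warp_resample(avg.grid, avg.intensities, a, b)
    return replace(avg, intensities=corrected)


def _window_mask(grid: MzGrid, windows) -> np.ndarray:
    mask = np.zeros(len(grid), dtype=bool)
    for lo, hi in windows:
        mask[grid.window_slice(lo, hi)] = True
    return mask


def normalize(spectrum: AverageSpectrum, windows=NORMALIZATION_WINDOWS) -> AverageSpectrum:
    """Divide by the summed intensity over the union of the mass windows."""
    if not spectrum.background_subtracted:
        raise ValueError("normalize requires a background-subtracted spectrum")
    mask = _window_mask(spectrum.grid, windows)
    if not mask.any():
        raise ValueError("normalization windows contain no grid points")
    const = float(spectrum.intensities[mask].sum())
    if const <= 0:
        raise ValueError(f"normalization constant {const} is not positive")
    return replace(spectrum, intensities=spectrum.intensities / const, normalized=True)


def integrate_features(spectrum, defs: list[FeatureDefinition]) -> pd.Series:
    """Feature values: summed intensity at grid points within each boundary pair.

    Boundaries are inclusive on both ends; adjacent features may share a
    boundary point.  Normally applied to a normalized average.
    """
    grid = spectrum.grid
    values = {}
    for fd in defs:
        sl = grid.window_slice(fd.left, fd.right)
        if sl.stop <= sl.start:
            raise ValueError(
                f"feature {fd.feature_id!r} [{fd.left}, {fd.right}] contains no grid points"
            )
        values[fd.feature_id] = float(spectrum.intensities[sl].sum())
    return pd.Series(values, name="value")


def process_average(
    avg: AverageSpectrum,
    defs: list[FeatureDefinition],
    calset: CalibrationSet | None = None,
    windows=NORMALIZATION_WINDOWS,
) -> tuple[AverageSpectrum, pd.Series]:
    """Standard post-averaging pipeline: background -> re-align -> normalize -> integrate."""
    spec = subtract_background(avg)
    if calset is not None:
        realigned = realign_average(spec, calset)
        if isinstance(realigned, Excluded):
            raise ValueError(f"average excluded during re-alignment: {realigned.reason}")
        spec = realigned
    spec = normalize(spec, windows=windows)
    return spec, integrate_features(spec, defs)
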