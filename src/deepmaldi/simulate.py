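"""Forward simulator of pooled linear MALDI-TOF raw spectra with known truth.

The simulated signal model is the one the averaging analysis rests on:
each 800-shot acquisition is y_i(x) = s(x) + r_i(x), where the signal
s(x) is a fixed sum of Gaussian protein peaks on a smooth chemical
baseline and r_i(x) is zero-mean high-frequency noise independent
between acquisitions.  Consequences that real deep averaging exhibits -
noise shrinking as 1/sqrt(n), peak counts saturating at the resolution
limit, CVs falling as a power law in shot number - all follow from this
model and are what the rest of the package measures.

Defaults emulate unfractionated serum profiling: m/z 3-30 kDa, peak
amplitudes spanning four orders of magnitude, peak width growing
linearly with m/z (constant resolving power), and a small per-acquisition
affine m/z miscalibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .grid import MzGrid
from .io import DEFAULT_SHOTS_PER_RAW, ProteinPanel, RawSpectrum, write_spectrum

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_reference_sample",
    "simulate_raw_spectrum",
    "simulate_pool",
    "simulate_cohort",
    "write_pool",
    "write_ground_truth",
    "read_ground_truth",
]

#: Gaussian FWHM in units of sigma.
FWHM_PER_SIGMA = 2.354820045030949  # 2*sqrt(2*ln 2)


def default_baseline(amp1: float = 200.0, scale1: float = 3000.0,
                     amp2: float = 20.0, scale2: float = 15000.0,
                     origin: float = 3000.0) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth non-negative chemical background: two decaying exponentials.

    Mimics matrix-related background that is intense at low m/z and
    decays over the acquisition range.
    """

    def baseline(mz: np.ndarray) -> np.ndarray:
        d = np.asarray(mz, dtype=np.float64) - origin
        return amp1 * np.exp(-d / scale1) + amp2 * np.exp(-d / scale2)

    return baseline


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated acquisition campaign.

    Parameters
    ----------
    grid
        Common m/z axis; default uniform 1 Da over 3-30 kDa.
    n_peaks
        Number of protein peaks in the reference sample.
    amp_range
        (low, high) bounds of the log-uniform amplitude draw.  The
        default spans four orders of magnitude, matching the dynamic
        range deep averaging makes observable in serum.
    resolving_power
        m/z over FWHM; peak sigma at mass m is m / (FWHM_PER_SIGMA * R).
    noise_sigma
        Standard deviation of the per-point noise of one 800-shot
        acquisition, in the same arbitrary units as the amplitudes.
    jitter_scale
        Scale of the per-acquisition affine m/z miscalibration: both the
        fractional stretch (a - 1) and the fractional offset b / m_mid
        are drawn N(0, jitter_scale).
    seed
        Mandatory seed for every stochastic call that takes the config.
    """

    grid: MzGrid = field(default_factory=MzGrid.uniform)
    n_peaks: int = 200
    amp_range: tuple[float, float] = (1.0, 1.0e4)
    resolving_power: float = 700.0
    noise_sigma: float = 1.0
    jitter_scale: float = 1.0e-4
    baseline_params: tuple[float, float, float, float] = (200.0, 3000.0, 20.0, 15000.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        lo, hi = self.amp_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("amplitude range bounds must be positive with high >= low")
        if self.resolving_power <= 0:
            raise ValueError("resolving power must be positive")
        if self.noise_sigma < 0 or self.jitter_scale < 0:
            raise ValueError("noise and jitter scales must be >= 0")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory for stochastic simulation")
        return int(self.seed)

    def baseline(self) -> Callable[[np.ndarray], np.ndarray]:
        a1, s1, a2, s2 = self.baseline_params
        return default_baseline(a1, s1, a2, s2, origin=self.grid.start)

    def peak_sigma(self, mz) -> np.ndarray:
        """Instrumental peak width (Gaussian sigma, Da) at mass ``mz``."""
        return np.asarray(mz, dtype=np.float64) / (FWHM_PER_SIGMA * self.resolving_power)


@dataclass(frozen=True)
class GroundTruth:
    """Known composition of one sample: peaks, baseline, and noise scales."""

    centers: np.ndarray
    amplitudes: np.ndarray
    widths: np.ndarray
    baseline: Callable[[np.ndarray], np.ndarray]
    noise_sigma: float
    jitter_scale: float

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=np.float64)
        a = np.asarray(self.amplitudes, dtype=np.float64)
        w = np.asarray(self.widths, dtype=np.float64)
        if not (c.shape == a.shape == w.shape):
            raise ValueError("centers, amplitudes and widths must have equal length")
        if np.any(a <= 0) or np.any(w <= 0):
            raise ValueError("amplitudes and widths must be positive")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "widths", w)

    @property
    def n_peaks(self) -> int:
        return int(self.centers.size)

    def signal(self, mz: np.ndarray) -> np.ndarray:
        """Clean signal s(x) = baseline + sum of Gaussian peaks at ``mz``.

        ``mz`` must be sorted ascending (peak evaluation windows rely on
        searchsorted).
        """
        mz = np.asarray(mz, dtype=np.float64)
        y = self.baseline(mz).astype(np.float64)
        for c, a, w in zip(self.centers, self.amplitudes, self.widths):
            lo = np.searchsorted(mz, c - 8.0 * w)
            hi = np.searchsorted(mz, c + 8.0 * w)
            if hi > lo:
                seg = mz[lo:hi]
                y[lo:hi] += a * np.exp(-0.5 * ((seg - c) / w) ** 2)
        return y

    def with_amplitudes(self, amplitudes: np.ndarray) -> "GroundTruth":
        return replace(self, amplitudes=np.asarray(amplitudes, dtype=np.float64))

    def with_widths(self, widths: np.ndarray) -> "GroundTruth":
        return replace(self, widths=np.asarray(widths, dtype=np.float64))


def simulate_reference_sample(config: SimConfig) -> GroundTruth:
    """Draw a reference-sample composition from the configured conditions.

    Peak centers are uniform over the grid interior, amplitudes
    log-uniform over ``amp_range``, widths set by the constant resolving
    power.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.require_seed())
    grid = config.grid
    if config.n_peaks == 0:
        empty = np.empty(0)
        return GroundTruth(empty, empty.copy(), empty.copy(), config.baseline(),
                           config.noise_sigma, config.jitter_scale)
    # keep peaks clear of the grid edges so apexes stay on-grid after jitter
    margin = 8.0 * config.peak_sigma(grid.stop)
    centers = rng.uniform(grid.start + margin, grid.stop - margin, size=config.n_peaks)
    centers.sort()
    lo, hi = config.amp_range
    amplitudes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_peaks))
    widths = config.peak_sigma(centers)
    return GroundTruth(centers, amplitudes, widths, config.baseline(),
                       config.noise_sigma, config.jitter_scale)


def simulate_raw_spectrum(truth: GroundTruth, grid: MzGrid, seed: int,
                          spot_id: str | None = None,
                          sample_id: str | None = None) -> RawSpectrum:
    """Simulate one 800-shot acquisition y = s(warped x) + noise.

    The miscalibration is affine, x -> a*x + b, with a - 1 and b/m_mid
    drawn at ``truth.jitter_scale``; the clean signal is evaluated
    directly at the warped coordinates (exact, no resampling error), then
    i.i.d. Gaussian noise of scale ``truth.noise_sigma`` is added.
    """
    if truth.n_peaks and not (grid.start <= truth.centers.min()
                              and truth.centers.max() <= grid.stop):
        raise ValueError("ground-truth peak centers fall outside the grid")
    rng = np.random.default_rng(seed)
    if truth.jitter_scale > 0:
        m_mid = 0.5 * (grid.start + grid.stop)
        a = 1.0 + truth.jitter_scale * rng.standard_normal()
        b = truth.jitter_scale * m_mid * rng.standard_normal()
    else:
        a, b = 1.0, 0.0
    y = truth.signal(a * grid.mz + b)
    if truth.noise_sigma > 0:
        y = y + truth.noise_sigma * rng.standard_normal(len(grid))
    return RawSpectrum(grid=grid, intensities=y, shots=DEFAULT_SHOTS_PER_RAW,
                       spot_id=spot_id, sample_id=sample_id,
                       aligned=(truth.jitter_scale == 0))


def simulate_pool(truth: GroundTruth, grid: MzGrid, n_raw: int, seed: int,
                  sample_id: str | None = None) -> list[RawSpectrum]:
    """Simulate a pool of ``n_raw`` independent acquisitions of one sample."""
    if n_raw < 1:
        raise ValueError("n_raw must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_raw) % (2 ** 31)
    return [
        simulate_raw_spectrum(truth, grid, int(s), spot_id=f"spot{i:05d}",
                              sample_id=sample_id)
        for i, s in enumerate(child_seeds)
    ]


def simulate_cohort(
    n_samples: int,
    config: SimConfig,
    seed: int,
    between_sample_cv: float = 0.15,
    n_proteins: int = 120,
    planted_links: Sequence[tuple[int, Sequence[int], float]] = (),
) -> tuple[list[GroundTruth], ProteinPanel]:
    """Simulate a cohort sharing one peak template plus a protein panel.

    Each sample's peak amplitudes vary lognormally around the cohort
    means with coefficient of variation ``between_sample_cv``.  The
    protein panel contains ``n_proteins`` relative abundances per sample;
    entries of ``planted_links`` are (peak_index, protein_indices, rho)
    tuples planting a Spearman correlation of about ``rho`` between the
    named peak's amplitude and each listed protein, via a Gaussian
    copula (latent Pearson r = 2 sin(pi * rho / 6)).  Unlinked proteins
    are independent lognormals.
    """
    if n_samples < 2:
        raise ValueError("a cohort needs at least 2 samples")
    if not 0 <= between_sample_cv:
        raise ValueError("between_sample_cv must be >= 0")
    base = simulate_reference_sample(config)
    rng = np.random.default_rng(seed)
    # lognormal multipliers with the requested CV around unit mean
    if between_sample_cv > 0:
        s = np.sqrt(np.log1p(between_sample_cv ** 2))
        z = rng.standard_normal((n_samples, base.n_peaks))
        multipliers = np.exp(s * z - 0.5 * s ** 2)
    else:
        z = np.zeros((n_samples, base.n_peaks))
        multipliers = np.ones((n_samples, base.n_peaks))
    truths = [base.with_amplitudes(base.amplitudes * multipliers[i]) for i in range(n_samples)]

    latent = rng.standard_normal((n_samples, n_proteins))
    for peak_idx, protein_idxs, rho in planted_links:
        if not -1.0 < rho < 1.0:
            raise ValueError("planted Spearman target must lie in (-1, 1)")
        if not 0 <= peak_idx < base.n_peaks:
            raise IndexError(f"planted peak index {peak_idx} out of range")
        r = 2.0 * np.sin(np.pi * rho / 6.0)  # Gaussian-copula latent correlation
        zq = z[:, peak_idx]
        for p in protein_idxs:
            latent[:, p] = r * zq + np.sqrt(1.0 - r ** 2) * latent[:, p]
    abundances = np.exp(0.5 * latent)  # lognormal relative abundances
    panel = ProteinPanel(pd.DataFrame(
        abundances,
        index=[f"S{i:03d}" for i in range(n_samples)],
        columns=[f"P{p:04d}" for p in range(n_proteins)],
    ))
    return truths, panel


# ---------------------------------------------------------------------------
# on-disk pools


def write_pool(pool: Sequence[RawSpectrum], directory, seed: int | None = None) -> Path:
    """Write a pool as 2-column text files plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, spec in enumerate(pool):
        fname = f"raw_{i:05d}.txt"
        write_spectrum(spec, directory / fname)
        entries.append({"file": fname, "sample_id": spec.sample_id,
                        "spot_id": spec.spot_id, "shots": spec.shots})
    manifest = {"n_spectra": len(pool), "seed": seed, "spectra": entries}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return directory


def write_ground_truth(truth: GroundTruth, path) -> None:
    pd.DataFrame({
        "center": truth.centers,
        "amplitude": truth.amplitudes,
        "width": truth.widths,
    }).to_csv(path, index=False)


def read_ground_truth(path, baseline: Callable[[np.ndarray], np.ndarray] | None = None,
                      noise_sigma: float = 0.0, jitter_scale: float = 0.0) -> GroundTruth:
    df = pd.read_csv(path)
    if baseline is None:
        baseline = lambda mz: np.zeros_like(np.asarray(mz, dtype=float))  # noqa: E731
    return GroundTruth(df["center"].to_numpy(), df["amplitude"].to_numpy(),
                       df["width"].to_numpy(), baseline, noise_sigma, jitter_scale)
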