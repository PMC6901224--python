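"""Common m/z axis shared by raw and averaged spectra.

Linear-mode TOF acquisitions are resampled onto one strictly increasing
m/z grid so that spectra can be averaged pointwise.  The default grid is
uniform at 1 Da over the 3-30 kDa protein profiling range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MzGrid"]


@dataclass(frozen=True)
class MzGrid:
    """Strictly increasing m/z axis in Da.

    Parameters
    ----------
    mz
        Ordered m/z values.  Must be strictly increasing and contain at
        least two points.
    """

    mz: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.float64)
        if mz.ndim != 1 or mz.size < 2:
            raise ValueError("m/z grid must be a 1-D array with at least 2 points")
        if not np.all(np.diff(mz) > 0):
            raise ValueError("m/z grid must be strictly increasing")
        object.__setattr__(self, "mz", mz)

    @classmethod
    def uniform(cls, start: float = 3000.0, stop: float = 30000.0, step: float = 1.0) -> "MzGrid":
        """Uniform grid covering [start, stop] with spacing ``step`` Da."""
        if step <= 0:
            raise ValueError("grid step must be positive")
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def start(self) -> float:
        return float(self.mz[0])

    @property
    def stop(self) -> float:
        return float(self.mz[-1])

    @property
    def step(self) -> float:
        """Median spacing in Da (exact spacing for uniform grids)."""
        return float(np.median(np.diff(self.mz)))

    def contains(self, value: float) -> bool:
        return bool(self.start <= value <= self.stop)

    def window_slice(self, lo: float, hi: float) -> slice:
        """Index slice of grid points with lo <= m/z <= hi (inclusive ends)."""
        i0 = int(np.searchsorted(self.mz, lo, side="left"))
        i1 = int(np.searchsorted(self.mz, hi, side="right"))
        return slice(i0, i1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MzGrid):
            return NotImplemented
        return self.mz.shape == other.mz.shape and bool(np.array_equal(self.mz, other.mz))

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((float(self.mz[0]), float(self.mz[-1]), int(self.mz.size)))
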