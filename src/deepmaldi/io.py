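"""Readers and writers for spectra, feature definitions, feature tables,
protein panels, and protein sets.

Spectra travel as plain 2-column (m/z, intensity) text; feature
definitions, feature tables and protein panels as CSV; protein sets as
GMT lines (name, description, protein ids).  Readers validate and reject
malformed input with the offending line number rather than coercing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import MzGrid

__all__ = [
    "RawSpectrum",
    "FeatureDefinition",
    "FeatureTable",
    "ProteinPanel",
    "ProteinSet",
    "read_spectrum",
    "write_spectrum",
    "read_feature_definitions",
    "write_feature_definitions",
    "read_feature_table",
    "write_feature_table",
    "read_protein_panel",
    "write_protein_panel",
    "read_protein_sets",
    "write_protein_sets",
]

DEFAULT_SHOTS_PER_RAW = 800


@dataclass
class RawSpectrum:
    """One acquisition: intensities on an m/z grid, 800 laser shots by default."""

    grid: MzGrid
    intensities: np.ndarray = field(repr=False)
    shots: int = DEFAULT_SHOTS_PER_RAW
    spot_id: str | None = None
    sample_id: str | None = None
    aligned: bool = False

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=np.float64)
        if y.shape != (len(self.grid),):
            raise ValueError(
                f"intensity vector length {y.size} does not match grid length {len(self.grid)}"
            )
        if self.shots <= 0:
            raise ValueError("shots must be positive")
        self.intensities = y

    def copy(self, **changes) -> "RawSpectrum":
        out = replace(self, **changes)
        out.intensities = out.intensities.copy()
        return out


@dataclass(frozen=True)
class FeatureDefinition:
    """An m/z interval [left, right] in Da whose integrated intensity is read out."""

    feature_id: str
    left: float
    right: float

    def __post_init__(self) -> None:
        if not self.left < self.right:
            raise ValueError(
                f"feature {self.feature_id!r}: left boundary {self.left} must be < right {self.right}"
            )


@dataclass(frozen=True)
class ProteinSet:
    """A named biological process and the protein ids annotated to it."""

    name: str
    proteins: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"protein set {self.name!r} has no proteins")


class ProteinPanel:
    """Sample x protein matrix of relative abundances (e.g. an aptamer panel)."""

    def __init__(self, data: pd.DataFrame):
        if data.isna().any().any():
            bad = data.index[data.isna().any(axis=1)].tolist()
            raise ValueError(f"protein panel has missing values for samples {bad}")
        if data.shape[0] < 2:
            raise ValueError("protein panel needs at least 2 samples")
        self.data = data.astype(np.float64)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def proteins(self) -> list[str]:
        return list(self.data.columns.astype(str))

    def __repr__(self) -> str:
        return f"ProteinPanel({self.data.shape[0]} samples x {self.data.shape[1]} proteins)"


class FeatureTable:
    """Feature values f(i, j, k) indexed by sample i, feature j, run k.

    Stored long-form with columns (sample, feature, run, value); must be
    rectangular over the declared sample/feature/run labels.
    """

    COLUMNS = ("sample", "feature", "run", "value")

    def __init__(self, data: pd.DataFrame):
        missing = set(self.COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        df = data.loc[:, list(self.COLUMNS)].copy()
        df["value"] = df["value"].astype(np.float64)
        counts = df.groupby(["sample", "feature", "run"], sort=False).size()
        if (counts > 1).any():
            raise ValueError("duplicate (sample, feature, run) entries in feature table")
        n = df["sample"].nunique() * df["feature"].nunique() * df["run"].nunique()
        if len(df) != n:
            raise ValueError(
                f"feature table is not rectangular: {len(df)} rows for "
                f"{df['sample'].nunique()} samples x {df['feature'].nunique()} features "
                f"x {df['run'].nunique()} runs"
            )
        self.data = df

    @property
    def samples(self) -> list:
        return list(pd.unique(self.data["sample"]))

    @property
    def features(self) -> list:
        return list(pd.unique(self.data["feature"]))

    @property
    def runs(self) -> list:
        return list(pd.unique(self.data["run"]))

    def cube(self) -> np.ndarray:
        """Values as an array of shape (samples, features, runs)."""
        wide = self.data.pivot_table(
            index="sample", columns=["feature", "run"], values="value", sort=False
        )
        i, j, k = len(self.samples), len(self.features), len(self.runs)
        return (
            wide.reindex(index=self.samples)
            .reindex(columns=pd.MultiIndex.from_product([self.features, self.runs]))
            .to_numpy()
            .reshape(i, j, k)
        )

    def wide(self, run) -> pd.DataFrame:
        """Sample x feature matrix for a single run."""
        sub = self.data[self.data["run"] == run]
        if sub.empty:
            raise KeyError(f"run {run!r} not present in feature table")
        return (
            sub.pivot(index="sample", columns="feature", values="value")
            .reindex(index=self.samples)
            .reindex(columns=self.features)
        )

    def __repr__(self) -> str:
        return (
            f"FeatureTable({len(self.samples)} samples x {len(self.features)} features "
            f"x {len(self.runs)} runs)"
        )


# ---------------------------------------------------------------------------
# spectrum text format


def _parse_number_pair(tokens: Sequence[str]) -> tuple[float, float] | None:
    if len(tokens) != 2:
        return None
    try:
        return float(tokens[0]), float(tokens[1])
    except ValueError:
        return None


def read_spectrum(path, shots: int = DEFAULT_SHOTS_PER_RAW) -> RawSpectrum:
    """Read a 2-column (m/z, intensity) text spectrum.

    Whitespace- or comma-delimited; ``#`` comment lines are ignored; a
    single leading non-numeric header line is skipped.  m/z must be
    strictly increasing.
    """
    path = Path(path)
    mz: list[float] = []
    y: list[float] = []
    header_allowed = True
    with open(path) as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.replace(",", " ").split()
            pair = _parse_number_pair(tokens)
            if pair is None:
                if header_allowed and not mz:
                    header_allowed = False
                    continue
                raise ValueError(f"{path.name}:{lineno}: expected two numeric columns, got {line!r}")
            mz.append(pair[0])
            y.append(pair[1])
    if not mz:
        raise ValueError(f"{path.name}: no data rows")
    mz_arr = np.asarray(mz)
    if not np.all(np.diff(mz_arr) > 0):
        bad = int(np.flatnonzero(np.diff(mz_arr) <= 0)[0]) + 2
        raise ValueError(f"{path.name}: m/z not strictly increasing at data row {bad}")
    return RawSpectrum(grid=MzGrid(mz_arr), intensities=np.asarray(y), shots=shots)


def write_spectrum(spectrum, path) -> None:
    """Write any spectrum-like object (``.grid``, ``.intensities``) as 2-column text."""
    arr = np.column_stack([spectrum.grid.mz, spectrum.intensities])
    np.savetxt(path, arr, fmt="%.10g", delimiter="\t")


# ---------------------------------------------------------------------------
# feature definitions


def read_feature_definitions(path, grid: MzGrid | None = None) -> list[FeatureDefinition]:
    """Read a CSV of feature boundaries with columns id,left,right.

    If ``grid`` is given, boundaries must fall inside its range.
    Overlapping features are legal (boundaries are designed wide to allow
    for peak-width variation and small alignment shifts).
    """
    path = Path(path)
    out: list[FeatureDefinition] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() in {"id", "feature", "feature_id"}:
                continue
            if len(row) < 3:
                raise ValueError(f"{path.name}:{lineno}: expected id,left,right")
            fid = row[0].strip()
            try:
                left, right = float(row[1]), float(row[2])
            except ValueError:
                raise ValueError(f"{path.name}:{lineno}: non-numeric boundary") from None
            try:
                fd = FeatureDefinition(fid, left, right)
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from None
            if grid is not None and not (grid.contains(left) and grid.contains(right)):
                raise ValueError(
                    f"{path.name}:{lineno}: feature {fid!r} boundary outside grid "
                    f"[{grid.start}, {grid.stop}]"
                )
            out.append(fd)
    return out


def write_feature_definitions(defs: Iterable[FeatureDefinition], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "left", "right"])
        for fd in defs:
            writer.writerow([fd.feature_id, f"{fd.left:.6g}", f"{fd.right:.6g}"])


# ---------------------------------------------------------------------------
# feature tables / protein panels


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path)
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_protein_panel(path) -> ProteinPanel:
    df = pd.read_csv(path, index_col=0)
    return ProteinPanel(df)


def write_protein_panel(panel: ProteinPanel, path) -> None:
    panel.data.to_csv(path)


# ---------------------------------------------------------------------------
# protein sets (GMT)


def read_protein_sets(path) -> list[ProteinSet]:
    """Read GMT-style protein sets: name TAB description TAB id TAB id ...

    Protein ids absent from a given panel are kept here; intersection
    with the measured panel happens at enrichment time.
    """
    path = Path(path)
    sets: list[ProteinSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs name, description and >= 1 protein id"
                )
            name, desc, ids = parts[0], parts[1], [p for p in parts[2:] if p.strip()]
            if name in seen:
                raise ValueError(f"{path.name}:{lineno}: duplicate process name {name!r}")
            if not ids:
                raise ValueError(f"{path.name}:{lineno}: protein set {name!r} has no ids")
            seen.add(name)
            sets.append(ProteinSet(name=name, description=desc, proteins=tuple(ids)))
    return sets


def write_protein_sets(sets: Iterable[ProteinSet], path) -> None:
    with open(path, "w") as fh:
        for ps in sets:
            fh.write("\t".join([ps.name, ps.description, *ps.proteins]) + "\n")
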