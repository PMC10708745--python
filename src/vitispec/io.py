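"""Spectral-library data model and wide-CSV readers/writers.

A *spectral library* is a set of samples measured on one shared wavelength
grid (here the 350-2500 nm VNIR-SWIR range at 1 nm native resolution),
optionally annotated with the three wet-chemistry maturity targets.  All
downstream modules consume :class:`SpectralLibrary` objects produced here.

The on-disk dialect is a wide CSV: one row per sample with columns
``sample_id, variety, date, brix, ph, ta`` followed by one column per
wavelength whose header is the wavelength in nm.  Reflectance is stored as a
unitless fraction in (0, 1]; files recorded in percent are auto-detected
(any value > 1.5) and rescaled, and out-of-range values are clipped to
[1e-6, 1] so that the pseudo-absorbance transform log10(1/R) stays finite.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WAVELENGTH_MIN_NM = 350.0
WAVELENGTH_MAX_NM = 2500.0

#: lower clip bound for reflectance after ingestion validation
REFLECTANCE_FLOOR = 1e-6

TARGET_NAMES = ("brix", "ph", "ta")


class LibraryFormatError(ValueError):
    """Malformed library file (missing/duplicate ids, bad columns)."""


class GridError(ValueError):
    """Wavelength-grid inconsistency or degeneracy."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths in nm, all within [350, 2500]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise GridError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(values) <= 0):
            raise GridError("wavelengths must be strictly increasing")
        if values[0] < WAVELENGTH_MIN_NM or values[-1] > WAVELENGTH_MAX_NM:
            raise GridError(
                f"wavelengths must lie within [{WAVELENGTH_MIN_NM:g}, "
                f"{WAVELENGTH_MAX_NM:g}] nm"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with ndarray field
        return hash(self.values.tobytes())


@dataclass
class Spectrum:
    """One spectrum on a grid.

    ``reflectance`` holds unitless fractions for measured spectra; derived
    quantities (pseudo-absorbance, derivatives) reuse the container, so only
    finiteness and length are enforced here.  The (0, 1] range contract is
    applied at ingestion (:func:`read_library`) and by the simulator.
    """

    grid: WavelengthGrid
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.shape != (len(self.grid),):
            raise GridError(
                f"spectrum length {self.reflectance.shape} does not match "
                f"grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("spectrum contains non-finite values")


@dataclass
class MaturityTargets:
    """Ground-truth maturity indicators for one sample.

    ta is expressed as tartaric-acid equivalents on the as-recorded scale
    (values of a few units to a few tens of units per liter).
    """

    brix: float
    ph: float
    ta: float

    def __post_init__(self) -> None:
        if not self.brix > 0:
            raise ValueError(f"brix must be positive, got {self.brix}")
        if not 0 < self.ph < 14:
            raise ValueError(f"ph must be in (0, 14), got {self.ph}")
        if not self.ta > 0:
            raise ValueError(f"ta must be positive, got {self.ta}")

    def as_array(self) -> np.ndarray:
        return np.array([self.brix, self.ph, self.ta], dtype=float)


@dataclass
class SampleRecord:
    sample_id: str
    variety: str
    sampling_date: datetime.date
    spectrum: Spectrum
    targets: Optional[MaturityTargets] = None


@dataclass
class SpectralLibrary:
    """Samples sharing one wavelength grid."""

    records: list[SampleRecord]
    grid: WavelengthGrid = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.records:
            raise LibraryFormatError("a spectral library must be non-empty")
        if self.grid is None:
            self.grid = self.records[0].spectrum.grid
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise LibraryFormatError("duplicate sample_id in library")
        for r in self.records:
            if r.spectrum.grid != self.grid:
                raise GridError(
                    f"record {r.sample_id} is not on the shared grid"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def has_targets(self) -> bool:
        return all(r.targets is not None for r in self.records)

    def reflectance_matrix(self) -> np.ndarray:
        """(n_samples, n_wavelengths) reflectance matrix."""
        return np.vstack([r.spectrum.reflectance for r in self.records])

    def target_matrix(self, targets: Sequence[str] = TARGET_NAMES) -> np.ndarray:
        """(n_samples, len(targets)) matrix of ground-truth values."""
        if not self.has_targets:
            raise LibraryFormatError("library has records without targets")
        rows = []
        for r in self.records:
            vals = r.targets.as_array()
            idx = [TARGET_NAMES.index(t) for t in targets]
            rows.append(vals[idx])
        return np.vstack(rows)

    def dates(self) -> np.ndarray:
        """ISO date strings, the stratification labels for outer CV."""
        return np.array([r.sampling_date.isoformat() for r in self.records])

    def varieties(self) -> np.ndarray:
        return np.array([r.variety for r in self.records])

    def subset(self, indices: Iterable[int]) -> "SpectralLibrary":
        return SpectralLibrary([self.records[i] for i in indices], self.grid)


def _validate_reflectance(matrix: np.ndarray) -> np.ndarray:
    """Apply the ingestion contract: fraction dialect, clipped to (0, 1]."""
    if not np.all(np.isfinite(matrix)):
        raise LibraryFormatError("non-finite reflectance values")
    if np.nanmax(matrix) > 1.5:
        logger.warning(
            "reflectance values > 1.5 detected; assuming percent dialect "
            "and dividing by 100"
        )
        matrix = matrix / 100.0
    if np.any(matrix <= 0) or np.any(matrix > 1):
        logger.warning(
            "reflectance outside (0, 1] after scaling; clipping to "
            "[%g, 1]", REFLECTANCE_FLOOR
        )
        matrix = np.clip(matrix, REFLECTANCE_FLOOR, 1.0)
    return matrix


def read_library(path: str | Path) -> SpectralLibrary:
    """Read a wide-CSV spectral library (optionally gzip-compressed).

    Wavelength columns are identified by numeric headers and sorted into
    ascending order; metadata columns ``sample_id``, ``variety`` and ``date``
    are required, target columns ``brix``/``ph``/``ta`` optional (empty cells
    mean absent targets).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"sample_id", "variety", "date"}
    missing = required - set(df.columns)
    if missing:
        raise LibraryFormatError(f"missing required columns: {sorted(missing)}")

    wl_cols: list[tuple[float, str]] = []
    for col in df.columns:
        try:
            wl_cols.append((float(col), col))
        except ValueError:
            continue
    if not wl_cols:
        raise LibraryFormatError("no wavelength columns found")
    wl_cols.sort(key=lambda t: t[0])
    wavelengths = np.array([w for w, _ in wl_cols])
    grid = WavelengthGrid(wavelengths)

    if df["sample_id"].duplicated().any():
        raise LibraryFormatError("duplicate sample_id values in file")

    try:
        matrix = df[[c for _, c in wl_cols]].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise LibraryFormatError(f"non-numeric reflectance value: {exc}") from exc
    if np.isnan(matrix).any():
        raise LibraryFormatError("missing reflectance values")
    matrix = _validate_reflectance(matrix)

    has_target_cols = all(t in df.columns for t in TARGET_NAMES)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        targets = None
        if has_target_cols:
            vals = [getattr(row, t) for t in TARGET_NAMES]
            if not any(pd.isna(v) for v in vals):
                targets = MaturityTargets(*(float(v) for v in vals))
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                variety=str(row.variety),
                sampling_date=datetime.date.fromisoformat(str(row.date)),
                spectrum=Spectrum(grid, matrix[i]),
                targets=targets,
            )
        )
    return SpectralLibrary(records, grid)


def write_library(lib: SpectralLibrary, path: str | Path) -> None:
    """Write a library in the wide-CSV dialect readable by :func:`read_library`.

    Floats are serialized with full (shortest round-trip) precision so the
    write/read round trip is the identity at value level.
    """
    path = Path(path)
    meta = {
        "sample_id": [r.sample_id for r in lib.records],
        "variety": [r.variety for r in lib.records],
        "date": [r.sampling_date.isoformat() for r in lib.records],
    }
    for j, t in enumerate(TARGET_NAMES):
        meta[t] = [
            r.targets.as_array()[j] if r.targets is not None else np.nan
            for r in lib.records
        ]
    df = pd.DataFrame(meta)
    spectra = pd.DataFrame(
        lib.reflectance_matrix(),
        columns=[format(w, "g") for w in lib.grid.values],
    )
    df = pd.concat([df, spectra], axis=1)
    # %.17g guarantees bit-exact float round trips through the CSV
    df.to_csv(path, index=False, float_format="%.17g")


def subsample_wavelengths(lib: SpectralLibrary, factor: int) -> SpectralLibrary:
    """Decimate the grid, keeping index 0 and every ``factor``-th point.

    On the native 350-2500 nm 1 nm grid (2151 points) a factor of 10 keeps
    the 216 wavelengths 350, 360, ..., 2500 nm used as model inputs.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return lib
    L = len(lib.grid)
    if factor > L:
        raise GridError(f"factor {factor} exceeds grid length {L}")
    keep = np.arange(0, L, factor)
    grid = WavelengthGrid(lib.grid.values[keep])
    records = [
        SampleRecord(
            r.sample_id,
            r.variety,
            r.sampling_date,
            Spectrum(grid, r.spectrum.reflectance[keep]),
            r.targets,
        )
        for r in lib.records
    ]
    return SpectralLibrary(records, grid)


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra (e.g. three berries per bunch)."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise GridError("replicate spectra are on different grids")
    mean = np.mean([s.reflectance for s in spectra], axis=0)
    return Spectrum(grid, mean)
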