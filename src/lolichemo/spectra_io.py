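"""Reading, writing and normalising wavelength-gridded NIR spectra.

Datasets are wide delimited tables: one row per (sample, replicate), the
columns being ``sample_id``, ``replicate``, any number of reference-value
columns (constituent concentrations, mg·kg⁻¹ for alkaloids, mg·g⁻¹ for
mycelium) and one column per wavelength, labelled by its position in nm.
Spectral values are absorbance, stored as log10(1/R) of the reflectance R.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    DuplicateSpectrumError,
    EmptyDatasetError,
    FormatError,
)

META_COLUMNS = ("sample_id", "replicate")

__all__ = [
    "WavelengthGrid",
    "SpectraSet",
    "DEFAULT_GRID",
    "read_spectra",
    "write_spectra",
    "reflectance_to_absorbance",
    "average_replicates",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """A uniform wavelength grid in nm.

    The conventional scanning-monochromator grid used throughout this
    package runs from 1100 to 2000 nm in 2 nm steps, i.e. 451 points.
    """

    start_nm: float
    end_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if self.step_nm <= 0 or self.end_nm <= self.start_nm:
            raise FormatError(
                f"invalid grid [{self.start_nm}, {self.end_nm}] step {self.step_nm}"
            )
        n = (self.end_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise FormatError("grid span is not an integer number of steps")

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    def values(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    @classmethod
    def from_values(cls, wavelengths: Sequence[float]) -> "WavelengthGrid":
        wl = np.asarray(wavelengths, dtype=float)
        if wl.size < 2:
            raise FormatError("a grid needs at least two wavelengths")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise FormatError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6 * steps[0]):
            raise FormatError("non-uniform wavelength spacing")
        return cls(float(wl[0]), float(wl[-1]), float(steps[0]))


DEFAULT_GRID = WavelengthGrid(1100.0, 2000.0, 2.0)


@dataclass
class SpectraSet:
    """A matrix of absorbance spectra with per-row metadata.

    Parameters
    ----------
    wavelengths
        Wavelength axis in nm, strictly increasing.  After derivative
        pre-treatments the axis is no longer uniform-from-file and is kept
        as an explicit vector.
    matrix
        ``(n_rows, n_points)`` absorbance values, log10(1/R).
    meta
        One row per spectrum: ``sample_id`` (required), ``replicate``
        (absent once replicates have been averaged) and reference-value
        columns.  Missing references are NaN.
    """

    wavelengths: np.ndarray
    matrix: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise FormatError("spectral matrix must be 2-D")
        if self.matrix.shape[1] != self.wavelengths.size:
            raise FormatError("matrix width does not match wavelength axis")
        if len(self.meta) != self.matrix.shape[0]:
            raise FormatError("metadata length does not match matrix rows")
        if "sample_id" not in self.meta.columns:
            raise FormatError("metadata must carry a sample_id column")
        if not np.all(np.isfinite(self.matrix)):
            raise FormatError("non-finite absorbance values")
        self.meta = self.meta.reset_index(drop=True)

    # -- basic views ---------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_points(self) -> int:
        return self.matrix.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.meta["sample_id"].to_numpy()

    @property
    def is_averaged(self) -> bool:
        return "replicate" not in self.meta.columns

    @property
    def reference_columns(self) -> list[str]:
        return [c for c in self.meta.columns if c not in META_COLUMNS]

    def references(self, constituent: str) -> np.ndarray:
        if constituent not in self.meta.columns:
            raise KeyError(f"no reference column {constituent!r}")
        return self.meta[constituent].to_numpy(dtype=float)

    # -- derivation helpers -------------------------------------------
    def subset(self, index: np.ndarray | Sequence[int]) -> "SpectraSet":
        """Row subset (boolean mask or integer positions), metadata aligned."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectraSet(
            wavelengths=self.wavelengths,
            matrix=self.matrix[index],
            meta=self.meta.iloc[index].reset_index(drop=True),
        )

    def with_matrix(
        self, matrix: np.ndarray, wavelengths: np.ndarray | None = None
    ) -> "SpectraSet":
        """Same samples, new spectral values (e.g. after a pre-treatment)."""
        return SpectraSet(
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            matrix=matrix,
            meta=self.meta.copy(),
        )


def reflectance_to_absorbance(r: np.ndarray | float) -> np.ndarray | float:
    """Convert reflectance fractions to absorbance, log10(1/R).

    Raises
    ------
    DomainError
        If any reflectance is <= 0 (or > 1, which is not physical for a
        referenced reflectance measurement).
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("reflectance must be strictly positive")
    if np.any(arr > 1):
        raise DomainError("reflectance fraction cannot exceed 1")
    out = -np.log10(arr)
    return out if np.ndim(r) else float(out)


def _detect_separator(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_spectra(
    path: str | Path | io.IOBase,
    layout: Mapping[str, str] | None = None,
    reflectance: bool = False,
) -> SpectraSet:
    """Read a wide delimited spectra table into a :class:`SpectraSet`.

    Parameters
    ----------
    path
        File path or open text handle, comma- or tab-separated, UTF-8.
    layout
        Optional column-name remapping, e.g. ``{"sample_id": "id"}`` if the
        file calls its identifier column ``id``.  Keys are the canonical
        names, values the on-file names.
    reflectance
        If True the spectral cells are reflectance fractions and are
        converted to log10(1/R) on ingest.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = path.read()
    lines = text.splitlines()
    if not lines:
        raise EmptyDatasetError("empty file")
    sep = _detect_separator(lines[0])
    header_cells = [c.strip() for c in lines[0].split(sep)]
    if len(header_cells) != len(set(header_cells)):
        raise DuplicateSpectrumError("duplicated column in header")
    # round_trip parsing so write/read reproduces float64 values bit-for-bit
    df = pd.read_csv(io.StringIO(text), sep=sep, float_precision="round_trip")
    if df.empty:
        raise EmptyDatasetError("no data rows")

    rename = {v: k for k, v in (layout or {}).items()}
    df = df.rename(columns=rename)

    wl_cols: list[str] = []
    wl_vals: list[float] = []
    for col in df.columns:
        try:
            wl_vals.append(float(col))
            wl_cols.append(col)
        except ValueError:
            continue
    if len(wl_cols) != len(set(wl_vals)):
        raise DuplicateSpectrumError("duplicated wavelength column")
    if len(wl_cols) < 2:
        raise FormatError("fewer than two wavelength columns")
    order = np.argsort(wl_vals)
    wl_cols = [wl_cols[i] for i in order]
    wl = np.asarray(wl_vals, dtype=float)[order]
    WavelengthGrid.from_values(wl)  # validates uniform spacing

    if "sample_id" not in df.columns:
        raise FormatError("missing sample_id column")
    meta_cols = [c for c in df.columns if c not in wl_cols]
    meta = df[meta_cols].copy()
    meta["sample_id"] = meta["sample_id"].astype(str)

    if "replicate" in meta.columns:
        key = meta[["sample_id", "replicate"]]
        if key.duplicated().any():
            raise DuplicateSpectrumError("duplicated (sample_id, replicate) row")
    elif meta["sample_id"].duplicated().any():
        raise DuplicateSpectrumError("duplicated sample_id without replicate index")

    matrix = df[wl_cols].to_numpy(dtype=float)
    if reflectance:
        matrix = reflectance_to_absorbance(matrix)
    return SpectraSet(wavelengths=wl, matrix=matrix, meta=meta)


def write_spectra(spectra: SpectraSet, path: str | Path, sep: str = ",") -> None:
    """Write a :class:`SpectraSet` as a wide delimited table.

    Float cells use Python's shortest round-trip repr, so a write/read
    cycle reproduces the matrix bit for bit.
    """
    wl_labels = [repr(float(w)) for w in spectra.wavelengths]
    spec_df = pd.DataFrame(spectra.matrix, columns=wl_labels)
    out = pd.concat([spectra.meta.reset_index(drop=True), spec_df], axis=1)
    out.to_csv(path, sep=sep, index=False)


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Average replicate spectra into one spectrum per sample.

    Probe replicates (conventionally three per sample, taken without
    moving the fibre-optic probe) are averaged arithmetically; reference
    values are carried through from the first replicate row of each
    sample.  Idempotent on an already-averaged set.
    """
    if spectra.n_rows == 0:
        raise EmptyDatasetError("nothing to average")
    if spectra.is_averaged:
        return spectra
    ids = spectra.meta["sample_id"]
    # preserve first-appearance order of samples
    codes, uniques = pd.factorize(ids)
    n = len(uniques)
    matrix = np.zeros((n, spectra.n_points))
    counts = np.bincount(codes, minlength=n).astype(float)
    for j in range(spectra.n_points):
        matrix[:, j] = np.bincount(codes, weights=spectra.matrix[:, j], minlength=n)
    matrix /= counts[:, None]
    first_rows = spectra.meta.groupby("sample_id", sort=False).head(1)
    meta = first_rows.drop(columns=["replicate"]).reset_index(drop=True)
    return SpectraSet(wavelengths=spectra.wavelengths, matrix=matrix, meta=meta)
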