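"""Spectral pre-treatments: scatter correction and gap-segment derivatives.

Treatments are written as a two-character code, a scatter letter followed
by a numeral digit:

* letters — ``n`` no scatter correction, ``s`` standard normal variate
  (SNV), ``d`` detrend (DT), ``m`` SNV followed by detrend;
* digits — shorthand for the derivative numerals ``(a, b, c, d)``:
  derivative order *a*, derivative gap *b* in grid points, first smoothing
  segment *c*, second smoothing segment *d*.  The conventional grid is
  ``0 = (0,0,1,1)``, ``1 = (1,4,4,1)``, ``2 = (2,4,4,1)``,
  ``3 = (2,10,10,1)``, ``4 = (2,8,6,1)``.

All treatments are per-spectrum (row-local): scatter correction first,
then segment smoothing of width *c*, the gap difference of order *a*, and
segment smoothing of width *d*.  Derivatives and smoothing shrink the
spectrum to its valid window; the wavelength axis is carried through the
same operators so truncation stays visible in the metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import DegenerateSpectrumError, TreatmentCodeError, WindowError
from .spectra_io import SpectraSet

__all__ = [
    "Scatter",
    "TreatmentCode",
    "NUMERAL_TABLE",
    "parse_treatment_code",
    "snv",
    "detrend",
    "gap_segment_derivative",
    "apply_treatment",
]


class Scatter(str, Enum):
    NONE = "n"
    SNV = "s"
    DT = "d"
    SNV_DT = "m"


#: digit shorthand -> (derivative order, gap, first smoothing, second smoothing)
NUMERAL_TABLE: dict[str, tuple[int, int, int, int]] = {
    "0": (0, 0, 1, 1),
    "1": (1, 4, 4, 1),
    "2": (2, 4, 4, 1),
    "3": (2, 10, 10, 1),
    "4": (2, 8, 6, 1),
}


@dataclass(frozen=True)
class TreatmentCode:
    """A scatter mode plus derivative/smoothing numerals."""

    scatter: Scatter
    numerals: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        a, b, c, d = self.numerals
        if a not in (0, 1, 2):
            raise TreatmentCodeError(f"derivative order {a} not in {{0,1,2}}")
        if a > 0 and b < 1:
            raise TreatmentCodeError("derivative gap must be positive")
        if a == 0 and b != 0:
            raise TreatmentCodeError("zeroth derivative takes gap 0")
        if c < 1 or d < 1:
            raise TreatmentCodeError("smoothing segments must be >= 1 point")

    def __str__(self) -> str:
        for digit, numerals in NUMERAL_TABLE.items():
            if numerals == self.numerals:
                return f"{self.scatter.value}{digit}"
        return f"{self.scatter.value}{self.numerals}"


def parse_treatment_code(code: str) -> TreatmentCode:
    """Parse a two-character code such as ``"s2"`` or ``"m3"``."""
    code = code.strip()
    if len(code) != 2:
        raise TreatmentCodeError(f"malformed treatment code {code!r}")
    letter, digit = code[0], code[1]
    try:
        scatter = Scatter(letter)
    except ValueError:
        raise TreatmentCodeError(f"unknown scatter letter {letter!r}") from None
    if digit not in NUMERAL_TABLE:
        raise TreatmentCodeError(f"unknown numeral digit {digit!r}")
    return TreatmentCode(scatter=scatter, numerals=NUMERAL_TABLE[digit])


def _rows(x: np.ndarray) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[None, :] if arr.ndim == 1 else arr


def _like(out: np.ndarray, x) -> np.ndarray:
    return out[0] if np.ndim(x) == 1 else out


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre each spectrum, scale to unit SD.

    The SD uses the n-1 (sample) denominator, so ``[1, 2, 3]`` maps to
    ``[-1, 0, 1]``.  Removes multiplicative scatter and additive offsets.
    """
    x = _rows(spectrum)
    if np.any(np.ptp(x, axis=1) == 0):
        raise DegenerateSpectrumError("constant spectrum has no SNV transform")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    return _like((x - mean) / sd, spectrum)


def detrend(
    spectrum: np.ndarray, wavelengths: np.ndarray, order: int = 2
) -> np.ndarray:
    """Residual of a least-squares polynomial baseline fit per spectrum.

    Degree-2 detrending is the standard baseline correction for powdered
    samples; the residual is orthogonal to {1, λ, ..., λ^order}.
    """
    x = _rows(spectrum)
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size <= order:
        raise WindowError("need more points than the polynomial degree")
    # scale the axis to [-1, 1] for a well-conditioned Vandermonde fit
    t = (wl - wl.mean()) / (np.ptp(wl) / 2 if np.ptp(wl) > 0 else 1.0)
    coeffs = np.polynomial.polynomial.polyfit(t, x.T, deg=order)
    baseline = np.polynomial.polynomial.polyval(t, coeffs)
    return _like(x - baseline, spectrum)


def _segment_smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Boxcar (moving mean) of the given width, valid window only."""
    if width == 1:
        return x
    if width > x.shape[1]:
        raise WindowError(f"smoothing segment {width} exceeds {x.shape[1]} points")
    c = np.cumsum(x, axis=1, dtype=float)
    c = np.concatenate([np.zeros((x.shape[0], 1)), c], axis=1)
    return (c[:, width:] - c[:, :-width]) / width


def _gap_difference(x: np.ndarray, order: int, gap: int) -> np.ndarray:
    if order == 0:
        return x
    n = x.shape[1]
    if order == 1:
        if gap >= n:
            raise WindowError("derivative gap exceeds spectrum length")
        return x[:, gap:] - x[:, :-gap]
    if 2 * gap >= n:
        raise WindowError("derivative gap exceeds spectrum length")
    return x[:, 2 * gap:] - 2.0 * x[:, gap:-gap] + x[:, :-2 * gap]


def gap_segment_derivative(
    spectrum: np.ndarray, numerals: tuple[int, int, int, int]
) -> np.ndarray:
    """Apply the (a, b, c, d) smoothing/derivative chain to spectra rows.

    Order of operations: boxcar smoothing of width *c*, then the *a*-th
    order gap difference with gap *b* points, then boxcar smoothing of
    width *d*.  ``(0, 0, 1, 1)`` is the identity.  The chain is linear
    and shrinks the spectrum to the window where every term is defined.
    """
    a, b, c, d = numerals
    TreatmentCode(Scatter.NONE, (a, b, c, d))  # validate
    x = _rows(spectrum)
    x = _segment_smooth(x, c)
    x = _gap_difference(x, a, b)
    x = _segment_smooth(x, d)
    return _like(x, spectrum)


def treated_wavelengths(
    wavelengths: np.ndarray, numerals: tuple[int, int, int, int]
) -> np.ndarray:
    """Wavelength axis after the (a, b, c, d) chain (window centres)."""
    a, b, c, d = numerals
    wl = np.asarray(wavelengths, dtype=float)[None, :]
    wl = _segment_smooth(wl, c)
    if a == 1:
        wl = (wl[:, b:] + wl[:, :-b]) / 2.0
    elif a == 2:
        wl = wl[:, b:-b]
    wl = _segment_smooth(wl, d)
    return wl[0]


def apply_treatment(spectra: SpectraSet, code: TreatmentCode | str) -> SpectraSet:
    """Apply scatter correction then derivative/smoothing to every spectrum.

    SNV+DT means SNV first, then detrending of the SNV output.  The
    returned set lives on the (possibly truncated) valid-window grid.
    """
    if isinstance(code, str):
        code = parse_treatment_code(code)
    if spectra.n_rows == 0:
        raise DegenerateSpectrumError("empty spectra set")
    x = spectra.matrix
    if code.scatter in (Scatter.SNV, Scatter.SNV_DT):
        x = snv(x)
    if code.scatter in (Scatter.DT, Scatter.SNV_DT):
        x = detrend(x, spectra.wavelengths)
    x = gap_segment_derivative(x, code.numerals)
    wl = treated_wavelengths(spectra.wavelengths, code.numerals)
    return spectra.with_matrix(x, wavelengths=wl)
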