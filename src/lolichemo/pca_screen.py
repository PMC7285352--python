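"""PCA decomposition of treated spectra and Mahalanobis H outlier screening.

A spectrum's *global H* statistic is its squared Mahalanobis distance in
the retained principal-component score space, with each score divided by
that component's standard deviation, scaled by 1/k (k = number of
components).  Training spectra then have mean H of (n-1)/n, and the
conventional cutoff H > 3.0 flags spectral outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSpectrumError, RankError
from .pretreatment import TreatmentCode, apply_treatment, parse_treatment_code
from .spectra_io import SpectraSet

__all__ = ["PCAModel", "HScreenResult", "fit_pca", "h_statistic", "screen_spectral_outliers"]

#: hard cap on retained components, matching the depth of typical
#: scanning-NIR calibration models
DEFAULT_K_CAP = 30


@dataclass
class PCAModel:
    center: np.ndarray           # mean spectrum of the training set
    loadings: np.ndarray         # (k, p) orthonormal rows
    score_variances: np.ndarray  # (k,) per-component score variance (ddof=1)
    explained_fraction: float    # cumulative share of total variance
    n_train: int

    @property
    def k(self) -> int:
        return self.loadings.shape[0]

    def scores(self, matrix: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(matrix, dtype=float))
        return (x - self.center) @ self.loadings.T


@dataclass
class HScreenResult:
    sample_ids: np.ndarray
    h_values: np.ndarray
    threshold: float
    pca: PCAModel
    code: TreatmentCode

    @property
    def outlier_mask(self) -> np.ndarray:
        return self.h_values > self.threshold

    @property
    def outlier_ids(self) -> list:
        return list(self.sample_ids[self.outlier_mask])


def fit_pca(
    spectra: SpectraSet | np.ndarray,
    variance_target: float | None = 0.99,
    k: int | None = None,
    k_cap: int = DEFAULT_K_CAP,
) -> PCAModel:
    """Principal component decomposition of (treated) spectra.

    Either request an exact number of components ``k`` or, by default,
    the smallest k whose cumulative explained variance reaches
    ``variance_target`` (capped at min(n-1, p, k_cap)).  The sign of
    each loading is fixed so its largest-magnitude element is positive,
    making the decomposition deterministic.
    """
    x = spectra.matrix if isinstance(spectra, SpectraSet) else np.asarray(spectra, float)
    n, p = x.shape
    max_k = min(n - 1, p)
    if max_k < 1:
        raise RankError("PCA needs at least two samples")
    if k is not None and k > max_k:
        raise RankError(f"k={k} exceeds the data rank bound {max_k}")

    center = x.mean(axis=0)
    xc = x - center
    # economy SVD: scores = u * s, loadings = vt
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    if total == 0:
        raise DegenerateSpectrumError("zero-variance spectra matrix")
    cum = np.cumsum(var) / total
    if k is None:
        cap = min(max_k, k_cap)
        k_sel = int(np.searchsorted(cum, variance_target) + 1)
        k_sel = min(k_sel, cap)
    else:
        k_sel = k

    loadings = vt[:k_sel].copy()
    flip = np.sign(loadings[np.arange(k_sel), np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    loadings *= flip[:, None]
    return PCAModel(
        center=center,
        loadings=loadings,
        score_variances=var[:k_sel].copy(),
        explained_fraction=float(cum[k_sel - 1]),
        n_train=n,
    )


def h_statistic(model: PCAModel, spectrum: np.ndarray) -> float | np.ndarray:
    """Global H of one spectrum (or rows of a matrix) under a PCA model.

    H = (1/k) * sum_j (t_j / s_j)^2 with t_j the j-th score and s_j the
    training score SD.  H = 0 at the training mean; averaged over the
    training set itself H is (n-1)/n.
    """
    if np.any(model.score_variances <= 0):
        raise DegenerateSpectrumError("zero-variance principal component")
    t = model.scores(spectrum)
    h = ((t**2) / model.score_variances).sum(axis=1) / model.k
    return float(h[0]) if np.ndim(spectrum) == 1 else h


def screen_spectral_outliers(
    spectra: SpectraSet,
    code: TreatmentCode | str = "n0",
    variance_target: float = 0.99,
    threshold: float = 3.0,
    k: int | None = None,
) -> HScreenResult:
    """Treat spectra, fit PCA and flag samples with H above the cutoff.

    The screen is single-pass: the PCA is not refitted after removal.
    """
    if isinstance(code, str):
        code = parse_treatment_code(code)
    treated = apply_treatment(spectra, code)
    pca = fit_pca(treated, variance_target=variance_target, k=k)
    h = h_statistic(pca, treated.matrix)
    return HScreenResult(
        sample_ids=spectra.sample_ids.copy(),
        h_values=np.asarray(h),
        threshold=threshold,
        pca=pca,
        code=code,
    )
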