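"""Grid search over pre-treatment pairs and best-equation selection.

The calibration workflow evaluates a 20 x 20 grid: 20 pre-treatment
codes at the PCA/outlier-screening stage crossed with 20 codes at the
MPLS regression stage, giving 400 candidate equations per constituent.
For each cell the pipeline is: treat spectra with the PCA-stage code,
fit PCA, discard spectral outliers (H > 3.0); treat the survivors with
the MPLS-stage code, cross-validate an MPLS model (6 groups), remove
chemical outliers (two rounds of |T| > 2.5), refit, and collect the
statistics.  The best equation minimises SECV with ties broken by
calibration RSQ, then internal-validation RPD, then grid order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyDatasetError,
    LolichemoError,
    SelectionError,
)
from .mpls import MPLSModel, fit_mpls, predict
from .pca_screen import DEFAULT_K_CAP, PCAModel, fit_pca, h_statistic
from .pretreatment import NUMERAL_TABLE, Scatter, TreatmentCode, apply_treatment
from .spectra_io import SpectraSet, average_replicates
from .validation_stats import (
    CalibrationStats,
    CVResult,
    compute_stats,
    t_outlier_elimination,
)

__all__ = [
    "GridConfig",
    "EquationCandidate",
    "GridReport",
    "enumerate_treatments",
    "split_calibration_validation",
    "exclude_zero_reference",
    "run_grid",
    "select_best",
]

SCATTER_ORDER = (Scatter.NONE, Scatter.SNV, Scatter.DT, Scatter.SNV_DT)

#: ordered selection criteria: minimise SECV, then maximise RSQ, then RPD
DEFAULT_SELECTION_RULE = ("min secv", "max rsq", "max rpd", "grid order")


@dataclass(frozen=True)
class GridConfig:
    n_factors: int = 10
    n_groups: int = 6
    variance_target: float = 0.99
    k_cap: int = DEFAULT_K_CAP
    h_threshold: float = 3.0
    t_threshold: float = 2.5
    t_rounds: int = 2
    seed: int = 0
    scale_residuals: bool = True
    scale_y_residual: bool = True


@dataclass
class EquationCandidate:
    """One cell of the 400-equation grid."""

    pca_code: TreatmentCode
    mpls_code: TreatmentCode
    order: tuple[int, int]
    pca_model: PCAModel | None = None
    n_spectral_outliers: int = 0
    n_chemical_outliers: int = 0
    mpls_model: MPLSModel | None = None
    cv: CVResult | None = None
    stats_calibration: CalibrationStats | None = None
    stats_internal: CalibrationStats | None = None
    stats_cv: CalibrationStats | None = None
    kept_ids: np.ndarray | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None and self.stats_calibration is not None

    @property
    def secv(self) -> float | None:
        return None if self.cv is None else self.cv.secv


@dataclass
class GridReport:
    constituent: str
    candidates: list[EquationCandidate]
    config: GridConfig
    n_input_samples: int
    selection_rule: tuple[str, ...] = DEFAULT_SELECTION_RULE
    best: EquationCandidate | None = None


def enumerate_treatments() -> list[TreatmentCode]:
    """The 20 pre-treatment codes, scatter-major: n0..n4, s0..s4, d0..d4, m0..m4."""
    return [
        TreatmentCode(scatter, NUMERAL_TABLE[d])
        for scatter in SCATTER_ORDER
        for d in "01234"
    ]


def split_calibration_validation(
    spectra: SpectraSet, fraction: float = 0.75, seed: int = 0
) -> tuple[SpectraSet, SpectraSet]:
    """Seeded random split into calibration and external-validation sets."""
    n = spectra.n_rows
    if n < 4:
        raise EmptyDatasetError("too few samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = int(round(fraction * n))
    cal = np.sort(perm[:n_cal])
    val = np.sort(perm[n_cal:])
    return spectra.subset(cal), spectra.subset(val)


def exclude_zero_reference(spectra: SpectraSet, constituent: str) -> SpectraSet:
    """Drop samples whose reference for the constituent is zero or missing.

    Alkaloid-free (endophyte-free) samples carry no signal for the
    constituent and would only distort the calibration.
    """
    ref = spectra.references(constituent)
    keep = np.isfinite(ref) & (ref > 0)
    if not keep.any():
        raise EmptyDatasetError(f"no positive {constituent} references")
    return spectra.subset(keep)


def _evaluate_cell(
    cand: EquationCandidate,
    X_mpls: np.ndarray,
    y: np.ndarray,
    ids: np.ndarray,
    config: GridConfig,
) -> None:
    keep, cv, removed = t_outlier_elimination(
        X_mpls,
        y,
        threshold=config.t_threshold,
        max_rounds=config.t_rounds,
        sample_index=ids,
        n_factors=config.n_factors,
        n_groups=config.n_groups,
        seed=config.seed,
        scale_residuals=config.scale_residuals,
        scale_y_residual=config.scale_y_residual,
    )
    model = fit_mpls(
        X_mpls[keep],
        y[keep],
        n_factors=config.n_factors,
        scale_residuals=config.scale_residuals,
        scale_y_residual=config.scale_y_residual,
    )
    fitted = predict(model, X_mpls[keep])
    cand.mpls_model = model
    cand.cv = cv
    cand.kept_ids = ids[keep]
    cand.n_chemical_outliers = int(sum(len(r) for r in removed))
    cand.stats_calibration = compute_stats(
        y[keep], fitted, context="calibration",
        n_factors=config.n_factors, secv=cv.secv,
    )
    cand.stats_internal = compute_stats(
        y[keep], fitted, context="internal_validation", secv=cv.secv,
    )
    cand.stats_cv = compute_stats(
        cv.y, cv.predictions, context="internal_validation", secv=cv.secv,
        rpd_denominator="secv",
    )


def run_grid(
    calibration: SpectraSet,
    constituent: str,
    config: GridConfig = GridConfig(),
) -> GridReport:
    """Evaluate all 400 treatment pairs for one constituent.

    The input set is replicate-averaged if needed and samples without a
    reference value for the constituent are excluded (they may still be
    used for other constituents).  Cell failures are recorded in the
    cell, never aborting the grid.  The grid is deterministic given
    (dataset, config): cells are independent, so evaluation order does
    not affect results.
    """
    spectra = average_replicates(calibration) if not calibration.is_averaged else calibration
    ref = spectra.references(constituent)
    spectra = spectra.subset(np.isfinite(ref))
    if spectra.n_rows == 0:
        raise EmptyDatasetError(f"no {constituent} references")
    y_all = spectra.references(constituent)
    ids_all = spectra.sample_ids

    codes = enumerate_treatments()
    treated = {str(c): apply_treatment(spectra, c) for c in codes}

    candidates: list[EquationCandidate] = []
    for i, pca_code in enumerate(codes):
        pca_model = None
        survivors = np.ones(spectra.n_rows, dtype=bool)
        n_spectral = 0
        pca_error: str | None = None
        try:
            tset = treated[str(pca_code)]
            pca_model = fit_pca(
                tset, variance_target=config.variance_target, k_cap=config.k_cap
            )
            h = h_statistic(pca_model, tset.matrix)
            survivors = h <= config.h_threshold
            n_spectral = int((~survivors).sum())
        except LolichemoError as exc:  # screening failed: record in every cell
            pca_error = f"PCA screening failed: {exc}"

        for j, mpls_code in enumerate(codes):
            cand = EquationCandidate(
                pca_code=pca_code,
                mpls_code=mpls_code,
                order=(i, j),
                pca_model=pca_model,
                n_spectral_outliers=n_spectral,
            )
            if pca_error is not None:
                cand.error = pca_error
            else:
                try:
                    X = treated[str(mpls_code)].matrix[survivors]
                    _evaluate_cell(
                        cand, X, y_all[survivors], ids_all[survivors], config
                    )
                except LolichemoError as exc:
                    cand.error = str(exc)
            candidates.append(cand)

    report = GridReport(
        constituent=constituent,
        candidates=candidates,
        config=config,
        n_input_samples=spectra.n_rows,
    )
    try:
        report.best = select_best(report)
    except SelectionError:
        report.best = None  # every cell failed; the per-cell errors say why
    return report


def _selection_key(cand: EquationCandidate) -> tuple:
    s = cand.stats_calibration
    rpd = cand.stats_internal.rpd if cand.stats_internal else None
    return (
        cand.secv,
        -(s.rsq if s else 0.0),
        -(rpd if rpd is not None else 0.0),
        cand.order,
    )


def select_best(report: GridReport) -> EquationCandidate:
    """Pick the winning equation under the recorded selection rule.

    Lexicographic: smallest SECV, then largest calibration RSQ, then
    largest internal-validation RPD, then grid order.  Independent of
    candidate list order.
    """
    ok = [c for c in report.candidates if c.ok]
    if not ok:
        raise SelectionError("no successful candidate equations")
    return min(ok, key=_selection_key)
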