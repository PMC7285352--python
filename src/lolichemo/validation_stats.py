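"""Cross-validation, chemical (T) outlier elimination and summary statistics.

Terminology follows forage-NIRS calibration practice:

SEC
    standard error of calibration, sqrt(SSE / (n - n_factors - 1));
SECV
    standard error of cross-validation, pooled from held-out residuals;
SEP / SEPc
    standard error of prediction, and its bias-corrected form;
BIAS
    mean residual (reference minus predicted);
RPD
    ratio of the reference SD to a prediction error; values above 2.0
    conventionally indicate a usable calibration;
T statistic
    a sample's held-out residual divided by SECV; samples with |T| > 2.5
    are chemical outliers and are removed in at most two rounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError, EmptyDatasetError, GroupingError

__all__ = [
    "CVResult",
    "CalibrationStats",
    "cross_validate",
    "t_outlier_elimination",
    "compute_stats",
    "paired_t_test",
    "rpd_ratio",
]

Context = Literal["calibration", "internal_validation", "external_validation"]


@dataclass
class CVResult:
    """Held-out predictions from grouped cross-validation."""

    n_groups: int
    seed: int
    assignments: np.ndarray   # group index per sample
    y: np.ndarray
    predictions: np.ndarray   # held-out prediction per sample
    secv: float

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.predictions

    @property
    def t_values(self) -> np.ndarray:
        if self.secv == 0:
            return np.zeros_like(self.y)
        return self.residuals / self.secv


@dataclass
class CalibrationStats:
    """The statistics bundle reported for one fitted equation."""

    context: Context
    n: int
    sd: float
    rsq: float
    bias: float
    rmse: float
    sec: float | None = None
    sep: float | None = None
    sepc: float | None = None
    secv: float | None = None
    rpd: float | None = None
    rpd_denominator: str | None = None
    t_test_p: float | None = None


def _balanced_groups(n: int, n_groups: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    groups = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(perm, n_groups)):
        groups[chunk] = g
    return groups


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int = 10,
    n_groups: int = 6,
    seed: int = 0,
    scale_residuals: bool = True,
    scale_y_residual: bool = True,
) -> CVResult:
    """Grouped cross-validation of an MPLS model on treated spectra.

    Samples are split into ``n_groups`` near-equal groups by a seeded
    random permutation; each group is predicted by a model fitted on the
    rest.  SECV is the root mean square of the pooled held-out residuals.
    ``n_groups == n`` is leave-one-out.
    """
    from .mpls import fit_mpls, predict

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n_groups < 2 or n_groups > n:
        raise GroupingError(f"n_groups={n_groups} incompatible with n={n}")
    groups = _balanced_groups(n, n_groups, seed)
    preds = np.empty(n)
    for g in range(n_groups):
        held = groups == g
        model = fit_mpls(
            X[~held],
            y[~held],
            n_factors=n_factors,
            scale_residuals=scale_residuals,
            scale_y_residual=scale_y_residual,
        )
        preds[held] = predict(model, X[held])
    secv = float(np.sqrt(np.mean((y - preds) ** 2)))
    return CVResult(
        n_groups=n_groups, seed=seed, assignments=groups, y=y.copy(),
        predictions=preds, secv=secv,
    )


def t_outlier_elimination(
    X: np.ndarray,
    y: np.ndarray,
    threshold: float = 2.5,
    max_rounds: int = 2,
    sample_index: Sequence | None = None,
    **cv_kwargs,
) -> tuple[np.ndarray, CVResult, list[np.ndarray]]:
    """Remove chemical outliers by the T > 2.5 rule, at most twice.

    Each round drops every sample whose held-out residual exceeds
    ``threshold`` times the current SECV, then re-runs cross-validation
    (same seed) on the survivors.  Rounds stop early once nothing is
    flagged.

    Returns
    -------
    kept, cv, removed_per_round
        ``kept`` indexes the surviving rows of X (positions, or entries
        of ``sample_index`` when given per round in ``removed_per_round``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    index = np.asarray(sample_index if sample_index is not None else np.arange(y.size))
    keep = np.arange(y.size)
    cv = cross_validate(X, y, **cv_kwargs)
    removed: list[np.ndarray] = []
    for _ in range(max_rounds):
        bad = np.abs(cv.t_values) > threshold
        if not bad.any():
            break
        if bad.all():
            raise EmptyDatasetError("T elimination removed every sample")
        removed.append(index[keep[bad]])
        keep = keep[~bad]
        cv = cross_validate(X[keep], y[keep], **cv_kwargs)
    return keep, cv, removed


def rpd_ratio(sd: float, error: float) -> float:
    """Ratio of performance to deviation: reference SD over a prediction error."""
    if error <= 0:
        raise DomainError("RPD needs a positive error denominator")
    return sd / error


def paired_t_test(y_ref: np.ndarray, y_pred: np.ndarray) -> float:
    """Two-sided paired Student's t-test p-value on (reference, predicted).

    Identical vectors (zero-variance, zero-mean differences) give p = 1
    by convention; zero-variance differences with nonzero mean give p = 0.
    """
    a = np.asarray(y_ref, dtype=float).ravel()
    b = np.asarray(y_pred, dtype=float).ravel()
    if a.size != b.size:
        raise DomainError("paired test needs equal-length vectors")
    if a.size < 2:
        raise DomainError("paired test needs n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        return 1.0 if np.mean(d) == 0 else 0.0
    return float(sps.ttest_rel(a, b).pvalue)


def compute_stats(
    y_ref: np.ndarray,
    y_pred: np.ndarray,
    context: Context = "internal_validation",
    n_factors: int = 10,
    secv: float | None = None,
    rpd_denominator: Literal["sep", "secv"] = "sep",
) -> CalibrationStats:
    """Full statistics bundle for one (reference, predicted) pair.

    In the calibration context the error of fit is SEC with
    ``n - n_factors - 1`` degrees of freedom; in validation contexts the
    errors are SEP (denominator n) and the bias-corrected SEPc
    (denominator n-1).  RSQ is the squared Pearson correlation.  RPD
    divides the reference SD by SEP by default, or by SECV when
    requested (and available).
    """
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    n = y_ref.size
    if n != y_pred.size:
        raise DomainError("length mismatch")
    if n < 3:
        raise DomainError("need at least 3 pairs")
    sd_ref = float(np.std(y_ref, ddof=1))
    if sd_ref == 0 or np.std(y_pred) == 0:
        raise DomainError("zero variance: RSQ undefined")

    res = y_ref - y_pred
    sse = float(res @ res)
    bias = float(res.mean())
    rmse = float(np.sqrt(sse / n))
    rsq = float(np.corrcoef(y_ref, y_pred)[0, 1] ** 2)

    sec = sep = sepc = rpd = None
    if context == "calibration":
        dof = n - n_factors - 1
        if dof <= 0:
            raise DomainError("too few samples for the SEC degrees of freedom")
        sec = float(np.sqrt(sse / dof))
    else:
        sep = rmse
        sepc = float(np.sqrt(((res - bias) ** 2).sum() / (n - 1)))

    denom = None
    if rpd_denominator == "secv" and secv is not None and secv > 0:
        denom = secv
    elif rpd_denominator == "sep" and sep is not None and sep > 0:
        denom = sep
    if denom is not None:
        rpd = sd_ref / denom

    return CalibrationStats(
        context=context,
        n=n,
        sd=sd_ref,
        rsq=rsq,
        bias=bias,
        rmse=rmse,
        sec=sec,
        sep=sep,
        sepc=sepc,
        secv=secv,
        rpd=rpd,
        rpd_denominator=rpd_denominator if rpd is not None else None,
        t_test_p=paired_t_test(y_ref, y_pred),
    )
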