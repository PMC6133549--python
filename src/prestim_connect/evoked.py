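"""Noxious-evoked response quantification.

Motion-corrupted volumes are flagged from DVARS (RMS volume-to-volume signal
change) with a boxplot upper-fence threshold and enter the GLM as unit
indicator regressors. Each ROI series is fitted by ordinary least squares
against the event-related design; the coefficient of the first (canonical)
basis regressor is the evoked-amplitude estimate, converted to percent BOLD
change against the ROI's mean raw signal and averaged over the units of the
activity mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .hrf import DesignMatrix

__all__ = [
    "GLMFit",
    "PercentChange",
    "detect_motion_outliers",
    "dvars",
    "fit_glm",
    "percent_bold_change",
]


def dvars(data: np.ndarray) -> np.ndarray:
    """Root-mean-square over units of the volume-to-volume difference.

    ``data`` is (n_volumes, n_units); element t of the result (t >= 1)
    measures the change from volume t-1 to volume t. Index 0 is 0 by
    convention so the vector aligns with volume indices.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 2:
        raise ValueError("DVARS needs at least 2 volumes")
    diff = np.diff(data, axis=0)
    d = np.sqrt((diff**2).mean(axis=1))
    return np.concatenate([[0.0], d])


def detect_motion_outliers(
    data: np.ndarray, absolute_threshold: float | None = None
) -> tuple[int, ...]:
    """Volumes whose DVARS exceeds the boxplot upper fence (Q3 + 1.5 IQR).

    An ``absolute_threshold`` overrides the adaptive fence. The flagged
    index is the later volume of each high-change pair.
    """
    d = dvars(data)
    body = d[1:]
    if absolute_threshold is None:
        q1, q3 = np.percentile(body, [25, 75])
        threshold = q3 + 1.5 * (q3 - q1)
    else:
        threshold = absolute_threshold
    flagged = np.nonzero(body > threshold)[0] + 1
    return tuple(int(v) for v in flagged)


@dataclass(frozen=True)
class GLMFit:
    coefficients: dict[str, float]
    canonical_coefficient: float
    canonical_t: float
    canonical_p: float
    residuals: np.ndarray
    residual_variance: float
    design_labels: tuple[str, ...]


@dataclass(frozen=True)
class PercentChange:
    """Mean percent BOLD change across activity-mask units for one subject."""

    value: float
    per_unit: dict[str, float]
    convention: str


def _collinear_columns(X: np.ndarray, labels: tuple[str, ...]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * X.shape[0] * np.finfo(float).eps
    return [labels[i] for i in np.nonzero(diag < tol)[0]]


def fit_glm(series: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares of one ROI series on the design.

    An intercept is appended internally, so the caller's design holds only
    task and nuisance columns. The first task regressor's coefficient,
    t-value and p-value are surfaced as the evoked-response estimate.
    """
    y = np.asarray(series, dtype=float)
    if y.shape[0] != design.n_volumes:
        raise ValueError(
            f"series length {y.shape[0]} != design rows {design.n_volumes}"
        )
    if design.n_task_regressors < 1:
        raise ValueError("design has no task regressors to estimate")
    X = np.column_stack([design.matrix, np.ones(design.n_volumes)])
    labels = design.labels + ("intercept",)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, labels)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    return GLMFit(
        coefficients=dict(zip(labels, res.params)),
        canonical_coefficient=float(res.params[0]),
        canonical_t=float(res.tvalues[0]),
        canonical_p=float(res.pvalues[0]),
        residuals=np.asarray(res.resid),
        residual_variance=float(res.mse_resid) if res.df_resid > 0 else 0.0,
        design_labels=labels,
    )


def percent_bold_change(
    fits: dict[str, GLMFit],
    baselines: dict[str, float],
    regressor_peak: float = 1.0,
) -> PercentChange:
    """Percent signal change per activity-mask unit, averaged over units.

    Follows the Featquery-style convention: the canonical coefficient is
    scaled by the task regressor's peak height and referenced to the unit's
    mean raw signal. Scale-invariant: doubling the raw data doubles both the
    coefficient and the baseline.
    """
    per_unit = {}
    for label, fit in fits.items():
        baseline = baselines[label]
        if baseline <= 0:
            raise ValueError(f"non-positive baseline for unit {label!r}")
        per_unit[label] = 100.0 * fit.canonical_coefficient * regressor_peak / baseline
    return PercentChange(
        value=float(np.mean(list(per_unit.values()))),
        per_unit=per_unit,
        convention=(
            "100 * canonical_coefficient * regressor_peak / mean_raw_signal, "
            "averaged over activity-mask units"
        ),
    )
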