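"""Simple linear calibration of a descriptor against experimental log P.

One-descriptor QSPR models here are ordinary least squares fits
Y = a + b*X of experimental log P on either the raw descriptor or a
method's calculated-log-P column, with the standard diagnostic suite:
Pearson r, r^2, residual standard deviation s (n-2 degrees of freedom),
the F statistic of the slope, and leave-one-out cross-validation
(PRESS and q^2_cv).  External test sets are summarised by per-compound
deviations and observed-vs-predicted regressions with and without an
intercept, following the usual external-validation practice of checking
that the slope is close to 1 and the intercept close to 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CalibrationModel",
    "RegressionReport",
    "ExternalValidationReport",
    "DegenerateFitError",
    "fit_ols",
    "loo_q2",
    "predict",
    "deviations",
    "external_validation",
    "f_statistic",
]


class DegenerateFitError(ValueError):
    """Constant predictor or otherwise unusable design."""


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted line log P = a + b * x."""

    a: float
    b: float
    n: int
    x_kind: Literal["raw_iset", "calculated_logp"] = "calculated_logp"
    class_label: str = ""

    def predict(self, x):
        return self.a + self.b * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class RegressionReport:
    r: float
    r2: float
    s: float
    f: float
    press: float | None = None
    q2_cv: float | None = None


@dataclass(frozen=True)
class ExternalValidationReport:
    """Two-way observed/predicted regression summary for an external set."""

    slope_op: float            # observed (Y) vs predicted (X)
    intercept_op: float
    r2_op: float
    slope_po: float            # predicted (Y) vs observed (X)
    intercept_po: float
    r2_po: float
    slope_origin_op: float     # through-origin fits
    r2_origin_op: float
    slope_origin_po: float
    r2_origin_po: float
    deviations: tuple[float, ...] = ()
    mean_abs_dev: float = float("nan")
    rms_dev: float = float("nan")


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-D of equal length, got {x.shape}, {y.shape}")
    return x, y


def fit_ols(
    x: Sequence[float],
    y: Sequence[float],
    x_kind: Literal["raw_iset", "calculated_logp"] = "calculated_logp",
    class_label: str = "",
    with_q2: bool = False,
) -> tuple[CalibrationModel, RegressionReport]:
    """Least-squares fit of y on x with the full diagnostic report.

    ``s`` is the residual standard error with n-2 degrees of freedom;
    ``f`` is computed from the unrounded r^2 as (n-2) r^2/(1-r^2).
    """
    x, y = _as_xy(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateFitError("predictor is constant; slope is undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    b = sxy / sxx
    a = float(y.mean() - b * x.mean())
    resid = y - (a + b * x)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # flat response: the fit is exact but correlation is undefined
        r = r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        r2 = max(min(r2, 1.0), 0.0)
        r = math.copysign(math.sqrt(r2), b)
    s = math.sqrt(ss_res / (n - 2))
    f = f_statistic(r2, n)
    press = q2 = None
    if with_q2:
        press, q2 = loo_q2(x, y)
    model = CalibrationModel(a=a, b=b, n=n, x_kind=x_kind, class_label=class_label)
    return model, RegressionReport(r=r, r2=r2, s=s, f=f, press=press, q2_cv=q2)


def f_statistic(r2: float, n: int) -> float:
    """F-test of the slope for simple linear regression: (n-2) r^2/(1-r^2)."""
    if not (0.0 <= r2 <= 1.0):
        raise ValueError(f"r2 must lie in [0, 1], got {r2}")
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if r2 == 1.0:
        return float("inf")
    return (n - 2) * r2 / (1.0 - r2)


def loo_q2(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["shortcut", "refit"] = "shortcut",
) -> tuple[float, float]:
    """Leave-one-out cross-validation: PRESS and q^2_cv.

    PRESS accumulates the squared deleted residuals (y_i - yhat_(-i))^2 over
    n single-holdout refits; q^2_cv = 1 - PRESS / SS_tot with SS_tot taken
    about the full-sample mean.  ``method="shortcut"`` uses the exact
    hat-matrix identity e_(-i) = e_i / (1 - h_ii); ``"refit"`` performs the
    n refits explicitly (the two agree to numerical precision and the
    explicit loop serves as a cross-check).
    """
    x, y = _as_xy(x, y)
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 points for LOO, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateFitError("predictor is constant")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if method == "shortcut":
        b = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
        a = float(y.mean() - b * x.mean())
        resid = y - (a + b * x)
        h = 1.0 / n + (x - x.mean()) ** 2 / sxx
        if np.any(h >= 1.0):
            raise DegenerateFitError("a holdout leaves a constant predictor")
        press = float(np.sum((resid / (1.0 - h)) ** 2))
    elif method == "refit":
        press = 0.0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            xi, yi = x[mask], y[mask]
            sxx_i = float(np.sum((xi - xi.mean()) ** 2))
            if sxx_i == 0.0:
                raise DegenerateFitError(f"holdout {i} leaves a constant predictor")
            b_i = float(np.sum((xi - xi.mean()) * (yi - yi.mean())) / sxx_i)
            a_i = float(yi.mean() - b_i * xi.mean())
            press += (y[i] - (a_i + b_i * x[i])) ** 2
    else:
        raise ValueError(f"unknown LOO method {method!r}")
    q2 = 1.0 - press / ss_tot if ss_tot > 0 else float("nan")
    return press, q2


def predict(model: CalibrationModel, x: float) -> float:
    """Predicted log P for a descriptor value."""
    return float(model.a + model.b * x)


def deviations(
    model: CalibrationModel,
    x_values: Sequence[float],
    exp_values: Sequence[float | None],
    names: Sequence[str] | None = None,
    decimals: int | None = 2,
) -> list[float]:
    """Per-compound deviation experimental - predicted.

    Records without an experimental value are skipped with a warning.
    ``decimals`` applies display rounding (2 by convention); pass None to
    keep full precision.
    """
    out: list[float] = []
    for k, (xv, ev) in enumerate(zip(x_values, exp_values, strict=True)):
        if ev is None or (isinstance(ev, float) and math.isnan(ev)):
            label = names[k] if names else f"record {k + 1}"
            warnings.warn(f"{label}: missing experimental log P, skipped")
            continue
        delta = float(ev) - predict(model, float(xv))
        out.append(round(delta, decimals) if decimals is not None else delta)
    return out


def _through_origin(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope through the origin and its r^2.

    The slope is sum(xy)/sum(x^2); r^2 is computed about the mean of y
    (1 - SS_res/SS_tot), the form used when comparing a constrained line
    with the free fit on the same axes.
    """
    sxx = float(x @ x)
    if sxx == 0.0:
        raise DegenerateFitError("all-zero predictor in through-origin fit")
    k = float(x @ y) / sxx
    resid = y - k * x
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return k, r2


def external_validation(
    observed: Sequence[float], predicted: Sequence[float]
) -> ExternalValidationReport:
    """Observed/predicted regressions (both directions, with and without
    intercept) plus per-compound deviations for an external test set."""
    obs, pred = _as_xy(observed, predicted)
    if obs.size < 3:
        raise ValueError(f"need at least 3 external compounds, got {obs.size}")
    m_op, rep_op = fit_ols(pred, obs)          # observed (Y) vs predicted (X)
    m_po, rep_po = fit_ols(obs, pred)          # predicted (Y) vs observed (X)
    k_op, r2k_op = _through_origin(pred, obs)
    k_po, r2k_po = _through_origin(obs, pred)
    devs = tuple(float(d) for d in (obs - pred))
    return ExternalValidationReport(
        slope_op=m_op.b, intercept_op=m_op.a, r2_op=rep_op.r2,
        slope_po=m_po.b, intercept_po=m_po.a, r2_po=rep_po.r2,
        slope_origin_op=k_op, r2_origin_op=r2k_op,
        slope_origin_po=k_po, r2_origin_po=r2k_po,
        deviations=devs,
        mean_abs_dev=float(np.mean(np.abs(devs))),
        rms_dev=float(np.sqrt(np.mean(np.square(devs)))),
    )
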