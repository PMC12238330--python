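"""Time-activity curve fitting and time-integrated (cumulated) activity.

Organ activity after administration is modelled as a sum of decaying
exponentials A(t) = A1*exp(-lambda1*t) [+ A2*exp(-lambda2*t)], fitted by
least squares to multi-time-point planar quantification results (the
standard schedule is 24, 72 and 168 h). The cumulated activity
(MBq*s) is the closed-form integral of the fitted model.

A free biexponential has four parameters and therefore needs at least four
time points; fitting it to three points is refused as underdetermined
rather than silently returning one of infinitely many solutions. With
three points either a monoexponential or a biexponential with one rate
pinned (e.g. to the physical decay constant) is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .planar_quant import I131_LAMBDA_PER_H

__all__ = [
    "TimeActivityCurve",
    "ExpFit",
    "UnderdeterminedFitError",
    "fit_tac",
    "time_integrated_activity",
    "trapezoid_tia",
]

_MIN_LAMBDA = 1e-6  # 1/h; lower bound keeping rates positive


class UnderdeterminedFitError(ValueError):
    """More free parameters than data points."""


@dataclass
class TimeActivityCurve:
    times_h: np.ndarray
    activities_MBq: np.ndarray
    organ: str = "tumor"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        a = np.asarray(self.activities_MBq, dtype=float)
        if t.size != a.size:
            raise ValueError("times and activities lengths differ")
        if t.size < 2:
            raise ValueError("a time-activity curve needs at least 2 points")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("activities must be >= 0")
        self.times_h = t
        self.activities_MBq = a


@dataclass
class ExpFit:
    """A fitted mono- or biexponential decay model."""

    model: str  # "monoexp" | "biexp"
    A1_MBq: float
    lambda1_per_h: float
    A2_MBq: float | None = None
    lambda2_per_h: float | None = None
    residual_ss: float = 0.0
    organ: str = "tumor"

    def __post_init__(self) -> None:
        if self.model not in ("monoexp", "biexp"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.lambda1_per_h <= 0:
            raise ValueError("lambda1 must be > 0")
        if self.model == "biexp":
            if self.A2_MBq is None or self.lambda2_per_h is None:
                raise ValueError("biexp requires A2 and lambda2")
            if self.lambda2_per_h <= 0:
                raise ValueError("lambda2 must be > 0")
            if math.isclose(self.lambda1_per_h, self.lambda2_per_h,
                            rel_tol=0.0, abs_tol=0.0):
                raise ValueError("biexp requires lambda1 != lambda2")
        if self.residual_ss < 0:
            raise ValueError("residual sum of squares must be >= 0")

    def __call__(self, t_h) -> np.ndarray:
        t = np.asarray(t_h, dtype=float)
        out = self.A1_MBq * np.exp(-self.lambda1_per_h * t)
        if self.model == "biexp":
            out = out + self.A2_MBq * np.exp(-self.lambda2_per_h * t)
        return out

    @property
    def terms(self) -> list[tuple[float, float]]:
        """(amplitude, rate) pairs of the model."""
        pairs = [(self.A1_MBq, self.lambda1_per_h)]
        if self.model == "biexp":
            pairs.append((self.A2_MBq, self.lambda2_per_h))
        return pairs


def _loglinear_start(t: np.ndarray, a: np.ndarray) -> tuple[float, float]:
    """Deterministic start: rate from the last two points (log slope),
    amplitude from the first point back-extrapolated."""
    a = np.maximum(a, 1e-12)
    lam = math.log(a[-2] / a[-1]) / (t[-1] - t[-2])
    lam = max(lam, _MIN_LAMBDA)
    amp = a[0] * math.exp(lam * t[0])
    return amp, lam


def fit_tac(
    tac: TimeActivityCurve,
    model: str = "monoexp",
    fixed_lambda: float | None = None,
) -> ExpFit:
    """Least-squares exponential fit to a time-activity curve.

    Parameters
    ----------
    model
        "monoexp" (2 parameters) or "biexp" (4 parameters, or 3 when
        ``fixed_lambda`` pins the second rate).
    fixed_lambda
        When given with model="biexp", the second component's rate (1/h)
        is held at this value (commonly the physical decay constant).

    The fit minimizes the sum of squared residuals in activity space and is
    deterministic: the optimizer is started from a log-linear tail estimate.
    """
    t, a = tac.times_h, tac.activities_MBq
    n = t.size

    if model == "monoexp":
        if fixed_lambda is not None:
            raise ValueError("fixed_lambda applies to biexp only")
        if n < 2:
            raise UnderdeterminedFitError("monoexp needs >= 2 points")
        if n == 2:
            lam = math.log(max(a[0], 1e-300) / max(a[1], 1e-300)) / (t[1] - t[0])
            lam = max(lam, _MIN_LAMBDA)
            amp = a[0] * math.exp(lam * t[0])
            return ExpFit("monoexp", amp, lam, residual_ss=0.0, organ=tac.organ)
        amp0, lam0 = _loglinear_start(t, a)

        def resid(p):
            return p[0] * np.exp(-p[1] * t) - a

        sol = least_squares(
            resid, x0=[amp0, lam0], bounds=([0.0, _MIN_LAMBDA], [np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        return ExpFit(
            "monoexp", float(sol.x[0]), float(sol.x[1]),
            residual_ss=float(np.sum(sol.fun ** 2)), organ=tac.organ,
        )

    if model != "biexp":
        raise ValueError(f"unknown model {model!r}")

    if fixed_lambda is not None:
        if fixed_lambda <= 0:
            raise ValueError("fixed_lambda must be > 0")
        if n < 3:
            raise UnderdeterminedFitError(
                "biexp with one fixed rate has 3 free parameters and needs >= 3 points"
            )
        amp0, lam0 = _loglinear_start(t, a)

        def resid_fixed(p):
            return (p[0] * np.exp(-p[1] * t) + p[2] * np.exp(-fixed_lambda * t)) - a

        sol = least_squares(
            resid_fixed,
            x0=[amp0 / 2, max(2 * lam0, 10 * fixed_lambda), amp0 / 2],
            bounds=([0.0, _MIN_LAMBDA, 0.0], [np.inf, np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        lam1 = float(sol.x[1])
        if math.isclose(lam1, fixed_lambda):
            lam1 *= 1.0 + 1e-9  # keep the two rates formally distinct
        return ExpFit(
            "biexp", float(sol.x[0]), lam1,
            A2_MBq=float(sol.x[2]), lambda2_per_h=fixed_lambda,
            residual_ss=float(np.sum(sol.fun ** 2)), organ=tac.organ,
        )

    if n < 4:
        raise UnderdeterminedFitError(
            f"free biexponential has 4 parameters but only {n} points were given; "
            "use monoexp or fix one rate (fixed_lambda)"
        )

    # Curve peeling start: slow component from the tail, fast from the
    # early residual. Deterministic given the data.
    half = max(n // 2, 2)
    amp_s, lam_s = _loglinear_start(t[-half:], a[-half:])
    early = a - amp_s * np.exp(-lam_s * t)
    pos = early > 0
    if pos.sum() >= 2:
        te, ae = t[pos], early[pos]
        with np.errstate(divide="ignore"):
            slope = np.polyfit(te, np.log(np.maximum(ae, 1e-12)), 1)
        lam_f = max(-slope[0], 2 * lam_s)
        amp_f = math.exp(slope[1])
    else:
        lam_f, amp_f = 10 * lam_s, amp_s

    def resid_bi(p):
        return (p[0] * np.exp(-p[1] * t) + p[2] * np.exp(-p[3] * t)) - a

    sol = least_squares(
        resid_bi,
        x0=[amp_f, max(lam_f, _MIN_LAMBDA), amp_s, lam_s],
        bounds=([0.0, _MIN_LAMBDA, 0.0, _MIN_LAMBDA], np.inf),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    A1, l1, A2, l2 = map(float, sol.x)
    if l1 < l2:  # order: fast component first
        A1, l1, A2, l2 = A2, l2, A1, l1
    if math.isclose(l1, l2):
        l1 *= 1.0 + 1e-9
    return ExpFit(
        "biexp", A1, l1, A2_MBq=A2, lambda2_per_h=l2,
        residual_ss=float(np.sum(sol.fun ** 2)), organ=tac.organ,
    )


def time_integrated_activity(
    fit: ExpFit, t_start_h: float = 0.0, t_end_h: float = math.inf
) -> float:
    """Cumulated activity (MBq*s): closed-form integral of the fitted model.

    Integral over [t_start, t_end] of sum_i A_i exp(-lambda_i t) equals
    sum_i (A_i/lambda_i)(exp(-lambda_i t_start) - exp(-lambda_i t_end)),
    converted from MBq*h to MBq*s.
    """
    if t_end_h <= t_start_h:
        raise ValueError("t_end must exceed t_start")
    total_h = 0.0
    for amp, lam in fit.terms:
        tail = 0.0 if math.isinf(t_end_h) else math.exp(-lam * t_end_h)
        total_h += (amp / lam) * (math.exp(-lam * t_start_h) - tail)
    return total_h * 3600.0


def trapezoid_tia(tac: TimeActivityCurve, tail: str = "none") -> float:
    """Model-free cumulated activity (MBq*s): trapezoid over the observed
    points, optionally extended past the last point with an analytic
    physical-decay tail A_last / lambda_phys.

    A robust fallback when an exponential fit is not warranted.
    """
    if tail not in ("none", "physical_decay"):
        raise ValueError(f"unknown tail option {tail!r}")
    area_h = float(np.trapezoid(tac.activities_MBq, tac.times_h))
    if tail == "physical_decay":
        area_h += float(tac.activities_MBq[-1]) / I131_LAMBDA_PER_H
    return area_h * 3600.0
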