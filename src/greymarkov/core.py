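"""SCGM(1,1)_c grey model: parameter estimation, restored fit, diagnostics.

The model assumes the accumulated mean-generated sequence follows a
nonhomogeneous exponential trend ``b * exp(a*(k-1)) - c``.  Its three
parameters are estimated in sequence:

``a`` (development coefficient)
    Weighted log-ratio of consecutive mean-generated terms,
    ``a = ln( sum_{k=3..n} xm(k-1)*xm(k) / sum_{k=3..n} xm(k-1)^2 )``.
    On a geometric sequence this recovers the log-ratio exactly.
``b`` (amplitude)
    Least-squares slope of the accumulated sequence on the regressor
    ``exp(a*(k-1))`` over ``k = 2..n`` with sample count ``n - 1``.
``c`` (offset)
    ``c = (1/(n-1)) * ( b * sum_{k=2..n} exp(a*k) - sum_{k=2..n} xa(k) )``,
    with ``U = a*c``.  Note the offset's exponent is ``a*k``, one step
    ahead of the amplitude regressor ``a*(k-1)``; the fit report flags
    this convention.

The restored (order-zero) prediction is ``x0hat(k) = 2*M*exp(a*(k-1))``
with ``M = (1 - exp(-a)) * b / (1 + exp(-a))``, defined for ``k >= 2``.
``restored_fit`` also accepts an exponent ``shift`` so callers can
evaluate the published-table convention ``2*M*exp(a*k)`` (shift=1) used
by the case-study pipeline; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateTrendError, SeriesValidationError
from .series import TimeSeries, accumulate, mean_generate

__all__ = [
    "SCGMParameters",
    "FitDiagnostics",
    "estimate_development",
    "estimate_amplitude",
    "estimate_offset",
    "fit",
    "restored_fit",
    "accumulated_response",
    "diagnostics",
]

#: |a| below this is treated as "no trend" (M -> 0 and the restored
#: exponential degenerates); fitting still succeeds but extrapolating
#: layers must refuse.
DEGENERATE_A = 1e-12


@dataclass(frozen=True)
class SCGMParameters:
    """Fitted grey-model parameters.

    ``a``: per-step log-ratio of the trend (negative = declining series).
    ``b``: amplitude of the accumulated-level exponential.
    ``c``: offset of the accumulated-level response; ``U = a*c``.
    ``M``: restored-level amplitude, ``(1 - e^-a) b / (1 + e^-a)``;
    the restored prediction is ``2*M*exp(a*(k-1))``.
    """

    a: float
    b: float
    c: float
    U: float
    M: float
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate:
            expected_m = (1.0 - np.exp(-self.a)) * self.b / (1.0 + np.exp(-self.a))
            if not np.isclose(self.M, expected_m, rtol=1e-9, atol=1e-9):
                raise ValueError(
                    f"inconsistent parameters: M={self.M} but "
                    f"(1-e^-a)b/(1+e^-a)={expected_m}"
                )


@dataclass(frozen=True)
class FitDiagnostics:
    """Per-index fit accuracy indicators for ``k = 2..n``.

    ``ratio``    Y(k)  = x0(k) / x0hat(k)   (the fit-ratio indicator)
    ``residual`` eps(k) = x0hat(k) - x0(k)
    ``delta``    Delta(k) = eps(k) / x0(k)  (signed relative deviation)
    """

    ks: np.ndarray
    actual: np.ndarray
    fitted: np.ndarray
    ratio: np.ndarray
    residual: np.ndarray
    delta: np.ndarray

    @property
    def max_abs_delta(self) -> float:
        return float(np.max(np.abs(self.delta)))


def estimate_development(mean_generated: Sequence[float]) -> float:
    """Development coefficient ``a`` from the mean-generated sequence.

    Returns 0.0 for a constant sequence (flagged degenerate downstream).
    """
    xm = np.asarray(mean_generated, dtype=float)
    if xm.size < 2:
        raise SeriesValidationError(
            "need at least two mean-generated terms to estimate a"
        )
    if np.any(xm <= 0):
        raise SeriesValidationError(
            "mean-generated sequence must be strictly positive"
        )
    num = float(np.sum(xm[:-1] * xm[1:]))
    den = float(np.sum(xm[:-1] ** 2))
    a = float(np.log(num / den))
    if not np.isfinite(a):
        raise SeriesValidationError("development coefficient is not finite")
    return a


def estimate_amplitude(a: float, accumulated: Sequence[float]) -> float:
    """Amplitude ``b``: least-squares slope of ``xa(k)`` on ``exp(a*(k-1))``.

    The regressor runs over ``k = 2..n``; the slope is invariant to any
    constant offset in ``xa``, so a pure-exponential-plus-constant input
    recovers its amplitude exactly.
    """
    xa = np.asarray(accumulated, dtype=float)
    n = xa.size + 1
    k = np.arange(2, n + 1, dtype=float)
    reg = np.exp(a * (k - 1))
    m = n - 1
    den = m * np.sum(reg**2) - np.sum(reg) ** 2
    if abs(a) < DEGENERATE_A or den == 0 or not np.isfinite(den):
        raise DegenerateTrendError(
            "regressor exp(a*(k-1)) is (numerically) constant; "
            "no exponential trend to fit (a ~ 0)"
        )
    num = m * np.sum(reg * xa) - np.sum(reg) * np.sum(xa)
    return float(num / den)


def estimate_offset(a: float, b: float, accumulated: Sequence[float]) -> tuple[float, float]:
    """Offset ``c`` and ``U = a*c`` for the accumulated-level response."""
    xa = np.asarray(accumulated, dtype=float)
    n = xa.size + 1
    k = np.arange(2, n + 1, dtype=float)
    c = float((b * np.sum(np.exp(a * k)) - np.sum(xa)) / (n - 1))
    return c, float(a * c)


def fit(series: TimeSeries) -> SCGMParameters:
    """Estimate all SCGM(1,1)_c parameters from a series.

    A (numerically) trendless series yields a degenerate parameter set:
    the restored fit is the constant series mean and extrapolating
    layers must refuse to use it.
    """
    xm = mean_generate(series)
    a = estimate_development(xm)
    xa = accumulate(xm)
    if abs(a) < DEGENERATE_A:
        level = float(np.mean(series.array()))
        return SCGMParameters(
            a=a, b=float("nan"), c=float("nan"), U=float("nan"),
            M=level / 2.0, degenerate=True,
        )
    b = estimate_amplitude(a, xa)
    c, u = estimate_offset(a, b, xa)
    m_amp = float((1.0 - np.exp(-a)) * b / (1.0 + np.exp(-a)))
    return SCGMParameters(a=a, b=b, c=c, U=u, M=m_amp)


def restored_fit(params: SCGMParameters, k_range: Iterable[int],
                 shift: int = 0) -> np.ndarray:
    """Restored predictions ``x0hat(k) = 2*M*exp(a*(k - 1 + shift))``.

    ``shift=0`` is the model's own convention (anchored at ``k = 2``);
    ``shift=1`` evaluates the published-table convention used in the
    case study.  ``k = 1`` has no restored value and yields NaN; the
    CLI's compatibility view prints it as 0.
    """
    ks = np.asarray(list(k_range), dtype=float)
    if np.any(ks < 1):
        raise ValueError("indices must be >= 1 (1-based)")
    if params.degenerate:
        out = np.full(ks.shape, 2.0 * params.M)
    else:
        out = 2.0 * params.M * np.exp(params.a * (ks - 1 + shift))
    out[ks == 1] = np.nan
    return out


def accumulated_response(params: SCGMParameters, k_range: Iterable[int]) -> np.ndarray:
    """Accumulated-level response ``b*exp(a*(k-1)) - c``.

    Differencing it and restoring through ``2/(1 + e^-a)`` reproduces
    the restored fit (the offset cancels), which is how the order-zero
    prediction arises from the accumulated trend.
    """
    if params.degenerate:
        raise DegenerateTrendError("accumulated response undefined for a ~ 0")
    ks = np.asarray(list(k_range), dtype=float)
    return params.b * np.exp(params.a * (ks - 1)) - params.c


def diagnostics(actual: TimeSeries, fitted: Sequence[float],
                first_k: int = 2) -> FitDiagnostics:
    """Accuracy indicators Y, eps, Delta aligning ``fitted`` to ``actual``.

    ``fitted`` holds restored values for ``k = first_k, first_k+1, ...``
    and must not run past ``n``.
    """
    f = np.asarray(fitted, dtype=float)
    ks = np.arange(first_k, first_k + f.size)
    if ks[-1] > actual.n:
        raise ValueError("fitted sequence extends beyond the observed series")
    x = actual.array()[ks - 1]
    if np.any(f <= 0) or np.any(~np.isfinite(f)):
        raise ValueError("fitted values must be positive and finite")
    residual = f - x
    return FitDiagnostics(
        ks=ks, actual=x, fitted=f,
        ratio=x / f, residual=residual, delta=residual / x,
    )
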