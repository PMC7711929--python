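"""Linear INGARCH(1,1) conditional-mean recursion and its gradient.

The observed counts ``Y_t`` have conditional mean ``X_t`` following

    X_t = omega + a * X_{t-1} + b * Y_{t-1},

with ``omega > 0``, ``a, b >= 0`` and the contraction ``a + b < 1`` that
guarantees stationarity and ergodicity.  Given data and a parameter value
the recursion is run forward from an initial value ``x1`` (whose influence
decays geometrically like ``a**t``), together with the gradient recursion

    dX_t/dtheta = (1, X_{t-1}, Y_{t-1})' + a * dX_{t-1}/dtheta,

needed by the estimating-equation scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .families import Family

#: half-width of the excluded boundary layer of the compact parameter space
THETA_EPSILON = 1e-3


@dataclass(frozen=True)
class INGARCHParams:
    """theta = (omega, a, b) of the linear INGARCH(1,1) mean recursion."""

    omega: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.omega, self.a, self.b], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "INGARCHParams":
        omega, a, b = np.asarray(theta, dtype=float)
        return cls(float(omega), float(a), float(b))

    def scaled(self, factors) -> "INGARCHParams":
        """Componentwise multiply, e.g. a 25% inflation of all parameters."""
        f = np.asarray(factors, dtype=float)
        return INGARCHParams.from_array(self.as_array() * f)


@dataclass
class FilterState:
    """Filtered means, natural parameters and mean gradients along a series."""

    means: np.ndarray  # X~_t, shape (n,)
    etas: np.ndarray  # B^{-1}(X~_t), shape (n,)
    grads: np.ndarray  # dX~_t/dtheta, shape (n, 3); grads[0] = 0
    x1: float


def contraction_check(params: INGARCHParams, epsilon: float = THETA_EPSILON) -> bool:
    """True iff theta lies in the interior of the admissible region.

    Requires ``omega > 0``, ``a, b >= 0`` and ``a + b <= 1 - epsilon``.
    """
    return (
        params.omega > 0
        and params.a >= 0
        and params.b >= 0
        and params.a + params.b <= 1.0 - epsilon
    )


def stationary_mean(params: INGARCHParams) -> float:
    """Long-run mean ``omega / (1 - a - b)`` of a stationary path."""
    s = params.a + params.b
    if s >= 1.0:
        raise ValueError(f"a + b = {s} >= 1: no stationary mean")
    return params.omega / (1.0 - s)


def _ar1(inputs: np.ndarray, a: float, init: float) -> np.ndarray:
    """Solve z_t = inputs_t + a * z_{t-1} with z_0 = init, returning z_1..z_T."""
    out, _ = lfilter([1.0], [1.0, -a], inputs, zi=np.array([a * init]))
    return out


def validate_counts(series) -> np.ndarray:
    arr = np.asarray(series)
    if arr.size == 0:
        raise ValueError("count series is empty")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("count series must contain non-negative integers")
    return arr.astype(float)


def filter_with_grad(
    series,
    params: INGARCHParams,
    x1: float,
    fam: Optional[Family] = None,
) -> FilterState:
    """One-pass filtered means and mean gradients along an observed series.

    ``X~_1 = x1`` and ``X~_t = omega + a X~_{t-1} + b Y_{t-1}`` for t >= 2.
    The gradient starts at zero (x1 is a constant, not a function of theta).
    The linear recursion is an AR(1) filter in its own output, so the whole
    pass is four vectorised IIR filters.
    """
    y = validate_counts(series)
    if x1 <= 0:
        raise ValueError("initial mean x1 must be positive")
    n = y.size
    omega, a, b = params.omega, params.a, params.b

    means = np.empty(n)
    means[0] = x1
    grads = np.zeros((n, 3))
    if n > 1:
        means[1:] = _ar1(omega + b * y[:-1], a, x1)
        grads[1:, 0] = _ar1(np.ones(n - 1), a, 0.0)
        grads[1:, 1] = _ar1(means[:-1], a, 0.0)
        grads[1:, 2] = _ar1(y[:-1], a, 0.0)

    etas = fam.Binv(means) if fam is not None else np.full(n, np.nan)
    return FilterState(means=means, etas=etas, grads=grads, x1=float(x1))


def default_x1(training=None, series=None) -> float:
    """Initial filtered mean: training-sample mean, else first value + 1."""
    if training is not None and len(training) > 0:
        return float(np.mean(training))
    return float(series[0]) + 1.0


def read_counts(path) -> np.ndarray:
    """Read a single-column count CSV (optional header ``count``)."""
    first = pd.read_csv(path, nrows=1, header=None)
    header = 0 if str(first.iloc[0, 0]).strip().lower() == "count" else None
    df = pd.read_csv(path, header=header)
    return validate_counts(df.iloc[:, 0].to_numpy()).astype(int)


def write_counts(series, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"count": np.asarray(series, dtype=int)}).to_csv(path, index=False)
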