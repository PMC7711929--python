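"""Scenario generation: INGARCH paths, parameter changes, contamination.

A scenario describes a surveillance experiment: a training segment of
length m generated under the in-control parameter theta0, a monitoring
stream of length n whose mean recursion switches to theta1 from the change
index tau onward (the filtered mean is carried continuously across the
change), and optional Bernoulli–Poisson contamination in which each
observation is independently replaced by an iid Poisson(lam) outlier with
probability p.  Contamination is applied after generation, so outliers do
not feed back into the mean recursion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .families import Family, get_family
from .ingarch import INGARCHParams, contraction_check, stationary_mean

#: default burn-in; geometric ergodicity makes residual initialisation
#: bias negligible at a + b <= 0.8
DEFAULT_BURN = 500


@dataclass
class Scenario:
    """One cell of the size/power study design."""

    theta0: INGARCHParams
    theta1: Optional[INGARCHParams] = None  # defaults to theta0 (no change)
    tau: Optional[int] = None  # 1-based change index in the stream
    n: int = 500
    m: int = 500
    family: str = "poisson"
    r: Optional[int] = None
    case_id: Optional[int] = None
    delta: Optional[float] = None
    contamination: Optional[Tuple[float, float]] = None  # (p, lam)
    burn: int = DEFAULT_BURN

    def __post_init__(self):
        if not contraction_check(self.theta0):
            raise ValueError("theta0 violates the contraction condition")
        if self.theta1 is not None and not contraction_check(self.theta1):
            raise ValueError("theta1 violates the contraction condition")
        if self.tau is not None and not 1 <= self.tau <= self.n:
            raise ValueError("change index tau must lie in 1..n")
        if self.contamination is not None:
            p, lam = self.contamination
            if not 0.0 <= p < 1.0:
                raise ValueError("contamination probability must lie in [0, 1)")
            if p > 0 and lam <= 0:
                raise ValueError("outlier intensity must be positive")

    def get_family(self) -> Family:
        return get_family(self.family, r=self.r)

    @classmethod
    def from_case(
        cls,
        case_id: int,
        theta0: INGARCHParams,
        delta: float,
        n: int,
        m: int,
        tau: Optional[int] = None,
        contamination: Optional[Tuple[float, float]] = None,
        family: str = "poisson",
        r: Optional[int] = None,
    ) -> "Scenario":
        """Build a scenario from the four canonical change patterns.

        Case 1 inflates all of (omega, a, b) by (1+delta); cases 2-4 change
        only omega, a, or b respectively.  The change occurs at ``tau``
        (default: mid-stream, ``n // 2``).
        """
        masks = {1: (1, 1, 1), 2: (1, 0, 0), 3: (0, 1, 0), 4: (0, 0, 1)}
        if case_id not in masks:
            raise ValueError("case_id must be 1-4")
        factors = 1.0 + delta * np.asarray(masks[case_id], dtype=float)
        return cls(
            theta0=theta0,
            theta1=theta0.scaled(factors),
            tau=tau if tau is not None else n // 2,
            n=n,
            m=m,
            family=family,
            r=r,
            case_id=case_id,
            delta=delta,
            contamination=contamination,
        )


def simulate_path(
    params: INGARCHParams,
    n: int,
    fam: Family,
    rng: np.random.Generator,
    burn: int = DEFAULT_BURN,
    x_init: Optional[float] = None,
) -> np.ndarray:
    """Simulate n counts from a stationary INGARCH(1,1) path.

    The mean recursion starts at the stationary mean and a burn-in of
    ``burn`` draws is discarded.
    """
    if burn < 0:
        raise ValueError("burn must be >= 0")
    x = stationary_mean(params) if x_init is None else float(x_init)
    omega, a, b = params.omega, params.a, params.b
    out = np.empty(n, dtype=np.int64)
    for t in range(burn + n):
        y = int(fam.sample_mean(x, rng))
        if t >= burn:
            out[t - burn] = y
        x = omega + a * x + b * y
    return out


def simulate_with_change(
    scenario: Scenario, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Training sample and monitoring stream, as one continuous path.

    The whole path runs under theta0 through the training segment and the
    first ``tau - 1`` stream observations; the recursion switches to theta1
    for stream indices t >= tau, with the conditional mean carried across
    the change.  If the scenario specifies contamination, both segments are
    contaminated (the training data come from the same contaminated law as
    the stream).
    """
    fam = scenario.get_family()
    theta0, theta1 = scenario.theta0, scenario.theta1 or scenario.theta0
    m, n, tau = scenario.m, scenario.n, scenario.tau

    x = stationary_mean(theta0)
    counts = np.empty(m + n, dtype=np.int64)
    for t in range(scenario.burn + m + n):
        stream_idx = t - scenario.burn - m + 1  # 1-based index into the stream
        y = int(fam.sample_mean(x, rng))
        if t >= scenario.burn:
            counts[t - scenario.burn] = y
        nxt = theta1 if (tau is not None and stream_idx + 1 >= tau) else theta0
        x = nxt.omega + nxt.a * x + nxt.b * y
    train, stream = counts[:m], counts[m:]

    if scenario.contamination is not None and scenario.contamination[0] > 0:
        p, lam = scenario.contamination
        train = contaminate(train, p, lam, rng)
        stream = contaminate(stream, p, lam, rng)
    return train, stream


def contaminate(series, p: float, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Replace each observation by an iid Poisson(lam) outlier w.p. p."""
    if not 0.0 <= p < 1.0:
        raise ValueError("p must lie in [0, 1)")
    series = np.asarray(series)
    if p == 0.0:
        return series.copy()
    if lam <= 0:
        raise ValueError("lam must be positive")
    mask = rng.random(series.size) < p
    z = rng.poisson(lam, series.size)
    return np.where(mask, z, series)
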