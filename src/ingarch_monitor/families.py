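"""One-parameter exponential-family count distributions.

The conditional law of an INGARCH observation given its past is a pmf of
the form ``p(y | eta) = exp(eta * y - A(eta)) * h(y)`` with natural
parameter ``eta``, log-partition ``A`` and base measure ``h``.  The mean
map is ``B = A'`` and the conditional variance is ``B'(eta)``.  Two
members are provided: Poisson, and negative binomial with a fixed integer
size ``r`` (natural parameter ``eta = log(1 - p)``, so the mean is
``r * exp(eta) / (1 - exp(eta))``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import special, stats

logger = logging.getLogger(__name__)

#: hard ceiling on truncation bounds for the infinite sums in the
#: density-power-divergence objective
HARD_CEILING = 10_000


@dataclass(frozen=True)
class Family:
    """An exponential-family pmf ``exp(eta*y - A(eta)) h(y)``.

    Parameters
    ----------
    name : str
        Family identifier ("poisson" or "nb").
    A, B, Bprime : callable
        Log-partition, mean map (``A'``) and variance map (``A''``), each
        vectorised over the natural parameter.
    Binv : callable
        Inverse mean map: mean -> natural parameter.
    logh : callable
        Log base measure, vectorised over counts.
    eta_max : float
        Open upper bound of the natural-parameter domain (``inf`` for
        Poisson, ``0`` for negative binomial).
    r : int, optional
        Negative-binomial size, fixed at construction.
    """

    name: str
    A: Callable[[np.ndarray], np.ndarray]
    B: Callable[[np.ndarray], np.ndarray]
    Bprime: Callable[[np.ndarray], np.ndarray]
    Binv: Callable[[np.ndarray], np.ndarray]
    logh: Callable[[np.ndarray], np.ndarray]
    eta_max: float
    r: Optional[int] = None

    def _check_eta(self, eta) -> None:
        if np.any(np.asarray(eta) >= self.eta_max):
            raise ValueError(
                f"natural parameter out of domain for family {self.name!r}: "
                f"require eta < {self.eta_max}"
            )

    def log_pmf(self, y, eta):
        """Log pmf, vectorised over ``y`` and ``eta`` (broadcasting)."""
        self._check_eta(eta)
        y = np.asarray(y)
        return eta * y - self.A(eta) + self.logh(y)

    def pmf(self, y, eta):
        """Pmf evaluated in log space to avoid underflow."""
        return np.exp(self.log_pmf(y, eta))

    def mean(self, eta):
        return self.B(eta)

    def variance(self, eta):
        return self.Bprime(eta)

    def sample(self, eta, rng: np.random.Generator, size=None):
        """Draw counts with natural parameter ``eta``."""
        self._check_eta(eta)
        return self.sample_mean(self.B(eta), rng, size=size)

    def sample_mean(self, mu, rng: np.random.Generator, size=None):
        """Draw counts with mean ``mu`` (the INGARCH recursion works on means)."""
        if self.name == "poisson":
            return rng.poisson(mu, size=size)
        # NB(r, p) with mean r(1-p)/p  =>  p = r / (r + mu)
        p = self.r / (self.r + mu)
        return rng.negative_binomial(self.r, p, size=size)

    def truncation_bound(self, eta, tol: float, ceiling: int = HARD_CEILING) -> int:
        """Smallest ``y*`` with cumulative pmf >= 1 - tol, capped at ``ceiling``.

        Used to truncate the infinite sums over the support in the
        density-power-divergence objective.
        """
        if not 0.0 < tol < 1.0:
            raise ValueError("tol must lie in (0, 1)")
        self._check_eta(eta)
        mu = float(np.max(self.B(eta)))
        if self.name == "poisson":
            bound = int(stats.poisson.ppf(1.0 - tol, mu))
        else:
            p = self.r / (self.r + mu)
            bound = int(stats.nbinom.ppf(1.0 - tol, self.r, p))
        if bound > ceiling:
            logger.warning(
                "truncation bound %d exceeds ceiling %d; using ceiling", bound, ceiling
            )
            return ceiling
        return bound


def poisson() -> Family:
    """Poisson family: ``eta = log(mean)``, ``A(eta) = exp(eta)``."""
    return Family(
        name="poisson",
        A=np.exp,
        B=np.exp,
        Bprime=np.exp,
        Binv=np.log,
        logh=lambda y: -special.gammaln(np.asarray(y) + 1.0),
        eta_max=np.inf,
    )


def negbin(r: int) -> Family:
    """Negative binomial with fixed integer size ``r``.

    ``eta = log(1 - p)`` (so eta < 0), mean ``r e^eta / (1 - e^eta)``
    and variance ``mu + mu^2 / r`` (overdispersed).
    """
    if not (isinstance(r, (int, np.integer)) and r >= 1):
        raise ValueError("negative-binomial size r must be a positive integer")
    r = int(r)
    return Family(
        name="nb",
        A=lambda eta: -r * np.log1p(-np.exp(eta)),
        B=lambda eta: r * np.exp(eta) / (1.0 - np.exp(eta)),
        Bprime=lambda eta: r * np.exp(eta) / (1.0 - np.exp(eta)) ** 2,
        Binv=lambda mu: np.log(mu / (r + mu)),
        logh=lambda y: special.gammaln(np.asarray(y) + r)
        - special.gammaln(r)
        - special.gammaln(np.asarray(y) + 1.0),
        eta_max=0.0,
        r=r,
    )


def get_family(name: str, r: Optional[int] = None) -> Family:
    """Resolve a family from its config name ("poisson" or "nb")."""
    name = name.lower()
    if name == "poisson":
        return poisson()
    if name in ("nb", "negbin", "negative_binomial"):
        if r is None:
            raise ValueError("negative binomial requires the integer size r")
        return negbin(r)
    raise ValueError(f"unknown family {name!r}")
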