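"""Score-based CUSUM monitoring of parameter change.

The monitoring process is the normalised cumulative score path

    W_k = Khat^{-1/2} sum_{t<=k} s_t,   k = 1..n,

where ``s_t`` is the per-observation MDPDE score on the monitoring stream
(evaluated at a known in-control theta0, or at the estimate fitted on the
training sample) and ``Khat`` is the empirical score covariance computed
from the training sample.  Three closed-end detector statistics are
tracked over a fixed horizon n:

    min:    max_k  n^{-1/2} || (min_{j<=k} W_j) - W_k ||_max
    max:    max_k  n^{-1/2} || (max_{j<=k} W_j) - W_k ||_max
    cusum:  max_k  max_{i<j<=k} n^{-1/2} || (i/j) W_j - W_i ||_2

(the min/max running extrema are componentwise).  An alarm is raised at
the first k whose statistic exceeds a control limit: the analytic quantile
of the Brownian supremum for min/max, a Monte-Carlo quantile of the bridge
functional for cusum, or a parametric-bootstrap quantile that corrects for
parameter-estimation effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from . import limits as _limits
from ._pairsup import pairwise_weighted_path
from .families import Family
from .ingarch import INGARCHParams, default_x1, filter_with_grad, validate_counts
from .mdpde import MDPDEFit, ScorePath, fit as mdpde_fit, khat as khat_of, loss_score_path
from .simulate import simulate_path

logger = logging.getLogger(__name__)

STAT_KINDS = ("min", "max", "cusum")

#: relative eigenvalue floor guarding near-singular score covariances
INV_SQRT_FLOOR = 1e-10


@dataclass
class WProcess:
    """Normalised cumulative score path and the covariance that scaled it."""

    w: np.ndarray  # (k, 3)
    khat_used: np.ndarray
    mode: str  # "known" | "estimated"


@dataclass
class MonitorResult:
    """One detector's path, control limit and alarm decision."""

    statistic_kind: str
    path: np.ndarray  # T(k), k = 1..n_observed
    overall: float
    limit: Optional[float] = None
    limit_source: Optional[str] = None
    alarm_time: Optional[int] = None  # 1-based first exceedance

    def to_dict(self) -> dict:
        return {
            "statistic_kind": self.statistic_kind,
            "overall": self.overall,
            "limit": self.limit,
            "limit_source": self.limit_source,
            "alarm_time": self.alarm_time,
        }


def inv_sqrt(mat: np.ndarray, floor: float = INV_SQRT_FLOOR) -> np.ndarray:
    """Symmetric inverse square root with a relative eigenvalue floor."""
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    vals, vecs = np.linalg.eigh(0.5 * (mat + mat.T))
    top = vals.max()
    if top <= 0:
        raise ValueError("matrix has no positive eigenvalue")
    clipped = np.maximum(vals, floor * top)
    if np.any(vals < floor * top):
        logger.warning("inv_sqrt: clipped %d near-zero eigenvalues", int((vals < floor * top).sum()))
    return (vecs / np.sqrt(clipped)) @ vecs.T


def w_process(scores: ScorePath, khat: np.ndarray, mode: str = "known") -> WProcess:
    """Cumulative score sums, left-multiplied by ``Khat^{-1/2}``."""
    m = inv_sqrt(khat)
    w = np.cumsum(scores.scores, axis=0) @ m  # symmetric, so right-multiply rows
    return WProcess(w=w, khat_used=np.asarray(khat, dtype=float), mode=mode)


def stat_paths(w: WProcess, n: int) -> Dict[str, MonitorResult]:
    """The three detector paths over k = 1..k_obs, scaled by the horizon n.

    The scaling uses the planned closed-end horizon n even for interim k,
    so a partially observed stream (k_obs < n) gives the same interim values
    it would in the full run.
    """
    path = np.atleast_2d(w.w)
    k_obs = path.shape[0]
    if k_obs > n:
        raise ValueError(f"observed {k_obs} steps but horizon is {n}")
    root_n = np.sqrt(n)

    lo = np.minimum.accumulate(path, axis=0)
    hi = np.maximum.accumulate(path, axis=0)
    min_path = np.maximum.accumulate(np.abs(lo - path).max(axis=1)) / root_n
    max_path = np.maximum.accumulate(np.abs(hi - path).max(axis=1)) / root_n
    cusum_path = pairwise_weighted_path(path) / root_n

    return {
        "min": MonitorResult("min", min_path, float(min_path[-1])),
        "max": MonitorResult("max", max_path, float(max_path[-1])),
        "cusum": MonitorResult("cusum", cusum_path, float(cusum_path[-1])),
    }


def _alarm_time(path: np.ndarray, limit: float) -> Optional[int]:
    hits = np.nonzero(path > limit)[0]
    return int(hits[0]) + 1 if hits.size else None


def scores_at(
    series, theta: INGARCHParams, alpha: float, fam: Family, x1: float
) -> ScorePath:
    """MDPDE score path of a series filtered at a fixed parameter value."""
    state = filter_with_grad(series, theta, x1, fam)
    return loss_score_path(series, state, alpha, fam)


def monitor(
    stream,
    training,
    fam: Family,
    alpha: float = 0.0,
    mode: str = "estimated",
    theta0: Optional[INGARCHParams] = None,
    level: float = 0.05,
    limit_source: str = "analytic",
    statistics: Sequence[str] = STAT_KINDS,
    horizon: Optional[int] = None,
    boot_B: int = 500,
    rng: Optional[np.random.Generator] = None,
    mc_settings: Optional[dict] = None,
) -> Dict[str, MonitorResult]:
    """Run the monitoring procedure on a stream given a training sample.

    In "known" mode the score covariance is estimated from the training
    sample at the supplied in-control ``theta0`` and the stream scores are
    evaluated at ``theta0``.  In "estimated" mode the MDPDE is fitted on
    the training sample and both the covariance and the stream scores use
    the fitted value.  ``limit_source`` selects analytic quantiles
    ("analytic"; Monte Carlo for the cusum detector), pure Monte-Carlo
    quantiles ("mc"), or a parametric bootstrap ("bootstrap").
    """
    stream = validate_counts(stream).astype(int)
    training = validate_counts(training).astype(int)
    if training.size < 50:
        logger.warning("training sample of %d is short; Khat may be unstable", training.size)
    n = horizon if horizon is not None else stream.size
    x1 = default_x1(training=training)
    fit_result: Optional[MDPDEFit] = None

    if mode == "known":
        if theta0 is None:
            raise ValueError("known mode requires theta0")
        theta_use = theta0
        K = khat_of(scores_at(training, theta_use, alpha, fam, x1))
    elif mode == "estimated":
        fit_result = mdpde_fit(training, alpha, fam, x1=x1)
        theta_use = fit_result.theta_hat
        K = fit_result.khat
    else:
        raise ValueError("mode must be 'known' or 'estimated'")

    stream_scores = scores_at(stream, theta_use, alpha, fam, x1)
    results = stat_paths(w_process(stream_scores, K, mode), n)
    results = {k: v for k, v in results.items() if k in statistics}

    rng = rng or np.random.default_rng()
    for kind, res in results.items():
        if limit_source == "analytic":
            if kind in ("min", "max"):
                limit = _limits.t_quantile(3, level)
            else:
                limit = _limits.tprime_quantile_mc(3, level, **(mc_settings or {}))
        elif limit_source == "mc":
            limit = (
                _limits.t_quantile(3, level)
                if kind in ("min", "max")
                else _limits.tprime_quantile_mc(3, level, **(mc_settings or {}))
            )
        elif limit_source == "bootstrap":
            if fit_result is None:
                fit_result = mdpde_fit(training, alpha, fam, x1=x1)
            limit = bootstrap_limit(
                fit_result, training.size, n, alpha, kind, level, boot_B, rng, fam
            )
        else:
            raise ValueError("limit_source must be analytic, mc or bootstrap")
        res.limit = float(limit)
        res.limit_source = limit_source
        res.alarm_time = _alarm_time(res.path, limit)
    return results


def bootstrap_statistic(
    theta: INGARCHParams,
    m: int,
    n: int,
    alpha: float,
    statistic_kind: str,
    fam: Family,
    rng: np.random.Generator,
    contamination=None,
) -> float:
    """One parametric-bootstrap replicate of a monitoring statistic.

    Simulates m + n counts from the fitted model, re-fits on the first m,
    and evaluates the detector on the last n — mirroring the estimation
    effect present in the observed statistic.  When the observations follow
    a contaminated law with known mechanism ``(p, lam)``, the bootstrap
    replicate applies the same mechanism so that the resulting quantile
    calibrates the statistic actually monitored.
    """
    series = simulate_path(theta, m + n, fam, rng)
    if contamination is not None and contamination[0] > 0:
        from .simulate import contaminate

        series = contaminate(series, contamination[0], contamination[1], rng)
    train, stream = series[:m], series[m:]
    x1 = default_x1(training=train)
    refit = mdpde_fit(train, alpha, fam, x1=x1)
    if not refit.converged:
        raise RuntimeError("bootstrap re-fit did not converge")
    sc = scores_at(stream, refit.theta_hat, alpha, fam, x1)
    return stat_paths(w_process(sc, refit.khat, "estimated"), n)[statistic_kind].overall


def bootstrap_limit(
    fit: MDPDEFit,
    m: int,
    n: int,
    alpha: float,
    statistic_kind: str,
    level: float,
    B: int,
    rng: np.random.Generator,
    fam: Family,
) -> float:
    """Parametric-bootstrap (1-level) quantile of a monitoring statistic.

    Replicates whose re-fit fails are dropped; more than 20% failures is an
    error.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if not fit.converged:
        raise ValueError("cannot bootstrap from a non-converged fit")
    stats, failures = [], 0
    for _ in range(B):
        try:
            stats.append(
                bootstrap_statistic(fit.theta_hat, m, n, alpha, statistic_kind, fam, rng)
            )
        except (RuntimeError, ValueError):
            failures += 1
    if failures > 0.2 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap re-fits failed")
    if failures:
        logger.warning("dropped %d failed bootstrap replicates", failures)
    return float(np.quantile(stats, 1.0 - level))
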