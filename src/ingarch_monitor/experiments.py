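"""Size/power study runner for the monitoring procedure.

Each cell of the study fixes a scenario (model, change pattern, change
location, contamination), a tuning parameter alpha and a detector, and
estimates the rejection probability over R independent replications.
Known-theta0 cells use the analytic control limit; estimated-parameter
cells use warp-speed bootstrap limits, in which each Monte-Carlo
replication contributes exactly one parametric-bootstrap replicate and the
pooled replicates form the common critical value — a standard device that
cuts the bootstrap cost of a simulation study by a factor of B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import limits as _limits
from .ingarch import default_x1
from .mdpde import fit as mdpde_fit, khat as khat_of
from .monitor import scores_at, stat_paths, w_process, bootstrap_statistic
from .simulate import Scenario, simulate_with_change

logger = logging.getLogger(__name__)

#: default replication scales (full-study value is 1000)
DEFAULT_R_KNOWN = 500
DEFAULT_R_BOOT = 200


@dataclass
class SizePowerTable:
    """Long-format table of empirical rejection rates with MC standard errors."""

    rows: List[dict] = field(default_factory=list)

    def add(self, **cell) -> None:
        cell["se"] = float(np.sqrt(cell["rate"] * (1.0 - cell["rate"]) / cell["reps"]))
        self.rows.append(cell)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _replication_seeds(seed: int, R: int) -> list:
    """Independent child seeds, one per replication, from a master seed."""
    return np.random.SeedSequence(seed).spawn(R)


def known_theta_statistics(
    scenario: Scenario, alpha: float, statistic: str, R: int, seed: int
) -> Tuple[np.ndarray, int]:
    """Observed detector statistics over R replications at the true theta0.

    Per replication: draw (training, stream), estimate the score covariance
    from the training scores at theta0, evaluate the stream scores at
    theta0 and return the overall detector value.  Returns the statistics
    and the number of failed replications (excluded).
    """
    fam = scenario.get_family()
    out, failures = [], 0
    for child in _replication_seeds(seed, R):
        rng = np.random.default_rng(child)
        try:
            train, stream = simulate_with_change(scenario, rng)
            x1 = default_x1(training=train)
            K = khat_of(scores_at(train, scenario.theta0, alpha, fam, x1))
            sc = scores_at(stream, scenario.theta0, alpha, fam, x1)
            res = stat_paths(w_process(sc, K, "known"), scenario.n)[statistic]
            out.append(res.overall)
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            failures += 1
            logger.warning("replication failed: %s", exc)
    return np.asarray(out), failures


def known_theta_cell(
    scenario: Scenario,
    alpha: float,
    statistic: str = "min",
    R: int = DEFAULT_R_KNOWN,
    level: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of a known-theta0 cell with the analytic limit."""
    if statistic in ("min", "max"):
        limit = _limits.t_quantile(3, level)
    else:
        limit = _limits.tprime_quantile_mc(3, level)
    stats, _ = known_theta_statistics(scenario, alpha, statistic, R, seed)
    return float(np.mean(stats > limit))


def warp_cell(
    scenario: Scenario,
    alpha: float,
    statistic: str = "cusum",
    R: int = DEFAULT_R_BOOT,
    level: float = 0.05,
    seed: int = 0,
) -> Tuple[float, float, int]:
    """Estimated-parameter cell with warp-speed bootstrap control limits.

    Per replication: draw (training, stream) — contaminated if the scenario
    says so — fit the MDPDE on the training sample, evaluate the detector
    on the stream at the fitted value, and draw ONE clean parametric
    bootstrap replicate from the fitted model (simulate m + n, re-fit on
    the first m, detector on the last n).  The pooled (1-level) quantile of
    the R bootstrap statistics is the common control limit.

    Returns (rejection rate, warp limit, failures).
    """
    fam = scenario.get_family()
    observed, boot, failures = [], [], 0
    for child in _replication_seeds(seed, R):
        rng = np.random.default_rng(child)
        try:
            train, stream = simulate_with_change(scenario, rng)
            x1 = default_x1(training=train)
            fit = mdpde_fit(train, alpha, fam, x1=x1)
            sc = scores_at(stream, fit.theta_hat, alpha, fam, x1)
            t_obs = stat_paths(w_process(sc, fit.khat, "estimated"), scenario.n)[
                statistic
            ].overall
            t_boot = bootstrap_statistic(
                fit.theta_hat,
                scenario.m,
                scenario.n,
                alpha,
                statistic,
                fam,
                rng,
                contamination=scenario.contamination,
            )
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            failures += 1
            logger.warning("replication failed: %s", exc)
            continue
        observed.append(t_obs)
        boot.append(t_boot)
    if failures > 0.2 * R:
        raise RuntimeError(f"{failures}/{R} replications failed")
    limit = float(np.quantile(boot, 1.0 - level))
    rate = float(np.mean(np.asarray(observed) > limit))
    return rate, limit, failures


def warp_limit(
    scenario: Scenario,
    statistic_kind: str,
    alpha: float,
    level: float = 0.05,
    R: int = DEFAULT_R_BOOT,
    seed: int = 0,
) -> float:
    """The pooled warp-speed bootstrap control limit for one study cell."""
    _, limit, _ = warp_cell(scenario, alpha, statistic_kind, R=R, level=level, seed=seed)
    return limit


def run_size_power(
    scenarios: Iterable[Scenario],
    statistics: Sequence[str] = ("min", "cusum"),
    alphas: Sequence[float] = (0.0, 0.1),
    R: Optional[int] = None,
    limit_source: str = "analytic",
    level: float = 0.05,
    seed: int = 0,
) -> SizePowerTable:
    """Run a grid of size/power cells and collect rejection rates.

    ``limit_source`` "analytic" runs known-theta0 cells against the fixed
    Brownian-functional quantile; "warp" runs estimated-parameter cells
    with warp-speed bootstrap limits.  Cells are independently seeded from
    the master seed, so any subset reproduces identically.
    """
    table = SizePowerTable()
    base = np.random.SeedSequence(seed)
    cell_idx = 0
    for scenario in scenarios:
        for alpha in alphas:
            for statistic in statistics:
                cell_seed = int(base.spawn(1)[0].generate_state(1)[0] % (2**31))
                cell_idx += 1
                reps = R if R is not None else (
                    DEFAULT_R_KNOWN if limit_source == "analytic" else DEFAULT_R_BOOT
                )
                if limit_source == "analytic":
                    rate = known_theta_cell(
                        scenario, alpha, statistic, R=reps, level=level, seed=cell_seed
                    )
                    limit = None
                elif limit_source in ("warp", "bootstrap"):
                    rate, limit, _ = warp_cell(
                        scenario, alpha, statistic, R=reps, level=level, seed=cell_seed
                    )
                else:
                    raise ValueError("limit_source must be 'analytic' or 'warp'")
                p, lam = scenario.contamination or (0.0, None)
                table.add(
                    statistic=statistic,
                    alpha=alpha,
                    n=scenario.n,
                    m=scenario.m,
                    tau=scenario.tau,
                    delta=scenario.delta,
                    p=p,
                    lam=lam,
                    rate=rate,
                    reps=reps,
                    limit_source=limit_source,
                    limit=limit,
                )
    return table
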