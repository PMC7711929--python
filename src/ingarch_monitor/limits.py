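"""Control limits from the limiting Brownian functionals.

Under no change the min- and max-type monitoring statistics converge to

    T = sup_{0<=s<=1} || B_d(s) ||_max,

the supremum of the max-norm of a d-dimensional standard Brownian motion,
whose quantiles follow from the scalar reflection series via independence
of components: ``P(T >= c) = 1 - (1 - P(sup|B| >= c))^d``.  The cusum-type
statistic converges to

    T' = sup_{0 < s <= s' <= 1} || (s/s') B_d°(s') - B_d°(s) ||,

a weighted Brownian-bridge increment functional with no closed form; its
quantiles are obtained by Monte Carlo.  The bridge terms cancel in the
weighted difference — ``(s/s') B°(s') - B°(s) = (s/s') B(s') - B(s)`` — so
plain Brownian paths can be simulated.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import optimize


@dataclass(frozen=True)
class LimitSpec:
    """A resolved control limit (kind T or T', with its provenance)."""

    d: int
    level: float
    kind: str  # "T" | "Tprime"
    value: float
    method: str  # "series" | "mc"
    mc_settings: Optional[dict] = None


def sup_abs_bm_tail(c: float) -> float:
    """``P(sup_{0<=s<=1} |B(s)| >= c)`` for scalar standard Brownian motion.

    Alternating reflection series, summed until terms fall below 1e-14:
    ``1 - (4/pi) sum_k (-1)^k/(2k+1) exp(-pi^2 (2k+1)^2 / (8 c^2))``.
    """
    if c <= 0:
        return 1.0
    total, k = 0.0, 0
    while True:
        term = ((-1.0) ** k / (2 * k + 1)) * np.exp(-np.pi**2 * (2 * k + 1) ** 2 / (8.0 * c**2))
        total += term
        if abs(term) < 1e-14:
            break
        k += 1
    return float(1.0 - 4.0 / np.pi * total)


def t_quantile(d: int, level: float) -> float:
    """Control limit c with ``P(sup ||B_d||_max >= c) = level``.

    Solves the per-component rule ``P(sup|B| >= c) = 1 - (1-level)^(1/d)``
    by bracketed root-finding to 1e-6.
    """
    if d < 1:
        raise ValueError("dimension d must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    target = 1.0 - (1.0 - level) ** (1.0 / d)
    return float(
        optimize.brentq(lambda c: sup_abs_bm_tail(c) - target, 1e-6, 100.0, xtol=1e-6)
    )


def _default_cache_path() -> Path:
    base = os.environ.get("XDG_CACHE_HOME", os.path.join(os.path.expanduser("~"), ".cache"))
    return Path(base) / "ingarch-monitor" / "limits.json"


def _cache_load(path: Path) -> dict:
    try:
        with open(path) as fh:
            return json.load(fh)
    except (OSError, json.JSONDecodeError):
        return {}


def _cache_store(path: Path, cache: dict) -> None:
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(cache, fh)
    except OSError:
        pass  # caching is best-effort


def tprime_samples(d: int, grid: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo draws of ``sup_{s<=s'} ||(s/s')B_d(s') - B_d(s)||`` on a grid.

    Paths are simulated on ``s_i = i/grid`` and the sup is taken exactly over
    all grid pairs; discretisation biases the sup slightly downward.
    """
    out = np.empty(reps)
    # chunk replicates to bound the (chunk, grid, d) working set
    chunk = max(1, int(2e6 // (grid * d)))
    done = 0
    while done < reps:
        k = min(chunk, reps - done)
        paths = np.cumsum(rng.normal(scale=np.sqrt(1.0 / grid), size=(k, grid, d)), axis=1)
        best = np.zeros(k)
        for j in range(1, grid):
            ratio = np.arange(1, j + 1) / (j + 1.0)
            diff = ratio[None, :, None] * paths[:, j, None, :] - paths[:, :j, :]
            np.maximum(best, (diff * diff).sum(axis=2).max(axis=1), out=best)
        out[done : done + k] = np.sqrt(best)
        done += k
    return out


def tprime_quantile_mc(
    d: int,
    level: float,
    grid: int = 2000,
    reps: int = 20000,
    seed: int = 20201116,
    cache_path: Optional[Path] = None,
) -> float:
    """(1-level) Monte-Carlo quantile of the bridge-increment functional T'.

    Results are cached on disk keyed by (d, grid, reps, seed) since the same
    limit is reused across simulation cells.
    """
    if grid < 2 or reps < 2:
        raise ValueError("grid and reps must each be >= 2")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    path = cache_path if cache_path is not None else _default_cache_path()
    key = f"tprime:d={d}:grid={grid}:reps={reps}:seed={seed}"
    cache = _cache_load(path)
    if key not in cache:
        samples = tprime_samples(d, grid, reps, np.random.default_rng(seed))
        # cache the empirical quantile function on a fine probability grid
        probs = np.linspace(0.0005, 0.9995, 1999)
        cache[key] = np.quantile(samples, probs).tolist()
        _cache_store(path, cache)
    probs = np.linspace(0.0005, 0.9995, 1999)
    return float(np.interp(1.0 - level, probs, np.asarray(cache[key])))
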