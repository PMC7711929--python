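import numpy as np
import pytest

from ingarch_monitor import (
    INGARCHParams,
    fit,
    inv_sqrt,
    monitor,
    poisson,
    simulate_path,
    stat_paths,
    w_process,
)
from ingarch_monitor.mdpde import ScorePath
from ingarch_monitor.monitor import WProcess, bootstrap_limit

_POIS = poisson()


def brute_stat_oracle(W, n):
    """Exhaustive enumeration of the three detector paths (tiny k only)."""
    k = W.shape[0]
    out = {"min": np.zeros(k), "max": np.zeros(k), "cusum": np.zeros(k)}
    for kk in range(1, k + 1):
        best = {"min": 0.0, "max": 0.0, "cusum": 0.0}
        for j in range(1, kk + 1):
            lo = W[:j].min(axis=0)
            hi = W[:j].max(axis=0)
            best["min"] = max(best["min"], np.abs(lo - W[j - 1]).max())
            best["max"] = max(best["max"], np.abs(hi - W[j - 1]).max())
            for i in range(1, j):
                best["cusum"] = max(
                    best["cusum"], np.linalg.norm((i / j) * W[j - 1] - W[i - 1])
                )
        for key in out:
            out[key][kk - 1] = best[key] / np.sqrt(n)
    # min/max/cusum paths are running maxima over k by construction
    for key in out:
        out[key] = np.maximum.accumulate(out[key])
    return out


def _wrap(scores, alpha=0.0):
    return ScorePath(alpha=alpha, losses=np.zeros(len(scores)), scores=np.asarray(scores, float))


class TestInvSqrt:
    def test_identity(self):
        assert inv_sqrt(np.eye(3)) == pytest.approx(np.eye(3))

    def test_diagonal(self):
        got = inv_sqrt(np.diag([4.0, 9.0, 16.0]))
        assert got == pytest.approx(np.diag([0.5, 1 / 3, 0.25]))

    def test_algebraic_identity_random_psd(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            A = rng.normal(size=(3, 3))
            M = A @ A.T + 0.1 * np.eye(3)
            R = inv_sqrt(M)
            assert R @ M @ R == pytest.approx(np.eye(3), abs=1e-8)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            inv_sqrt(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            inv_sqrt(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestWProcess:
    def test_zero_scores(self):
        w = w_process(_wrap(np.zeros((5, 3))), np.eye(3))
        assert np.all(w.w == 0)

    def test_single_score_identity_k(self):
        s = np.array([[1.0, -2.0, 0.5]])
        w = w_process(_wrap(s), np.eye(3))
        assert w.w[0] == pytest.approx(s[0])

    def test_last_row_is_standardized_column_sum(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(20, 3))
        K = np.cov(scores.T) + 0.5 * np.eye(3)
        w = w_process(_wrap(scores), K)
        assert w.w[-1] == pytest.approx(inv_sqrt(K) @ scores.sum(axis=0))


class TestStatPaths:
    def test_degenerate_paths_give_zero(self):
        # running-extremum detectors vanish on any constant path; the
        # cusum detector vanishes on the zero path (a constant nonzero W
        # still has (i/j)W - W != 0)
        W = np.tile([1.0, -2.0, 3.0], (6, 1))
        res = stat_paths(WProcess(W, np.eye(3), "known"), 6)
        assert np.all(res["min"].path == 0)
        assert np.all(res["max"].path == 0)
        zero = stat_paths(WProcess(np.zeros((6, 3)), np.eye(3), "known"), 6)
        for r in zero.values():
            assert np.all(r.path == 0)

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_matches_exhaustive_oracle(self, k):
        rng = np.random.default_rng(k)
        for _ in range(25):
            W = rng.normal(size=(k, 3)).cumsum(axis=0)
            res = stat_paths(WProcess(W, np.eye(3), "known"), k)
            oracle = brute_stat_oracle(W, k)
            for kind in ("min", "max", "cusum"):
                assert res[kind].path == pytest.approx(oracle[kind], abs=1e-12), kind

    def test_paths_monotone_and_nonnegative(self):
        rng = np.random.default_rng(9)
        W = rng.normal(size=(200, 3)).cumsum(axis=0)
        res = stat_paths(WProcess(W, np.eye(3), "known"), 400)
        for r in res.values():
            assert np.all(r.path >= 0)
            assert np.all(np.diff(r.path) >= -1e-15)
            assert r.overall == pytest.approx(r.path[-1])

    def test_horizon_shorter_than_path_errors(self):
        with pytest.raises(ValueError):
            stat_paths(WProcess(np.zeros((5, 3)), np.eye(3), "known"), 3)


class TestMonitor:
    theta0 = INGARCHParams(2.0, 0.2, 0.3)

    def _data(self, seed, change=None):
        rng = np.random.default_rng(seed)
        train = simulate_path(self.theta0, 300, _POIS, rng)
        if change is None:
            stream = simulate_path(self.theta0, 300, _POIS, rng)
        else:
            pre = simulate_path(self.theta0, 150, _POIS, rng)
            post = simulate_path(change, 150, _POIS, rng)
            stream = np.concatenate([pre, post])
        return train, stream

    def test_known_mode_quiet_under_null(self):
        alarms = 0
        for seed in range(10):
            train, stream = self._data(seed)
            res = monitor(
                stream, train, _POIS, mode="known", theta0=self.theta0,
                statistics=("min",), limit_source="analytic",
            )
            alarms += res["min"].alarm_time is not None
        assert alarms <= 2

    def test_known_mode_detects_large_change(self):
        # doubled omega/a/b: the alarm fires, and not systematically early
        change = INGARCHParams(4.0, 0.4, 0.45)
        detected, early = 0, 0
        for seed in range(10):
            train, stream = self._data(seed, change=change)
            res = monitor(
                stream, train, _POIS, mode="known", theta0=self.theta0,
                statistics=("min",), limit_source="analytic",
            )
            t = res["min"].alarm_time
            detected += t is not None
            early += t is not None and t < 100
        assert detected >= 8
        assert early == 0

    def test_estimated_mode_runs(self):
        train, stream = self._data(123)
        res = monitor(stream, train, _POIS, mode="estimated", statistics=("min",))
        r = res["min"]
        assert r.limit > 0 and r.path.size == stream.size
        assert r.overall == pytest.approx(r.path.max())

    def test_mode_validation(self):
        train, stream = self._data(0)
        with pytest.raises(ValueError):
            monitor(stream, train, _POIS, mode="known")  # theta0 missing
        with pytest.raises(ValueError):
            monitor(stream, train, _POIS, mode="nope")


def test_bootstrap_limit_positive_and_monotone(pois):
    rng = np.random.default_rng(4)
    train = simulate_path(INGARCHParams(2.0, 0.2, 0.3), 200, pois, rng)
    f = fit(train, 0.0, pois)
    lim05 = bootstrap_limit(f, 150, 150, 0.0, "min", 0.05, 100, np.random.default_rng(1), pois)
    lim20 = bootstrap_limit(f, 150, 150, 0.0, "min", 0.20, 100, np.random.default_rng(1), pois)
    assert lim05 > 0
    assert lim05 >= lim20  # stricter level, larger limit
    with pytest.raises(ValueError):
        bootstrap_limit(f, 150, 150, 0.0, "min", 0.05, 50, rng, pois)
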