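import numpy as np
import pytest

from ingarch_monitor import INGARCHParams, contaminate, fit, khat, simulate_path
from ingarch_monitor.ingarch import filter_with_grad
from ingarch_monitor.mdpde import (
    ScorePath,
    dpd_loss_t,
    loss_score_path,
    objective,
    objective_grad,
    score_t,
)


def brute_dpd_loss(y, eta, alpha, fam, bound=200):
    """Independent oracle: direct truncated summation of pmf powers."""
    grid = np.arange(bound + 1)
    p = fam.pmf(grid, eta)
    return float((p ** (1 + alpha)).sum() - (1 + 1 / alpha) * fam.pmf(y, eta) ** alpha)


def test_loss_alpha0_is_negative_log_pmf(pois):
    # -log(2 e^{-2}) = 2 - log 2
    assert dpd_loss_t(2, np.log(2.0), 0.0, pois) == pytest.approx(2 - np.log(2), rel=1e-12)


@pytest.mark.parametrize("alpha,y,mean", [(0.5, 0, 1.0), (0.2, 3, 2.5), (1.0, 7, 4.0)])
def test_loss_matches_brute_force(alpha, y, mean, pois):
    eta = np.log(mean)
    assert dpd_loss_t(y, eta, alpha, pois) == pytest.approx(
        brute_dpd_loss(y, eta, alpha, pois), rel=1e-10
    )


def test_score_zero_at_fitted_mean(pois):
    s = score_t(4, 4.0, np.log(4.0), np.array([1.0, 2.0, 3.0]), 0.0, pois)
    assert s == pytest.approx([0, 0, 0], abs=1e-12)


@pytest.mark.parametrize("alpha", [0.0, 0.1, 0.3, 0.7])
def test_scores_match_finite_differences(alpha, pois):
    """Analytic score vectors equal numerical gradients of the objective."""
    rng = np.random.default_rng(3)
    y = simulate_path(INGARCHParams(2.0, 0.3, 0.3), 150, pois, rng)
    theta = INGARCHParams(1.7, 0.25, 0.35)
    x1 = 4.0
    _, g = objective_grad(y, theta, alpha, pois, x1)
    t = theta.as_array()
    for i in range(3):
        h = 1e-6 * max(abs(t[i]), 1.0)
        up, dn = t.copy(), t.copy()
        up[i] += h
        dn[i] -= h
        num = (
            objective(y, INGARCHParams.from_array(up), alpha, pois, x1)
            - objective(y, INGARCHParams.from_array(dn), alpha, pois, x1)
        ) / (2 * h)
        assert g[i] == pytest.approx(num, rel=1e-5)


def test_score_continuous_at_alpha_zero(pois):
    grad = np.array([1.0, 3.0, 2.0])
    s0 = score_t(5, 3.0, np.log(3.0), grad, 0.0, pois)
    s_eps = score_t(5, 3.0, np.log(3.0), grad, 1e-6, pois)
    assert s_eps == pytest.approx(s0, rel=1e-3)


def test_objective_is_mean_of_per_t_losses(pois):
    y = [3, 1]
    theta = INGARCHParams(1.0, 0.5, 0.5)
    st = filter_with_grad(y, theta, 2.0, pois)
    hand = (dpd_loss_t(3, st.etas[0], 0.3, pois) + dpd_loss_t(1, st.etas[1], 0.3, pois)) / 2
    assert objective(y, theta, 0.3, pois, 2.0) == pytest.approx(hand, rel=1e-12)


def test_khat_outer_product_and_psd():
    v = np.array([1.0, -2.0, 0.5])
    sp = ScorePath(alpha=0.0, losses=np.zeros(4), scores=np.tile(v, (4, 1)))
    assert khat(sp) == pytest.approx(np.outer(v, v))
    rng = np.random.default_rng(0)
    K = khat(rng.normal(size=(50, 3)))
    assert np.linalg.eigvalsh(K).min() >= -1e-10
    with pytest.raises(ValueError):
        khat(rng.normal(size=(2, 3)))


def test_fit_recovers_truth_within_3se(pois, h0_series):
    f = fit(h0_series, 0.0, pois)
    assert f.converged
    err = np.abs(f.theta_hat.as_array() - [2.0, 0.3, 0.3])
    assert np.all(err <= 3 * f.se())


def test_alpha0_fit_minimizes_nll(pois, h0_series):
    """The alpha=0 branch is exactly the negative log-likelihood."""
    f = fit(h0_series, 0.0, pois)
    state = filter_with_grad(h0_series, f.theta_hat, float(np.mean(h0_series)), pois)
    nll = -pois.log_pmf(h0_series, state.etas).mean()
    assert f.objective_value == pytest.approx(nll, rel=1e-10)
    # and it beats the truth on the evaluated objective
    truth = objective(h0_series, INGARCHParams(2.0, 0.3, 0.3), 0.0, pois, float(np.mean(h0_series)))
    assert f.objective_value <= truth + 1e-12


def test_information_identity_at_mle(pois, h0_series):
    """At alpha=0 the score covariance matches the Hessian (J = K) under H0."""
    f = fit(h0_series, 0.0, pois)
    rel = np.linalg.norm(f.khat - f.jhat) / np.linalg.norm(f.jhat)
    assert rel < 0.1


def test_scores_center_at_truth(pois, h0_series):
    theta0 = INGARCHParams(2.0, 0.3, 0.3)
    st = filter_with_grad(h0_series, theta0, float(np.mean(h0_series)), pois)
    path = loss_score_path(h0_series, st, 0.0, pois)
    mean = path.scores.mean(axis=0)
    se = path.scores.std(axis=0) / np.sqrt(path.scores.shape[0])
    assert np.all(np.abs(mean) < 3 * se + 1e-3)


def test_efficiency_loss_grows_with_alpha(pois, h0_series):
    """On clean data the sandwich variance is no smaller for larger alpha."""
    tr0 = np.trace(fit(h0_series, 0.0, pois).cov)
    tr3 = np.trace(fit(h0_series, 0.3, pois).cov)
    assert tr3 >= 0.9 * tr0  # allow small numerical slack


def test_robustness_to_outliers(pois):
    """MDPDE omega-bias under contamination is below the MLE's."""
    theta0 = INGARCHParams(2.0, 0.3, 0.3)
    err = {0.0: [], 0.2: []}
    for seed in range(40):
        rng = np.random.default_rng(1000 + seed)
        y = simulate_path(theta0, 500, pois, rng)
        y = contaminate(y, 0.1, 30.0, rng)
        for alpha in err:
            err[alpha].append(fit(y, alpha, pois).theta_hat.omega - 2.0)
    assert abs(np.mean(err[0.2])) < abs(np.mean(err[0.0]))


def test_fit_serialization_roundtrip(pois, h0_series, tmp_path):
    import json

    f = fit(h0_series, 0.1, pois)
    out = tmp_path / "fit.json"
    f.to_json(out)
    data = json.loads(out.read_text())
    assert data["alpha"] == 0.1
    assert data["n_obs"] == len(h0_series)
    assert data["theta_hat"] == pytest.approx(list(f.theta_hat.as_array()))
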