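import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from statedyn.model import (
    ModelConfig,
    SwitchingStateModel,
    dominant_state_sequence_from_gamma,
    estimate_shared_ar,
    forward_backward,
    whiten,
)
from conftest import make_ts, reduced_config
from statedyn.simulate import generate_cohort


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------

def enumerate_posteriors(log_obs, log_init, log_trans):
    """Exhaustive-path smoothing oracle: sum over all K^T state paths."""
    T, K = log_obs.shape
    joint = {}
    for path in itertools.product(range(K), repeat=T):
        lp = log_init[path[0]] + log_obs[0, path[0]]
        for t in range(1, T):
            lp += log_trans[path[t - 1], path[t]] + log_obs[t, path[t]]
        joint[path] = np.exp(lp)
    Z = sum(joint.values())
    gamma = np.zeros((T, K))
    xi = np.zeros((T - 1, K, K))
    for path, p in joint.items():
        for t, k in enumerate(path):
            gamma[t, k] += p
        for t in range(T - 1):
            xi[t, path[t], path[t + 1]] += p
    return gamma / Z, xi / Z


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_forward_backward_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    T, K = 3, 2
    log_obs = rng.normal(size=(T, K))
    log_init = np.log(rng.dirichlet(np.ones(K)))
    log_trans = np.log(rng.dirichlet(np.ones(K), size=K))
    gamma, xi, _ = forward_backward(log_obs, log_init, log_trans)
    g_ref, xi_ref = enumerate_posteriors(log_obs, log_init, log_trans)
    np.testing.assert_allclose(gamma, g_ref, atol=1e-10)
    np.testing.assert_allclose(xi, xi_ref, atol=1e-10)


def test_forward_backward_loglik_matches_enumeration():
    rng = np.random.default_rng(5)
    log_obs = rng.normal(size=(4, 3))
    log_init = np.log(rng.dirichlet(np.ones(3)))
    log_trans = np.log(rng.dirichlet(np.ones(3), size=3))
    _, _, ll = forward_backward(log_obs, log_init, log_trans)
    total = 0.0
    for path in itertools.product(range(3), repeat=4):
        lp = log_init[path[0]] + log_obs[0, path[0]]
        for t in range(1, 4):
            lp += log_trans[path[t - 1], path[t]] + log_obs[t, path[t]]
        total += np.exp(lp)
    assert np.isclose(ll, np.log(total), atol=1e-10)


def test_time_reversal_symmetry():
    # symmetric transitions + uniform initial weights: reversing the
    # observation sequence reverses the smoothed posteriors
    rng = np.random.default_rng(3)
    log_obs = rng.normal(size=(12, 3))
    S = rng.random((3, 3))
    S = S + S.T                     # symmetric joint weights -> reversible chain
    log_trans = np.log(S / S.sum(axis=1, keepdims=True))
    log_init = np.log(S.sum(axis=1) / S.sum())
    g_fwd, _, _ = forward_backward(log_obs, log_init, log_trans)
    g_rev, _, _ = forward_backward(log_obs[::-1], log_init, log_trans)
    np.testing.assert_allclose(g_rev[::-1], g_fwd, atol=1e-8)


def test_forward_backward_matches_hmmlearn():
    hmm = pytest.importorskip("hmmlearn.hmm")
    rng = np.random.default_rng(7)
    K, d, T = 3, 2, 60
    means = rng.normal(size=(K, d)) * 2
    startprob = rng.dirichlet(np.ones(K))
    transmat = rng.dirichlet(np.ones(K) * 3, size=K)
    X = rng.normal(size=(T, d))
    m = hmm.GaussianHMM(n_components=K, covariance_type="spherical",
                        init_params="")
    m.startprob_, m.transmat_ = startprob, transmat
    m.means_, m.covars_ = means, np.ones(K)
    _, ref = m.score_samples(X)
    log_obs = np.stack([multivariate_normal.logpdf(X, means[k], np.eye(d))
                        for k in range(K)], axis=1)
    gamma, _, _ = forward_backward(log_obs, np.log(startprob), np.log(transmat))
    np.testing.assert_allclose(gamma, ref, atol=1e-8)


# ----------------------------------------------------------------------
# fitting behaviour
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def reduced_fit():
    cohort = [ts for ts, _ in generate_cohort(reduced_config(n_control=0))]
    cfg = ModelConfig(k_max=5, n_restarts=2, ar_refinements=1, seed=1)
    return cohort, SwitchingStateModel(cohort, cfg).fit()


def test_single_state_iid_data_collapses_to_one_state(rng):
    mean = np.array([1.0, -2.0, 0.5])
    cov = np.array([[1.0, 0.3, 0.0], [0.3, 1.0, 0.2], [0.0, 0.2, 0.8]])
    y = rng.multivariate_normal(mean, cov, size=800)
    ts = make_ts(y)
    res = SwitchingStateModel([ts], ModelConfig(
        k_max=4, ar_order=0, n_restarts=2, seed=0)).fit()
    eff = res.effective_states()
    assert len(eff) == 1
    k = eff[0]
    np.testing.assert_allclose(res.state_means[k], y.mean(axis=0), atol=1e-6)
    assert np.linalg.norm(res.state_covs[k] - np.cov(y.T)) \
        / np.linalg.norm(np.cov(y.T)) < 0.05
    assert np.abs(res.state_means[k] - mean).max() < 0.05 * np.abs(mean).max() + 0.1


def test_elbo_trace_non_decreasing(reduced_fit):
    _, res = reduced_fit
    diffs = np.diff(res.elbo_trace)
    assert np.all(diffs >= -1e-8)
    assert res.elbo == res.elbo_trace[-1]


def test_posterior_invariants(reduced_fit):
    _, res = reduced_fit
    for p in res.posteriors:
        np.testing.assert_allclose(p.gamma.sum(axis=1), 1.0, atol=1e-10)
        if p.xi.shape[0]:
            np.testing.assert_allclose(p.xi.sum(axis=(1, 2)), 1.0, atol=1e-10)
            np.testing.assert_allclose(p.xi.sum(axis=2), p.gamma[:-1], atol=1e-8)
    np.testing.assert_allclose(res.transition_matrix.sum(axis=1), 1.0, atol=1e-10)


def test_infer_posteriors_matches_training_subjects(reduced_fit):
    cohort, res = reduced_fit
    p_new = res.infer_posteriors(cohort[0])
    np.testing.assert_allclose(p_new.gamma, res.posteriors[0].gamma, atol=1e-8)
    assert np.isfinite(p_new.log_evidence)


def test_infer_posteriors_input_validation(reduced_fit):
    cohort, res = reduced_fit
    bad = make_ts(np.zeros((10, 3)) + np.arange(10)[:, None])
    with pytest.raises(ValueError, match="ROI labels"):
        res.infer_posteriors(bad)


def test_state_recovery_on_model_family_data(rng):
    # well-separated 2-state HMM data from the model family itself
    T, d = 600, 3
    means = np.array([[2.0, 0.0, -2.0], [-2.0, 1.0, 2.0]])
    z = np.zeros(T, dtype=int)
    for t in range(1, T):
        z[t] = z[t - 1] if rng.random() < 0.97 else 1 - z[t - 1]
    y = means[z] + rng.standard_normal((T, d))
    res = SwitchingStateModel([make_ts(y)], ModelConfig(
        k_max=4, ar_order=0, n_restarts=2, seed=0)).fit()
    assert res.effective_state_count() == 2
    eff = res.effective_states()
    err = min(np.abs(res.state_means[list(perm)] - means).max()
              for perm in itertools.permutations(eff, 2))
    assert err < 0.3


class TestDominantSequence:
    def test_argmax(self):
        g = np.array([[0.2, 0.7, 0.1], [0.9, 0.05, 0.05]])
        np.testing.assert_array_equal(dominant_state_sequence_from_gamma(g), [1, 0])

    def test_tie_breaks_toward_lower_index(self):
        g = np.array([[0.5, 0.5], [0.3, 0.7]])
        np.testing.assert_array_equal(dominant_state_sequence_from_gamma(g), [0, 1])

    def test_uniform_gamma_constant_lowest_state(self):
        g = np.full((5, 4), 0.25)
        np.testing.assert_array_equal(dominant_state_sequence_from_gamma(g),
                                      np.zeros(5, dtype=int))


class TestStateConnectivity:
    def test_diagonal_gives_identity(self, reduced_fit):
        _, res = reduced_fit
        res2 = res
        res2.state_covs = res.state_covs.copy()
        res2.state_covs[0] = np.diag([1.0, 2.0, 3.0, 4.0, 0.5])
        np.testing.assert_allclose(res2.state_connectivity(0), np.eye(5), atol=1e-12)

    def test_two_by_two_closed_form(self, reduced_fit):
        _, res = reduced_fit
        res.state_covs[1][:2, :2] = [[1.0, 0.5], [0.5, 1.0]]
        corr = res.state_connectivity(1)
        assert np.isclose(corr[0, 1], 0.5 / np.sqrt(res.state_covs[1][1, 1]
                                                    * res.state_covs[1][0, 0]))

    def test_zero_variance_rejected(self, reduced_fit):
        _, res = reduced_fit
        res.state_covs[2][0, :] = 0
        res.state_covs[2][:, 0] = 0
        with pytest.raises(ValueError, match="zero variance"):
            res.state_connectivity(2)


def test_degenerate_prune_threshold(reduced_fit):
    _, res = reduced_fit
    assert res.effective_state_count(prune_threshold=1.0) == 0


def test_whitening_round_trip_properties(rng):
    y = rng.standard_normal((50, 2)).cumsum(axis=0)
    coef = np.array([[0.5, 0.2], [0.9, -0.1]])
    e = whiten(y, coef)
    t = 10
    np.testing.assert_allclose(
        e[t], y[t] - coef[:, 0] * y[t - 1] - coef[:, 1] * y[t - 2], atol=1e-12)
    # order 0: identity
    np.testing.assert_array_equal(whiten(y, np.zeros((2, 0))), y)


def test_estimate_shared_ar_recovers_ar1(rng):
    a = 0.7
    x = np.zeros((4000, 1))
    for t in range(1, 4000):
        x[t] = a * x[t - 1] + rng.standard_normal()
    coef = estimate_shared_ar([make_ts(np.hstack([x, x]))], order=1)
    assert np.abs(coef - a).max() < 0.05


def test_summary_table(reduced_fit):
    _, res = reduced_fit
    tab = res.summary()
    assert set(tab.columns) >= {"weight", "effective", "mean_norm",
                                "self_transition"}
    assert len(tab) == res.config.k_max
    np.testing.assert_allclose(tab["weight"].sum(), 1.0, atol=1e-8)


def test_model_input_validation():
    with pytest.raises(ValueError, match="empty"):
        SwitchingStateModel([])
    a = make_ts(np.random.default_rng(0).standard_normal((20, 2)))
    b = make_ts(np.random.default_rng(1).standard_normal((20, 2)),
                labels=("x", "y"), subject_id="s2")
    with pytest.raises(ValueError, match="ROI labels"):
        SwitchingStateModel([a, b])
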