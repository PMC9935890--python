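"""Variational-Bayes switching-state model of multi-ROI time series.

Each subject's run is a hidden Markov chain over ``k_max`` latent brain
states.  The observed signal combines slow shared temporal dynamics (hemodynamic
filtering, within-state fluctuation) with state-specific structure; the
model separates the two by passing each channel through a shared
autoregressive prewhitening filter of order ``ar_order`` estimated once
from the pooled data,

    e_t = y_t - sum_l  a_l * y_{t-l},      e_t | z_t = k  ~  N( c_k, Q_k ),

so the switching chain is inferred from near-white innovations in which
every state keeps its own innovation level ``c_k`` and innovation
covariance ``Q_k``.  Sharing the temporal dynamics across states is what
makes the switching process identifiable: were each state free to carry
its own unconstrained dynamics, a single near-unit-root state could
explain any smooth series and the state structure would collapse;
conversely, ignoring the dynamics entirely makes consecutive correlated
samples masquerade as extra states.  With ``ar_order=0`` no whitening is
applied and the model reduces exactly to a Gaussian-mixture hidden Markov
model.

State summaries on the signal scale (activation means, state covariance /
functional connectivity, per-state lag-1 propagation) are posterior-
weighted moments of the original series, so they are directly comparable
with condition-averaged data.

Inference is conjugate coordinate-ascent variational Bayes: Dirichlet
posteriors on the initial distribution and transition rows, Normal-Wishart
posteriors on the per-state innovation mean and precision, and exact
forward-backward smoothing of the switching chain under expected
log-parameters.  Small Dirichlet concentrations act as automatic relevance
determination: states that explain no data lose expected prior mass and
drop out of the effective state set, so the number of states is learned
rather than fixed.  Fitting is at the group level on subject-concatenated
data with chain resets at subject boundaries; per-subject posteriors come
from the shared parameter posterior.  The evidence lower bound is
non-decreasing across iterations up to floating-point error.

The public surface follows the Model/Results convention: build a
:class:`SwitchingStateModel` from a cohort, call
:meth:`~SwitchingStateModel.fit`, and read estimates off the returned
:class:`SwitchingStateResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln
from sklearn.cluster import KMeans

from .io import RoiTimeSeries

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ModelConfig:
    """Hyperparameters of the switching-state model.

    ``k_max`` is the initial (maximal) state count; automatic relevance
    determination prunes unused states (threshold: expected weight below
    ``prune_threshold``, default 1/(10 k_max)).  Dirichlet concentrations
    below 1 drive the pruning.  ``ar_order`` is the order of the shared
    per-channel autoregressive prewhitening filter (0: plain
    Gaussian-mixture HMM on the raw samples).  The
    Normal-Wishart scales are weakly informative for z-scored data (prior
    mean 0, prior noise precision ~ identity).  ``latent_dim`` records the
    dimension of the dynamical state (defaults to the ROI count).
    """

    k_max: int = 10
    ar_order: int = 2
    latent_dim: int = None
    init_concentration: float = None       # default 1/k_max
    trans_concentration: float = None      # default 1/k_max
    mean_scale: float = 1.0                # beta0 of the Normal-Wishart
    wishart_dof_extra: float = 2.0         # nu0 = d + extra
    max_iterations: int = 200
    elbo_tolerance: float = 1e-6
    n_restarts: int = 5
    ar_refinements: int = 2
    prune_threshold: float = None
    ridge: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.elbo_tolerance <= 0:
            raise ValueError("elbo_tolerance must be > 0")
        if self.ar_order < 0:
            raise ValueError("ar_order must be >= 0")
        if self.ar_refinements < 0:
            raise ValueError("ar_refinements must be >= 0")
        if self.init_concentration is None:
            self.init_concentration = 1.0 / self.k_max
        if self.trans_concentration is None:
            self.trans_concentration = 1.0 / self.k_max
        if self.prune_threshold is None:
            self.prune_threshold = 1.0 / (10.0 * self.k_max)


@dataclass(frozen=True)
class StatePosterior:
    """Smoothed state posteriors for one subject.

    ``gamma[t, k]``: posterior probability of state ``k`` at sample ``t``
    given the whole run; ``xi[t]``: pairwise posterior over
    ``(z_t, z_{t+1})`` (each slab sums to 1, and marginalising over the
    second state recovers ``gamma[t]``); ``dominant[t]``: argmax state,
    ties broken toward the lower index.
    """

    subject_id: str
    gamma: np.ndarray
    xi: np.ndarray
    dominant: np.ndarray
    log_evidence: float


def forward_backward(log_obs: np.ndarray, log_init: np.ndarray, log_trans: np.ndarray):
    """Scaled forward-backward smoothing of one hidden Markov chain.

    Arguments are per-sample observation log-densities ``(T, K)``, initial
    log-weights ``(K,)`` and transition log-weights ``(K, K)`` (rows need
    not normalise: variational "tilde" parameters are sub-normalised).

    Returns ``(gamma, xi, loglik)``; ``xi`` has shape ``(T-1, K, K)``.
    """
    T, K = log_obs.shape
    shift = log_obs.max(axis=1)
    b = np.exp(log_obs - shift[:, None])
    pi = np.exp(log_init - log_init.max())
    A = np.exp(log_trans - log_trans.max())

    alpha = np.empty((T, K))
    c = np.empty(T)
    a0 = pi * b[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    if T > 1:
        xi = (alpha[:-1, :, None] * A[None, :, :]
              * (b[1:] * beta[1:])[:, None, :]) / c[1:, None, None]
        xi /= xi.sum(axis=(1, 2), keepdims=True)
    else:
        xi = np.zeros((0, K, K))

    loglik = float(np.sum(np.log(c)) + shift.sum()
                   + log_init.max() + (T - 1) * log_trans.max())
    return gamma, xi, loglik


def estimate_shared_ar(cohort, order: int = 2, ridge: float = 1e-8) -> np.ndarray:
    """Shared per-ROI AR(``order``) prewhitening coefficients.

    Per channel, least squares of ``y_t`` on its ``order`` lags pooled
    within subjects (no cross-subject pairs).  Returns a ``(d, order)``
    coefficient array; the whitener ``1 - sum_l a_l L^l`` is finite
    impulse response, hence always stable.
    """
    return _ar_from_arrays([ts.data for ts in cohort], order, ridge)


def _ar_from_arrays(arrays, order: int, ridge: float = 1e-8) -> np.ndarray:
    d = arrays[0].shape[1]
    if order == 0:
        return np.zeros((d, 0))
    coef = np.zeros((d, order))
    for j in range(d):
        xtx = np.zeros((order, order))
        xty = np.zeros(order)
        for y2 in arrays:
            y = y2[:, j]
            if y.size <= order:
                continue
            X = np.column_stack([y[order - l:-l] for l in range(1, order + 1)])
            xtx += X.T @ X
            xty += X.T @ y[order:]
        coef[j] = np.linalg.solve(xtx + ridge * np.eye(order), xty)
    return coef


def whiten(data: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """Per-channel innovations under the shared AR prewhitening filter.

    ``e_t = y_t - sum_l a_l y_{t-l}``; the first ``order`` samples (with
    incomplete lag context) are scaled by the filter's DC gain so their
    expectation matches the innovation level of their state.
    """
    order = coef.shape[1]
    if order == 0:
        return data.copy()
    out = data.copy()
    for l in range(1, order + 1):
        out[l:] -= coef[:, l - 1][None, :] * data[:-l]
    dc = 1.0 - coef.sum(axis=1)
    out[:order] = dc[None, :] * data[:order]
    return out


def _weighted_moments(cohort, gammas):
    """Posterior-weighted per-state mean and covariance of the raw signal."""
    K = gammas[0].shape[1]
    d = cohort[0].data.shape[1]
    mass = np.zeros(K)
    mean = np.zeros((K, d))
    for ts, g in zip(cohort, gammas):
        mass += g.sum(axis=0)
        mean += g.T @ ts.data
    safe = np.maximum(mass, 1e-12)
    mean /= safe[:, None]
    cov = np.zeros((K, d, d))
    for ts, g in zip(cohort, gammas):
        for k in range(K):
            r = ts.data - mean[k]
            cov[k] += (g[:, k][:, None] * r).T @ r
    cov /= safe[:, None, None]
    # pruned states carry no data: report neutral summaries
    empty = mass < 1e-3
    mean[empty] = 0.0
    cov[empty] = np.eye(d)
    return mass, mean, cov


def _weighted_lag1_dynamics(cohort, gammas, means, covs, ridge=1e-6):
    """Per-state lag-1 propagation and innovation covariance by
    posterior-weighted least squares on within-state fluctuations."""
    K, d = means.shape
    A = np.zeros((K, d, d))
    Q = np.zeros((K, d, d))
    for k in range(K):
        num = np.zeros((d, d))
        den = np.zeros((d, d))
        for ts, g in zip(cohort, gammas):
            r = ts.data - means[k]
            w = g[1:, k] * g[:-1, k]
            num += (w[:, None] * r[1:]).T @ r[:-1]
            den += (w[:, None] * r[:-1]).T @ r[:-1]
        den += (ridge * max(np.trace(den), 1.0) / d + 1e-12) * np.eye(d)
        A[k] = num @ np.linalg.inv(den)
        q = covs[k] - A[k] @ covs[k] @ A[k].T
        Q[k] = 0.5 * (q + q.T)
    return A, Q


def _dirichlet_kl(a_q, a_p) -> float:
    a_q = np.asarray(a_q, float)
    a_p = np.asarray(a_p, float)
    s_q, s_p = a_q.sum(), a_p.sum()
    return float(
        gammaln(s_q) - gammaln(s_p)
        - np.sum(gammaln(a_q) - gammaln(a_p))
        + np.sum((a_q - a_p) * (digamma(a_q) - digamma(s_q)))
    )


def _log_wishart_B(W: np.ndarray, nu: float) -> float:
    d = W.shape[0]
    _, logdet = np.linalg.slogdet(W)
    return float(
        -0.5 * nu * logdet
        - 0.5 * nu * d * np.log(2.0)
        - 0.25 * d * (d - 1) * np.log(np.pi)
        - np.sum(gammaln(0.5 * (nu - np.arange(d))))
    )


class _VBPosterior:
    """Variational block q(pi) q(Pi) q(mu_k, Lambda_k) of the innovation HMM."""

    def __init__(self, K: int, d: int, cfg: ModelConfig, prior_var=None):
        self.K, self.d = K, d
        self.a_init0 = np.full(K, cfg.init_concentration)
        self.a_trans0 = np.full((K, K), cfg.trans_concentration)
        self.beta0 = cfg.mean_scale
        self.m0 = np.zeros(d)
        self.nu0 = d + cfg.wishart_dof_extra
        # unit-scale precision prior: deliberately conservative for
        # innovation-scale data, so each retained state carries a real
        # complexity cost and residual autocorrelation cannot fragment
        # states (a data-scaled prior removes that cost and over-segments)
        if prior_var is None:
            prior_var = np.ones(d)
        self.W0 = np.diag(1.0 / prior_var) / self.nu0
        self.W0_inv = np.linalg.inv(self.W0)

        self.a_init = self.a_init0.copy()
        self.a_trans = self.a_trans0.copy()
        self.beta = np.full(K, self.beta0)
        self.m = np.zeros((K, d))
        self.nu = np.full(K, self.nu0)
        self.W = np.array([self.W0] * K)

    # ----- expected log parameters ---------------------------------------
    def log_init_tilde(self):
        return digamma(self.a_init) - digamma(self.a_init.sum())

    def log_trans_tilde(self):
        return digamma(self.a_trans) - digamma(self.a_trans.sum(axis=1))[:, None]

    def expected_logdet_precision(self):
        out = np.empty(self.K)
        for k in range(self.K):
            _, logdet = np.linalg.slogdet(self.W[k])
            out[k] = np.sum(digamma(0.5 * (self.nu[k] - np.arange(self.d)))) \
                + self.d * np.log(2.0) + logdet
        return out

    def expected_log_obs(self, e: np.ndarray) -> np.ndarray:
        """E_q[log N(e_t | mu_k, Lambda_k^-1)] per sample and state."""
        eld = self.expected_logdet_precision()
        out = np.empty((e.shape[0], self.K))
        for k in range(self.K):
            diff = e - self.m[k]
            quad = self.nu[k] * np.einsum("ti,ij,tj->t", diff, self.W[k], diff)
            out[:, k] = 0.5 * (eld[k] - self.d * LOG2PI) \
                - 0.5 * (quad + self.d / self.beta[k])
        return out

    # ----- sufficient statistics and conjugate update ---------------------
    def stats(self, whitened, gammas, xis):
        K, d = self.K, self.d
        Nk = np.zeros(K)
        ysum = np.zeros((K, d))
        init_counts = np.zeros(K)
        trans_counts = np.zeros((K, K))
        for e, g, xi in zip(whitened, gammas, xis):
            Nk += g.sum(axis=0)
            ysum += g.T @ e
            init_counts += g[0]
            if xi.shape[0]:
                trans_counts += xi.sum(axis=0)
        safe = np.maximum(Nk, 1e-12)
        ybar = ysum / safe[:, None]
        Sk = np.zeros((K, d, d))
        for e, g in zip(whitened, gammas):
            for k in range(K):
                diff = e - ybar[k]
                Sk[k] += (g[:, k][:, None] * diff).T @ diff
        Sk /= safe[:, None, None]
        return Nk, ybar, Sk, init_counts, trans_counts

    def update(self, stats, ridge: float):
        Nk, ybar, Sk, init_counts, trans_counts = stats
        self.a_init = self.a_init0 + init_counts
        self.a_trans = self.a_trans0 + trans_counts
        self.beta = self.beta0 + Nk
        self.nu = self.nu0 + Nk
        self.m = (self.beta0 * self.m0[None, :] + Nk[:, None] * ybar) \
            / self.beta[:, None]
        for k in range(self.K):
            diff = ybar[k] - self.m0
            W_inv = (self.W0_inv + Nk[k] * Sk[k]
                     + (self.beta0 * Nk[k] / self.beta[k]) * np.outer(diff, diff))
            W_inv = 0.5 * (W_inv + W_inv.T)
            try:
                self.W[k] = np.linalg.inv(W_inv)
                if np.linalg.eigvalsh(W_inv).min() <= 0:
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                logger.warning("singular precision update for state %d; "
                               "ridge-regularizing", k)
                W_inv = W_inv + ridge * abs(np.trace(W_inv)) / self.d \
                    * np.eye(self.d) + 1e-10 * np.eye(self.d)
                self.W[k] = np.linalg.inv(W_inv)

    # ----- KL(q(parameters) || prior) -------------------------------------
    def kl_to_prior(self) -> float:
        kl = _dirichlet_kl(self.a_init, self.a_init0)
        for i in range(self.K):
            kl += _dirichlet_kl(self.a_trans[i], self.a_trans0[i])
        eld = self.expected_logdet_precision()
        d = self.d
        for k in range(self.K):
            diff = self.m[k] - self.m0
            e_quad = self.beta0 * (d / self.beta[k]
                                   + self.nu[k] * diff @ self.W[k] @ diff)
            kl_mu = 0.5 * (d * np.log(self.beta[k] / self.beta0) - d + e_quad)
            kl_lam = (_log_wishart_B(self.W[k], self.nu[k])
                      - _log_wishart_B(self.W0, self.nu0)
                      + 0.5 * (self.nu[k] - self.nu0) * eld[k]
                      + 0.5 * (self.nu[k] * np.trace(self.W0_inv @ self.W[k])
                               - self.nu[k] * d))
            kl += kl_mu + kl_lam
        return float(kl)

    # ----- point summaries (innovation scale) ------------------------------
    def innovation_means(self):
        return self.m.copy()

    def innovation_covariances(self):
        covs = np.empty_like(self.W)
        for k in range(self.K):
            denom = max(self.nu[k] - self.d - 1.0, 1e-6)
            c = np.linalg.inv(self.W[k]) / denom
            covs[k] = 0.5 * (c + c.T)
        return covs

    def transition_matrix(self):
        return self.a_trans / self.a_trans.sum(axis=1, keepdims=True)

    def initial_distribution(self):
        return self.a_init / self.a_init.sum()


def _init_responsibilities(data: np.ndarray, K: int, rng) -> np.ndarray:
    n = data.shape[0]
    if n >= K:
        km = KMeans(n_clusters=K, n_init=1,
                    random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(data)
    else:
        labels = rng.integers(K, size=n)
    resp = np.full((n, K), 0.1 / K)
    resp[np.arange(n), labels] += 0.9
    resp /= resp.sum(axis=1, keepdims=True)
    return resp


class SwitchingStateModel:
    """Group-level switching-state model of a cohort of ROI time series.

    Parameters
    ----------
    cohort : sequence of RoiTimeSeries
        Normalised subject runs sharing ROI labels and repetition time.
    config : ModelConfig, optional
    **config_kwargs
        Overrides forwarded to :class:`ModelConfig`.
    """

    def __init__(self, cohort, config: ModelConfig = None, **config_kwargs):
        cohort = list(cohort)
        if not cohort:
            raise ValueError("empty cohort")
        labels = cohort[0].roi_labels
        tr = cohort[0].tr
        for ts in cohort:
            if ts.roi_labels != labels:
                raise ValueError(f"subject {ts.subject_id}: ROI labels differ")
            if ts.tr != tr:
                raise ValueError(f"subject {ts.subject_id}: repetition time differs")
        self.cohort = cohort
        self.roi_labels = labels
        self.tr = tr
        self.config = config or ModelConfig(**config_kwargs)
        if self.config.latent_dim is None:
            self.config.latent_dim = len(labels)
        self.shared_ar = estimate_shared_ar(cohort, self.config.ar_order)
        self._whitened = [whiten(ts.data, self.shared_ar) for ts in cohort]

    @classmethod
    def from_cohort(cls, cohort, **kwargs):
        return cls(cohort, **kwargs)

    # ------------------------------------------------------------------
    def _e_step(self, post: _VBPosterior):
        log_pi = post.log_init_tilde()
        log_A = post.log_trans_tilde()
        gammas, xis = [], []
        bound_data = 0.0
        for e in self._whitened:
            log_b = post.expected_log_obs(e)
            g, x, ll = forward_backward(log_b, log_pi, log_A)
            gammas.append(g)
            xis.append(x)
            bound_data += ll
        return gammas, xis, bound_data

    def _fit_once(self, rng):
        cfg = self.config
        K = cfg.k_max
        post = _VBPosterior(K, self._whitened[0].shape[1], cfg)

        # cluster the *original* series (where state separation lives) to
        # seed responsibilities, then iterate VB on the innovations
        pooled = np.vstack([ts.data for ts in self.cohort])
        resp = _init_responsibilities(pooled, K, rng)
        splits = np.cumsum([ts.n_timepoints for ts in self.cohort])[:-1]
        gammas = np.split(resp, splits)
        xis = []
        for g in gammas:                     # sticky initial bigram posteriors
            x = g[:-1, :, None] * g[1:, None, :]
            x = x + 5.0 * np.einsum("tk,tl->tkl", g[:-1], g[:-1]) * np.eye(K)
            x /= x.sum(axis=(1, 2), keepdims=True)
            xis.append(x)
        post.update(post.stats(self._whitened, gammas, xis), cfg.ridge)

        trace = []
        converged = False
        for _ in range(cfg.max_iterations):
            gammas, xis, bound_data = self._e_step(post)
            elbo = bound_data - post.kl_to_prior()
            trace.append(elbo)
            if len(trace) > 1:
                rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-12)
                if rel < cfg.elbo_tolerance:
                    converged = True
                    break
            post.update(post.stats(self._whitened, gammas, xis), cfg.ridge)
        return post, gammas, xis, np.array(trace), converged

    def _fit_restarts(self):
        cfg = self.config
        master = np.random.default_rng(cfg.seed)
        best = None
        for _ in range(cfg.n_restarts):
            rng = np.random.default_rng(master.integers(2**31 - 1))
            candidate = self._fit_once(rng)
            if best is None or candidate[3][-1] > best[3][-1]:
                best = candidate
        return best

    def fit(self) -> "SwitchingStateResults":
        """Variational EM with restarts and prewhitening refinement.

        After the best-of-restarts fit, the shared AR coefficients are
        re-estimated on state-mean-removed residuals (the initial pooled
        estimate over-whitens because sustained state structure inflates
        apparent persistence) and the model is refitted;
        ``config.ar_refinements`` controls the number of passes.  The
        reported ELBO trace belongs to the final pass and is
        non-decreasing within it.
        """
        cfg = self.config
        best = self._fit_restarts()
        for _ in range(cfg.ar_refinements if cfg.ar_order > 0 else 0):
            post, gammas, xis, trace, converged = best
            _, means, _ = _weighted_moments(self.cohort, gammas)
            resid = [ts.data - g @ means for ts, g in zip(self.cohort, gammas)]
            self.shared_ar = _ar_from_arrays(resid, cfg.ar_order)
            self._whitened = [whiten(ts.data, self.shared_ar)
                              for ts in self.cohort]
            best = self._fit_restarts()
        post, gammas, xis, trace, converged = best
        if not converged:
            logger.warning("variational EM did not converge within %d iterations",
                           cfg.max_iterations)
        return SwitchingStateResults(self, post, gammas, xis, trace, converged)


class SwitchingStateResults:
    """Fitted switching-state model: estimates, posteriors and diagnostics.

    Attributes
    ----------
    state_means : (K, d) array
        Stationary activation level of each state per ROI (z-units).
    state_covs : (K, d, d) array
        Stationary observation covariance per state.
    dynamics_matrices : (K, d, d) array
        Lag-1 propagation matrix per state (the shared diagonal operator).
    innovation_covs : (K, d, d) array
        Innovation (driving-noise) covariance per state.
    transition_matrix : (K, K) array
        Posterior-mean switching probabilities (rows sum to 1).
    state_weights : (K,) array
        Expected fraction of samples each state explains (ARD mass).
    elbo_trace : array
        Evidence lower bound per iteration (non-decreasing).
    posteriors : list of StatePosterior
        Smoothed posteriors of the training subjects.
    """

    def __init__(self, model, post, gammas, xis, trace, converged):
        self.model = model
        self._post = post
        self.config = model.config
        self.roi_labels = model.roi_labels
        self.shared_ar = model.shared_ar
        self.converged = bool(converged)
        self.elbo_trace = trace
        self.elbo = float(trace[-1])

        K = self.config.k_max
        Nk, self.state_means, self.state_covs = _weighted_moments(
            model.cohort, gammas)
        self.dynamics_matrices, self.innovation_covs = _weighted_lag1_dynamics(
            model.cohort, gammas, self.state_means, self.state_covs,
            self.config.ridge)
        self.transition_matrix = post.transition_matrix()
        self.initial_distribution = post.initial_distribution()
        self.state_weights = Nk / Nk.sum()
        self.posteriors = [
            StatePosterior(
                subject_id=ts.subject_id,
                gamma=g,
                xi=x,
                dominant=dominant_state_sequence_from_gamma(g),
                log_evidence=float("nan"),
            )
            for ts, g, x in zip(model.cohort, gammas, xis)
        ]

    # ------------------------------------------------------------------
    def infer_posteriors(self, subject: RoiTimeSeries) -> StatePosterior:
        """Smoothed state posteriors for a (possibly new) subject."""
        if subject.roi_labels != self.roi_labels:
            raise ValueError(f"subject {subject.subject_id}: ROI labels differ "
                             "from the fitted model")
        if subject.n_timepoints == 0:
            raise ValueError("length-0 series")
        e = whiten(subject.data, self.shared_ar)
        log_b = self._post.expected_log_obs(e)
        g, x, ll = forward_backward(
            log_b, self._post.log_init_tilde(), self._post.log_trans_tilde())
        return StatePosterior(subject.subject_id, g, x,
                              dominant_state_sequence_from_gamma(g), ll)

    def effective_states(self, prune_threshold: float = None) -> list:
        """States with ARD weight above the threshold that are dominant for
        at least one sample in at least one training subject."""
        thr = self.config.prune_threshold if prune_threshold is None \
            else prune_threshold
        dominant_any = set()
        for p in self.posteriors:
            dominant_any.update(np.unique(p.dominant).tolist())
        return [k for k in range(self.config.k_max)
                if self.state_weights[k] > thr and k in dominant_any]

    def effective_state_count(self, prune_threshold: float = None) -> int:
        return len(self.effective_states(prune_threshold))

    def state_connectivity(self, state: int) -> np.ndarray:
        """State covariance rescaled to a correlation matrix (unit diagonal)."""
        cov = self.state_covs[state]
        sd = np.sqrt(np.diag(cov))
        if np.any(sd == 0):
            raise ValueError(f"state {state}: zero variance on some ROI")
        corr = cov / np.outer(sd, sd)
        np.fill_diagonal(corr, 1.0)
        return np.clip(corr, -1.0, 1.0)

    def summary(self) -> pd.DataFrame:
        """Per-state summary: ARD weight, effective flag, activation norm,
        self-transition probability."""
        eff = set(self.effective_states())
        rows = [{
            "state": k,
            "weight": self.state_weights[k],
            "effective": k in eff,
            "mean_norm": float(np.linalg.norm(self.state_means[k])),
            "self_transition": float(self.transition_matrix[k, k]),
        } for k in range(self.config.k_max)]
        return pd.DataFrame(rows).set_index("state")

    def plot_posteriors(self, subject_index: int = 0, ax=None):
        """Posterior time courses of the effective states for one subject."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        p = self.posteriors[subject_index]
        for k in self.effective_states():
            ax.plot(p.gamma[:, k], label=f"state {k}", lw=0.8)
        ax.set_xlabel("time (samples)")
        ax.set_ylabel("posterior probability")
        ax.legend(loc="upper right", fontsize=8)
        return ax


# ----------------------------------------------------------------------
# functional conveniences mirroring the Results methods
# ----------------------------------------------------------------------

def fit(cohort, config: ModelConfig = None, **kwargs) -> SwitchingStateResults:
    """Fit the group switching-state model to a cohort."""
    return SwitchingStateModel(cohort, config, **kwargs).fit()


def infer_posteriors(results: SwitchingStateResults, subject: RoiTimeSeries):
    return results.infer_posteriors(subject)


def dominant_state_sequence_from_gamma(gamma: np.ndarray) -> np.ndarray:
    """Argmax state per sample; ties break toward the lower index (logged)."""
    gamma = np.asarray(gamma)
    dom = gamma.argmax(axis=1)
    is_tie = (gamma == gamma.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if np.any(is_tie):
        logger.info("dominant-state ties at %d sample(s); broken toward the "
                    "lower state index", int(is_tie.sum()))
    return dom


def dominant_state_sequence(posterior: StatePosterior) -> np.ndarray:
    return dominant_state_sequence_from_gamma(posterior.gamma)


def state_connectivity(results: SwitchingStateResults, state: int) -> np.ndarray:
    return results.state_connectivity(state)


def effective_state_count(results: SwitchingStateResults,
                          prune_threshold: float = None) -> int:
    return results.effective_state_count(prune_threshold)
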