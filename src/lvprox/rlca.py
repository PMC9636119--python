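"""Restricted latent class analysis (cognitive diagnosis) back-end.

Each person carries a binary attribute profile alpha in {0,1}^K with
categorical prior P(alpha) = softmax(nu)_alpha (the all-zero profile's nu is
pinned to 0), and answers item j correctly with probability
logistic(theta_{j,alpha}).  A binary Q-matrix declares which skills each item
requires; the induced feasible set demands that all profiles mastering an
item's skills share one (maximal) success logit, with every other profile's
logit between that value and the no-skill profile's.

The posterior over profiles is an explicit categorical distribution, so the
stochastic step samples it exactly; the proximal step projects each item's
logits onto its monotone constraint polyhedron.

Profiles are indexed by their bit pattern with attribute 1 as the low-order
bit (profile 0 is the all-zero profile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, softmax

from .optimizer import RunConfig, run
from .prox import ConstraintPenaltySpec, build_constraints, make_prox

__all__ = [
    "RlcaParams",
    "profile_posterior",
    "sample_xi_exact",
    "grad_and_diag_hess_rlca",
    "dina_theta",
    "marginal_loglik",
    "RestrictedLCA",
    "RlcaResults",
]


@dataclass
class RlcaParams:
    """theta (J, 2^K) item success logits per profile; nu (2^K,) profile
    logits with nu[0] = 0."""

    theta: np.ndarray
    nu: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if self.nu[0] != 0.0:
            raise ValueError("nu[0] (all-zero profile) must be pinned to 0")
        if self.theta.shape[1] != self.nu.shape[0]:
            raise ValueError("theta and nu disagree on the number of profiles")

    @property
    def J(self):
        return self.theta.shape[0]

    @property
    def n_profiles(self):
        return self.nu.shape[0]

    @property
    def class_probs(self):
        return softmax(self.nu)

    def copy(self):
        return RlcaParams(self.theta.copy(), self.nu.copy())


def dina_theta(s, g, Q):
    """DINA logits: log((1-s)/s) for capable profiles, log(g/(1-g)) otherwise.

    Feasible for the Q-induced monotone constraints whenever s_j + g_j < 1.
    """
    s = np.asarray(s, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any((s <= 0) | (s >= 1) | (g <= 0) | (g >= 1)):
        raise ValueError("slipping and guessing probabilities must lie in (0,1)")
    cons = build_constraints(Q)
    theta = np.where(cons.capable,
                     np.log((1.0 - s) / s)[:, None],
                     np.log(g / (1.0 - g))[:, None])
    return theta


def _profile_loglik(Y, params):
    """(N, 2^K) matrix of log P(y_i | alpha) + log P(alpha)."""
    theta = params.theta
    l1p = np.logaddexp(0.0, theta)                    # log(1 + e^theta)
    ll = Y @ theta - l1p.sum(axis=0)[None, :]         # (N, 2^K)
    logprior = params.nu - np.logaddexp.reduce(params.nu)
    return ll + logprior[None, :]


def profile_posterior(y_i, params):
    """Exact normalized posterior over attribute profiles for one person."""
    L = _profile_loglik(np.asarray(y_i, dtype=float)[None, :], params)[0]
    L -= L.max()
    w = np.exp(L)
    return w / w.sum()


def posterior_matrix(Y, params):
    """Posterior over profiles for every person, (N, 2^K)."""
    L = _profile_loglik(np.asarray(Y, dtype=float), params)
    L -= L.max(axis=1, keepdims=True)
    W = np.exp(L)
    W /= W.sum(axis=1, keepdims=True)
    return W


def sample_xi_exact(Y, params, rng):
    """Independent exact categorical draws of each person's profile index."""
    W = posterior_matrix(Y, params)
    cum = np.cumsum(W, axis=1)
    u = rng.random(W.shape[0])
    return np.argmax(u[:, None] < cum, axis=1)


def marginal_loglik(Y, params):
    """Marginal log-likelihood by direct summation over the 2^K profiles."""
    L = _profile_loglik(np.asarray(Y, dtype=float), params)
    m = L.max(axis=1, keepdims=True)
    return float(np.sum(m.ravel() + np.log(np.sum(np.exp(L - m), axis=1))))


# ---------------------------------------------------------------------------
# flat parameter layout: [theta row-major (j, alpha)] + [nu[1:]]
# ---------------------------------------------------------------------------

class RlcaLayout:
    def __init__(self, J, K):
        self.J, self.K = J, K
        self.C = 2 ** K
        self.n_theta = J * self.C
        self.n_params = self.n_theta + self.C - 1
        self.theta_slice = slice(0, self.n_theta)
        self.nu_slice = slice(self.n_theta, self.n_params)
        self.block_map = {"theta": self.theta_slice, "nu": self.nu_slice}

    def pack(self, params):
        return np.concatenate([params.theta.ravel(), params.nu[1:]])

    def unpack(self, beta):
        theta = np.array(beta[self.theta_slice]).reshape(self.J, self.C)
        nu = np.concatenate([[0.0], beta[self.nu_slice]])
        return RlcaParams(theta, nu)

    def param_names(self):
        names = [f"theta[{j},{a:0{self.K}b}]" for j in range(self.J)
                 for a in range(self.C)]
        names += [f"nu[{a:0{self.K}b}]" for a in range(1, self.C)]
        return names


def grad_and_diag_hess_rlca(z, params, Y, layout=None):
    """Gradient and diagonal Hessian of the complete-data negative
    log-likelihood given sampled profile indices ``z``.

    theta_{j,alpha}: sum_{i: z_i = alpha} (p_{j,alpha} - y_ij), Hessian
    n_alpha p (1-p); nu_alpha (alpha != 0): N pi_alpha - n_alpha, Hessian
    N pi (1 - pi).
    """
    Y = np.asarray(Y, dtype=float)
    N, J = Y.shape
    C = params.n_profiles
    if layout is None:
        layout = RlcaLayout(J, int(np.log2(C)))
    onehot = np.zeros((N, C))
    onehot[np.arange(N), z] = 1.0
    n_alpha = onehot.sum(axis=0)                     # (C,)
    S = Y.T @ onehot                                 # (J, C): sum of y in class
    P = expit(params.theta)
    g_theta = n_alpha[None, :] * P - S
    h_theta = n_alpha[None, :] * P * (1.0 - P)
    pi = params.class_probs
    g_nu = N * pi - n_alpha
    h_nu = N * pi * (1.0 - pi)
    grad = np.concatenate([g_theta.ravel(), g_nu[1:]])
    hess = np.concatenate([h_theta.ravel(), h_nu[1:]])
    return grad, hess


# ---------------------------------------------------------------------------
# engine back-end and model class
# ---------------------------------------------------------------------------

class RlcaBackend:
    def __init__(self, Y, Q):
        Y = np.asarray(Y)
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("Y must be binary")
        self.Y = Y.astype(np.float64)
        self.Q = np.asarray(Q, dtype=int)
        self.constraints = build_constraints(self.Q)
        J, K = self.Q.shape
        self.layout = RlcaLayout(J, K)
        self.n_params = self.layout.n_params
        self.block_map = self.layout.block_map
        C = self.layout.C
        items = [(np.arange(j * C, (j + 1) * C), self.constraints.capable[j])
                 for j in range(J)]
        self._spec = ConstraintPenaltySpec(kind="monotone",
                                           monotone_items=items)
        self._prox = make_prox(self._spec)

    def initial_latent(self, beta, rng):
        return sample_xi_exact(self.Y, self.layout.unpack(beta), rng)

    def sample_latent(self, latent, beta, rng):
        return sample_xi_exact(self.Y, self.layout.unpack(beta), rng)

    def grad_and_diag_hess(self, latent, beta):
        # engine works on the per-observation objective H/N
        params = self.layout.unpack(beta)
        g, h = grad_and_diag_hess_rlca(latent, params, self.Y, self.layout)
        N = self.Y.shape[0]
        return g / N, h / N

    def prox(self, beta_tilde, weights, gamma):
        return self._prox(beta_tilde, weights, gamma)

    def complete_data_objective(self, latent, beta):
        params = self.layout.unpack(beta)
        z = np.asarray(latent)
        N = self.Y.shape[0]
        theta_z = params.theta[:, z].T                # (N, J)
        bern = -np.sum(self.Y * theta_z - np.logaddexp(0.0, theta_z))
        logprior = params.nu - np.logaddexp.reduce(params.nu)
        return float(bern - logprior[z].sum()) / N

    def loglik_score_full(self, latent, beta):
        g, _ = self.grad_and_diag_hess(latent, beta)
        return -g

    def loglik_hessian_full(self, latent, beta):
        params = self.layout.unpack(beta)
        z = np.asarray(latent)
        N = self.Y.shape[0]
        C = params.n_profiles
        n_alpha = np.bincount(z, minlength=C).astype(float)
        P = expit(params.theta)
        h_theta = (n_alpha[None, :] * P * (1.0 - P)).ravel()
        p = self.n_params
        H = np.zeros((p, p))
        nt = self.layout.n_theta
        H[np.arange(nt), np.arange(nt)] = -h_theta
        pi = params.class_probs
        H_nu = -N * (np.diag(pi) - np.outer(pi, pi))
        H[nt:, nt:] = H_nu[1:, 1:]
        return H


class RestrictedLCA:
    """Restricted latent class model under a Q-matrix (statsmodels-style)."""

    def __init__(self, Y, Q):
        self.backend = RlcaBackend(Y, Q)
        self.layout = self.backend.layout
        self.Y = self.backend.Y
        self.Q = self.backend.Q

    def default_start(self):
        """Feasible interior start: nu = 0, theta +1 on capable profiles and
        -1 elsewhere."""
        theta = np.where(self.backend.constraints.capable, 1.0, -1.0)
        return RlcaParams(theta, np.zeros(self.layout.C))

    def start_vector(self, start):
        if start is None:
            start = self.default_start()
        if isinstance(start, RlcaParams):
            return self.layout.pack(start)
        return np.asarray(start, dtype=float)

    def fit(self, start=None, config=None, rng=None, **config_kwargs):
        if config is None:
            config = RunConfig(**config_kwargs)
        beta0 = self.start_vector(start)
        trace = run(self.backend, beta0, config, rng=rng)
        return RlcaResults(self, trace, config)


class RlcaResults:
    def __init__(self, model, trace, config):
        self.model = model
        self.trace = trace
        self.config = config
        self.beta = trace.average
        self.params = model.layout.unpack(trace.average)

    @property
    def n_iterations(self):
        return self.trace.n_iterations

    def louis_information(self, n_draws=500, burn_in=100, rng=None):
        """Observed information via Louis' formula from a fresh stream of
        exact posterior profile draws at the fitted parameters."""
        from .optimizer import louis_hessian

        if rng is None:
            rng = np.random.default_rng(self.config.seed)
        backend = self.model.backend
        beta = self.beta

        def stream():
            for _ in range(n_draws):
                yield backend.sample_latent(None, beta, rng)

        return -louis_hessian(backend, beta, stream(), burn_in=burn_in)

    def standard_errors(self, **kwargs):
        info = self.louis_information(**kwargs)
        cov = np.linalg.pinv(info)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    def constraints_satisfied(self, tol=1e-8):
        return self.model.backend.constraints.is_feasible(self.params.theta,
                                                          tol=tol)

    def summary(self):
        import pandas as pd

        rows = pd.DataFrame({
            "parameter": self.model.layout.param_names(),
            "estimate": self.beta,
        })
        head = (f"Restricted latent class model ({self.trace.variant}), "
                f"N={self.model.Y.shape[0]}, J={self.model.layout.J}, "
                f"K={self.model.layout.K}; "
                f"iterations={self.trace.n_iterations}"
                + (f" (stopped at {self.trace.stop_iteration})"
                   if self.trace.stop_iteration else ""))
        return head + "\n" + rows.to_string(index=False)
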