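"""Item factor analysis back-end.

The model: person i holds latent factors xi_i ~ N(0, Sigma) with Sigma a
correlation matrix reparameterised through its Cholesky factor B (lower
triangular, unit-norm rows, so Sigma = B B^T has unit diagonal), and item j
is answered correctly with logistic probability

    P(Y_ij = 1 | xi_i) = logistic(d_j + a_j^T xi_i).

Confirmatory analysis fixes loadings to zero where a binary design matrix Q
says an item does not measure a factor; exploratory analysis estimates a
full loading matrix under an L1 (or elastic net) penalty, which selects a
sparse, rotation-free solution.

Latent factors are refreshed by Gibbs sampling with adaptive rejection
sampling per coordinate (each full conditional is log-concave).  A tensor
Gauss-Hermite quadrature EM solver is provided as the deterministic
reference for low-dimensional problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from . import _ars
from .optimizer import RunConfig, louis_hessian, run
from .prox import ConstraintPenaltySpec, make_prox, project_sphere_weighted

__all__ = [
    "IfaParams",
    "IfaData",
    "item_response_prob",
    "complete_data_negloglik",
    "gibbs_sample_xi",
    "marginal_loglik_quadrature",
    "em_reference",
    "ConfirmatoryIFA",
    "ExploratoryIFA",
    "IfaResults",
]


# ---------------------------------------------------------------------------
# parameters and data containers
# ---------------------------------------------------------------------------

@dataclass
class IfaParams:
    """Item factor analysis parameters: intercepts d (J,), loadings A (J, K),
    and the correlation Cholesky factor B (K, K, lower triangular with
    unit-norm rows)."""

    d: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)

    @property
    def J(self):
        return self.d.shape[0]

    @property
    def K(self):
        return self.A.shape[1]

    @property
    def sigma(self):
        """Factor correlation matrix Sigma = B B^T."""
        return self.B @ self.B.T

    def copy(self):
        return IfaParams(self.d.copy(), self.A.copy(), self.B.copy())


@dataclass
class IfaData:
    """Binary responses Y (N, J) and optional design matrix Q (J, K)."""

    Y: np.ndarray
    Q: np.ndarray | None = None

    def __post_init__(self):
        Y = np.asarray(self.Y)
        if Y.ndim != 2 or not np.isin(Y, (0, 1)).all():
            raise ValueError("Y must be a binary N x J matrix with no missing entries")
        self.Y = Y.astype(np.float64)
        if self.Q is not None:
            Q = np.asarray(self.Q, dtype=int)
            if Q.shape[0] != Y.shape[1] or not np.isin(Q, (0, 1)).all():
                raise ValueError("Q must be binary with one row per item")
            if (Q.sum(axis=1) == 0).any():
                bad = int(np.flatnonzero(Q.sum(axis=1) == 0)[0])
                raise ValueError(f"Q row {bad} is all zero: item loads on no factor")
            self.Q = Q

    @property
    def N(self):
        return self.Y.shape[0]

    @property
    def J(self):
        return self.Y.shape[1]


def item_response_prob(d_j, a_j, xi):
    """Logistic response probability P(Y=1 | xi) = expit(d_j + a_j.xi)."""
    return expit(d_j + np.dot(np.asarray(a_j, float), np.asarray(xi, float)))


def _log1pexp(x):
    out = np.empty_like(x, dtype=float)
    hi = x > 35
    lo = x < -35
    mid = ~(hi | lo)
    out[hi] = x[hi] + np.exp(-x[hi])
    out[lo] = np.exp(x[lo])
    out[mid] = np.log1p(np.exp(x[mid]))
    return out


# ---------------------------------------------------------------------------
# free-parameter layout
# ---------------------------------------------------------------------------

class IfaLayout:
    """Flat layout [d | free loadings (row-major) | free Cholesky entries].

    In confirmatory mode Q-fixed loadings are excluded from the parameter
    vector entirely; in exploratory mode all J*K loadings are free.  Row k of
    B contributes its k+1 leading entries (the rest are structural zeros).
    """

    def __init__(self, J, K, Q=None):
        self.J, self.K = J, K
        if Q is None:
            jj, kk = np.meshgrid(np.arange(J), np.arange(K), indexing="ij")
            self.a_j = jj.ravel()
            self.a_k = kk.ravel()
        else:
            self.a_j, self.a_k = np.nonzero(np.asarray(Q, dtype=int))
        self.b_k, self.b_l = map(np.asarray, zip(*[(k, l) for k in range(K)
                                                   for l in range(k + 1)]))
        self.n_a = len(self.a_j)
        self.n_b = len(self.b_k)
        self.n_params = J + self.n_a + self.n_b
        self.d_slice = slice(0, J)
        self.a_slice = slice(J, J + self.n_a)
        self.b_slice = slice(J + self.n_a, self.n_params)
        self.block_map = {"intercepts": self.d_slice,
                          "loadings": self.a_slice,
                          "cholesky": self.b_slice}

    def pack(self, params):
        beta = np.empty(self.n_params)
        beta[self.d_slice] = params.d
        beta[self.a_slice] = params.A[self.a_j, self.a_k]
        beta[self.b_slice] = params.B[self.b_k, self.b_l]
        return beta

    def unpack(self, beta):
        d = np.array(beta[self.d_slice])
        A = np.zeros((self.J, self.K))
        A[self.a_j, self.a_k] = beta[self.a_slice]
        B = np.zeros((self.K, self.K))
        B[self.b_k, self.b_l] = beta[self.b_slice]
        return IfaParams(d, A, B)

    def sphere_rows(self):
        """Index arrays (into the flat vector) of each Cholesky row."""
        base = self.J + self.n_a
        rows = []
        start = 0
        for k in range(self.K):
            rows.append(np.arange(base + start, base + start + k + 1))
            start += k + 1
        return rows

    def param_names(self):
        names = [f"d[{j}]" for j in range(self.J)]
        names += [f"a[{j},{k}]" for j, k in zip(self.a_j, self.a_k)]
        names += [f"b[{k},{l}]" for k, l in zip(self.b_k, self.b_l)]
        return names


# ---------------------------------------------------------------------------
# complete-data objective and derivatives
# ---------------------------------------------------------------------------

def complete_data_negloglik(Xi, params, data, ridge=0.0):
    """H(xi, beta): negative complete-data log-likelihood plus the smooth
    ridge part of the penalty (``ridge`` is the absolute coefficient of
    sum a^2)."""
    Xi = np.asarray(Xi, dtype=float)
    Y = data.Y
    N, K = Xi.shape
    eta = params.d[None, :] + Xi @ params.A.T
    bern = -np.sum(Y * eta - _log1pexp(eta))
    sign, logdet = np.linalg.slogdet(params.sigma)
    if sign <= 0:
        raise FloatingPointError("rank-deficient Cholesky factor B")
    Sig_inv_Xi = np.linalg.solve(params.sigma, Xi.T)
    quad = float(np.sum(Xi.T * Sig_inv_Xi))
    gauss = 0.5 * (N * logdet + quad + N * K * np.log(2.0 * np.pi))
    pen = ridge * float(np.sum(params.A ** 2))
    return bern + gauss + pen


def _gauss_negloglik(Xi, B):
    """Gaussian part of the complete-data negative log-likelihood (no
    constant), used by line searches."""
    N = Xi.shape[0]
    Sigma = B @ B.T
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    quad = float(np.sum(Xi.T * np.linalg.solve(Sigma, Xi.T)))
    return 0.5 * (N * logdet + quad)


def _gaussian_block_derivs(Xi, B):
    """Gradient and diagonal Hessian of the Gaussian part of H w.r.t. the
    free entries of B, plus intermediates reused by the full Hessian."""
    N = Xi.shape[0]
    Sigma = B @ B.T
    c, low = cho_factor(Sigma, lower=True)
    P = cho_solve((c, low), np.eye(B.shape[0]))
    S = Xi.T @ Xi
    M = P @ B
    T = P @ S @ P
    W = B.T @ M                     # B^T P B
    TB = T @ B
    BtTB = B.T @ TB
    grad = N * M - TB               # (K, K); select lower-tri free entries
    K = B.shape[0]
    kk, ll = np.tril_indices(K)
    hess = (N * (P[kk, kk] - P[kk, kk] * W[ll, ll] - M[kk, ll] ** 2)
            + (P[kk, kk] * BtTB[ll, ll] + 2.0 * M[kk, ll] * TB[kk, ll]
               + T[kk, kk] * W[ll, ll] - T[kk, kk]))
    return grad, hess, (P, M, T, W, TB, BtTB)


def grad_and_diag_hess(Xi, params, data, layout, ridge=0.0):
    """Exact gradient and diagonal second derivatives of H w.r.t. the free
    parameters in `layout` order."""
    Xi = np.asarray(Xi, dtype=float)
    Y = data.Y
    eta = params.d[None, :] + Xi @ params.A.T
    P_ij = expit(eta)
    R = P_ij - Y                    # residuals
    V = P_ij * (1.0 - P_ij)

    grad = np.empty(layout.n_params)
    hess = np.empty(layout.n_params)
    grad[layout.d_slice] = R.sum(axis=0)
    hess[layout.d_slice] = V.sum(axis=0)

    GA = R.T @ Xi                   # (J, K)
    HA = V.T @ (Xi ** 2)
    grad[layout.a_slice] = GA[layout.a_j, layout.a_k] \
        + 2.0 * ridge * params.A[layout.a_j, layout.a_k]
    hess[layout.a_slice] = HA[layout.a_j, layout.a_k] + 2.0 * ridge

    gB, hB, _ = _gaussian_block_derivs(Xi, params.B)
    grad[layout.b_slice] = gB[layout.b_k, layout.b_l]
    hess[layout.b_slice] = hB
    return grad, hess


def loglik_hessian_full(Xi, params, data, layout):
    """Full Hessian of the complete-data log-likelihood log f (p x p).

    Block diagonal across items for (d_j, a_j); dense within the Cholesky
    block; zero between the item and Cholesky blocks.
    """
    Xi = np.asarray(Xi, dtype=float)
    eta = params.d[None, :] + Xi @ params.A.T
    V = expit(eta) * (1.0 - expit(eta))
    p = layout.n_params
    H = np.zeros((p, p))

    # item blocks: Hessian of -H restricted to (d_j, a_j free)
    a_pos = {(j, k): layout.a_slice.start + i
             for i, (j, k) in enumerate(zip(layout.a_j, layout.a_k))}
    for j in range(layout.J):
        ks = [k for k in range(layout.K) if (j, k) in a_pos]
        idx = np.array([j] + [a_pos[(j, k)] for k in ks])
        X = np.column_stack([np.ones(Xi.shape[0])] + [Xi[:, k] for k in ks])
        H[np.ix_(idx, idx)] = -(X.T * V[:, j]) @ X

    # Cholesky block
    N = Xi.shape[0]
    _, _, (P, M, T, W, TB, BtTB) = _gaussian_block_derivs(Xi, params.B)
    nb = layout.n_b
    base = layout.b_slice.start
    for i1 in range(nb):
        k1, l1 = layout.b_k[i1], layout.b_l[i1]
        for i2 in range(i1, nb):
            k2, l2 = layout.b_k[i2], layout.b_l[i2]
            same_l = 1.0 if l1 == l2 else 0.0
            val = (N * (P[k1, k2] * same_l - P[k1, k2] * W[l2, l1]
                        - M[k1, l2] * M[k2, l1])
                   + (P[k1, k2] * BtTB[l2, l1] + M[k1, l2] * TB[k2, l1]
                      + T[k1, k2] * W[l2, l1] + TB[k1, l2] * M[k2, l1]
                      - T[k1, k2] * same_l))
            # val is the Hessian of the *negative* log-likelihood part
            H[base + i1, base + i2] = -val
            H[base + i2, base + i1] = -val
    return H


# ---------------------------------------------------------------------------
# Gibbs sampling of the latent factors
# ---------------------------------------------------------------------------

def _prior_conditionals(Sigma):
    """Per-coordinate Gaussian conditional weights and precisions."""
    K = Sigma.shape[0]
    W = np.zeros((K, K))
    ivar = np.empty(K)
    for k in range(K):
        others = np.array([l for l in range(K) if l != k])
        if others.size:
            sol = np.linalg.solve(Sigma[np.ix_(others, others)],
                                  Sigma[others, k])
            W[k, others] = sol
            v = Sigma[k, k] - Sigma[k, others] @ sol
        else:
            v = Sigma[k, k]
        ivar[k] = 1.0 / v
    return W, ivar


def gibbs_sample_xi(data, params, xi_prev, rng, n_sweeps=1):
    """Refresh all latent factors with `n_sweeps` full Gibbs scans.

    Each coordinate is drawn from its exact full conditional by adaptive
    rejection sampling.  Persons are conditionally independent given the
    parameters, so the result does not depend on the person ordering.
    """
    Xi = np.array(xi_prev, dtype=float, copy=True)
    W, ivar = _prior_conditionals(params.sigma)
    eta = params.d[None, :] + Xi @ params.A.T
    _ars._seed(int(rng.integers(2 ** 31 - 1)))
    _ars._gibbs_sweep(data.Y, params.A, eta, Xi, W, ivar, n_sweeps)
    return Xi


# ---------------------------------------------------------------------------
# marginal likelihood by quadrature, and the EM reference solver
# ---------------------------------------------------------------------------

def _gh_nodes(K, B, n_quad):
    """Tensor Gauss-Hermite nodes/weights for integrating against N(0, BB^T)."""
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    grids = np.meshgrid(*([z] * K), indexing="ij")
    Z = np.column_stack([g.ravel() for g in grids])
    X = np.sqrt(2.0) * Z @ B.T
    logw = np.sum(np.log(np.meshgrid(*([w] * K), indexing="ij"))
                  .reshape(K, -1), axis=0) - 0.5 * K * np.log(np.pi)
    return X, logw


def marginal_loglik_quadrature(params, data, n_quad=31):
    """Marginal log-likelihood evaluated by tensor-product Gauss-Hermite
    quadrature (reference use; K <= 3)."""
    K = params.K
    if K > 3:
        raise ValueError("quadrature reference supports K <= 3 only")
    X, logw = _gh_nodes(K, params.B, n_quad)
    eta_g = params.d[None, :] + X @ params.A.T          # (G, J)
    l1p = _log1pexp(eta_g)
    # log P(y_i | x_g) = sum_j y_ij eta_gj - log1pexp(eta_gj)
    Lg = data.Y @ eta_g.T - l1p.sum(axis=1)[None, :]    # (N, G)
    Lg = Lg + logw[None, :]
    m = Lg.max(axis=1, keepdims=True)
    return float(np.sum(m.ravel() + np.log(np.sum(np.exp(Lg - m), axis=1))))


def em_reference(data, Q=None, n_quad=31, tol=1e-6, max_iter=500,
                 start=None, return_loglik=False):
    """Quadrature EM solver for confirmatory IFA with K = 2.

    E-step: posterior weights over the tensor Gauss-Hermite grid adapted to
    the current correlation.  M-step: per-item Newton updates of the weighted
    logistic regressions, and a 1-D search for the factor correlation.  The
    marginal log-likelihood is nondecreasing across iterations and the run
    stops when its change falls below `tol`.
    """
    from scipy.optimize import minimize_scalar

    Q = data.Q if Q is None else np.asarray(Q, dtype=int)
    J = data.J
    K = Q.shape[1]
    if K != 2:
        raise ValueError("the EM reference implementation supports K = 2")
    N = data.N

    if start is None:
        d = np.zeros(J)
        A = Q.astype(float)
        rho = 0.0
    else:
        d = start.d.copy()
        A = start.A.copy()
        rho = float(start.sigma[0, 1])

    def chol_of(r):
        return np.linalg.cholesky(np.array([[1.0, r], [r, 1.0]]))

    ll_prev = -np.inf
    ll_hist = []
    for _ in range(max_iter):
        B = chol_of(rho)
        X, logw = _gh_nodes(K, B, n_quad)
        eta_g = d[None, :] + X @ A.T
        l1p = _log1pexp(eta_g)
        Lg = data.Y @ eta_g.T - l1p.sum(axis=1)[None, :] + logw[None, :]
        m = Lg.max(axis=1, keepdims=True)
        ll = float(np.sum(m.ravel() + np.log(np.sum(np.exp(Lg - m), axis=1))))
        ll_hist.append(ll)
        Rw = np.exp(Lg - m)
        Rw /= Rw.sum(axis=1, keepdims=True)              # (N, G) posteriors

        n_g = Rw.sum(axis=0)                             # (G,)
        S_yg = data.Y.T @ Rw                             # (J, G)

        # M-step: per-item Newton on (d_j, free a_j)
        for j in range(J):
            ks = np.flatnonzero(Q[j])
            Xj = np.column_stack([np.ones(X.shape[0])] + [X[:, k] for k in ks])
            theta = np.concatenate([[d[j]], A[j, ks]])
            for _newton in range(50):
                eta_j = Xj @ theta
                p = expit(eta_j)
                g = Xj.T @ (n_g * p - S_yg[j])
                Hj = (Xj.T * (n_g * p * (1.0 - p))) @ Xj
                try:
                    step = np.linalg.solve(Hj, g)
                except np.linalg.LinAlgError:
                    break
                theta = theta - step
                if np.max(np.abs(step)) < 1e-10:
                    break
            d[j] = theta[0]
            A[j, ks] = theta[1:]

        # M-step for the correlation: expected second-moment matrix
        Sbar = (X.T * n_g) @ X                           # sum_i E[x x^T | y_i]

        def neg_gauss(r):
            Sig = np.array([[1.0, r], [r, 1.0]])
            sign, logdet = np.linalg.slogdet(Sig)
            return 0.5 * (N * logdet
                          + np.trace(np.linalg.solve(Sig, Sbar)))

        res = minimize_scalar(neg_gauss, bounds=(-0.99, 0.99),
                              method="bounded",
                              options={"xatol": 1e-10})
        rho = float(res.x)

        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll

    params = IfaParams(d, A, chol_of(rho))
    if return_loglik:
        return params, np.array(ll_hist)
    return params


def _jml_refine(Y, d, A, Xi, n_rounds=4, ridge=1.0):
    """Alternating logistic Newton rounds for a joint-ML-style start.

    Holds person scores fixed to update each item's (d_j, a_j), then holds
    items fixed to update each person's scores under a ridge (standard
    normal prior) penalty.  One Newton step per block per round; all person
    updates are batched.  Deliberately few rounds: the joint-ML objective is
    unbounded along separation directions and loadings inflate if iterated
    to convergence.
    """
    N, J = Y.shape
    K = A.shape[1]
    for _ in range(n_rounds):
        # item updates, one Newton step each
        Xd = np.column_stack([np.ones(N), Xi])
        eta = d[None, :] + Xi @ A.T
        P = expit(eta)
        W = P * (1.0 - P)
        for j in range(J):
            g = Xd.T @ (P[:, j] - Y[:, j])
            H = (Xd.T * W[:, j]) @ Xd + 1e-8 * np.eye(K + 1)
            step = np.linalg.solve(H, g)
            d[j] -= step[0]
            A[j] -= step[1:]
        # person updates, one batched Newton step each
        eta = d[None, :] + Xi @ A.T
        P = expit(eta)
        W = P * (1.0 - P)
        G = (P - Y) @ A + ridge * Xi                       # (N, K)
        H = np.einsum("nj,jk,jl->nkl", W, A, A)            # (N, K, K)
        H += ridge * np.eye(K)[None, :, :]
        Xi = Xi - np.linalg.solve(H, G[:, :, None])[:, :, 0]
        # renormalise scores to unit scale (absorbed by the loadings);
        # pins down the scale indeterminacy and blocks logit inflation
        sd = Xi.std(axis=0)
        sd[sd == 0] = 1.0
        Xi = Xi / sd[None, :]
        A = A * sd[None, :]
    return d, A, Xi


def _quartimin_gpa(L, T0, max_iter=500, tol=1e-8):
    """Gradient-projection minimisation of the quartimin complexity from a
    given oblique rotation start; returns (criterion, Lambda, Phi)."""
    K = L.shape[1]
    N = 1.0 - np.eye(K)

    def criterion(Lam):
        L2 = Lam ** 2
        return float(np.sum(L2 * (L2 @ N)) / 4.0), Lam * (L2 @ N)

    T = T0 / np.sqrt(np.sum(T0 ** 2, axis=0))[None, :]
    Ti = np.linalg.inv(T)
    Lam = L @ Ti.T
    f, Gq = criterion(Lam)
    alpha = 1.0
    for _ in range(max_iter):
        G = -(Lam.T @ Gq @ Ti).T
        Gp = G - T * np.sum(T * G, axis=0)[None, :]
        s = np.sqrt(np.sum(Gp ** 2))
        if s < tol:
            break
        ok = False
        for _ls in range(20):
            Tt = T - alpha * Gp
            Tt = Tt / np.sqrt(np.sum(Tt ** 2, axis=0))[None, :]
            try:
                Tti = np.linalg.inv(Tt)
            except np.linalg.LinAlgError:
                alpha *= 0.5
                continue
            Lt = L @ Tti.T
            ft, Gqt = criterion(Lt)
            if ft < f - 0.5 * s ** 2 * alpha:
                ok = True
                break
            alpha *= 0.5
        if not ok:
            break
        T, Ti, Lam, f, Gq = Tt, Tti, Lt, ft, Gqt
        alpha *= 2.0
    return f, Lam, T.T @ T


def _quartimin(A, max_iter=500, tol=1e-8, n_starts=12, seed=0):
    """Oblique quartimin rotation by the gradient-projection algorithm.

    Returns the pattern matrix Lambda = A (T^T)^-1 and the factor
    correlation matrix Phi = T^T T (unit diagonal by the column-norm
    constraint on T), minimising the quartimin complexity
    Q = sum_j sum_{k != l} lambda_jk^2 lambda_jl^2 / 4.  The criterion has
    local optima; the identity start is supplemented with random rotation
    restarts (fixed internal seed) and the lowest criterion value wins.
    """
    J, K = A.shape
    if K < 2:
        return A.copy(), np.eye(K)
    L = _varimax(A)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        T0 = np.eye(K) if s == 0 else rng.standard_normal((K, K))
        try:
            f, Lam, Phi = _quartimin_gpa(L, T0, max_iter=max_iter, tol=tol)
        except np.linalg.LinAlgError:
            continue
        if np.linalg.eigvalsh(Phi).min() < 1e-3:
            continue
        if best is None or f < best[0]:
            best = (f, Lam, Phi)
    if best is None:
        return L, np.eye(K)
    return best[1], best[2]


def _varimax(A, tol=1e-8, max_iter=200):
    """Varimax rotation (orthogonal, Kaiser-normalised) of a loading matrix."""
    J, K = A.shape
    if K < 2:
        return A.copy()
    h = np.sqrt((A ** 2).sum(axis=1))
    h[h == 0] = 1.0
    L = A / h[:, None]
    R = np.eye(K)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        U, s, Vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr * (Lr ** 2).sum(axis=0)[None, :] / J))
        R = U @ Vt
        var = s.sum()
        if var_old != 0 and var - var_old < tol * var:
            break
        var_old = var
    return (L @ R) * h[:, None]


# ---------------------------------------------------------------------------
# engine back-end
# ---------------------------------------------------------------------------

class IfaBackend:
    """ModelBackend implementation for (confirmatory or penalised
    exploratory) item factor analysis.

    The engine works on the per-observation objective H/N (same minimiser;
    gradients are self-averaging and the scaling metric is O(1), which is the
    scale on which the default truncation bounds and the identity-metric
    comparison variant are meaningful).  ``lam`` and ``ridge`` are absolute
    penalty weights on the summed log-likelihood objective -l + lam*sum|a|
    + ridge*sum a^2 and are divided by N internally.
    """

    def __init__(self, data, layout, lam=0.0, ridge=0.0, n_sweeps=1):
        self.data = data
        self.layout = layout
        self.n_params = layout.n_params
        self.block_map = layout.block_map
        self.lam = lam
        self.ridge = ridge
        self.n_sweeps = n_sweeps
        kind = "l1+sphere" if lam > 0 else "sphere"
        a_idx = np.arange(layout.a_slice.start, layout.a_slice.stop)
        self._spec = ConstraintPenaltySpec(
            kind=kind, l1_indices=a_idx, lam=lam / data.N,
            sphere_rows=layout.sphere_rows())
        self._prox = make_prox(self._spec)

    def initial_latent(self, beta, rng):
        params = self.layout.unpack(beta)
        L = np.linalg.cholesky(params.sigma)
        return rng.standard_normal((self.data.N, self.layout.K)) @ L.T

    def sample_latent(self, latent, beta, rng):
        params = self.layout.unpack(beta)
        return gibbs_sample_xi(self.data, params, latent, rng,
                               n_sweeps=self.n_sweeps)

    def grad_and_diag_hess(self, latent, beta):
        params = self.layout.unpack(beta)
        N = self.data.N
        g, h = grad_and_diag_hess(latent, params, self.data, self.layout,
                                  ridge=self.ridge)
        return g / N, h / N

    def prox(self, beta_tilde, weights, gamma):
        return self._prox(beta_tilde, weights, gamma)

    def complete_data_objective(self, latent, beta):
        params = self.layout.unpack(beta)
        return complete_data_negloglik(latent, params, self.data,
                                       ridge=self.ridge) / self.data.N

    def full_maximize(self, latent, beta):
        """Exact M-step for the stochastic-EM variant.

        The complete-data objective separates: per-item logistic
        regressions in (d_j, free a_j) solved by full Newton (the diagonal
        quasi-Newton iteration zig-zags on the correlated intercept/loading
        pair), and the Gaussian block over the sphere-constrained Cholesky
        rows solved by the iterated scaled proximal update.  Only defined
        for smooth objectives (no L1 part).
        """
        if self.lam > 0:
            from .optimizer import _prox_newton_maximize
            return _prox_newton_maximize(self, latent, beta, 1e-2, 1e4)
        params = self.layout.unpack(beta)
        Xi = np.asarray(latent, dtype=float)
        N = self.data.N
        Y = self.data.Y
        lay = self.layout
        d = params.d.copy()
        A = params.A.copy()
        ridge_term = 2.0 * self.ridge
        for j in range(lay.J):
            ks = lay.a_k[lay.a_j == j]
            X = np.column_stack([np.ones(N)] + [Xi[:, k] for k in ks])
            th = np.concatenate([[d[j]], A[j, ks]])
            mask = np.r_[0.0, np.ones(len(ks))]
            for _ in range(50):
                p = expit(X @ th)
                g = X.T @ (p - Y[:, j]) + ridge_term * mask * th
                H = (X.T * (p * (1 - p))) @ X + ridge_term * np.diag(mask)
                step = np.linalg.solve(H + 1e-10 * np.eye(len(th)), g)
                th = th - step
                if np.max(np.abs(step)) < 1e-9:
                    break
            d[j] = th[0]
            A[j, ks] = th[1:]

        B = params.B.copy()
        obj = _gauss_negloglik(Xi, B)
        kk, ll = np.tril_indices(lay.K)
        for _ in range(200):
            gB, hB, _ = _gaussian_block_derivs(Xi, B)
            gflat = gB[kk, ll] / N
            hflat = np.clip(hB / N, 1e-2, 1e4)
            step = 1.0
            for _ls in range(25):
                Bn = np.zeros_like(B)
                Bn[kk, ll] = B[kk, ll] - step * gflat / hflat
                Hw = np.zeros_like(B)
                Hw[kk, ll] = hflat
                for r in range(lay.K):
                    Bn[r, :r + 1] = project_sphere_weighted(
                        Bn[r, :r + 1], Hw[r, :r + 1])
                obj_new = _gauss_negloglik(Xi, Bn)
                if obj_new <= obj + 1e-12 * max(1.0, abs(obj)):
                    break
                step *= 0.5
            delta = float(np.max(np.abs(Bn - B)))
            B, obj = Bn, obj_new
            if delta < 1e-8:
                break

        return lay.pack(IfaParams(d, A, B))

    def loglik_score_full(self, latent, beta):
        params = self.layout.unpack(beta)
        g, _ = grad_and_diag_hess(latent, params, self.data, self.layout,
                                  ridge=0.0)
        return -g

    def loglik_hessian_full(self, latent, beta):
        params = self.layout.unpack(beta)
        return loglik_hessian_full(latent, params, self.data, self.layout)


# ---------------------------------------------------------------------------
# model / results classes
# ---------------------------------------------------------------------------

class _IfaModelBase:
    def __init__(self, data, layout, lam=0.0, ridge=0.0, n_sweeps=1):
        self.data = data
        self.layout = layout
        self.backend = IfaBackend(data, layout, lam=lam, ridge=ridge,
                                  n_sweeps=n_sweeps)

    def default_start(self):
        raise NotImplementedError

    def start_vector(self, start):
        if start is None:
            start = self.default_start()
        if isinstance(start, IfaParams):
            return self.layout.pack(start)
        return np.asarray(start, dtype=float)

    def fit(self, start=None, config=None, rng=None, **config_kwargs):
        """Run the stochastic proximal engine; returns :class:`IfaResults`.

        Keyword arguments are forwarded to :class:`RunConfig` (for example
        ``variant="USP"``, ``n_iterations=1000``, ``burn_in=500``,
        ``adaptive_stop=True``, ``seed=0``).
        """
        if config is None:
            config = RunConfig(**config_kwargs)
        beta0 = self.start_vector(start)
        trace = run(self.backend, beta0, config, rng=rng)
        return IfaResults(self, trace, config)


class ConfirmatoryIFA(_IfaModelBase):
    """Confirmatory item factor analysis (marginal ML under a Q-matrix)."""

    def __init__(self, Y, Q, n_sweeps=1):
        data = IfaData(Y=Y, Q=Q)
        super().__init__(data, IfaLayout(data.J, Q.shape[1], Q=data.Q),
                         n_sweeps=n_sweeps)

    def default_start(self):
        return IfaParams(np.zeros(self.data.J),
                         self.data.Q.astype(float),
                         np.eye(self.layout.K))

    def fit_em(self, n_quad=31, tol=1e-6, **kwargs):
        """Deterministic quadrature-EM reference solution (K = 2)."""
        return em_reference(self.data, n_quad=n_quad, tol=tol, **kwargs)


class ExploratoryIFA(_IfaModelBase):
    """Exploratory IFA with an L1 (optionally elastic net) loading penalty.

    ``lam`` is the absolute L1 weight in the fitted objective
    -l(beta) + lam * sum |a_jk|; ``ridge`` likewise the weight of the smooth
    quadratic part of an elastic net (routed to the gradient, not the prox).
    """

    def __init__(self, Y, K, lam, ridge=0.0, n_sweeps=1):
        data = IfaData(Y=Y)
        if lam < 0 or ridge < 0:
            raise ValueError("penalty weights must be nonnegative")
        super().__init__(data, IfaLayout(data.J, K), lam=lam, ridge=ridge,
                         n_sweeps=n_sweeps)
        self.lam = lam
        self.ridge = ridge

    def default_start(self, n_jml_rounds=3):
        """Constrained joint-ML start, quartimin rotated.

        A spectral decomposition of the linearised (centred, variance
        weighted) responses seeds person scores and loadings; a few
        alternating ridge-penalised logistic Newton rounds (items given
        scores, scores given items) refine them; an oblique quartimin
        rotation then picks the sparse orientation and the implied factor
        correlations.  A start with distinct, roughly correct and sparse
        column directions matters here: the likelihood is flat along oblique
        rotations with unit-diagonal factor correlation, the L1 term breaks
        the tie only weakly, and under stronger penalties an unstructured
        start lets entire loading columns be absorbed at zero.
        """
        Y = self.data.Y
        N, J = Y.shape
        K = self.layout.K
        pbar = np.clip(Y.mean(axis=0), 0.02, 0.98)
        d = np.log(pbar / (1.0 - pbar))
        w = pbar * (1.0 - pbar)
        # whitened linearisation: dividing by sqrt(w) gives unit-variance
        # noise per cell (dividing by w amplifies extreme items' noise and
        # occasionally wrecks the leading subspace)
        X = (Y - pbar[None, :]) / np.sqrt(w)[None, :]
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        A = ((Vt[:K].T * s[:K]) / np.sqrt(N)) / np.sqrt(w)[:, None]
        Xi = np.sqrt(N) * U[:, :K]
        d, A, Xi = _jml_refine(Y, d, A, Xi, n_rounds=n_jml_rounds)
        A, Phi = _quartimin(A)
        flip = np.where(A.sum(axis=0) < 0, -1.0, 1.0)
        A *= flip[None, :]
        Phi = Phi * np.outer(flip, flip)
        return IfaParams(d, A, np.linalg.cholesky(Phi))


class IfaResults:
    """Fitted IFA parameters plus the engine trace."""

    def __init__(self, model, trace, config):
        self.model = model
        self.trace = trace
        self.config = config
        self.beta = trace.average
        self.params = model.layout.unpack(trace.average)
        # averaging unit-norm rows lands strictly inside the sphere; map the
        # reported estimate back onto the feasible set
        norms = np.linalg.norm(self.params.B, axis=1)
        norms[norms == 0] = 1.0
        self.params.B /= norms[:, None]

    @property
    def n_iterations(self):
        return self.trace.n_iterations

    def louis_information(self, n_draws=500, burn_in=100, rng=None):
        """Observed-information estimate: minus the Louis-formula Hessian of
        the marginal log-likelihood at the fitted parameters, from a fresh
        stream of Gibbs draws."""
        if rng is None:
            rng = np.random.default_rng(self.config.seed)
        backend = self.model.backend
        beta = self.beta

        def stream():
            latent = backend.initial_latent(beta, rng)
            for _ in range(n_draws):
                latent = backend.sample_latent(latent, beta, rng)
                yield latent

        H = louis_hessian(backend, beta, stream(), burn_in=burn_in)
        return -H

    def standard_errors(self, **kwargs):
        info = self.louis_information(**kwargs)
        cov = np.linalg.pinv(info)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    def summary(self):
        import pandas as pd

        layout = self.model.layout
        rows = pd.DataFrame({
            "parameter": layout.param_names(),
            "estimate": self.beta,
        })
        head = (f"Item factor analysis ({self.trace.variant}), "
                f"N={self.model.data.N}, J={self.model.data.J}, "
                f"K={layout.K}; iterations={self.trace.n_iterations}"
                + (f" (stopped at {self.trace.stop_iteration})"
                   if self.trace.stop_iteration else ""))
        return head + "\n" + rows.to_string(index=False)

    def plot_trace(self, ax=None):
        """Convergence diagnostic: successive max-norm differences."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(np.arange(1, len(self.trace.diff_history) + 1),
                    self.trace.diff_history)
        ax.set_xlabel("iteration")
        ax.set_ylabel(r"max $|\Delta\beta|$")
        return ax
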