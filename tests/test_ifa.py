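"""Item factor analysis tests: likelihood closed forms, derivative oracles,
Gibbs/ARS distributional checks, quadrature, the EM reference, and the
model-class surface."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import expit

from lvprox.ifa import (ConfirmatoryIFA, ExploratoryIFA, IfaBackend, IfaData,
                        IfaLayout, IfaParams, complete_data_negloglik,
                        em_reference, gibbs_sample_xi, grad_and_diag_hess,
                        item_response_prob, loglik_hessian_full,
                        marginal_loglik_quadrature)
from lvprox.optimizer import RunConfig, louis_hessian

# ---------------------------------------------------------------------------
# response probability and complete-data likelihood
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("d, a, xi, expected", [
    (0.0, [0.0], [0.0], 0.5),
    (np.log(3.0), [0.0], [1.7], 0.75),
    (1.0, [2.0, -1.0], [1.0, 1.0], expit(2.0)),
])
def test_item_response_prob_closed_form(d, a, xi, expected):
    assert item_response_prob(d, np.array(a), np.array(xi)) == \
        pytest.approx(expected, rel=1e-12)


def test_item_response_prob_deep_tail():
    # linear predictor -30: probability matches exp(-30) to 1% relative
    p = item_response_prob(-30.0, np.array([0.0]), np.array([0.0]))
    assert p == pytest.approx(np.exp(-30.0), rel=0.01)
    assert item_response_prob(700.0, np.array([0.0]), np.array([0.0])) == 1.0


def test_complete_data_negloglik_single_cell_closed_form():
    """N=J=K=1, y=1, everything zero: ln 2 + (1/2) ln(2 pi)."""
    data = IfaData(Y=np.array([[1]]))
    params = IfaParams(np.zeros(1), np.zeros((1, 1)), np.eye(1))
    val = complete_data_negloglik(np.zeros((1, 1)), params, data)
    assert val == pytest.approx(np.log(2.0) + 0.5 * np.log(2 * np.pi),
                                rel=1e-12)


def test_complete_data_negloglik_additive_over_persons(small_ifa_instance):
    data, layout, params, Xi = small_ifa_instance
    single = complete_data_negloglik(Xi, params, data)
    stacked = IfaData(Y=np.vstack([data.Y, data.Y]))
    double = complete_data_negloglik(np.vstack([Xi, Xi]), params, stacked)
    assert double == pytest.approx(2 * single, rel=1e-12)


def test_complete_data_negloglik_matches_naive_double_loop(
        small_ifa_instance):
    data, layout, params, Xi = small_ifa_instance
    val = complete_data_negloglik(Xi, params, data)
    # term-by-term independent summation
    Sigma = params.B @ params.B.T
    Sinv = np.linalg.inv(Sigma)
    ref = 0.0
    for i in range(data.N):
        for j in range(data.J):
            eta = params.d[j] + params.A[j] @ Xi[i]
            ref -= data.Y[i, j] * eta - np.log(1 + np.exp(eta))
        ref += 0.5 * (Xi[i] @ Sinv @ Xi[i]
                      + np.log(np.linalg.det(2 * np.pi * Sigma)))
    assert val == pytest.approx(ref, rel=1e-10)


def test_rank_deficient_cholesky_rejected(small_ifa_instance):
    data, layout, params, Xi = small_ifa_instance
    bad = params.copy()
    bad.B = np.zeros_like(bad.B)
    with pytest.raises(FloatingPointError):
        complete_data_negloglik(Xi, bad, data)


# ---------------------------------------------------------------------------
# derivative oracles
# ---------------------------------------------------------------------------


def test_gradient_matches_finite_differences(small_ifa_instance):
    data, layout, params, Xi = small_ifa_instance
    beta = layout.pack(params)
    g, _ = grad_and_diag_hess(Xi, params, data, layout, ridge=0.2)
    eps = 1e-6

    def f(b):
        return complete_data_negloglik(Xi, layout.unpack(b), data, ridge=0.2)

    for i in range(len(beta)):
        e = np.zeros_like(beta)
        e[i] = eps
        fd = (f(beta + e) - f(beta - e)) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-5)


def test_diag_hessian_matches_finite_differences_of_gradient(
        small_ifa_instance):
    data, layout, params, Xi = small_ifa_instance
    beta = layout.pack(params)
    _, h = grad_and_diag_hess(Xi, params, data, layout)
    eps = 1e-6
    for i in range(len(beta)):
        e = np.zeros_like(beta)
        e[i] = eps
        gp, _ = grad_and_diag_hess(Xi, layout.unpack(beta + e), data, layout)
        gm, _ = grad_and_diag_hess(Xi, layout.unpack(beta - e), data, layout)
        fd = (gp[i] - gm[i]) / (2 * eps)
        assert h[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


def test_full_hessian_matches_finite_differences_of_gradient(
        small_ifa_instance):
    data, layout, params, Xi = small_ifa_instance
    beta = layout.pack(params)
    H = loglik_hessian_full(Xi, params, data, layout)   # Hessian of +log f
    eps = 1e-6
    p = len(beta)
    for i in range(p):
        e = np.zeros(p)
        e[i] = eps
        gp, _ = grad_and_diag_hess(Xi, layout.unpack(beta + e), data, layout)
        gm, _ = grad_and_diag_hess(Xi, layout.unpack(beta - e), data, layout)
        fd_row = -(gp - gm) / (2 * eps)                 # -d(grad H) = d(score)
        np.testing.assert_allclose(H[i], fd_row, rtol=1e-4, atol=1e-5)


def test_bernoulli_gradient_vanishes_at_saturation():
    """When p_ij ~= y_ij everywhere the residual gradient goes to zero."""
    data = IfaData(Y=np.array([[1, 0], [1, 0]]))
    layout = IfaLayout(2, 1, Q=np.array([[1], [1]]))
    params = IfaParams(np.array([40.0, -40.0]), np.zeros((2, 1)), np.eye(1))
    g, _ = grad_and_diag_hess(np.zeros((2, 1)), params, data, layout)
    np.testing.assert_allclose(g[layout.d_slice], 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# Gibbs sampling with adaptive rejection sampling
# ---------------------------------------------------------------------------


def test_gibbs_prior_only_moments():
    """With no items the sampler must reproduce N(0, Sigma)."""
    rho = 0.5
    B = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    params = IfaParams(np.zeros(0), np.zeros((0, 2)), B)
    data = IfaData(Y=np.zeros((4000, 0)))
    rng = np.random.default_rng(0)
    Xi = np.zeros((4000, 2))
    acc = np.zeros((2, 2))
    n_keep = 0
    for t in range(25):
        Xi = gibbs_sample_xi(data, params, Xi, rng)
        if t >= 5:
            acc += Xi.T @ Xi / 4000
            n_keep += 1
    cov = acc / n_keep
    se = 3.0 / np.sqrt(4000 * n_keep / 5)     # generous: draws autocorrelated
    assert abs(cov[0, 1] - rho) < max(3 * se, 0.03)
    assert abs(cov[0, 0] - 1.0) < max(3 * se, 0.03)


def test_gibbs_flat_likelihood_is_prior():
    """All loadings zero: the conditional is exactly the Gaussian prior."""
    params = IfaParams(np.array([0.3]), np.zeros((1, 1)), np.eye(1))
    data = IfaData(Y=np.ones((2000, 1), dtype=int))
    rng = np.random.default_rng(1)
    draws = []
    Xi = np.zeros((2000, 1))
    for _ in range(10):
        Xi = gibbs_sample_xi(data, params, Xi, rng)
        draws.append(Xi[:, 0].copy())
    d = np.concatenate(draws)
    assert abs(d.mean()) < 3 / np.sqrt(d.size)
    assert abs(d.std() - 1.0) < 0.02


def test_gibbs_1item_histogram_matches_quadrature_posterior():
    """Long-run ARS-Gibbs histogram vs the numerically normalised 1-D
    posterior density (sup-norm of binned difference < 0.02)."""
    d0, a0 = 0.3, 1.2
    params = IfaParams(np.array([d0]), np.array([[a0]]), np.eye(1))
    data = IfaData(Y=np.ones((40, 1), dtype=int))
    rng = np.random.default_rng(5)
    n_rounds = 1500                     # 40 persons x 1500 rounds = 60k draws
    draws = np.empty((n_rounds, 40))
    Xi = np.zeros((40, 1))
    for t in range(n_rounds):
        Xi = gibbs_sample_xi(data, params, Xi, rng)
        draws[t] = Xi[:, 0]
    x = draws.ravel()

    def dens(t):
        return expit(d0 + a0 * t) * np.exp(-t * t / 2) / np.sqrt(2 * np.pi)

    Z, _ = quad(dens, -10, 10)
    edges = np.linspace(-3.5, 3.5, 36)
    hist, _ = np.histogram(x, bins=edges, density=True)
    ref = np.array([quad(dens, edges[i], edges[i + 1])[0]
                    / Z / (edges[i + 1] - edges[i]) for i in range(35)])
    assert np.abs(hist - ref).max() < 0.02


def test_gibbs_reproducible_and_independent_of_person_count():
    params = IfaParams(np.array([0.1]), np.array([[0.8]]), np.eye(1))
    data = IfaData(Y=np.array([[1], [0], [1]]))
    out = []
    for _ in range(2):
        rng = np.random.default_rng(3)
        out.append(gibbs_sample_xi(data, params, np.zeros((3, 1)), rng))
    np.testing.assert_array_equal(out[0], out[1])


# ---------------------------------------------------------------------------
# quadrature marginal likelihood
# ---------------------------------------------------------------------------


def test_quadrature_constant_integrand():
    """d = 0, a = 0: every response has probability 1/2."""
    data = IfaData(Y=np.array([[1, 0], [0, 0], [1, 1]]))
    params = IfaParams(np.zeros(2), np.zeros((2, 1)), np.eye(1))
    ll = marginal_loglik_quadrature(params, data, n_quad=15)
    assert ll == pytest.approx(6 * np.log(0.5), rel=1e-12)


def test_quadrature_k1_matches_adaptive_integration():
    rng = np.random.default_rng(2)
    data = IfaData(Y=(rng.random((7, 3)) < 0.5).astype(int))
    params = IfaParams(rng.normal(size=3), rng.uniform(0.5, 1.5, (3, 1)),
                       np.eye(1))
    ll = marginal_loglik_quadrature(params, data, n_quad=31)
    ref = 0.0
    for i in range(7):
        def integrand(x, i=i):
            p = expit(params.d + params.A[:, 0] * x)
            lik = np.prod(np.where(data.Y[i] == 1, p, 1 - p))
            return lik * np.exp(-x * x / 2) / np.sqrt(2 * np.pi)
        val, _ = quad(integrand, -9, 9, epsabs=1e-12)
        ref += np.log(val)
    assert ll == pytest.approx(ref, abs=1e-8)


def test_quadrature_self_consistency_in_node_count(small_ifa_instance):
    data, layout, params, Xi = small_ifa_instance
    vals = [marginal_loglik_quadrature(params, data, n_quad=n)
            for n in (11, 21, 31)]
    assert abs(vals[2] - vals[1]) <= abs(vals[1] - vals[0]) + 1e-12
    assert abs(vals[2] - vals[1]) < 1e-6


def test_quadrature_rejects_large_k():
    params = IfaParams(np.zeros(1), np.zeros((1, 4)), np.eye(4))
    with pytest.raises(ValueError):
        marginal_loglik_quadrature(params, IfaData(Y=np.ones((1, 1),
                                                             dtype=int)))


# ---------------------------------------------------------------------------
# EM reference solver
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def em_recovery_run():
    from lvprox.simulation import (generate_ifa_data, generate_ifa_params,
                                   study_design)

    design = study_design("I")
    rng = np.random.default_rng(77)
    truth = generate_ifa_params(design, rng)
    Y = generate_ifa_data(truth, 8000, rng)
    data = IfaData(Y=Y, Q=design.Q)
    params, ll_hist = em_reference(data, start=truth, return_loglik=True,
                                   n_quad=21, tol=1e-5)
    return truth, params, ll_hist


def test_em_recovers_truth_at_large_n(em_recovery_run):
    truth, params, _ = em_recovery_run
    assert np.sqrt(np.mean((params.d - truth.d) ** 2)) < 0.1
    mask = truth.A != 0
    assert np.sqrt(np.mean((params.A[mask] - truth.A[mask]) ** 2)) < 0.1
    assert abs(params.sigma[0, 1] - truth.sigma[0, 1]) < 0.05


def test_em_loglik_nondecreasing(em_recovery_run):
    _, _, ll_hist = em_recovery_run
    assert np.all(np.diff(ll_hist) > -1e-7)


# ---------------------------------------------------------------------------
# Louis-formula by-product on a quadrature-checkable toy
# ---------------------------------------------------------------------------


def test_louis_hessian_matches_marginal_loglik_curvature():
    """1-item K=1 confirmatory toy: the Louis Monte-Carlo Hessian of the
    marginal log-likelihood matches central finite differences of the
    quadrature-evaluated marginal log-likelihood."""
    rng = np.random.default_rng(4)
    Y = (rng.random((60, 1)) < 0.6).astype(int)
    Q = np.array([[1]])
    data = IfaData(Y=Y, Q=Q)
    layout = IfaLayout(1, 1, Q=Q)
    backend = IfaBackend(data, layout)
    params = IfaParams(np.array([0.2]), np.array([[0.9]]), np.eye(1))
    beta = layout.pack(params)

    # with K=1 and one coordinate per person the "Gibbs" draws are exact
    # i.i.d. posterior samples; the 1/t recursion is then a plain mean
    def stream():
        latent = backend.initial_latent(beta, rng)
        for _ in range(20000):
            latent = backend.sample_latent(latent, beta, rng)
            yield latent

    H = louis_hessian(backend, beta, stream())

    eps = 1e-4
    idx = [0, 1]                      # d and a entries; b is sphere-pinned
    fd = np.zeros((2, 2))
    for r, i in enumerate(idx):
        for c, j in enumerate(idx):
            vals = {}
            for si in (1, -1):
                for sj in (1, -1):
                    b = beta.copy()
                    b[i] += si * eps
                    b[j] += sj * eps
                    vals[(si, sj)] = marginal_loglik_quadrature(
                        layout.unpack(b), data, n_quad=41)
            fd[r, c] = (vals[(1, 1)] - vals[(1, -1)] - vals[(-1, 1)]
                        + vals[(-1, -1)]) / (4 * eps * eps)
    # the loading element is a near-total cancellation of complete and
    # missing information (one item barely identifies a); allow its Monte
    # Carlo error an absolute band, the rest a tight relative one
    np.testing.assert_allclose(H[:2, :2], fd, rtol=0.02, atol=0.12)


def test_stochastic_gradient_unbiasedness_proxy():
    """Averaged complete-data gradients over refreshed Gibbs draws approach
    the finite-difference gradient of the (quadrature) marginal deviance."""
    rng = np.random.default_rng(10)
    Q = np.array([[1, 0], [0, 1], [1, 1]])
    from lvprox.simulation import generate_ifa_data

    truth = IfaParams(np.array([0.2, -0.3, 0.1]),
                      np.array([[1.0, 0.0], [0.0, 0.8], [0.6, 0.7]]),
                      np.linalg.cholesky(np.array([[1.0, 0.3], [0.3, 1.0]])))
    Y = generate_ifa_data(truth, 300, rng)
    data = IfaData(Y=Y, Q=Q)
    layout = IfaLayout(3, 2, Q=Q)
    backend = IfaBackend(data, layout)
    beta = layout.pack(truth)

    latent = backend.initial_latent(beta, rng)
    for _ in range(30):
        latent = backend.sample_latent(latent, beta, rng)
    G = np.zeros(layout.n_params)
    M = 600
    for _ in range(M):
        latent = backend.sample_latent(latent, beta, rng)
        g, _ = backend.grad_and_diag_hess(latent, beta)
        G += g / M

    eps = 1e-5
    for i in range(layout.n_params):
        e = np.zeros(layout.n_params)
        e[i] = eps
        lp = marginal_loglik_quadrature(layout.unpack(beta + e), data, 31)
        lm = marginal_loglik_quadrature(layout.unpack(beta - e), data, 31)
        fd = -(lp - lm) / (2 * eps) / data.N     # per-observation scale
        assert G[i] == pytest.approx(fd, abs=0.01)


# ---------------------------------------------------------------------------
# model classes and feasibility preservation
# ---------------------------------------------------------------------------


def test_confirmatory_fit_preserves_feasibility(small_ifa_instance):
    data, layout, params, Xi = small_ifa_instance
    model = ConfirmatoryIFA(data.Y.astype(int), data.Q)
    cfg = RunConfig(n_iterations=60, burn_in=20, seed=0, keep_history=True)
    res = model.fit(start=params, config=cfg)
    for beta in res.trace.beta_history:
        p = model.layout.unpack(beta)
        norms = np.linalg.norm(p.B, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)
        assert np.all(p.A[data.Q == 0] == 0.0)
    assert res.summary().startswith("Item factor analysis")


def test_exploratory_strong_penalty_produces_exact_zeros(rng):
    """Soft-thresholding yields literal zeros (not small values) once the
    penalty outweighs a loading's evidence."""
    from lvprox.simulation import generate_ifa_data

    truth = IfaParams(np.zeros(12),
                      np.vstack([np.column_stack([np.full(6, 1.2),
                                                  np.zeros(6)]),
                                 np.column_stack([np.zeros(6),
                                                  np.full(6, 1.2)])]),
                      np.eye(2))
    Y = generate_ifa_data(truth, 400, rng)
    model = ExploratoryIFA(Y, 2, lam=0.05 * 400)   # strong absolute penalty
    cfg = RunConfig(n_iterations=300, burn_in=100, seed=1, keep_history=True)
    res = model.fit(config=cfg)
    # the thresholded iterates carry literal zeros (the trajectory average
    # blurs them whenever a coordinate leaves the dead zone even once)
    lay = model.layout
    for beta in res.trace.beta_history[100:]:
        assert int(np.sum(lay.unpack(beta).A == 0.0)) > 0
    norms = np.linalg.norm(res.params.B, axis=1)
    np.testing.assert_allclose(norms, 1.0, atol=1e-10)


def test_exploratory_huge_penalty_kills_all_loadings(rng):
    Y = (rng.random((200, 8)) < 0.5).astype(int)
    model = ExploratoryIFA(Y, 2, lam=1e4)
    res = model.fit(config=RunConfig(n_iterations=100, burn_in=20, seed=0))
    assert np.all(res.params.A == 0.0)


def test_ifa_data_validation():
    with pytest.raises(ValueError):
        IfaData(Y=np.array([[0, 2]]))
    with pytest.raises(ValueError, match="all zero"):
        IfaData(Y=np.array([[0, 1]]), Q=np.array([[0, 0], [1, 0]]))
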