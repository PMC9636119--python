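import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_ifa_instance():
    """A small confirmatory IFA instance with known feasible parameters."""
    from lvprox.ifa import IfaData, IfaLayout, IfaParams

    rng = np.random.default_rng(42)
    J, K, N = 6, 2, 50
    Q = np.array([[1, 0], [1, 0], [0, 1], [0, 1], [1, 1], [1, 1]])
    d = rng.normal(size=J)
    A = rng.uniform(0.5, 1.5, size=(J, K)) * Q
    rho = 0.4
    B = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    params = IfaParams(d, A, B)
    Xi = rng.standard_normal((N, K)) @ B.T
    from scipy.special import expit
    P = expit(d[None, :] + Xi @ A.T)
    Y = (rng.random(P.shape) < P).astype(int)
    data = IfaData(Y=Y, Q=Q)
    layout = IfaLayout(J, K, Q=Q)
    return data, layout, params, Xi


@pytest.fixture(scope="session")
def small_rlca_instance():
    """A small restricted LCA instance (K=2) with feasible parameters."""
    from lvprox.prox import build_constraints
    from lvprox.rlca import RlcaParams, dina_theta

    rng = np.random.default_rng(7)
    Q = np.array([[1, 0], [0, 1], [1, 1], [1, 0], [0, 1]])
    J, K = Q.shape
    s = rng.uniform(0.05, 0.2, size=J)
    g = rng.uniform(0.05, 0.2, size=J)
    theta = dina_theta(s, g, Q)
    nu = np.array([0.0, 0.3, -0.2, 0.1])
    params = RlcaParams(theta, nu)
    z = rng.integers(0, 4, size=40)
    from scipy.special import expit
    P = expit(theta[:, z].T)
    Y = (rng.random(P.shape) < P).astype(int)
    return Y, Q, params, z, build_constraints(Q)
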