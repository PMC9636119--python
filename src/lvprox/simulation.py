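"""Synthetic-data generators, evaluation metrics and study drivers.

Three benchmark designs are built in:

* Study I  — confirmatory IFA, N=1000, J=20, K=2, factor correlation 0.4;
  items 1-5 measure factor 1 only, 6-10 factor 2 only, 11-20 both.  Five
  stochastic algorithm variants are compared against the quadrature-EM
  solution started from the generating parameters.
* Study II — exploratory IFA with L1 regularisation, J=80, K=5, a fixed
  sparse loading pattern (each factor measured by 10 unique items plus
  shared pairwise/triple-wise blocks), compound-symmetric correlation 0.4,
  penalty lambda_N = sqrt(log J / N).
* Study III — restricted latent class model, J=20, K=4, a fixed Q-matrix;
  data generated from a DINA model with slipping/guessing ~ U(0.05, 0.2)
  and uniform profiles, fitted under the general monotone-constrained model.

Intercepts are drawn N(0,1) and nonzero loadings U(0.5, 1.5) in the IFA
designs.  Loading-matrix error uses the column-swap mean squared error,
minimising over column permutations to absorb factor-label indeterminacy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .ifa import ConfirmatoryIFA, ExploratoryIFA, IfaData, IfaParams, em_reference
from .optimizer import RunConfig
from .rlca import RestrictedLCA, RlcaParams, dina_theta

__all__ = [
    "StudyDesign",
    "study_design",
    "study1_q_matrix",
    "study2_loading_pattern",
    "study3_q_matrix",
    "generate_ifa_params",
    "generate_ifa_data",
    "generate_rlca_truth",
    "generate_rlca_data",
    "mse_block",
    "mse_loadings_swap",
    "MseReport",
    "run_study",
]


# ---------------------------------------------------------------------------
# printed design matrices
# ---------------------------------------------------------------------------

def study1_q_matrix():
    """items 1-5 -> factor 1, 6-10 -> factor 2, 11-20 -> both."""
    Q = np.zeros((20, 2), dtype=int)
    Q[:5, 0] = 1
    Q[5:10, 1] = 1
    Q[10:, :] = 1
    return Q

#: Study II sparse loading membership (1-based item ids per factor)
_STUDY2_ITEMS = {
    1: list(range(1, 11)) + [51, 52, 54, 57, 61, 62, 64, 67,
                             71, 72, 73, 75, 76, 78],
    2: list(range(11, 21)) + [51, 53, 55, 58, 61, 63, 65, 68,
                              71, 72, 74, 75, 77, 79],
    3: list(range(21, 31)) + [52, 53, 56, 59, 62, 63, 66, 69,
                              71, 73, 74, 76, 77, 80],
    4: list(range(31, 41)) + [54, 55, 56, 60, 64, 65, 66, 70,
                              72, 73, 74, 78, 79, 80],
    5: list(range(41, 51)) + [57, 58, 59, 60, 67, 68, 69, 70,
                              75, 76, 77, 78, 79, 80],
}


def study2_loading_pattern():
    """Binary 80 x 5 support pattern of the true loading matrix."""
    Q = np.zeros((80, 5), dtype=int)
    for k, items in _STUDY2_ITEMS.items():
        Q[np.asarray(items) - 1, k - 1] = 1
    return Q


def study3_q_matrix():
    """20 items x 4 attributes design matrix (rows = items)."""
    rows = [
        "10001000100011011110",
        "01000100010010101101",
        "00100010001001101011",
        "00010001000100010111",
    ]
    return np.array([[int(c) for c in r] for r in rows], dtype=int).T


@dataclass
class StudyDesign:
    """One benchmark design; ``study_design`` fills in the printed values."""

    study: str                       # "I", "II" or "III"
    N: int
    J: int
    K: int
    Q: np.ndarray                    # support pattern / design matrix
    correlation: float = 0.4         # IFA factor correlation (compound symm.)
    n_replications: int = 50
    loading_low: float = 0.5
    loading_high: float = 1.5
    sg_low: float = 0.05             # DINA slipping/guessing support
    sg_high: float = 0.2
    redraw_truth: bool = True        # redraw item parameters per replication


def study_design(study, N=None, n_replications=None, redraw_truth=None):
    study = str(study).upper()
    if study == "I":
        d = StudyDesign(study="I", N=1000, J=20, K=2, Q=study1_q_matrix(),
                        n_replications=100, redraw_truth=False)
    elif study == "II":
        d = StudyDesign(study="II", N=1000, J=80, K=5,
                        Q=study2_loading_pattern(), n_replications=50)
    elif study == "III":
        d = StudyDesign(study="III", N=1000, J=20, K=4, Q=study3_q_matrix(),
                        n_replications=50)
    else:
        raise ValueError(f"unknown study {study!r}")
    if N is not None:
        d.N = int(N)
    if n_replications is not None:
        d.n_replications = int(n_replications)
    if redraw_truth is not None:
        d.redraw_truth = bool(redraw_truth)
    return d


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _compound_symmetric_chol(K, rho):
    Sigma = np.full((K, K), rho)
    np.fill_diagonal(Sigma, 1.0)
    return np.linalg.cholesky(Sigma)


def generate_ifa_params(design, rng):
    """True IFA parameters: d ~ N(0,1); nonzero a ~ U(low, high) on the
    design's support; B the Cholesky factor of the compound-symmetric
    correlation matrix."""
    if design.study not in ("I", "II"):
        raise ValueError("IFA parameter generation applies to Studies I and II")
    d = rng.standard_normal(design.J)
    A = np.zeros((design.J, design.K))
    mask = design.Q.astype(bool)
    A[mask] = rng.uniform(design.loading_low, design.loading_high,
                          size=int(mask.sum()))
    B = _compound_symmetric_chol(design.K, design.correlation)
    return IfaParams(d, A, B)


def generate_ifa_data(params, N, rng):
    """Draw xi ~ N(0, Sigma) then Bernoulli responses."""
    Xi = rng.standard_normal((N, params.K)) @ params.B.T
    P = expit(params.d[None, :] + Xi @ params.A.T)
    Y = (rng.random(P.shape) < P).astype(np.int8)
    return Y


def generate_rlca_truth(design, rng):
    """DINA truth: s, g ~ U(0.05, 0.2), theta from the DINA rule, nu = 0."""
    if design.study != "III":
        raise ValueError("restricted LCA generation applies to Study III")
    s = rng.uniform(design.sg_low, design.sg_high, size=design.J)
    g = rng.uniform(design.sg_low, design.sg_high, size=design.J)
    theta = dina_theta(s, g, design.Q)
    nu = np.zeros(2 ** design.K)
    return RlcaParams(theta, nu), s, g


def generate_rlca_data(truth, N, rng):
    """Uniform profiles (nu = 0) and Bernoulli responses from theta."""
    C = truth.n_profiles
    pi = truth.class_probs
    z = rng.choice(C, size=N, p=pi)
    P = expit(truth.theta[:, z].T)                 # (N, J)
    Y = (rng.random(P.shape) < P).astype(np.int8)
    return Y, z


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mse_block(est, truth, mask=None):
    """Mean squared difference over (optionally masked) entries."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError("shape mismatch")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        est, truth = est[mask], truth[mask]
    return float(np.mean((est - truth) ** 2))


def mse_loadings_swap(A_hat, A_true):
    """Column-swap loading MSE: min over column permutations of A_hat of
    ||A' - A_true||_F^2 / (J K).  Exact enumeration (K <= 8)."""
    A_hat = np.asarray(A_hat, dtype=float)
    A_true = np.asarray(A_true, dtype=float)
    if A_hat.shape != A_true.shape:
        raise ValueError("shape mismatch")
    J, K = A_true.shape
    if K > 8:
        raise ValueError("column-swap MSE supports K <= 8")
    # cost[k, k'] = squared distance when column k' of A_hat plays column k
    cost = ((A_hat[:, None, :] - A_true[:, :, None]) ** 2).sum(axis=0)
    best = np.inf
    for perm in itertools.permutations(range(K)):
        tot = cost[np.arange(K), perm].sum()
        if tot < best:
            best = tot
    return float(best / (J * K))


# ---------------------------------------------------------------------------
# study drivers
# ---------------------------------------------------------------------------

@dataclass
class MseReport:
    """Per-replication MSEs with empirical quantile summaries."""

    study: str
    N: int
    per_replication: pd.DataFrame
    failures: list = field(default_factory=list)

    def quantiles(self, qs=(0.25, 0.5, 0.75)):
        """Empirical quantiles (linear interpolation) across replications."""
        out = self.per_replication.quantile(list(qs))
        out.index = [f"{int(q * 100)}%" for q in qs]
        return out

    def median(self, column):
        return float(self.per_replication[column].median())

    def to_json_dict(self):
        q = self.quantiles()
        return {
            "study": self.study,
            "N": self.N,
            "n_replications": int(len(self.per_replication)),
            "quantiles": {c: {r: float(q.loc[r, c]) for r in q.index}
                          for c in q.columns},
            "n_failures": len(self.failures),
        }


def _default_config(study, variant="USP", seed=None, n_iterations=None,
                    burn_in=None):
    if study == "I":
        return RunConfig(n_iterations=n_iterations or 1000,
                         burn_in=500 if burn_in is None else burn_in,
                         adaptive_stop=False, variant=variant, seed=seed)
    # Studies II/III: adaptive stop at threshold 1e-3 with an iteration cap
    # as the compute budget (the estimate is insensitive to the cap well
    # before the successive-difference noise floor reaches the threshold)
    cap = n_iterations or (600 if study == "II" else 1500)
    return RunConfig(n_iterations=cap,
                     burn_in=50 if burn_in is None else burn_in,
                     adaptive_stop=True, stop_threshold=1e-3, stop_window=3,
                     variant=variant, seed=seed)


def run_study(design, variants=("USP",), seed=0, n_iterations=None,
              burn_in=None, em_kwargs=None, progress=False):
    """Run one benchmark study end to end and return an :class:`MseReport`.

    Replication r uses an independent child RNG stream spawned from `seed`.
    Study I scores each variant against the quadrature-EM solution of the
    same dataset; Studies II and III score against the generating truth.
    """
    rng_root = np.random.default_rng(seed)
    truth_rng = np.random.default_rng(rng_root.integers(2 ** 31 - 1))
    rep_seeds = rng_root.integers(2 ** 31 - 1, size=design.n_replications)

    fixed_truth = None
    if not design.redraw_truth:
        if design.study in ("I", "II"):
            fixed_truth = generate_ifa_params(design, truth_rng)
        else:
            fixed_truth = generate_rlca_truth(design, truth_rng)[0]

    rows = []
    failures = []
    for r in range(design.n_replications):
        rng = np.random.default_rng(rep_seeds[r])
        try:
            if design.study == "I":
                rows.append(_replicate_study1(design, fixed_truth, variants,
                                              rng, n_iterations, burn_in,
                                              em_kwargs or {}))
            elif design.study == "II":
                truth = fixed_truth or generate_ifa_params(design, rng)
                rows.append(_replicate_study2(design, truth, rng,
                                              n_iterations, burn_in))
            else:
                truth = fixed_truth
                if truth is None:
                    truth = generate_rlca_truth(design, rng)[0]
                rows.append(_replicate_study3(design, truth, rng,
                                              n_iterations, burn_in))
        except Exception as exc:  # noqa: BLE001 - record, keep going
            failures.append((r, repr(exc)))
        if progress:
            print(f"  replication {r + 1}/{design.n_replications} done")
    report = MseReport(study=design.study, N=design.N,
                       per_replication=pd.DataFrame(rows), failures=failures)
    return report


def _replicate_study1(design, truth, variants, rng, n_iterations, burn_in,
                      em_kwargs):
    Y = generate_ifa_data(truth, design.N, rng)
    data = IfaData(Y=Y, Q=design.Q)
    em = em_reference(data, start=truth, **em_kwargs)
    mask = design.Q.astype(bool)
    row = {}
    for variant in variants:
        cfg = _default_config("I", variant,
                              seed=int(rng.integers(2 ** 31 - 1)),
                              n_iterations=n_iterations, burn_in=burn_in)
        model = ConfirmatoryIFA(Y, design.Q)
        res = model.fit(start=truth, config=cfg)
        est = res.params
        row[f"d_{variant}"] = mse_block(est.d, em.d)
        row[f"a_{variant}"] = mse_block(est.A, em.A, mask=mask)
        row[f"sigma12_{variant}"] = float((est.sigma[0, 1] - em.sigma[0, 1]) ** 2)
    return row


def _replicate_study2(design, truth, rng, n_iterations, burn_in):
    Y = generate_ifa_data(truth, design.N, rng)
    lam = np.sqrt(np.log(design.J) / design.N)
    cfg = _default_config("II", "USP", seed=int(rng.integers(2 ** 31 - 1)),
                          n_iterations=n_iterations, burn_in=burn_in)
    model = ExploratoryIFA(Y, design.K, lam=lam)
    res = model.fit(config=cfg)
    return {
        "loading_swap_mse": mse_loadings_swap(res.params.A, truth.A),
        "n_zero_loadings": int(np.sum(res.params.A == 0.0)),
        "n_iterations": res.n_iterations,
    }


def _replicate_study3(design, truth, rng, n_iterations, burn_in):
    Y, _ = generate_rlca_data(truth, design.N, rng)
    cfg = _default_config("III", "USP", seed=int(rng.integers(2 ** 31 - 1)),
                          n_iterations=n_iterations, burn_in=burn_in)
    model = RestrictedLCA(Y, design.Q)
    res = model.fit(config=cfg)
    return {
        "theta_mse": mse_block(res.params.theta, truth.theta),
        "nu_mse": mse_block(res.params.nu[1:], truth.nu[1:]),
        "n_iterations": res.n_iterations,
    }
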