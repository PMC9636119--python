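"""Quasi-Newton stochastic proximal engine.

The engine alternates a stochastic step (refreshing the latent variables from
their posterior, exactly or by one MCMC sweep) with a scaled proximal step

    beta_t = Prox_{gamma_t, g}^{D_t}( beta_{t-1} - gamma_t * D_t^{-1} * G_t ),

where ``G_t`` is the complete-data gradient of the smooth objective part at
the current latent draw and ``D_t`` is a running, truncated diagonal estimate
of the marginal objective's Hessian built from complete-data first and second
derivatives (a Louis-type identity).  The estimator is the Polyak-Ruppert
average of the post-burn-in iterates.

Model back-ends plug in through :class:`ModelBackend`; the engine itself is
model agnostic.  Five algorithm variants are supported:

====== ====================================================================
USP     full algorithm (quasi-Newton scaling, averaging, gamma_t = t^-0.51)
USP-PPG perturbed proximal gradient: identity scaling (c1 = c2), averaging
USP-RM1 quasi-Newton scaling, no averaging (last iterate returned)
USP-RM2 as RM1 with the Robbins-Monro step size gamma_t = 1/t
StEM    stochastic EM: full maximization of the complete-data objective,
        with averaging
====== ====================================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Protocol

import numpy as np

logger = logging.getLogger("lvprox")

__all__ = [
    "StepSchedule",
    "ScalingState",
    "RunConfig",
    "RunTrace",
    "ModelBackend",
    "NumericalError",
    "step_size",
    "truncate",
    "update_scaling",
    "polyak_ruppert_average",
    "stopping_check",
    "ByproductAverager",
    "louis_hessian",
    "run",
    "GaussianMeanModel",
    "VARIANTS",
]

VARIANTS = ("USP", "USP-PPG", "USP-RM1", "USP-RM2", "StEM")


class NumericalError(RuntimeError):
    """Divergence or non-finite values, annotated with iteration context."""


# ---------------------------------------------------------------------------
# step size schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepSchedule:
    """Step size gamma_t = mu * t^(-1/2 - epsilon), or 1/t in 'rm2' mode.

    The default (mu=1, epsilon=0.01) gives gamma_t = t^-0.51, which satisfies
    the stochastic-approximation conditions sum gamma = inf, sum gamma^2 < inf.
    """

    mu: float = 1.0
    epsilon: float = 0.01
    mode: str = "power"  # "power" or "rm2"

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.mode == "power" and not (0 < self.epsilon <= 0.5):
            raise ValueError("epsilon must lie in (0, 1/2]")
        if self.mode not in ("power", "rm2"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")

    def gamma(self, t):
        return step_size(t, self)


def step_size(t, schedule):
    """Evaluate the step-size schedule at iteration t >= 1."""
    if t < 1:
        raise ValueError("iteration index t must be >= 1")
    if schedule.mode == "rm2":
        return 1.0 / t
    return schedule.mu * float(t) ** (-0.5 - schedule.epsilon)


def truncate(x, c1, c2):
    """Clamp x into [c1, c2] (scalar or elementwise)."""
    if np.any(np.asarray(c1) > np.asarray(c2)):
        raise ValueError("truncation bounds must satisfy c1 <= c2")
    return np.clip(x, c1, c2)


# ---------------------------------------------------------------------------
# diagonal quasi-Newton scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingState:
    """Running diagonal Hessian estimate.

    ``delta1`` tracks E[d2H/db_i^2 - (dH/db_i)^2], ``delta2`` tracks
    E[dH/db_i]; their combination delta1 + delta2^2 estimates the marginal
    Hessian diagonal (Louis' identity).  ``d_avg`` is the iteration-averaged,
    truncated diagonal actually used as the metric; its entries always lie in
    [c1, c2].  Zero-initialised: the recursions forget initial conditions.
    """

    delta1: np.ndarray
    delta2: np.ndarray
    d_avg: np.ndarray
    c1: float
    c2: float
    t: int = 0

    @classmethod
    def initial(cls, p, c1, c2):
        if not (0 < c1 <= c2):
            raise ValueError("need 0 < c1 <= c2")
        return cls(delta1=np.zeros(p), delta2=np.zeros(p),
                   d_avg=np.full(p, c1), c1=c1, c2=c2, t=0)


def update_scaling(state, grad, hess_diag, gamma_t):
    """One scaling update (in place); returns the state.

    delta1 <- (1-g) delta1 + g (hess_diag - grad^2)
    delta2 <- (1-g) delta2 + g grad
    d_avg  <- ((t-1)/t) d_avg + (1/t) T(delta1 + delta2^2; c1, c2)
    """
    grad = np.asarray(grad, dtype=float)
    hess_diag = np.asarray(hess_diag, dtype=float)
    if grad.shape != state.delta1.shape or hess_diag.shape != state.delta1.shape:
        raise ValueError("gradient/hessian length mismatch with scaling state")
    g = gamma_t
    state.delta1 *= (1.0 - g)
    state.delta1 += g * (hess_diag - grad ** 2)
    state.delta2 *= (1.0 - g)
    state.delta2 += g * grad
    state.t += 1
    t = state.t
    cand = truncate(state.delta1 + state.delta2 ** 2, state.c1, state.c2)
    if t == 1:
        state.d_avg = cand
    else:
        state.d_avg *= (t - 1) / t
        state.d_avg += cand / t
    return state


# ---------------------------------------------------------------------------
# averaging and stopping
# ---------------------------------------------------------------------------

def polyak_ruppert_average(history, burn_in):
    """Arithmetic mean of history entries burn_in+1 .. n (1-based)."""
    history = np.asarray(history, dtype=float)
    n = history.shape[0]
    if n <= burn_in:
        raise ValueError(f"history length {n} must exceed burn-in {burn_in}")
    return history[burn_in:].mean(axis=0)


def stopping_check(recent_diffs, window, threshold):
    """True iff the last `window` successive max-norm differences are all
    below `threshold`; False when fewer than `window` differences exist."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(recent_diffs) < window:
        return False
    return all(d < threshold for d in list(recent_diffs)[-window:])


class ByproductAverager:
    """Running average of a posterior by-product m(y, xi | beta).

    Maintains the smoothed sequence M_t = M_{t-1} + gamma_t (m_t - M_{t-1})
    (initialised at the first observation) and the Polyak-Ruppert average of
    M_t over post-burn-in iterations.
    """

    def __init__(self, burn_in=0):
        self.burn_in = burn_in
        self.M = None
        self._sum = None
        self._count = 0
        self.t = 0

    def update(self, m, gamma_t):
        m = np.asarray(m, dtype=float)
        self.t += 1
        if self.M is None:
            self.M = m.copy()
        else:
            if m.shape != self.M.shape:
                raise ValueError("by-product shape changed mid-stream")
            self.M += gamma_t * (m - self.M)
        if self.t > self.burn_in:
            if self._sum is None:
                self._sum = np.zeros_like(self.M)
            self._sum += self.M
            self._count += 1
        return self

    @property
    def average(self):
        if self._count == 0:
            if self.M is None:
                raise ValueError("by-product averager received no values")
            return self.M.copy()
        return self._sum / self._count


# ---------------------------------------------------------------------------
# model back-end contract
# ---------------------------------------------------------------------------

class ModelBackend(Protocol):
    """Operations the engine requires from a model back-end."""

    n_params: int
    block_map: dict

    def initial_latent(self, beta, rng): ...
    def sample_latent(self, latent, beta, rng): ...
    def grad_and_diag_hess(self, latent, beta): ...
    def prox(self, beta_tilde, weights, gamma): ...
    def complete_data_objective(self, latent, beta): ...

    # optional: full maximization for StEM (a default is provided by run()),
    # and complete-data score/Hessian of log f for Louis-formula by-products:
    # loglik_score_full(latent, beta) -> (p,), loglik_hessian_full -> (p, p)


def _prox_newton_maximize(backend, latent, beta0, c1, c2, tol=1e-6, max_iter=500):
    """Full maximization of the complete-data objective (StEM M-step).

    Iterates the quasi-Newton proximal update with the truncated
    complete-data Hessian diagonal as metric, backtracking on the
    complete-data objective (the diagonal metric ignores cross-coordinate
    coupling, so a unit step can overshoot).  Exact in one step for
    quadratic objectives.
    """
    beta = np.array(beta0, dtype=float, copy=True)
    obj = backend.complete_data_objective(latent, beta)
    for _ in range(max_iter):
        grad, hess = backend.grad_and_diag_hess(latent, beta)
        d = truncate(hess, c1, c2)
        step = 1.0
        for _ls in range(25):
            beta_new = backend.prox(beta - step * grad / d, d, step)
            obj_new = backend.complete_data_objective(latent, beta_new)
            if obj_new <= obj + 1e-12 * max(1.0, abs(obj)):
                break
            step *= 0.5
        delta = float(np.max(np.abs(beta_new - beta)))
        beta, obj = beta_new, obj_new
        if delta < tol:
            break
    return beta


# ---------------------------------------------------------------------------
# run configuration / trace
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Engine configuration.

    With ``adaptive_stop=False`` exactly ``n_iterations`` steps run; otherwise
    iteration stops as soon as the last ``stop_window`` successive max-norm
    parameter differences all fall below ``stop_threshold`` (never before
    ``burn_in + stop_window`` steps, and never beyond ``n_iterations``).
    """

    n_iterations: int = 1000
    burn_in: int = 500
    schedule: StepSchedule = field(default_factory=StepSchedule)
    c1: float = 1e-2
    c2: float = 1e4
    adaptive_stop: bool = False
    stop_threshold: float = 1e-3
    stop_window: int = 3
    variant: str = "USP"
    keep_history: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.stop_window < 1:
            raise ValueError("stop_window must be >= 1")
        if not (0 < self.c1 <= self.c2):
            raise ValueError("need 0 < c1 <= c2")

    def resolve(self):
        """Apply variant-specific overrides (schedule / scaling bounds)."""
        cfg = self
        if cfg.variant == "USP-PPG" and cfg.c1 != cfg.c2:
            cfg = replace(cfg, c1=1.0, c2=1.0)
        if cfg.variant == "USP-RM2" and cfg.schedule.mode != "rm2":
            cfg = replace(cfg, schedule=StepSchedule(mode="rm2", mu=1.0, epsilon=0.01))
        return cfg

    def to_dict(self):
        return {
            "n_iterations": self.n_iterations,
            "burn_in": self.burn_in,
            "mu": self.schedule.mu,
            "epsilon": self.schedule.epsilon,
            "schedule_mode": self.schedule.mode,
            "c1": self.c1,
            "c2": self.c2,
            "adaptive_stop": self.adaptive_stop,
            "stop_threshold": self.stop_threshold,
            "stop_window": self.stop_window,
            "variant": self.variant,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        sched = StepSchedule(mu=d.pop("mu", 1.0), epsilon=d.pop("epsilon", 0.01),
                             mode=d.pop("schedule_mode", "power"))
        d.pop("keep_history", None)
        return cls(schedule=sched, **d)


@dataclass
class RunTrace:
    """Output of one engine run."""

    average: np.ndarray                 # the estimate (PR average, or last iterate)
    last: np.ndarray
    n_iterations: int
    stop_iteration: int | None
    scaling: ScalingState | None
    beta_history: np.ndarray | None
    diff_history: np.ndarray
    byproducts: dict
    variant: str


def run(backend, beta0, config, rng=None, byproducts=None, latent0=None):
    """Run the stochastic proximal engine.

    Parameters
    ----------
    backend : ModelBackend
    beta0 : feasible starting parameter vector
    config : RunConfig
    rng : numpy Generator (created from config.seed when omitted)
    byproducts : optional dict name -> callable(latent, beta) -> array,
        accumulated with the smoothed-recursion + averaging machinery.
    """
    cfg = config.resolve()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    beta = np.array(beta0, dtype=float, copy=True)
    p = beta.shape[0]
    if p != backend.n_params:
        raise ValueError(f"beta0 has length {p}, model expects {backend.n_params}")

    scaling = ScalingState.initial(p, cfg.c1, cfg.c2)
    latent = latent0 if latent0 is not None else backend.initial_latent(beta, rng)
    averaging = cfg.variant in ("USP", "USP-PPG", "StEM")

    avg_sum = np.zeros(p)
    avg_count = 0
    history = [] if cfg.keep_history else None
    diffs = []
    bp = {name: ByproductAverager(burn_in=cfg.burn_in)
          for name in (byproducts or {})}

    stop_iteration = None
    t = 0
    while t < cfg.n_iterations:
        t += 1
        gamma_t = cfg.schedule.gamma(t)

        latent = backend.sample_latent(latent, beta, rng)
        grad, hess_diag = backend.grad_and_diag_hess(latent, beta)
        if not np.all(np.isfinite(grad)):
            bad = _offending_block(backend, grad)
            raise NumericalError(
                f"non-finite gradient at iteration {t} (block {bad})")

        if cfg.variant == "StEM":
            maximize = getattr(backend, "full_maximize", None)
            if maximize is not None:
                beta_new = maximize(latent, beta)
            else:
                beta_new = _prox_newton_maximize(backend, latent, beta,
                                                 cfg.c1, cfg.c2)
        else:
            update_scaling(scaling, grad, hess_diag, gamma_t)
            beta_tilde = beta - gamma_t * grad / scaling.d_avg
            beta_new = backend.prox(beta_tilde, scaling.d_avg, gamma_t)

        if not np.all(np.isfinite(beta_new)):
            bad = _offending_block(backend, beta_new)
            raise NumericalError(
                f"divergence (non-finite parameters) at iteration {t} "
                f"(block {bad})")

        diffs.append(float(np.max(np.abs(beta_new - beta))))
        beta = beta_new
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug("t=%d gamma=%.3g max|dbeta|=%.3g d_avg=[%.3g,%.3g]",
                         t, gamma_t, diffs[-1],
                         scaling.d_avg.min(), scaling.d_avg.max())

        if history is not None:
            history.append(beta.copy())
        if t > cfg.burn_in:
            avg_sum += beta
            avg_count += 1
        for name, fn in (byproducts or {}).items():
            bp[name].update(fn(latent, beta), gamma_t)

        if cfg.adaptive_stop and t > cfg.burn_in + cfg.stop_window:
            if stopping_check(diffs, cfg.stop_window, cfg.stop_threshold):
                stop_iteration = t
                break

    if averaging and avg_count > 0:
        estimate = avg_sum / avg_count
    else:
        estimate = beta.copy()

    return RunTrace(
        average=estimate,
        last=beta.copy(),
        n_iterations=t,
        stop_iteration=stop_iteration,
        scaling=scaling if cfg.variant != "StEM" else None,
        beta_history=np.asarray(history) if history is not None else None,
        diff_history=np.asarray(diffs),
        byproducts={name: a.average for name, a in bp.items()},
        variant=cfg.variant,
    )


def _offending_block(backend, vec):
    bad = np.flatnonzero(~np.isfinite(vec))
    if bad.size == 0:
        return "none"
    i = bad[0]
    for name, sl in getattr(backend, "block_map", {}).items():
        idx = np.arange(len(vec))[sl]
        if i in idx:
            return name
    return f"coordinate {i}"


# ---------------------------------------------------------------------------
# Louis-formula Hessian of the marginal log-likelihood
# ---------------------------------------------------------------------------

def louis_hessian(backend, beta, latent_stream, schedule=None, burn_in=0):
    """Monte-Carlo Hessian of the marginal log-likelihood at a fixed beta.

    Uses Louis' missing-information identity

        d2l = E[d2 log f + s s^T | y] - E[s | y] E[s | y]^T,

    with the conditional expectations estimated by the smoothed-recursion
    averages over a stream of posterior latent draws.  At fixed beta the
    appropriate recursion weight is 1/t (the running mean), which is the
    default; pass a slow-decay schedule only when tracking a drifting
    parameter.  The back-end must provide ``loglik_score_full`` and
    ``loglik_hessian_full`` (derivatives of the complete-data
    log-likelihood).  Symmetric by construction.
    """
    if schedule is None:
        schedule = StepSchedule(mode="rm2")
    acc1 = ByproductAverager(burn_in=burn_in)
    acc2 = ByproductAverager(burn_in=burn_in)
    n = 0
    for latent in latent_stream:
        n += 1
        gamma_t = schedule.gamma(n)
        s = backend.loglik_score_full(latent, beta)
        h = backend.loglik_hessian_full(latent, beta)
        acc1.update(h + np.outer(s, s), gamma_t)
        acc2.update(s, gamma_t)
    if n < 2:
        raise ValueError("Louis-formula estimate needs at least 2 latent draws")
    sbar = acc2.average
    out = acc1.average - np.outer(sbar, sbar)
    return 0.5 * (out + out.T)


# ---------------------------------------------------------------------------
# degenerate no-latent Gaussian model (reference/testing back-end)
# ---------------------------------------------------------------------------

class GaussianMeanModel:
    """y_i ~ N(beta, 1) with no latent variable and g == 0.

    The smallest instance of the back-end contract: the "posterior" is a point
    mass, the complete-data objective is the exact objective, and the MLE is
    the sample mean.  Used to validate the engine against closed forms.
    """

    def __init__(self, y):
        self.y = np.asarray(y, dtype=float).ravel()
        self.n_params = 1
        self.block_map = {"mean": slice(0, 1)}

    def initial_latent(self, beta, rng):
        return None

    def sample_latent(self, latent, beta, rng):
        return None

    def grad_and_diag_hess(self, latent, beta):
        n = self.y.size
        grad = np.array([n * beta[0] - self.y.sum()])
        hess = np.array([float(n)])
        return grad, hess

    def prox(self, beta_tilde, weights, gamma):
        return np.asarray(beta_tilde, dtype=float).copy()

    def complete_data_objective(self, latent, beta):
        return float(0.5 * np.sum((self.y - beta[0]) ** 2))

    def loglik_score_full(self, latent, beta):
        return np.array([self.y.sum() - self.y.size * beta[0]])

    def loglik_hessian_full(self, latent, beta):
        return np.array([[-float(self.y.size)]])


class GaussianRandomEffectModel:
    """y_i | xi_i ~ N(xi_i, 1), xi_i ~ N(beta, 1); marginal MLE = sample mean.

    A one-parameter latent model with exact posterior sampling
    (xi_i | y_i ~ N((beta + y_i)/2, 1/2)), used to exercise the engine with a
    genuinely stochastic gradient against the closed-form MLE.
    """

    def __init__(self, y):
        self.y = np.asarray(y, dtype=float).ravel()
        self.n_params = 1
        self.block_map = {"mean": slice(0, 1)}

    def initial_latent(self, beta, rng):
        return self.y.copy()

    def sample_latent(self, latent, beta, rng):
        m = 0.5 * (beta[0] + self.y)
        return m + rng.normal(size=self.y.size) * np.sqrt(0.5)

    def grad_and_diag_hess(self, latent, beta):
        n = self.y.size
        grad = np.array([n * beta[0] - latent.sum()])
        hess = np.array([float(n)])
        return grad, hess

    def prox(self, beta_tilde, weights, gamma):
        return np.asarray(beta_tilde, dtype=float).copy()

    def complete_data_objective(self, latent, beta):
        return float(0.5 * np.sum((self.y - latent) ** 2)
                     + 0.5 * np.sum((latent - beta[0]) ** 2))
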