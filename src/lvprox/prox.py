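"""Scaled proximal operators.

All operators solve, for a diagonal metric ``D = diag(w)`` and step ``gamma``,

    Prox(t) = argmin_x  g(x) + (1/(2*gamma)) * sum_i w_i (x_i - t_i)^2 ,

for a specific non-smooth ``g``: an L1 penalty (soft-thresholding), the
indicator of a unit sphere intersected with a zero pattern (factor-correlation
Cholesky rows), or the indicator of the monotone constraint polyhedron of a
restricted latent class item.  Pure projections do not depend on ``gamma``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "soft_threshold",
    "project_sphere_weighted",
    "project_item_monotone",
    "MonotoneConstraintSet",
    "build_constraints",
    "ConstraintPenaltySpec",
    "make_prox",
]


def soft_threshold(beta_tilde, kappa):
    """Elementwise soft-thresholding: the prox of ``kappa * |x|``.

    Returns ``beta_tilde - kappa`` above ``kappa``, ``beta_tilde + kappa``
    below ``-kappa`` and 0 inside the dead zone.  ``kappa`` may be a scalar
    or an array broadcastable to ``beta_tilde``.
    """
    beta_tilde = np.asarray(beta_tilde, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("soft-threshold parameter kappa must be nonnegative")
    return np.sign(beta_tilde) * np.maximum(np.abs(beta_tilde) - kappa, 0.0)


def _sphere_norm2(lam, w, t):
    b = w * t / (w + lam)
    return float(b @ b)


def project_sphere_weighted(b_tilde, weights, free_mask=None):
    """Project onto the unit sphere under a diagonal metric.

    Solves ``min sum_l w_l (b_l - t_l)^2  s.t. ||b|| = 1`` with masked
    coordinates forced to zero.  The KKT system gives
    ``b_l = w_l t_l / (w_l + lam)`` with the multiplier ``lam`` the root of
    ``||b(lam)|| = 1`` on ``(-min w, inf)``; the norm is strictly decreasing
    there, so the root is found by bracketing and Brent's method.  The
    trust-region "hard case" (target orthogonal to the smallest-weight
    coordinates, residual norm deficit) is handled by placing the remaining
    mass on the first such coordinate.
    """
    b_tilde = np.asarray(b_tilde, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("sphere projection weights must be strictly positive")
    K = b_tilde.shape[0]
    if free_mask is None:
        free_mask = np.ones(K, dtype=bool)
    free_mask = np.asarray(free_mask, dtype=bool)
    if not free_mask.any():
        raise ValueError("sphere projection needs at least one free coordinate")

    t = b_tilde[free_mask]
    w = weights[free_mask]
    out = np.zeros(K)

    if np.max(np.abs(t)) == 0.0:
        warnings.warn(
            "degenerate sphere projection target (all free coordinates zero); "
            "falling back to the first free coordinate",
            RuntimeWarning,
        )
        out[np.flatnonzero(free_mask)[0]] = 1.0
        return out

    wmin = w.min()
    min_mask = w <= wmin * (1.0 + 1e-12)
    b = np.empty_like(t)
    if np.all(t[min_mask] == 0.0):
        # possible hard case: norm stays bounded as lam -> -wmin
        denom = w[~min_mask] + (-wmin)
        partial = w[~min_mask] * t[~min_mask] / denom
        n0 = float(partial @ partial)
        if n0 < 1.0:
            b[:] = 0.0
            b[~min_mask] = partial
            b[np.flatnonzero(min_mask)[0]] = np.sqrt(1.0 - n0)
            out[free_mask] = b
            return out

    # bracket the multiplier
    scale = max(wmin, 1.0)
    eps = 1e-8 * scale
    lo = -wmin + eps
    while _sphere_norm2(lo, w, t) <= 1.0 and eps > 1e-18 * scale:
        eps *= 0.1
        lo = -wmin + eps
    hi = max(w.max() * float(np.linalg.norm(t)), wmin) + 1.0
    while _sphere_norm2(hi, w, t) >= 1.0:
        hi *= 2.0
    if _sphere_norm2(lo, w, t) <= 1.0:
        lam = lo  # numerically at the hard-case boundary
    else:
        lam = brentq(lambda l: _sphere_norm2(l, w, t) - 1.0, lo, hi,
                     xtol=1e-15, rtol=8.9e-16, maxiter=200)
    b = w * t / (w + lam)
    b /= np.linalg.norm(b)  # exact unit norm
    out[free_mask] = b
    return out


# ---------------------------------------------------------------------------
# Monotone constraint set for restricted latent class items
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonotoneConstraintSet:
    """Per-item partition of attribute profiles induced by a Q-matrix.

    ``capable[j, a]`` is True when profile ``a`` dominates the skill
    requirement of item ``j`` (``alpha >= q_j`` componentwise).  The feasible
    set requires, for each item: all capable values equal, every incapable
    value between the all-zero profile's value and the shared capable value.
    """

    Q: np.ndarray            # (J, K) binary
    capable: np.ndarray      # (J, 2^K) boolean
    profiles: np.ndarray     # (2^K, K) binary, row a = bit pattern of a

    @property
    def n_items(self):
        return self.Q.shape[0]

    @property
    def n_profiles(self):
        return self.capable.shape[1]

    def is_feasible(self, theta, tol=1e-9):
        """Check the full constraint set for a (J, 2^K) theta matrix."""
        theta = np.asarray(theta, dtype=float)
        for j in range(self.n_items):
            cap = theta[j, self.capable[j]]
            if cap.max() - cap.min() > tol:
                return False
            inc = theta[j, ~self.capable[j]]
            if inc.size:
                c = cap.min()
                if inc.max() > c + tol:
                    return False
                if not self.capable[j, 0] and inc.min() < theta[j, 0] - tol:
                    return False
        return True


def profile_matrix(K):
    """All 2^K binary attribute profiles; attribute 1 is the low-order bit."""
    idx = np.arange(2 ** K)
    return (idx[:, None] >> np.arange(K)[None, :]) & 1


def build_constraints(Q):
    """Construct the monotone constraint structure from a binary Q-matrix."""
    Q = np.asarray(Q, dtype=int)
    if Q.ndim != 2 or not np.isin(Q, (0, 1)).all():
        raise ValueError("Q must be a binary items x attributes matrix")
    J, K = Q.shape
    profiles = profile_matrix(K)
    # alpha >= q_j componentwise
    capable = np.all(profiles[None, :, :] >= Q[:, None, :], axis=2)
    return MonotoneConstraintSet(Q=Q, capable=capable, profiles=profiles)


def _pwq_argmin(w_base, t_base, w_cond, t_cond, active_above):
    """Exact minimizer of a 1-D convex piecewise-quadratic function.

    Minimizes ``sum w_base (v - t_base)^2 + sum w_cond (v - t_cond)^2 * 1[cond]``
    where the condition is ``t_cond > v`` (``active_above=True``, targets above
    v are pulled down to it) or ``t_cond < v``.  The derivative is piecewise
    linear and nondecreasing; scan the breakpoints for its root.
    """
    Wb = float(np.sum(w_base))
    Sb = float(np.sum(w_base * t_base))
    m = len(t_cond)
    if m == 0:
        return Sb / Wb
    order = np.argsort(t_cond)
    ts = t_cond[order]
    ws = w_cond[order]
    if active_above:
        # on segment v in (ts[i-1], ts[i]): active = i..m-1 (suffix)
        seg_w = Wb + np.concatenate([np.cumsum(ws[::-1])[::-1], [0.0]])
        seg_s = Sb + np.concatenate([np.cumsum((ws * ts)[::-1])[::-1], [0.0]])
    else:
        # on segment v in (ts[i-1], ts[i]): active = 0..i-1 (prefix)
        seg_w = Wb + np.concatenate([[0.0], np.cumsum(ws)])
        seg_s = Sb + np.concatenate([[0.0], np.cumsum(ws * ts)])
    # the derivative 2(W v - S) is continuous and nondecreasing in v: take
    # the first segment whose right-end derivative is nonnegative and clamp
    # the segment root into it (robust to breakpoint-boundary round-off)
    for i in range(m + 1):
        hi = np.inf if i == m else ts[i]
        if i == m or seg_w[i] * hi - seg_s[i] >= 0.0:
            v = seg_s[i] / seg_w[i]
            lo = -np.inf if i == 0 else ts[i - 1]
            return float(min(max(v, lo), hi))
    raise AssertionError("unreachable")


def project_item_monotone(theta_tilde, weights, capable_mask):
    """Project one item's profile values onto its monotone constraint set.

    Solves ``min sum_a w_a (x_a - t_a)^2`` subject to: all capable profiles
    share one value ``c``; every incapable value lies in ``[x_0, c]`` where
    ``x_0`` is the all-zero profile's value.  After eliminating the interior
    values (which clip to ``[x_0, c]``) the objective separates into convex
    piecewise quadratics ``A(c) + B(x_0)``, each minimized exactly by a
    breakpoint scan; if the unconstrained pair violates ``c >= x_0`` the
    optimum ties at the overall weighted mean.
    """
    t = np.asarray(theta_tilde, dtype=float)
    w = np.asarray(weights, dtype=float)
    cap = np.asarray(capable_mask, dtype=bool)
    if np.any(w <= 0):
        raise ValueError("projection weights must be strictly positive")
    if not cap.any():
        raise ValueError("capable class is empty (the all-ones profile is always capable)")

    out = np.empty_like(t)
    if cap.all():
        # item requires no skill: a single shared value, no inequalities
        out[:] = np.sum(w * t) / np.sum(w)
        return out

    # feasible input short-circuits: exact projection of a feasible point
    cap_vals = t[cap]
    if cap_vals.max() == cap_vals.min():
        c = cap_vals[0]
        inc = t[~cap]
        if inc.max() <= c and inc.min() >= t[0] and not cap[0]:
            return t.copy()

    inc_idx = np.flatnonzero(~cap)
    mid_idx = inc_idx[inc_idx != 0]  # incapable profiles other than all-zero
    t_mid = t[mid_idx]
    w_mid = w[mid_idx]

    c_star = _pwq_argmin(w[cap], t[cap], w_mid, t_mid, active_above=True)
    x0_star = _pwq_argmin(np.array([w[0]]), np.array([t[0]]),
                          w_mid, t_mid, active_above=False)
    if c_star < x0_star:
        c_star = x0_star = float(np.sum(w * t) / np.sum(w))

    out[cap] = c_star
    out[0] = x0_star
    out[mid_idx] = np.clip(t_mid, x0_star, c_star)
    return out


# ---------------------------------------------------------------------------
# Composite operators
# ---------------------------------------------------------------------------

@dataclass
class ConstraintPenaltySpec:
    """Blockwise description of the non-smooth part ``g = R2 + indicator``.

    ``kind`` selects the composite: "none" (identity), "sphere" (confirmatory
    factor analysis: correlation Cholesky rows on unit spheres), "l1+sphere"
    (exploratory factor analysis with an L1 loading penalty), or "monotone"
    (restricted latent class items).  Index arrays refer to positions in the
    flat parameter vector.
    """

    kind: str
    l1_indices: np.ndarray | None = None       # coordinates carrying lam*|x|
    lam: float = 0.0                           # absolute L1 weight
    sphere_rows: list = field(default_factory=list)    # list of index arrays
    monotone_items: list = field(default_factory=list) # list of (indices, capable)

    def to_dict(self):
        return {
            "kind": self.kind,
            "lam": self.lam,
            "n_l1": 0 if self.l1_indices is None else int(len(self.l1_indices)),
            "n_sphere_rows": len(self.sphere_rows),
            "n_monotone_items": len(self.monotone_items),
        }


_KNOWN_KINDS = {"none", "l1", "sphere", "l1+sphere", "monotone"}


def make_prox(spec):
    """Build the composite scaled proximal operator for a penalty spec.

    Returns ``prox(beta_tilde, weights, gamma) -> beta``.  The composite
    applies, blockwise: identity to unconstrained coordinates,
    soft-thresholding with ``kappa_i = lam * gamma / w_i`` to penalized ones,
    weighted sphere projection to each correlation row, and the monotone
    projection to each restricted latent class item.  Blocks are separable,
    so the composite equals the exact joint prox.
    """
    if spec.kind not in _KNOWN_KINDS:
        raise ValueError(f"unknown constraint/penalty spec kind {spec.kind!r}")

    def prox(beta_tilde, weights, gamma):
        beta = np.array(beta_tilde, dtype=float, copy=True)
        if spec.kind in ("l1", "l1+sphere") and spec.l1_indices is not None \
                and spec.lam > 0:
            idx = spec.l1_indices
            kappa = spec.lam * gamma / weights[idx]
            beta[idx] = soft_threshold(beta[idx], kappa)
        if spec.kind in ("sphere", "l1+sphere"):
            for row in spec.sphere_rows:
                beta[row] = project_sphere_weighted(beta[row], weights[row])
        if spec.kind == "monotone":
            for idx, capable in spec.monotone_items:
                beta[idx] = project_item_monotone(beta[idx], weights[idx], capable)
        return beta

    return prox
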