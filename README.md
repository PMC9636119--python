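# lvprox

Quasi-Newton **stochastic proximal** estimation for latent variable models
with intractable marginal likelihoods, non-smooth penalties and complex
parameter constraints.

`lvprox` computes penalized / constrained marginal maximum likelihood
estimates

    beta_hat = argmin_{beta in B}  -l(beta) + R(beta)

by alternating a *stochastic step* — refreshing the latent variables from
their posterior, exactly or by one Gibbs scan with adaptive rejection
sampling — with a *scaled proximal step*

    beta_t = Prox_{gamma_t, g}^{D_t}( beta_{t-1} - gamma_t D_t^{-1} G_t ),

where `G_t` is the complete-data gradient at the sampled latents, `D_t` a
running, truncated diagonal quasi-Newton metric built from complete-data
first and second derivatives (a Louis-type identity), `gamma_t = t^(-0.51)`,
and the proximal operator handles the non-smooth penalty and the feasible
set exactly (soft-thresholding, sphere projection, monotone-cone
projection).  The estimator is the Polyak–Ruppert average of the
post-burn-in iterates; the marginal-likelihood Hessian (for standard
errors) falls out as a by-product via Louis' formula.

Two model families ship as statsmodels-style model classes:

* **Item factor analysis** — binary responses, logistic items, correlated
  Gaussian factors with the correlation matrix Cholesky-parameterised on
  unit-norm rows.  `ConfirmatoryIFA(Y, Q)` (zero constraints from a design
  matrix) and `ExploratoryIFA(Y, K, lam=...)` (L1 / elastic-net loading
  penalty, rotation-free sparse solutions).
* **Restricted latent class analysis** — `RestrictedLCA(Y, Q)`: binary
  skill profiles, categorical prior, and the Q-matrix-induced monotone
  constraint set (profiles mastering an item's skills share the maximal
  success logit) enforced exactly at every iteration.

It is aimed at psychometric and biostatistical settings — educational and
clinical questionnaires, cognitive diagnosis, symptom checklists — where
the latent dimension makes quadrature EM infeasible and penalties or
inequality constraints defeat plain stochastic approximation.

## Worked example

Fit the monotone-constrained latent class model to a synthetic cognitive
diagnosis dataset (20 items, 4 skills, N = 1000, DINA-generated):

```python
import numpy as np
from lvprox import RestrictedLCA, mse_block
from lvprox.simulation import (generate_rlca_data, generate_rlca_truth,
                               study_design)

design = study_design("III", N=1000)
rng = np.random.default_rng(42)
truth, s, g = generate_rlca_truth(design, rng)
Y, _ = generate_rlca_data(truth, design.N, rng)

model = RestrictedLCA(Y, design.Q)
result = model.fit(n_iterations=1500, burn_in=50, adaptive_stop=True,
                   stop_threshold=1e-3, seed=1)

print("feasible:", result.constraints_satisfied())
print("theta MSE vs truth:", round(mse_block(result.params.theta, truth.theta), 3))
print("nu MSE vs truth:", round(mse_block(result.params.nu[1:], truth.nu[1:]), 3))
```

prints

```
feasible: True
theta MSE vs truth: 0.185
nu MSE vs truth: 0.044
```

`theta MSE` is the mean squared error of the item success logits over all
items and profiles (0.185 here matches the benchmark median at this sample
size), `nu MSE` the error of the 15 free class-membership logits, and
`feasible: True` confirms the estimate satisfies every equality and
inequality of the constraint set — the proximal step projects exactly, so
this holds by construction.  For item 1 the fit recovers a capable-profile
logit of 1.65 (truth 1.61) against a no-skill logit of −2.23 (truth −1.63).

The same surface drives the factor models:

```python
from lvprox import ExploratoryIFA
# Y: binary N x J response matrix; penalty weight sqrt(log J / N)
model = ExploratoryIFA(Y, K=5, lam=np.sqrt(np.log(Y.shape[1]) / Y.shape[0]))
result = model.fit(n_iterations=600, burn_in=50, seed=0)
result.params.A        # sparse-oriented loading matrix
result.params.sigma    # estimated factor correlations
```

A CLI mirrors the library (`lvprox fit-ifa-conf / fit-ifa-l1 / fit-rlca /
simulate / study / validate`), reading headerless CSV matrices and writing
CSV + JSON results.

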