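"""Marginal likelihood of a causal configuration via the approximate Laplace method.

Given summary data D = (beta_hat, S, R) for a locus, the likelihood of the
observed marginal estimates under a joint effect vector beta is the
multivariate normal

    beta_hat | beta  ~  MVN( S R S^-1 beta,  S R S ),

with S = diag(SE).  For a causal configuration m (a set of d variant
indices) the marginal likelihood pi_m(D) integrates the product of this
likelihood and the piMOM prior over the d active effects.  Writing
f(beta) = -log likelihood - log prior (constants independent of beta
dropped), the *approximate* Laplace method evaluates everything at the
plug-in joint estimate

    beta~_m = R_m^-1 beta_hat_m

instead of the mode of f:

    log pi_m(D) ~= -f(beta~) + (d/2) log 2pi - 1/2 log|H| + 1/2 g' H^-1 g,

where g and H are the closed-form gradient and Hessian of f at beta~.
This skips the inner optimization entirely; when R_m or H is numerically
ill-conditioned we fall back to the conventional Laplace method (minimize
f, drop the gradient-correction term).

All matrix algebra is restricted to the d active rows/columns; the full
P x P matrix S^-1 R S^-1 is never formed.  The dropped normalizing
constant of the likelihood is identical across models, so differences of
``log_ml`` (Bayes factors) are exact.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.special import gammaln

from .data import LDMatrix, SummaryData
from .exceptions import NumericalError, ValidationError
from .priors import Hyperparameters

#: condition-number threshold above which R_m is treated as ill-conditioned
COND_MAX = 1e8
#: ridge added to R_m when ill-conditioned
RIDGE = 1e-6
#: magnitude to which exactly-zero plug-in coordinates are nudged
ZERO_NUDGE = 1e-8


@dataclasses.dataclass
class ModelState:
    """A causal configuration with its cached posterior quantities.

    ``members`` is the strictly increasing index tuple m; ``beta_tilde``
    the plug-in joint effect estimate; ``log_ml`` the cached log marginal
    likelihood; ``resid_stat`` the length-P residual correlation statistic
    beta_hat - R @ beta_full (beta_full embeds beta_tilde in the active
    slots), which drives the sampler's add weights; ``used_fallback``
    records a conventional-Laplace evaluation.
    """

    members: tuple[int, ...]
    beta_tilde: np.ndarray
    log_ml: float
    resid_stat: np.ndarray
    used_fallback: bool

    @property
    def dim(self) -> int:
        return len(self.members)


def _active(model_idx) -> np.ndarray:
    idx = np.asarray(model_idx, dtype=int)
    if idx.size == 0:
        raise ValidationError("a model must contain at least one variant")
    if len(set(idx.tolist())) != idx.size:
        raise ValidationError(f"duplicate indices in model {idx.tolist()}")
    return idx


def joint_effect_estimate(model_idx, data: SummaryData, ld: LDMatrix,
                          *, return_flag: bool = False):
    """Plug-in joint effect estimate beta~ = R_m^-1 beta_hat_m.

    If cond(R_m) exceeds ``COND_MAX`` the ridge-regularized system
    (R_m + RIDGE*I) is solved instead and the ill-conditioning flag is
    set, which routes the marginal-likelihood evaluation to the
    conventional-Laplace fallback.
    """
    idx = _active(model_idx)
    rm = ld.r[np.ix_(idx, idx)]
    bm = data.beta_hat[idx]
    flagged = bool(np.linalg.cond(rm) > COND_MAX)
    if flagged:
        rm = rm + RIDGE * np.eye(idx.size)
    beta = np.linalg.solve(rm, bm)
    return (beta, flagged) if return_flag else beta


def _slices(model_idx, data: SummaryData, ld: LDMatrix):
    """Active-index slices: (idx, A = (S^-1 R S^-1)_mm, z_over_s = z_m/s_m)."""
    idx = _active(model_idx)
    s = data.se[idx]
    a = ld.r[np.ix_(idx, idx)] / np.outer(s, s)
    return idx, a, data.beta_hat[idx] / s ** 2


def f_neg_log(beta_m, model_idx, data: SummaryData, ld: LDMatrix,
              hyper: Hyperparameters) -> float:
    """Negative log likelihood-times-prior at ``beta_m`` (constants dropped).

    f(b) = -d[(r/2)ln tau - ln Gamma(r/2)] + ((r+1)/2) sum ln(b_i^2)
           + sum tau/b_i^2 + 1/2 b' A b - (z/s)' b,
    with A the active slice of S^-1 R S^-1.
    """
    beta = np.atleast_1d(np.asarray(beta_m, dtype=float))
    if np.any(beta == 0.0):
        raise ValidationError("f is singular at beta components equal to 0")
    idx, a, zs = _slices(model_idx, data, ld)
    tau, r = hyper.tau, hyper.r
    d = idx.size
    prior = (-d * (0.5 * r * np.log(tau) - gammaln(0.5 * r))
             + 0.5 * (r + 1) * np.sum(np.log(beta ** 2))
             + tau * np.sum(beta ** -2.0))
    lik = 0.5 * beta @ a @ beta - zs @ beta
    return float(prior + lik)


def grad_hessian(beta_m, model_idx, data: SummaryData, ld: LDMatrix,
                 hyper: Hyperparameters):
    """Closed-form gradient and Hessian of f at ``beta_m``.

    g = (r+1)/b - 2 tau/b^3 + A b - z/s
    H = A + diag(6 tau/b^4 - (r+1)/b^2)
    """
    beta = np.atleast_1d(np.asarray(beta_m, dtype=float))
    if np.any(beta == 0.0):
        raise ValidationError("gradient undefined at beta components equal to 0")
    _, a, zs = _slices(model_idx, data, ld)
    tau, r = hyper.tau, hyper.r
    g = (r + 1) / beta - 2.0 * tau / beta ** 3 + a @ beta - zs
    h = a + np.diag(6.0 * tau / beta ** 4 - (r + 1) / beta ** 2)
    return g, h


def _nudge(beta: np.ndarray) -> np.ndarray:
    """Move exactly-zero coordinates off the piMOM singularity."""
    if np.any(beta == 0.0):
        beta = beta.copy()
        beta[beta == 0.0] = ZERO_NUDGE
    return beta


def log_marginal(model_idx, data: SummaryData, ld: LDMatrix,
                 hyper: Hyperparameters):
    """Log marginal likelihood of a configuration (plus fallback indicator).

    Returns ``(log_ml, used_fallback)``.  The approximate-Laplace value is
    -f(beta~) + (d/2) ln 2pi - 1/2 ln|H| + 1/2 g'H^-1 g via a Cholesky
    factorization of H; if R_m was ill-conditioned or H is not positive
    definite, f is minimized by BFGS from beta~ (conventional Laplace).
    """
    idx = _active(model_idx)
    beta_t, flagged = joint_effect_estimate(idx, data, ld, return_flag=True)
    beta_t = _nudge(beta_t)
    d = idx.size
    if not flagged:
        g, h = grad_hessian(beta_t, idx, data, ld, hyper)
        try:
            low = np.linalg.cholesky(h)
        except np.linalg.LinAlgError:
            flagged = True
        else:
            half_logdet = np.sum(np.log(np.diag(low)))
            hinv_g = scipy.linalg.cho_solve((low, True), g)
            f_val = f_neg_log(beta_t, idx, data, ld, hyper)
            log_ml = (-f_val + 0.5 * d * np.log(2.0 * np.pi)
                      - half_logdet + 0.5 * g @ hinv_g)
            return float(log_ml), False
    # conventional Laplace: optimize f, no gradient correction
    res = scipy.optimize.minimize(
        f_neg_log, beta_t, args=(idx, data, ld, hyper),
        jac=lambda b, *a: grad_hessian(b, *a)[0],
        method="BFGS", options={"maxiter": 500, "gtol": 1e-8})
    if not (res.success or np.linalg.norm(res.jac) < 1e-5):
        raise NumericalError(
            f"conventional-Laplace optimization failed for model {idx.tolist()}: "
            f"{res.message}")
    beta_star = _nudge(np.atleast_1d(res.x))
    _, h_star = grad_hessian(beta_star, idx, data, ld, hyper)
    sign, logdet = np.linalg.slogdet(h_star)
    if sign <= 0:
        raise NumericalError(
            f"Hessian not positive definite at the optimum for model {idx.tolist()}")
    log_ml = -res.fun + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet
    return float(log_ml), True


def model_state(model_idx, data: SummaryData, ld: LDMatrix,
                hyper: Hyperparameters) -> ModelState:
    """Build the cached :class:`ModelState` for a configuration.

    Bundles the plug-in estimate, log marginal likelihood and the
    residual statistic beta_hat - R[:, m] @ beta~ used by the sampler's
    add/delete proposal weights.
    """
    idx = _active(model_idx)
    order = np.argsort(idx)
    idx = idx[order]
    log_ml, fallback = log_marginal(idx, data, ld, hyper)
    beta_t = _nudge(joint_effect_estimate(idx, data, ld))
    resid = data.beta_hat - ld.r[:, idx] @ beta_t
    return ModelState(members=tuple(int(i) for i in idx),
                      beta_tilde=beta_t, log_ml=float(log_ml),
                      resid_stat=resid, used_fallback=fallback)
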