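"""Prior distributions: piMOM effect-size prior and beta-binomial dimension prior.

Two priors drive the model search.  For the effect sizes of the variants in
a causal configuration we use a product of independent inverse-moment
(iMOM) densities,

    pi(beta | tau, r) = prod_k  tau^(r/2)/Gamma(r/2) * |beta_k|^-(r+1)
                                * exp(-tau / beta_k^2),

a *nonlocal* prior: its density is exactly zero at beta_k = 0, which
separates null from non-null models far more sharply than a zero-centred
Gaussian.  r=1 gives Cauchy-like tails.  The scale tau sets the smallest
effect size deemed detectable and is chosen from the GWAS sample size by
:func:`select_tau`.

For the number of causal variants d we use a beta-binomial prior
truncated to 1 <= d <= K, with a=1 and b=P^u: under the substitution
b = P^u, larger u concentrates mass on smaller models, which is the knob
used to guard against LD-reference misspecification.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import betaln, gammaincinv, gammaln

from .exceptions import ValidationError

_SQRT_PI = np.sqrt(np.pi)


@dataclasses.dataclass
class Hyperparameters:
    """Hyperparameters of the fine-mapping model and sampler.

    Parameters
    ----------
    tau
        iMOM scale; ``None`` means "select from sample size" via
        :func:`select_tau` (resolved by the pipeline, not here).
    r
        iMOM tail parameter; r=1 (default) gives Cauchy-like tails.
    u
        Dimension-prior sparsity exponent, b = P^u.  Default 2.0 for
        in-sample LD; 2.25 is recommended when the LD comes from an
        external reference panel.
    a
        First beta-binomial shape parameter (default 1).
    k_max
        Maximum model dimension K (must satisfy K < P).
    alpha
        Credible-set level in (0, 1).
    n_iter, burn_in
        MCMC chain length and discarded initial iterations.
    seed
        Seed for the sampler's random stream.
    per_set_alpha
        If True, each credible set targets coverage alpha; if False
        (default) sets target alpha**(1/l*) so the joint coverage across
        the l* sets is at least alpha.
    """

    tau: float | None = None
    r: int = 1
    u: float = 2.0
    a: float = 1.0
    k_max: int = 10
    alpha: float = 0.95
    n_iter: int = 12500
    burn_in: int = 2500
    seed: int = 0
    per_set_alpha: bool = False

    def __post_init__(self) -> None:
        if self.tau is not None and not self.tau > 0:
            raise ValidationError(f"tau={self.tau} must be > 0")
        if self.r < 1:
            raise ValidationError("r must be a positive integer")
        if not self.u > 1:
            raise ValidationError("u must exceed 1")
        if not self.a > 0:
            raise ValidationError("a must be > 0")
        if self.k_max < 1:
            raise ValidationError("k_max must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0,1)")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValidationError("need 0 <= burn_in < n_iter")

    def b(self, p: int) -> float:
        """Second beta-binomial shape parameter, b = P^u (never stored)."""
        return float(p) ** self.u


def pimom_logpdf(beta_vec, tau: float, r: int = 1) -> float:
    """Log density of the product inverse-moment prior at ``beta_vec``.

    Returns -inf (not an error) if any component is exactly zero — the
    defining property of a nonlocal prior.
    """
    if not tau > 0:
        raise ValidationError(f"tau={tau} must be > 0")
    if r < 1:
        raise ValidationError("r must be a positive integer")
    beta = np.atleast_1d(np.asarray(beta_vec, dtype=float))
    if np.any(beta == 0.0):
        return -np.inf
    d = beta.size
    return float(d * (0.5 * r * np.log(tau) - gammaln(0.5 * r))
                 - (r + 1) * np.sum(np.log(np.abs(beta)))
                 - tau * np.sum(beta ** -2.0))


def select_tau(n: int, z_q: float = 3.29, q: float = 0.05, r: int = 1) -> float:
    """Choose the iMOM scale tau from the GWAS sample size.

    tau is the unique scale for which an effect drawn from the marginal
    iMOM(tau, r) prior exceeds the detectability threshold z_q/sqrt(n) in
    magnitude with probability 1-q.  Under w = tau/beta^2 the marginal is
    w ~ Gamma(r/2, 1), so the condition inverts in closed form:

        tau = (z_q^2 / n) * gammaincinv(r/2, 1 - q).

    For r=1 this reduces to (z_q/sqrt(n))^2 * erfinv(1-q)^2.  Defaults
    z_q=3.29, q=0.05.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    if not z_q > 0:
        raise ValidationError("z_q must be > 0")
    if not 0 < q < 1:
        raise ValidationError("q must lie in (0,1)")
    if r < 1:
        raise ValidationError("r must be a positive integer")
    return float(z_q ** 2 / n * gammaincinv(0.5 * r, 1.0 - q))


def imom_mode(tau: float, r: int = 1) -> float:
    """|beta| at which the marginal iMOM density is maximal: sqrt(2*tau/(r+1))."""
    return float(np.sqrt(2.0 * tau / (r + 1)))


def dim_log_prior(d: int, p: int, hyper: Hyperparameters) -> float:
    """Unnormalized log prior for model dimension ``d`` at a P-variant locus.

    ln C(P,d) + ln B(a+d, P-d+b) - ln B(a,b) with b = P^u, computed
    entirely through log-gamma; -inf outside the truncated support
    1 <= d <= K.  Only ratios of these values enter the sampler, so no
    normalization over the support is applied here.
    """
    if d < 0:
        raise ValidationError(f"model dimension d={d} must be >= 0")
    if p < 2:
        raise ValidationError("need at least 2 variants")
    if d == 0 or d > hyper.k_max:
        return -np.inf
    a, b = hyper.a, hyper.b(p)
    log_choose = gammaln(p + 1) - gammaln(d + 1) - gammaln(p - d + 1)
    return float(log_choose + betaln(a + d, p - d + b) - betaln(a, b))


def dim_prior_pmf(p: int, hyper: Hyperparameters) -> np.ndarray:
    """Normalized dimension prior over d = 1..K (for reporting)."""
    logs = np.array([dim_log_prior(d, p, hyper)
                     for d in range(1, hyper.k_max + 1)])
    logs -= logs.max()
    w = np.exp(logs)
    return w / w.sum()
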