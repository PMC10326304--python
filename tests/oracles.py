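"""Independent numerical oracles used by the test suite.

These deliberately re-derive quantities along different routes from the
implementation: dense P-dimensional multivariate-normal densities via
scipy factorizations, the piMOM density written out term by term, and
adaptive quadrature for the marginal likelihood.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln
from scipy.stats import multivariate_normal

import finimom as fm


class DenseNegLog:
    """-log[likelihood * prior] via dense P-dimensional MVN evaluation,
    up to the same model-independent constant the implementation drops:
    c = 0.5 ln|2 pi Sigma| + 0.5 beta_hat' Sigma^-1 beta_hat,
    with Sigma = S R S.  The factorization is computed once; each call
    costs one dense P-vector solve."""

    def __init__(self, model_idx, data, ld, hyper):
        self.idx = list(model_idx)
        p = data.p
        s_mat = np.diag(data.se)
        self.sigma = s_mat @ ld.r @ s_mat
        self.chol = cho_factor(self.sigma)
        self.mean_map = s_mat @ ld.r / data.se  # beta -> likelihood mean
        self.beta_hat = data.beta_hat
        self.tau, self.r = hyper.tau, hyper.r
        self.p = p

    def __call__(self, beta_m):
        beta = np.zeros(self.p)
        beta[self.idx] = beta_m
        resid = self.beta_hat - self.mean_map @ beta
        quad = resid @ cho_solve(self.chol, resid)
        quad0 = self.beta_hat @ cho_solve(self.chol, self.beta_hat)
        neg_ll_minus_const = 0.5 * (quad - quad0)  # normalizers cancel
        tau, r = self.tau, self.r
        lp = sum(0.5 * r * np.log(tau) - gammaln(r / 2)
                 - (r + 1) * np.log(abs(b)) - tau / b ** 2
                 for b in np.atleast_1d(beta_m))
        return neg_ll_minus_const - lp


def dense_f(beta_m, model_idx, data, ld, hyper):
    """One-shot dense evaluation (see :class:`DenseNegLog`), cross-checked
    against scipy.stats.multivariate_normal for independence."""
    p = data.p
    s_mat = np.diag(data.se)
    sigma = s_mat @ ld.r @ s_mat
    beta = np.zeros(p)
    beta[list(model_idx)] = beta_m
    mean = s_mat @ ld.r @ (beta / data.se)
    ll = multivariate_normal(mean=mean, cov=sigma).logpdf(data.beta_hat)
    tau, r = hyper.tau, hyper.r
    lp = sum(0.5 * r * np.log(tau) - gammaln(r / 2)
             - (r + 1) * np.log(abs(b)) - tau / b ** 2
             for b in np.atleast_1d(beta_m))
    const = -multivariate_normal(mean=np.zeros(p), cov=sigma).logpdf(data.beta_hat)
    return -(ll + lp) - const


def quadrature_log_marginal(model_idx, data, ld, hyper, width: float = 12.0):
    """ln of the likelihood-times-prior integral by adaptive quadrature,
    on the same constant convention as ``finimom.log_marginal``.

    Integrates exp(-(f - f0)) over a box of +- ``width`` posterior SEs
    around the plug-in joint estimate (f0 = f at the plug-in, a shift
    that keeps the integrand O(1)) and adds f0 back.  Signals are strong
    enough in all uses that opposite-sign mass is negligible.  Supports
    d in {1, 2}.
    """
    idx = list(model_idx)
    f = DenseNegLog(idx, data, ld, hyper)
    bt = fm.joint_effect_estimate(idx, data, ld)
    s = data.se[idx]
    f0 = f(bt)
    if len(idx) == 1:
        val, _ = integrate.quad(
            lambda b: np.exp(f0 - f([b])),
            bt[0] - width * s[0], bt[0] + width * s[0], limit=200)
    elif len(idx) == 2:
        val, _ = integrate.dblquad(
            lambda b2, b1: np.exp(f0 - f([b1, b2])),
            bt[0] - width * s[0], bt[0] + width * s[0],
            lambda _: bt[1] - width * s[1], lambda _: bt[1] + width * s[1],
            epsabs=1e-10, epsrel=1e-9)
    else:
        raise ValueError("quadrature oracle supports d <= 2")
    return np.log(val) - f0


def ols_slope_se(x, y):
    """Textbook two-pass simple-regression slope and SE for one column."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(y)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    resid = (y - ym) - slope * (x - xm)
    se = np.sqrt(np.sum(resid ** 2) / (n - 2) / sxx)
    return slope, se
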