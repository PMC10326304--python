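"""Shared fixtures and helpers for the finimom test suite.

The expensive simulation batches are session-scoped so the calibration,
recovery and evaluation tests share one set of replicates.
"""

from __future__ import annotations

import numpy as np
import pytest

import finimom as fm


def make_sumstats(z=None, beta_hat=None, se=None, n=5000, var_y=1.0,
                  eaf=0.3, units="standardized") -> fm.SummaryData:
    """Construct a SummaryData directly from z-scores or effect sizes."""
    if beta_hat is None:
        z = np.asarray(z, dtype=float)
        se = np.full(z.size, 1.0 / np.sqrt(n)) if se is None else np.asarray(se, float)
        beta_hat = z * se
    else:
        beta_hat = np.asarray(beta_hat, dtype=float)
        se = np.asarray(se, dtype=float)
    p = beta_hat.size
    return fm.SummaryData(
        variant_id=np.array([f"v{i}" for i in range(p)]),
        chrom=np.full(p, "1"), pos=np.arange(p) + 1,
        effect_allele=np.full(p, "A"), other_allele=np.full(p, "G"),
        eaf=np.full(p, float(eaf)) if np.isscalar(eaf) else np.asarray(eaf, float),
        beta_hat=beta_hat, se=se, n=n, var_y=var_y, units=units)


def ar1_ld(p: int, rho: float) -> fm.LDMatrix:
    """AR(1) correlation matrix rho^|i-j|."""
    idx = np.arange(p)
    return fm.LDMatrix(r=rho ** np.abs(idx[:, None] - idx[None, :]))


def run_replicate(seed: int, *, p=500, n=5000, c=1, h2=0.03,
                  min_separation=10, rho=0.9):
    """One simulate -> fine-map replicate under the default study conditions."""
    spec = fm.LocusSpec(p=p, rho=rho, seed=seed)
    scen = fm.ScenarioSpec(n=n, c=c, h2=h2, min_separation=min_separation,
                           seed=seed)
    data, ld, causal, _ = fm.simulate_locus(spec, scen, np.random.default_rng(seed))
    out = fm.fine_map(data, ld, fm.Hyperparameters(seed=seed))
    return {"result": out.result, "samples": out.samples, "causal": causal,
            "seed": seed}


@pytest.fixture(scope="session")
def single_signal_batch():
    """100 replicates of the calibration scenario: P=500, N=5000, one causal
    variant explaining 3% of phenotypic variance, in-sample LD, seeds 1..100."""
    return [run_replicate(seed) for seed in range(1, 101)]


@pytest.fixture(scope="session")
def two_signal_batch():
    """80 replicates with two causal variants (P=100, N=5000, h2=0.03) used
    for pooled credible-set calibration (enough replicates that the pooled
    one- and two-signal set count exceeds 200)."""
    return [run_replicate(seed, p=100, c=2) for seed in range(201, 281)]
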