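"""High-level fine-mapping pipeline: conditioning, sampling, summarizing.

:func:`fine_map` is the programmatic equivalent of ``finimom run``:
standardize the summary statistics, optionally clump near-duplicate
variants and screen for LD inconsistencies, resolve hyperparameter
defaults (tau from the sample size, u from the LD provenance), run the
MCMC, and summarize the draws into PIPs, the dimension posterior, and
credible sets.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .data import LDMatrix, SummaryData, standardize
from .posterior import FineMapResult, credible_sets, expand_clumps
from .preprocess import ClumpMap, clump_variants, ld_consistency_check
from .priors import Hyperparameters, select_tau
from .sampler import PosteriorSamples, run_mcmc

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineOutput:
    """Everything ``fine_map`` produced, for serialization and inspection.

    ``data``/``ld`` are the post-conditioning inputs the sampler actually
    saw (clumped and/or with flagged variants dropped), so result indices
    refer to their rows.
    """

    result: FineMapResult
    samples: PosteriorSamples
    data: SummaryData
    ld: LDMatrix
    hyper: Hyperparameters
    clump_map: ClumpMap | None = None
    ld_flagged: list[int] = dataclasses.field(default_factory=list)


def resolve_hyper(data: SummaryData, ld: LDMatrix,
                  hyper: Hyperparameters | None = None) -> Hyperparameters:
    """Fill hyperparameter defaults that depend on the data.

    tau=None resolves via :func:`select_tau` from the GWAS sample size;
    a fresh default ``Hyperparameters`` gets u=2.0 for in-sample LD and
    u=2.25 for a reference panel.
    """
    if hyper is None:
        hyper = Hyperparameters(u=2.0 if ld.in_sample else 2.25)
    if hyper.tau is None:
        hyper = dataclasses.replace(hyper, tau=select_tau(data.n, r=hyper.r))
    return hyper


def fine_map(data: SummaryData, ld: LDMatrix,
             hyper: Hyperparameters | None = None, *,
             clump_r2: float | None = None,
             ld_check: str | None = None,
             rng: np.random.Generator | int | None = None) -> PipelineOutput:
    """Fine-map one locus from summary statistics and an LD matrix.

    Parameters
    ----------
    clump_r2
        If set, collapse variants with pairwise r^2 above this threshold
        before sampling; their proxies are re-attached to credible sets.
    ld_check
        ``None`` (skip), ``"warn"`` (log flagged variants) or ``"drop"``
        (remove them before sampling).  Meant for out-of-sample LD.
    rng
        Seed or generator for the sampler; defaults to ``hyper.seed``.
    """
    hyper = resolve_hyper(data, ld, hyper)
    if data.units == "per_allele":
        data = standardize(data)

    clump_map = None
    if clump_r2 is not None:
        data, ld, clump_map = clump_variants(data, ld, clump_r2)
        logger.info("clumping at r2=%g kept %d representatives", clump_r2, data.p)

    flagged: list[int] = []
    if ld_check is not None:
        flagged = ld_consistency_check(data, ld)
        if flagged:
            logger.warning("LD consistency check flagged %d variant(s): %s",
                           len(flagged), [str(data.variant_id[j]) for j in flagged])
        if ld_check == "drop" and flagged:
            keep = [j for j in range(data.p) if j not in set(flagged)]
            data, ld = data.subset(keep), ld.subset(keep)

    logger.info("sampling: P=%d tau=%.6g r=%d u=%g K=%d iter=%d burn=%d",
                data.p, hyper.tau, hyper.r, hyper.u, hyper.k_max,
                hyper.n_iter, hyper.burn_in)
    samples = run_mcmc(data, ld, hyper, rng)
    logger.info("acceptance rate %.3f", samples.accept_rate)
    result = credible_sets(samples, ld)
    if clump_map is not None:
        result = expand_clumps(result, clump_map)
    return PipelineOutput(result=result, samples=samples, data=data, ld=ld,
                          hyper=hyper, clump_map=clump_map, ld_flagged=flagged)
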