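"""Posterior summaries: PIPs, the dimension posterior, and credible sets.

A credible set at level alpha is a set of variants that contains a true
causal variant with posterior probability above alpha.  The number of
sets is read off the posterior distribution of the model dimension: with
l* the modal number of signals, the draws are conditioned on dimension
l* and partitioned into l* clusters seeded by the highest
conditional-inclusion variants, with the remaining variants attached to
the seed they are most correlated with.  Each cluster is then grown, in
decreasing order of conditional inclusion frequency, until the fraction
of conditional draws intersecting the set reaches the per-set level
alpha_l.  By default alpha_l = alpha**(1/l*), so that the l* sets jointly
achieve coverage at least alpha; ``per_set_alpha`` in the hyperparameters
restores alpha_l = alpha.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd

from .data import LDMatrix
from .exceptions import DegeneratePosteriorError, ValidationError
from .sampler import PosteriorSamples


@dataclasses.dataclass
class CredibleSet:
    """One credible set: members, attained conditional coverage, and the
    conditional inclusion frequency of each member (aligned with members)."""

    members: list[int]
    coverage: float
    member_cond_pip: list[float]
    proxies: dict[int, list[int]] = dataclasses.field(default_factory=dict)

    @property
    def size(self) -> int:
        """Number of members (clump proxies excluded)."""
        return len(self.members)


@dataclasses.dataclass
class FineMapResult:
    """Full posterior summary for one locus."""

    pip: np.ndarray
    dim_posterior: np.ndarray
    credible_sets: list[CredibleSet]
    l_star: int
    alpha: float
    alpha_l: float

    def to_json(self) -> str:
        return json.dumps({
            "alpha": self.alpha,
            "alpha_per_set": self.alpha_l,
            "l_star": self.l_star,
            "dim_posterior": self.dim_posterior.tolist(),
            "credible_sets": [
                {"members": cs.members, "coverage": cs.coverage,
                 "member_cond_pip": cs.member_cond_pip,
                 "proxies": {str(k): v for k, v in cs.proxies.items()}}
                for cs in self.credible_sets],
        }, indent=1)

    def to_frame(self, variant_id=None) -> pd.DataFrame:
        """One row per variant: id, pip, credible-set index, conditional pip."""
        p = len(self.pip)
        set_idx = np.full(p, -1)
        cond = np.full(p, np.nan)
        for k, cs in enumerate(self.credible_sets):
            for j, cp in zip(cs.members, cs.member_cond_pip):
                set_idx[j] = k
                cond[j] = cp
        ids = variant_id if variant_id is not None else np.arange(p)
        return pd.DataFrame({"ID": ids, "PIP": self.pip, "CS": set_idx,
                             "COND_PIP": cond})


def compute_pips(samples: PosteriorSamples) -> np.ndarray:
    """PIP_j = fraction of retained draws whose model includes variant j."""
    if samples.n_draws < 1:
        raise ValidationError("no retained draws")
    counts = np.zeros(samples.p)
    for m in samples.models:
        counts[list(m)] += 1.0
    return counts / samples.n_draws


def dimension_posterior(samples: PosteriorSamples) -> np.ndarray:
    """Empirical pmf of the model dimension over 1..K (sums to one)."""
    if samples.n_draws < 1:
        raise ValidationError("no retained draws")
    k = samples.hyper.k_max
    counts = np.bincount(samples.dims, minlength=k + 1)[1:k + 1]
    return counts / samples.n_draws


def credible_sets(samples: PosteriorSamples, ld: LDMatrix,
                  alpha: float | None = None) -> FineMapResult:
    """Construct level-alpha credible sets from the retained draws.

    Conditions on the modal dimension l* (ties to the smaller l), seeds
    l* clusters with the highest conditional-PIP variants, assigns every
    other variant seen in the conditional draws to the seed with maximal
    |r| (ties to the higher conditional-PIP seed), and grows each cluster
    by conditional inclusion frequency until the fraction of conditional
    draws intersecting it reaches alpha_l.
    """
    hyper = samples.hyper
    if alpha is None:
        alpha = hyper.alpha
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0,1)")
    if samples.n_draws < 100:
        warnings.warn(f"only {samples.n_draws} retained draws; credible sets "
                      "may be unstable", stacklevel=2)

    pip = compute_pips(samples)
    dim_post = dimension_posterior(samples)
    l_star = int(np.argmax(dim_post)) + 1  # argmax takes the smallest l on ties

    cond_draws = [set(m) for m in samples.models if len(m) == l_star]
    n_cond = len(cond_draws)
    cond_counts = np.zeros(samples.p)
    for m in cond_draws:
        cond_counts[list(m)] += 1.0
    present = np.flatnonzero(cond_counts > 0)
    if present.size < l_star:
        raise DegeneratePosteriorError(
            f"only {present.size} distinct variants appear in the {n_cond} "
            f"draws of modal dimension {l_star}")
    cond_pip = cond_counts / n_cond

    # seeds: l* highest conditional-PIP variants, ties to the lower index
    order = sorted(present.tolist(), key=lambda j: (-cond_pip[j], j))
    seeds = order[:l_star]

    clusters: dict[int, list[int]] = {s: [s] for s in seeds}
    for j in order[l_star:]:
        abs_r = np.abs(ld.r[j, seeds])
        best = np.flatnonzero(abs_r == abs_r.max())
        if best.size > 1:  # tie -> seed with higher conditional PIP
            best = sorted(best.tolist(),
                          key=lambda b: (-cond_pip[seeds[b]], seeds[b]))[:1]
        clusters[seeds[int(best[0])]].append(j)

    alpha_l = alpha if hyper.per_set_alpha else alpha ** (1.0 / l_star)
    sets = []
    for s in seeds:
        ranked = sorted(clusters[s], key=lambda j: (-cond_pip[j], j))
        members: list[int] = []
        covered = np.zeros(n_cond, dtype=bool)
        attained = 0.0
        for j in ranked:
            members.append(j)
            covered |= np.fromiter((j in m for m in cond_draws), bool, n_cond)
            attained = covered.mean()
            if attained >= alpha_l:
                break
        sets.append(CredibleSet(members=members, coverage=float(attained),
                                member_cond_pip=[float(cond_pip[j]) for j in members]))

    return FineMapResult(pip=pip, dim_posterior=dim_post, credible_sets=sets,
                         l_star=l_star, alpha=float(alpha), alpha_l=float(alpha_l))


def expand_clumps(result: FineMapResult, clump_map) -> FineMapResult:
    """Annotate credible sets with the clump proxies of their members.

    ``clump_map`` is a :class:`finimom.preprocess.ClumpMap` built on the
    same (reduced) variant indexing as the result.  Proxies are attached
    as annotations; they do not count toward set sizes.  An empty map
    returns the result unchanged.
    """
    if clump_map is None or not clump_map.rep_to_proxies:
        return result
    sets = []
    for cs in result.credible_sets:
        proxies = {}
        for j in cs.members:
            plist = clump_map.proxies_of_reduced(j)
            if plist:
                proxies[j] = plist
        sets.append(dataclasses.replace(cs, proxies=proxies))
    return dataclasses.replace(result, credible_sets=sets)
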