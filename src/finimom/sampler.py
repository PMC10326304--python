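"""Trans-dimensional MCMC over causal configurations.

The sampler walks the space of causal configurations m (index sets of size
1..K) with three move types:

* **add** — include an inactive variant, drawn with probability
  proportional to its squared correlation with the residuals of the
  current model, p_add ~ (beta_hat - R beta_curr)^2, floored so every
  variant keeps nonzero probability;
* **delete** — drop an active variant chosen uniformly;
* **swap** — drop a uniformly chosen active variant i and bring in an
  inactive variant j with probability proportional to r_ij^2, which keeps
  the proposal near an already good fit in high-LD groups.

The move type is drawn uniformly from the *feasible* moves (delete is
infeasible at d=1, add at d=K), and the proposal density q(m'|m) includes
that move-type factor.  Proposals are accepted with the Barker probability
a = m_p/(m_p + m_c), where each side is (dimension prior) x (marginal
likelihood) x (reverse/forward proposal density) — the optimal acceptance
rule for binary-inclusion samplers.

Marginal likelihoods are cached per configuration (keyed by the sorted
index tuple), so revisiting a model costs a dictionary lookup.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .data import LDMatrix, SummaryData
from .exceptions import ValidationError
from .marginal import ModelState, model_state
from .priors import Hyperparameters, dim_log_prior

logger = logging.getLogger(__name__)

#: floor applied to proposal weights so every variant keeps nonzero
#: probability and reverse-move densities stay finite
WEIGHT_FLOOR = 1e-12

_ADD, _DELETE, _SWAP = "add", "delete", "swap"


@dataclasses.dataclass
class Proposal:
    """A proposed transition with its forward/backward log densities."""

    move: str
    model_prop: tuple[int, ...]
    log_q_fwd: float
    log_q_bwd: float


@dataclasses.dataclass
class PosteriorSamples:
    """Retained MCMC draws over causal configurations."""

    models: list  # list of sorted index tuples, one per retained iteration
    dims: np.ndarray
    accept_rate: float
    p: int
    hyper: Hyperparameters
    rng_seed: int

    @property
    def n_draws(self) -> int:
        return len(self.models)


def init_model(data: SummaryData) -> tuple[int, ...]:
    """Initial configuration: the single variant with the largest |z|.

    Ties break to the lowest index (np.argmax convention).
    """
    return (int(np.argmax(np.abs(data.z))),)


def add_weights(state: ModelState, data: SummaryData, ld: LDMatrix) -> np.ndarray:
    """Probability of adding each variant given the current configuration.

    Weights are the squared residual statistic (beta_hat - R beta_full)^2,
    zero for active variants, floored at WEIGHT_FLOOR for inactive ones,
    and normalized to sum to one.
    """
    w = state.resid_stat ** 2
    w = np.maximum(w, WEIGHT_FLOOR)
    w[list(state.members)] = 0.0
    return w / w.sum()


def _swap_weights(out_idx: int, active, ld: LDMatrix) -> np.ndarray:
    """Swap-in probabilities: r^2 with the outgoing variant, over inactive."""
    w = ld.r[out_idx] ** 2
    w = np.maximum(w, WEIGHT_FLOOR)
    w[list(active)] = 0.0
    return w / w.sum()


def _feasible_moves(d: int, k_max: int) -> list[str]:
    moves = []
    if d < k_max:
        moves.append(_ADD)
    if d > 1:
        moves.append(_DELETE)
    moves.append(_SWAP)
    return moves


def _pick(weights: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an index from a normalized weight vector."""
    return int(np.searchsorted(np.cumsum(weights), rng.random(), side="right"))


def propose(state: ModelState, data: SummaryData, ld: LDMatrix,
            hyper: Hyperparameters, rng: np.random.Generator,
            get_state=None) -> Proposal:
    """Draw one add/delete/swap proposal from ``state``.

    ``get_state`` maps an index tuple to its (possibly cached)
    :class:`ModelState`; it is needed to evaluate the reverse add-weights
    of a delete move.  Defaults to an uncached construction.
    """
    if get_state is None:
        def get_state(m):
            return model_state(m, data, ld, hyper)

    members = state.members
    d = len(members)
    moves = _feasible_moves(d, hyper.k_max)
    log_nf = np.log(len(moves))
    move = moves[rng.integers(len(moves))]

    if move == _ADD:
        w = add_weights(state, data, ld)
        j = _pick(w, rng)
        prop = tuple(sorted(members + (j,)))
        moves_prop = _feasible_moves(d + 1, hyper.k_max)
        log_q_fwd = -log_nf + np.log(w[j])
        log_q_bwd = -np.log(len(moves_prop)) - np.log(d + 1)
    elif move == _DELETE:
        j = members[rng.integers(d)]
        prop = tuple(i for i in members if i != j)
        moves_prop = _feasible_moves(d - 1, hyper.k_max)
        w_rev = add_weights(get_state(prop), data, ld)
        log_q_fwd = -log_nf - np.log(d)
        log_q_bwd = -np.log(len(moves_prop)) + np.log(w_rev[j])
    else:  # swap
        i = members[rng.integers(d)]
        w = _swap_weights(i, members, ld)
        j = _pick(w, rng)
        prop = tuple(sorted([m for m in members if m != i] + [j]))
        w_rev = _swap_weights(j, prop, ld)
        log_q_fwd = -log_nf - np.log(d) + np.log(w[j])
        log_q_bwd = -log_nf - np.log(d) + np.log(w_rev[i])

    return Proposal(move=move, model_prop=prop,
                    log_q_fwd=float(log_q_fwd), log_q_bwd=float(log_q_bwd))


def barker_accept(log_mp: float, log_mc: float, rng: np.random.Generator) -> bool:
    """Accept with the Barker probability a = m_p / (m_p + m_c).

    Computed in log space as a = 1/(1 + exp(log_mc - log_mp)); saturates
    cleanly for |differences| up to and beyond 700.
    """
    delta = log_mc - log_mp
    if delta > 700.0:
        a = 0.0
    elif delta < -700.0:
        a = 1.0
    else:
        a = 1.0 / (1.0 + np.exp(delta))
    return bool(rng.random() < a)


def run_mcmc(data: SummaryData, ld: LDMatrix, hyper: Hyperparameters,
             rng: np.random.Generator | int | None = None,
             log_every: int = 0, audit_cache: float = 0.0) -> PosteriorSamples:
    """Run the add/delete/swap chain and return the retained draws.

    The log target of a configuration m is dim_log_prior(|m|) +
    log_marginal(m); marginal likelihoods are cached by index tuple.
    Identical seeds produce bit-identical traces.  ``audit_cache`` > 0
    enables a debug mode that, on that fraction of cache hits, recomputes
    the marginal likelihood from scratch and raises if the cached value
    differs; the audit uses a separate random stream so it does not
    perturb the trace.
    """
    p = data.p
    if ld.p != p:
        raise ValidationError(f"LD matrix is {ld.p}x{ld.p} but locus has {p} variants")
    if hyper.k_max >= p:
        raise ValidationError(f"k_max={hyper.k_max} must be < P={p}")
    if hyper.tau is None:
        raise ValidationError("tau unset; resolve with select_tau(n) or set explicitly")
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = hyper.seed if rng is None else int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = hyper.seed

    dim_lp = np.full(hyper.k_max + 1, -np.inf)
    for d in range(1, hyper.k_max + 1):
        dim_lp[d] = dim_log_prior(d, p, hyper)

    cache: dict[tuple[int, ...], ModelState] = {}
    audit_rng = np.random.default_rng(seed + 2 ** 20) if audit_cache > 0 else None

    def get_state(m: tuple[int, ...]) -> ModelState:
        st = cache.get(m)
        if st is None:
            st = model_state(m, data, ld, hyper)
            cache[m] = st
        elif audit_rng is not None and audit_rng.random() < audit_cache:
            fresh = model_state(m, data, ld, hyper)
            if fresh.log_ml != st.log_ml:
                from .exceptions import NumericalError
                raise NumericalError(
                    f"cache mismatch for model {m}: {st.log_ml} vs {fresh.log_ml}")
        return st

    curr = get_state(init_model(data))
    models: list[tuple[int, ...]] = []
    dims = np.empty(hyper.n_iter - hyper.burn_in, dtype=np.int64)
    n_accept = 0
    retained = 0
    for it in range(hyper.n_iter):
        prop = propose(curr, data, ld, hyper, rng, get_state=get_state)
        cand = get_state(prop.model_prop)
        log_mp = dim_lp[cand.dim] + cand.log_ml + prop.log_q_bwd
        log_mc = dim_lp[curr.dim] + curr.log_ml + prop.log_q_fwd
        if barker_accept(log_mp, log_mc, rng):
            curr = cand
            n_accept += 1
        if it >= hyper.burn_in:
            models.append(curr.members)
            dims[retained] = curr.dim
            retained += 1
        if log_every and (it + 1) % log_every == 0:
            logger.info("iteration %d/%d dim=%d accept=%.3f",
                        it + 1, hyper.n_iter, curr.dim, n_accept / (it + 1))

    return PosteriorSamples(models=models, dims=dims,
                            accept_rate=n_accept / hyper.n_iter,
                            p=p, hyper=hyper, rng_seed=seed)
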