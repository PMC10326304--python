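"""Input conditioning: clumping of near-duplicate variants and an LD
consistency check for out-of-sample references.

Clumping collapses groups of variants in near-perfect LD (r^2 above a
threshold, 0.99 by default) to a single representative — the member with
the strongest marginal signal — before model search; the absorbed proxies
can be re-attached to credible sets afterwards.

The consistency check screens for variants whose z-score disagrees with
the prediction implied by their best-LD partner, a symptom of an LD
reference that does not match the summary statistics (allele flips,
different populations, QC differences).  For each variant j with a
partner k = argmax_{k != j} |r_jk| at |r_jk| >= 0.8, the standardized
discrepancy

    t_j = (z_j - r_jk * z_k)^2 / (1 - r_jk^2 + 1e-6)

is approximately chi^2(1) under a correct reference; j is flagged when
t_j exceeds ``z_threshold**2`` (default 25).  Variants with no strong-LD
partner are never flagged.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .data import LDMatrix, SummaryData
from .exceptions import ValidationError


@dataclasses.dataclass
class ClumpMap:
    """Mapping from clump representatives to their absorbed proxies.

    Indices in ``rep_to_proxies`` and ``kept`` refer to the ORIGINAL
    (pre-clumping) variant order; ``kept`` lists, in order, the original
    index of each row of the reduced data, so reduced index j corresponds
    to original index ``kept[j]``.
    """

    rep_to_proxies: dict[int, list[int]]
    kept: list[int]
    r2_threshold: float

    def proxies_of_reduced(self, j_reduced: int) -> list[int]:
        """Original-index proxies of the reduced-index representative."""
        return self.rep_to_proxies.get(self.kept[j_reduced], [])

    def to_frame(self, variant_id=None) -> pd.DataFrame:
        rows = []
        for rep, proxies in self.rep_to_proxies.items():
            for prox in proxies:
                rows.append((rep, prox))
        df = pd.DataFrame(rows, columns=["REP", "PROXY"])
        if variant_id is not None and len(df):
            df["REP_ID"] = np.asarray(variant_id)[df["REP"]]
            df["PROXY_ID"] = np.asarray(variant_id)[df["PROXY"]]
        return df


def clump_variants(data: SummaryData, ld: LDMatrix, r2: float = 0.99
                   ) -> tuple[SummaryData, LDMatrix, ClumpMap]:
    """Greedily clump variants whose pairwise r^2 exceeds ``r2``.

    Variants are visited by decreasing |z| (increasing p-value); each
    unassigned variant becomes a representative and absorbs every
    still-unassigned variant with r^2 strictly above the threshold
    against it.  The reduced data and LD keep the original relative
    order.  The variant with the global maximum |z| is always retained.
    """
    if not 0 < r2 <= 1:
        raise ValidationError("r2 threshold must lie in (0, 1]")
    if ld.p != data.p:
        raise ValidationError("summary data and LD matrix sizes differ")
    r2_mat = ld.r ** 2
    order = sorted(range(data.p), key=lambda j: (-np.abs(data.z[j]), j))
    assigned = np.zeros(data.p, dtype=bool)
    rep_to_proxies: dict[int, list[int]] = {}
    for j in order:
        if assigned[j]:
            continue
        assigned[j] = True
        mates = np.flatnonzero((r2_mat[j] > r2) & ~assigned)
        assigned[mates] = True
        rep_to_proxies[j] = sorted(int(m) for m in mates)
    kept = sorted(rep_to_proxies)
    cmap = ClumpMap(rep_to_proxies={k: v for k, v in rep_to_proxies.items() if v},
                    kept=kept, r2_threshold=r2)
    return data.subset(kept), ld.subset(kept), cmap


def ld_consistency_check(data: SummaryData, ld: LDMatrix,
                         z_threshold: float = 5.0,
                         partner_r: float = 0.8) -> list[int]:
    """Flag variants whose z-score conflicts with their best-LD partner.

    Returns the flagged indices; the caller decides whether to drop them
    or abort.  Intended for out-of-sample references — a warning is
    emitted if the LD is declared in-sample.
    """
    if ld.in_sample:
        warnings.warn("LD consistency check applied to an in-sample LD matrix",
                      stacklevel=2)
    z = data.z
    absr = np.abs(ld.r - np.eye(data.p))
    flagged = []
    for j in range(data.p):
        k = int(np.argmax(absr[j]))
        if absr[j, k] < partner_r:
            continue
        r_jk = ld.r[j, k]
        t = (z[j] - r_jk * z[k]) ** 2 / (1.0 - r_jk ** 2 + 1e-6)
        if t > z_threshold ** 2:
            flagged.append(j)
    return flagged
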