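"""Simulation-study metrics: credible-set coverage, power, median size.

Coverage is the proportion of credible sets that contain at least one
true causal variant; power is the proportion of true causal variants
captured by at least one credible set.  Both are binomial proportions
and get exact Clopper-Pearson 95% intervals; the median set size gets a
bootstrap interval (1000 resamples by default).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from statsmodels.stats.proportion import proportion_confint


@dataclasses.dataclass
class EvaluationReport:
    """Pooled metrics over simulation replicates (CIs at 95%)."""

    coverage: float | None
    coverage_ci: tuple[float, float] | None
    power: float | None
    power_ci: tuple[float, float] | None
    median_set_size: float | None
    median_ci: tuple[float, float] | None
    n_sets: int
    n_causal: int
    scenario: dict = dataclasses.field(default_factory=dict)

    def to_json(self) -> str:
        def _pair(x):
            return list(x) if x is not None else None
        return json.dumps({
            "coverage": self.coverage, "coverage_ci": _pair(self.coverage_ci),
            "power": self.power, "power_ci": _pair(self.power_ci),
            "median_set_size": self.median_set_size,
            "median_ci": _pair(self.median_ci),
            "n_sets": self.n_sets, "n_causal": self.n_causal,
            "scenario": self.scenario}, indent=1)


def evaluate(sets_by_replicate, truths_by_replicate, *, seed: int = 0,
             n_boot: int = 1000, scenario: dict | None = None) -> EvaluationReport:
    """Compute coverage/power/median-size over aligned replicates.

    ``sets_by_replicate[i]`` is the list of credible sets (each a
    collection of variant indices) for replicate i and
    ``truths_by_replicate[i]`` the true causal indices of that replicate.
    With zero sets the coverage and median are reported as missing
    (None), not as 0.
    """
    if len(sets_by_replicate) != len(truths_by_replicate):
        raise ValueError("sets and truths must be replicate-aligned")
    covered = 0
    n_sets = 0
    detected = 0
    n_causal = 0
    sizes = []
    for sets, truth in zip(sets_by_replicate, truths_by_replicate):
        truth = set(int(t) for t in truth)
        n_causal += len(truth)
        for s in sets:
            s = set(int(v) for v in s)
            n_sets += 1
            sizes.append(len(s))
            if s & truth:
                covered += 1
        union = set().union(*[set(map(int, s)) for s in sets]) if sets else set()
        detected += len(truth & union)

    if n_sets:
        coverage = covered / n_sets
        cov_ci = tuple(proportion_confint(covered, n_sets, method="beta"))
        sizes_arr = np.asarray(sizes)
        median = float(np.median(sizes_arr))
        rng = np.random.default_rng(seed)
        boots = np.median(
            sizes_arr[rng.integers(0, n_sets, size=(n_boot, n_sets))], axis=1)
        med_ci = (float(np.quantile(boots, 0.025)),
                  float(np.quantile(boots, 0.975)))
    else:
        coverage, cov_ci, median, med_ci = None, None, None, None
    if n_causal:
        power = detected / n_causal
        pow_ci = tuple(proportion_confint(detected, n_causal, method="beta"))
    else:
        power, pow_ci = None, None

    return EvaluationReport(
        coverage=coverage, coverage_ci=cov_ci, power=power, power_ci=pow_ci,
        median_set_size=median, median_ci=med_ci, n_sets=n_sets,
        n_causal=n_causal, scenario=scenario or {})
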