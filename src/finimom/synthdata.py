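"""Synthetic single-locus data: genotypes with block LD, phenotypes, summaries.

The generator emulates the inputs of a typical protein-QTL fine-mapping
study: a locus of P variants organized in LD blocks, N individuals, and
1-5 causal variants jointly explaining 1.5-3% of the phenotypic variance.
Genotypes are drawn from a Gaussian copula — within each block a latent
AR(1) Gaussian vector (adjacent correlation ``rho``) is thresholded at
each variant's minor-allele-frequency quantile, twice independently, and
the two allele draws summed to a Hardy-Weinberg 0/1/2 dosage.  This
reproduces the one property the fine-mapping model consumes, a realistic
correlation matrix, without any coalescent machinery.

Phenotypes follow the additive model y = X beta + eps with the genetic
component rescaled so the realized variance fraction equals h2 exactly
(removing one noise source from calibration experiments).  Marginal
summary statistics are per-variant simple regressions, exactly as a GWAS
would produce them, and the in-sample LD matrix is the sample genotype
correlation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import norm

from .data import LDMatrix, SummaryData
from .exceptions import ValidationError


@dataclasses.dataclass
class LocusSpec:
    """Geometry of a synthetic locus.

    ``block_sizes`` must sum to P (default: blocks of 50); ``rho`` is the
    latent adjacent correlation within a block (AR(1), so variants k
    apart correlate as rho^k on the latent scale); MAFs are drawn
    uniformly in ``maf_range``.
    """

    p: int
    block_sizes: list[int] | None = None
    rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_sizes is None:
            full, rem = divmod(self.p, 50)
            self.block_sizes = [50] * full + ([rem] if rem else [])
        if sum(self.block_sizes) != self.p:
            raise ValidationError(
                f"block sizes sum to {sum(self.block_sizes)}, expected P={self.p}")
        if not 0 <= self.rho < 1:
            raise ValidationError("rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must be within (0, 0.5]")


@dataclasses.dataclass
class ScenarioSpec:
    """One simulation scenario: sample size, causal count, variance explained."""

    n: int
    c: int = 1
    h2: float = 0.03
    min_separation: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.h2 < 1:
            raise ValidationError("h2 must lie in (0,1)")
        if self.c < 1:
            raise ValidationError("need at least one causal variant")


def locus_mafs(spec: LocusSpec) -> np.ndarray:
    """Per-variant minor-allele frequencies of the locus (deterministic in
    ``spec.seed``)."""
    return np.random.default_rng(spec.seed).uniform(*spec.maf_range,
                                                    size=spec.p)


def simulate_genotypes(spec: LocusSpec, n: int,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw an n x P genotype dosage matrix (values 0/1/2)."""
    if n < 50:
        raise ValidationError("need n >= 50 individuals")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    # MAFs are a property of the locus, fixed by spec.seed, so independent
    # samples (GWAS cohort, reference panel) share the same variants
    mafs = locus_mafs(spec)
    thresholds = norm.ppf(mafs)
    geno = np.empty((n, spec.p), dtype=np.int8)
    start = 0
    for size in spec.block_sizes:
        alleles = np.zeros((n, size), dtype=np.int8)
        for _ in range(2):  # two independent allele draws per individual
            latent = rng.standard_normal((n, size))
            mix = np.sqrt(1.0 - spec.rho ** 2)
            for i in range(1, size):
                latent[:, i] = spec.rho * latent[:, i - 1] + mix * latent[:, i]
            alleles += latent < thresholds[start:start + size]
        geno[:, start:start + size] = alleles
        start += size
    return geno


def simulate_phenotype(x: np.ndarray, scen: ScenarioSpec,
                       rng: np.random.Generator | None = None):
    """Draw a phenotype under the additive model y = X beta + eps.

    Causal variants are chosen uniformly subject to ``min_separation``
    index gaps; raw effects are standard normal on standardized genotype
    columns and rescaled so the realized genetic variance fraction equals
    h2 exactly (the noise is residualized against the genetic component
    for the same reason).  Returns ``(y, causal_idx, beta_true)`` with
    ``beta_true`` on the standardized-genotype scale, embedded in a
    length-P vector.
    """
    if rng is None:
        rng = np.random.default_rng(scen.seed)
    n, p = x.shape
    if scen.c > p:
        raise ValidationError(f"c={scen.c} causal variants but only P={p}")
    causal = None
    for _ in range(1000):
        cand = np.sort(rng.choice(p, size=scen.c, replace=False))
        if scen.c == 1 or np.diff(cand).min() >= scen.min_separation:
            causal = cand
            break
    if causal is None:
        raise ValidationError(
            f"could not place {scen.c} causal variants with min_separation="
            f"{scen.min_separation} in P={p} after 1000 tries")

    xs = x[:, causal].astype(float)
    xs = (xs - xs.mean(axis=0)) / xs.std(axis=0)
    raw = rng.standard_normal(scen.c)
    g = xs @ raw
    scale = np.sqrt(scen.h2) / g.std()
    g = g * scale
    eps = rng.standard_normal(n)
    eps = eps - eps.mean()
    eps = eps - (eps @ g) / (g @ g) * g  # exact sample orthogonality
    eps *= np.sqrt(1.0 - scen.h2) / eps.std()
    y = g + eps
    beta_true = np.zeros(p)
    beta_true[causal] = raw * scale
    return y - y.mean(), causal.astype(int), beta_true


def compute_summary(x: np.ndarray, y: np.ndarray,
                    chrom: str = "1", pos_start: int = 1_000_000,
                    pos_step: int = 500) -> tuple[SummaryData, LDMatrix]:
    """Marginal per-variant regressions and the in-sample LD matrix.

    Each variant's slope and SE come from the simple regression of y on
    its dosage column (per-allele units); EAF is the dosage mean over 2;
    Var(Y) the sample variance of y.  Variant IDs/positions are
    synthesized on a regular grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    xc = x - x.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    constant = np.flatnonzero(sxx == 0.0)
    if constant.size:
        raise ValidationError(f"constant genotype column(s): {constant.tolist()}")
    yc = y - y.mean()
    slope = xc.T @ yc / sxx
    sse = yc @ yc - slope ** 2 * sxx
    se = np.sqrt(sse / (n - 2) / sxx)
    ld = np.corrcoef(x, rowvar=False)
    data = SummaryData(
        variant_id=np.array([f"rs{j + 1}" for j in range(p)]),
        chrom=np.full(p, chrom),
        pos=pos_start + pos_step * np.arange(p),
        effect_allele=np.full(p, "A"), other_allele=np.full(p, "G"),
        eaf=x.mean(axis=0) / 2.0,
        beta_hat=slope, se=se, n=n, var_y=float(yc @ yc / (n - 1)))
    return data, LDMatrix(r=ld, n_ref=n, in_sample=True)


def out_of_sample_ld(spec: LocusSpec, n_ref: int,
                     rng: np.random.Generator | None = None) -> LDMatrix:
    """LD matrix from an independent genotype draw of the same locus.

    Emulates a reference panel: same LD-generating process, different
    individuals.  Pass an independent ``rng`` stream (or rely on
    ``spec.seed + 1`` by default) so the panel is not the GWAS sample.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    geno = simulate_genotypes(spec, n_ref, rng)
    return LDMatrix(r=np.corrcoef(geno, rowvar=False), n_ref=n_ref,
                    in_sample=False)


def simulate_locus(spec: LocusSpec, scen: ScenarioSpec,
                   rng: np.random.Generator | None = None):
    """One full replicate: ``(SummaryData, in-sample LDMatrix, causal_idx,
    beta_true)``.  All randomness flows from ``rng`` (default: spec.seed)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    geno = simulate_genotypes(spec, scen.n, rng)
    y, causal, beta_true = simulate_phenotype(geno, scen, rng)
    data, ld = compute_summary(geno, y)
    return data, ld, causal, beta_true
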