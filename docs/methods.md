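# Methods

## Problem and model

Fine-mapping asks which of the P variants at a GWAS-associated locus are
causal for a quantitative trait, given that linkage disequilibrium (LD)
makes non-causal neighbours of a causal variant show association too.
`finimom` works entirely from summary data: per-variant marginal effect
estimates β̂_j with standard errors, effect-allele frequencies, the GWAS
sample size N, the phenotypic variance Var(Y), and a P×P LD correlation
matrix R̂.

Under the standard large-N / small-effect approximation, the observed
marginal estimates follow

    β̂ | β ~ MVN( Ŝ R̂ Ŝ⁻¹ β , Ŝ R̂ Ŝ ),      Ŝ = diag(SE),

where β is the joint (multivariable) effect vector. A causal
configuration m is a set of d variant indices with β_j ≠ 0 exactly for
j ∈ m, with d at most K « P. Per-allele summary statistics are converted
to standardized units by multiplying β̂_j and SE_j by
√(2·EAF_j(1−EAF_j)/Var(Y)) (Hardy–Weinberg genotype variance over trait
variance); z-scores are invariant under this conversion.

## Priors

**Effect sizes.** Conditioned on m, the active effects get a product
inverse-moment (piMOM) prior,

    π(β|τ,r) = ∏_{k∈m} τ^{r/2}/Γ(r/2) · |β_k|^{−(r+1)} · exp(−τ/β_k²).

This is a *nonlocal* prior: the density is exactly zero at β_k = 0, so a
configuration that includes an effectively null variant is penalized hard
rather than absorbed by prior mass near zero. r = 1 (default) gives
Cauchy-like tails that avoid over-shrinking large effects. The scale τ is
chosen from the sample size by requiring that a prior effect exceeds the
detectability threshold z_q/√N with probability 1−q. Under w = τ/β² the
marginal prior maps to w ~ Gamma(r/2, 1), so the rule inverts in closed
form:

    τ = (z_q²/N) · gammaincinv(r/2, 1−q),    defaults z_q = 3.29, q = 0.05.

This gives τ = 0.00566 at N = 3675 and τ = 0.00385 at N = 5400.

**Model dimension.** The number of causal variants d gets a truncated
beta-binomial prior, π(d) ∝ C(P,d)·B(a+d, P−d+b)/B(a,b) for 1 ≤ d ≤ K,
zero otherwise, with a = 1 and b = P^u. Larger u concentrates mass on
smaller models; defaults are u = 2.0 with in-sample LD and u = 2.25 with
a reference-panel LD, where sparser priors guard against the false
positives an imperfect R̂ induces. The prior is kept unnormalized
internally (only ratios enter the sampler); `dim_prior_pmf` gives the
normalized version for reporting.

## Marginal likelihood

The posterior over configurations needs π_m(D) = ∫ likelihood × prior dβ_m.
Writing f(β) = −log likelihood − log prior (model-independent constants
dropped), the *approximate* Laplace method evaluates everything at the
plug-in joint estimate β̃_m = R̂_m⁻¹ β̂_m instead of optimizing f:

    log π_m(D) ≈ −f(β̃) + (d/2)·ln 2π − ½·ln|H| + ½·gᵀH⁻¹g,

with the closed-form gradient g = (r+1)/β − 2τ/β³ + Aβ − z/s and Hessian
H = A + diag(6τ/β⁴ − (r+1)/β²), where A is the active d×d slice of
Ŝ⁻¹R̂Ŝ⁻¹. The full P×P product is never formed; everything is O(dP) or
smaller per evaluation. The dropped multivariate-normal normalizer is
identical across models, so Bayes factors are exact.

Numerical safeguards: if cond(R̂_m) > 1e8 the solve is ridge-regularized
(λ = 1e-6) and the evaluation falls back to the conventional Laplace
method (BFGS minimization of f started at β̃, no gradient-correction
term); the same fallback fires when H fails its Cholesky factorization.
Exactly-zero plug-in coordinates are nudged to ±1e-8 before evaluating
the piMOM terms, which are singular at 0.

**A property worth knowing.** When a configuration contains a variant
whose *joint* effect is near zero (a null variant, or a pure proxy of an
included causal variant), τ/β̃² diverges and the plug-in evaluation drives
the score toward −∞ even though the exact integral is finite. This is the
intended behaviour of evaluating a nonlocal prior at the plug-in estimate
— such configurations are precisely the ones the prior is built to
reject — but it means the approximation tracks adaptive quadrature only
for models whose joint effects are all non-degenerate (in practice,
members with |z| ≳ 5 and no complete LD cancellation). The test suite
verifies sub-nat agreement with quadrature in that regime and the
correct partial ordering (causal beats null-containing) outside it.

## Sampler

A trans-dimensional Metropolis chain over configurations with three
moves: **add** an inactive variant with probability ∝ its squared
residual correlation (β̂ − R̂β_full)², floored at 1e-12 so every variant
stays reachable; **delete** a uniformly chosen active variant; **swap**
a uniformly chosen active variant out and an inactive variant in with
probability ∝ r² with the outgoing variant, which keeps proposals inside
high-LD signal groups. The move type is drawn uniformly from the
*feasible* moves (no delete at d = 1, no add at d = K) and the proposal
density q(m′|m) includes the move-type factor — the choice is validated
empirically by an exhaustive-enumeration test (total variation ≤ 0.05
against the exact posterior on a 10-variant locus). Proposals are
accepted with the Barker probability a = m_p/(m_p + m_c), the optimal
rule for binary-inclusion samplers, computed in log space.

Defaults: 12 500 iterations with 2 500 burn-in (10 000 retained draws),
one chain. Marginal likelihoods are cached by sorted index tuple; a
debug flag re-verifies a fraction of cache hits. Identical seeds give
bit-identical traces. Acceptance rates are naturally low (~0.01–0.03)
when the posterior concentrates on one configuration, and 0.03–0.09 in
high-LD multi-signal loci where the swap move does real work; genuine
proposal degeneracy shows up as rates near 0 or 1.

## Posterior summaries

PIP_j is the fraction of retained draws containing j. The number of
credible sets is read off the posterior of the model dimension: l* is
the modal dimension (ties to the smaller value). Conditioning on draws
of dimension l*, the l* highest conditional-inclusion variants seed l*
clusters; every other variant seen in the conditional draws joins the
seed it is most correlated with (|r|, ties to the higher-PIP seed); each
cluster is grown in decreasing conditional-inclusion order until the
fraction of conditional draws it intersects reaches α_l. By default
α_l = α^(1/l*), so the l* sets jointly achieve coverage ≥ α; the
`per_set_alpha` switch restores α_l = α. Sets are disjoint by
construction. The exact set-construction rule is an interpretation —
several reasonable constructions exist — and the default is the more
conservative reading; the full dimension posterior is always reported
alongside.

## Input conditioning

**Clumping** (optional, r² > 0.99 by default): variants are visited by
decreasing |z|; each unassigned variant becomes a representative and
absorbs the still-unassigned variants exceeding the r² threshold with
it. Proxies are re-attached to credible sets afterwards as annotations.
The representative is the strongest-signal member, so the searchable
unit keeps the best marginal evidence.

**LD consistency check** (for reference-panel LD): for each variant with
a partner at |r| ≥ 0.8, the discrepancy t = (z_j − r·z_k)²/(1−r²+1e-6)
is ~χ²(1) under a correct reference; t > 25 flags the variant. This is
the DENTIST/SLALOM-style pairwise statistic; the partner threshold and
cut-off are exposed as arguments since several variants of this check
exist in the field.

## Synthetic data

The generator emulates a pQTL-style locus. Genotypes come from a
Gaussian copula: within blocks (default 50 variants), a latent AR(1)
Gaussian vector (adjacent correlation ρ, default 0.9) is thresholded at
each variant's MAF quantile (MAF ~ U(0.05, 0.5)), twice independently,
and summed to a 0/1/2 dosage — Hardy–Weinberg by construction. This
reproduces the only property the model consumes (a realistic block
correlation structure) and supports ρ up to 0.99 to exercise swaps and
clumping; it does *not* model recombination maps, population structure,
allele-frequency-dependent architectures, or case-control traits, so
passing tests say nothing about those regimes. Phenotypes are additive,
y = Xβ + ε, with 1–5 causal variants and locus heritability h² ∈
{0.015, 0.03}; effects are rescaled so the realized in-sample variance
fraction equals h² exactly and the noise is residualized against the
genetic component, removing one noise source from calibration tests.
Summary statistics are genuine per-variant simple regressions; the
in-sample LD is the sample genotype correlation; an out-of-sample panel
is an independent draw from the same copula.

## Problem sizes used by the test suite

The calibration suite runs 100 replicates at P = 500, N = 5000, c = 1,
h² = 0.03 with in-sample LD and the full default chain (12 500
iterations), plus 80 two-signal replicates at P = 100 for pooled set
coverage — locus sizes at the lower end of the realistic range, chosen
so the whole suite runs in minutes on a laptop core while still using
the method's default chain settings. The enumeration check uses P = 10,
K = 3 with 50 000 retained draws against all 175 exactly enumerated
configurations.

## Known limitations

- Single ancestry, single locus, quantitative traits only; no polygenic
  background, no multivariate outcomes.
- τ is one scalar for all variants (no allele-frequency-dependent τ).
- Summary statistics and LD must cover exactly the same variants in the
  same order; variants missing from the LD reference are an error, not
  an imputation target.
- The credible-set construction conditions on the single modal dimension
  rather than mixing over dimensions; loci with a flat dimension
  posterior get sets that under-represent that uncertainty (the reported
  dimension posterior makes this visible).
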