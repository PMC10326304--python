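"""Reading, validation and harmonization of GWAS summary statistics and LD.

The two containers defined here, :class:`SummaryData` and :class:`LDMatrix`,
are the in-memory currency of the whole package: a locus is a vector of
per-variant marginal effect estimates (with standard errors, effect-allele
frequencies and z-scores) paired with a square correlation matrix over the
same variants, in the same order.

Effect sizes arrive in per-allele units from a typical GWAS and are
converted to standardized (unit-variance genotype, unit-variance trait)
units by :func:`standardize`, using the Hardy-Weinberg variance
``2*EAF*(1-EAF)`` and the phenotypic variance ``Var(Y)``.  z-scores are
invariant under this rescaling.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError, ValidationError

#: default header names for summary-statistic files
DEFAULT_COLUMNS = {
    "chrom": "CHR",
    "pos": "POS",
    "variant_id": "ID",
    "effect_allele": "EA",
    "other_allele": "NEA",
    "eaf": "EAF",
    "beta_hat": "BETA",
    "se": "SE",
}

#: EAF band outside which variants are rejected at read time; too-rare
#: variants give unstable marginal estimates and corrupt LD correspondence
#: if silently dropped downstream.
EAF_BOUNDS = (0.005, 0.995)


@dataclasses.dataclass
class SummaryData:
    """Per-variant GWAS marginal statistics for one locus.

    Parameters
    ----------
    variant_id, chrom, effect_allele, other_allele
        String arrays of length P.  Coordinates are 1-based inclusive.
    pos
        Base-pair positions (int).
    eaf
        Effect-allele frequencies, strictly inside (0, 1).
    beta_hat, se
        Marginal effect estimates and their standard errors (se > 0).
        Units are per-allele on input; ``standardize`` flips ``units``.
    n
        GWAS sample size.
    var_y
        Phenotypic variance of the trait the betas refer to.
    units
        ``"per_allele"`` or ``"standardized"``.
    """

    variant_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    eaf: np.ndarray
    beta_hat: np.ndarray
    se: np.ndarray
    n: int
    var_y: float
    units: str = "per_allele"

    def __post_init__(self) -> None:
        for name in ("variant_id", "chrom", "pos", "effect_allele",
                     "other_allele", "eaf", "beta_hat", "se"):
            setattr(self, name, np.asarray(getattr(self, name)))
        lengths = {len(getattr(self, f)) for f in (
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta_hat", "se")}
        if len(lengths) != 1:
            raise ValidationError(f"per-variant vectors differ in length: {lengths}")
        if self.p < 1:
            raise ValidationError("empty summary data")
        if self.n < 2:
            raise ValidationError(f"sample size n={self.n} must be >= 2")
        if not self.var_y > 0:
            raise ValidationError(f"var_y={self.var_y} must be > 0")
        bad_se = np.flatnonzero(~(self.se > 0))
        if bad_se.size:
            raise ValidationError(f"non-positive SE at rows {bad_se.tolist()}")
        bad_eaf = np.flatnonzero(~((self.eaf > 0.0) & (self.eaf < 1.0)))
        if bad_eaf.size:
            raise ValidationError(f"EAF outside (0,1) at rows {bad_eaf.tolist()}")
        if self.units not in ("per_allele", "standardized"):
            raise ValidationError(f"unknown units {self.units!r}")

    @property
    def p(self) -> int:
        """Number of variants at the locus."""
        return len(self.beta_hat)

    @property
    def z(self) -> np.ndarray:
        """Signed z-scores beta_hat / se (invariant under standardize)."""
        return self.beta_hat / self.se

    def subset(self, idx: Sequence[int]) -> "SummaryData":
        """Return a new SummaryData restricted to rows ``idx`` in order."""
        idx = np.asarray(idx, dtype=int)
        return SummaryData(
            variant_id=self.variant_id[idx], chrom=self.chrom[idx],
            pos=self.pos[idx], effect_allele=self.effect_allele[idx],
            other_allele=self.other_allele[idx], eaf=self.eaf[idx],
            beta_hat=self.beta_hat[idx], se=self.se[idx],
            n=self.n, var_y=self.var_y, units=self.units)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view using the default column names."""
        return pd.DataFrame({
            "CHR": self.chrom, "POS": self.pos, "ID": self.variant_id,
            "EA": self.effect_allele, "NEA": self.other_allele,
            "EAF": self.eaf, "BETA": self.beta_hat, "SE": self.se})


@dataclasses.dataclass
class LDMatrix:
    """A P x P genotype correlation matrix with provenance.

    ``in_sample`` records whether the matrix was estimated from the same
    individuals as the summary statistics (True) or from an external
    reference panel (False); several defaults downstream (the dimension
    prior exponent u, the consistency check) key off this flag.
    ``n_ref`` is the LD panel size, 0 if unknown.
    """

    r: np.ndarray
    n_ref: int = 0
    in_sample: bool = True

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise FormatError(f"LD matrix must be square, got {self.r.shape}")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise FormatError("LD matrix not symmetric within 1e-8")
        if np.any(np.abs(self.r) > 1.0 + 1e-6):
            raise FormatError("LD entries outside [-1, 1] beyond tolerance")
        self.r = np.clip((self.r + self.r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(self.r, 1.0)

    @property
    def p(self) -> int:
        return self.r.shape[0]

    def subset(self, idx: Sequence[int]) -> "LDMatrix":
        idx = np.asarray(idx, dtype=int)
        return LDMatrix(r=self.r[np.ix_(idx, idx)], n_ref=self.n_ref,
                        in_sample=self.in_sample)


def read_sumstats(path, column_map: Mapping[str, str] | None = None, *,
                  n: int, var_y: float,
                  eaf_bounds: tuple[float, float] = EAF_BOUNDS) -> SummaryData:
    """Read delimited summary statistics into a validated :class:`SummaryData`.

    ``column_map`` maps internal field names (``beta_hat``, ``se``, ``eaf``,
    ``variant_id``, ``chrom``, ``pos``, ``effect_allele``, ``other_allele``)
    to header names in the file; unmapped fields use :data:`DEFAULT_COLUMNS`.
    Rows are kept in file order.  gzip input is handled transparently.

    Raises
    ------
    ConfigurationError
        If a mapped column is absent from the header.
    ValidationError
        For non-positive SEs, EAFs outside ``eaf_bounds`` or duplicate IDs;
        the offending rows are listed rather than dropped, because silent
        filtering would break the row correspondence with the LD matrix.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise ConfigurationError(f"unknown field names in column_map: {sorted(unknown)}")
        cols.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", dtype={cols["chrom"]: str},
                     float_precision="round_trip")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"missing column(s) {missing} in {path}; present: {list(df.columns)}")

    lo, hi = eaf_bounds
    eaf = df[cols["eaf"]].to_numpy(float)
    bad = np.flatnonzero(~((eaf > lo) & (eaf < hi)))
    if bad.size:
        raise ValidationError(
            f"EAF outside ({lo}, {hi}) at rows {bad.tolist()} of {path}")
    ids = df[cols["variant_id"]].astype(str)
    dup = ids[ids.duplicated()].unique()
    if dup.size:
        raise ValidationError(f"duplicate variant IDs in {path}: {dup.tolist()}")

    return SummaryData(
        variant_id=ids.to_numpy(),
        chrom=df[cols["chrom"]].astype(str).to_numpy(),
        pos=df[cols["pos"]].to_numpy(int),
        effect_allele=df[cols["effect_allele"]].astype(str).to_numpy(),
        other_allele=df[cols["other_allele"]].astype(str).to_numpy(),
        eaf=eaf,
        beta_hat=df[cols["beta_hat"]].to_numpy(float),
        se=df[cols["se"]].to_numpy(float),
        n=int(n), var_y=float(var_y))


def write_sumstats(data: SummaryData, path) -> None:
    """Write summary statistics as TSV with the default header names.

    Floats are written with 17 significant digits so a read back is
    bit-identical.
    """
    data.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def standardize(data: SummaryData) -> SummaryData:
    """Convert per-allele effect estimates to standardized units.

    Both ``beta_hat`` and ``se`` are multiplied component-wise by
    ``sqrt(2*EAF*(1-EAF)/Var(Y))`` (Hardy-Weinberg genotype variance over
    phenotypic variance), so z-scores are unchanged.  The returned object
    carries ``units="standardized"``; the transformation is applied
    unconditionally — idempotence is the caller's responsibility via the
    units flag.
    """
    factor = np.sqrt(2.0 * data.eaf * (1.0 - data.eaf) / data.var_y)
    out = dataclasses.replace(data, beta_hat=data.beta_hat * factor,
                              se=data.se * factor)
    out.units = "standardized"
    return out


def harmonize_alleles(data: SummaryData, panel_ea: Sequence[str],
                      panel_oa: Sequence[str]) -> SummaryData:
    """Align effect alleles to an external LD panel's allele convention.

    Where the panel's (effect, other) pair is the swap of ours, the beta
    sign is flipped and the EAF complemented; identical pairs pass through;
    any other combination is a mismatch error.  Strand flips are not
    inferred.
    """
    panel_ea = np.asarray(panel_ea)
    panel_oa = np.asarray(panel_oa)
    same = (data.effect_allele == panel_ea) & (data.other_allele == panel_oa)
    swapped = (data.effect_allele == panel_oa) & (data.other_allele == panel_ea)
    bad = np.flatnonzero(~(same | swapped))
    if bad.size:
        raise ValidationError(
            f"allele mismatch with LD panel at rows {bad.tolist()}")
    sign = np.where(swapped, -1.0, 1.0)
    out = dataclasses.replace(
        data,
        beta_hat=data.beta_hat * sign,
        eaf=np.where(swapped, 1.0 - data.eaf, data.eaf),
        effect_allele=np.where(swapped, data.other_allele, data.effect_allele),
        other_allele=np.where(swapped, data.effect_allele, data.other_allele))
    return out


def read_ld(path, fmt: str = "square_text", *,
            variant_ids: Sequence[str] | None = None,
            n_ref: int = 0, in_sample: bool = True) -> LDMatrix:
    """Read an LD correlation matrix.

    ``fmt="square_text"``: whitespace-separated square matrix, one row per
    line, no header.  ``fmt="plink_ld"``: PLINK pairwise table with columns
    SNP_A, SNP_B and a signed R column, densified to P x P (pairs absent
    from the table get r=0); ``variant_ids`` fixes the row order and must
    be given for this format.  gzip is handled transparently by numpy /
    pandas.  Symmetry is enforced as (M + M')/2 and the diagonal reset to
    1; entries beyond 1 + 1e-6 in magnitude are a format error, smaller
    excursions are clipped.
    """
    if fmt == "square_text":
        m = np.loadtxt(path, ndmin=2)
        if m.shape[0] != m.shape[1]:
            raise FormatError(f"{path}: expected a square matrix, got {m.shape}")
    elif fmt == "plink_ld":
        tab = pd.read_csv(path, sep=r"\s+")
        for col in ("SNP_A", "SNP_B"):
            if col not in tab.columns:
                raise FormatError(f"{path}: PLINK table lacks column {col}")
        if "R" not in tab.columns:
            raise FormatError(
                f"{path}: need a signed R column (R2 loses the correlation sign)")
        if variant_ids is None:
            seen: dict[str, int] = {}
            for v in pd.concat([tab["SNP_A"], tab["SNP_B"]]):
                seen.setdefault(str(v), len(seen))
            index = seen
        else:
            index = {str(v): i for i, v in enumerate(variant_ids)}
        p = len(index)
        m = np.zeros((p, p))
        for a, b, r in zip(tab["SNP_A"], tab["SNP_B"], tab["R"]):
            a, b = str(a), str(b)
            if a not in index or b not in index:
                raise FormatError(f"{path}: variant {a if a not in index else b} "
                                  "not in the supplied variant list")
            m[index[a], index[b]] = r
            m[index[b], index[a]] = r
        np.fill_diagonal(m, 1.0)
    else:
        raise ConfigurationError(f"unknown LD format {fmt!r}")
    return LDMatrix(r=m, n_ref=n_ref, in_sample=in_sample)


def write_ld(ld: LDMatrix, path) -> None:
    """Write the square_text dialect (full precision, round-trip safe)."""
    np.savetxt(path, ld.r, fmt="%.17g")
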