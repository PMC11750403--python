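"""Per-locus sexual-antagonism statistics.

A sexually antagonistic (SA) locus carries an allele whose fitness effects in
males and females have opposite signs.  This module converts GWAS z-scores to
Cohen's *d*, forms the cross-sex effect-size ratio (beneficial effect divided
by deleterious effect), classifies the net effect of an allele across the two
sexes, and computes the sexual antagonism index (SAI)

    SAI = d_M * d_F / sqrt((d_M^2 + d_F^2) / 2),

a conflict-intensity proxy that is negative for SA pairs, symmetric in the two
sexes, and proportional to the absolute magnitude of the antagonistic effects.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "Category",
    "NetEffect",
    "SnpRecord",
    "z_to_r",
    "z_to_cohens_d",
    "effect_size_ratio",
    "classify_net_effect",
    "sai",
    "sai_array",
    "annotate_snp_frame",
]

#: Variant functional categories recognised in the SNP table.
CATEGORIES = ("missense", "synonymous", "regulatory")


class Category(str, enum.Enum):
    """Broad variant functional category."""

    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    REGULATORY = "regulatory"


class NetEffect(str, enum.Enum):
    """Net cross-sex effect of an SA allele, from its effect-size ratio.

    ``NET_BENEFICIAL``: the beneficial effect exceeds the deleterious one in
    magnitude (ratio < -1).  ``NET_DELETERIOUS``: the deleterious effect
    dominates (ratio > -1).  ``BOUNDARY``: equal magnitudes (ratio == -1).
    """

    NET_BENEFICIAL = "net_beneficial"
    NET_DELETERIOUS = "net_deleterious"
    BOUNDARY = "boundary"


@dataclass(frozen=True)
class SnpRecord:
    """One candidate SA variant.

    Parameters
    ----------
    snp_id : str
        Unique variant identifier.
    chrom : str
        Chromosome name.
    pos : int
        1-based base-pair position.
    gene_id : str
        Identifier of the gene the variant is assigned to.
    category : str
        One of ``missense``, ``synonymous``, ``regulatory``.
    d_male, d_female : float
        Sex-specific effect sizes as Cohen's *d*.
    weight : float
        Inverse-variance regression weight; strictly positive.
    allele_freq : float
        Minor-allele frequency, in (0, 0.5].
    """

    snp_id: str
    chrom: str
    pos: int
    gene_id: str
    category: str
    d_male: float
    d_female: float
    weight: float
    allele_freq: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown category {self.category!r} for SNP {self.snp_id}"
            )
        if not self.weight > 0:
            raise ValidationError(f"weight must be > 0 for SNP {self.snp_id}")
        if not (0.0 < self.allele_freq <= 0.5):
            raise ValidationError(
                f"allele_freq must lie in (0, 0.5] for SNP {self.snp_id}"
            )
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1 for SNP {self.snp_id}")

    @property
    def is_sa(self) -> bool:
        """True when the sex-specific effects have strictly opposite signs."""
        return self.d_male * self.d_female < 0

    @property
    def sai(self) -> float:
        return sai(self.d_male, self.d_female)

    @property
    def ratio(self) -> float:
        """Beneficial-over-deleterious effect-size ratio (SA records only)."""
        if self.d_male > 0 > self.d_female:
            return effect_size_ratio(self.d_male, self.d_female)
        if self.d_female > 0 > self.d_male:
            return effect_size_ratio(self.d_female, self.d_male)
        raise ValidationError(f"SNP {self.snp_id} is not sexually antagonistic")


def z_to_r(z: float, sample_size: int) -> float:
    """Convert a standard-normal deviate to a correlation, r = z / sqrt(N)."""
    if sample_size < 2:
        raise ValidationError("sample_size must be >= 2")
    return z / math.sqrt(sample_size)


def z_to_cohens_d(z: float, sample_size: int) -> float:
    """Convert a GWAS z-score to Cohen's *d* via the z -> r -> d chain.

    r = z / sqrt(N), then d = 2 r / sqrt(1 - r^2).  The map is odd in ``z``
    and strictly increasing at fixed ``sample_size``.

    Raises
    ------
    ValidationError
        If ``sample_size`` < 2.
    DomainError
        If |z| / sqrt(N) >= 1 (the conversion is undefined).
    """
    r = z_to_r(z, sample_size)
    if abs(r) >= 1.0:
        raise DomainError(
            f"|z|/sqrt(N) = {abs(r):g} >= 1: Cohen's d conversion undefined"
        )
    return 2.0 * r / math.sqrt(1.0 - r * r)


def effect_size_ratio(d_benefit: float, d_detriment: float) -> float:
    """Ratio of the beneficial to the deleterious effect size.

    Always negative for a valid SA pair: ``d_benefit`` > 0 and
    ``d_detriment`` < 0.  A ratio below -1 means the benefit outweighs the
    detriment in magnitude.
    """
    if d_detriment == 0:
        raise ZeroDivisionError("deleterious effect size is zero")
    if not (d_benefit > 0 and d_detriment < 0):
        raise ValidationError(
            "effect_size_ratio requires d_benefit > 0 and d_detriment < 0 "
            "(locus not sexually antagonistic)"
        )
    return d_benefit / d_detriment


def classify_net_effect(ratio: float) -> NetEffect:
    """Classify the net cross-sex effect of an allele from its ratio.

    ratio < -1 -> net beneficial; ratio > -1 -> net deleterious;
    ratio == -1 -> boundary.  Non-negative ratios are invalid (the pair is
    then not sexually antagonistic).
    """
    if ratio >= 0:
        raise ValidationError("net-effect classification requires ratio < 0")
    if ratio < -1.0:
        return NetEffect.NET_BENEFICIAL
    if ratio > -1.0:
        return NetEffect.NET_DELETERIOUS
    return NetEffect.BOUNDARY


def sai(d_male: float, d_female: float, *, root_denominator: bool = True) -> float:
    """Sexual antagonism index of a (d_M, d_F) pair.

    SAI = d_M d_F / sqrt((d_M^2 + d_F^2)/2).  The denominator is the
    quadratic-mean magnitude of the two effects, so SAI carries units of
    Cohen's d, is symmetric in its arguments, scale-equivariant
    (sai(c a, c b) = c sai(a, b) for c > 0), and negative exactly for SA
    pairs.  ``root_denominator=False`` uses the non-root denominator
    (d_M^2 + d_F^2)/2 instead; that variant is dimensionless in d and kept
    only for sensitivity checks.

    Raises
    ------
    DomainError
        If both effects are zero (0/0).
    """
    if d_male == 0.0 and d_female == 0.0:
        raise DomainError("SAI undefined when both effect sizes are zero")
    denom = (d_male * d_male + d_female * d_female) / 2.0
    if root_denominator:
        denom = math.sqrt(denom)
    return d_male * d_female / denom


def sai_array(
    d_male: np.ndarray, d_female: np.ndarray, *, root_denominator: bool = True
) -> np.ndarray:
    """Vectorised :func:`sai`; element pairs that are both zero raise."""
    d_male = np.asarray(d_male, dtype=float)
    d_female = np.asarray(d_female, dtype=float)
    denom = (d_male**2 + d_female**2) / 2.0
    if np.any(denom == 0.0):
        raise DomainError("SAI undefined when both effect sizes are zero")
    if root_denominator:
        denom = np.sqrt(denom)
    return d_male * d_female / denom


def annotate_snp_frame(df, *, root_denominator: bool = True):
    """Add per-SNP statistics to a SNP table.

    Appends columns ``is_sa`` (opposite-sign effects), ``sai``, ``ratio``
    (beneficial/deleterious effect-size ratio; NaN for non-SA records) and
    ``net_effect`` (NaN for non-SA records) to a copy of ``df``.  Records
    that are not SA after conversion keep their SAI (which is then >= 0) but
    are excluded from ratio-based statistics, per the ``is_sa`` flag.
    """
    out = df.copy()
    d_m = out["d_male"].to_numpy(dtype=float)
    d_f = out["d_female"].to_numpy(dtype=float)
    out["is_sa"] = (d_m * d_f) < 0
    out["sai"] = sai_array(d_m, d_f, root_denominator=root_denominator)
    benefit = np.maximum(d_m, d_f)
    detriment = np.minimum(d_m, d_f)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(out["is_sa"], benefit / detriment, np.nan)
    out["ratio"] = ratio
    net = np.full(len(out), None, dtype=object)
    sa = out["is_sa"].to_numpy()
    net[sa & (ratio < -1)] = NetEffect.NET_BENEFICIAL.value
    net[sa & (ratio > -1)] = NetEffect.NET_DELETERIOUS.value
    net[sa & (ratio == -1)] = NetEffect.BOUNDARY.value
    out["net_effect"] = net
    return out
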