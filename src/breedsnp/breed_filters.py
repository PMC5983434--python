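"""Within-breed genotype filters: sites fixed for the alternative allele.

A site survives when, over the breed's samples, the missing-genotype
rate is at most 7% and the alternative allele frequency equals one —
i.e. every observed diploid genotype is homozygous-alternative.  Both
quantities are computed in exact rational arithmetic; AF == 1 is tested
as an integer identity (alt-allele count == 2 x non-missing genotypes),
never with a floating-point tolerance.

Only SNP-class records enter this stage: InDels exist in the pipeline
solely to drive the site-level proximity filter.  Diploid autosomal
genotypes are assumed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from breedsnp.site_filters import VariantClass, classify_variant
from breedsnp.vcf_io import MISSING, VariantKey, VariantRecord

__all__ = [
    "BreedFilterConfig",
    "missing_rate",
    "alt_allele_frequency",
    "is_fixed_alt",
    "fixed_alt_sites",
]


@dataclass(frozen=True)
class BreedFilterConfig:
    """Thresholds of the within-breed fixation screen."""

    max_missing_rate: float = 0.07
    require_af_unity: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must lie in [0, 1]")


def _subset_indices(record: VariantRecord, sample_indices: Sequence[int] | None) -> list[int]:
    if sample_indices is None:
        return list(range(len(record.genotypes)))
    if not sample_indices:
        raise ValueError("sample subset is empty")
    for i in sample_indices:
        if not 0 <= i < len(record.genotypes):
            raise ValueError(f"sample index {i} out of range")
    return list(sample_indices)


def missing_rate(
    record: VariantRecord, sample_indices: Sequence[int] | None = None
) -> Fraction:
    """Fraction of samples in the subset with a MISSING genotype."""
    idx = _subset_indices(record, sample_indices)
    n_missing = sum(1 for i in idx if record.genotypes[i] is MISSING)
    return Fraction(n_missing, len(idx))


def alt_allele_frequency(
    record: VariantRecord, sample_indices: Sequence[int] | None = None
) -> Fraction:
    """Alternative allele frequency over non-missing diploid genotypes.

    Requires a biallelic record and at least one non-missing genotype in
    the subset.
    """
    if not record.is_biallelic:
        raise ValueError("alt_allele_frequency requires a biallelic record")
    idx = _subset_indices(record, sample_indices)
    n_obs = 0
    n_alt = 0
    for i in idx:
        gt = record.genotypes[i]
        if gt is MISSING:
            continue
        n_obs += 1
        n_alt += (gt[0] == 1) + (gt[1] == 1)
    if n_obs == 0:
        raise ValueError(
            f"all genotypes missing at {record.contig}:{record.pos}"
        )
    return Fraction(n_alt, 2 * n_obs)


def is_fixed_alt(
    record: VariantRecord,
    sample_indices: Sequence[int] | None = None,
    config: BreedFilterConfig | None = None,
) -> bool:
    """True iff missingness <= threshold and AF == 1 (integer identity)."""
    config = config or BreedFilterConfig()
    idx = _subset_indices(record, sample_indices)
    n_missing = sum(1 for i in idx if record.genotypes[i] is MISSING)
    if Fraction(n_missing, len(idx)) > Fraction(config.max_missing_rate).limit_denominator(10**6):
        return False
    n_obs = 0
    n_alt = 0
    for i in idx:
        gt = record.genotypes[i]
        if gt is MISSING:
            continue
        n_obs += 1
        n_alt += (gt[0] == 1) + (gt[1] == 1)
    if n_obs == 0:
        return False
    if config.require_af_unity:
        return n_alt == 2 * n_obs
    return True


def fixed_alt_sites(
    records: Iterable[VariantRecord],
    sample_indices: Sequence[int] | None = None,
    config: BreedFilterConfig | None = None,
) -> set[VariantKey]:
    """Keys of SNPs fixed for the alternative allele in the subset.

    Non-SNP records (InDels, MNPs, multiallelics) are ignored.
    """
    config = config or BreedFilterConfig()
    keys: set[VariantKey] = set()
    for rec in records:
        if not rec.is_biallelic:
            continue
        if classify_variant(rec) is not VariantClass.SNP:
            continue
        if is_fixed_alt(rec, sample_indices, config):
            keys.add(rec.key())
    return keys
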