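"""Site-level hard-filter cascade applied independently to each breed's VCF.

Cascade order (fixed):

1. multiallelic removal — only biallelic records continue;
2. class removal — records that are neither SNP nor InDel (e.g. MNPs)
   are dropped;
3. strand support — at least one alternative-allele read on each strand
   (DP4 alt-forward >= 1 and alt-reverse >= 1 by default);
4. quality — site quality >= 20 and mapping quality >= 30;
5. depth window — min <= DP <= median(DP) + 3 x sample SD of DP, the
   ceiling estimated from the records that survived steps 1–4;
6. duplicate positions — every record sharing (contig, pos) with another
   record is removed, all members of the collision group;
7. proximity — single pass over the surviving set: a SNP with another
   SNP closer than 3 bp or an InDel closer than 5 bp is removed; an
   InDel with another InDel closer than 10 bp is removed.  "closer than
   X" is strict: distance exactly X survives.

Records with a null QUAL/MQ/DP/DP4 fail the corresponding filter by
default (absent evidence is treated conservatively); this is
configurable per field.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from breedsnp.vcf_io import VariantRecord

__all__ = [
    "VariantClass",
    "SiteFilterConfig",
    "FilterTrace",
    "is_biallelic",
    "classify_variant",
    "passes_strand_support",
    "passes_quality",
    "compute_depth_ceiling",
    "passes_depth",
    "remove_duplicate_positions",
    "proximity_filter",
    "apply_site_filters",
]


class VariantClass(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"
    OTHER = "OTHER"


@dataclass(frozen=True)
class SiteFilterConfig:
    """Thresholds of the hard-filter cascade.

    Defaults follow the published hard-filtering protocol: >=1
    alternative read per strand, site quality >= 20, mapping quality
    >= 30, depth in [10, median + 3 sigma], and proximity windows of
    3 bp (SNP-SNP), 5 bp (SNP-InDel) and 10 bp (InDel-InDel).
    """

    min_alt_forward: int = 1
    min_alt_reverse: int = 1
    min_qual: float = 20.0
    min_mq: float = 30.0
    min_dp: int = 10
    dp_sigma_mult: float = 3.0
    indel_indel_dist: int = 10
    snp_snp_dist: int = 3
    snp_indel_dist: int = 5
    # policy for records missing the annotation a filter needs:
    # True (strict, default) -> the record fails that filter.
    fail_on_missing_dp4: bool = True
    fail_on_missing_qual: bool = True
    fail_on_missing_dp: bool = True

    def __post_init__(self) -> None:
        for name in (
            "min_alt_forward",
            "min_alt_reverse",
            "min_qual",
            "min_mq",
            "min_dp",
            "dp_sigma_mult",
            "indel_indel_dist",
            "snp_snp_dist",
            "snp_indel_dist",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FilterTrace:
    """Audit trail of the cascade: per-record first failing filter.

    ``failures`` maps a record's index in the input list to the label of
    the first filter it failed; a record is retained iff it has no
    entry.  Labels: multiallelic, mnp, strand, qual, mq, depth_low,
    depth_high, duplicate_pos, prox_snp_snp, prox_snp_indel,
    prox_indel_indel.
    """

    failures: dict[int, str] = field(default_factory=dict)
    depth_ceiling: float | None = None

    def kept_indices(self, n: int) -> list[int]:
        return [i for i in range(n) if i not in self.failures]


def is_biallelic(record: VariantRecord) -> bool:
    """True iff the record carries exactly one alternative allele."""
    return len(record.alts) == 1


def classify_variant(record: VariantRecord) -> VariantClass:
    """SNP (1 bp -> 1 bp), INDEL (length change) or OTHER (MNP etc.).

    Defined for biallelic records only.
    """
    if not is_biallelic(record):
        raise ValueError("classify_variant requires a biallelic record")
    ref, alt = record.ref, record.alts[0]
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNP
    if len(ref) != len(alt):
        return VariantClass.INDEL
    return VariantClass.OTHER


def passes_strand_support(record: VariantRecord, config: SiteFilterConfig) -> bool:
    """Alternative allele seen on both strands (DP4[2] and DP4[3])."""
    if record.dp4 is None:
        return not config.fail_on_missing_dp4
    _, _, alt_fwd, alt_rev = record.dp4
    return alt_fwd >= config.min_alt_forward and alt_rev >= config.min_alt_reverse


def passes_quality(record: VariantRecord, config: SiteFilterConfig) -> bool:
    """Site quality >= min_qual and mapping quality >= min_mq."""
    if record.qual is None or record.mq is None:
        return not config.fail_on_missing_qual
    return record.qual >= config.min_qual and record.mq >= config.min_mq


def compute_depth_ceiling(
    records: Iterable[VariantRecord], config: SiteFilterConfig | None = None
) -> float:
    """median(DP) + dp_sigma_mult x sample SD(DP) over the given records.

    The SD uses the n-1 denominator.  Records with null DP are ignored;
    fewer than two usable values is an error.
    """
    config = config or SiteFilterConfig()
    depths = [r.dp for r in records if r.dp is not None]
    if len(depths) < 2:
        raise ValueError(
            f"depth ceiling needs >= 2 records with DP, got {len(depths)}"
        )
    return statistics.median(depths) + config.dp_sigma_mult * statistics.stdev(depths)


def passes_depth(
    record: VariantRecord, ceiling: float, config: SiteFilterConfig
) -> bool:
    """min_dp <= DP <= ceiling (both bounds inclusive)."""
    if record.dp is None:
        return not config.fail_on_missing_dp
    return config.min_dp <= record.dp <= ceiling


def _depth_label(record: VariantRecord, ceiling: float, config: SiteFilterConfig) -> str:
    if record.dp is None or record.dp < config.min_dp:
        return "depth_low"
    return "depth_high"


def remove_duplicate_positions(
    records: Sequence[VariantRecord],
) -> list[VariantRecord]:
    """Drop every record whose (contig, pos) is shared with another.

    All members of a collision group are removed, not just the extras.
    """
    counts: dict[tuple[str, int], int] = {}
    for rec in records:
        key = (rec.contig, rec.pos)
        counts[key] = counts.get(key, 0) + 1
    return [rec for rec in records if counts[(rec.contig, rec.pos)] == 1]


def proximity_filter(
    records: Sequence[VariantRecord], config: SiteFilterConfig | None = None
) -> list[VariantRecord]:
    """Remove clustered variants in a single pass over the input set.

    Distances are |pos_a - pos_b| between VCF anchor positions on the
    same contig; removal decisions are all taken against the
    pre-removal set (no cascading re-evaluation).  A SNP is removed when
    any other SNP lies closer than ``snp_snp_dist`` or any InDel closer
    than ``snp_indel_dist``; an InDel is removed when any other InDel
    lies closer than ``indel_indel_dist``.  For a SNP near an InDel only
    the SNP is removed.
    """
    config = config or SiteFilterConfig()
    by_contig: dict[str, list[tuple[int, VariantClass, int]]] = {}
    for idx, rec in enumerate(records):
        by_contig.setdefault(rec.contig, []).append(
            (rec.pos, classify_variant(rec), idx)
        )
    removed: set[int] = set()
    for entries in by_contig.values():
        entries.sort()
        positions = [e[0] for e in entries]
        for i, (pos, vclass, idx) in enumerate(entries):
            window = max(
                config.snp_snp_dist, config.snp_indel_dist, config.indel_indel_dist
            )
            # scan neighbours within the widest window on either side
            j = i - 1
            neighbours = []
            while j >= 0 and pos - positions[j] < window:
                neighbours.append(entries[j])
                j -= 1
            j = i + 1
            while j < len(entries) and positions[j] - pos < window:
                neighbours.append(entries[j])
                j += 1
            for npos, nclass, _ in neighbours:
                dist = abs(pos - npos)
                if vclass is VariantClass.SNP:
                    if nclass is VariantClass.SNP and dist < config.snp_snp_dist:
                        removed.add(idx)
                    elif nclass is VariantClass.INDEL and dist < config.snp_indel_dist:
                        removed.add(idx)
                elif vclass is VariantClass.INDEL:
                    if nclass is VariantClass.INDEL and dist < config.indel_indel_dist:
                        removed.add(idx)
    return [rec for idx, rec in enumerate(records) if idx not in removed]


def _proximity_failure_label(
    rec_class: VariantClass,
    rec_pos: int,
    contig_entries: list[tuple[int, VariantClass]],
    config: SiteFilterConfig,
) -> str | None:
    for npos, nclass in contig_entries:
        if npos == rec_pos and nclass is rec_class:
            continue
        dist = abs(rec_pos - npos)
        if rec_class is VariantClass.SNP:
            if nclass is VariantClass.SNP and 0 < dist < config.snp_snp_dist:
                return "prox_snp_snp"
        elif rec_class is VariantClass.INDEL:
            if nclass is VariantClass.INDEL and 0 < dist < config.indel_indel_dist:
                return "prox_indel_indel"
    if rec_class is VariantClass.SNP:
        for npos, nclass in contig_entries:
            if nclass is VariantClass.INDEL and abs(rec_pos - npos) < config.snp_indel_dist:
                return "prox_snp_indel"
    return None


def apply_site_filters(
    records: Sequence[VariantRecord], config: SiteFilterConfig | None = None
) -> tuple[list[VariantRecord], FilterTrace]:
    """Run the full cascade; returns survivors and a per-record trace.

    The kept set is independent of input order (grouping and proximity
    are computed on sorted positions) and the operation is idempotent.
    """
    config = config or SiteFilterConfig()
    trace = FilterTrace()
    survivors: list[int] = []

    # stages 1-4: per-record predicates
    for idx, rec in enumerate(records):
        if not is_biallelic(rec):
            trace.failures[idx] = "multiallelic"
            continue
        if classify_variant(rec) is VariantClass.OTHER:
            trace.failures[idx] = "mnp"
            continue
        if not passes_strand_support(rec, config):
            trace.failures[idx] = "strand"
            continue
        if rec.qual is None or rec.qual < config.min_qual:
            if config.fail_on_missing_qual or rec.qual is not None:
                trace.failures[idx] = "qual"
                continue
        if rec.mq is None or rec.mq < config.min_mq:
            if config.fail_on_missing_qual or rec.mq is not None:
                trace.failures[idx] = "mq"
                continue
        survivors.append(idx)

    # stage 5: depth window, ceiling from the survivors of stages 1-4
    if survivors:
        usable = [records[i] for i in survivors if records[i].dp is not None]
        if len(usable) >= 2:
            ceiling = compute_depth_ceiling(usable, config)
        else:
            ceiling = float("inf")
        trace.depth_ceiling = ceiling
        next_survivors = []
        for idx in survivors:
            if passes_depth(records[idx], ceiling, config):
                next_survivors.append(idx)
            else:
                trace.failures[idx] = _depth_label(records[idx], ceiling, config)
        survivors = next_survivors

    # stage 6: duplicate positions among depth survivors
    pos_counts: dict[tuple[str, int], int] = {}
    for idx in survivors:
        key = (records[idx].contig, records[idx].pos)
        pos_counts[key] = pos_counts.get(key, 0) + 1
    next_survivors = []
    for idx in survivors:
        if pos_counts[(records[idx].contig, records[idx].pos)] > 1:
            trace.failures[idx] = "duplicate_pos"
        else:
            next_survivors.append(idx)
    survivors = next_survivors

    # stage 7: proximity, single pass over the deduplicated survivor set
    by_contig: dict[str, list[tuple[int, VariantClass]]] = {}
    classes: dict[int, VariantClass] = {}
    for idx in survivors:
        rec = records[idx]
        cls = classify_variant(rec)
        classes[idx] = cls
        by_contig.setdefault(rec.contig, []).append((rec.pos, cls))
    for entries in by_contig.values():
        entries.sort()
    kept: list[VariantRecord] = []
    for idx in survivors:
        rec = records[idx]
        label = _proximity_failure_label(
            classes[idx], rec.pos, by_contig[rec.contig], config
        )
        if label is None:
            kept.append(rec)
        else:
            trace.failures[idx] = label
    return kept, trace
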