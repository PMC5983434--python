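"""Simplified SNV coding-consequence classification against a gene model.

For a single-base substitution the affected codon is reconstructed from
the transcript's CDS (reverse-complemented for minus-strand models),
translated with the standard genetic code, and classified as
synonymous, missense, stop_gained, stop_lost or start_lost.  Variants
near a CDS/intron junction are flagged splice_region_variant using the
Sequence Ontology convention of mainstream annotators: the 1-3 terminal
exonic bases and the 1-8 intronic bases flanking a junction (the 1-2
intronic "splice site" bases are folded into the splice-region term
rather than reported separately).  Everything else inside a transcript
span is intron_variant; outside every transcript, intergenic_variant.

One most-severe call per variant is reported by default, with severity
start_lost > stop_gained > stop_lost > missense_variant >
splice_region_variant > synonymous_variant > intron_variant >
intergenic_variant.  UTR/upstream/downstream terms are intentionally
collapsed into the intron/intergenic categories.  Standard genetic code
only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import Seq
from intervaltree import IntervalTree

from breedsnp.vcf_io import VariantKey

__all__ = [
    "GeneModel",
    "ConsequenceCall",
    "SEVERITY_ORDER",
    "CODING_TERMS",
    "read_gene_models",
    "annotate_snv",
    "annotate_all",
    "consequence_summary",
    "read_bed",
    "overlap_features",
]

SEVERITY_ORDER: tuple[str, ...] = (
    "start_lost",
    "stop_gained",
    "stop_lost",
    "missense_variant",
    "splice_region_variant",
    "synonymous_variant",
    "intron_variant",
    "intergenic_variant",
)

#: Terms counted in the coding-region summary denominators.
CODING_TERMS = frozenset(SEVERITY_ORDER[:6])

_RANK = {term: i for i, term in enumerate(SEVERITY_ORDER)}


@dataclass(frozen=True)
class GeneModel:
    """One transcript: strand plus its CDS segments in genome order.

    ``cds`` holds 1-based inclusive, non-overlapping intervals sorted by
    start.  ``exons``, when given, define the intron boundaries used for
    splice-region calls; otherwise the CDS segments do.
    """

    transcript_id: str
    contig: str
    strand: str
    cds: tuple[tuple[int, int], ...]
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds:
            raise ValueError(f"transcript {self.transcript_id} has no CDS")
        prev_end = 0
        for start, end in self.cds:
            if start > end or start <= prev_end:
                raise ValueError(
                    f"CDS segments of {self.transcript_id} must be sorted and "
                    "non-overlapping"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        segs = self.exons or self.cds
        return segs[0][0], segs[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds)

    def coding_sequence(self, template: Mapping[str, str]) -> str:
        """Spliced CDS in 5'->3' coding orientation."""
        seq = "".join(
            template[self.contig][start - 1 : end] for start, end in self.cds
        ).upper()
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass(frozen=True)
class ConsequenceCall:
    key: VariantKey
    transcript_id: str | None
    term: str
    codon_change: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        in_codon_terms = self.term in SEVERITY_ORDER[:4] or self.term == "synonymous_variant"
        if in_codon_terms and self.codon_change is None:
            raise ValueError(f"{self.term} requires a codon_change")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Load transcripts from a GFF3 file (CDS grouped by Parent)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    cds_by_tx: dict[str, list] = {}
    exons_by_tx: dict[str, list] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "exon"):
            continue
        parents = feat.attributes.get("Parent", [feat.id])
        store = cds_by_tx if feat.featuretype == "CDS" else exons_by_tx
        for parent in parents:
            store.setdefault(parent, []).append(feat)
    models = []
    for tx, feats in cds_by_tx.items():
        feats.sort(key=lambda f: f.start)
        exons = exons_by_tx.get(tx)
        models.append(
            GeneModel(
                transcript_id=tx,
                contig=feats[0].seqid,
                strand=feats[0].strand,
                cds=tuple((f.start, f.end) for f in feats),
                exons=tuple((f.start, f.end) for f in sorted(exons, key=lambda f: f.start))
                if exons
                else None,
            )
        )
    return models


def _cds_offset(model: GeneModel, pos: int) -> int | None:
    """0-based offset of a genomic position within the spliced CDS, in
    genome order; None when the position is not coding."""
    offset = 0
    for start, end in model.cds:
        if start <= pos <= end:
            return offset + (pos - start)
        offset += end - start + 1
    return None


def _splice_region(model: GeneModel, pos: int) -> bool:
    """True when pos sits in the splice region of an internal junction:
    1-3 terminal exonic bases or 1-8 intronic bases."""
    segs = model.exons or model.cds
    if len(segs) < 2:
        return False
    for i in range(len(segs) - 1):
        exon_end = segs[i][1]
        next_start = segs[i + 1][0]
        # donor side: 3 terminal exonic bases, 8 intronic bases
        if exon_end - 2 <= pos <= exon_end:
            return True
        if exon_end + 1 <= pos <= exon_end + 8:
            return True
        # acceptor side
        if next_start <= pos <= next_start + 2:
            return True
        if next_start - 8 <= pos <= next_start - 1:
            return True
    return False


def _classify_coding(
    model: GeneModel, snp: VariantKey, template: Mapping[str, str], offset: int
) -> tuple[str, tuple[str, str]]:
    cds_seq = model.coding_sequence(template)
    if model.strand == "+":
        cds_index = offset
        alt_base = snp.alt.upper()
    else:
        cds_index = len(cds_seq) - 1 - offset
        alt_base = str(Seq(snp.alt.upper()).complement())
    codon_index = cds_index // 3
    within = cds_index % 3
    ref_codon = cds_seq[codon_index * 3 : codon_index * 3 + 3]
    if len(ref_codon) < 3:  # trailing partial codon of an incomplete model
        return "synonymous_variant", (ref_codon, ref_codon)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_index == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        term = "start_lost"
    elif ref_aa != "*" and alt_aa == "*":
        term = "stop_gained"
    elif ref_aa == "*" and alt_aa != "*":
        term = "stop_lost"
    elif ref_aa == alt_aa:
        term = "synonymous_variant"
    else:
        term = "missense_variant"
    return term, (ref_codon, alt_codon)


def _annotate_one(
    model: GeneModel, snp: VariantKey, template: Mapping[str, str]
) -> ConsequenceCall | None:
    if model.contig != snp.contig:
        return None
    offset = _cds_offset(model, snp.pos)
    if offset is not None:
        found = template[snp.contig][snp.pos - 1].upper()
        if found != snp.ref.upper():
            raise ValueError(
                f"{snp.contig}:{snp.pos}: template base {found!r} disagrees "
                f"with variant REF {snp.ref.upper()!r}"
            )
        term, codon_change = _classify_coding(model, snp, template, offset)
        # a coding base in the 1-3 terminal exonic bases of a junction is
        # also splice-region; report the more severe of the two terms
        if _splice_region(model, snp.pos) and _RANK["splice_region_variant"] < _RANK[term]:
            return ConsequenceCall(snp, model.transcript_id, "splice_region_variant")
        return ConsequenceCall(snp, model.transcript_id, term, codon_change)
    if _splice_region(model, snp.pos):
        return ConsequenceCall(snp, model.transcript_id, "splice_region_variant")
    lo, hi = model.span
    if lo <= snp.pos <= hi:
        return ConsequenceCall(snp, model.transcript_id, "intron_variant")
    return None


def annotate_snv(
    snp: VariantKey,
    models: Sequence[GeneModel],
    template: Mapping[str, str],
    all_transcripts: bool = False,
) -> ConsequenceCall | list[ConsequenceCall]:
    """Classify one SNV; most severe transcript wins unless
    ``all_transcripts`` requests per-transcript calls."""
    if len(snp.ref) != 1 or len(snp.alt) != 1:
        raise ValueError("annotate_snv handles single-base substitutions only")
    calls = [c for m in models if (c := _annotate_one(m, snp, template)) is not None]
    if all_transcripts:
        return calls or [ConsequenceCall(snp, None, "intergenic_variant")]
    if not calls:
        return ConsequenceCall(snp, None, "intergenic_variant")
    return min(calls, key=lambda c: _RANK[c.term])


def annotate_all(
    snps: Iterable[VariantKey],
    models: Sequence[GeneModel],
    template: Mapping[str, str],
) -> list[ConsequenceCall]:
    return [annotate_snv(snp, models, template) for snp in sorted(set(snps))]


def _round_half_up(value: float, ndigits: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def consequence_summary(
    calls_per_breed: Mapping[str, Sequence[ConsequenceCall]]
) -> dict[str, dict[str, tuple[int, float | None]]]:
    """Per-breed term counts with percentages over coding-region calls.

    Percentages (1 decimal, half-up) are reported for coding/splice
    terms only; intron/intergenic rows carry an exact count and a None
    percentage.
    """
    summary: dict[str, dict[str, tuple[int, float | None]]] = {}
    for breed, calls in calls_per_breed.items():
        counts: dict[str, int] = {}
        for call in calls:
            counts[call.term] = counts.get(call.term, 0) + 1
        n_coding = sum(n for t, n in counts.items() if t in CODING_TERMS)
        summary[breed] = {
            term: (
                n,
                _round_half_up(100.0 * n / n_coding, 1)
                if term in CODING_TERMS and n_coding
                else None,
            )
            for term, n in sorted(counts.items(), key=lambda kv: _RANK[kv[0]])
        }
    return summary


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED3/BED4 intervals (0-based half-open)."""
    intervals: list[tuple[str, int, int, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            contig, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else f"{contig}:{start}-{end}"
            intervals.append((contig, start, end, name))
    return intervals


def overlap_features(
    snps: Iterable[VariantKey],
    features: Sequence[tuple[str, int, int, str]],
) -> dict[str, set[VariantKey]]:
    """Map each BED feature name to the SNPs it contains.

    A SNP at 1-based position p overlaps [start, end) iff
    start <= p-1 < end.  Malformed intervals (start >= end) raise.
    """
    trees: dict[str, IntervalTree] = {}
    result: dict[str, set[VariantKey]] = {}
    for contig, start, end, name in features:
        if start >= end:
            raise ValueError(
                f"malformed interval {contig}:[{start},{end}) for {name!r}"
            )
        trees.setdefault(contig, IntervalTree()).addi(start, end, name)
        result.setdefault(name, set())
    for snp in snps:
        tree = trees.get(snp.contig)
        if tree is None:
            continue
        for hit in tree.at(snp.pos - 1):
            result[hit.data].add(snp)
    return result
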