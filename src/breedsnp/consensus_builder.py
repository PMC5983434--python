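"""Breed-consensus reference construction by single-base substitution.

The breed reference is the species reference with, at every
breed-specific SNP position, the reference nucleotide replaced by the
breed's fixed alternative nucleotide.  Only SNPs are applied — InDel
application with coordinate shifts is out of scope — so output contigs
keep their input lengths and coordinates.  VCF positions are 1-based;
indexing converts to 0-based internally.  Soft-masking case is
preserved: a lowercase template base is replaced by the lowercase
alternative.  An IUPAC ambiguity code or any base disagreeing with the
key's REF raises a mismatch error rather than being fuzzily matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from breedsnp.vcf_io import VariantKey

__all__ = [
    "SubstitutionLog",
    "RefMismatchError",
    "build_breed_reference",
    "diff_references",
    "read_fasta",
    "write_fasta",
]


class RefMismatchError(ValueError):
    """Template base at a substitution site disagrees with the key's REF."""


@dataclass
class SubstitutionLog:
    """Ordered record of applied substitutions and per-contig counts."""

    entries: list[tuple[str, int, str, str]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for contig, _, _, _ in self.entries:
            out[contig] = out.get(contig, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.entries)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {contig-id: sequence} preserving case."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write sequences in input order, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def build_breed_reference(
    template: Mapping[str, str], snps: Iterable[VariantKey]
) -> tuple[dict[str, str], SubstitutionLog]:
    """Substitute each SNP's alternative base into the template.

    Every key must be a single-base substitution on a template contig,
    with 1 <= pos <= contig length and a template base equal
    (case-insensitively) to the key's REF.  Output lengths equal input
    lengths and the output differs from the template at exactly the
    substituted positions.
    """
    snps = sorted(set(snps))
    seen: set[tuple[str, int]] = set()
    mutable = {name: list(seq) for name, seq in template.items()}
    log = SubstitutionLog()
    for key in snps:
        if len(key.ref) != 1 or len(key.alt) != 1:
            raise ValueError(
                f"non-SNP key at {key.contig}:{key.pos} ({key.ref}->{key.alt})"
            )
        if key.contig not in mutable:
            raise KeyError(f"contig {key.contig!r} absent from the template")
        seq = mutable[key.contig]
        if not 1 <= key.pos <= len(seq):
            raise IndexError(
                f"position {key.pos} out of range on {key.contig} "
                f"(length {len(seq)})"
            )
        if (key.contig, key.pos) in seen:
            raise ValueError(
                f"colliding substitutions at {key.contig}:{key.pos}"
            )
        found = seq[key.pos - 1]
        if found.upper() not in "ACGT":
            raise RefMismatchError(
                f"{key.contig}:{key.pos}: template base {found!r} is ambiguous; "
                "no fuzzy IUPAC matching"
            )
        if found.upper() != key.ref.upper():
            raise RefMismatchError(
                f"{key.contig}:{key.pos}: expected {key.ref.upper()!r}, "
                f"found {found!r}"
            )
        alt = key.alt.lower() if found.islower() else key.alt.upper()
        seq[key.pos - 1] = alt
        seen.add((key.contig, key.pos))
        log.entries.append((key.contig, key.pos, found, alt))
    return {name: "".join(seq) for name, seq in mutable.items()}, log


def diff_references(
    a: Mapping[str, str], b: Mapping[str, str]
) -> list[tuple[str, int, str, str]]:
    """Every 1-based position at which two same-shaped references differ."""
    if set(a) != set(b):
        raise ValueError(
            f"contig sets differ: {sorted(set(a) ^ set(b))!r}"
        )
    diffs: list[tuple[str, int, str, str]] = []
    for contig in a:
        sa, sb = a[contig], b[contig]
        if len(sa) != len(sb):
            raise ValueError(
                f"contig {contig!r} lengths differ: {len(sa)} vs {len(sb)}"
            )
        for i, (ba, bb) in enumerate(zip(sa, sb)):
            if ba != bb:
                diffs.append((contig, i + 1, ba, bb))
    return diffs
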