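"""Readers and writers for the VCF/TSV dialects the pipeline consumes.

The supported VCF subset is fixed: CHROM, POS, ID, REF, ALT, QUAL,
FILTER, INFO/DP, INFO/MQ, INFO/DP4 and FORMAT/GT.  Any other INFO or
FORMAT key is carried through as opaque text and round-trips verbatim,
but is never interpreted.  Genotypes are unphased ("/" and "|" are
equivalent) and any half-call (e.g. "./1") is treated as missing, since
the downstream missingness filter has no half-call category.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

__all__ = [
    "MISSING",
    "VariantRecord",
    "VariantKey",
    "BreedPanel",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_panel",
    "write_panel",
]

#: Sentinel for a missing diploid genotype ("./.", ".|." or any half-call).
MISSING = None

_DNA_RE = re.compile(r"^[ACGTacgt]+$")

_DEFAULT_HEADER_LINES = (
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">',
    '##INFO=<ID=MQ,Number=1,Type=Integer,Description="Root-mean-square mapping quality">',
    '##INFO=<ID=DP4,Number=4,Type=Integer,Description="Ref-forward, ref-reverse, alt-forward, alt-reverse read counts">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
)


class VcfParseError(ValueError):
    """Malformed VCF content; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UnsupportedVcfError(ValueError):
    """The file lacks a feature the pipeline requires (e.g. FORMAT/GT)."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Cross-breed identity of a biallelic variant: exact
    (contig, pos, ref, alt) match; the same position with a different
    alternative allele is a different key."""

    contig: str
    pos: int
    ref: str
    alt: str


@dataclass
class VariantRecord:
    """One VCF data line restricted to the fields the filters consume.

    ``genotypes`` holds one entry per sample of the file header: either a
    diploid ``(a, b)`` pair of allele indices (0 = ref, k = k-th alt) or
    :data:`MISSING`.  ``extra_info`` / ``extra_format`` preserve
    undeclared keys as opaque text for lossless round trips.
    """

    contig: str
    pos: int
    id: str | None
    ref: str
    alts: list[str]
    qual: float | None
    mq: float | None
    dp: int | None
    dp4: tuple[int, int, int, int] | None
    genotypes: list[tuple[int, int] | None]
    filter: str = "."
    extra_info: str | None = None
    extra_format: list[tuple[str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"POS must be >= 1, got {self.pos}")
        if not _DNA_RE.match(self.ref):
            raise ValueError(f"REF {self.ref!r} is not a DNA string")
        if not self.alts:
            raise ValueError("at least one ALT allele is required")
        for alt in self.alts:
            if not _DNA_RE.match(alt):
                raise ValueError(f"ALT {alt!r} is not a DNA string")
            if alt.upper() == self.ref.upper():
                raise ValueError(f"ALT equals REF at {self.contig}:{self.pos}")
        if self.dp is not None and self.dp < 0:
            raise ValueError("DP must be non-negative")
        if self.dp4 is not None:
            if len(self.dp4) != 4 or any(x < 0 for x in self.dp4):
                raise ValueError("DP4 must be 4 non-negative integers")
            if self.dp is not None and sum(self.dp4) > self.dp:
                raise ValueError(
                    f"DP4 sum {sum(self.dp4)} exceeds DP {self.dp} at "
                    f"{self.contig}:{self.pos}"
                )
        n_alleles = len(self.alts)
        for gt in self.genotypes:
            if gt is MISSING:
                continue
            a, b = gt
            if not (0 <= a <= n_alleles and 0 <= b <= n_alleles):
                raise ValueError(
                    f"genotype allele index out of range at {self.contig}:{self.pos}"
                )

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def key(self) -> VariantKey:
        if not self.is_biallelic:
            raise ValueError("VariantKey is defined only for biallelic records")
        return VariantKey(self.contig, self.pos, self.ref.upper(), self.alts[0].upper())


@dataclass
class BreedPanel:
    """Cohort composition: breed name -> ordered sample IDs.

    Sample IDs are globally unique (a sample cannot sit in two breeds)
    and every breed has at least one sample.
    """

    samples: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for breed, ids in self.samples.items():
            if not ids:
                raise ValueError(f"breed {breed!r} has no samples")
            for sid in ids:
                if sid in seen:
                    raise ValueError(
                        f"sample {sid!r} listed under both {seen[sid]!r} and {breed!r}"
                    )
                seen[sid] = breed

    @property
    def breeds(self) -> list[str]:
        return list(self.samples)

    @property
    def n_samples(self) -> int:
        return sum(len(v) for v in self.samples.values())


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _parse_gt(token: str) -> tuple[int, int] | None:
    alleles = re.split(r"[/|]", token)
    if len(alleles) != 2:
        return MISSING
    try:
        return (int(alleles[0]), int(alleles[1]))
    except ValueError:
        return MISSING  # "./.", ".|." and half-calls like "./1"


def _parse_info(info: str) -> tuple[float | None, int | None, tuple[int, ...] | None, str | None]:
    """Split INFO into (MQ, DP, DP4, leftover-opaque-text)."""
    mq: float | None = None
    dp: int | None = None
    dp4: tuple[int, ...] | None = None
    opaque: list[str] = []
    if info not in (".", ""):
        for item in info.split(";"):
            key, _, value = item.partition("=")
            if key == "DP" and value:
                dp = int(value)
            elif key == "MQ" and value:
                mq = float(value)
            elif key == "DP4" and value:
                dp4 = tuple(int(x) for x in value.split(","))
            else:
                opaque.append(item)
    return mq, dp, dp4, ";".join(opaque) or None


def read_vcf(path: str | Path) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCFv4.x text file (optionally gzip-compressed).

    Returns the header sample list and the records in file order.
    Raises :class:`VcfParseError` with a line number on malformed lines
    and :class:`UnsupportedVcfError` when FORMAT lacks GT.
    """
    samples: list[str] | None = None
    records: list[VariantRecord] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10 or cols[8] != "FORMAT":
                    raise VcfParseError("header lacks FORMAT/sample columns", lineno)
                samples = cols[9:]
                continue
            if samples is None:
                raise VcfParseError("data line before #CHROM header", lineno)
            cols = line.split("\t")
            if len(cols) != 9 + len(samples):
                raise VcfParseError(
                    f"expected {9 + len(samples)} columns, found {len(cols)}", lineno
                )
            (contig, pos_s, vid, ref, alt_s, qual_s, filt, info, fmt) = cols[:9]
            fmt_keys = fmt.split(":")
            if "GT" not in fmt_keys:
                raise UnsupportedVcfError(
                    f"line {lineno}: FORMAT lacks GT; genotype-free VCFs are unsupported"
                )
            gt_idx = fmt_keys.index("GT")
            try:
                pos = int(pos_s)
                qual = None if qual_s == "." else float(qual_s)
                mq, dp, dp4, opaque = _parse_info(info)
                genotypes: list[tuple[int, int] | None] = []
                sample_fields: list[list[str]] = []
                for token in cols[9:]:
                    parts = token.split(":")
                    genotypes.append(_parse_gt(parts[gt_idx]))
                    sample_fields.append(parts)
                extra_format: list[tuple[str, list[str]]] = []
                for i, key in enumerate(fmt_keys):
                    if key == "GT":
                        continue
                    extra_format.append(
                        (key, [p[i] if i < len(p) else "." for p in sample_fields])
                    )
                record = VariantRecord(
                    contig=contig,
                    pos=pos,
                    id=None if vid == "." else vid,
                    ref=ref,
                    alts=alt_s.split(","),
                    qual=qual,
                    mq=mq,
                    dp=dp,
                    dp4=dp4 if dp4 is None else tuple(dp4),  # type: ignore[arg-type]
                    genotypes=genotypes,
                    filter=filt,
                    extra_info=opaque,
                    extra_format=extra_format,
                )
            except UnsupportedVcfError:
                raise
            except (ValueError, IndexError) as exc:
                raise VcfParseError(str(exc), lineno) from exc
            records.append(record)
    if samples is None:
        raise VcfParseError("no #CHROM header found in file")
    return samples, records


def _format_info(rec: VariantRecord) -> str:
    parts: list[str] = []
    if rec.dp is not None:
        parts.append(f"DP={rec.dp}")
    if rec.mq is not None:
        mq = rec.mq
        parts.append(f"MQ={int(mq) if float(mq).is_integer() else mq}")
    if rec.dp4 is not None:
        parts.append("DP4=" + ",".join(str(x) for x in rec.dp4))
    if rec.extra_info:
        parts.append(rec.extra_info)
    return ";".join(parts) or "."


def _format_qual(qual: float | None) -> str:
    if qual is None:
        return "."
    return str(int(qual)) if float(qual).is_integer() else repr(float(qual))


def write_vcf(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    extra_header_lines: Sequence[str] = (),
) -> None:
    """Write records as a plain-text VCFv4.2 file.

    The output re-reads to field-identical records (round trip).  A
    record whose genotype count disagrees with ``samples`` raises a
    ``ValueError`` before anything is written.
    """
    records = list(records)
    for rec in records:
        if len(rec.genotypes) != len(samples):
            raise ValueError(
                f"record {rec.contig}:{rec.pos} has {len(rec.genotypes)} genotypes "
                f"for {len(samples)} samples"
            )
    with open(path, "w", encoding="utf-8") as out:
        for line in _DEFAULT_HEADER_LINES:
            out.write(line + "\n")
        for line in extra_header_lines:
            out.write(line + "\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in records:
            fmt_keys = ["GT"] + [k for k, _ in rec.extra_format]
            sample_cols = []
            for i in range(len(samples)):
                gt = rec.genotypes[i]
                gt_s = "./." if gt is MISSING else f"{gt[0]}/{gt[1]}"
                fields = [gt_s] + [vals[i] for _, vals in rec.extra_format]
                sample_cols.append(":".join(fields))
            out.write(
                "\t".join(
                    [
                        rec.contig,
                        str(rec.pos),
                        rec.id or ".",
                        rec.ref,
                        ",".join(rec.alts),
                        _format_qual(rec.qual),
                        rec.filter or ".",
                        _format_info(rec),
                        ":".join(fmt_keys),
                    ]
                    + sample_cols
                )
                + "\n"
            )


def read_panel(path: str | Path) -> BreedPanel:
    """Read a two-column breed panel TSV (breed<TAB>sample)."""
    samples: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"panel line {lineno}: expected 2 columns, got {len(cols)}")
            breed, sid = cols
            samples.setdefault(breed, []).append(sid)
    return BreedPanel(samples=samples)


def write_panel(panel: BreedPanel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for breed, ids in panel.samples.items():
            for sid in ids:
                out.write(f"{breed}\t{sid}\n")
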