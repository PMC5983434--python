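"""End-to-end orchestration: the only module that wires file paths.

Stage order: site filters per breed -> within-breed fixation ->
cross-breed specificity -> breed reference construction -> (optional)
consequence annotation -> summary reports.  Every artifact lands under
the output directory and is listed in a manifest with a SHA-256
checksum, so a rerun on identical inputs is verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from breedsnp.breed_filters import BreedFilterConfig, fixed_alt_sites
from breedsnp.consensus_builder import (
    build_breed_reference,
    read_fasta,
    write_fasta,
)
from breedsnp.consequence_annotator import (
    annotate_all,
    consequence_summary,
    read_gene_models,
)
from breedsnp.reporting import cohort_composition, filtration_summary_frame
from breedsnp.site_filters import (
    SiteFilterConfig,
    VariantClass,
    apply_site_filters,
    classify_variant,
)
from breedsnp.specificity import breed_specific_sets, venn_partition
from breedsnp.vcf_io import (
    BreedPanel,
    VariantKey,
    read_panel,
    read_vcf,
    write_vcf,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "read_keys_tsv", "write_keys_tsv"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    vcfs: dict[str, Path]  # breed -> VCF path
    panel: Path
    reference: Path
    outdir: Path
    gff3: Path | None = None
    bed: Path | None = None
    site_filter: SiteFilterConfig = field(default_factory=SiteFilterConfig)
    breed_filter: BreedFilterConfig = field(default_factory=BreedFilterConfig)

    def validate(self) -> None:
        missing = [
            str(p)
            for p in [*self.vcfs.values(), self.panel, self.reference, self.gff3, self.bed]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")


def write_keys_tsv(keys: set[VariantKey], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("contig\tpos\tref\talt\n")
        for key in sorted(keys):
            out.write(f"{key.contig}\t{key.pos}\t{key.ref}\t{key.alt}\n")


def read_keys_tsv(path: Path) -> set[VariantKey]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    return {
        VariantKey(r.contig, int(r.pos), r.ref, r.alt) for r in df.itertuples()
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON).

    Per breed: filtered VCF, filter-trace TSV, fixed-SNP keys TSV,
    breed-specific keys TSV, breed reference FASTA and substitution
    log.  Global: Venn TSV, filtration summary, cohort composition and
    (when a GFF3 is supplied) the consequence summary.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    panel = read_panel(config.panel)
    template = read_fasta(config.reference)

    fixed: dict[str, set[VariantKey]] = {}
    filtration_counts: dict[str, tuple[int, int]] = {}

    for breed, vcf_path in config.vcfs.items():
        samples, records = _stage("read_vcf")(read_vcf)(vcf_path)
        expected = panel.samples.get(breed)
        if expected is not None and samples != expected:
            raise PipelineError(
                f"stage 'read_vcf' failed: sample columns of {vcf_path} do not "
                f"match the panel entry for {breed!r}"
            )
        kept, trace = _stage("site_filters")(apply_site_filters)(
            records, config.site_filter
        )
        filtered_vcf = outdir / f"{breed}.sitefiltered.vcf"
        write_vcf(kept, samples, filtered_vcf)
        artifacts[f"{breed}/sitefiltered_vcf"] = filtered_vcf

        trace_path = outdir / f"{breed}.trace.tsv"
        with open(trace_path, "w", encoding="utf-8") as out:
            out.write("contig\tpos\tref\talt\tfailed_filter\n")
            for idx in sorted(trace.failures):
                rec = records[idx]
                out.write(
                    f"{rec.contig}\t{rec.pos}\t{rec.ref}\t"
                    f"{','.join(rec.alts)}\t{trace.failures[idx]}\n"
                )
        artifacts[f"{breed}/trace"] = trace_path

        keys = _stage("breed_filters")(fixed_alt_sites)(
            kept, None, config.breed_filter
        )
        fixed[breed] = keys
        fixed_path = outdir / f"{breed}.fixed.tsv"
        write_keys_tsv(keys, fixed_path)
        artifacts[f"{breed}/fixed_keys"] = fixed_path

        n_total_snps = sum(
            1
            for r in records
            if r.is_biallelic and classify_variant(r) is VariantClass.SNP
        )
        filtration_counts[breed] = (n_total_snps, len(keys))

    specific = _stage("specificity")(breed_specific_sets)(fixed)
    venn = _stage("specificity")(venn_partition)(fixed)
    venn_path = outdir / "venn.tsv"
    with open(venn_path, "w", encoding="utf-8") as out:
        out.write("breed_subset\tcount\n")
        for label, count in venn.to_rows():
            out.write(f"{label}\t{count}\n")
    artifacts["venn"] = venn_path

    for breed, keys in specific.items():
        specific_path = outdir / f"{breed}.specific.tsv"
        write_keys_tsv(keys, specific_path)
        artifacts[f"{breed}/specific_keys"] = specific_path

        seqs, log = _stage("consensus_builder")(build_breed_reference)(
            template, keys
        )
        ref_path = outdir / f"{breed}.reference.fa"
        write_fasta(seqs, ref_path)
        artifacts[f"{breed}/reference"] = ref_path
        log_path = outdir / f"{breed}.substitutions.tsv"
        with open(log_path, "w", encoding="utf-8") as out:
            out.write("contig\tpos\tref\talt\n")
            for contig, pos, ref, alt in log.entries:
                out.write(f"{contig}\t{pos}\t{ref}\t{alt}\n")
        artifacts[f"{breed}/substitution_log"] = log_path

    summary_path = outdir / "filtration_summary.tsv"
    filtration_summary_frame(filtration_counts).to_csv(
        summary_path, sep="\t", index=False
    )
    artifacts["filtration_summary"] = summary_path

    composition_path = outdir / "cohort_composition.tsv"
    comp = cohort_composition(panel)
    with open(composition_path, "w", encoding="utf-8") as out:
        out.write("breed\tn_samples\tpercent\n")
        for breed, ids in panel.samples.items():
            out.write(f"{breed}\t{len(ids)}\t{comp[breed]:.2f}\n")
    artifacts["cohort_composition"] = composition_path

    if config.gff3 is not None:
        models = _stage("consequence_annotator")(read_gene_models)(config.gff3)
        calls = {
            breed: annotate_all(keys, models, template)
            for breed, keys in specific.items()
        }
        summary = consequence_summary(calls)
        cons_path = outdir / "consequence_summary.tsv"
        with open(cons_path, "w", encoding="utf-8") as out:
            out.write("breed\tterm\tcount\tpercent_of_coding\n")
            for breed, terms in summary.items():
                for term, (count, pct) in terms.items():
                    pct_s = "" if pct is None else f"{pct}"
                    out.write(f"{breed}\t{term}\t{count}\t{pct_s}\n")
        artifacts["consequence_summary"] = cons_path

    manifest = {
        "outdir": str(outdir),
        "breeds": list(config.vcfs),
        "artifacts": {
            name: {"path": str(path), "sha256": _sha256(path)}
            for name, path in artifacts.items()
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
        out.write("\n")
    return manifest
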