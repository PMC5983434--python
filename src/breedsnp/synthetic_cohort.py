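"""Synthetic multi-breed cohort generator with a planted-truth table.

The generator emulates, at desk scale, the data layout of a pooled
multi-breed resequencing study: one multi-sample VCF per breed called
against a shared reference, with site annotations (QUAL, MQ, DP, DP4)
and diploid genotypes.  Planted record categories cover the signal the
pipeline must recover (breed-specific fixed SNPs, SNPs fixed in all or
a subset of breeds, segregating SNPs) and one decoy per site filter
(low quality, low mapping quality, strand bias, depth outliers,
duplicate positions, SNP clusters, SNPs near InDels, InDel pairs,
multiallelic sites).

Every decoy is constructed to violate exactly one filter; planted
positions are laid out on a 30 bp grid so that unrelated records never
trip the proximity rules (within-category offsets < 10 bp create the
clustered configurations on purpose).  Per-sample missingness of
records meant to survive is capped strictly at the 7% screen.  All
randomness flows from one seed; identical config + seed gives
byte-identical outputs.

The truth table is the pipeline's end-to-end oracle: one row per
planted record per breed VCF, with the record's category and its
expected fate at the site-filter and fixation stages, plus the breed
(if any) for which it must emerge as breed-specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from breedsnp.consensus_builder import write_fasta
from breedsnp.vcf_io import (
    MISSING,
    BreedPanel,
    VariantRecord,
    write_panel,
    write_vcf,
)

__all__ = ["CohortConfig", "Cohort", "write_reference", "generate_cohort", "default_config"]

_GRID_STEP = 30  # >= proximity window (10) + max within-block offset (9) + margin
_BLOCK_MARGIN = 100  # keep planted sites away from contig ends

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs of the synthetic cohort.

    ``depth_mean``/``depth_sd`` describe per-sample coverage; the
    site-level pooled DP of an n-sample breed is drawn around
    n x depth_mean.  ``n_partial`` lists (breed-subset, count) pairs of
    SNPs fixed in exactly that subset of breeds.
    """

    breeds: tuple[str, ...] = ("ANG", "BSW", "FLV", "HER", "JER", "LIM", "SIM")
    samples_per_breed: dict[str, int] = field(
        default_factory=lambda: {
            "ANG": 20, "BSW": 15, "FLV": 10, "HER": 12,
            "JER": 11, "LIM": 13, "SIM": 18,
        }
    )
    contigs: tuple[tuple[str, int], ...] = (("1", 300_000), ("2", 200_000))
    n_breed_specific: dict[str, int] | int = 80
    n_shared_all: int = 250
    n_partial: tuple[tuple[tuple[str, ...], int], ...] = (
        (("JER", "FLV"), 40),
        (("JER", "BSW"), 35),
        (("SIM", "FLV"), 25),
        (("ANG", "HER"), 15),
    )
    n_segregating: int = 3200
    n_lowqual: int = 40
    n_lowmq: int = 40
    n_strandbias: int = 40
    n_depth_outlier: int = 40
    n_duplicate_pos: int = 30
    n_snp_cluster: int = 30
    n_snp_near_indel: int = 30
    n_indel_pair: int = 30
    n_multiallelic: int = 40
    missing_rate_range: tuple[float, float] = (0.0, 0.05)
    depth_mean: float = 12.0
    depth_sd: float = 4.0
    seed: int = 0

    def specific_counts(self) -> dict[str, int]:
        if isinstance(self.n_breed_specific, int):
            return {b: self.n_breed_specific for b in self.breeds}
        return dict(self.n_breed_specific)

    def n_units(self) -> int:
        return (
            sum(self.specific_counts().values())
            + self.n_shared_all
            + sum(c for _, c in self.n_partial)
            + self.n_segregating
            + self.n_lowqual
            + self.n_lowmq
            + self.n_strandbias
            + self.n_depth_outlier
            + self.n_duplicate_pos
            + self.n_snp_cluster
            + self.n_snp_near_indel
            + self.n_indel_pair
            + self.n_multiallelic
        )


@dataclass
class Cohort:
    """In-memory synthetic cohort: per-breed VCF contents, the reference,
    the breed panel and the planted-truth table."""

    config: CohortConfig
    panel: BreedPanel
    reference: dict[str, str]
    records: dict[str, list[VariantRecord]]  # breed -> sorted records
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit reference FASTA, per-breed VCFs, panel TSV and truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["reference"] = outdir / "reference.fa"
        write_fasta(self.reference, paths["reference"])
        paths["panel"] = outdir / "panel.tsv"
        write_panel(self.panel, paths["panel"])
        for breed in self.config.breeds:
            p = outdir / f"{breed}.vcf"
            write_vcf(self.records[breed], self.panel.samples[breed], p)
            paths[f"vcf:{breed}"] = p
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def write_reference(
    contigs: Sequence[tuple[str, int]], seed: int | np.random.SeedSequence
) -> dict[str, str]:
    """Uniformly random A/C/G/T sequences, reproducible for a seed."""
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for name, length in contigs:
        if length < 1:
            raise ValueError(f"contig {name!r} length must be >= 1")
        out[name] = "".join(_BASES[rng.integers(0, 4, size=length)])
    return out


def _allocate_blocks(config: CohortConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Pick one grid-aligned base position per planted unit, collision-free."""
    grid: list[tuple[str, int]] = []
    for name, length in config.contigs:
        start = _BLOCK_MARGIN
        stop = length - _BLOCK_MARGIN - _GRID_STEP
        grid.extend((name, int(p)) for p in range(start, stop, _GRID_STEP))
    n = config.n_units()
    if n > len(grid):
        raise ValueError(
            f"requested {n} planted units but contigs only hold {len(grid)} "
            f"blocks at {_GRID_STEP} bp spacing"
        )
    chosen = rng.choice(len(grid), size=n, replace=False)
    return [grid[i] for i in sorted(chosen)]


def _alt_base(ref: str, rng: np.random.Generator, exclude: str = "") -> str:
    choices = [b for b in "ACGT" if b != ref.upper() and b not in exclude]
    return choices[int(rng.integers(0, len(choices)))]


class _Builder:
    def __init__(self, config: CohortConfig):
        self.config = config
        s_main, s_ref = np.random.SeedSequence(config.seed).spawn(2)
        self.rng = np.random.default_rng(s_main)
        self.reference = write_reference(config.contigs, s_ref)
        self.records: dict[str, list[VariantRecord]] = {b: [] for b in config.breeds}
        self.truth_rows: list[dict] = []
        self.blocks = _allocate_blocks(config, self.rng)
        self._next_block = 0

    # -- low-level draws ------------------------------------------------

    def _take_block(self) -> tuple[str, int]:
        block = self.blocks[self._next_block]
        self._next_block += 1
        return block

    def _site_depth(self, breed: str) -> int:
        """Pooled DP for a record meant to pass the depth window."""
        n = self.config.samples_per_breed[breed]
        mu = n * self.config.depth_mean
        sigma = math.sqrt(n) * self.config.depth_sd
        # truncate at 2 sigma so survivors stay under the median + 3 SD ceiling
        dp = self.rng.normal(mu, sigma)
        dp = min(max(dp, mu - 2 * sigma), mu + 2 * sigma)
        return max(10, int(round(dp)))

    def _dp4(self, dp: int, alt_frac: float, strandbias: bool = False) -> tuple[int, int, int, int]:
        n_alt = int(round(dp * alt_frac))
        n_alt = min(max(n_alt, 0), dp)
        n_ref = dp - n_alt
        if strandbias:
            alt_f, alt_r = 0, n_alt
        else:
            alt_f = n_alt // 2
            alt_r = n_alt - alt_f
            if n_alt >= 2 and alt_f == 0:
                alt_f, alt_r = 1, n_alt - 1
        ref_f = n_ref // 2
        return (ref_f, n_ref - ref_f, alt_f, alt_r)

    def _qual(self, low: bool = False) -> float:
        if low:
            return float(round(self.rng.uniform(1.0, 19.5), 1))
        return float(round(self.rng.uniform(30.0, 200.0), 1))

    def _mq(self, low: bool = False) -> float:
        if low:
            return float(int(self.rng.integers(5, 30)))
        return float(int(self.rng.integers(40, 61)))

    def _fixed_genotypes(self, breed: str, allow_missing: bool = True) -> list:
        n = self.config.samples_per_breed[breed]
        lo, hi = self.config.missing_rate_range
        cap = int(math.floor(min(hi, 0.07) * n))
        m = int(self.rng.integers(0, cap + 1)) if (allow_missing and cap > 0) else 0
        gts: list = [(1, 1)] * n
        if m:
            for i in self.rng.choice(n, size=m, replace=False):
                gts[int(i)] = MISSING
        return gts

    def _segregating_genotypes(self, breed: str) -> list:
        n = self.config.samples_per_breed[breed]
        draws = self.rng.choice(3, size=n, p=[0.25, 0.5, 0.25])
        gts: list = [[(0, 0), (0, 1), (1, 1)][int(d)] for d in draws]
        if all(g == (1, 1) for g in gts):
            gts[0] = (0, 1)
        return gts

    # -- record factory --------------------------------------------------

    def _snp_record(
        self,
        breed: str,
        contig: str,
        pos: int,
        genotypes: list,
        alt: str | None = None,
        qual: float | None = None,
        mq: float | None = None,
        dp: int | None = None,
        strandbias: bool = False,
        alts: list[str] | None = None,
    ) -> VariantRecord:
        ref = self.reference[contig][pos - 1]
        if alts is None:
            alts = [alt or _alt_base(ref, self.rng)]
        dp = self._site_depth(breed) if dp is None else dp
        n_obs = sum(1 for g in genotypes if g is not MISSING)
        n_alt = sum((g[0] != 0) + (g[1] != 0) for g in genotypes if g is not MISSING)
        alt_frac = n_alt / (2 * n_obs) if n_obs else 1.0
        return VariantRecord(
            contig=contig,
            pos=pos,
            id=None,
            ref=ref,
            alts=alts,
            qual=self._qual() if qual is None else qual,
            mq=self._mq() if mq is None else mq,
            dp=dp,
            dp4=self._dp4(dp, alt_frac, strandbias=strandbias),
            genotypes=genotypes,
        )

    def _indel_record(self, breed: str, contig: str, pos: int) -> VariantRecord:
        ref = self.reference[contig][pos - 1 : pos + 1]  # 2 bp deletion anchor
        dp = self._site_depth(breed)
        gts = self._fixed_genotypes(breed, allow_missing=False)
        return VariantRecord(
            contig=contig,
            pos=pos,
            id=None,
            ref=ref,
            alts=[ref[0]],
            qual=self._qual(),
            mq=self._mq(),
            dp=dp,
            dp4=self._dp4(dp, 1.0),
            genotypes=gts,
        )

    def _add(
        self,
        breed: str,
        rec: VariantRecord,
        category: str,
        *,
        role: str = "primary",
        site_pass: bool,
        fixed: bool,
        specific_for: str = "",
    ) -> None:
        self.records[breed].append(rec)
        self.truth_rows.append(
            {
                "contig": rec.contig,
                "pos": rec.pos,
                "ref": rec.ref.upper(),
                "alt": ",".join(a.upper() for a in rec.alts),
                "breed": breed,
                "category": category,
                "role": role,
                "expect_site_pass": site_pass,
                "expect_fixed": fixed,
                "specific_for": specific_for,
            }
        )

    def _round_robin(self) -> str:
        breed = self.config.breeds[self._rr % len(self.config.breeds)]
        self._rr += 1
        return breed

    # -- categories ------------------------------------------------------

    def build(self) -> Cohort:
        cfg = self.config
        self._rr = 0

        for breed, count in cfg.specific_counts().items():
            for _ in range(count):
                contig, pos = self._take_block()
                rec = self._snp_record(breed, contig, pos, self._fixed_genotypes(breed))
                self._add(
                    breed, rec, "breed_specific",
                    site_pass=True, fixed=True, specific_for=breed,
                )

        for _ in range(cfg.n_shared_all):
            contig, pos = self._take_block()
            ref = self.reference[contig][pos - 1]
            alt = _alt_base(ref, self.rng)
            for breed in cfg.breeds:
                rec = self._snp_record(
                    breed, contig, pos, self._fixed_genotypes(breed), alt=alt
                )
                self._add(breed, rec, "shared_all", site_pass=True, fixed=True)

        for subset, count in cfg.n_partial:
            for _ in range(count):
                contig, pos = self._take_block()
                ref = self.reference[contig][pos - 1]
                alt = _alt_base(ref, self.rng)
                for breed in subset:
                    rec = self._snp_record(
                        breed, contig, pos, self._fixed_genotypes(breed), alt=alt
                    )
                    self._add(breed, rec, "partial", site_pass=True, fixed=True)

        for _ in range(cfg.n_segregating):
            breed = self._round_robin()
            contig, pos = self._take_block()
            rec = self._snp_record(breed, contig, pos, self._segregating_genotypes(breed))
            self._add(breed, rec, "segregating", site_pass=True, fixed=False)

        for _ in range(cfg.n_lowqual):
            breed = self._round_robin()
            contig, pos = self._take_block()
            rec = self._snp_record(
                breed, contig, pos, self._fixed_genotypes(breed, allow_missing=False),
                qual=self._qual(low=True),
            )
            self._add(breed, rec, "lowqual", site_pass=False, fixed=False)

        for _ in range(cfg.n_lowmq):
            breed = self._round_robin()
            contig, pos = self._take_block()
            rec = self._snp_record(
                breed, contig, pos, self._fixed_genotypes(breed, allow_missing=False),
                mq=self._mq(low=True),
            )
            self._add(breed, rec, "lowmq", site_pass=False, fixed=False)

        for _ in range(cfg.n_strandbias):
            breed = self._round_robin()
            contig, pos = self._take_block()
            rec = self._snp_record(
                breed, contig, pos, self._fixed_genotypes(breed, allow_missing=False),
                strandbias=True,
            )
            self._add(breed, rec, "strandbias", site_pass=False, fixed=False)

        for i in range(cfg.n_depth_outlier):
            breed = self._round_robin()
            contig, pos = self._take_block()
            n = cfg.samples_per_breed[breed]
            if i % 2 == 0:
                dp = int(self.rng.integers(2, 10))  # below the min-depth floor
            else:
                dp = int(20 * n * cfg.depth_mean)  # far above any plausible ceiling
            rec = self._snp_record(
                breed, contig, pos, self._fixed_genotypes(breed, allow_missing=False),
                dp=dp,
            )
            self._add(breed, rec, "depth_outlier", site_pass=False, fixed=False)

        for _ in range(cfg.n_duplicate_pos):
            breed = self._round_robin()
            contig, pos = self._take_block()
            ref = self.reference[contig][pos - 1]
            alt1 = _alt_base(ref, self.rng)
            alt2 = _alt_base(ref, self.rng, exclude=alt1)
            for alt in (alt1, alt2):
                rec = self._snp_record(
                    breed, contig, pos,
                    self._fixed_genotypes(breed, allow_missing=False), alt=alt,
                )
                self._add(breed, rec, "duplicate_pos", site_pass=False, fixed=False)

        for _ in range(cfg.n_snp_cluster):
            breed = self._round_robin()
            contig, pos = self._take_block()
            for offset in (0, 2):  # 2 bp apart: closer than the 3 bp SNP-SNP rule
                rec = self._snp_record(
                    breed, contig, pos + offset,
                    self._fixed_genotypes(breed, allow_missing=False),
                )
                self._add(breed, rec, "snp_cluster", site_pass=False, fixed=False)

        for _ in range(cfg.n_snp_near_indel):
            breed = self._round_robin()
            contig, pos = self._take_block()
            rec = self._snp_record(
                breed, contig, pos, self._fixed_genotypes(breed, allow_missing=False)
            )
            self._add(breed, rec, "snp_near_indel", site_pass=False, fixed=False)
            # companion InDel 4 bp away: kills the SNP, itself survives the
            # site filters but is excluded from the SNP-only fixation stage
            indel = self._indel_record(breed, contig, pos + 4)
            self._add(
                breed, indel, "snp_near_indel", role="companion_indel",
                site_pass=True, fixed=False,
            )

        for _ in range(cfg.n_indel_pair):
            breed = self._round_robin()
            contig, pos = self._take_block()
            for offset in (0, 9):  # 9 bp apart: closer than the 10 bp InDel rule
                indel = self._indel_record(breed, contig, pos + offset)
                self._add(breed, indel, "indel_pair", site_pass=False, fixed=False)

        for _ in range(cfg.n_multiallelic):
            breed = self._round_robin()
            contig, pos = self._take_block()
            ref = self.reference[contig][pos - 1]
            alt1 = _alt_base(ref, self.rng)
            alt2 = _alt_base(ref, self.rng, exclude=alt1)
            n = cfg.samples_per_breed[breed]
            gts = [(1, 1)] * (n - 1) + [(1, 2)]
            rec = self._snp_record(
                breed, contig, pos, gts, alts=[alt1, alt2],
            )
            self._add(breed, rec, "multiallelic", site_pass=False, fixed=False)

        for breed in cfg.breeds:
            self.records[breed].sort(key=lambda r: (r.contig, r.pos, ",".join(r.alts)))
        self._check_depth_separation()

        panel = BreedPanel(
            samples={
                b: [f"{b}_{i:03d}" for i in range(cfg.samples_per_breed[b])]
                for b in cfg.breeds
            }
        )
        truth = pd.DataFrame(self.truth_rows).sort_values(
            ["breed", "contig", "pos", "alt"], kind="mergesort"
        ).reset_index(drop=True)
        return Cohort(
            config=cfg,
            panel=panel,
            reference=self.reference,
            records=self.records,
            truth=truth,
        )

    def _check_depth_separation(self) -> None:
        """Planted fates must be realizable: per breed, every record meant
        to pass the depth window must sit at or below the realized
        median + 3 SD ceiling, and every high outlier above it."""
        import statistics

        truth = pd.DataFrame(self.truth_rows)
        for breed in self.config.breeds:
            recs = self.records[breed]
            sub = truth[truth.breed == breed]
            failing_early = {
                (r.contig, r.pos, r.alt)
                for r in sub[sub.category.isin(["multiallelic", "lowqual", "lowmq", "strandbias"])].itertuples()
            }
            depths = [
                r.dp for r in recs
                if (r.contig, r.pos, ",".join(a.upper() for a in r.alts)) not in failing_early
            ]
            ceiling = statistics.median(depths) + 3 * statistics.stdev(depths)
            by_key: dict[tuple, int] = {
                (r.contig, r.pos, ",".join(a.upper() for a in r.alts)): r.dp for r in recs
            }
            for row in sub.itertuples():
                dp = by_key[(row.contig, row.pos, row.alt)]
                if row.category == "depth_outlier":
                    if 10 <= dp <= ceiling:
                        raise RuntimeError(
                            f"depth decoy at {row.contig}:{row.pos} ({breed}) "
                            f"landed inside the depth window [10, {ceiling:.1f}]"
                        )
                elif row.expect_site_pass or row.category in (
                    "duplicate_pos", "snp_cluster", "snp_near_indel", "indel_pair",
                ):
                    if not 10 <= dp <= ceiling:
                        raise RuntimeError(
                            f"planted record at {row.contig}:{row.pos} ({breed}) "
                            f"fell outside the depth window [10, {ceiling:.1f}]"
                        )


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    return replace(CohortConfig(seed=seed), **overrides)


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort for a config (see module doc)."""
    config = config or CohortConfig()
    for subset, _ in config.n_partial:
        unknown = set(subset) - set(config.breeds)
        if unknown:
            raise ValueError(f"partial subset names unknown breeds: {sorted(unknown)}")
    return _Builder(config).build()
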