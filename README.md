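# breedsnp

Discovery of **breed-specific SNPs** from multi-breed resequencing
cohorts, and construction of **breed-specific consensus reference
genomes** from them.

When a species' reference genome derives from one or two closely
related animals (as the cattle reference does, from the Hereford
Domino lineage), variant calls for every other breed are biased toward
that lineage's haplotype. A direct remedy is to find, for each breed,
the variants on which the breed itself is monomorphic for the
non-reference allele — fixed differences from the reference — and,
where such a variant occurs in exactly one breed, call it
*breed-specific* and substitute it into the reference to obtain a
breed-specific template. `breedsnp` implements that analysis as a
tested, deterministic pipeline for population geneticists working with
per-breed multi-sample VCFs.

## The method

Given one multi-sample VCF per breed (with INFO `DP`, `MQ`, `DP4` and
per-sample `GT`), a breed panel TSV and the reference FASTA:

1. **Site filters** (per breed, in order): drop multiallelic records;
   drop non-SNP/non-InDel records; require ≥ 1 alternative-allele read
   on each strand (`DP4`); require site quality ≥ 20 and mapping
   quality ≥ 30; require depth 10 ≤ DP ≤ median(DP) + 3·SD(DP), the
   ceiling estimated from the records surviving the previous steps;
   remove all records sharing a position; remove SNPs with another SNP
   closer than 3 bp or an InDel closer than 5 bp, and InDels with
   another InDel closer than 10 bp ("closer than" is strict).
2. **Within-breed fixation**: keep SNPs with ≤ 7 % missing genotypes
   whose alternative allele frequency equals 1 — i.e. every observed
   genotype is homozygous-alternative. Computed in exact rational
   arithmetic; AF = 1 is an integer identity, never a float tolerance.
3. **Cross-breed specificity**: the per-breed fixed-SNP sets are
   Venn-partitioned over all 2^B − 1 breed subsets; keys in exactly one
   breed's set are that breed's specific SNPs.
4. **Consensus construction**: each breed-specific SNP's alternative
   base replaces the reference base (1-based VCF coordinates, case
   preserved, REF verified against the template).
5. **Consequence annotation** (optional, with a GFF3): a compact SNV
   classifier reconstructs and translates the affected codon
   (strand-aware, standard genetic code) and reports
   synonymous/missense/stop-gained/stop-lost/start-lost, splice-region
   (SO convention: 1–3 exonic / 1–8 intronic bases at a junction),
   intron and intergenic terms.

A bundled synthetic-cohort generator plants breed-specific, shared,
partially shared and segregating SNPs plus one decoy family per site
filter, and records every planted record's expected fate in a truth
table — the oracle for the package's end-to-end tests.

## Worked example

Simulate a 7-breed cohort and run the full pipeline:

```sh
breedsnp simulate --seed 7 --outdir cohort
# wrote 11 files under cohort

breedsnp run \
  --vcf ANG=cohort/ANG.vcf --vcf BSW=cohort/BSW.vcf --vcf FLV=cohort/FLV.vcf \
  --vcf HER=cohort/HER.vcf --vcf JER=cohort/JER.vcf --vcf LIM=cohort/LIM.vcf \
  --vcf SIM=cohort/SIM.vcf \
  --panel cohort/panel.tsv --reference cohort/reference.fa --outdir out
# 45 artifacts; manifest at out/manifest.json
```

`out/venn.tsv` is the exclusive Venn partition of the per-breed
fixed-SNP sets (non-empty cells only):

```text
breed_subset	count
ANG	80
BSW	80
...
ANG,HER	15
BSW,JER	35
FLV,JER	40
FLV,SIM	25
ANG,BSW,FLV,HER,JER,LIM,SIM	250
```

The singleton cells (80 per breed here) are the breed-specific SNPs;
the all-breeds cell (250) holds variants fixed in every breed —
differences of the reference individual from the species consensus
rather than of any one breed. Per breed, `out/<breed>.specific.tsv`
lists the specific keys, `out/<breed>.reference.fa` is the consensus
reference with exactly those bases substituted (verifiable with
`out/<breed>.substitutions.tsv`), and `out/filtration_summary.tsv`
reports the fixation-filter yield:

```text
breed	total_snps	after_filtration	percent
ANG	847	345	40.732
BSW	867	365	42.099
...
```

(The yield is high here because the simulated cohort plants a large
fraction of fixed sites; on real whole-genome data it is a fraction of
a percent.) Each stage is also exposed as its own subcommand
(`site-filter`, `breed-filter`, `specificity`, `build-ref`, `annotate`,
`report`) and as plain library functions.

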