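# Methods

## Model and assumptions

`breedsnp` targets cohorts in which variant calling was performed
**pooled per breed**: one multi-sample VCF per breed, called against a
common reference, with site-level annotations (QUAL, MQ, DP, DP4)
describing the pooled evidence and per-sample diploid genotypes (GT).
All genotypes are treated as unphased diploid autosomal calls; `|` and
`/` separators are equivalent and half-calls (`./1`) are treated as
missing, because the downstream missingness screen has no half-call
category. Only the VCF subset the filters consume is interpreted
(CHROM, POS, ID, REF, ALT, QUAL, FILTER, INFO DP/MQ/DP4, FORMAT GT);
other INFO/FORMAT keys round-trip as opaque text.

A *breed-specific SNP* is a biallelic single-nucleotide variant that,
after site filtering, is fixed for the alternative allele (AF = 1)
with ≤ 7 % missing genotypes in exactly one breed and absent from the
**filtered** sets of all other breeds. Absence is judged against the
other breeds' fixed-SNP sets, the semantics under which the Venn
partition of the filtered sets is drawn; a strict mode judging absence
against other breeds' raw post-site-filter call sets would require
per-breed raw call books and is not the default.

## The site-filter cascade

Stages run in a fixed order, and each record's first failing stage is
recorded in an audit trace:

| stage | rule | default |
|---|---|---|
| multiallelic | records with ≥ 2 ALT alleles removed | — |
| class | records neither SNP nor InDel (MNPs) removed | — |
| strand | alt reads required on each strand (DP4) | ≥ 1 forward and ≥ 1 reverse |
| quality | site and mapping quality floors | QUAL ≥ 20, MQ ≥ 30 |
| depth | window on pooled site depth | 10 ≤ DP ≤ median + 3·SD |
| duplicates | all records sharing (contig, pos) removed | — |
| proximity | clustered variants removed, single pass | SNP–SNP < 3, SNP–InDel < 5, InDel–InDel < 10 bp |

Numerical and semantic choices:

- **Depth ceiling.** median(DP) + 3 × sample standard deviation (n−1
  denominator; the estimator is a package choice, as is computing the
  statistic genome-wide per breed VCF rather than per chromosome —
  both configurable). The ceiling is estimated over the records that
  survived the multiallelic/class/strand/quality stages, so upstream
  garbage does not distort it; with fewer than two usable DP values the
  ceiling is unbounded. Note that the ceiling is estimated from data
  that still contains the depth outliers themselves; a single extreme
  outlier among fewer than ~10 records inflates the SD enough to place
  the ceiling above the outlier, which is statistically correct
  behaviour of the estimator, not a bug — at realistic call-set sizes
  (hundreds of sites and up) outliers are always caught.
- **"Closer than X"** is strict: a pair at distance exactly X
  survives. Distances are between VCF anchor positions (POS); the
  inserted/deleted span of an InDel is ignored for distance purposes.
- **Proximity is single-pass**: removal decisions are all evaluated
  against the pre-removal record set, with no cascading re-evaluation.
  For a SNP near an InDel only the SNP is removed; InDels are governed
  solely by the InDel–InDel rule.
- **Duplicate positions**: every member of a collision group is
  removed, not just the extras — two calls at one base pair are
  mutually discrediting.
- **Null annotations** (QUAL/MQ/DP/DP4 absent) fail the corresponding
  stage by default; each policy is independently relaxable in
  `SiteFilterConfig` for call sets that lack an annotation entirely.

## Fixation and specificity

Missing rate and alternative allele frequency use `fractions.Fraction`;
AF = 1 is tested as `alt_count == 2 × non_missing`, never with a float
tolerance, so "fixed" means literally that every observed genotype is
1/1. AF is computed over non-missing genotypes only — the two criteria
are stated jointly, and counting missing genotypes as reference would
make fixation unsatisfiable at any missingness. InDels never enter
this stage; they exist in the pipeline only to drive the proximity
filter. Cross-breed identity is the exact (contig, pos, ref, alt)
tuple: the same position with a different alternative allele is a
different variant, since it is the allele that gets substituted into
the reference.

## Consensus references

Only SNPs are substituted (coordinate-shifting InDel application is out
of scope), so output contigs keep their lengths and all annotation
coordinates remain valid. The template base is verified against each
key's REF (IUPAC ambiguity codes are a hard error, not fuzzy-matched),
soft-mask case is preserved, and the substitution log equals
`diff_references(template, output)` by construction — re-applying the
same substitution set to its own output raises REF-mismatch errors,
which is the intended tamper check.

## Consequence classifier

A deliberately compact SNV classifier, not a full annotator: the
affected codon is rebuilt from the spliced CDS (reverse-complemented
for minus-strand transcripts), translated with the standard genetic
code only, and ranked with severity start_lost > stop_gained >
stop_lost > missense > splice_region > synonymous > intron >
intergenic. One most-severe call per variant is reported (per-transcript
calls behind a flag). The splice region follows the Sequence Ontology
convention of mainstream annotators — 1–3 terminal exonic and 1–8
intronic bases at a junction, with the 1–2 intronic splice-site bases
folded into the same term — and a coding base inside the exonic splice
region receives the more severe of its codon-derived term and
splice_region (so a synonymous change at a junction reports as
splice_region, a missense change stays missense). UTR, up/downstream
and regulatory terms are intentionally collapsed into intron/intergenic.
Incomplete models whose CDS length is not a multiple of 3 classify
their trailing partial codon as synonymous rather than guessing.

## Synthetic cohort

The generator emulates the study layout the pipeline assumes — seven
breeds with sample counts roughly proportional to a real multi-breed
bull cohort but at desk scale (ANG 20, BSW 15, FLV 10, HER 12, JER 11,
LIM 13, SIM 18), two contigs totalling 500 kb, and ~4,400 planted
units (~6,200 VCF records): per breed 80 breed-specific fixed SNPs,
250 SNPs fixed in all breeds, four partially-shared subsets, 3,200
segregating SNPs, and 30–40 decoys per site filter. Per-sample
coverage is modelled at mean 12× (motivated by the 7–17× genome
averages typical of such cohorts), and a breed's pooled site depth is
drawn as a truncated normal around n_samples × 12. Missingness for
records meant to survive is drawn strictly below the 7 % screen;
planted units sit on a 30 bp grid so unrelated records never trip the
proximity rules, while the duplicate/cluster/near-InDel categories
create their collisions within a unit on purpose.

Construction guarantees, checked at generation time and again by the
test suite: every decoy violates exactly one filter; survivor depths
fall inside the realized median + 3·SD window and high outliers
outside it; no planted record belongs to two categories; all outputs
are byte-identical for a fixed seed.

What the generator does **not** emulate: linkage disequilibrium,
demography or drift (sites are independent), read-level errors
(annotations are drawn consistent with each record's intended fate
rather than from reads), reference errors, and sex-chromosome ploidy.
Passing the planted-truth test therefore demonstrates that the
pipeline's set logic and filter semantics are exact, not that the
thresholds are optimal for any real cohort.

## Problem sizes and determinism

Default test and verification sizes — a ~6,200-record 7-breed cohort
for end-to-end recovery, 100 random fixtures of ≤ 200 records for the
cascade-vs-brute-force battery, 20 trials each for the Venn and
consensus batteries — were chosen so the whole suite exercises every
code path in seconds while keeping the brute-force oracles (O(n²)
all-pairs scans) comfortably tractable. All randomness in the package,
tests and acceptance script flows from explicit seeds; reruns are
reproducible bit-for-bit, and the pipeline manifest records a SHA-256
checksum per artifact to make that verifiable.

## Known limitations

- One VCF per breed is required; merging a joint multi-breed VCF is
  out of scope.
- BCF, tabix indexing and genotype likelihood refinements are
  unsupported; the text VCF subset above is the contract.
- The consequence classifier is a reduced vocabulary, not a VEP
  replacement; severity ordering beyond the eight terms is undefined.
- The fixation screen assumes diploid autosomes; haploid or mixed
  ploidy input will misestimate AF.
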