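import numpy as np
import pytest

from breedsnp.synthetic_cohort import CohortConfig, generate_cohort
from breedsnp.vcf_io import MISSING, VariantKey, VariantRecord


SMALL_CONFIG = CohortConfig(
    breeds=("ANG", "JER", "SIM"),
    samples_per_breed={"ANG": 12, "JER": 15, "SIM": 10},
    contigs=(("1", 60_000),),
    n_breed_specific=20,
    n_shared_all=15,
    n_partial=((("ANG", "JER"), 8),),
    n_segregating=120,
    n_lowqual=6,
    n_lowmq=6,
    n_strandbias=6,
    n_depth_outlier=6,
    n_duplicate_pos=5,
    n_snp_cluster=5,
    n_snp_near_indel=5,
    n_indel_pair=5,
    n_multiallelic=6,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    """3-breed toy cohort shared across tests (read-only)."""
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_cohort():
    """The full 7-breed cohort at default study conditions."""
    return generate_cohort(CohortConfig(seed=1))


def make_record(
    contig="1",
    pos=100,
    ref="A",
    alts=("G",),
    qual=50.0,
    mq=50.0,
    dp=100,
    dp4=None,
    genotypes=None,
    n_samples=4,
):
    """Convenience constructor for filter-level tests."""
    if dp4 is None and dp is not None:
        dp4 = (0, 0, dp // 2, dp - dp // 2)
    if genotypes is None:
        genotypes = [(1, 1)] * n_samples
    return VariantRecord(
        contig=contig,
        pos=pos,
        id=None,
        ref=ref,
        alts=list(alts),
        qual=qual,
        mq=mq,
        dp=dp,
        dp4=dp4,
        genotypes=genotypes,
    )


def random_records(rng: np.random.Generator, n: int, span: int = 2000):
    """Random biallelic SNP/InDel records with adversarial clustering,
    duplicate positions and threshold-straddling annotations."""
    records = []
    positions = rng.integers(1, span, size=n)
    for pos in positions:
        is_indel = rng.random() < 0.3
        if is_indel:
            if rng.random() < 0.5:
                ref, alt = "AT", "A"
            else:
                ref, alt = "A", "AT"
        else:
            ref, alt = "A", "G"
        dp = int(rng.integers(0, 60))
        alt_reads = int(rng.integers(0, dp + 1))
        alt_f = int(rng.integers(0, alt_reads + 1))
        ref_reads = dp - alt_reads
        ref_f = int(rng.integers(0, ref_reads + 1))
        records.append(
            VariantRecord(
                contig=str(rng.integers(1, 3)),
                pos=int(pos),
                id=None,
                ref=ref,
                alts=[alt],
                qual=float(rng.integers(0, 60)),
                mq=float(rng.integers(0, 60)),
                dp=dp,
                dp4=(ref_f, ref_reads - ref_f, alt_f, alt_reads - alt_f),
                genotypes=[(1, 1), MISSING],
            )
        )
    return records


def truth_specific_keys(cohort):
    """Expected breed-specific key sets from the planted-truth table."""
    expected = {b: set() for b in cohort.config.breeds}
    truth = cohort.truth
    for row in truth[truth.specific_for != ""].itertuples():
        expected[row.specific_for].add(
            VariantKey(row.contig, int(row.pos), row.ref, row.alt)
        )
    return expected
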