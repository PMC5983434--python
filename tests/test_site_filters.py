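"""Site-level hard-filter cascade: predicates, ordering and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breedsnp.site_filters import (
    SiteFilterConfig,
    VariantClass,
    apply_site_filters,
    classify_variant,
    compute_depth_ceiling,
    is_biallelic,
    passes_depth,
    passes_quality,
    passes_strand_support,
    proximity_filter,
    remove_duplicate_positions,
)

from conftest import make_record, random_records
from oracles import brute_force_site_filter

CFG = SiteFilterConfig()


class TestPredicates:
    @pytest.mark.parametrize(
        "alts,expected",
        [(("T",), True), (("T", "G"), False), (("T", "G", "C"), False)],
    )
    def test_biallelic(self, alts, expected):
        assert is_biallelic(make_record(alts=alts)) is expected

    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", VariantClass.SNP),
            ("A", "AT", VariantClass.INDEL),
            ("AT", "A", VariantClass.INDEL),
            ("AC", "GT", VariantClass.OTHER),
        ],
    )
    def test_classify(self, ref, alt, expected):
        assert classify_variant(make_record(ref=ref, alts=(alt,))) is expected

    @pytest.mark.parametrize(
        "dp4,expected",
        [
            ((10, 12, 0, 5), False),  # alt never seen on the forward strand
            ((10, 12, 1, 1), True),   # both strand minima met exactly
            ((0, 0, 7, 0), False),    # alt-reverse absent
        ],
    )
    def test_strand_support(self, dp4, expected):
        rec = make_record(dp=sum(dp4), dp4=dp4)
        assert passes_strand_support(rec, CFG) is expected

    def test_strand_support_null_dp4_policy(self):
        rec = make_record(dp4=None, dp=None)
        assert passes_strand_support(rec, CFG) is False
        lenient = SiteFilterConfig(fail_on_missing_dp4=False)
        assert passes_strand_support(rec, lenient) is True

    @pytest.mark.parametrize(
        "qual,mq,expected",
        [
            (19.9, 60.0, False),  # "below 20" removed
            (20.0, 30.0, True),   # boundary values retained
            (50.0, 29.0, False),
            (None, 60.0, False),  # absent evidence fails (strict default)
        ],
    )
    def test_quality(self, qual, mq, expected):
        assert passes_quality(make_record(qual=qual, mq=mq), CFG) is expected

    @pytest.mark.parametrize(
        "dp,ceiling,expected",
        [(9, 30.0, False), (10, 30.0, True), (30, 30.0, True), (31, 30.0, False)],
    )
    def test_depth_window(self, dp, ceiling, expected):
        assert passes_depth(make_record(dp=dp, dp4=(0, 0, 1, 1)), ceiling, CFG) is expected


class TestDepthCeiling:
    @pytest.mark.parametrize(
        "depths,expected",
        [
            ([10, 10, 10, 10, 10], 10.0),
            ([8, 10, 12, 14, 16], 21.486832980505138),
            ([5, 100], 254.02543263816605),
        ],
    )
    def test_median_plus_three_sample_sd(self, depths, expected):
        records = [make_record(pos=1 + 20 * i, dp=d, dp4=(0, 0, 1, 1)) for i, d in enumerate(depths)]
        assert compute_depth_ceiling(records) == pytest.approx(expected)

    def test_fewer_than_two_depths_is_an_error(self):
        with pytest.raises(ValueError):
            compute_depth_ceiling([make_record(dp=12)])


class TestDuplicatePositions:
    def test_collision_pair_both_removed(self):
        a = make_record(pos=100, alts=("G",))
        b = make_record(pos=100, alts=("T",))
        assert remove_duplicate_positions([a, b]) == []

    def test_unique_positions_untouched(self):
        recs = [make_record(pos=p) for p in (100, 150, 200)]
        assert remove_duplicate_positions(recs) == recs

    def test_triple_collision_all_removed(self):
        recs = [make_record(pos=100, alts=(a,)) for a in "GTC"]
        recs.append(make_record(pos=500))
        kept = remove_duplicate_positions(recs)
        assert [r.pos for r in kept] == [500]


class TestProximity:
    def test_snp_pair_closer_than_3_removed(self):
        recs = [make_record(pos=100), make_record(pos=102)]
        assert proximity_filter(recs) == []

    def test_snp_pair_at_exactly_3_kept(self):
        recs = [make_record(pos=100), make_record(pos=103)]
        assert proximity_filter(recs) == recs

    def test_snp_indel_indel_triple_all_removed(self):
        # SNP 4 bp from an InDel (< 5) and two InDels 9 bp apart (< 10)
        recs = [
            make_record(pos=100),
            make_record(pos=104, ref="AT", alts=("A",)),
            make_record(pos=113, ref="AT", alts=("A",)),
        ]
        assert proximity_filter(recs) == []

    def test_snp_near_lone_indel_only_snp_removed(self):
        snp = make_record(pos=100)
        indel = make_record(pos=104, ref="AT", alts=("A",))
        assert proximity_filter([snp, indel]) == [indel]

    def test_different_contigs_never_interact(self):
        recs = [make_record(contig="1", pos=100), make_record(contig="2", pos=101)]
        assert proximity_filter(recs) == recs


class TestCascade:
    def test_engineered_fixture_one_failure_per_stage(self):
        # enough well-behaved records that the depth ceiling (median +
        # 3 x sample SD) stays below the planted high outlier
        goods = [make_record(pos=1000 + 50 * i, dp=100 + i) for i in range(10)]
        fixture = goods + [
            make_record(pos=100, alts=("G", "T")),            # multiallelic
            make_record(pos=200, ref="AC", alts=("GT",)),      # MNP
            make_record(pos=300, dp4=(50, 50, 0, 5), dp=105),  # strand
            make_record(pos=400, qual=5.0, dp=100),            # qual
            make_record(pos=500, mq=10.0, dp=100),             # mq
            make_record(pos=600, dp=2, dp4=(0, 0, 1, 1)),      # depth low
            make_record(pos=700, dp=100000),                   # depth high
            make_record(pos=800, alts=("G",), dp=100),         # duplicate pair
            make_record(pos=800, alts=("T",), dp=100),
            make_record(pos=900, dp=100),                      # SNP cluster pair
            make_record(pos=901, dp=100),
        ]
        kept, trace = apply_site_filters(fixture)
        assert kept == goods
        labels = [trace.failures[i] for i in sorted(trace.failures)]
        assert labels == [
            "multiallelic", "mnp", "strand", "qual", "mq", "depth_low",
            "depth_high", "duplicate_pos", "duplicate_pos",
            "prox_snp_snp", "prox_snp_snp",
        ]
        assert kept == brute_force_site_filter(fixture, CFG)

    def test_all_passing_fixture_identity(self):
        recs = [make_record(pos=p, dp=100) for p in range(100, 400, 20)]
        kept, trace = apply_site_filters(recs)
        assert kept == recs and trace.failures == {}

    def test_empty_input(self):
        kept, trace = apply_site_filters([])
        assert kept == [] and trace.failures == {}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        recs = random_records(rng, int(rng.integers(2, 120)))
        kept, _ = apply_site_filters(recs)
        expected = brute_force_site_filter(recs, CFG)
        assert [id(r) for r in kept] == [id(r) for r in expected]

    @pytest.mark.parametrize("seed", [3, 17])
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        recs = random_records(rng, 80)
        once, _ = apply_site_filters(recs)
        twice, trace = apply_site_filters(once)
        assert twice == once and trace.failures == {}

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_kept_set_independent_of_input_order(self, seed):
        rng = np.random.default_rng(seed)
        recs = random_records(rng, 50)
        kept_a, _ = apply_site_filters(recs)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        kept_b, _ = apply_site_filters(shuffled)
        key = lambda r: (r.contig, r.pos, r.ref, tuple(r.alts))
        assert sorted(map(key, kept_a)) == sorted(map(key, kept_b))

    @pytest.mark.parametrize("seed", [5, 23])
    def test_proximity_stage_only_shrinks_the_kept_set(self, seed):
        rng = np.random.default_rng(seed)
        recs = random_records(rng, 100)
        kept, _ = apply_site_filters(recs)
        wide = SiteFilterConfig(snp_snp_dist=0, snp_indel_dist=0, indel_indel_dist=0)
        kept_no_prox, _ = apply_site_filters(recs, wide)
        assert {id(r) for r in kept} <= {id(r) for r in kept_no_prox}
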