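"""SNV consequence classification, splice regions and interval overlap."""

import numpy as np
import pytest
from Bio.Seq import Seq

from breedsnp.consequence_annotator import (
    ConsequenceCall,
    GeneModel,
    annotate_snv,
    consequence_summary,
    overlap_features,
    read_gene_models,
)
from breedsnp.vcf_io import VariantKey

from oracles import brute_force_overlap, expected_codon_term

# single-exon gene: ATG AAA TAA at 101..109 (+)
TX1_CDS = "ATGAAATAA"
# two-exon gene: ATG AAA CCC GGG | TTG TCT TAA split 201..212 / 241..249,
# intron 213..240 (28 bp) so mid-intron bases are not splice region
TX2_EXON1, TX2_EXON2 = "ATGAAACCCGGG", "TTGTCTTAA"


@pytest.fixture(scope="module")
def template():
    rng = np.random.default_rng(123)
    bases = np.array(list("ACGT"))
    seq = list("".join(bases[rng.integers(0, 4, size=400)]))
    seq[100:109] = TX1_CDS
    seq[200:212] = TX2_EXON1
    seq[240:249] = TX2_EXON2
    return {"chr1": "".join(seq)}


@pytest.fixture(scope="module")
def models():
    return [
        GeneModel("tx1", "chr1", "+", ((101, 109),)),
        GeneModel("tx2", "chr1", "+", ((201, 212), (241, 249))),
    ]


def _snp(template, pos, alt):
    ref = template["chr1"][pos - 1]
    return VariantKey("chr1", pos, ref, alt)


class TestCodingClassification:
    def test_fixture_cds_translates_from_start_to_stop(self, template, models):
        for model in models:
            protein = str(Seq(model.coding_sequence(template)).translate())
            assert protein.startswith("M") and protein.endswith("*")
            assert "*" not in protein[:-1]

    @pytest.mark.parametrize(
        "pos,alt,term",
        [
            (106, "G", "synonymous_variant"),  # AAA->AAG, Lys->Lys
            (104, "T", "stop_gained"),         # AAA->TAA
            (101, "G", "start_lost"),          # ATG->GTG
            (107, "C", "stop_lost"),           # TAA->CAA
            (105, "C", "missense_variant"),    # AAA->ACA, Lys->Thr
        ],
    )
    def test_single_exon_codon_terms(self, template, models, pos, alt, term):
        call = annotate_snv(_snp(template, pos, alt), models, template)
        assert call.term == term
        assert call.transcript_id == "tx1"
        assert call.codon_change is not None
        # ref codon must translate to the pre-substitution amino acid
        ref_codon, alt_codon = call.codon_change
        codon_index = (pos - 101) // 3
        assert term == expected_codon_term(ref_codon, alt_codon, codon_index)

    def test_template_ref_disagreement_raises(self, template, models):
        ref = template["chr1"][105]  # pos 106 is 'A'
        wrong = "C" if ref != "C" else "G"
        with pytest.raises(ValueError, match="disagrees"):
            annotate_snv(VariantKey("chr1", 106, wrong, "T"), models, template)

    def test_strand_symmetry_on_mirrored_construction(self, template, models):
        """Annotating the + strand gene equals annotating its
        reverse-complemented mirror gene on the - strand."""
        L = len(template["chr1"])
        mirror_template = {"chr1": str(Seq(template["chr1"]).reverse_complement())}
        comp = lambda b: str(Seq(b).complement())
        fwd = GeneModel("tx2", "chr1", "+", ((201, 212), (241, 249)))
        rev = GeneModel(
            "tx2m", "chr1", "-",
            tuple(sorted((L + 1 - e, L + 1 - s) for s, e in fwd.cds)),
        )
        for pos in [201, 205, 212, 241, 245, 249, 213, 220, 230, 239]:
            ref = template["chr1"][pos - 1]
            for alt in "ACGT".replace(ref, ""):
                call_f = annotate_snv(
                    VariantKey("chr1", pos, ref, alt), [fwd], template
                )
                call_r = annotate_snv(
                    VariantKey("chr1", L + 1 - pos, comp(ref), comp(alt)),
                    [rev], mirror_template,
                )
                assert call_f.term == call_r.term, (pos, alt)


class TestSpliceAndNonCoding:
    @pytest.mark.parametrize(
        "pos,term",
        [
            (213, "splice_region_variant"),   # 1st intronic base (donor)
            (220, "splice_region_variant"),   # 8th intronic base
            (233, "splice_region_variant"),   # 8th intronic base before acceptor
            (240, "splice_region_variant"),   # last intronic base before exon 2
            (225, "intron_variant"),          # deep intron
            (232, "intron_variant"),
            (350, "intergenic_variant"),
            (50, "intergenic_variant"),
        ],
    )
    def test_positional_terms(self, template, models, pos, term):
        ref = template["chr1"][pos - 1]
        alt = "ACGT".replace(ref, "")[0]
        call = annotate_snv(VariantKey("chr1", pos, ref, alt), models, template)
        assert call.term == term

    def test_terminal_exonic_synonymous_upgrades_to_splice_region(
        self, template, models
    ):
        # pos 212 is the 3rd base of codon GGG: every substitution is
        # synonymous, but it is a terminal exonic base of the junction
        call = annotate_snv(_snp(template, 212, "A"), models, template)
        assert call.term == "splice_region_variant"

    def test_terminal_exonic_missense_stays_missense(self, template, models):
        # pos 211 is the 2nd base of codon GGG: GAG -> Glu (missense),
        # more severe than splice_region
        call = annotate_snv(_snp(template, 211, "A"), models, template)
        assert call.term == "missense_variant"


class TestGff3:
    GFF = """##gff-version 3
chr1\ttest\tmRNA\t101\t109\t.\t+\t.\tID=tx1
chr1\ttest\tCDS\t101\t109\t.\t+\t0\tID=cds1;Parent=tx1
chr1\ttest\tmRNA\t201\t249\t.\t+\t.\tID=tx2
chr1\ttest\texon\t201\t212\t.\t+\t.\tParent=tx2
chr1\ttest\texon\t241\t249\t.\t+\t.\tParent=tx2
chr1\ttest\tCDS\t201\t212\t.\t+\t0\tParent=tx2
chr1\ttest\tCDS\t241\t249\t.\t+\t0\tParent=tx2
"""

    def test_read_gene_models(self, tmp_path, template, models):
        path = tmp_path / "genes.gff3"
        path.write_text(self.GFF)
        loaded = sorted(read_gene_models(path), key=lambda m: m.transcript_id)
        assert [m.transcript_id for m in loaded] == ["tx1", "tx2"]
        assert loaded[1].cds == ((201, 212), (241, 249))
        assert loaded[1].exons == ((201, 212), (241, 249))
        # classification through the parsed models matches the direct ones
        snp = _snp(template, 106, "G")
        assert (
            annotate_snv(snp, loaded, template).term
            == annotate_snv(snp, models, template).term
        )


class TestSummary:
    def _call(self, term, i, codon=None):
        return ConsequenceCall(
            VariantKey("1", 10 * i + 10, "A", "G"), "tx", term, codon
        )

    def test_percentages_over_coding_calls(self):
        calls = [
            self._call("missense_variant", i, ("AAA", "ACA")) for i in range(100)
        ] + [
            self._call("synonymous_variant", 100 + i, ("AAA", "AAG"))
            for i in range(81)
        ] + [self._call("intron_variant", 300 + i) for i in range(50)]
        summary = consequence_summary({"FLV": calls})
        count, pct = summary["FLV"]["missense_variant"]
        assert (count, pct) == (100, 55.2)
        assert summary["FLV"]["intron_variant"] == (50, None)

    def test_empty_input(self):
        assert consequence_summary({}) == {}

    def test_all_synonymous(self):
        calls = [self._call("synonymous_variant", i, ("AAA", "AAG")) for i in range(3)]
        assert consequence_summary({"X": calls})["X"]["synonymous_variant"] == (3, 100.0)


class TestOverlapFeatures:
    def test_coordinate_conversion(self):
        snp100 = VariantKey("1", 100, "A", "G")
        snp101 = VariantKey("1", 101, "A", "G")
        assert overlap_features({snp100}, [("1", 99, 100, "f")])["f"] == {snp100}
        result = overlap_features({snp100, snp101}, [("1", 100, 200, "f")])
        assert result["f"] == {snp101}

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            overlap_features(set(), [("1", 100, 100, "f")])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        snps = {
            VariantKey(str(rng.integers(1, 3)), int(p), "A", "G")
            for p in rng.integers(1, 300, size=60)
        }
        features = []
        for i in range(20):
            start = int(rng.integers(0, 280))
            end = start + int(rng.integers(1, 40))
            features.append((str(rng.integers(1, 3)), start, end, f"feat{i}"))
        assert overlap_features(snps, features) == brute_force_overlap(snps, features)
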