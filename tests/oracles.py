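"""Independent brute-force reference implementations used as oracles.

Everything here is written from the filter definitions directly, with
O(n^2) scans and numpy statistics, and must stay independent of the
package code paths it checks.
"""

from collections import Counter

import numpy as np


def _cls(record):
    ref, alt = record.ref, record.alts[0]
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if len(ref) != len(alt):
        return "INDEL"
    return "OTHER"


def brute_force_site_filter(records, config):
    """All-pairs re-implementation of the hard-filter cascade."""
    stage14 = []
    for r in records:
        if len(r.alts) != 1:
            continue
        if _cls(r) == "OTHER":
            continue
        if r.dp4 is None:
            continue
        if r.dp4[2] < config.min_alt_forward or r.dp4[3] < config.min_alt_reverse:
            continue
        if r.qual is None or r.qual < config.min_qual:
            continue
        if r.mq is None or r.mq < config.min_mq:
            continue
        stage14.append(r)
    dps = [r.dp for r in stage14 if r.dp is not None]
    if len(dps) >= 2:
        ceiling = float(np.median(dps)) + config.dp_sigma_mult * float(
            np.std(dps, ddof=1)
        )
    else:
        ceiling = float("inf")
    stage5 = [
        r for r in stage14 if r.dp is not None and config.min_dp <= r.dp <= ceiling
    ]
    counts = Counter((r.contig, r.pos) for r in stage5)
    stage6 = [r for r in stage5 if counts[(r.contig, r.pos)] == 1]
    kept = []
    for r in stage6:
        removed = False
        for o in stage6:
            if o is r or o.contig != r.contig:
                continue
            d = abs(r.pos - o.pos)
            cr, co = _cls(r), _cls(o)
            if cr == "SNP" and co == "SNP" and d < config.snp_snp_dist:
                removed = True
            if cr == "SNP" and co == "INDEL" and d < config.snp_indel_dist:
                removed = True
            if cr == "INDEL" and co == "INDEL" and d < config.indel_indel_dist:
                removed = True
        if not removed:
            kept.append(r)
    return kept


def brute_force_venn(per_breed):
    """Per-key membership bit-vector partition."""
    union = set()
    for keys in per_breed.values():
        union |= keys
    cells = {}
    for key in union:
        members = frozenset(b for b, keys in per_breed.items() if key in keys)
        cells[members] = cells.get(members, 0) + 1
    return cells


def brute_force_overlap(snps, features):
    """All-pairs containment scan for BED interval overlap."""
    result = {name: set() for _, _, _, name in features}
    for snp in snps:
        for contig, start, end, name in features:
            if snp.contig == contig and start <= snp.pos - 1 < end:
                result[name].add(snp)
    return result


def translate_both_codons(ref_codon, alt_codon):
    """Stand-alone standard-genetic-code translation of two codons."""
    table = {
        "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
        "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
        "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
        "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
        "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
        "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
        "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
        "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
        "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
        "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
        "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
        "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
        "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
        "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
        "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
        "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
    }
    return table[ref_codon], table[alt_codon]


def expected_codon_term(ref_codon, alt_codon, codon_index):
    """Classify a codon change from first principles."""
    ref_aa, alt_aa = translate_both_codons(ref_codon, alt_codon)
    if codon_index == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_lost"
    if ref_aa != "*" and alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost"
    if ref_aa == alt_aa:
        return "synonymous_variant"
    return "missense_variant"
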