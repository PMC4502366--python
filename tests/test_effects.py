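"""Tests for effect annotation under the invertebrate mitochondrial code."""

import numpy as np
import pytest
from Bio.Seq import Seq

from isomito._seq import DELETION, random_seq, revcomp
from isomito.effects import (
    CDS_FRAMESHIFT,
    CDS_SUBSTITUTION,
    NONCODING,
    PALINDROME,
    TRNA_ANTICODON,
    TRNA_BODY,
    FeatureAnnotation,
    annotate_site,
    decode_anticodon,
    detect_terminal_palindromes,
    locate_anticodon,
    translate_cds,
)
from isomito.synthetic import PRODUCT_ANTICODON, generate_monomer


class _Site:
    def __init__(self, position, ref, alt):
        self.position, self.ref_allele, self.alt_allele = position, ref, alt


class TestTranslateCds:
    @pytest.mark.parametrize(
        "seq,strand,expected",
        [
            ("ATATGATTA", "+", "MWL"),  # ATA=Met, TGA=Trp under table 5
            ("AGAAGG", "+", "SS"),  # AGA/AGG are serine, not arginine/stop
            ("TAAATGATG", "+", ""),  # immediate stop
            ("ATGAAATTTTAA", "+", "MKF"),
            (revcomp("ATGAAATTT"), "-", "MKF"),
        ],
    )
    def test_table5_semantics(self, seq, strand, expected):
        assert translate_cds(seq, strand) == expected

    def test_codon_start_offsets_frame(self):
        assert translate_cds("GATGAAA", codon_start=2) == "MK"

    def test_trailing_incomplete_codon_ignored(self):
        assert translate_cds("ATGAAAG") == "MK"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            translate_cds("")


class TestDecodeAnticodon:
    @pytest.mark.parametrize(
        "anticodon,identity",
        [
            ("TAG", "Leu1"), ("TAA", "Leu2"),  # the G/A anticodon heteroplasmy
            ("TGC", "Ala"), ("TAC", "Val"),  # the classic Ala/Val dual gene
            ("TCG", "Arg"), ("TCC", "Gly"),  # the G/C anticodon heteroplasmy
            ("TCT", "Ser1"), ("TGA", "Ser2"),
            ("CAT", "Met"), ("TCA", "Trp"), ("TTA", "Stop"),
        ],
    )
    def test_known_identities(self, anticodon, identity):
        assert decode_anticodon(anticodon) == identity

    def test_exhaustive_against_biopython_oracle(self):
        """All 64 anticodons versus a direct table-5 translation oracle."""
        bases = "ACGT"
        for b1 in bases:
            for b2 in bases:
                for b3 in bases:
                    ac = b1 + b2 + b3
                    codon = str(Seq(ac).reverse_complement())
                    aa = str(Seq(codon).translate(table=5))
                    got = decode_anticodon(ac)
                    if aa == "*":
                        assert got == "Stop"
                    elif aa == "L":
                        assert got == ("Leu1" if codon[:2] == "CT" else "Leu2")
                    elif aa == "S":
                        assert got == ("Ser1" if codon[:2] == "AG" else "Ser2")
                    else:
                        three = {"A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp",
                                 "C": "Cys", "Q": "Gln", "E": "Glu", "G": "Gly",
                                 "H": "His", "I": "Ile", "K": "Lys", "M": "Met",
                                 "F": "Phe", "P": "Pro", "T": "Thr", "W": "Trp",
                                 "Y": "Tyr", "V": "Val"}[aa]
                        assert got == three

    def test_product_anticodon_table_is_self_consistent(self):
        for product, anticodon in PRODUCT_ANTICODON.items():
            assert decode_anticodon(anticodon) == product

    def test_invalid_anticodon_rejected(self):
        with pytest.raises(ValueError):
            decode_anticodon("TNX")


def _toy_genome(cds_seq, cds_start=101, strand="+", extra=()):
    rng = np.random.default_rng(3)
    seq = random_seq(cds_start - 1, rng) + cds_seq + random_seq(100, rng)
    body = cds_seq if strand == "+" else revcomp(cds_seq)
    seq = seq[: cds_start - 1] + body + seq[cds_start - 1 + len(cds_seq) :]
    feats = [
        FeatureAnnotation("cds1", "CDS", strand, cds_start,
                          cds_start + len(cds_seq) - 1, product="toy")
    ] + list(extra)
    return seq, feats


class TestAnnotateSite:
    def test_cds_substitution_label(self):
        cds = "ATGAAAGAATTATAA"
        seq, feats = _toy_genome(cds)
        pos = 101 + 6  # first base of codon 3 (GAA)
        rep = annotate_site(_Site(pos, "G", "C"), seq, feats)
        (eff,) = rep.effects
        assert eff.kind == CDS_SUBSTITUTION
        assert (eff.codon_index, eff.label) == (3, "E3Q")

    def test_minus_strand_substitution(self):
        cds = "ATGAAAGAATTATAA"
        seq, feats = _toy_genome(cds, strand="-")
        # codon 3 first base sits at end - 6 on the minus strand
        pos = 101 + len(cds) - 1 - 6
        ref = seq[pos - 1]
        assert ref == "C"  # genome shows the complement of the coding G
        rep = annotate_site(_Site(pos, ref, "G"), seq, feats)
        (eff,) = rep.effects
        assert eff.label == "E3Q"

    def test_frameshift_against_brute_force(self):
        cds = "ATGAAATTTAAAGAGTAA"
        seq, feats = _toy_genome(cds)
        pos = 101 + 4  # inside codon 2
        rep = annotate_site(_Site(pos, seq[pos - 1], DELETION), seq, feats)
        (eff,) = rep.effects
        assert eff.kind == CDS_FRAMESHIFT
        assert eff.first_affected_codon == 2
        mutated = cds[:4] + cds[5:]
        stops = [i // 3 + 1 for i in range(0, len(mutated) - 2, 3)
                 if mutated[i : i + 3] in ("TAA", "TAG")]
        assert eff.premature_stop_codon == (stops[0] if stops else None)
        assert eff.last_affected_codon == len(translate_cds(cds))

    def test_frameshift_property_random_cds(self):
        """100 random CDSs: premature stop equals brute-force translation."""
        from isomito.synthetic import random_cds

        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(20, 120))
            cds = random_cds(n, rng)
            seq, feats = _toy_genome(cds)
            off = int(rng.integers(0, 3 * (n - 1)))
            pos = 101 + off
            rep = annotate_site(_Site(pos, seq[pos - 1], DELETION), seq, feats)
            (eff,) = rep.effects
            mutated = cds[:off] + cds[off + 1 :]
            stops = [i // 3 + 1 for i in range(0, len(mutated) - 2, 3)
                     if mutated[i : i + 3] in ("TAA", "TAG")]
            assert eff.premature_stop_codon == (stops[0] if stops else None)
            assert eff.first_affected_codon == off // 3 + 1

    def test_substitution_retranslation_property(self):
        """Mutated protein differs exactly at the reported codon index."""
        from isomito.synthetic import random_cds

        rng = np.random.default_rng(78)
        for _ in range(50):
            cds = random_cds(40, rng)
            seq, feats = _toy_genome(cds)
            off = int(rng.integers(3, 3 * 39))
            pos = 101 + off
            ref = seq[pos - 1]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            rep = annotate_site(_Site(pos, ref, alt), seq, feats)
            (eff,) = rep.effects
            mutated = cds[:off] + alt + cds[off + 1 :]
            p_ref = translate_cds(cds)
            p_alt = translate_cds(mutated)
            if eff.alt_aa == "*":
                assert len(p_alt) < len(p_ref)
            elif eff.ref_aa == eff.alt_aa:
                assert p_alt == p_ref
            else:
                diffs = [i + 1 for i, (x, y) in enumerate(zip(p_ref, p_alt))
                         if x != y]
                assert diffs == [eff.codon_index]

    def test_trna_anticodon_site_with_cds_overlap(self):
        """A site in an anticodon inside a CDS reports both effects."""
        cds = "ATGAAAGAATTATAA"
        trna = FeatureAnnotation("trnX", "tRNA", "+", 105, 112, product="X",
                                 anticodon_span=(107, 109))
        seq, feats = _toy_genome(cds, extra=[trna])
        rep = annotate_site(_Site(107, seq[106], "C"), seq, feats)
        assert rep.kinds() == {CDS_SUBSTITUTION, TRNA_ANTICODON}
        assert len(rep.effects) == 2

    def test_minus_strand_anticodon_identity(self):
        rng = np.random.default_rng(4)
        seq = random_seq(200, rng)
        # plant anticodon TGC (Ala) on the minus strand at positions 101-103
        seq = seq[:100] + revcomp("TGC") + seq[103:]
        trna = FeatureAnnotation("trnA", "tRNA", "-", 81, 144, product="Ala",
                                 anticodon_span=(101, 103))
        # genome shows GCA; the middle base C is anticodon G's complement...
        rep = annotate_site(_Site(102, seq[101], "T"), seq, [trna])
        (eff,) = rep.effects
        assert eff.kind == TRNA_ANTICODON
        assert eff.ref_identity == "Ala"
        assert eff.alt_identity == decode_anticodon("TAC")  # C->T on genome

    def test_trna_body_and_noncoding_fallback(self):
        trna = FeatureAnnotation("trnX", "tRNA", "+", 50, 113, product="X",
                                 anticodon_span=(82, 84))
        rng = np.random.default_rng(5)
        seq = random_seq(200, rng)
        rep = annotate_site(_Site(60, seq[59], "A" if seq[59] != "A" else "C"),
                            seq, [trna])
        assert rep.kinds() == {TRNA_BODY}
        rep = annotate_site(_Site(150, seq[149], "A" if seq[149] != "A" else "C"),
                            seq, [trna])
        assert rep.kinds() == {NONCODING}

    def test_palindrome_feature(self):
        pal = FeatureAnnotation("pal", "palindrome", "+", 1, 54)
        rng = np.random.default_rng(6)
        seq = random_seq(200, rng)
        rep = annotate_site(_Site(30, seq[29], "A" if seq[29] != "A" else "C"),
                            seq, [pal])
        assert rep.kinds() == {PALINDROME}

    def test_deletion_outside_frame_rejected(self):
        cds = "ATGAAAGAATTATAA"
        seq, feats = _toy_genome(cds)
        feats[0] = FeatureAnnotation("cds1", "CDS", "+", 101, 115,
                                     product="toy", codon_start=2)
        with pytest.raises(ValueError, match="boundary"):
            annotate_site(_Site(101, seq[100], DELETION), seq, feats)


class TestTerminalPalindromes:
    def test_generated_hairpins_detected(self, small_genome):
        hit5, hit3 = detect_terminal_palindromes(small_genome.monomer_seq,
                                                 min_arm=15, max_loop=8)
        assert hit5 is not None and hit5.arm >= 25 and hit5.start == 1
        assert hit3 is not None and hit3.arm >= 25
        assert hit3.end == len(small_genome.monomer_seq)

    def test_random_sequence_has_no_long_hairpin(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            seq = random_seq(600, rng)
            hit5, hit3 = detect_terminal_palindromes(seq, min_arm=15,
                                                     max_loop=0, max_mismatch=0)
            assert hit5 is None and hit3 is None

    def test_short_self_revcomp_prefix(self):
        rng = np.random.default_rng(9)
        seq = "ACGTAACGT" + random_seq(300, rng)  # 4+1+4 hairpin? no: build one
        seq = "ACGTTAACGT" + random_seq(300, rng)  # ACGTT|AACGT self-revcomp
        hit5, _ = detect_terminal_palindromes(seq, min_arm=5, max_loop=2)
        assert hit5 is not None and hit5.arm >= 5 and hit5.start == 1


class TestLocateAnticodon:
    def test_explicit_span_returned(self):
        trna = FeatureAnnotation("t", "tRNA", "+", 10, 73, product="Ala",
                                 anticodon_span=(40, 42))
        res = locate_anticodon(trna, "A" * 100)
        assert res.span == (40, 42) and res.status == "OK"

    def test_planted_anticodon_located(self):
        rng = np.random.default_rng(10)
        g = generate_monomer(2000, 0, 0, None, seed=10)
        seq = list(g.monomer_seq)
        start = 500
        seq[start - 1 + 32 : start - 1 + 35] = list("TGC")  # Ala at offset 32
        seq = "".join(seq)
        trna = FeatureAnnotation("t", "tRNA", "+", start, start + 63,
                                 product="Ala")
        res = locate_anticodon(trna, seq)
        if res.status == "OK":  # unique candidate in the scan window
            assert res.span == (start + 32, start + 34)
        else:  # a second Ala triplet arose by chance in the window
            assert res.status == "AMBIGUOUS"

    def test_no_candidate_is_ambiguous(self):
        rng = np.random.default_rng(11)
        seq = "A" * 200  # poly-A decodes nothing but Phe-family triplets
        trna = FeatureAnnotation("t", "tRNA", "+", 1, 64, product="Ala")
        assert locate_anticodon(trna, seq).status == "AMBIGUOUS"

    def test_non_trna_rejected(self):
        cds = FeatureAnnotation("c", "CDS", "+", 1, 90)
        with pytest.raises(ValueError):
            locate_anticodon(cds, "A" * 100)
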