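"""Synthetic stand-in genomes emulating the two deposited isopod mitogenomes.

The study's assembled monomers (GenBank KR013001, *Trachelipus rathkei*,
14,129 bp; KR013002, *Cylisticus convexus*, 14,154 bp) are not bundled and
cannot be fetched in an offline run.  This module constructs SYNTHETIC
stand-ins that embed the published site/annotation geometry on otherwise
random sequence, so that every downstream computation (effect labels,
anticodon identities, orthology mapping, targeted assembly) can be
exercised end to end at the genuine genome scale:

* 14,129 / 14,154 bp monomers with 40+4+40 bp hairpin terminal palindromes;
* cox3 with the Glu->Gln substitution site at codon 273 (E273Q) whose
  reference base is simultaneously the third anticodon base of an
  overlapping tRNA-Arg (the Arg/Gly dual gene), and a 1-bp deletion site at
  the last base of codon 92 whose frameshift hits a premature stop at
  codon 106 of the shifted frame;
* nad2 with codon 118 = TTT at an A2/T8 homopolymer boundary (F118I);
* tRNA genes holding the Leu1/Leu2 and Ala/Val anticodon heteroplasmies;
* the *C. convexus* stand-in is derived from the *T. rathkei* one by 28%
  substitution divergence plus block indels that reproduce the published
  coordinate offsets of the three orthologous anticodon sites.

Everything here is deterministic (fixed internal seeds): the stand-ins play
the role of fixed reference records, not of simulation replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import BASES, DELETION, random_seq, revcomp
from .effects import STOP_CODONS, FeatureAnnotation
from .synthetic import GenomeModel, random_cds

_SEED_TR = 20150424  # fixed: the stand-ins emulate fixed records

TR_LENGTH = 14129
CC_LENGTH = 14154
_ARM, _LOOP = 40, 4

# printed heteroplasmic sites (1-based position, ref, alt) per species
TR_SITES = [
    (62, "T", "A"), (73, "T", "A"), (9346, "G", "A"), (10074, "G", "A"),
    (11244, "A", DELETION), (11785, "G", "C"), (12188, "A", "G"),
    (14107, "T", "A"),
]
TR_TRNA_SITES = [9346, 11785, 12188]
CC_SITES = [(6998, "T", "A"), (9309, "A", "G"), (11755, "G", "C"),
            (12160, "G", "A")]
CC_TRNA_SITES = [9309, 11755, 12160]

#: orthologous anticodon site pairs (T. rathkei pos, C. convexus pos)
ORTHOLOGOUS_ANTICODON_SITES = [(9346, 9309), (11785, 11755), (12188, 12160)]

# T. rathkei stand-in feature coordinates
_TR_NAD2 = (6647, 7636)  # 330 codons; codon 118 starts at 6998
_TR_COX3 = (10969, 11802)  # 278 codons = 277 aa + stop; codon 273 at 11785
_TR_TRNL = (9312, 9375, (9344, 9346))  # anticodon TAG (Leu1)
_TR_TRNR = (11751, 11814, (11783, 11785))  # anticodon TCG (Arg), inside cox3
_TR_TRNV = (12155, 12218, (12187, 12189))  # anticodon TAC (Val)


def _write_palindromes(seq: list[str], arm: int, loop: int) -> None:
    L = len(seq)
    head = "".join(seq[arm + loop : 2 * arm + loop])
    seq[0:arm] = list(revcomp(head))
    tail = "".join(seq[L - 2 * arm - loop : L - arm - loop])
    seq[L - arm : L] = list(revcomp(tail))


def _patch(seq: list[str], pos1: int, bases: str) -> None:
    seq[pos1 - 1 : pos1 - 1 + len(bases)] = list(bases)


def _engineer_cox3(rng: np.random.Generator) -> str:
    """cox3 coding sequence with the published variant geometry baked in.

    Codon 92 = GCA (ref base A at its third position, the deletion site);
    codon 272 ends TC and codon 273 = GAA so that bases 814..816 read TCG
    (the overlapping tRNA-Arg anticodon, E273Q under G->C); the frame
    shifted by deleting base 275 carries its first stop at shifted codon 15,
    i.e. premature stop at protein position 106.
    """
    coding = list(random_cds(278, rng))
    coding[273:276] = list("GCA")  # codon 92
    coding[813:816] = [coding[813], "T", "C"]  # codon 272 tail -> anticodon T,C
    coding[816:819] = list("GAA")  # codon 273 (E); site base is the G
    # clear stops from shifted-frame codons j=2..14 (first base -> C)
    for j in range(2, 15):
        s = 271 + 3 * j
        if "".join(coding[s : s + 3]) in STOP_CODONS:
            coding[s] = "C"
    coding[316:319] = list("TAA")  # shifted codon 15 -> stop at protein 106
    return "".join(coding)


def _engineer_nad2(rng: np.random.Generator) -> str:
    """nad2 coding sequence with codon 118 on an A2/T8 homopolymer boundary."""
    coding = list(random_cds(330, rng))
    # codons 117..120 relative offsets 348..359: CAA TTT TTT TT?
    coding[348:358] = list("CAATTTTTTT")
    if "".join(coding[357:360]) in STOP_CODONS:
        coding[359] = "C"
    return "".join(coding)


def trachelipus_standin() -> GenomeModel:
    """Synthetic stand-in for the deposited *T. rathkei* monomer (14,129 bp)."""
    rng = np.random.default_rng(_SEED_TR)
    seq = list(random_seq(TR_LENGTH, rng))

    _patch(seq, _TR_NAD2[0], _engineer_nad2(rng))
    _patch(seq, _TR_COX3[0], _engineer_cox3(rng))
    _patch(seq, _TR_TRNL[2][0], "TAG")  # Leu1 anticodon, ref G at 9346
    _patch(seq, _TR_TRNV[2][0], "TAC")  # Val anticodon, ref A at 12188
    _patch(seq, 10074, "G")  # noncoding individual-specific site
    # terminal-site reference bases: 62/73 sit in the written half of the 5'
    # palindrome; 14107 is derived from its mirror base, set the mirror
    _patch(seq, 62, "T")
    _patch(seq, 73, "T")
    _patch(seq, 14068, "A")  # mirror of 14107 under the 3' hairpin
    _write_palindromes(seq, _ARM, _LOOP)

    monomer = "".join(seq)
    features = [
        FeatureAnnotation("pal5", "palindrome", "+", 1, 2 * _ARM + _LOOP,
                          product="5' terminal palindrome"),
        FeatureAnnotation("nad2", "CDS", "+", *_TR_NAD2, product="nad2"),
        FeatureAnnotation("trnL1", "tRNA", "+", _TR_TRNL[0], _TR_TRNL[1],
                          product="Leu1", anticodon_span=_TR_TRNL[2]),
        FeatureAnnotation("cox3", "CDS", "+", *_TR_COX3, product="cox3"),
        FeatureAnnotation("trnR", "tRNA", "+", _TR_TRNR[0], _TR_TRNR[1],
                          product="Arg", anticodon_span=_TR_TRNR[2]),
        FeatureAnnotation("trnV", "tRNA", "+", _TR_TRNV[0], _TR_TRNV[1],
                          product="Val", anticodon_span=_TR_TRNV[2]),
        FeatureAnnotation("pal3", "palindrome", "+",
                          TR_LENGTH - (2 * _ARM + _LOOP) + 1, TR_LENGTH,
                          product="3' terminal palindrome"),
    ]
    model = GenomeModel(monomer_seq=monomer, features=features,
                        palindrome_arm_len=_ARM, palindrome_loop_len=_LOOP)
    _check_sites(model, TR_SITES)
    return model


# block offsets from T. rathkei to C. convexus coordinates: a 37-bp deletion
# at 7700 and insertions of 4/5/53 bp after 9500/11900/12600 reproduce the
# published site offsets (9346->9309, 11785->11755, 12188->12160) and the
# 14,154 bp total length.
_CC_BLOCKS = [(0, 7700, 0), (7737, 9500, -37), (9500, 11900, -33),
              (11900, 12600, -28), (12600, TR_LENGTH, +25)]


def tr_to_cc_position(pos: int) -> int | None:
    """Map a 1-based T. rathkei stand-in coordinate to the C. convexus one."""
    p0 = pos - 1
    for lo, hi, off in _CC_BLOCKS:
        if lo <= p0 < hi:
            return pos + off
    return None  # deleted block


def cylisticus_standin() -> GenomeModel:
    """Synthetic stand-in for the deposited *C. convexus* monomer (14,154 bp).

    Derived from the *T. rathkei* stand-in by 28% substitution divergence
    (protected: the engineered nad2/cox3 variant codons and anticodon
    spans), block indels matching the published coordinate offsets, and
    fresh terminal palindromes.
    """
    tr = trachelipus_standin().monomer_seq
    rng = np.random.default_rng(_SEED_TR + 1)
    # protected from divergence: the engineered variant codons and the three
    # tRNA gene bodies (tRNAs are far more conserved than the 72% background,
    # and the published anticodon orthology rests on that conservation)
    protected = set()
    for lo, hi in [(6995, 7006), (11242, 11244), (11782, 11790),
                   (_TR_TRNL[0], _TR_TRNL[1]), (_TR_TRNR[0], _TR_TRNR[1]),
                   (_TR_TRNV[0], _TR_TRNV[1])]:
        protected.update(range(lo - 1, hi))
    div = list(tr)
    sub = rng.random(len(div)) < 0.28
    shift = rng.integers(1, 4, size=len(div))
    for i in range(len(div)):
        if sub[i] and i not in protected:
            div[i] = BASES[(BASES.index(div[i]) + shift[i]) % 4]
    cc = (
        div[0:7700] + div[7737:9500] + list(random_seq(4, rng))
        + div[9500:11900] + list(random_seq(5, rng))
        + div[11900:12600] + list(random_seq(53, rng)) + div[12600:]
    )
    assert len(cc) == CC_LENGTH
    # species-specific alleles at the orthologous anticodon loci
    _patch(cc, 9307, "TAA")  # Leu2 anticodon, ref A at 9309
    _patch(cc, 11753, "TC")  # tRNA-Arg anticodon prefix (codon 273 tail)
    _patch(cc, 11755, "GAT")  # codon 274 = GAT (Asp); D274H under G->C
    _patch(cc, 12159, "TGC")  # Ala anticodon, ref G at 12160
    _write_palindromes(cc, _ARM, _LOOP)

    monomer = "".join(cc)
    nad2 = (6647, 7636)
    cox3 = (10936, 11769)
    features = [
        FeatureAnnotation("pal5", "palindrome", "+", 1, 2 * _ARM + _LOOP,
                          product="5' terminal palindrome"),
        FeatureAnnotation("nad2", "CDS", "+", *nad2, product="nad2"),
        FeatureAnnotation("trnL2", "tRNA", "+", 9275, 9338, product="Leu2",
                          anticodon_span=(9307, 9309)),
        FeatureAnnotation("cox3", "CDS", "+", *cox3, product="cox3"),
        FeatureAnnotation("trnR", "tRNA", "+", 11721, 11784, product="Arg",
                          anticodon_span=(11753, 11755)),
        FeatureAnnotation("trnA", "tRNA", "+", 12127, 12190, product="Ala",
                          anticodon_span=(12159, 12161)),
        FeatureAnnotation("pal3", "palindrome", "+",
                          CC_LENGTH - (2 * _ARM + _LOOP) + 1, CC_LENGTH,
                          product="3' terminal palindrome"),
    ]
    model = GenomeModel(monomer_seq=monomer, features=features,
                        palindrome_arm_len=_ARM, palindrome_loop_len=_LOOP)
    _check_sites(model, CC_SITES)
    return model


def _check_sites(model: GenomeModel, sites) -> None:
    for pos, ref, _alt in sites:
        have = model.monomer_seq[pos - 1]
        if have != ref:
            raise AssertionError(
                f"stand-in construction error: expected {ref} at {pos}, got {have}"
            )


@dataclass(frozen=True)
class StandinCall:
    """Minimal call-like record for feeding printed sites to annotate_site."""

    position: int
    ref_allele: str
    alt_allele: str


def printed_calls(sites) -> list[StandinCall]:
    return [StandinCall(p, r, a) for p, r, a in sites]
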