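"""Functional interpretation of heteroplasmic sites.

Each confirmed site is read against the genome annotation and classified:
inside a terminal palindrome, in noncoding sequence, a coding substitution,
a frameshifting 1-bp deletion, or — the hallmark of isopod mitogenomes — a
substitution inside a tRNA anticodon that turns one locus into a "dual"
tRNA gene supplying two different isoacceptors.

All translation uses the invertebrate mitochondrial genetic code (NCBI
translation table 5: AGA/AGG = Ser, ATA = Met, TGA = Trp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Data import CodonTable

from ._seq import DELETION, revcomp, encode

# ---------------------------------------------------------------------------
# genetic code (table 5)

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
CODON_TO_AA = dict(_TABLE5.forward_table)  # codon -> one-letter aa
STOP_CODONS = frozenset(_TABLE5.stop_codons)

_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

# effect kinds
PALINDROME = "PALINDROME"
NONCODING = "NONCODING"
TRNA_ANTICODON = "TRNA_ANTICODON"
TRNA_BODY = "TRNA_BODY"
CDS_SUBSTITUTION = "CDS_SUBSTITUTION"
CDS_FRAMESHIFT = "CDS_FRAMESHIFT"


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class FeatureAnnotation:
    """A gene/feature on the monomer, 1-based inclusive coordinates."""

    id: str
    type: str  # CDS | rRNA | tRNA | palindrome | other
    strand: str  # "+" | "-"
    start: int
    end: int
    product: str = ""
    anticodon_span: Optional[tuple[int, int]] = None  # tRNA only, 1-based
    codon_start: int = 1  # CDS only

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.id}: start > end")
        if self.anticodon_span is not None:
            a, b = self.anticodon_span
            if b - a != 2:
                raise ValueError(f"feature {self.id}: anticodon span must be 3 bp")
            if a < self.start or b > self.end:
                raise ValueError(f"feature {self.id}: anticodon span outside feature")
        if not 1 <= self.codon_start <= 3:
            raise ValueError(f"feature {self.id}: codon_start must be 1..3")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class Effect:
    kind: str
    feature_id: Optional[str] = None
    product: Optional[str] = None
    # TRNA_ANTICODON
    ref_identity: Optional[str] = None
    alt_identity: Optional[str] = None
    # CDS_SUBSTITUTION
    codon_index: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    label: Optional[str] = None
    # CDS_FRAMESHIFT
    first_affected_codon: Optional[int] = None
    premature_stop_codon: Optional[int] = None
    last_affected_codon: Optional[int] = None


@dataclass
class EffectReport:
    position: int
    effects: list[Effect] = field(default_factory=list)

    def kinds(self) -> set[str]:
        return {e.kind for e in self.effects}


@dataclass(frozen=True)
class PalindromeHit:
    """An intra-terminus inverted repeat: arm + loop + revcomp(arm)."""

    start: int  # 1-based, first base of the 5' arm
    end: int  # 1-based, last base of the 3' arm
    arm: int
    loop: int
    mismatches: int


@dataclass(frozen=True)
class AnticodonLocation:
    span: Optional[tuple[int, int]]
    status: str  # "OK" | "AMBIGUOUS"


# ---------------------------------------------------------------------------
# translation

def translate_cds(seq: str, strand: str = "+", codon_start: int = 1) -> str:
    """Translate an annotated CDS span under the invertebrate mito code.

    ``seq`` is the reference-strand slice of the annotated span; minus-strand
    genes are reverse-complemented before translation.  Translation runs to
    the first stop codon (exclusive) or to the end of the sequence; a
    trailing incomplete codon is ignored.
    """
    if not seq:
        raise ValueError("empty CDS sequence")
    coding = revcomp(seq) if strand == "-" else seq
    coding = coding[codon_start - 1 :].upper()
    aas: list[str] = []
    for i in range(0, len(coding) - 2, 3):
        codon = coding[i : i + 3]
        if codon in STOP_CODONS:
            break
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            raise ValueError(f"untranslatable codon {codon!r}")
        aas.append(aa)
    return "".join(aas)


def _first_stop_index(coding: str) -> Optional[int]:
    """1-based codon index of the first stop in ``coding``, or None."""
    for i in range(0, len(coding) - 2, 3):
        if coding[i : i + 3] in STOP_CODONS:
            return i // 3 + 1
    return None


def decode_anticodon(anticodon: str) -> str:
    """Isoacceptor identity of a tRNA anticodon (read 5'->3').

    The decoded codon is the reverse complement of the anticodon.  Leucine
    and serine isoacceptors are disambiguated by codon family: Leu1 = CUN,
    Leu2 = UUR, Ser1 = AGN, Ser2 = UCN.  Anticodons whose codon is a stop
    decode to "Stop" (no such tRNA exists; useful for exhaustive scans).
    """
    ac = anticodon.upper().replace("U", "T")
    if len(ac) != 3 or any(b not in "ACGT" for b in ac):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    codon = revcomp(ac)
    if codon in STOP_CODONS:
        return "Stop"
    aa = CODON_TO_AA[codon]
    if aa == "L":
        return "Leu1" if codon.startswith("CT") else "Leu2"
    if aa == "S":
        return "Ser1" if codon.startswith("AG") else "Ser2"
    return _ONE_TO_THREE[aa]


# ---------------------------------------------------------------------------
# per-site annotation

def _coding_offset(feature: FeatureAnnotation, position: int) -> int:
    """0-based offset of a genome position on the feature's coding strand."""
    if feature.strand == "-":
        off = feature.end - position
    else:
        off = position - feature.start
    return off - (feature.codon_start - 1)

def _coding_seq(feature: FeatureAnnotation, genome_seq: str) -> str:
    span = genome_seq[feature.start - 1 : feature.end]
    coding = revcomp(span) if feature.strand == "-" else span
    return coding[feature.codon_start - 1 :]


def _strand_base(base: str, strand: str) -> str:
    return revcomp(base) if strand == "-" else base


def _anticodon_effect(
    feature: FeatureAnnotation, genome_seq: str, position: int, ref: str, alt: str
) -> Effect:
    a, b = feature.anticodon_span  # type: ignore[misc]
    span = genome_seq[a - 1 : b]
    if feature.strand == "-":
        ac_ref = revcomp(span)
        idx = b - position
    else:
        ac_ref = span
        idx = position - a
    ac_alt = ac_ref[:idx] + _strand_base(alt, feature.strand) + ac_ref[idx + 1 :]
    return Effect(
        kind=TRNA_ANTICODON,
        feature_id=feature.id,
        product=feature.product,
        ref_identity=decode_anticodon(ac_ref),
        alt_identity=decode_anticodon(ac_alt),
    )


def _cds_substitution_effect(
    feature: FeatureAnnotation, genome_seq: str, position: int, alt: str
) -> Effect:
    coding = _coding_seq(feature, genome_seq)
    off = _coding_offset(feature, position)
    if off < 0:
        # inside the trimmed partial codon at the 5' end
        return Effect(kind=CDS_SUBSTITUTION, feature_id=feature.id,
                      product=feature.product)
    ci = off // 3 + 1
    codon = coding[3 * (ci - 1) : 3 * ci]
    j = off % 3
    alt_codon = codon[:j] + _strand_base(alt, feature.strand) + codon[j + 1 :]
    ref_aa = "*" if codon in STOP_CODONS else CODON_TO_AA.get(codon, "X")
    alt_aa = "*" if alt_codon in STOP_CODONS else CODON_TO_AA.get(alt_codon, "X")
    return Effect(
        kind=CDS_SUBSTITUTION,
        feature_id=feature.id,
        product=feature.product,
        codon_index=ci,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        label=f"{ref_aa}{ci}{alt_aa}",
    )


def _cds_frameshift_effect(
    feature: FeatureAnnotation, genome_seq: str, position: int
) -> Effect:
    coding = _coding_seq(feature, genome_seq)
    off = _coding_offset(feature, position)
    if off < 0 or off >= len(coding):
        raise ValueError(
            f"deletion at {position} spans the boundary of feature {feature.id}"
        )
    mutated = coding[:off] + coding[off + 1 :]
    ref_protein_len = len(translate_cds(coding))
    return Effect(
        kind=CDS_FRAMESHIFT,
        feature_id=feature.id,
        product=feature.product,
        first_affected_codon=off // 3 + 1,
        premature_stop_codon=_first_stop_index(mutated),
        last_affected_codon=ref_protein_len,
    )


def annotate_site(call, genome_seq: str, features: list[FeatureAnnotation]) -> EffectReport:
    """Classify one heteroplasmic site against every overlapping feature.

    ``call`` needs ``position``, ``ref_allele`` and ``alt_allele`` attributes
    (a :class:`~isomito.het_caller.HeteroplasmyCall` or any stand-in).  A site
    overlapped by no feature yields exactly one NONCODING effect.
    """
    pos = call.position
    if not 1 <= pos <= len(genome_seq):
        raise ValueError(f"position {pos} outside genome of length {len(genome_seq)}")
    ref, alt = call.ref_allele, call.alt_allele
    is_deletion = alt == DELETION
    report = EffectReport(position=pos)
    for feat in features:
        if not feat.contains(pos):
            continue
        if feat.type == "palindrome":
            report.effects.append(
                Effect(kind=PALINDROME, feature_id=feat.id, product=feat.product)
            )
        elif feat.type == "tRNA":
            span = feat.anticodon_span
            if span is not None and span[0] <= pos <= span[1] and not is_deletion:
                report.effects.append(_anticodon_effect(feat, genome_seq, pos, ref, alt))
            else:
                report.effects.append(
                    Effect(kind=TRNA_BODY, feature_id=feat.id, product=feat.product)
                )
        elif feat.type == "CDS":
            if is_deletion:
                report.effects.append(_cds_frameshift_effect(feat, genome_seq, pos))
            else:
                report.effects.append(
                    _cds_substitution_effect(feat, genome_seq, pos, alt)
                )
        # rRNA and "other" features carry no specific consequence model;
        # they fall through to NONCODING below only if nothing else matched.
    if not report.effects:
        report.effects.append(Effect(kind=NONCODING))
    return report


# ---------------------------------------------------------------------------
# terminal palindromes

def _scan_palindrome(
    seq: str, min_arm: int, max_loop: int, max_mismatch: int, anchor: int,
    max_arm: int = 150,
) -> Optional[tuple[int, int, int, int]]:
    """Best (start0, arm, loop, mismatches) hit anchored in seq[:anchor]."""
    codes = encode(seq)
    n = codes.size
    best: Optional[tuple[int, int, int, int]] = None
    for i in range(min(anchor, n)):
        for loop in range(max_loop + 1):
            m_max = min((n - i - loop) // 2, max_arm)
            for m in range(m_max, min_arm - 1, -1):
                if best is not None and m < best[1]:
                    break
                a = codes[i : i + m]
                b = (3 - codes[i + m + loop : i + 2 * m + loop])[::-1]
                mm = int((a != b).sum())
                if mm <= max_mismatch:
                    cand = (i, m, loop, mm)
                    if best is None or (m, -loop, -i) > (best[1], -best[2], -best[0]):
                        best = cand
                    break
    return best


def detect_terminal_palindromes(
    seq: str,
    min_arm: int = 10,
    max_loop: int = 8,
    max_mismatch: int = 0,
    anchor: int = 200,
) -> tuple[Optional[PalindromeHit], Optional[PalindromeHit]]:
    """Find the longest hairpin-forming inverted repeat at each terminus.

    Each hit is a segment arm + loop + revcomp(arm) whose 5' arm starts
    within ``anchor`` bp of the respective terminus.  Returns a pair
    (5' hit, 3' hit); a terminus with no qualifying segment yields None.
    """
    if len(seq) <= 2 * min_arm + max_loop:
        raise ValueError("sequence too short for palindrome scan")
    L = len(seq)
    five = _scan_palindrome(seq, min_arm, max_loop, max_mismatch, anchor)
    three = _scan_palindrome(revcomp(seq), min_arm, max_loop, max_mismatch, anchor)
    hit5 = hit3 = None
    if five is not None:
        i, m, loop, mm = five
        hit5 = PalindromeHit(start=i + 1, end=i + 2 * m + loop, arm=m, loop=loop,
                             mismatches=mm)
    if three is not None:
        i, m, loop, mm = three
        t = 2 * m + loop
        hit3 = PalindromeHit(start=L - (i + t) + 1, end=L - i, arm=m, loop=loop,
                             mismatches=mm)
    return hit5, hit3


# ---------------------------------------------------------------------------
# anticodon localisation

def locate_anticodon(
    trna: FeatureAnnotation, seq: str, window: tuple[int, int] = (28, 40)
) -> AnticodonLocation:
    """Return the tRNA's anticodon span, locating it by decoding if absent.

    When the annotation carries no explicit span, offsets ``window`` of the
    strand-corrected tRNA sequence are scanned for the unique triplet whose
    decoded identity matches the annotated product; zero or multiple
    candidates yield status AMBIGUOUS.
    """
    if trna.type != "tRNA":
        raise ValueError(f"feature {trna.id} is not a tRNA")
    if trna.anticodon_span is not None:
        return AnticodonLocation(span=trna.anticodon_span, status="OK")
    body = seq[trna.start - 1 : trna.end]
    if trna.strand == "-":
        body = revcomp(body)
    lo, hi = window
    candidates = []
    for off in range(lo, min(hi + 1, len(body) - 2)):
        triplet = body[off : off + 3]
        try:
            ident = decode_anticodon(triplet)
        except ValueError:
            continue
        if ident == trna.product:
            candidates.append(off)
    if len(candidates) != 1:
        return AnticodonLocation(span=None, status="AMBIGUOUS")
    off = candidates[0]
    if trna.strand == "-":
        g_end = trna.end - off
        span = (g_end - 2, g_end)
    else:
        g_start = trna.start + off
        span = (g_start, g_start + 2)
    return AnticodonLocation(span=span, status="OK")
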