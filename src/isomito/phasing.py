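"""Haplotype phase of heteroplasmic site pairs from co-spanning reads.

A phasing unit is a single read covering both sites or, optionally, a
proper read pair whose mates cover one site each.  Units are tallied into
the four ref/alt combinations; anything showing a third allele, or a pair
whose two mates disagree about the same site, lands in ``n_other``.  Two
heteroplasmies riding on the same two haplotypes then show up as two large
diagonal classes and (up to sequencing error) zero recombinant classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from ._seq import DELETION
from .mapping import DEL, INS, MAPPED, MATCH, MISMATCH, AlignmentRecord

COMPLETE_LINKAGE = "COMPLETE_LINKAGE"
MIXED = "MIXED"
INSUFFICIENT = "INSUFFICIENT"


@dataclass
class HaplotypePairCount:
    site_a: int
    site_b: int
    n_rr: int = 0
    n_ra: int = 0
    n_ar: int = 0
    n_aa: int = 0
    n_other: int = 0

    @property
    def informative(self) -> int:
        return self.n_rr + self.n_ra + self.n_ar + self.n_aa

    @property
    def total(self) -> int:
        return self.informative + self.n_other


def allele_at(rec: AlignmentRecord, position: int) -> Optional[str]:
    """Read allele at a 1-based reference position, or None if uncovered.

    Walks the alignment: MATCH/MISMATCH yield the read base, a DEL op
    spanning the position yields the deletion allele, insertions consume
    read bases only.
    """
    if rec.status != MAPPED:
        return None
    pos0 = position - 1
    ref_pos = rec.ref_start
    q = 0
    for op, ln in rec.ops:
        if op in (MATCH, MISMATCH):
            if ref_pos <= pos0 < ref_pos + ln:
                return rec.seq[q + (pos0 - ref_pos)]
            ref_pos += ln
            q += ln
        elif op == DEL:
            if ref_pos <= pos0 < ref_pos + ln:
                return DELETION
            ref_pos += ln
        elif op == INS:
            q += ln
    return None


def _pair_key(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def phase_pair(
    alignments: Iterable[AlignmentRecord],
    site_a,
    site_b,
    use_pairs: bool = True,
) -> HaplotypePairCount:
    """Count ref/alt haplotype combinations across units spanning two sites.

    ``site_a``/``site_b`` need ``position``, ``ref_allele`` and
    ``alt_allele`` attributes with site_a.position < site_b.position.
    Each unit contributes to exactly one of the five counts.
    """
    if site_a.position >= site_b.position:
        raise ValueError("site_a must precede site_b")
    counts = HaplotypePairCount(site_a.position, site_b.position)

    # collect per-unit observations; unit = pair id when use_pairs else read id
    obs: dict[str, dict[int, set[str]]] = {}
    for rec in alignments:
        if rec.status != MAPPED:
            continue
        unit = _pair_key(rec.read_id) if use_pairs else rec.read_id
        for site in (site_a, site_b):
            a = allele_at(rec, site.position)
            if a is not None:
                obs.setdefault(unit, {}).setdefault(site.position, set()).add(a)

    for unit in sorted(obs):
        seen = obs[unit]
        if site_a.position not in seen or site_b.position not in seen:
            continue
        al_a, al_b = seen[site_a.position], seen[site_b.position]
        if len(al_a) > 1 or len(al_b) > 1:
            counts.n_other += 1  # mates disagree about the same site
            continue
        a, b = next(iter(al_a)), next(iter(al_b))
        a_state = "r" if a == site_a.ref_allele else ("a" if a == site_a.alt_allele else "?")
        b_state = "r" if b == site_b.ref_allele else ("a" if b == site_b.alt_allele else "?")
        if "?" in (a_state, b_state):
            counts.n_other += 1
        elif (a_state, b_state) == ("r", "r"):
            counts.n_rr += 1
        elif (a_state, b_state) == ("r", "a"):
            counts.n_ra += 1
        elif (a_state, b_state) == ("a", "r"):
            counts.n_ar += 1
        else:
            counts.n_aa += 1
    return counts


def classify_linkage(
    counts: HaplotypePairCount,
    min_units: int = 20,
    max_recomb_frac: float = 0.05,
) -> str:
    """COMPLETE_LINKAGE / MIXED / INSUFFICIENT for one phased site pair.

    Complete linkage requires the two minority classes (whichever diagonal
    they are) to total at most ``max_recomb_frac`` of informative units,
    with both majority classes observed.
    """
    n = counts.informative
    if n < min_units:
        return INSUFFICIENT
    diag = counts.n_rr + counts.n_aa
    off = counts.n_ra + counts.n_ar
    if diag >= off:
        majors, minors = (counts.n_rr, counts.n_aa), off
    else:
        majors, minors = (counts.n_ra, counts.n_ar), diag
    if minors <= max_recomb_frac * n and all(m > 0 for m in majors):
        return COMPLETE_LINKAGE
    return MIXED
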