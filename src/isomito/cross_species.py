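"""Anchor-based pairwise genome alignment and orthologous-site mapping.

Two monomer genomes are aligned by chaining unique shared k-mers
(longest collinear subsequence) and closing the inter-anchor gaps with
optimal global alignment (match +1, mismatch -1, gap -2); gaps larger than
``max_gap`` are left as unaligned blocks emitted as one-sided gap columns.
Percent identity is reported both gap-included (identical columns over all
columns) and gap-excluded; heteroplasmic sites of one species are mapped
through the alignment columns onto the other to test orthology.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

from ._seq import revcomp

GAP = -1


@dataclass
class PairwiseAlignment:
    columns: list[tuple[int, int]]  # (posA, posB) 0-based, GAP for a gap
    anchors: list[tuple[int, int]] = field(default_factory=list)
    b_reversed: bool = False
    len_a: int = 0
    len_b: int = 0

    def a_to_column(self) -> dict[int, int]:
        return {a: i for i, (a, _) in enumerate(self.columns) if a != GAP}


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in seen:
            del seen[km]
            dup.add(km)
        else:
            seen[km] = i
    return seen


def _chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain strictly increasing in both coordinates (LIS on posB)."""
    anchors = sorted(anchors)
    tails: list[int] = []  # tails[i] = smallest posB ending a chain of len i+1
    back: list[int] = [-1] * len(anchors)
    idx_at: list[int] = []
    for i, (_, b) in enumerate(anchors):
        j = bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            idx_at.append(i)
        else:
            tails[j] = b
            idx_at[j] = i
        back[i] = idx_at[j - 1] if j > 0 else -1
    chain = []
    cur = idx_at[len(tails) - 1] if tails else -1
    while cur != -1:
        chain.append(anchors[cur])
        cur = back[cur]
    chain.reverse()
    return chain


def _drop_overlaps(chain: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for a, b in chain:
        if out and (a < out[-1][0] + k or b < out[-1][1] + k):
            continue
        out.append((a, b))
    return out


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2


def _global_columns(sa: str, sb: str, oa: int, ob: int) -> list[tuple[int, int]]:
    """Columns of an optimal global alignment of two short segments."""
    if not sa and not sb:
        return []
    if not sa:
        return [(GAP, ob + j) for j in range(len(sb))]
    if not sb:
        return [(oa + i, GAP) for i in range(len(sa))]
    aln = _aligner.align(sa, sb)[0]
    cols: list[tuple[int, int]] = []
    a_done, b_done = 0, 0  # bases of sa/sb already emitted
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        cols.extend((oa + i, GAP) for i in range(a_done, a0))
        cols.extend((GAP, ob + j) for j in range(b_done, b0))
        cols.extend((oa + a0 + t, ob + b0 + t) for t in range(a1 - a0))
        a_done, b_done = a1, b1
    cols.extend((oa + i, GAP) for i in range(a_done, len(sa)))
    cols.extend((GAP, ob + j) for j in range(b_done, len(sb)))
    return cols


def _anchor_align_oriented(
    seqA: str, seqB: str, k: int, max_gap: int
) -> Optional[PairwiseAlignment]:
    ua = _unique_kmer_positions(seqA, k)
    ub = _unique_kmer_positions(seqB, k)
    anchors = [(ua[km], ub[km]) for km in ua.keys() & ub.keys()]
    if not anchors:
        return None
    chain = _drop_overlaps(_chain(anchors), k)
    if not chain:
        return None
    cols: list[tuple[int, int]] = []
    prev_a = prev_b = 0
    for a, b in chain:
        ga, gb = seqA[prev_a:a], seqB[prev_b:b]
        if max(len(ga), len(gb)) <= max_gap:
            cols.extend(_global_columns(ga, gb, prev_a, prev_b))
        else:
            cols.extend((prev_a + i, GAP) for i in range(len(ga)))
            cols.extend((GAP, prev_b + j) for j in range(len(gb)))
        cols.extend((a + t, b + t) for t in range(k))
        prev_a, prev_b = a + k, b + k
    ga, gb = seqA[prev_a:], seqB[prev_b:]
    if max(len(ga), len(gb)) <= max_gap:
        cols.extend(_global_columns(ga, gb, prev_a, prev_b))
    else:
        cols.extend((prev_a + i, GAP) for i in range(len(ga)))
        cols.extend((GAP, prev_b + j) for j in range(len(gb)))
    return PairwiseAlignment(
        columns=cols, anchors=chain, len_a=len(seqA), len_b=len(seqB)
    )


def anchor_align(
    seqA: str, seqB: str, k: int = 15, max_gap: int = 2000
) -> PairwiseAlignment:
    """Align two genomes by unique-anchor chaining plus bounded global fill.

    Both orientations of seqB are attempted; the one yielding the longer
    anchor chain wins, and ``b_reversed`` records the choice (column posB
    values then refer to the reverse-complemented sequence).
    """
    if not seqA or not seqB:
        raise ValueError("both sequences must be non-empty")
    fwd = _anchor_align_oriented(seqA, seqB, k, max_gap)
    rev = _anchor_align_oriented(seqA, revcomp(seqB), k, max_gap)
    if fwd is None and rev is None:
        raise ValueError("no chainable anchors; consider a smaller k")
    if rev is None or (fwd is not None and len(fwd.anchors) >= len(rev.anchors)):
        return fwd  # type: ignore[return-value]
    rev.b_reversed = True
    return rev


def percent_identity(
    aln: PairwiseAlignment, seqA: str, seqB: str
) -> tuple[float, float]:
    """(gap-included, gap-excluded) percent identity of an alignment.

    Gap-included counts identical-base columns over all columns, the
    convention under which two diverged ~14-kb mitogenomes land near their
    overall sequence identity; gap-excluded restricts to non-gap columns.
    """
    if not aln.columns:
        raise ValueError("empty alignment")
    sb = revcomp(seqB) if aln.b_reversed else seqB
    ident = 0
    nongap = 0
    for a, b in aln.columns:
        if a != GAP and b != GAP:
            nongap += 1
            if seqA[a] == sb[b]:
                ident += 1
    total = len(aln.columns)
    return 100.0 * ident / total, (100.0 * ident / nongap if nongap else 0.0)


def map_orthologous_position(aln: PairwiseAlignment, posA: int) -> Optional[int]:
    """1-based position in B orthologous to 1-based ``posA``, or None (gap).

    When the alignment used the reverse complement of B, the returned
    coordinate is converted back to the original B strand.
    """
    if not 1 <= posA <= aln.len_a:
        raise ValueError(f"position {posA} outside sequence A")
    col = aln.a_to_column().get(posA - 1)
    if col is None:
        return None
    b = aln.columns[col][1]
    if b == GAP:
        return None
    if aln.b_reversed:
        return aln.len_b - b
    return b + 1


@dataclass
class OrthologyTable:
    pairs: list[tuple[int, int]]  # (posA, posB) 1-based
    unpaired_a: list[int]
    unpaired_b: list[int]


def compare_heteroplasmies(
    callsA: Sequence, callsB: Sequence, aln: PairwiseAlignment, tolerance: int = 0
) -> OrthologyTable:
    """Pair heteroplasmic sites of two species through the alignment.

    A pair is formed when the orthologous projection of an A site lands
    within ``tolerance`` bp of a B site; each call joins at most one pair
    (nearest first).
    """
    a_positions = [c.position for c in callsA]
    b_positions = sorted(c.position for c in callsB)
    available = list(b_positions)
    pairs: list[tuple[int, int]] = []
    unpaired_a: list[int] = []
    for pa in sorted(a_positions):
        proj = map_orthologous_position(aln, pa)
        best = None
        if proj is not None and available:
            i = bisect_left(available, proj)
            for j in (i - 1, i):
                if 0 <= j < len(available) and abs(available[j] - proj) <= tolerance:
                    if best is None or abs(available[j] - proj) < abs(best - proj):
                        best = available[j]
        if best is None:
            unpaired_a.append(pa)
        else:
            pairs.append((pa, best))
            available.remove(best)
    return OrthologyTable(pairs=pairs, unpaired_a=unpaired_a, unpaired_b=available)
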