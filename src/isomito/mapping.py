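"""Seed-and-extend read mapping against the monomer reference.

A k-mer seed index collects candidate diagonals, the best diagonal is
voted, and the read is verified by direct comparison; reads that fail the
ungapped check fall back to a small banded alignment (1-bp indels from the
planted deletion) and finally to a best-local-segment soft-clip (reads that
run across a head-to-head dimer junction).  Base qualities are ignored
throughout; downstream calling uses counts only.

Coordinates are 0-based half-open internally; pileup output is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from ._seq import encode, rc_codes, revcomp

MAPPED = "MAPPED"
AMBIGUOUS = "AMBIGUOUS"
UNMAPPED = "UNMAPPED"

MATCH = "MATCH"
MISMATCH = "MISMATCH"
INS = "INS"
DEL = "DEL"

_ALLELE_CODES = {0: "A", 1: "C", 2: "G", 3: "T", 4: "DEL"}


@dataclass
class SeedIndex:
    k: int
    lookup: dict[str, list[int]]
    ref: str
    ref_codes: np.ndarray


def build_index(ref: str, k: int) -> SeedIndex:
    """Index every k-mer of the reference (forward strand only)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ref):
        raise ValueError("k exceeds reference length")
    codes = encode(ref)  # raises on non-ACGT
    lookup: dict[str, list[int]] = {}
    for o in range(len(ref) - k + 1):
        lookup.setdefault(ref[o : o + k], []).append(o)
    return SeedIndex(k=k, lookup=lookup, ref=ref, ref_codes=codes)


@dataclass
class AlignmentRecord:
    read_id: str
    ref_start: int  # 0-based
    strand: str
    ops: list[tuple[str, int]]
    identity: float
    status: str
    seq: str = ""  # oriented, aligned portion of the read (soft clips removed)
    mate_id: Optional[str] = None

    def ref_span(self) -> int:
        return sum(ln for op, ln in self.ops if op in (MATCH, MISMATCH, DEL))

    def read_span(self) -> int:
        return sum(ln for op, ln in self.ops if op in (MATCH, MISMATCH, INS))


def _ops_from_matchvec(match: np.ndarray) -> list[tuple[str, int]]:
    """Compress a boolean match vector into MATCH/MISMATCH runs."""
    ops: list[tuple[str, int]] = []
    if match.size == 0:
        return ops
    changes = np.flatnonzero(np.diff(match.view(np.int8)))
    start = 0
    for c in changes:
        ops.append((MATCH if match[start] else MISMATCH, int(c) + 1 - start))
        start = int(c) + 1
    ops.append((MATCH if match[start] else MISMATCH, match.size - start))
    return ops


def _banded_align(
    rcodes: np.ndarray, ref_codes: np.ndarray, diag: int, band: int
) -> Optional[tuple[int, list[tuple[str, int]], int, int]]:
    """Semi-global alignment of the read against a window around ``diag``.

    Returns (ref_start, ops, matches, aligned_cols) or None.  The read must
    align end to end; reference overhangs are free.
    """
    m = rcodes.size
    ws = max(0, diag - band)
    we = min(ref_codes.size, diag + m + band)
    win = ref_codes[ws:we]
    n = win.size
    if n < m - band:
        return None
    INF = 1 << 30
    # cost DP, rows = read prefix, cols = window prefix; free leading ref gap
    prev = [0] * (n + 1)
    ptr: list[list[int]] = []  # 0 diag, 1 up (read gap / INS), 2 left (DEL)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        row_ptr = [1] * (n + 1)
        ri = rcodes[i - 1]
        for j in range(1, n + 1):
            c_diag = prev[j - 1] + (0 if win[j - 1] == ri else 1)
            c_up = prev[j] + 1
            c_left = cur[j - 1] + 1
            best = c_diag
            p = 0
            if c_up < best:
                best, p = c_up, 1
            if c_left < best:
                best, p = c_left, 2
            cur[j] = best
            row_ptr[j] = p
        ptr.append(row_ptr)
        prev = cur
    j_end = int(np.argmin(prev[m - band if m - band > 0 else 0 :])) + max(m - band, 0)
    # traceback
    i, j = m, j_end
    rev_ops: list[str] = []
    while i > 0:
        p = ptr[i - 1][j] if j >= 0 else 1
        if p == 0 and j > 0:
            rev_ops.append("M" if win[j - 1] == rcodes[i - 1] else "X")
            i -= 1
            j -= 1
        elif p == 1 or j == 0:
            rev_ops.append("I")
            i -= 1
        else:
            rev_ops.append("D")
            j -= 1
    rev_ops.reverse()
    ref_start = ws + j
    ops: list[tuple[str, int]] = []
    names = {"M": MATCH, "X": MISMATCH, "I": INS, "D": DEL}
    for sym in rev_ops:
        nm = names[sym]
        if ops and ops[-1][0] == nm:
            ops[-1] = (nm, ops[-1][1] + 1)
        else:
            ops.append((nm, 1))
    matches = sum(1 for s in rev_ops if s == "M")
    return ref_start, ops, matches, len(rev_ops)


def _best_segment(match: np.ndarray, penalty: int = 3) -> tuple[int, int]:
    """Kadane scan: maximal-scoring contiguous segment of a match vector."""
    best_s = best_e = cur_s = 0
    best = cur = 0
    for i, ok in enumerate(match):
        cur += 1 if ok else -penalty
        if cur <= 0:
            cur = 0
            cur_s = i + 1
        elif cur > best:
            best = cur
            best_s, best_e = cur_s, i + 1
    return best_s, best_e


@dataclass
class _Candidate:
    score: int
    ref_start: int
    strand: str
    ops: list[tuple[str, int]]
    identity: float
    seq: str


def map_read(
    read: str,
    index: SeedIndex,
    *,
    read_id: str = "",
    max_mismatch_frac: float = 0.1,
    band: int = 3,
    min_aligned: int = 30,
    n_seeds: int = 4,
) -> AlignmentRecord:
    """Map one read to the indexed reference, trying both strands.

    Seed hits vote diagonals; nearby diagonals (within ``band``) cluster
    together so 1-bp indels do not split the evidence.  A read is MAPPED
    when its best alignment reaches identity >= 1 - max_mismatch_frac over
    at least ``min_aligned`` columns, AMBIGUOUS when two distinct placements
    tie on score, UNMAPPED otherwise.
    """
    k = index.k
    m = len(read)
    if m < k:
        raise ValueError("read shorter than index k")
    thresh = 1.0 - max_mismatch_frac
    codes_f = encode(read)
    codes_r = rc_codes(codes_f)
    oriented = {"+": (read, codes_f), "-": (revcomp(read), codes_r)}

    span = m - k
    offs = sorted({round(span * t / (n_seeds - 1)) for t in range(n_seeds)}) if n_seeds > 1 else [0]
    votes: dict[tuple[str, int], int] = {}
    for strand, (s, _) in oriented.items():
        for off in offs:
            for h in index.lookup.get(s[off : off + k], ()):
                key = (strand, h - off)
                votes[key] = votes.get(key, 0) + 1
    if not votes:
        return AlignmentRecord(read_id, -1, "+", [], 0.0, UNMAPPED)

    # cluster diagonals within ±band per strand
    clusters: list[tuple[int, str, list[int]]] = []  # (votes, strand, diags)
    for strand in ("+", "-"):
        diags = sorted(d for (s, d) in votes if s == strand)
        group: list[int] = []
        for d in diags:
            if group and d - group[-1] > band:
                clusters.append(
                    (sum(votes[(strand, g)] for g in group), strand, group)
                )
                group = []
            group.append(d)
        if group:
            clusters.append((sum(votes[(strand, g)] for g in group), strand, group))
    clusters.sort(key=lambda c: (-c[0], c[1], c[2][0]))

    results: list[_Candidate] = []
    for _v, strand, diags in clusters[:4]:
        s_read, s_codes = oriented[strand]
        d = max(diags, key=lambda g: votes[(strand, g)])
        qs = max(0, -d)
        qe = m - max(0, d + m - index.ref_codes.size)
        cand: Optional[_Candidate] = None
        if qe - qs >= min_aligned:
            seg = index.ref_codes[d + qs : d + qe]
            match = seg == s_codes[qs:qe]
            nmatch = int(match.sum())
            # an indel near a read end leaves a single voted diagonal with a
            # terminal block of mismatches; send that pattern to the banded
            # aligner instead of accepting it as substitutions
            mism_idx = np.flatnonzero(~match)
            terminal_block = (
                mism_idx.size >= 3
                and (mism_idx.max() < 25 or mism_idx.min() >= match.size - 25)
            )
            if (len(diags) == 1 and qs == 0 and qe == m
                    and nmatch / m >= thresh and not terminal_block):
                cand = _Candidate(nmatch, d, strand, _ops_from_matchvec(match),
                                  nmatch / m, s_read)
            elif band > 0:
                res = _banded_align(s_codes, index.ref_codes, d, band)
                if res is not None:
                    rs, ops, bmatch, cols = res
                    if cols and bmatch / cols >= thresh:
                        cand = _Candidate(bmatch, rs, strand, ops, bmatch / cols,
                                          s_read)
            if cand is None:
                # soft-clip fallback (e.g. dimer-junction reads)
                bs, be = _best_segment(match)
                if be - bs >= max(min_aligned, k):
                    sub = match[bs:be]
                    nm = int(sub.sum())
                    if nm / (be - bs) >= thresh:
                        cand = _Candidate(nm, d + qs + bs, strand,
                                          _ops_from_matchvec(sub),
                                          nm / (be - bs),
                                          s_read[qs + bs : qs + be])
        if cand is not None:
            results.append(cand)

    if not results:
        return AlignmentRecord(read_id, -1, "+", [], 0.0, UNMAPPED)
    results.sort(key=lambda c: (-c.score, c.strand, c.ref_start))
    best = results[0]
    status = MAPPED
    if len(results) > 1 and results[1].score == best.score and (
        results[1].ref_start != best.ref_start or results[1].strand != best.strand
    ):
        status = AMBIGUOUS
    return AlignmentRecord(
        read_id=read_id, ref_start=best.ref_start, strand=best.strand,
        ops=best.ops, identity=best.identity, status=status, seq=best.seq,
    )


def map_reads(
    reads: Iterable[tuple[str, str]],
    index: SeedIndex,
    **kwargs,
) -> list[AlignmentRecord]:
    return [map_read(seq, index, read_id=rid, **kwargs) for rid, seq in reads]


# ---------------------------------------------------------------------------
# pileup

@dataclass
class PileupColumn:
    position: int  # 1-based
    ref_base: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def pileup_counts(alignments: Iterable[AlignmentRecord], ref_len: int) -> np.ndarray:
    """(5, L) array of A/C/G/T/DEL counts from MAPPED alignments."""
    counts = np.zeros((5, ref_len), dtype=np.int64)
    pos_chunks: list[np.ndarray] = []
    code_chunks: list[np.ndarray] = []
    for rec in alignments:
        if rec.status != MAPPED:
            continue
        if rec.ref_start < 0 or rec.ref_start + rec.ref_span() > ref_len:
            raise ValueError(
                f"alignment of {rec.read_id!r} extends past the reference end"
            )
        rcodes = encode(rec.seq)
        ref_pos = rec.ref_start
        q = 0
        for op, ln in rec.ops:
            if op in (MATCH, MISMATCH):
                pos_chunks.append(np.arange(ref_pos, ref_pos + ln))
                code_chunks.append(rcodes[q : q + ln])
                ref_pos += ln
                q += ln
            elif op == DEL:
                pos_chunks.append(np.arange(ref_pos, ref_pos + ln))
                code_chunks.append(np.full(ln, 4, dtype=np.uint8))
                ref_pos += ln
            elif op == INS:
                q += ln
    if pos_chunks:
        allpos = np.concatenate(pos_chunks)
        allcodes = np.concatenate(code_chunks).astype(np.int64)
        np.add.at(counts, (allcodes, allpos), 1)
    return counts


def compute_pileup(
    alignments: Iterable[AlignmentRecord], ref: str
) -> list[PileupColumn]:
    """Per-position allele counts (1-based) from MAPPED alignments.

    MATCH/MISMATCH columns receive the read base, deleted reference
    positions receive DEL counts, inserted read bases are assigned to no
    column.  AMBIGUOUS and UNMAPPED records contribute nothing.
    """
    counts = pileup_counts(alignments, len(ref))
    cols = []
    for p in range(len(ref)):
        c = counts[:, p]
        cols.append(
            PileupColumn(
                position=p + 1,
                ref_base=ref[p],
                counts={_ALLELE_CODES[i]: int(c[i]) for i in range(5)},
            )
        )
    return cols
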