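"""Targeted assembly by de Bruijn unitigs and iterative read recruitment.

The workflow mirrors targeted organelle assembly from whole-genome data:
an initial assembly of all reads, selection of a seed contig that combines
high coverage with similarity to a related reference mitogenome, then
repeated cycles of "map all reads to the current assembly, recruit the
mapped reads together with their mates, re-assemble" (default 10 cycles),
and finally selection of the single longest contig across a small
parameter sweep.

K-mers are canonicalised (a k-mer and its reverse complement share one
count; with A<C<G<T this is simply the lexicographic minimum of the two
strings), and unitig extension stops at branches and at already-emitted
canonical k-mers; the latter rule makes walks terminate near the centres
of the terminal hairpin palindromes and a few bases past head-to-head
dimer junctions instead of folding back through the genome's reverse
complement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._seq import _CODE_LUT, _DECODE, BASES, encode, kmer_ints, kmer_ints_2d, \
    rc_kmer_ints, revcomp
from .mapping import MAPPED, build_index, map_read


@dataclass
class Contig:
    seq: str
    mean_cov: float

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class DeBruijnGraph:
    k: int
    kmer_counts: dict[str, int]  # canonical k-mer string -> count

    def count(self, kmer: str) -> int:
        return self.kmer_counts.get(min(kmer, revcomp(kmer)), 0)


def _canonical_counts(seqs: Sequence[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical packed k-mer values and counts over all sequences."""
    chunks: list[np.ndarray] = []
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        if len(s) >= k:
            by_len.setdefault(len(s), []).append(s)
    for ln, group in by_len.items():
        buf = np.frombuffer("".join(group).encode("ascii"), dtype=np.uint8)
        codes = _CODE_LUT[buf].reshape(len(group), ln)
        if codes.size and codes.max() > 3:
            raise ValueError("non-ACGT character in reads")
        fwd = kmer_ints_2d(codes, k).ravel()
        chunks.append(np.minimum(fwd, rc_kmer_ints(fwd, k)))
    if not chunks:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(chunks), return_counts=True)


def _decode_kmers(vals: np.ndarray, k: int) -> list[str]:
    mat = np.empty((vals.size, k), dtype=np.uint8)
    for j in range(k):
        mat[:, j] = _DECODE[(vals >> (2 * (k - 1 - j))) & 3]
    blob = mat.tobytes().decode("ascii")
    return [blob[i * k : (i + 1) * k] for i in range(vals.size)]


def build_graph(
    reads: Sequence[str], k: int, min_count: int, rel_prune: float = 0.0
) -> DeBruijnGraph:
    """Count canonical k-mers and drop those below the abundance floor.

    ``min_count`` is the absolute floor.  ``rel_prune`` > 0 additionally
    drops k-mers below that fraction of the median surviving count —
    the equivalent of tip/error-branch cleaning at high coverage, where
    recurrent sequencing errors can exceed a small absolute floor.
    """
    vals, cnt = _canonical_counts(reads, k)
    keep = cnt >= min_count
    if rel_prune > 0 and keep.any():
        floor = max(min_count, math.ceil(rel_prune * float(np.median(cnt[keep]))))
        keep = cnt >= floor
    vals, cnt = vals[keep], cnt[keep]
    kmers = _decode_kmers(vals, k)
    return DeBruijnGraph(k=k, kmer_counts=dict(zip(kmers, cnt.tolist())))


def _walk(
    counts: dict[str, int], start: str, visited: set[str]
) -> tuple[str, list[str]]:
    """Maximal unambiguous path through ``start``: (contig seq, canon path)."""

    def present(km: str) -> Optional[str]:
        c = min(km, revcomp(km))
        return c if c in counts else None

    def neighbors(km: str, forward: bool) -> list[str]:
        if forward:
            stem = km[1:]
            return [stem + b for b in BASES if present(stem + b)]
        stem = km[:-1]
        return [b + stem for b in BASES if present(b + stem)]

    def extend(cur: str, forward: bool, seen: set[str]) -> list[str]:
        out: list[str] = []
        while True:
            nxt = neighbors(cur, forward)
            if len(nxt) != 1:
                break
            nk = nxt[0]
            if len(neighbors(nk, not forward)) != 1:
                break
            c = min(nk, revcomp(nk))
            if c in seen or c in visited:
                break
            out.append(nk)
            seen.add(c)
            cur = nk
        return out

    start_c = min(start, revcomp(start))
    seen = {start_c}
    right = extend(start, True, seen)
    left = extend(start, False, seen)
    left.reverse()
    path = left + [start] + right
    canons = [min(p, revcomp(p)) for p in path]
    seq = path[0] + "".join(p[-1] for p in path[1:])
    return seq, canons


def assemble(
    reads: Sequence[str], k: int = 31, min_count: int = 3, rel_prune: float = 0.0
) -> list[Contig]:
    """Assemble reads into unitig contigs, longest first.

    K-mers below the abundance floor are dropped as sequencing error;
    contigs are maximal non-branching de Bruijn paths over canonical
    k-mers.  An empty surviving k-mer set yields an empty list.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (avoids self-reverse-complement k-mers)")
    graph = build_graph(reads, k, min_count, rel_prune)
    counts = graph.kmer_counts
    if not counts:
        return []
    visited: set[str] = set()
    contigs: list[Contig] = []
    for start in counts:  # insertion order = sorted packed value, deterministic
        if start in visited:
            continue
        seq, canons = _walk(counts, start, visited)
        visited.update(canons)
        cov = float(np.mean([counts[c] for c in canons]))
        contigs.append(Contig(seq=seq, mean_cov=cov))
    contigs.sort(key=lambda c: (-c.length, -c.mean_cov, c.seq))
    return contigs


# ---------------------------------------------------------------------------
# seed selection and recruitment

def shared_kmer_fraction(contig: str, reference: str, k: int) -> float:
    """Fraction of contig k-mers present in the reference, either strand."""
    cv = kmer_ints(encode(contig), k)
    if cv.size == 0:
        return 0.0
    cc = np.minimum(cv, rc_kmer_ints(cv, k))
    rv = kmer_ints(encode(reference), k)
    rset = np.unique(np.minimum(rv, rc_kmer_ints(rv, k)))
    return float(np.isin(cc, rset).mean())


def select_seed_contig(
    contigs: Sequence[Contig], related_reference: str, k: int = 15
) -> Contig:
    """Pick the putative mitochondrial contig from a whole-genome assembly.

    Score = (mean coverage / median contig coverage) x (fraction of contig
    k-mers shared with a related reference mitogenome, either strand); ties
    break toward the longer contig.
    """
    if not contigs:
        raise ValueError("empty contig list")
    if not related_reference:
        raise ValueError("empty related reference")
    med = float(np.median([c.mean_cov for c in contigs]))
    med = med if med > 0 else 1.0
    scored = [
        ((c.mean_cov / med) * shared_kmer_fraction(c.seq, related_reference, k),
         c.length, i)
        for i, c in enumerate(contigs)
    ]
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return contigs[scored[0][2]]


def recruit_iterate(
    all_pairs: Sequence[tuple[str, str, str]],
    seed: Contig,
    iterations: int = 10,
    map_params: Optional[dict] = None,
    asm_params: Optional[dict] = None,
) -> Contig:
    """Iterative read recruitment: map, recruit mates, re-assemble.

    ``all_pairs`` holds (pair_id, seq1, seq2).  Each cycle maps every read
    to the current assembly and recruits both mates of any pair with at
    least one MAPPED read (the mate of an AMBIGUOUS read is recruited only
    if itself MAPPED, which keeps palindrome arms from looping in ever more
    reads).  Cycles stop early when the recruited set stops changing.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    current = seed
    for _it, _recruited, contig in recruit_cycles(
        all_pairs, seed, iterations, map_params, asm_params
    ):
        current = contig
    return current


def recruit_cycles(
    all_pairs: Sequence[tuple[str, str, str]],
    seed: Contig,
    iterations: int = 10,
    map_params: Optional[dict] = None,
    asm_params: Optional[dict] = None,
):
    """Yield (iteration, recruited pair ids, contig) per recruitment cycle."""
    mp = {"k": 21, "max_mismatch_frac": 0.1, "band": 3}
    mp.update(map_params or {})
    ap = {"k": 31, "min_count": 3, "rel_prune": 0.05}
    ap.update(asm_params or {})
    current = seed
    recruited_prev: Optional[frozenset[str]] = None
    for it in range(1, iterations + 1):
        index = build_index(current.seq, mp["k"])
        recruited_ids: set[str] = set()
        for pid, s1, s2 in all_pairs:
            st1 = map_read(s1, index, max_mismatch_frac=mp["max_mismatch_frac"],
                           band=mp["band"]).status
            st2 = map_read(s2, index, max_mismatch_frac=mp["max_mismatch_frac"],
                           band=mp["band"]).status
            if st1 == MAPPED or st2 == MAPPED:
                recruited_ids.add(pid)
        recruited = frozenset(recruited_ids)
        if recruited == recruited_prev:
            break
        recruited_prev = recruited
        reads = []
        for pid, s1, s2 in all_pairs:
            if pid in recruited:
                reads.append(s1)
                reads.append(s2)
        contigs = assemble(reads, k=ap["k"], min_count=ap["min_count"],
                           rel_prune=ap["rel_prune"])
        if not contigs:
            raise RuntimeError(f"assembly collapsed to empty at iteration {it}")
        current = contigs[0]
        yield it, recruited, current


def finalize(sweep_results: Sequence[Contig]) -> Contig:
    """Final reference = single longest contig; ties favour higher coverage."""
    if not sweep_results:
        raise ValueError("empty sweep result list")
    return max(sweep_results, key=lambda c: (c.length, c.mean_cov))


def orient_to_reference(contig: Contig, reference: str, k: int = 15) -> Contig:
    """Report the contig on the strand sharing more k-mers with a reference."""
    fwd = _strand_share(contig.seq, reference, k)
    rev = _strand_share(revcomp(contig.seq), reference, k)
    if rev > fwd:
        return Contig(seq=revcomp(contig.seq), mean_cov=contig.mean_cov)
    return contig


def _strand_share(contig: str, reference: str, k: int) -> float:
    cv = kmer_ints(encode(contig), k)
    rv = np.unique(kmer_ints(encode(reference), k))
    if cv.size == 0:
        return 0.0
    return float(np.isin(cv, rv).mean())
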