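"""Heteroplasmy calling from pileup allele counts.

The rule is deliberately simple and count-based: a site is a putative
constitutive heteroplasmy when its depth is at least ``min_cov`` (default
100x) and the most frequent non-reference allele — a base or a deletion —
exceeds frequency ``min_freq`` (default 0.2, strict inequality).  Depth is
">=", frequency is ">".  Base qualities play no role.

Per-sample call tables mirror the shape of a multi-individual heteroplasmy
table: the union of called positions, with the observed alternate-allele
frequency and coverage reported for every sample, including samples in
which the site did not itself pass the calling rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._seq import DELETION
from .mapping import PileupColumn

HOMOPOLYMER = "HOMOPOLYMER"
MULTIALLELIC = "MULTIALLELIC"
LOW_TERMINAL_COVERAGE = "LOW_TERMINAL_COVERAGE"

_DEL_KEY = "DEL"


@dataclass(frozen=True)
class HeteroplasmyCall:
    position: int  # 1-based
    ref_allele: str
    alt_allele: str  # base, or "-" for a 1-bp deletion
    per_sample: dict[str, tuple[float, int]] = field(default_factory=dict)
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.alt_allele == self.ref_allele:
            raise ValueError("alt allele equals ref allele")
        for sample, (freq, cov) in self.per_sample.items():
            if not 0.0 <= freq <= 1.0 or cov < 0:
                raise ValueError(f"invalid frequency/coverage for sample {sample}")

    def alt_freq(self, sample: str) -> float:
        return self.per_sample[sample][0]

    def coverage(self, sample: str) -> int:
        return self.per_sample[sample][1]


def _column_alt(col: PileupColumn) -> tuple[Optional[str], int, Optional[str], int]:
    """(top non-ref allele, count, runner-up allele, count) for one column."""
    items = [
        (allele, n) for allele, n in col.counts.items()
        if allele != col.ref_base and n > 0
    ]
    items.sort(key=lambda t: (-t[1], t[0]))
    first = items[0] if items else (None, 0)
    second = items[1] if len(items) > 1 else (None, 0)
    return first[0], first[1], second[0], second[1]


def _as_allele(key: Optional[str]) -> Optional[str]:
    return DELETION if key == _DEL_KEY else key


def call_sites(
    pileup: Sequence[PileupColumn],
    min_cov: int = 100,
    min_freq: float = 0.2,
    sample: str = "sample",
) -> list[HeteroplasmyCall]:
    """Apply the coverage/frequency rule to every pileup column.

    Deterministic in the pileup; the MULTIALLELIC flag marks columns where
    a second non-reference allele also exceeds ``min_freq``.
    """
    seen = set()
    calls: list[HeteroplasmyCall] = []
    for col in pileup:
        if col.position in seen:
            raise ValueError(f"duplicate pileup position {col.position}")
        seen.add(col.position)
        depth = col.depth
        if depth < min_cov:
            continue
        top, n_top, second, n_second = _column_alt(col)
        if top is None or n_top / depth <= min_freq:
            continue
        flags = set()
        if second is not None and n_second / depth > min_freq:
            flags.add(MULTIALLELIC)
        calls.append(
            HeteroplasmyCall(
                position=col.position,
                ref_allele=col.ref_base,
                alt_allele=_as_allele(top),
                per_sample={sample: (n_top / depth, depth)},
                flags=frozenset(flags),
            )
        )
    return calls


def observed_at(
    pileup_by_pos: Mapping[int, PileupColumn], position: int, alt_allele: str
) -> tuple[float, int]:
    """Observed frequency/coverage of a specific allele, called or not."""
    col = pileup_by_pos.get(position)
    if col is None or col.depth == 0:
        return 0.0, 0
    key = _DEL_KEY if alt_allele == DELETION else alt_allele
    return col.counts.get(key, 0) / col.depth, col.depth


def merge_samples(
    per_sample_calls: Mapping[str, Sequence[HeteroplasmyCall]],
    pileups: Mapping[str, Sequence[PileupColumn]],
) -> list[HeteroplasmyCall]:
    """Union of called positions with per-sample frequencies for all samples.

    For a sample in which a position was not called, the observed frequency
    of the calling sample's alternate allele and the local coverage are
    still reported (so a 0.04-frequency deletion in the second individual
    remains visible).  Rows are sorted by position.
    """
    lengths = {len(p) for p in pileups.values()}
    if len(lengths) > 1:
        raise ValueError("samples were piled up against different references")
    by_pos_pileup = {
        s: {c.position: c for c in cols} for s, cols in pileups.items()
    }
    chosen: dict[int, HeteroplasmyCall] = {}
    for sample in per_sample_calls:
        for call in per_sample_calls[sample]:
            prev = chosen.get(call.position)
            if prev is None:
                chosen[call.position] = call
            elif prev.alt_allele != call.alt_allele:
                # keep the allele with the higher supporting frequency
                if max(f for f, _ in call.per_sample.values()) > max(
                    f for f, _ in prev.per_sample.values()
                ):
                    chosen[call.position] = call
    merged: list[HeteroplasmyCall] = []
    for pos in sorted(chosen):
        call = chosen[pos]
        per_sample = {}
        flags = set(call.flags)
        for sample in pileups:
            own = next(
                (c for c in per_sample_calls.get(sample, [])
                 if c.position == pos and c.alt_allele == call.alt_allele),
                None,
            )
            if own is not None:
                per_sample[sample] = own.per_sample[sample]
                flags |= own.flags
            else:
                per_sample[sample] = observed_at(
                    by_pos_pileup[sample], pos, call.alt_allele
                )
        merged.append(replace(call, per_sample=per_sample, flags=frozenset(flags)))
    return merged


def flag_homopolymer(
    call: HeteroplasmyCall, ref: str, min_run: int = 4, window: int = 1
) -> HeteroplasmyCall:
    """Flag calls at or next to homopolymer runs (platform artifact risk).

    The HOMOPOLYMER flag is set when a single-base run of length at least
    ``min_run`` begins or ends within ``window`` bp of the site.
    """
    pos0 = call.position - 1
    if not 0 <= pos0 < len(ref):
        raise ValueError(f"position {call.position} outside reference")
    flagged = False
    i = 0
    L = len(ref)
    while i < L and not flagged:
        j = i
        while j < L and ref[j] == ref[i]:
            j += 1
        if j - i >= min_run:
            # run occupies [i, j-1]; boundaries are its first and last base
            if abs(i - pos0) <= window or abs((j - 1) - pos0) <= window:
                flagged = True
        i = j
    if not flagged:
        return call
    return replace(call, flags=call.flags | {HOMOPOLYMER})


def flag_terminal_coverage(
    calls: Sequence[HeteroplasmyCall],
    palindrome_spans: Sequence[tuple[int, int]],
    min_depth: int = 300,
) -> list[HeteroplasmyCall]:
    """Flag calls inside terminal palindromes whose coverage is thin."""
    out = []
    for call in calls:
        in_term = any(a <= call.position <= b for a, b in palindrome_spans)
        thin = any(cov < min_depth for _, cov in call.per_sample.values())
        if in_term and thin:
            out.append(replace(call, flags=call.flags | {LOW_TERMINAL_COVERAGE}))
        else:
            out.append(call)
    return out


def calls_table(calls: Sequence[HeteroplasmyCall], samples: Sequence[str]) -> pd.DataFrame:
    """Flat table of calls (one row per site, freq/cov columns per sample)."""
    rows = []
    for c in calls:
        row: dict = {
            "position": c.position,
            "ref_allele": c.ref_allele,
            "alt_allele": c.alt_allele,
        }
        for s in samples:
            freq, cov = c.per_sample.get(s, (float("nan"), 0))
            row[f"alt_freq_{s}"] = round(freq, 4)
            row[f"cov_{s}"] = cov
        row["flags"] = ",".join(sorted(c.flags))
        rows.append(row)
    return pd.DataFrame(rows)
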