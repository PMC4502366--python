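"""Ground-truth genome and read simulation for linear/dimeric mitogenomes.

The generator emulates the salient structure of terrestrial-isopod
mitochondrial DNA: a ~14-kb monomer carrying self-reverse-complementary
(hairpin-forming) terminal palindromes, a gene complement of 13 CDS, 2 rRNA
and ~22 tRNA genes, and a molecule population mixing linear monomers with
circular head-to-head dimers.  Constitutive heteroplasmies are planted as
two (or more) linked haplotype classes, matching the observation that reads
carry either all reference or all alternate alleles of a class; sites that
are idiosyncratic to an individual can be simulated as UNLINKED and are
realised by independent per-molecule draws.

Simulated reads are paired-end with uniform substitution errors and
constant Q30 qualities; downstream callers use counts only, so no indel
error model or quality decay is simulated.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, DELETION, random_seq, revcomp
from .effects import CODON_TO_AA, STOP_CODONS, FeatureAnnotation

UNLINKED = "UNLINKED"

#: canonical anticodon used when planting each isoacceptor's tRNA
PRODUCT_ANTICODON = {
    "Ala": "TGC", "Arg": "TCG", "Asn": "GTT", "Asp": "GTC", "Cys": "GCA",
    "Gln": "TTG", "Glu": "TTC", "Gly": "TCC", "His": "GTG", "Ile": "GAT",
    "Leu1": "TAG", "Leu2": "TAA", "Lys": "TTT", "Met": "CAT", "Phe": "GAA",
    "Pro": "TGG", "Ser1": "TCT", "Ser2": "TGA", "Thr": "TGT", "Trp": "TCA",
    "Tyr": "GTA", "Val": "TAC",
}


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class HeteroplasmySpec:
    """One planted heteroplasmic site (1-based monomer coordinates)."""

    position: int
    ref_allele: str
    alt_allele: str  # a base, or DELETION ("-") for a 1-bp deletion
    alt_freq: float
    haplotype_class: str = UNLINKED

    def __post_init__(self) -> None:
        if not 0 < self.alt_freq < 1:
            raise ValueError("alt_freq must be in (0, 1)")
        if self.alt_allele != DELETION and self.alt_allele not in BASES:
            raise ValueError(f"invalid alt allele {self.alt_allele!r}")
        if self.alt_allele == self.ref_allele:
            raise ValueError("alt allele equals ref allele")

    @property
    def linked(self) -> bool:
        return self.haplotype_class != UNLINKED


@dataclass(frozen=True)
class ReadSimParams:
    coverage: float
    read_len: int = 100
    insert_mean: float = 750.0
    insert_sd: float = 75.0
    sub_error_rate: float = 0.0
    dimer_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0 <= self.dimer_fraction <= 1:
            raise ValueError("dimer_fraction must be in [0, 1]")
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must not exceed insert_mean")


@dataclass(frozen=True)
class Haplotype:
    """One full-length monomer haplotype and its population weight."""

    name: str
    seq: str
    weight: float
    carries: frozenset[str] = frozenset()  # haplotype classes in alt state
    deleted_positions: tuple[int, ...] = ()  # 1-based monomer coords

    def monomer_to_hap(self, position: int) -> Optional[int]:
        """0-based haplotype coordinate of a 1-based monomer position."""
        if position in self.deleted_positions:
            return None
        shift = bisect_left(self.deleted_positions, position)
        return position - 1 - shift


@dataclass
class GenomeModel:
    monomer_seq: str
    features: list[FeatureAnnotation]
    palindrome_arm_len: int
    palindrome_loop_len: int = 0
    het_truth: list[HeteroplasmySpec] = field(default_factory=list)
    haplotypes: list[Haplotype] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.haplotypes:
            self.haplotypes = [Haplotype("H0", self.monomer_seq, 1.0)]

    @property
    def haplotype_seqs(self) -> list[tuple[str, float]]:
        return [(h.seq, h.weight) for h in self.haplotypes]

    @property
    def unlinked_specs(self) -> list[HeteroplasmySpec]:
        return [s for s in self.het_truth if not s.linked]

    @property
    def linked_specs(self) -> list[HeteroplasmySpec]:
        return [s for s in self.het_truth if s.linked]


@dataclass(frozen=True)
class FeatureTemplate:
    """Relative placement recipe for one feature of a generated genome."""

    id: str
    type: str  # CDS | rRNA | tRNA | other
    length: int
    strand: str = "+"
    product: str = ""
    anticodon_offset: int = 32  # tRNA only; 0-based on the strand-corrected body
    spacer_before: Optional[int] = None  # None -> small random spacer
    within: Optional[str] = None  # id of a CDS this tRNA is allowed to overlap
    within_offset: int = 0


def default_feature_template() -> list[FeatureTemplate]:
    """An isopod-like gene complement: 13 CDS, 2 rRNA, 22 tRNA."""
    cds = [
        ("cox1", 1401), ("cox2", 660), ("atp8", 150), ("atp6", 660),
        ("cox3", 780), ("nad3", 330), ("nad5", 1500), ("nad4", 1200),
        ("nad4l", 270), ("nad6", 480), ("cob", 1101), ("nad1", 900),
        ("nad2", 960),
    ]
    rrna = [("rrnL", 1050), ("rrnS", 700)]
    trna = list(PRODUCT_ANTICODON)
    out: list[FeatureTemplate] = []
    strands = itertools.cycle("++-+")
    for name, ln in cds:
        out.append(FeatureTemplate(id=name, type="CDS", length=ln,
                                   strand=next(strands), product=name))
    for name, ln in rrna:
        out.append(FeatureTemplate(id=name, type="rRNA", length=ln,
                                   strand="-", product=name))
    for prod in trna:
        out.append(FeatureTemplate(id=f"trn{prod}", type="tRNA", length=64,
                                   strand="+", product=prod))
    return out


# ---------------------------------------------------------------------------
# genome generation

def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random internal non-stop codons + TAA, under table 5."""
    sense = [c for c in CODON_TO_AA if c not in STOP_CODONS]
    body = rng.choice(len(sense), size=n_codons - 2)
    return "ATG" + "".join(sense[i] for i in body) + "TAA"


def _write_palindromes(seq: list[str], arm: int, loop: int) -> None:
    L = len(seq)
    if arm <= 0:
        return
    head = "".join(seq[arm + loop : 2 * arm + loop])
    seq[0:arm] = list(revcomp(head))
    tail = "".join(seq[L - 2 * arm - loop : L - arm - loop])
    seq[L - arm : L] = list(revcomp(tail))


def plant_anticodon_span(
    seq: list[str], feat: FeatureAnnotation, anticodon: str
) -> None:
    a, b = feat.anticodon_span  # type: ignore[misc]
    triplet = anticodon if feat.strand == "+" else revcomp(anticodon)
    seq[a - 1 : b] = list(triplet)


def generate_monomer(
    length: int = 14000,
    palindrome_arm: int = 25,
    loop: int = 4,
    feature_template: Optional[Sequence[FeatureTemplate]] = None,
    seed: int = 0,
) -> GenomeModel:
    """Generate a random monomer genome with hairpin termini and features.

    Features are placed sequentially downstream of the 5' palindrome with
    small random spacers; CDS spans are filled with stop-free coding
    sequence (table 5), tRNA spans receive their isoacceptor's anticodon at
    ``anticodon_offset``.  Raises ValueError when the template cannot be
    packed into the sequence.
    """
    template = list(feature_template) if feature_template is not None else []
    rng = np.random.default_rng(seed)
    terminal = 2 * palindrome_arm + loop if palindrome_arm > 0 else 0
    span_total = sum(t.length for t in template)
    if length <= 2 * terminal + span_total:
        raise ValueError("genome length too small for palindromes plus features")

    seq = list(random_seq(length, rng))
    features: list[FeatureAnnotation] = []
    by_id: dict[str, FeatureAnnotation] = {}

    cursor = terminal  # 0-based start of unused core
    core_end = length - terminal
    for t in template:
        if t.type == "CDS" and t.length % 3:
            raise ValueError(f"CDS template {t.id}: length must be a multiple of 3")
        if t.within is not None:
            host = by_id.get(t.within)
            if host is None:
                raise ValueError(f"template {t.id}: unknown host feature {t.within}")
            start0 = host.start - 1 + t.within_offset
        else:
            spacer = t.spacer_before
            if spacer is None:
                spacer = int(rng.integers(2, 9))
            start0 = cursor + spacer
        end0 = start0 + t.length - 1
        if t.within is None:
            if end0 >= core_end:
                raise ValueError(
                    f"feature {t.id} does not fit: needs bases up to {end0 + 1}, "
                    f"core ends at {core_end}"
                )
            cursor = end0 + 1
        anticodon_span = None
        if t.type == "tRNA":
            if not 0 <= t.anticodon_offset <= t.length - 3:
                raise ValueError(f"tRNA {t.id}: anticodon offset outside body")
            if t.strand == "+":
                g = start0 + 1 + t.anticodon_offset
                anticodon_span = (g, g + 2)
            else:
                g = end0 + 1 - t.anticodon_offset
                anticodon_span = (g - 2, g)
        feat = FeatureAnnotation(
            id=t.id, type=t.type, strand=t.strand, start=start0 + 1, end=end0 + 1,
            product=t.product, anticodon_span=anticodon_span,
        )
        features.append(feat)
        by_id[feat.id] = feat

        if t.type == "CDS":
            coding = random_cds(t.length // 3, rng)
            if t.strand == "-":
                coding = revcomp(coding)
            seq[start0 : end0 + 1] = list(coding)
        elif t.type == "tRNA":
            anticodon = PRODUCT_ANTICODON.get(t.product)
            if anticodon is not None:
                plant_anticodon_span(seq, feat, anticodon)

    # overlap check: features must be disjoint unless one is a tRNA placed
    # inside its declared host CDS
    spans = sorted(
        (f.start, f.end, f.id) for f in features
        if by_id[f.id] and not any(t.id == f.id and t.within for t in template)
    )
    for (s1, e1, id1), (s2, e2, id2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"features {id1} and {id2} overlap")

    _write_palindromes(seq, palindrome_arm, loop)
    monomer = "".join(seq)

    for f in features:
        if f.type == "CDS":
            body = monomer[f.start - 1 : f.end]
            coding = revcomp(body) if f.strand == "-" else body
            internal = [coding[i : i + 3] for i in range(0, len(coding) - 3, 3)]
            if any(c in STOP_CODONS for c in internal):
                raise ValueError(f"CDS {f.id} contains an internal stop codon")

    return GenomeModel(
        monomer_seq=monomer,
        features=features,
        palindrome_arm_len=palindrome_arm,
        palindrome_loop_len=loop,
    )


# ---------------------------------------------------------------------------
# heteroplasmy planting

def _apply_alleles(
    monomer: str, specs: Sequence[HeteroplasmySpec]
) -> tuple[str, tuple[int, ...]]:
    seq = list(monomer)
    deleted: list[int] = []
    for s in sorted(specs, key=lambda s: -s.position):
        if s.alt_allele == DELETION:
            del seq[s.position - 1]
            deleted.append(s.position)
        else:
            seq[s.position - 1] = s.alt_allele
    return "".join(seq), tuple(sorted(deleted))


def plant_heteroplasmies(
    genome: GenomeModel, specs: Sequence[HeteroplasmySpec]
) -> GenomeModel:
    """Derive the haplotype population realising a set of heteroplasmies.

    Sites sharing a ``haplotype_class`` co-occur on the same haplotypes;
    distinct classes segregate independently, so k classes yield 2**k
    haplotypes whose weights are products of the class frequencies.
    UNLINKED sites are not baked into haplotypes; the read simulator
    realises them by independent Bernoulli draws per molecule.
    """
    positions = [s.position for s in specs]
    if len(set(positions)) != len(positions):
        raise ValueError("two heteroplasmy specs at the same position")
    for s in specs:
        ref = genome.monomer_seq[s.position - 1]
        if s.ref_allele != ref:
            raise ValueError(
                f"spec at {s.position}: ref allele {s.ref_allele} does not match "
                f"monomer base {ref}"
            )
    classes: list[str] = []
    class_freq: dict[str, float] = {}
    for s in specs:
        if not s.linked:
            continue
        if s.haplotype_class not in classes:
            classes.append(s.haplotype_class)
            class_freq[s.haplotype_class] = s.alt_freq
        elif abs(class_freq[s.haplotype_class] - s.alt_freq) > 1e-9:
            raise ValueError(
                f"sites of class {s.haplotype_class} declare different alt_freqs"
            )

    haplotypes: list[Haplotype] = []
    for i, combo in enumerate(itertools.product([False, True], repeat=len(classes))):
        carried = frozenset(c for c, on in zip(classes, combo) if on)
        weight = 1.0
        for c in classes:
            f = class_freq[c]
            weight *= f if c in carried else (1.0 - f)
        applied = [s for s in specs if s.linked and s.haplotype_class in carried]
        seq, deleted = _apply_alleles(genome.monomer_seq, applied)
        haplotypes.append(
            Haplotype(name=f"H{i}", seq=seq, weight=weight, carries=carried,
                      deleted_positions=deleted)
        )
    return replace(genome, het_truth=list(specs), haplotypes=haplotypes)


# ---------------------------------------------------------------------------
# read simulation

@dataclass(frozen=True)
class SimReadPair:
    pair_id: str
    seq1: str
    seq2: str


@dataclass
class SimResult:
    pairs: list[SimReadPair]
    truth: pd.DataFrame
    params: ReadSimParams
    genome: GenomeModel

    def reads(self) -> list[tuple[str, str]]:
        """Flatten to (read_id, sequence) with /1 and /2 suffixes."""
        out = []
        for p in self.pairs:
            out.append((p.pair_id + "/1", p.seq1))
            out.append((p.pair_id + "/2", p.seq2))
        return out

    def write_fastq(self, path1, path2) -> None:
        q = "?"  # constant Q30; callers in this package ignore qualities
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for p in self.pairs:
                f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{q * len(p.seq1)}\n")
                f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{q * len(p.seq2)}\n")

    def write_truth(self, path) -> None:
        cols = ["read_id", "haplotype", "ref_start0", "strand", "molecule_type"]
        self.truth[cols].to_csv(path, sep="\t", index=False)

    def site_read_truth(self, position: int) -> pd.DataFrame:
        """Per-read truth at a planted substitution site.

        Returns the truth rows of reads whose source interval covers the
        site on its molecule, with a ``carries_alt`` column derived from the
        source haplotype (linked sites only; sequencing error not applied).
        """
        spec = next(s for s in self.genome.het_truth if s.position == position)
        if not spec.linked:
            raise ValueError("per-read truth is only defined for linked sites")
        haps = {h.name: h for h in self.genome.haplotypes}
        rows = []
        rl = self.params.read_len
        for t in self.truth.itertuples():
            if t.molecule_type == "monomer":
                h = haps[t.haplotype]
                p = h.monomer_to_hap(position)
                if p is not None and t.ref_start0 <= p < t.ref_start0 + rl:
                    rows.append((t.read_id, spec.haplotype_class in h.carries))
            else:
                name_a, name_b = t.haplotype.split("+")
                ha, hb = haps[name_a], haps[name_b]
                la, lb = len(ha.seq), len(hb.seq)
                ld = la + lb
                pa = ha.monomer_to_hap(position)
                pb = hb.monomer_to_hap(position)
                if pa is not None and (pa - t.ref_start0) % ld < rl:
                    rows.append((t.read_id, spec.haplotype_class in ha.carries))
                if pb is not None:
                    q = la + (lb - 1 - pb)
                    if (q - t.ref_start0) % ld < rl:
                        rows.append((t.read_id, spec.haplotype_class in hb.carries))
        return pd.DataFrame(rows, columns=["read_id", "carries_alt"])


def _mutate_read(
    seq: str, n_err: int, rng: np.random.Generator
) -> str:
    chars = list(seq)
    pos = rng.integers(0, len(chars), size=n_err)
    shift = rng.integers(1, 4, size=n_err)
    for p, sh in zip(pos, shift):
        chars[p] = BASES[(BASES.index(chars[p]) + sh) % 4]
    return "".join(chars)


def simulate_reads(genome: GenomeModel, params: ReadSimParams) -> SimResult:
    """Simulate paired-end reads from a monomer/dimer molecule population.

    Each fragment is drawn from a linear monomer haplotype (probability
    1 - dimer_fraction; fragments never cross the termini) or from a
    circular head-to-head dimer built as haplotype + revcomp(haplotype)
    (fragments may cross both junctions).  Total sequenced bases equal
    coverage x monomer length by construction.
    """
    L = len(genome.monomer_seq)
    rl = params.read_len
    if params.insert_mean > L:
        raise ValueError("insert_mean exceeds monomer length")
    haps = genome.haplotypes
    weights = np.array([h.weight for h in haps], dtype=float)
    weights = weights / weights.sum()
    n_pairs = int(round(params.coverage * L / (2 * rl)))

    rng = np.random.default_rng(params.seed)
    is_dimer = rng.random(n_pairs) < params.dimer_fraction
    hap_a = rng.choice(len(haps), size=n_pairs, p=weights)
    hap_b = rng.choice(len(haps), size=n_pairs, p=weights)
    frag_len = np.rint(
        rng.normal(params.insert_mean, params.insert_sd, size=n_pairs)
    ).astype(int)
    frag_len = np.clip(frag_len, rl + 2, L)
    u_start = rng.random(n_pairs)
    unlinked = genome.unlinked_specs
    unl_draws = {
        s.position: (rng.random(n_pairs) < s.alt_freq, rng.random(n_pairs) < s.alt_freq)
        for s in unlinked
    }
    err = (
        rng.binomial(rl, params.sub_error_rate, size=2 * n_pairs)
        if params.sub_error_rate > 0
        else np.zeros(2 * n_pairs, dtype=int)
    )

    dimer_cache: dict[tuple[int, int], str] = {}
    max_frag = int(frag_len.max())

    pairs: list[SimReadPair] = []
    truth_rows: list[tuple] = []
    for i in range(n_pairs):
        fl = int(frag_len[i])
        a = int(hap_a[i])
        if is_dimer[i]:
            b = int(hap_b[i])
            key = (a, b)
            doubled = dimer_cache.get(key)
            la, lb = len(haps[a].seq), len(haps[b].seq)
            ld = la + lb
            if doubled is None:
                s = haps[a].seq + revcomp(haps[b].seq)
                doubled = s + s[: max_frag + len(unlinked) + 1]
                dimer_cache[key] = doubled
            start = int(u_start[i] * ld)
            frag = doubled[start : start + fl]
            hap_label = f"{haps[a].name}+{haps[b].name}"
            mol = "dimer"
            mol_len = ld
        else:
            hseq = haps[a].seq
            lh = len(hseq)
            if fl > lh:
                fl = lh
            start = int(u_start[i] * (lh - fl + 1))
            frag = hseq[start : start + fl]
            hap_label = haps[a].name
            mol = "monomer"
            mol_len = lh

        if unlinked:
            frag = _apply_unlinked(
                frag, start, fl, i, a, int(hap_b[i]), is_dimer[i], haps,
                unlinked, unl_draws, mol_len,
            )

        r1 = frag[:rl]
        r2 = revcomp(frag[-rl:])
        if err[2 * i]:
            r1 = _mutate_read(r1, int(err[2 * i]), rng)
        if err[2 * i + 1]:
            r2 = _mutate_read(r2, int(err[2 * i + 1]), rng)
        pid = f"sim{i:07d}"
        pairs.append(SimReadPair(pid, r1, r2))
        truth_rows.append((pid + "/1", hap_label, start % mol_len, "+", mol,
                           start % mol_len, len(frag)))
        truth_rows.append((pid + "/2", hap_label, (start + len(frag) - rl) % mol_len,
                           "-", mol, start % mol_len, len(frag)))

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "haplotype", "ref_start0", "strand", "molecule_type",
                 "frag_start0", "frag_len"],
    )
    return SimResult(pairs=pairs, truth=truth, params=params, genome=genome)


def _apply_unlinked(
    frag: str, start: int, fl: int, i: int, a: int, b: int, dimer: bool,
    haps: list[Haplotype], unlinked: list[HeteroplasmySpec],
    unl_draws: dict, mol_len: int,
) -> str:
    """Realise UNLINKED sites on one fragment by per-molecule draws."""
    edits: list[tuple[int, str]] = []  # (fragment offset, new base or DELETION)
    for s in unlinked:
        draw_a, draw_b = unl_draws[s.position]
        if dimer:
            ha, hb = haps[a], haps[b]
            la, lb = len(ha.seq), len(hb.seq)
            pa = ha.monomer_to_hap(s.position)
            pb = hb.monomer_to_hap(s.position)
            if pa is not None and draw_a[i]:
                off = (pa - start) % mol_len
                if off < fl:
                    edits.append((off, s.alt_allele))
            if pb is not None and draw_b[i]:
                q = la + (lb - 1 - pb)
                off = (q - start) % mol_len
                if off < fl:
                    alt = s.alt_allele if s.alt_allele == DELETION else revcomp(s.alt_allele)
                    edits.append((off, alt))
        else:
            h = haps[a]
            p = h.monomer_to_hap(s.position)
            if p is not None and draw_a[i] and start <= p < start + fl:
                edits.append((p - start, s.alt_allele))
    if not edits:
        return frag
    chars = list(frag)
    for off, alt in sorted(edits, key=lambda e: -e[0]):
        if alt == DELETION:
            del chars[off]
        else:
            chars[off] = alt
    return "".join(chars)
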