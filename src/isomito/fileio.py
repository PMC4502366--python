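"""Readers and writers for the standard formats the pipeline touches.

FASTA and GenBank flat files go through Biopython; GFF3 is read with
gffutils.  All coordinates in files are 1-based inclusive (GFF/GenBank
convention, matching the site numbering used in heteroplasmy tables); VCF
output follows the VCF 4.2 anchor-base convention for deletions.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import gffutils
from Bio import SeqIO

from ._seq import DELETION, encode
from .effects import EffectReport, FeatureAnnotation
from .het_caller import HeteroplasmyCall

_TRNA_AA = {
    "ala": "Ala", "arg": "Arg", "asn": "Asn", "asp": "Asp", "cys": "Cys",
    "gln": "Gln", "glu": "Glu", "gly": "Gly", "his": "His", "ile": "Ile",
    "leu": "Leu", "leu1": "Leu1", "leu2": "Leu2", "lys": "Lys", "met": "Met",
    "phe": "Phe", "pro": "Pro", "ser": "Ser", "ser1": "Ser1", "ser2": "Ser2",
    "thr": "Thr", "trp": "Trp", "tyr": "Tyr", "val": "Val",
}


def normalise_trna_product(product: str) -> str:
    """Map 'tRNA-Ala', 'trnL1' etc. to the package's isoacceptor labels."""
    p = product.strip()
    for prefix in ("tRNA-", "trn", "tRNA "):
        if p.startswith(prefix):
            p = p[len(prefix) :]
            break
    return _TRNA_AA.get(p.lower(), p)


# ---------------------------------------------------------------------------
# FASTA / GFF3

def write_fasta(seq: str, seq_id: str, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq_id}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> tuple[str, str]:
    """(id, sequence) of a single-record FASTA; validates the alphabet."""
    rec = SeqIO.read(path, "fasta")
    seq = str(rec.seq).upper()
    try:
        encode(seq)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return rec.id, seq


def write_gff3(
    features: Sequence[FeatureAnnotation], seq_id: str, seq_len: int, path
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seq_id} 1 {seq_len}\n")
        for f in features:
            attrs = [f"ID={f.id}"]
            if f.product:
                attrs.append(f"product={f.product}")
            if f.anticodon_span is not None:
                a, b = f.anticodon_span
                attrs.append(f"anticodon_span={a}..{b}")
            phase = str(f.codon_start - 1) if f.type == "CDS" else "."
            fh.write(
                "\t".join(
                    [seq_id, "isomito", f.type, str(f.start), str(f.end), ".",
                     f.strand, phase, ";".join(attrs)]
                )
                + "\n"
            )


def read_gff3(path) -> list[FeatureAnnotation]:
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise ValueError(f"malformed GFF3 {path}: {exc}") from exc
    feats: list[FeatureAnnotation] = []
    for f in db.all_features():
        attrs = f.attributes
        anticodon = None
        if "anticodon_span" in attrs:
            a, b = attrs["anticodon_span"][0].split("..")
            anticodon = (int(a), int(b))
        product = attrs["product"][0] if "product" in attrs else ""
        if f.featuretype == "tRNA":
            product = normalise_trna_product(product)
        codon_start = 1
        if f.featuretype == "CDS" and f.frame not in (None, "."):
            codon_start = int(f.frame) + 1
        feats.append(
            FeatureAnnotation(
                id=f.id, type=f.featuretype, strand=f.strand or "+",
                start=f.start, end=f.end, product=product,
                anticodon_span=anticodon, codon_start=codon_start,
            )
        )
    feats.sort(key=lambda x: (x.start, x.end))
    return feats


# ---------------------------------------------------------------------------
# GenBank

def _read_genbank(path) -> tuple[str, list[FeatureAnnotation]]:
    try:
        rec = SeqIO.read(path, "genbank")
    except Exception as exc:
        raise ValueError(f"malformed GenBank record {path}: {exc}") from exc
    seq = str(rec.seq).upper()
    encode(seq)
    feats: list[FeatureAnnotation] = []
    n = 0
    for f in rec.features:
        if f.type not in ("CDS", "tRNA", "rRNA"):
            continue
        n += 1
        q = f.qualifiers
        product = q.get("product", [q.get("gene", [""])[0]])[0]
        if f.type == "tRNA":
            product = normalise_trna_product(product)
        fid = q.get("gene", q.get("locus_tag", [f"{f.type.lower()}{n}"]))[0]
        feats.append(
            FeatureAnnotation(
                id=fid, type=f.type,
                strand="-" if f.location.strand == -1 else "+",
                start=int(f.location.start) + 1, end=int(f.location.end),
                product=product,
                codon_start=int(q.get("codon_start", ["1"])[0]),
            )
        )
    return seq, feats


def read_genome_record(
    path, gff: Optional[str] = None
) -> tuple[str, list[FeatureAnnotation]]:
    """Read a genome plus annotations from GenBank or FASTA(+GFF3).

    A file starting with ``LOCUS`` is treated as a GenBank flat file;
    anything else as FASTA, with features from the optional ``gff``.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("LOCUS"):
        return _read_genbank(path)
    _, seq = read_fasta(path)
    feats = read_gff3(gff) if gff else []
    return seq, feats


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq_pairs(path1, path2) -> list[tuple[str, str, str]]:
    """Paired reads as (pair_id, seq1, seq2); ids must match mate-wise."""
    r1 = list(SeqIO.parse(path1, "fastq"))
    r2 = list(SeqIO.parse(path2, "fastq"))
    if len(r1) != len(r2):
        raise ValueError("FASTQ mate files differ in read count")
    pairs = []
    for a, b in zip(r1, r2):
        pid = a.id[:-2] if a.id.endswith("/1") else a.id
        pairs.append((pid, str(a.seq).upper(), str(b.seq).upper()))
    return pairs


# ---------------------------------------------------------------------------
# VCF

def _effect_info(report: Optional[EffectReport]) -> str:
    if report is None:
        return "."
    parts = []
    for e in report.effects:
        bits = [e.kind]
        if e.product:
            bits.append(e.product)
        if e.kind == "TRNA_ANTICODON":
            bits.append(f"{e.ref_identity}/{e.alt_identity}")
        elif e.kind == "CDS_SUBSTITUTION" and e.label:
            bits.append(e.label)
        elif e.kind == "CDS_FRAMESHIFT":
            bits.append(
                f"codons_{e.first_affected_codon}-{e.last_affected_codon}"
                f"_stop_{e.premature_stop_codon}"
            )
        parts.append("|".join(bits))
    return "&".join(parts) if parts else "."


def write_calls_vcf(
    calls: Sequence[HeteroplasmyCall],
    effects: dict[int, EffectReport],
    ref: str,
    path,
    ref_id: str = "monomer",
) -> None:
    """Write calls as VCF 4.2 with per-sample AF/DP and effects in INFO.

    Substitutions are written as-is; the 1-bp deletion uses the anchor-base
    convention (POS = site - 1, two-base REF, one-base ALT).
    """
    if list(calls) != sorted(calls, key=lambda c: c.position):
        raise ValueError("calls must be sorted by position")
    samples = sorted({s for c in calls for s in c.per_sample})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref_id},length={len(ref)}>\n")
        fh.write('##INFO=<ID=EFF,Number=1,Type=String,'
                 'Description="Functional effects">\n')
        fh.write('##FORMAT=<ID=AF,Number=1,Type=Float,'
                 'Description="Alternate allele frequency">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                  "INFO", "FORMAT"] + samples
        fh.write("\t".join(header) + "\n")
        for c in calls:
            if c.alt_allele == DELETION:
                if c.position < 2:
                    raise ValueError("cannot anchor a deletion at position 1")
                pos = c.position - 1
                anchor = ref[pos - 1]
                vref = anchor + c.ref_allele
                valt = anchor
            else:
                pos = c.position
                vref = c.ref_allele
                valt = c.alt_allele
            info = f"EFF={_effect_info(effects.get(c.position))}"
            row = [ref_id, str(pos), ".", vref, valt, ".", "PASS", info, "AF:DP"]
            for s in samples:
                freq, cov = c.per_sample.get(s, (0.0, 0))
                row.append(f"{freq:.4f}:{cov}")
            fh.write("\t".join(row) + "\n")


def write_effects_tsv(reports: Sequence[EffectReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tkind\tfeature\tproduct\tdetail\n")
        for r in reports:
            for e in r.effects:
                detail = ""
                if e.kind == "TRNA_ANTICODON":
                    detail = f"{e.ref_identity}/{e.alt_identity}"
                elif e.kind == "CDS_SUBSTITUTION":
                    detail = e.label or ""
                elif e.kind == "CDS_FRAMESHIFT":
                    detail = (f"first={e.first_affected_codon};"
                              f"stop={e.premature_stop_codon};"
                              f"last={e.last_affected_codon}")
                fh.write(f"{r.position}\t{e.kind}\t{e.feature_id or ''}\t"
                         f"{e.product or ''}\t{detail}\n")


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
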