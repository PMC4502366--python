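"""End-to-end pipeline: simulate/load -> map -> (assemble) -> call -> phase
-> annotate -> (compare), with a flat sectioned configuration.

The configuration is a YAML mapping of stage sections to key/value pairs;
unknown sections or keys raise immediately (silent typos in threshold names
are worse than errors).  Every stage writes its parameters to the run log,
and all outputs are deterministic functions of the configuration, seeds
included.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from . import assembly as asm
from . import cross_species as xsp
from .effects import EffectReport, FeatureAnnotation, annotate_site, \
    detect_terminal_palindromes
from .fileio import (
    ensure_dir,
    read_fastq_pairs,
    read_genome_record,
    write_calls_vcf,
    write_effects_tsv,
    write_fasta,
    write_gff3,
)
from .het_caller import HeteroplasmyCall, call_sites, calls_table, \
    flag_homopolymer, flag_terminal_coverage, merge_samples
from .mapping import build_index, compute_pileup, map_read
from .phasing import classify_linkage, phase_pair
from .synthetic import (
    HeteroplasmySpec,
    ReadSimParams,
    default_feature_template,
    generate_monomer,
    plant_heteroplasmies,
    simulate_reads,
)

_SCHEMA: dict[str, dict[str, Any]] = {
    "io": {"outdir": "out", "sample": "sample"},
    "simulate": {
        "enabled": True, "length": 14000, "palindrome_arm": 25, "loop": 4,
        "genome_seed": 1, "features": "default", "sites": [],
        "coverage": 300.0, "read_len": 100, "insert_mean": 750.0,
        "insert_sd": 75.0, "sub_error_rate": 0.0, "dimer_fraction": 0.5,
        "seed": 1,
    },
    "inputs": {"reference": None, "gff": None, "fastq1": None, "fastq2": None},
    "map": {"k": 21, "max_mismatch_frac": 0.1, "band": 3},
    "assemble": {"enabled": False, "k": 31, "min_count": 3, "iterations": 10,
                 "rel_prune": 0.05},
    "call": {"enabled": True, "min_cov": 100, "min_freq": 0.2,
             "homopolymer_min_run": 4, "homopolymer_window": 1,
             "terminal_min_depth": 300},
    "phase": {"enabled": True, "min_units": 20, "max_recomb_frac": 0.05,
              "max_distance": 1000},
    "annotate": {"enabled": True},
    "compare": {"enabled": False, "reference": None, "gff": None, "k": 15,
                "max_gap": 2000, "tolerance": 0},
}


@dataclass
class PipelineConfig:
    sections: dict[str, dict[str, Any]]

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls({s: dict(v) for s, v in _SCHEMA.items()})

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls.default()
        for section, values in data.items():
            if section not in _SCHEMA:
                raise ValueError(f"unknown config section {section!r}")
            if not isinstance(values, dict):
                raise ValueError(f"section {section!r} must be a mapping")
            for key, val in values.items():
                if key not in _SCHEMA[section]:
                    raise ValueError(
                        f"unknown key {key!r} in config section {section!r}"
                    )
                cfg.sections[section][key] = val
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def __getitem__(self, section: str) -> dict[str, Any]:
        return self.sections[section]


@dataclass
class ReportBundle:
    genome_seq: str
    features: list[FeatureAnnotation]
    calls: list[HeteroplasmyCall]
    effects: dict[int, EffectReport]
    phase_rows: list[dict]
    contig_length: Optional[int]
    compare_identity: Optional[float]
    outputs: dict[str, str] = field(default_factory=dict)


def _log(lines: list[str], stage: str, params: dict) -> None:
    for k in sorted(params):
        lines.append(f"{stage}.{k} = {params[k]!r}")


def _simulate_stage(cfg: PipelineConfig, outdir: str, log: list[str]):
    p = cfg["simulate"]
    template = default_feature_template() if p["features"] == "default" else []
    genome = generate_monomer(
        length=p["length"], palindrome_arm=p["palindrome_arm"], loop=p["loop"],
        feature_template=template, seed=p["genome_seed"],
    )
    specs = []
    for site in p["sites"]:
        specs.append(
            HeteroplasmySpec(
                position=site["position"],
                ref_allele=genome.monomer_seq[site["position"] - 1],
                alt_allele=site["alt"],
                alt_freq=site.get("alt_freq", 0.5),
                haplotype_class=site.get("haplotype_class", "UNLINKED"),
            )
        )
    genome = plant_heteroplasmies(genome, specs)
    sim = simulate_reads(
        genome,
        ReadSimParams(
            coverage=p["coverage"], read_len=p["read_len"],
            insert_mean=p["insert_mean"], insert_sd=p["insert_sd"],
            sub_error_rate=p["sub_error_rate"],
            dimer_fraction=p["dimer_fraction"], seed=p["seed"],
        ),
    )
    write_fasta(genome.monomer_seq, "monomer", os.path.join(outdir, "monomer.fasta"))
    write_gff3(genome.features, "monomer", len(genome.monomer_seq),
               os.path.join(outdir, "features.gff3"))
    sim.write_fastq(os.path.join(outdir, "reads_1.fastq"),
                    os.path.join(outdir, "reads_2.fastq"))
    sim.write_truth(os.path.join(outdir, "truth.tsv"))
    _log(log, "simulate", p)
    pairs = [(q.pair_id, q.seq1, q.seq2) for q in sim.pairs]
    return genome, pairs


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute the configured stages; any stage error halts with context."""
    io = cfg["io"]
    outdir = ensure_dir(io["outdir"])
    sample = io["sample"]
    log: list[str] = []
    outputs: dict[str, str] = {}

    stage = "simulate"
    try:
        if cfg["simulate"]["enabled"]:
            genome, pairs = _simulate_stage(cfg, outdir, log)
            ref, features = genome.monomer_seq, genome.features
        else:
            inp = cfg["inputs"]
            if not inp["reference"] or not inp["fastq1"] or not inp["fastq2"]:
                raise ValueError("simulate disabled but inputs are incomplete")
            ref, features = read_genome_record(inp["reference"], inp["gff"])
            pairs = read_fastq_pairs(inp["fastq1"], inp["fastq2"])
            _log(log, "inputs", inp)

        stage = "map"
        mp = cfg["map"]
        index = build_index(ref, mp["k"])
        alignments = []
        for pid, s1, s2 in pairs:
            a1 = map_read(s1, index, read_id=pid + "/1",
                          max_mismatch_frac=mp["max_mismatch_frac"], band=mp["band"])
            a2 = map_read(s2, index, read_id=pid + "/2",
                          max_mismatch_frac=mp["max_mismatch_frac"], band=mp["band"])
            a1.mate_id, a2.mate_id = a2.read_id, a1.read_id
            alignments.extend((a1, a2))
        _log(log, "map", mp)

        stage = "assemble"
        contig_length = None
        ap = cfg["assemble"]
        if ap["enabled"]:
            seed_contigs = asm.assemble(
                [s for _, s1, s2 in pairs for s in (s1, s2)],
                k=ap["k"], min_count=ap["min_count"], rel_prune=ap["rel_prune"],
            )
            seed = asm.select_seed_contig(seed_contigs, ref)
            final = asm.recruit_iterate(
                pairs, seed, iterations=ap["iterations"],
                map_params={"k": mp["k"],
                            "max_mismatch_frac": mp["max_mismatch_frac"],
                            "band": mp["band"]},
                asm_params={"k": ap["k"], "min_count": ap["min_count"],
                            "rel_prune": ap["rel_prune"]},
            )
            final = asm.orient_to_reference(final, ref)
            contig_length = final.length
            write_fasta(final.seq, "assembled_monomer",
                        os.path.join(outdir, "assembly.fasta"))
            outputs["assembly"] = os.path.join(outdir, "assembly.fasta")
            _log(log, "assemble", ap)
            log.append(f"assemble.final_contig_length = {final.length}")

        stage = "call"
        calls: list[HeteroplasmyCall] = []
        cp = cfg["call"]
        pileup = compute_pileup(alignments, ref)
        if cp["enabled"]:
            raw = call_sites(pileup, min_cov=cp["min_cov"],
                             min_freq=cp["min_freq"], sample=sample)
            calls = merge_samples({sample: raw}, {sample: pileup})
            calls = [
                flag_homopolymer(c, ref, min_run=cp["homopolymer_min_run"],
                                 window=cp["homopolymer_window"])
                for c in calls
            ]
            pal5, pal3 = detect_terminal_palindromes(ref)
            spans = [(h.start, h.end) for h in (pal5, pal3) if h is not None]
            calls = flag_terminal_coverage(calls, spans,
                                           min_depth=cp["terminal_min_depth"])
            table = calls_table(calls, [sample])
            table_path = os.path.join(outdir, "calls.tsv")
            table.to_csv(table_path, sep="\t", index=False)
            outputs["calls"] = table_path
            _log(log, "call", cp)

        stage = "phase"
        phase_rows: list[dict] = []
        pp = cfg["phase"]
        if pp["enabled"] and len(calls) >= 2:
            for a, b in zip(calls, calls[1:]):
                if b.position - a.position > pp["max_distance"]:
                    continue
                counts = phase_pair(alignments, a, b, use_pairs=True)
                phase_rows.append(
                    {
                        "site_a": a.position, "site_b": b.position,
                        "n_rr": counts.n_rr, "n_ra": counts.n_ra,
                        "n_ar": counts.n_ar, "n_aa": counts.n_aa,
                        "n_other": counts.n_other,
                        "classification": classify_linkage(
                            counts, min_units=pp["min_units"],
                            max_recomb_frac=pp["max_recomb_frac"],
                        ),
                    }
                )
            phase_path = os.path.join(outdir, "phase.tsv")
            with open(phase_path, "w") as fh:
                cols = ["site_a", "site_b", "n_rr", "n_ra", "n_ar", "n_aa",
                        "n_other", "classification"]
                fh.write("\t".join(cols) + "\n")
                for row in phase_rows:
                    fh.write("\t".join(str(row[c]) for c in cols) + "\n")
            outputs["phase"] = phase_path
            _log(log, "phase", pp)

        stage = "annotate"
        effects: dict[int, EffectReport] = {}
        if cfg["annotate"]["enabled"] and calls:
            feats = list(features)
            if not any(f.type == "palindrome" for f in feats):
                pal5, pal3 = detect_terminal_palindromes(ref)
                for i, hit in enumerate((pal5, pal3)):
                    if hit is not None:
                        feats.append(
                            FeatureAnnotation(f"palindrome{i}", "palindrome",
                                              "+", hit.start, hit.end)
                        )
            for c in calls:
                effects[c.position] = annotate_site(c, ref, feats)
            eff_path = os.path.join(outdir, "effects.tsv")
            write_effects_tsv([effects[c.position] for c in calls], eff_path)
            outputs["effects"] = eff_path
            vcf_path = os.path.join(outdir, "calls.vcf")
            write_calls_vcf(calls, effects, ref, vcf_path)
            outputs["vcf"] = vcf_path
            _log(log, "annotate", cfg["annotate"])

        stage = "compare"
        compare_identity = None
        xp = cfg["compare"]
        if xp["enabled"]:
            other_ref, _ = read_genome_record(xp["reference"], xp["gff"])
            aln = xsp.anchor_align(ref, other_ref, k=xp["k"], max_gap=xp["max_gap"])
            compare_identity, _ = xsp.percent_identity(aln, ref, other_ref)
            log.append(f"compare.percent_identity = {compare_identity:.2f}")
            _log(log, "compare", {k: v for k, v in xp.items() if k != "reference"})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log_path = os.path.join(outdir, "pipeline.log")
    with open(log_path, "w") as fh:
        fh.write("\n".join(log) + "\n")
    outputs["log"] = log_path
    return ReportBundle(
        genome_seq=ref, features=list(features), calls=calls, effects=effects,
        phase_rows=phase_rows, contig_length=contig_length,
        compare_identity=compare_identity, outputs=outputs,
    )
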