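"""Tests for the genome generator and the paired-end read simulator."""

import numpy as np
import pytest

from isomito._seq import DELETION, revcomp
from isomito.effects import translate_cds
from isomito.synthetic import (
    FeatureTemplate,
    HeteroplasmySpec,
    ReadSimParams,
    default_feature_template,
    generate_monomer,
    plant_heteroplasmies,
    simulate_reads,
)


def _alt(base):
    return "A" if base != "A" else "C"


class TestGenerateMonomer:
    @pytest.mark.parametrize("arm,loop", [(25, 4), (40, 0), (12, 8)])
    def test_terminal_palindromes(self, arm, loop):
        g = generate_monomer(3000, arm, loop, None, seed=1)
        s = g.monomer_seq
        assert s[0:arm] == revcomp(s[arm + loop : 2 * arm + loop])
        L = len(s)
        assert s[L - arm :] == revcomp(s[L - 2 * arm - loop : L - arm - loop])

    def test_degenerate_arm_is_plain_random_sequence(self):
        g = generate_monomer(500, 0, 0, None, seed=7)
        assert len(g.monomer_seq) == 500
        assert set(g.monomer_seq) <= set("ACGT")

    def test_same_seed_same_genome(self):
        a = generate_monomer(14000, 25, 4, default_feature_template(), seed=1)
        b = generate_monomer(14000, 25, 4, default_feature_template(), seed=1)
        assert a.monomer_seq == b.monomer_seq
        assert a.features == b.features

    def test_default_template_places_full_gene_complement(self):
        g = generate_monomer(14000, 25, 4, default_feature_template(), seed=1)
        by_type = {}
        for f in g.features:
            by_type.setdefault(f.type, []).append(f)
        assert len(by_type["CDS"]) == 13
        assert len(by_type["rRNA"]) == 2
        assert len(by_type["tRNA"]) == 22
        # every CDS translates stop-free over its full annotated length
        for f in by_type["CDS"]:
            prot = translate_cds(g.monomer_seq[f.start - 1 : f.end], f.strand)
            assert len(prot) == (f.end - f.start + 1) // 3 - 1

    def test_infeasible_packing_names_feature(self):
        template = [
            FeatureTemplate(id="huge", type="rRNA", length=880, spacer_before=60)
        ]
        with pytest.raises(ValueError, match="huge"):
            generate_monomer(1000, 25, 4, template, seed=1)


class TestPlantHeteroplasmies:
    def test_linked_class_on_one_haplotype(self, small_genome):
        s = small_genome.monomer_seq
        specs = [
            HeteroplasmySpec(p, s[p - 1], _alt(s[p - 1]), 0.5, "H2")
            for p in (1000, 1500, 2000)
        ]
        gm = plant_heteroplasmies(small_genome, specs)
        assert len(gm.haplotypes) == 2
        assert [h.weight for h in gm.haplotypes] == [0.5, 0.5]
        carrier = next(h for h in gm.haplotypes if h.carries)
        for sp in specs:
            assert carrier.seq[sp.position - 1] == sp.alt_allele
        ref_hap = next(h for h in gm.haplotypes if not h.carries)
        assert ref_hap.seq == s

    def test_deletion_haplotype_is_one_base_shorter(self, small_genome):
        s = small_genome.monomer_seq
        gm = plant_heteroplasmies(
            small_genome, [HeteroplasmySpec(1200, s[1199], DELETION, 0.4, "D")]
        )
        alt = next(h for h in gm.haplotypes if h.carries)
        assert len(alt.seq) == len(s) - 1
        assert alt.seq == s[:1199] + s[1200:]
        assert alt.monomer_to_hap(1200) is None
        assert alt.monomer_to_hap(1300) == 1298

    def test_empty_specs_identity(self, small_genome):
        gm = plant_heteroplasmies(small_genome, [])
        assert gm.haplotype_seqs == [(small_genome.monomer_seq, 1.0)]

    def test_duplicate_position_rejected(self, small_genome):
        s = small_genome.monomer_seq
        specs = [
            HeteroplasmySpec(900, s[899], _alt(s[899]), 0.5, "A"),
            HeteroplasmySpec(900, s[899], DELETION, 0.5, "B"),
        ]
        with pytest.raises(ValueError, match="same position"):
            plant_heteroplasmies(small_genome, specs)

    def test_two_classes_make_four_haplotypes(self, small_genome):
        s = small_genome.monomer_seq
        specs = [
            HeteroplasmySpec(800, s[799], _alt(s[799]), 0.5, "A"),
            HeteroplasmySpec(2500, s[2499], _alt(s[2499]), 0.3, "B"),
        ]
        gm = plant_heteroplasmies(small_genome, specs)
        assert len(gm.haplotypes) == 4
        assert sum(h.weight for h in gm.haplotypes) == pytest.approx(1.0)
        # linkage: each haplotype carries all sites of a class or none
        for h in gm.haplotypes:
            for sp in specs:
                carried = h.seq[h.monomer_to_hap(sp.position)] == sp.alt_allele
                assert carried == (sp.haplotype_class in h.carries)


class TestSimulateReads:
    def test_error_free_monomer_reads_are_haplotype_substrings(self, linked_sim):
        haps = [h.seq for h in linked_sim.genome.haplotypes]
        for pair in linked_sim.pairs[:300]:
            assert any(
                pair.seq1 in h or pair.seq1 in revcomp(h) for h in haps
            )
            assert any(
                pair.seq2 in h or pair.seq2 in revcomp(h) for h in haps
            )

    def test_total_bases_match_requested_coverage(self, linked_sim):
        total = sum(len(p.seq1) + len(p.seq2) for p in linked_sim.pairs)
        L = len(linked_sim.genome.monomer_seq)
        assert abs(total - 120 * L) / (120 * L) < 0.05

    def test_planted_alt_fraction_near_frequency(self, small_genome):
        s = small_genome.monomer_seq
        gm = plant_heteroplasmies(
            small_genome, [HeteroplasmySpec(2000, s[1999], _alt(s[1999]), 0.5, "H")]
        )
        sim = simulate_reads(
            gm, ReadSimParams(coverage=1000, read_len=100, insert_mean=400,
                              insert_sd=30, dimer_fraction=0.0, seed=1)
        )
        t = sim.site_read_truth(2000)
        assert len(t) > 500
        assert 0.45 <= t.carries_alt.mean() <= 0.55

    def test_dimer_junction_reads_cross_head_to_head(self, small_genome):
        sim = simulate_reads(
            small_genome,
            ReadSimParams(coverage=30, read_len=100, insert_mean=400,
                          insert_sd=30, dimer_fraction=1.0, seed=3),
        )
        mono = small_genome.monomer_seq
        L = len(mono)
        doubled = (mono + revcomp(mono)) * 2
        reads = {r for r, _ in zip(sim.reads(), range(10**9))}
        checked = 0
        by_id = dict(sim.reads())
        for t in sim.truth.itertuples():
            if t.strand != "+":
                continue
            start = t.ref_start0
            if start < L <= start + 100:  # spans the head-to-head junction
                assert by_id[t.read_id] == doubled[start : start + 100]
                checked += 1
        assert checked > 0

    def test_same_seed_byte_identical_fastq(self, linked_genome, tmp_path):
        params = ReadSimParams(coverage=20, read_len=100, insert_mean=400,
                               insert_sd=30, sub_error_rate=0.01,
                               dimer_fraction=0.5, seed=11)
        files = []
        for tag in ("a", "b"):
            sim = simulate_reads(linked_genome, params)
            p1, p2 = tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq"
            sim.write_fastq(p1, p2)
            files.append((p1.read_bytes(), p2.read_bytes()))
        assert files[0] == files[1]

    def test_frequency_calibration_over_replicates(self, small_genome):
        """Mean realised alt fraction within 2 binomial SE of the target."""
        s = small_genome.monomer_seq
        gm = plant_heteroplasmies(
            small_genome, [HeteroplasmySpec(2000, s[1999], _alt(s[1999]), 0.5, "H")]
        )
        fracs, total = [], 0
        for seed in range(20):
            sim = simulate_reads(
                gm, ReadSimParams(coverage=100, read_len=100, insert_mean=400,
                                  insert_sd=30, dimer_fraction=0.5, seed=seed)
            )
            t = sim.site_read_truth(2000)
            fracs.append(t.carries_alt.sum())
            total += len(t)
        mean = sum(fracs) / total
        se = np.sqrt(0.25 / total)
        assert abs(mean - 0.5) < 2 * se

    def test_unlinked_site_realised_per_molecule(self, small_genome):
        s = small_genome.monomer_seq
        gm = plant_heteroplasmies(
            small_genome,
            [HeteroplasmySpec(2000, s[1999], _alt(s[1999]), 0.3, "UNLINKED")],
        )
        assert len(gm.haplotypes) == 1  # unlinked sites stay off haplotypes
        sim = simulate_reads(
            gm, ReadSimParams(coverage=400, read_len=100, insert_mean=400,
                              insert_sd=30, dimer_fraction=0.0, seed=5)
        )
        alt = _alt(s[1999])
        n_alt = n_cov = 0
        for t in sim.truth.itertuples():
            if t.strand == "+" and t.ref_start0 <= 1999 < t.ref_start0 + 100:
                n_cov += 1
                rd = dict(sim.reads())[t.read_id]
                if rd[1999 - t.ref_start0] == alt:
                    n_alt += 1
        assert n_cov > 100
        assert abs(n_alt / n_cov - 0.3) < 3 * np.sqrt(0.21 / n_cov)

    def test_insert_longer_than_monomer_rejected(self, small_genome):
        with pytest.raises(ValueError, match="insert_mean"):
            simulate_reads(
                small_genome,
                ReadSimParams(coverage=5, read_len=100, insert_mean=5000,
                              insert_sd=1, seed=1),
            )
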