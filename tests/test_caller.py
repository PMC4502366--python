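"""Tests for the coverage/frequency heteroplasmy-calling rule."""

import numpy as np
import pytest

from isomito._seq import DELETION, random_seq
from isomito.het_caller import (
    HOMOPOLYMER,
    MULTIALLELIC,
    HeteroplasmyCall,
    call_sites,
    flag_homopolymer,
    merge_samples,
)
from isomito.mapping import PileupColumn, build_index, compute_pileup, map_reads
from isomito.synthetic import HeteroplasmySpec, ReadSimParams, \
    plant_heteroplasmies, simulate_reads


def _col(position, ref, **counts):
    base = {"A": 0, "C": 0, "G": 0, "T": 0, "DEL": 0}
    base.update(counts)
    return PileupColumn(position=position, ref_base=ref, counts=base)


class TestCallSites:
    @pytest.mark.parametrize(
        "ref_n,alt_n,called",
        [
            (818, 922, True),   # deep site, alt fraction 0.53
            (0, 99, False),     # full alt but below the 100x coverage gate
            (80, 20, False),    # frequency exactly 0.2 fails the strict rule
            (79, 21, True),     # one read above the threshold passes
        ],
    )
    def test_threshold_semantics(self, ref_n, alt_n, called):
        cols = [_col(9346, "G", G=ref_n, A=alt_n)]
        calls = call_sites(cols, min_cov=100, min_freq=0.2, sample="m")
        assert bool(calls) is called
        if called:
            c = calls[0]
            assert c.alt_allele == "A"
            assert c.alt_freq("m") == pytest.approx(alt_n / (ref_n + alt_n))
            assert c.coverage("m") == ref_n + alt_n

    def test_deletion_competes_as_allele(self):
        cols = [_col(11244, "A", A=1053, DEL=673)]
        (call,) = call_sites(cols, sample="m")
        assert call.alt_allele == DELETION
        assert call.alt_freq("m") == pytest.approx(0.39, abs=0.005)

    def test_multiallelic_flag(self):
        cols = [_col(5, "A", A=40, C=30, G=30)]
        (call,) = call_sites(cols, sample="m")
        assert MULTIALLELIC in call.flags
        cols = [_col(5, "A", A=60, C=30, G=10)]
        (call,) = call_sites(cols, sample="m")
        assert MULTIALLELIC not in call.flags

    def test_duplicate_positions_rejected(self):
        cols = [_col(5, "A", A=200), _col(5, "A", A=200)]
        with pytest.raises(ValueError, match="duplicate"):
            call_sites(cols)

    def test_deterministic(self):
        cols = [_col(i, "A", A=150, C=60) for i in range(1, 30)]
        assert call_sites(cols) == call_sites(cols)


class TestMergeSamples:
    def test_uncalled_sample_still_reported(self):
        """A site present in one individual shows its 0/NNN in the other."""
        male = [_col(10074, "G", G=1737)]
        female = [_col(10074, "G", G=348, A=309)]
        calls_m = call_sites(male, sample="M")
        calls_f = call_sites(female, sample="F")
        merged = merge_samples(
            {"M": calls_m, "F": calls_f}, {"M": male, "F": female}
        )
        (row,) = merged
        assert row.per_sample["M"] == (0.0, 1737)
        assert row.per_sample["F"][0] == pytest.approx(0.47, abs=0.005)
        assert row.per_sample["F"][1] == 657

    def test_low_frequency_deletion_retained(self):
        male = [_col(11244, "A", A=1053, DEL=673)]
        female = [_col(11244, "A", A=726, DEL=30)]
        merged = merge_samples(
            {"M": call_sites(male, sample="M"),
             "F": call_sites(female, sample="F")},
            {"M": male, "F": female},
        )
        (row,) = merged
        assert row.alt_allele == DELETION
        assert row.per_sample["M"][0] == pytest.approx(0.39, abs=0.005)
        assert row.per_sample["F"][0] == pytest.approx(0.04, abs=0.005)

    def test_no_calls_empty_table(self):
        cols = [_col(1, "A", A=500)]
        assert merge_samples({"M": call_sites(cols, sample="M")},
                             {"M": cols}) == []

    def test_reference_length_mismatch_rejected(self):
        a = [_col(1, "A", A=500)]
        b = [_col(1, "A", A=500), _col(2, "C", C=500)]
        with pytest.raises(ValueError, match="different references"):
            merge_samples({"M": [], "F": []}, {"M": a, "F": b})


class TestHomopolymerFlag:
    def _call(self, pos, ref_base, alt="A"):
        if alt == ref_base:
            alt = "C"
        return HeteroplasmyCall(pos, ref_base, alt, {"s": (0.3, 500)})

    def test_run_boundary_is_flagged(self):
        ref = "GCGCAATTTTTTTTGCGC"  # A2 then T8, boundary at position 7
        call = self._call(7, ref[6], alt="A")
        assert HOMOPOLYMER in flag_homopolymer(call, ref).flags

    def test_alternating_sequence_not_flagged(self):
        ref = "ACGTACGTACGTACGT"
        call = self._call(8, ref[7])
        assert HOMOPOLYMER not in flag_homopolymer(call, ref).flags

    def test_min_run_two_flags_dinucleotide_boundary(self):
        ref = "GCAATTGC"
        call = self._call(5, ref[4])
        assert HOMOPOLYMER in flag_homopolymer(call, ref, min_run=2).flags

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(23)
        ref = random_seq(300, rng)
        min_run, window = 4, 1

        def oracle(pos0):
            for i in range(len(ref)):
                j = i
                while j < len(ref) and ref[j] == ref[i]:
                    j += 1
                if j - i >= min_run and (
                    abs(i - pos0) <= window or abs(j - 1 - pos0) <= window
                ):
                    return True
                i = j
            return False

        for pos in range(1, 301):
            call = self._call(pos, ref[pos - 1])
            got = HOMOPOLYMER in flag_homopolymer(call, ref, min_run, window).flags
            assert got == oracle(pos - 1), f"position {pos}"


class TestEndToEndCalling:
    def test_planted_sites_called_no_false_positives(self, linked_sim):
        """Error-free reads: every planted site called, nothing else."""
        genome = linked_sim.genome
        ref = genome.monomer_seq
        recs = map_reads(linked_sim.reads(), build_index(ref, 21))
        pileup = compute_pileup(recs, ref)
        calls = call_sites(pileup, min_cov=50, min_freq=0.2)
        assert {c.position for c in calls} == {1600, 2000}
        for c in calls:
            assert 0.4 < c.alt_freq("sample") < 0.6

    def test_estimated_frequency_unbiased(self, small_genome):
        """Mean estimate over 20 replicates within 2 binomial SE of truth."""
        s = small_genome.monomer_seq
        alt = "A" if s[1999] != "A" else "C"
        gm = plant_heteroplasmies(
            small_genome, [HeteroplasmySpec(2000, s[1999], alt, 0.5, "H")]
        )
        idx = build_index(s, 21)
        freqs, total_cov = [], 0
        for seed in range(20):
            sim = simulate_reads(
                gm, ReadSimParams(coverage=120, read_len=100, insert_mean=400,
                                  insert_sd=30, sub_error_rate=0.005,
                                  dimer_fraction=0.5, seed=seed)
            )
            recs = map_reads(sim.reads(), idx)
            pileup = compute_pileup(recs, s)
            col = pileup[1999]
            freqs.append(col.counts[alt] / col.depth)
            total_cov += col.depth
        se = np.sqrt(0.25 / total_cov)
        assert abs(np.mean(freqs) - 0.5) < 2 * se + 0.005  # error adds ~e/3 bias
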