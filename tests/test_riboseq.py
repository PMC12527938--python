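"""Codon-resolution occupancy analysis: unit, oracle and property tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonflux import riboseq, synthetic
from codonflux.types import SENSE_CODONS, STOP_CODONS, TranscriptCDS, transcriptome_index
from conftest import (
    brute_force_codon_occupancy,
    brute_force_pausing_sums,
    brute_force_third_base_fraction,
)


def _reads(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "five_prime_pos", "length"])


class TestFilterReads:
    def test_length_window(self):
        reads = _reads([("t", 0, l) for l in (27, 28, 29, 30)])
        kept, hist = riboseq.filter_reads(reads)
        assert sorted(kept["length"]) == [28, 29]
        assert hist.to_dict() == {27: 1, 28: 1, 29: 1, 30: 1}

    def test_empty_input(self):
        kept, hist = riboseq.filter_reads(_reads([]))
        assert len(kept) == 0 and len(hist) == 0

    def test_single_length(self):
        reads = _reads([("t", 0, l) for l in (28, 28, 29)])
        kept, _ = riboseq.filter_reads(reads, 28, 28)
        assert set(kept["length"]) == {28}


class TestPsiteOffsets:
    def test_recovers_true_offset_from_simulation(self, sim_transcriptome, sim_config):
        transcripts, _ = sim_transcriptome
        txome = transcriptome_index(transcripts)
        reads = synthetic.gen_footprints(transcripts, sim_config, "control", seed=2)
        offsets = riboseq.estimate_psite_offsets(reads, txome)
        assert offsets == {28: 12, 29: 12}

    def test_recovers_two_different_offsets(self):
        cfg = synthetic.SimConfig(
            n_genes=80,
            read_depth=300_000,
            psite_offset={28: 12, 29: 13},
            stall_multipliers={"control": {}},
            seed=31,
        )
        transcripts, _ = synthetic.gen_transcriptome(cfg)
        txome = transcriptome_index(transcripts)
        reads = synthetic.gen_footprints(transcripts, cfg, "control", seed=32)
        offsets = riboseq.estimate_psite_offsets(reads, txome)
        assert offsets == {28: 12, 29: 13}

    def test_fallback_to_default_when_sparse(self, small_transcriptome, caplog):
        reads = _reads([("t1", 0, 28)] * 10)
        with caplog.at_level("WARNING"):
            offsets = riboseq.estimate_psite_offsets(reads, small_transcriptome)
        assert offsets == {28: 12}
        assert "falling back" in caplog.text


class TestPsiteDepth:
    def test_single_read_single_increment(self, small_transcriptome):
        reads = _reads([("t1", 0, 28)])
        depths, dropped = riboseq.psite_depth(reads, {28: 12}, small_transcriptome)
        assert dropped == 0
        assert depths["t1"][12] == 1 and depths["t1"].sum() == 1

    def test_a_site_is_p_site_shifted(self, small_transcriptome):
        reads = _reads([("t1", i, 28) for i in range(3)])
        p, _ = riboseq.psite_depth(reads, {28: 12}, small_transcriptome, site="P")
        a, _ = riboseq.psite_depth(reads, {28: 12}, small_transcriptome, site="A")
        assert np.array_equal(a["t1"][3:], p["t1"][:-3])

    def test_out_of_cds_positions_dropped(self, small_transcriptome):
        # t1 CDS is 18 nt; P-site at 5'+12 beyond the CDS must be dropped
        reads = _reads([("t1", 10, 28)])
        depths, dropped = riboseq.psite_depth(reads, {28: 12}, small_transcriptome)
        assert dropped == 1 and depths["t1"].sum() == 0

    def test_matches_generator_intended_counts(self):
        cfg = synthetic.SimConfig(
            n_genes=4,
            cds_length_range=(60, 60),
            read_depth=5_000,
            stall_multipliers={"control": {}},
            seed=41,
        )
        transcripts, _ = synthetic.gen_transcriptome(cfg)
        txome = transcriptome_index(transcripts)
        reads = synthetic.gen_footprints(transcripts, cfg, "control", seed=42)
        depths, dropped = riboseq.psite_depth(reads, cfg.psite_offset, txome)
        assert dropped == 0
        assert sum(int(d.sum()) for d in depths.values()) == len(reads)
        # recompute intended P-site codon of every read independently
        for tid, d in depths.items():
            sub = reads[reads["transcript_id"] == tid]
            intended = np.zeros_like(d)
            for row in sub.itertuples():
                pos = row.five_prime_pos + cfg.psite_offset[row.length] - txome[tid].cds_start
                intended[pos] += 1
            assert np.array_equal(d, intended)


class TestPPKM:
    def test_formula_arithmetic(self):
        # one 1000-nt transcript holding all 10^6 P-sites -> PPKM 10^6
        d = {"t": np.zeros(1000, dtype=int)}
        d["t"][5] = 10**6
        assert riboseq.ppkm(d)["t"] == pytest.approx(1e6)

    def test_zero_count_transcript(self):
        d = {"a": np.zeros(300, dtype=int), "b": np.ones(300, dtype=int)}
        assert riboseq.ppkm(d)["a"] == 0

    def test_scale_invariance(self):
        d = {"a": np.arange(30), "b": np.ones(60, dtype=int)}
        d2 = {k: v * 2 for k, v in d.items()}
        pd.testing.assert_series_equal(riboseq.ppkm(d), riboseq.ppkm(d2))

    def test_zero_sample_total_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            riboseq.ppkm({"a": np.zeros(30, dtype=int)})


class TestFilterExpressed:
    def test_requires_all_samples_above_threshold(self):
        ppkm_df = pd.DataFrame({"s1": [1.2, 2.0], "s2": [0.9, 3.0]}, index=["t1", "t2"])
        assert riboseq.filter_expressed(ppkm_df) == ["t2"]

    def test_threshold_zero_keeps_positive(self):
        ppkm_df = pd.DataFrame({"s1": [0.1, 2.0]}, index=["t1", "t2"])
        assert riboseq.filter_expressed(ppkm_df, threshold=0) == ["t1", "t2"]


class TestNormalize:
    def test_uniform_depth_gives_ones(self):
        norm = riboseq.normalize_profiles({"t": np.full(12, 7.0)})
        assert np.allclose(norm["t"], 1.0)

    def test_mean_one_and_sum_equals_length(self):
        norm = riboseq.normalize_profiles({"t": np.array([0, 0, 3.0])})
        assert np.allclose(norm["t"], [0, 0, 3.0])
        assert norm["t"].mean() == pytest.approx(1.0, abs=1e-12)
        assert norm["t"].sum() == pytest.approx(3.0)

    def test_zero_depth_skipped(self):
        norm = riboseq.normalize_profiles({"t": np.zeros(6)})
        assert "t" not in norm

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=60)
        .map(lambda l: l + [1])  # ensure nonzero total
    )
    @settings(max_examples=50, deadline=None)
    def test_mean_is_always_one(self, depths):
        arr = np.array(depths, dtype=float)
        norm = riboseq.normalize_profiles({"t": arr})
        assert norm["t"].mean() == pytest.approx(1.0, abs=1e-12)


class TestPolyproTracts:
    def test_single_tract(self, tiny_cds):
        tracts = riboseq.find_polypro_tracts({"t1": tiny_cds})
        assert tracts["t1"] == [(1, 4)]

    def test_run_of_two_is_no_tract(self):
        tx = TranscriptCDS("t", "g", "ATGCCACCGAAATAA")
        assert riboseq.find_polypro_tracts({"t": tx})["t"] == []

    def test_two_separated_runs(self):
        # ATG CCA CCC CCG AAA CCT CCA CCG TAA
        tx = TranscriptCDS("t", "g", "ATGCCACCCCCGAAACCTCCACCGTAA")
        assert riboseq.find_polypro_tracts({"t": tx})["t"] == [(1, 4), (5, 8)]

    def test_tract_at_cds_end_is_flushed(self):
        tx = TranscriptCDS("t", "g", "ATGCCACCACCATAA")
        assert riboseq.find_polypro_tracts({"t": tx})["t"] == [(1, 4)]


class TestCodonOccupancyAndRDO:
    def _norm(self, txome, seed=0):
        rng = np.random.default_rng(seed)
        return riboseq.normalize_profiles(
            {tid: rng.poisson(5, len(tx.sequence)).astype(float)
             for tid, tx in txome.items()}
        )

    def test_matches_brute_force_oracle(self, small_transcriptome):
        norm = self._norm(small_transcriptome, seed=3)
        occ = riboseq.codon_occupancy([norm], small_transcriptome)
        oracle = brute_force_codon_occupancy(norm, small_transcriptome)
        for codon, val in oracle.items():
            assert occ.loc[codon, "occupancy"] == pytest.approx(val, abs=1e-12)

    def test_census_conservation(self, small_transcriptome):
        norm = self._norm(small_transcriptome, seed=4)
        occ = riboseq.codon_occupancy([norm], small_transcriptome)
        total = sum(tx.n_codons for tx in small_transcriptome.values())
        assert occ["n_instances"].sum() == total

    def test_identical_conditions_rdo_zero(self, small_transcriptome):
        norm = self._norm(small_transcriptome, seed=5)
        occ = riboseq.codon_occupancy([norm], small_transcriptome)
        r = riboseq.rdo(occ, occ)
        assert np.allclose(r.values, 0.0)

    def test_rdo_antisymmetry(self, small_transcriptome):
        a = riboseq.codon_occupancy([self._norm(small_transcriptome, 6)], small_transcriptome)
        b = riboseq.codon_occupancy([self._norm(small_transcriptome, 7)], small_transcriptome)
        r_ab = riboseq.rdo(a, b)
        r_ba = riboseq.rdo(b, a)
        assert np.allclose(r_ab.values, -r_ba.values, equal_nan=True)

    def test_zero_occupancy_reported_as_nan(self, small_transcriptome):
        norm = self._norm(small_transcriptome, seed=8)
        occ_a = riboseq.codon_occupancy([norm], small_transcriptome)
        occ_b = occ_a.copy()
        occ_b.loc["AAA", "occupancy"] = 0.0
        r = riboseq.rdo(occ_a, occ_b)
        assert np.isnan(r["AAA"]) and np.isfinite(r.drop("AAA")).all()

    def test_exclude_polypro_changes_only_proline_instances(self, small_transcriptome):
        norm = self._norm(small_transcriptome, seed=9)
        full = riboseq.codon_occupancy([norm], small_transcriptome)
        excl = riboseq.codon_occupancy(
            [norm], small_transcriptome, exclude_polypro=True
        )
        # t1 has a CCA CCG CCC tract; those types lose instances
        assert excl["n_instances"].get("CCA", 0) < full["n_instances"]["CCA"]
        # non-proline codons unchanged
        assert excl.loc["AAA", "occupancy"] == pytest.approx(full.loc["AAA", "occupancy"])


class TestMetagene:
    def test_uniform_profiles_flat(self, small_transcriptome):
        norm = {tid: np.ones(len(tx.sequence)) for tid, tx in small_transcriptome.items()}
        mg = riboseq.metagene_codon(norm, small_transcriptome, "AAA", window=6)
        vals = mg["mean"].dropna()
        assert np.allclose(vals, 1.0)

    def test_window_zero_equals_occupancy_numerator(self, small_transcriptome):
        rng = np.random.default_rng(12)
        norm = riboseq.normalize_profiles(
            {tid: rng.poisson(4, len(tx.sequence)).astype(float)
             for tid, tx in small_transcriptome.items()}
        )
        mg = riboseq.metagene_codon(norm, small_transcriptome, "CCA", window=0)
        # window 0 covers exactly the anchor codon: its mean equals the
        # per-codon-type occupancy (the RDO numerator)
        occ = riboseq.codon_occupancy([norm], small_transcriptome)
        assert mg["mean"].mean() == pytest.approx(occ.loc["CCA", "occupancy"])

    def test_absent_codon_flagged_empty(self, small_transcriptome, caplog):
        norm = {tid: np.ones(len(tx.sequence)) for tid, tx in small_transcriptome.items()}
        with caplog.at_level("WARNING"):
            mg = riboseq.metagene_codon(norm, small_transcriptome, "TGG", window=3)
        assert mg["n_instances"].sum() == 0
        assert mg["mean"].isna().all()

    def test_edge_positions_use_fewer_instances(self, small_transcriptome):
        norm = {tid: np.ones(len(tx.sequence)) for tid, tx in small_transcriptome.items()}
        mg = riboseq.metagene_codon(norm, small_transcriptome, "ATG", window=6)
        # ATG is at CDS position 0 in all transcripts: nothing upstream
        assert mg.loc[-1, "n_instances"] == 0
        assert mg.loc[0, "n_instances"] == len(small_transcriptome)

    def test_start_stop_flat_on_uniform(self, small_transcriptome):
        norm = {tid: np.ones(len(tx.sequence)) for tid, tx in small_transcriptome.items()}
        start, stop = riboseq.metagene_start_stop(norm, small_transcriptome, window=6)
        assert np.allclose(start["mean"].dropna(), 1.0)
        assert np.allclose(stop["mean"].dropna(), 1.0)


class TestPausing:
    def test_equal_profiles_give_zero(self):
        a = np.array([0.5, 1.0, 2.0])
        assert np.allclose(riboseq.pausing_track(a, a), 0.0)

    def test_pseudocount_formula(self):
        track = riboseq.pausing_track(np.array([1.0, 0.0]), np.array([0.0, 0.0]))
        assert track[0] == pytest.approx(1.0)  # log2(2/1)
        assert track[1] == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            riboseq.pausing_track(np.ones(3), np.ones(6))

    def test_bucket_sums_match_brute_force(self, tiny_cds):
        rng = np.random.default_rng(21)
        track = rng.normal(size=len(tiny_cds.sequence))
        sums = riboseq.pausing_sum_by_base(track, tiny_cds)
        oracle = brute_force_pausing_sums(track, tiny_cds.sequence)
        for b in "ACGT":
            assert sums[b] == pytest.approx(oracle[b], abs=1e-12)

    def test_bucket_conservation(self, tiny_cds):
        rng = np.random.default_rng(22)
        track = rng.normal(size=len(tiny_cds.sequence))
        sums = riboseq.pausing_sum_by_base(track, tiny_cds)
        assert sum(sums.values()) == pytest.approx(track.sum(), abs=1e-9)

    def test_only_matching_bucket_nonzero(self, tiny_cds):
        # nonzero only at the AAA codon (ends A), positions 12-14
        track = np.zeros(len(tiny_cds.sequence))
        track[12:15] = 1.0
        sums = riboseq.pausing_sum_by_base(track, tiny_cds)
        assert sums["A"] == pytest.approx(3.0)
        assert sums["C"] == sums["G"] == sums["T"] == 0.0


class TestThirdBaseFraction:
    def test_direct_count(self):
        tx = TranscriptCDS("t", "g", "ATGAAATAA")
        f = riboseq.third_base_fraction(tx)
        assert f["A"] == pytest.approx(2 / 3)
        assert f["G"] == pytest.approx(1 / 3)

    def test_homopolymer_a_ending(self):
        tx = TranscriptCDS("t", "g", "ATGAAAAAATAA")
        f = riboseq.third_base_fraction(tx, include_start_stop=False)
        assert f["A"] == 1.0

    def test_matches_brute_force_and_sums_to_one(self, small_transcriptome):
        for tx in small_transcriptome.values():
            f = riboseq.third_base_fraction(tx)
            oracle = brute_force_third_base_fraction(tx.sequence)
            assert f == oracle
            assert sum(f.values()) == pytest.approx(1.0)

    @given(st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=80))
    @settings(max_examples=50, deadline=None)
    def test_fractions_sum_to_one_property(self, codons):
        seq = "ATG" + "".join(codons) + "TAA"
        tx = TranscriptCDS("t", "g", seq)
        f = riboseq.third_base_fraction(tx)
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-12)
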