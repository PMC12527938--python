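"""Shared fixtures: tiny hand-built transcriptomes and simulation configs."""

import numpy as np
import pytest

from codonflux import synthetic
from codonflux.types import TranscriptCDS, transcriptome_index


@pytest.fixture
def tiny_cds():
    """One hand-written CDS: ATG, 4 internal codons, polypro run, stop."""
    # codons: ATG CCA CCG CCC AAA TAA
    return TranscriptCDS(
        transcript_id="t1", gene_id="g1", sequence="ATGCCACCGCCCAAATAA"
    )


@pytest.fixture
def small_transcriptome():
    """Three short transcripts with known codon content."""
    txs = [
        TranscriptCDS("t1", "g1", "ATGCCACCGCCCAAATAA", gene_sets=("setA",)),
        TranscriptCDS("t2", "g2", "ATGAAAGGGTTTCCCTGA", gene_sets=("setA",)),
        TranscriptCDS("t3", "g3", "ATGGCAGCAGCATAG", gene_sets=("setB",)),
    ]
    return transcriptome_index(txs)


@pytest.fixture(scope="session")
def sim_config():
    return synthetic.SimConfig(
        n_genes=60,
        cds_length_range=(150, 300),
        read_depth=200_000,
        stall_multipliers={"control": {}, "treated": {"NNA": 1.5}},
        seed=42,
    )


@pytest.fixture(scope="session")
def sim_transcriptome(sim_config):
    transcripts, gene_sets = synthetic.gen_transcriptome(sim_config)
    return transcripts, gene_sets


def brute_force_third_base_fraction(sequence, include_start_stop=True):
    """Independent loop oracle for wobble-base fractions."""
    codons = [sequence[i : i + 3] for i in range(0, len(sequence), 3)]
    if not include_start_stop:
        codons = codons[1:-1]
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for c in codons:
        counts[c[2]] += 1
    return {b: counts[b] / len(codons) for b in counts}


def brute_force_codon_occupancy(norm_profiles, transcriptome):
    """Per-codon-type mean normalized occupancy by explicit loops."""
    acc = {}
    for tid, vals in norm_profiles.items():
        seq = transcriptome[tid].sequence
        for j in range(len(seq) // 3):
            codon = seq[3 * j : 3 * j + 3]
            inst = (vals[3 * j] + vals[3 * j + 1] + vals[3 * j + 2]) / 3.0
            acc.setdefault(codon, []).append(inst)
    return {c: float(np.mean(v)) for c, v in acc.items()}


def brute_force_pausing_sums(track, sequence):
    """Wobble-base pausing-sum buckets by explicit per-codon loops."""
    out = {"A": 0.0, "C": 0.0, "G": 0.0, "T": 0.0}
    for j in range(len(sequence) // 3):
        codon = sequence[3 * j : 3 * j + 3]
        out[codon[2]] += track[3 * j] + track[3 * j + 1] + track[3 * j + 2]
    return out
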