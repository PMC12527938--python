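"""End-to-end recovery workflows on simulated data.

Convenience drivers that wire the synthetic generators through the full
analysis layer and report recovery statistics against the generative
ground truth.  Problem sizes default to the scales used for validation:
a few hundred genes and ~10^6 P-sites per condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from codonflux import flux, riboseq, synthetic
from codonflux.types import STOP_CODONS, transcriptome_index


def _occupancy_for(transcripts, config, condition, seed):
    txome = transcriptome_index(transcripts)
    reads = synthetic.gen_footprints(transcripts, config, condition, seed=seed)
    reads, _ = riboseq.filter_reads(reads)
    offsets = riboseq.estimate_psite_offsets(reads, txome)
    depths, _ = riboseq.psite_depth(reads, offsets, txome)
    expressed = riboseq.filter_expressed(
        riboseq.ppkm_table({condition: depths})
    )
    norm = riboseq.normalize_profiles({t: depths[t] for t in expressed})
    return txome, norm


def rdo_recovery(
    seed: int,
    n_genes: int = 150,
    read_depth: int = 1_000_000,
    nna_multiplier: float = 1.5,
) -> dict:
    """Recover an injected wobble-A stall from simulated footprints.

    Simulates control and treated samples where every A-ending codon
    dwells ``nna_multiplier`` times longer in the treated condition,
    computes the per-codon RDO, and compares it with the closed-form
    expectation from the generative weights.

    Returns per-codon results plus summary statistics: the measured and
    expected mean RDO over sense A-ending codons, the absolute gap, and
    the fraction of (A-ending, G-ending) codon pairs ranked correctly
    (1.0 = every sense A-ending codon above every sense G-ending one).
    """
    cfg = synthetic.SimConfig(
        n_genes=n_genes,
        read_depth=read_depth,
        stall_multipliers={"control": {}, "treated": {"NNA": nna_multiplier}},
        seed=seed,
    )
    transcripts, _ = synthetic.gen_transcriptome(cfg)
    occ = {}
    for i, cond in enumerate(["control", "treated"]):
        txome, norm = _occupancy_for(transcripts, cfg, cond, seed=seed + 1 + i)
        occ[cond] = riboseq.codon_occupancy([norm], txome)
    measured = riboseq.rdo(occ["treated"], occ["control"])
    expected = np.log2(
        synthetic.expected_codon_occupancy(transcripts, cfg, "treated")[
            "expected_occupancy"
        ]
        / synthetic.expected_codon_occupancy(transcripts, cfg, "control")[
            "expected_occupancy"
        ]
    )
    sense_a = [c for c in measured.index if c[2] == "A" and c not in STOP_CODONS]
    sense_g = [c for c in measured.index if c[2] == "G" and c not in STOP_CODONS]
    pairs = [(a, g) for a in sense_a for g in sense_g]
    correct = sum(measured[a] > measured[g] for a, g in pairs)
    return {
        "rdo": measured,
        "expected_rdo": expected,
        "mean_rdo_nna": float(measured[sense_a].mean()),
        "expected_mean_rdo_nna": float(expected[sense_a].mean()),
        "abs_gap_nna": float(abs(measured[sense_a].mean() - expected[sense_a].mean())),
        "rank_fraction_a_over_g": correct / len(pairs),
        "n_sense_a": len(sense_a),
        "n_sense_g": len(sense_g),
        "read_depth": read_depth,
    }


def stop_stall_metagene(
    seed: int,
    n_genes: int = 80,
    read_depth: int = 400_000,
    stop_multiplier: float = 3.0,
    window: int = 30,
) -> dict:
    """Stop-codon stalling and its stop-anchored metagene signature.

    Simulates a condition where the stop codon dwells
    ``stop_multiplier`` times longer, and reports the mean normalized
    occupancy over the stop codon's three positions against the
    analytic expectation from the renormalized generative weights, plus
    the upstream baseline.
    """
    cfg = synthetic.SimConfig(
        n_genes=n_genes,
        read_depth=read_depth,
        stall_multipliers={"stalled": {"STOP": stop_multiplier}},
        seed=seed,
    )
    transcripts, _ = synthetic.gen_transcriptome(cfg)
    txome, norm = _occupancy_for(transcripts, cfg, "stalled", seed=seed + 1)
    _, stop_mg = riboseq.metagene_start_stop(norm, txome, window=window)
    peak = float(stop_mg.loc[0:2, "mean"].mean())
    baseline = float(stop_mg.loc[-window:-6, "mean"].mean())
    expected = synthetic.expected_codon_occupancy(transcripts, cfg, "stalled")
    stop_rows = [c for c in expected.index if c in STOP_CODONS]
    expected_peak = float(
        np.average(
            expected.loc[stop_rows, "expected_occupancy"],
            weights=expected.loc[stop_rows, "n_instances"],
        )
    )
    return {
        "stop_peak": peak,
        "baseline": baseline,
        "peak_over_baseline": peak / baseline,
        "expected_stop_peak": expected_peak,
    }


def polypro_metagene_response(
    seed: int,
    n_genes: int = 80,
    read_depth: int = 400_000,
    cca_multiplier: float = 2.5,
    window: int = 30,
) -> dict:
    """Codon-specific proline stalling at polyproline tracts.

    Simulates a stalled condition (CCA dwell multiplied) and an
    unstalled control on a proline-rich transcriptome, and reports
    (a) the mean normalized occupancy over polyproline-tract codons
    and (b) the anchor-codon metagene occupancy for CCA and CCG, in
    both conditions.  Only the stalled condition should elevate the
    tract occupancy, and only at CCA, not CCG.
    """
    results = {}
    for label, mults in [("stalled", {"CCA": cca_multiplier}), ("control", {})]:
        cfg = synthetic.SimConfig(
            n_genes=n_genes,
            read_depth=read_depth,
            # extra proline content so tracts exist
            codon_bias={
                "pro_rich": {"A": 0.3, "C": 0.4, "G": 0.15, "T": 0.15},
            },
            stall_multipliers={label: mults},
            seed=seed,
        )
        transcripts, _ = synthetic.gen_transcriptome(cfg)
        txome, norm = _occupancy_for(transcripts, cfg, label, seed=seed + 1)
        for codon in ("CCA", "CCG"):
            mg = riboseq.metagene_codon(norm, txome, codon, window=window)
            results[f"{codon}_{label}"] = float(mg.loc[0:2, "mean"].mean())
        tracts = riboseq.find_polypro_tracts(txome)
        vals = [
            norm[tid][3 * a : 3 * b]
            for tid, runs in tracts.items()
            if tid in norm
            for a, b in runs
        ]
        results[f"tract_occupancy_{label}"] = float(
            np.mean(np.concatenate(vals))
        )
    return results


def labeling_recovery(seed: int, noise_sd: float = 0.01, n_boot: int = 100) -> dict:
    """Deconvolution recovery of known direct-contribution fractions.

    Noiseless data must reproduce the truth to machine precision; at
    the given noise level the bootstrap estimates stay within a small
    bias and same-seed runs give identical standard errors.
    """
    truth = synthetic.LabelingSimTruth(
        metabolites=["proline", "arginine", "glutamine"],
        M_true=np.array(
            [[1.0, 0.2, 0.1], [0.3, 1.0, 0.05], [0.1, 0.15, 1.0]]
        ),
        f_true=np.array([0.25, 0.35, 0.2]),
    )
    M0, L0 = synthetic.gen_labeling(truth, seed=seed)
    exact = flux.direct_contributions(M0.values, L0.values)

    noisy = synthetic.LabelingSimTruth(
        metabolites=truth.metabolites,
        M_true=truth.M_true,
        f_true=truth.f_true,
        noise_sd=noise_sd,
    )
    Mn, Ln = synthetic.gen_labeling(noisy, seed=seed + 1)
    model = flux.SourceContributionModel(Mn.values, Ln.values)
    r1 = model.fit(M_sd=noise_sd, L_sd=noise_sd, n_boot=n_boot, seed=seed + 2)
    r2 = model.fit(M_sd=noise_sd, L_sd=noise_sd, n_boot=n_boot, seed=seed + 2)
    return {
        "f_true": truth.f_true,
        "f_noiseless": exact.params.values,
        "max_abs_error_noiseless": float(
            np.max(np.abs(exact.params.values - truth.f_true))
        ),
        "f_noisy": r1.params.values,
        "max_abs_bias_noisy": float(np.max(np.abs(r1.params.values - truth.f_true))),
        "bootstrap_se": r1.bse,
        "se_reproducible": bool(np.array_equal(r1.bse, r2.bse)),
    }
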