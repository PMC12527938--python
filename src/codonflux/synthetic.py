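"""Synthetic-data generators with known ground truth.

Every downstream stage of the package has a parameter-recovery test
against data produced here: transcriptomes with controllable third-base
codon bias between gene sets, ribosome footprints sampled under a
codon-type dwell model with condition-specific stall multipliers,
steady-state labeling vectors generated from a known interconversion
matrix, and serum MIDs generated by inverting the turnover-flux formula.

The dwell model is multiplicative and renormalized per gene: condition
effects scale per-codon dwell weights, and a gene's total footprint mass
stays proportional to its expression times its codon count, matching the
CDS-mean-normalized read-out used by the analysis layer.  Footprint
counts are multinomial across (gene, codon) cells, i.e. Poisson-like at
large depth.  A fixed seed makes every generator byte-reproducible.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from codonflux.types import (
    BASES,
    SENSE_CODONS,
    STOP_CODONS,
    TranscriptCDS,
)

# Sense codons grouped by third base, for biased codon sampling.
_SENSE_BY_THIRD = {b: [c for c in SENSE_CODONS if c[2] == b] for b in BASES}


@dataclass
class SimConfig:
    """Parameters of the footprint simulation.

    ``codon_bias`` maps a gene-set label to per-third-base sampling
    weights; ``stall_multipliers`` maps a condition label to
    ``{pattern: multiplier}`` where a pattern is an exact codon
    ("CCA"), a wildcard over the first two bases ("NNA"), or the
    special classes "START" (the initiator codon) and "STOP".
    ``psite_offset`` gives the 5'-end-to-P-site offset per footprint
    length.  UTR lengths place the CDS inside a longer transcript so
    that footprints over the first codons have non-negative transcript
    coordinates.
    """

    n_genes: int = 200
    cds_length_range: tuple[int, int] = (150, 600)  # nt, multiples of 3
    codon_bias: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "cell_cycle_like": {"A": 0.40, "C": 0.20, "G": 0.20, "T": 0.20},
            "neuronal_like": {"A": 0.10, "C": 0.30, "G": 0.35, "T": 0.25},
        }
    )
    expression_law: tuple[float, float] = (0.0, 1.0)  # log-normal mu, sigma
    stall_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"control": {}, "treated": {}}
    )
    start_multiplier: float = 3.0  # initiation-peak dwell, all conditions
    read_depth: int = 1_000_000
    footprint_lengths: dict[int, float] = field(
        default_factory=lambda: {28: 0.5, 29: 0.5}
    )
    psite_offset: dict[int, int] = field(default_factory=lambda: {28: 12, 29: 12})
    utr5: int = 18
    utr3: int = 18
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.cds_length_range
        if lo % 3 or hi % 3 or lo < 9 or hi < lo:
            raise ValueError(
                "cds_length_range must be multiples of 3 with 9 <= lo <= hi"
            )
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for cond, mults in self.stall_multipliers.items():
            for pat, m in mults.items():
                if m <= 0:
                    raise ValueError(f"multiplier {pat}={m} in {cond} must be > 0")
        if self.start_multiplier <= 0:
            raise ValueError("start_multiplier must be > 0")
        for label, weights in self.codon_bias.items():
            w = np.array([weights.get(b, 0.0) for b in BASES], dtype=float)
            if w.sum() <= 0 or np.any(w < 0):
                raise ValueError(f"invalid third-base weights for set {label}")
        if not self.footprint_lengths:
            raise ValueError("at least one footprint length required")
        for length in self.footprint_lengths:
            if length not in self.psite_offset:
                raise ValueError(f"no P-site offset configured for length {length}")
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")


def gen_transcriptome(
    config: SimConfig,
) -> tuple[list[TranscriptCDS], pd.DataFrame]:
    """Generate a biased transcriptome and its gene-set table.

    Each CDS starts with ATG, ends with a uniformly chosen stop codon,
    and draws its internal codons by first sampling the third base from
    the gene set's weights and then a uniform sense codon with that
    third base.  Genes are assigned round-robin to the configured gene
    sets.  Returns the transcript list and a (pathway, gene_id) table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    set_labels = sorted(config.codon_bias)
    lo, hi = config.cds_length_range
    n_codon_choices = np.arange(lo // 3, hi // 3 + 1)
    stops = sorted(STOP_CODONS)

    transcripts: list[TranscriptCDS] = []
    rows = []
    for g in range(config.n_genes):
        label = set_labels[g % len(set_labels)]
        weights = config.codon_bias[label]
        p3 = np.array([weights.get(b, 0.0) for b in BASES], dtype=float)
        p3 = p3 / p3.sum()
        n_codons = int(rng.choice(n_codon_choices))
        thirds = rng.choice(len(BASES), size=n_codons - 2, p=p3)
        internal = [
            _SENSE_BY_THIRD[BASES[t]][rng.integers(len(_SENSE_BY_THIRD[BASES[t]]))]
            for t in thirds
        ]
        seq = "ATG" + "".join(internal) + stops[rng.integers(3)]
        gene_id = f"gene{g:05d}"
        transcripts.append(
            TranscriptCDS(
                transcript_id=f"tx{g:05d}",
                gene_id=gene_id,
                sequence=seq,
                gene_sets=(label,),
                cds_start=config.utr5,
                utr3=config.utr3,
            )
        )
        rows.append({"pathway": label, "gene_id": gene_id})
    return transcripts, pd.DataFrame(rows)


def _pattern_matches(pattern: str, codon: str, codon_index: int, n_codons: int) -> bool:
    if pattern == "START":
        return codon_index == 0
    if pattern == "STOP":
        return codon in STOP_CODONS
    return fnmatch.fnmatchcase(codon, pattern.replace("N", "?"))


def dwell_weights(
    tx: TranscriptCDS, config: SimConfig, condition: str
) -> np.ndarray:
    """Per-codon dwell weights for one transcript under a condition.

    The base weight is 1; all matching stall multipliers for the
    condition apply multiplicatively, as does the initiation-peak
    multiplier on the start codon.
    """
    mults = config.stall_multipliers.get(condition)
    if mults is None:
        raise KeyError(f"unknown condition {condition!r}")
    codons = tx.codons
    n = len(codons)
    w = np.ones(n, dtype=float)
    w[0] *= config.start_multiplier
    for pat, m in mults.items():
        for j, codon in enumerate(codons):
            if _pattern_matches(pat, codon, j, n):
                w[j] *= m
    return w


def gen_footprints(
    transcripts: list[TranscriptCDS],
    config: SimConfig,
    condition: str,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample a footprint read table for one sample of one condition.

    P-sites land on codon j of gene g with probability proportional to
    ``expr_g * n_codons_g * w_gj / sum_j w_gj`` (per-gene renormalized
    dwell weights).  Each P-site draws a footprint length from the
    configured mixture; 5'-end position = cds_start + 3j - offset(len).
    Reads that would extend outside the transcript are dropped.

    Returns a DataFrame with columns transcript_id, five_prime_pos,
    length (0-based transcript coordinates).
    """
    if not transcripts:
        raise ValueError("transcriptome is empty")
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mu, sigma = config.expression_law
    expr = rng.lognormal(mu, sigma, size=len(transcripts))

    # Flatten (gene, codon) cells into one categorical distribution.
    cell_probs = []
    cell_tx: list[int] = []
    cell_codon: list[np.ndarray] = []
    for i, tx in enumerate(transcripts):
        w = dwell_weights(tx, config, condition)
        p = expr[i] * tx.n_codons * (w / w.sum())
        cell_probs.append(p)
        cell_tx.append(i)
        cell_codon.append(np.arange(tx.n_codons))
    probs = np.concatenate(cell_probs)
    probs /= probs.sum()
    tx_of_cell = np.concatenate(
        [np.full(len(cp), i) for i, cp in zip(cell_tx, cell_probs)]
    )
    codon_of_cell = np.concatenate(cell_codon)

    if config.read_depth == 0:
        return pd.DataFrame(columns=["transcript_id", "five_prime_pos", "length"])

    counts = rng.multinomial(config.read_depth, probs)
    lengths = sorted(config.footprint_lengths)
    lweights = np.array([config.footprint_lengths[l] for l in lengths], dtype=float)
    lweights /= lweights.sum()

    out_tx: list[str] = []
    out_pos: list[int] = []
    out_len: list[int] = []
    nz = np.nonzero(counts)[0]
    for cell in nz:
        k = counts[cell]
        tx = transcripts[tx_of_cell[cell]]
        j = codon_of_cell[cell]
        lc = rng.multinomial(k, lweights)
        for length, c in zip(lengths, lc):
            if c == 0:
                continue
            pos = tx.cds_start + 3 * int(j) - config.psite_offset[length]
            if pos < 0 or pos + length > tx.transcript_length:
                continue  # footprint would fall off the transcript
            out_tx.extend([tx.transcript_id] * int(c))
            out_pos.extend([pos] * int(c))
            out_len.extend([length] * int(c))
    return pd.DataFrame(
        {"transcript_id": out_tx, "five_prime_pos": out_pos, "length": out_len}
    )


def expected_codon_occupancy(
    transcripts: list[TranscriptCDS],
    config: SimConfig,
    condition: str,
) -> pd.DataFrame:
    """Analytic expectation of CDS-mean-normalized occupancy per codon type.

    Under the generative dwell model the expected normalized depth of
    codon j in gene g is ``w_gj / mean_j(w_gj)``, independent of
    expression and depth.  The table averages that over every instance
    of each codon type, mirroring how the analysis layer aggregates.
    Used as the closed-form oracle in recovery tests.
    """
    sums: dict[str, float] = {}
    ns: dict[str, int] = {}
    for tx in transcripts:
        w = dwell_weights(tx, config, condition)
        norm = w / w.mean()
        for j, codon in enumerate(tx.codons):
            sums[codon] = sums.get(codon, 0.0) + norm[j]
            ns[codon] = ns.get(codon, 0) + 1
    rows = [
        {"codon": c, "expected_occupancy": sums[c] / ns[c], "n_instances": ns[c]}
        for c in sorted(sums)
    ]
    return pd.DataFrame(rows).set_index("codon")


@dataclass
class LabelingSimTruth:
    """Ground truth for the labeling deconvolution simulation.

    ``M_true`` is the circulating interconversion matrix (rows/cols in
    ``metabolites`` order, diagonal exactly 1, entries in [0, 1]);
    ``f_true`` the non-negative direct-contribution fractions of a
    tissue metabolite; ``F_true`` the true turnover flux per metabolite
    (nmol min^-1 g^-1).
    """

    metabolites: list[str]
    M_true: np.ndarray
    f_true: np.ndarray
    noise_sd: float = 0.0
    F_true: np.ndarray | None = None

    def validate(self) -> None:
        M = np.asarray(self.M_true, dtype=float)
        f = np.asarray(self.f_true, dtype=float)
        n = len(self.metabolites)
        if M.shape != (n, n):
            raise ValueError("M_true must be n x n")
        if not np.allclose(np.diag(M), 1.0):
            raise ValueError("M_true diagonal must be exactly 1")
        if np.any(M < 0) or np.any(M > 1):
            raise ValueError("M_true entries must lie in [0, 1]")
        if f.shape != (n,) or np.any(f < 0):
            raise ValueError("f_true must be length n and non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_labeling(
    truth: LabelingSimTruth, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate noisy serum interconversion measurements and tissue labeling.

    Tissue labeling is ``L = M_true . f_true`` plus Gaussian noise
    (sd = noise_sd), clipped to [0, 1].  Serum measurements are
    ``M_true`` plus the same noise on off-diagonal entries (the
    tracer's self-labeling is identically 1 by definition), clipped to
    [0, 1].
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    n = len(truth.metabolites)
    M = np.asarray(truth.M_true, dtype=float)
    f = np.asarray(truth.f_true, dtype=float)

    L = M @ f
    if truth.noise_sd > 0:
        L = L + rng.normal(0.0, truth.noise_sd, size=n)
        M = M + rng.normal(0.0, truth.noise_sd, size=(n, n))
        np.fill_diagonal(M, 1.0)
    L = np.clip(L, 0.0, 1.0)
    M = np.clip(M, 0.0, 1.0)
    M_df = pd.DataFrame(M, index=truth.metabolites, columns=truth.metabolites)
    return M_df, pd.Series(L, index=truth.metabolites, name="labeling")


def gen_serum_mid(
    F_true: float,
    R: float,
    C: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    metabolite: str = "tracer",
):
    """Serum MID of an infused tracer implied by a true turnover flux.

    Inverts the turnover relation: the fully labeled fraction is
    ``L[M+C] = R / (R + F_true)`` plus optional Gaussian noise, with the
    remainder assigned to M+0.  The result always sums to 1.
    """
    from codonflux.types import MIDVector

    if F_true < 0:
        raise ValueError("F_true must be >= 0")
    if R <= 0:
        raise ValueError("infusion rate R must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lc = R / (R + F_true)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        lc = float(np.clip(lc + rng.normal(0.0, noise_sd), 1e-12, 1.0))
    fractions = [0.0] * (C + 1)
    fractions[-1] = lc
    fractions[0] = 1.0 - lc
    return MIDVector(metabolite=metabolite, fractions=tuple(fractions))
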