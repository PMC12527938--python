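"""Codon-resolution ribosome-occupancy analysis.

Pipeline, from transcript-space footprints to codon statistics:

1. length-filter reads (28/29 nt ribosome-protected fragments);
2. estimate the 5'-end-to-P-site offset per read length from the
   start-codon metagene;
3. accumulate P-site (or A/E-site) depth per CDS nucleotide;
4. express transcripts as PPKM (P-sites per kilobase of CDS per million
   mapped P-sites) and keep those with PPKM above threshold in every
   sample;
5. normalize each retained profile to its CDS mean;
6. derive codon metagenes, per-codon mean occupancies, the relative
   dwelling occupancy (RDO) log2 ratio between conditions, per-position
   pausing tracks with a +1 pseudocount, and per-gene pausing sums
   bucketed by each codon's third (wobble) base.

Profiles are plain ``dict[str, numpy.ndarray]`` keyed by transcript id,
with one value per CDS nucleotide in 0-based CDS coordinates.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from codonflux.types import (
    BASES,
    PROLINE_CODONS,
    STOP_CODONS,
    TranscriptCDS,
)

logger = logging.getLogger(__name__)

Profiles = dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# read filtering and P-site assignment
# ---------------------------------------------------------------------------

def filter_reads(
    reads: pd.DataFrame, min_len: int = 28, max_len: int = 29
) -> tuple[pd.DataFrame, pd.Series]:
    """Retain reads whose length is within [min_len, max_len].

    Returns the filtered table and the full length histogram (computed
    before filtering, for QC).
    """
    if min_len < 1 or max_len < min_len:
        raise ValueError("need 1 <= min_len <= max_len")
    hist = reads["length"].value_counts().sort_index() if len(reads) else pd.Series(
        dtype=int
    )
    kept = reads[(reads["length"] >= min_len) & (reads["length"] <= max_len)]
    return kept.reset_index(drop=True), hist


def estimate_psite_offsets(
    reads: pd.DataFrame,
    transcriptome: dict[str, TranscriptCDS],
    search: tuple[int, int] = (9, 15),
    default: int = 12,
    min_reads: int = 1000,
) -> dict[int, int]:
    """Estimate the 5'-end-to-P-site offset per read length.

    For each length class the offset is the value in ``search`` that
    maximizes the number of reads whose implied P-site falls on the
    annotated start codon (the initiation peak), ties broken toward
    ``default``.  Length classes with fewer than ``min_reads`` reads
    whose 5' ends lie within ``search[1]`` nt of a start codon fall back
    to ``default`` with a warning.
    """
    lo, hi = search
    offsets: dict[int, int] = {}
    for length, sub in reads.groupby("length"):
        rel = np.array(
            [
                row.five_prime_pos - transcriptome[row.transcript_id].cds_start
                for row in sub.itertuples()
                if row.transcript_id in transcriptome
            ]
        )
        near_start = rel[(rel >= -hi) & (rel < 3)]
        if near_start.size < min_reads:
            logger.warning(
                "length %d: only %d start-proximal reads (<%d); "
                "falling back to default offset %d",
                length,
                near_start.size,
                min_reads,
                default,
            )
            offsets[int(length)] = default
            continue
        scores = {
            o: int(np.sum((near_start + o >= 0) & (near_start + o < 3)))
            for o in range(lo, hi + 1)
        }
        best = max(scores.values())
        candidates = [o for o, s in scores.items() if s == best]
        offsets[int(length)] = min(candidates, key=lambda o: (abs(o - default), o))
    return offsets


def psite_depth(
    reads: pd.DataFrame,
    offsets: dict[int, int],
    transcriptome: dict[str, TranscriptCDS],
    site: str = "P",
) -> tuple[Profiles, int]:
    """Per-CDS-nucleotide ribosome-site depth profiles.

    The P-site nucleotide is ``five_prime_pos + offset(length)`` in
    transcript coordinates; the A site sits +3 nt and the E site -3 nt
    from it.  Positions outside the CDS are dropped and counted.
    Returns (profiles, n_dropped).
    """
    shift = {"E": -3, "P": 0, "A": 3}
    if site not in shift:
        raise ValueError(f"site must be one of E/P/A, got {site!r}")
    profiles: Profiles = {
        tid: np.zeros(len(tx.sequence), dtype=np.int64)
        for tid, tx in transcriptome.items()
    }
    if len(reads) == 0:
        return profiles, 0
    unknown_lengths = set(reads["length"].unique()) - set(offsets)
    if unknown_lengths:
        raise KeyError(
            f"no P-site offset for read length(s) {sorted(unknown_lengths)}"
        )
    dropped = 0
    offset_of = reads["length"].map(offsets).to_numpy()
    pos = reads["five_prime_pos"].to_numpy() + offset_of + shift[site]
    tids = reads["transcript_id"].to_numpy()
    order = np.argsort(tids, kind="stable")
    tids_sorted = tids[order]
    pos_sorted = pos[order]
    boundaries = np.flatnonzero(
        np.r_[True, tids_sorted[1:] != tids_sorted[:-1], True]
    )
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        tid = tids_sorted[a]
        tx = transcriptome.get(tid)
        if tx is None:
            dropped += b - a
            continue
        p = pos_sorted[a:b] - tx.cds_start
        ok = (p >= 0) & (p < len(tx.sequence))
        dropped += int((~ok).sum())
        np.add.at(profiles[tid], p[ok], 1)
    return profiles, dropped


# ---------------------------------------------------------------------------
# expression filtering and normalization
# ---------------------------------------------------------------------------

def ppkm(depths: Profiles) -> pd.Series:
    """P-sites per kilobase of CDS per million mapped P-sites."""
    total = sum(int(d.sum()) for d in depths.values())
    if total == 0:
        raise ValueError("zero total P-site count in sample")
    vals = {
        tid: d.sum() / (len(d) / 1e3) / (total / 1e6) for tid, d in depths.items()
    }
    return pd.Series(vals, name="ppkm")


def ppkm_table(samples: dict[str, Profiles]) -> pd.DataFrame:
    """PPKM matrix, transcripts x samples."""
    return pd.DataFrame({name: ppkm(depths) for name, depths in samples.items()})


def filter_expressed(ppkm_df: pd.DataFrame, threshold: float = 1.0) -> list[str]:
    """Transcripts with PPKM strictly above threshold in every sample."""
    mask = (ppkm_df > threshold).all(axis=1)
    return list(ppkm_df.index[mask])


def normalize_profiles(depths: Profiles) -> Profiles:
    """Divide each profile by its CDS mean depth; zero-depth CDS skipped.

    For every returned profile, mean(values) == 1 exactly (up to float
    rounding).
    """
    out: Profiles = {}
    for tid, d in depths.items():
        m = d.mean()
        if m == 0:
            logger.info("transcript %s has zero depth; skipped", tid)
            continue
        out[tid] = d / m
    return out


def mean_profiles(per_sample: Sequence[Profiles]) -> Profiles:
    """Equal-weight mean across replicate samples, per transcript.

    Only transcripts present in every sample's profile set are retained.
    """
    if not per_sample:
        raise ValueError("no samples given")
    common = set(per_sample[0])
    for p in per_sample[1:]:
        common &= set(p)
    return {
        tid: np.mean([p[tid] for p in per_sample], axis=0) for tid in common
    }


# ---------------------------------------------------------------------------
# codon occupancy and RDO
# ---------------------------------------------------------------------------

def find_polypro_tracts(
    transcriptome: dict[str, TranscriptCDS], min_run: int = 3
) -> dict[str, list[tuple[int, int]]]:
    """Maximal runs of >= min_run consecutive proline codons per transcript.

    Intervals are 0-based half-open codon indices.
    """
    tracts: dict[str, list[tuple[int, int]]] = {}
    for tid, tx in transcriptome.items():
        runs = []
        start = None
        codons = tx.codons
        for j, codon in enumerate(codons + ["XXX"]):  # sentinel flushes last run
            if codon in PROLINE_CODONS:
                if start is None:
                    start = j
            else:
                if start is not None and j - start >= min_run:
                    runs.append((start, j))
                start = None
        tracts[tid] = runs
    return tracts


def _instance_mask(
    tx: TranscriptCDS, exclude: list[tuple[int, int]] | None
) -> np.ndarray:
    mask = np.ones(tx.n_codons, dtype=bool)
    if exclude:
        for a, b in exclude:
            mask[a:b] = False
    return mask


def codon_occupancy(
    per_sample_norm: Sequence[Profiles],
    transcriptome: dict[str, TranscriptCDS],
    exclude_polypro: bool = False,
    min_run: int = 3,
) -> pd.DataFrame:
    """Mean normalized occupancy per codon type.

    For each sample, every instance of a codon contributes the mean of
    its three per-nucleotide normalized depths; the per-codon-type mean
    over all instances is taken per sample, then samples are averaged
    with equal weight.  With ``exclude_polypro`` the instances inside
    polyproline tracts are left out (used to separate tract stalling
    from single-codon effects).

    Returns a DataFrame indexed by codon with columns ``occupancy`` and
    ``n_instances`` (instances counted once, not per sample).
    """
    tracts = (
        find_polypro_tracts(transcriptome, min_run) if exclude_polypro else None
    )
    per_sample_tables = []
    counts: dict[str, int] = {}
    for s_idx, norm in enumerate(per_sample_norm):
        sums: dict[str, float] = {}
        ns: dict[str, int] = {}
        for tid, vals in norm.items():
            tx = transcriptome[tid]
            mask = _instance_mask(tx, tracts.get(tid) if tracts else None)
            codon_means = vals.reshape(-1, 3).mean(axis=1)
            for j, codon in enumerate(tx.codons):
                if not mask[j]:
                    continue
                sums[codon] = sums.get(codon, 0.0) + codon_means[j]
                ns[codon] = ns.get(codon, 0) + 1
        table = pd.Series({c: sums[c] / ns[c] for c in sums}, name=f"s{s_idx}")
        per_sample_tables.append(table)
        if s_idx == 0:
            counts = ns
    occ = pd.concat(per_sample_tables, axis=1).mean(axis=1)
    out = pd.DataFrame({"occupancy": occ})
    out["n_instances"] = pd.Series(counts)
    return out.sort_index()


def rdo(occupancy_a: pd.DataFrame, occupancy_b: pd.DataFrame) -> pd.Series:
    """Relative dwelling occupancy: log2 ratio of mean codon occupancies.

    Codons with zero mean occupancy in either condition are reported as
    NaN (flagged undefined), never as +/- infinity.
    """
    a = occupancy_a["occupancy"]
    b = occupancy_b["occupancy"]
    common = a.index.intersection(b.index)
    a, b = a[common], b[common]
    vals = np.full(len(common), np.nan)
    ok = (a.values > 0) & (b.values > 0)
    vals[ok] = np.log2(a.values[ok] / b.values[ok])
    n_undef = int((~ok).sum())
    if n_undef:
        logger.warning("RDO undefined for %d codon types (zero occupancy)", n_undef)
    return pd.Series(vals, index=common, name="rdo")


# ---------------------------------------------------------------------------
# metagenes
# ---------------------------------------------------------------------------

def metagene_codon(
    norm_profiles: Profiles,
    transcriptome: dict[str, TranscriptCDS],
    codons: str | Iterable[str],
    window: int = 90,
) -> pd.DataFrame:
    """Mean normalized depth around every instance of a codon (set).

    The result is indexed by nucleotide offset -window..+window+2
    relative to each instance's first nucleotide (the +2 keeps the
    anchor codon's three nucleotides inside every window, so window=0
    reduces to the anchor codon itself); positions outside a CDS are
    excluded from that instance's average.  Columns: ``mean`` and
    ``n_instances`` (per-position contributing instance counts).
    """
    if isinstance(codons, str):
        codons = {codons}
    codons = set(codons)
    width = 2 * window + 3
    total = np.zeros(width)
    count = np.zeros(width, dtype=np.int64)
    for tid, vals in norm_profiles.items():
        tx = transcriptome[tid]
        L = len(vals)
        for j, codon in enumerate(tx.codons):
            if codon not in codons:
                continue
            anchor = 3 * j
            lo = max(0, anchor - window)
            hi = min(L, anchor + window + 3)
            sl = slice(lo - anchor + window, hi - anchor + window)
            total[sl] += vals[lo:hi]
            count[sl] += 1
    if count.sum() == 0:
        logger.warning("codon(s) %s absent from transcriptome", sorted(codons))
    mean = np.divide(total, count, out=np.full(width, np.nan), where=count > 0)
    return pd.DataFrame(
        {"mean": mean, "n_instances": count},
        index=pd.RangeIndex(-window, window + 3, name="offset"),
    )


def metagene_start_stop(
    norm_profiles: Profiles,
    transcriptome: dict[str, TranscriptCDS],
    window: int = 90,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean occupancy anchored at the start codon and at the stop codon.

    Anchors are the first nucleotide of the start codon and of the
    terminal stop codon.  CDS-edge-aware averaging as in
    :func:`metagene_codon`.
    """
    width = 2 * window + 3
    out = []
    for which in ("start", "stop"):
        total = np.zeros(width)
        count = np.zeros(width, dtype=np.int64)
        for tid, vals in norm_profiles.items():
            tx = transcriptome[tid]
            L = len(vals)
            anchor = 0 if which == "start" else L - 3
            lo = max(0, anchor - window)
            hi = min(L, anchor + window + 3)
            sl = slice(lo - anchor + window, hi - anchor + window)
            total[sl] += vals[lo:hi]
            count[sl] += 1
        mean = np.divide(total, count, out=np.full(width, np.nan), where=count > 0)
        out.append(
            pd.DataFrame(
                {"mean": mean, "n_instances": count},
                index=pd.RangeIndex(-window, window + 3, name="offset"),
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# pausing tracks and sums
# ---------------------------------------------------------------------------

def pausing_track(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    """Per-position relative pausing: log2((a+1)/(b+1)) of normalized depths.

    Inputs are the (sample-mean) CDS-normalized depth vectors of the
    same transcript in two conditions; the +1 pseudocount keeps every
    value finite.
    """
    a = np.asarray(norm_a, dtype=float)
    b = np.asarray(norm_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    return np.log2((a + 1.0) / (b + 1.0))


def pausing_sum_by_base(track: np.ndarray, cds: TranscriptCDS) -> dict[str, float]:
    """Pausing sums bucketed by each codon's third (wobble) base.

    Each codon's pausing value is the sum of the track over its three
    nucleotides; values are accumulated into the bucket of the codon's
    ending base.  The four bucket sums add up exactly to the whole-CDS
    pausing sum.
    """
    track = np.asarray(track, dtype=float)
    if len(track) != len(cds.sequence):
        raise ValueError("track not aligned to CDS")
    per_codon = track.reshape(-1, 3).sum(axis=1)
    out = {b: 0.0 for b in BASES}
    for j, codon in enumerate(cds.codons):
        out[codon[2]] += per_codon[j]
    return out


# ---------------------------------------------------------------------------
# codon composition
# ---------------------------------------------------------------------------

def third_base_fraction(
    cds: TranscriptCDS, include_start_stop: bool = True
) -> dict[str, float]:
    """Fraction of codons with each base at the third (wobble) position.

    By default every codon of the annotated CDS counts, including the
    start codon and the terminal stop; ``include_start_stop=False``
    drops those two.  Fractions sum to 1.
    """
    codons = cds.codons
    if not include_start_stop:
        codons = codons[1:-1]
    if not codons:
        raise ValueError(f"{cds.transcript_id}: no codons to count")
    n = len(codons)
    out = {b: 0 for b in BASES}
    for codon in codons:
        out[codon[2]] += 1
    return {b: out[b] / n for b in BASES}


def gene_third_base_fractions(
    transcriptome: dict[str, TranscriptCDS], include_start_stop: bool = True
) -> pd.DataFrame:
    """Per-gene third-base fraction table (genes x bases A/C/G/T)."""
    rows = {
        tx.gene_id: third_base_fraction(tx, include_start_stop)
        for tx in transcriptome.values()
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(BASES)]
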