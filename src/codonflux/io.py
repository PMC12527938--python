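"""Readers, writers, and the run manifest.

Internal coordinates are 0-based half-open; SAM's 1-based convention is
converted at this boundary only.  Transcript-space alignments may be
supplied either as a plain TSV read table (transcript_id,
five_prime_pos, length; 0-based) or as SAM/BAM against the canonical
transcriptome.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from codonflux.types import BASES, TranscriptCDS

logger = logging.getLogger(__name__)


def read_fasta(
    path,
    gene_table: pd.DataFrame | None = None,
    cds_start: int = 0,
    utr3: int = 0,
) -> list[TranscriptCDS]:
    """Read CDS sequences from FASTA into TranscriptCDS records.

    Sequences are upper-cased; records with non-ACGT characters or a
    length not divisible by 3 are skipped with a warning (counts
    logged).  ``gene_table`` (columns transcript_id, gene_id, optional
    pathway) attaches gene ids and gene-set labels; without it the
    record id doubles as the gene id.
    """
    gene_of = {}
    sets_of: dict[str, tuple[str, ...]] = {}
    if gene_table is not None:
        gene_of = dict(zip(gene_table["transcript_id"], gene_table["gene_id"]))
        if "pathway" in gene_table.columns:
            grouped = gene_table.groupby("transcript_id")["pathway"].agg(
                lambda s: tuple(sorted(set(s)))
            )
            sets_of = grouped.to_dict()
    out: list[TranscriptCDS] = []
    n_bad = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad_chars = set(seq) - set(BASES)
        if bad_chars:
            logger.warning(
                "%s: %d non-ACGT characters; record skipped",
                rec.id,
                sum(seq.count(c) for c in bad_chars),
            )
            n_bad += 1
            continue
        if len(seq) % 3 != 0:
            logger.warning("%s: length %d not divisible by 3; skipped", rec.id, len(seq))
            n_bad += 1
            continue
        out.append(
            TranscriptCDS(
                transcript_id=rec.id,
                gene_id=gene_of.get(rec.id, rec.id),
                sequence=seq,
                gene_sets=sets_of.get(rec.id, ()),
                cds_start=cds_start,
                utr3=utr3,
            )
        )
    if n_bad:
        logger.warning("skipped %d invalid FASTA records", n_bad)
    return out


def write_fasta(transcripts, path) -> None:
    """Write CDS sequences to FASTA (deterministic record order)."""
    records = [
        SeqRecord(Seq(tx.sequence), id=tx.transcript_id, description=tx.gene_id)
        for tx in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_read_table(path) -> pd.DataFrame:
    """Read a TSV footprint table (transcript_id, five_prime_pos, length)."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "five_prime_pos", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    return df


def write_read_table(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_sam_reads(path, known_transcripts=None) -> tuple[pd.DataFrame, int]:
    """Read transcript-space SAM/BAM alignments into a footprint table.

    SAM's 1-based POS is converted to a 0-based 5' position.
    Reverse-strand and unmapped records are rejected (transcript space
    is stranded); records on unknown transcripts are dropped and
    counted.  Returns (table, n_dropped).
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    rows = []
    dropped = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_reverse:
                dropped += 1
                continue
            if known_transcripts is not None and aln.reference_name not in known_transcripts:
                dropped += 1
                continue
            rows.append(
                {
                    "transcript_id": aln.reference_name,
                    "five_prime_pos": aln.reference_start,  # pysam is 0-based
                    "length": aln.query_length or aln.infer_query_length(),
                }
            )
    return pd.DataFrame(rows, columns=["transcript_id", "five_prime_pos", "length"]), dropped


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (pathway, description, genes...) or
    two-column TSV (pathway, gene_id)."""
    path = Path(path)
    text = path.read_text().strip().splitlines()
    if not text:
        return {}
    sets: dict[str, list[str]] = {}
    if path.suffix.lower() == ".gmt":
        for line in text:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
        return sets
    df = pd.read_csv(path, sep="\t")
    if {"pathway", "gene_id"} <= set(df.columns):
        for pw, sub in df.groupby("pathway"):
            sets[pw] = list(sub["gene_id"])
        return sets
    # headerless two-column fallback
    df = pd.read_csv(path, sep="\t", header=None, names=["pathway", "gene_id"])
    for pw, sub in df.groupby("pathway"):
        sets[str(pw)] = list(sub["gene_id"])
    return sets


def read_mids_csv(path) -> pd.DataFrame:
    """Read a corrected MID table: metabolite, compartment, tracer, M_i, fraction."""
    df = pd.read_csv(path)
    required = {"metabolite", "compartment", "tracer", "M_i", "fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MID table missing columns: {sorted(missing)}")
    return df


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_path,
    config: dict,
    seeds: dict,
    inputs: list,
    outputs: list,
) -> dict:
    """Write a machine-readable run manifest (JSON).

    Records the package version, a hash of the configuration, all
    seeds, input checksums, and the output file list so that a run is
    reproducible from the manifest alone.
    """
    from codonflux import __version__

    config_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "codonflux",
        "version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seeds": seeds,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    Path(out_path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
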