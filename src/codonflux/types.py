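"""Core domain types shared across the analysis layers.

Coordinates are 0-based, half-open throughout.  Codon ``i`` of a CDS
occupies nucleotides ``[3i, 3i+3)`` of the CDS; ``cds_start`` locates the
CDS within the surrounding transcript so that read coordinates (which are
transcript-space) can be converted to CDS-space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
PROLINE_CODONS = frozenset({"CCA", "CCC", "CCG", "CCT"})
BASES = ("A", "C", "G", "T")

ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)


class FootprintRead(NamedTuple):
    """A ribosome-protected fragment placed in transcript space.

    ``five_prime_pos`` is the 0-based transcript coordinate of the
    fragment's 5' end; ``length`` its trimmed length in nucleotides.
    """

    transcript_id: str
    five_prime_pos: int
    length: int


@dataclass(frozen=True)
class TranscriptCDS:
    """A coding sequence with its gene annotation.

    ``sequence`` is the CDS only (start codon through terminal stop).
    ``cds_start`` is the transcript coordinate of the first CDS
    nucleotide (i.e. the 5' UTR length); ``utr3`` the 3' UTR length.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    gene_sets: tuple[str, ...] = ()
    cds_start: int = 0
    utr3: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.sequence)} "
                "is not divisible by 3"
            )
        bad = set(self.sequence) - set(BASES)
        if bad:
            raise ValueError(
                f"{self.transcript_id}: non-ACGT characters {sorted(bad)}"
            )

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    @property
    def codons(self) -> list[str]:
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    @property
    def transcript_length(self) -> int:
        return self.cds_start + len(self.sequence) + self.utr3


@dataclass(frozen=True)
class MIDVector:
    """Mass-isotopomer distribution of one metabolite.

    ``fractions[i]`` is the fraction of the M+i isotopomer; the carbon
    count C is ``len(fractions) - 1``.  Fractions must lie in [0, 1] and
    sum to 1 (within 1e-6).
    """

    metabolite: str
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if fr.size < 2:
            raise ValueError("an MID needs at least M+0 and M+1 entries (C >= 1)")
        if np.any(fr < -1e-12) or np.any(fr > 1 + 1e-12):
            raise ValueError(f"{self.metabolite}: MID fractions outside [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"{self.metabolite}: MID fractions sum to {fr.sum():.8f}, not 1"
            )

    @property
    def carbon_count(self) -> int:
        return len(self.fractions) - 1

    @property
    def fully_labeled(self) -> float:
        """Fraction of the fully labeled M+C form."""
        return float(self.fractions[-1])


def transcriptome_index(
    transcripts: list[TranscriptCDS],
) -> dict[str, TranscriptCDS]:
    """Index a transcript list by transcript_id, rejecting duplicates."""
    idx: dict[str, TranscriptCDS] = {}
    for tx in transcripts:
        if tx.transcript_id in idx:
            raise ValueError(f"duplicate transcript_id {tx.transcript_id}")
        idx[tx.transcript_id] = tx
    return idx
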