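"""Locate a transcription start site from an mRNA 5' end.

The TSS is defined by the genomic base corresponding to the transcript's
first nucleotide, so a full (spliced) alignment of the transcript is
unnecessary: it suffices to place the mRNA's 5'-terminal anchor (default
30 bases) on either genomic strand, allowing a configurable number of
mismatches. A unique placement is required; ambiguity is an error rather
than a silent tie-break, because a single-TSS annotation presumes a unique
anchor site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import (
    NucleotideSequence,
    Strand,
    StrandedLocus,
    reverse_complement,
)

__all__ = [
    "TssAnnotation",
    "TssMappingError",
    "NoAnchorError",
    "AmbiguousTssError",
    "map_tss",
]


class TssMappingError(ValueError):
    """Anchor placement failed."""


class NoAnchorError(TssMappingError):
    """The mRNA 5' anchor was not found on either strand."""


class AmbiguousTssError(TssMappingError):
    """More than one anchor placement; the TSS cannot be called uniquely."""

    def __init__(self, placements: list["TssAnnotation"]):
        self.placements = placements
        sites = ", ".join(str(p.locus) for p in placements)
        super().__init__(
            f"ambiguous TSS: anchor places at {len(placements)} sites ({sites})"
        )


@dataclass(frozen=True)
class TssAnnotation:
    """Strand-aware 1-based transcription start locus."""

    locus: StrandedLocus
    source_mrna: str
    anchor_length: int
    mismatches: int


def _hamming_hits(genome: str, pattern: str, max_mismatches: int) -> np.ndarray:
    """0-based start indices where pattern matches with <= max_mismatches.

    N never matches anything, including N itself.
    """
    g = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    p = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    k = len(p)
    n_pos = len(g) - k + 1
    if n_pos <= 0:
        return np.empty(0, dtype=np.int64)
    n_code = ord("N")
    mism = np.zeros(n_pos, dtype=np.int32)
    for j in range(k):
        col = g[j : j + n_pos]
        mism += (col != p[j]) | (col == n_code) | (p[j] == n_code)
    return np.nonzero(mism <= max_mismatches)[0]


def map_tss(
    genome: NucleotideSequence,
    mrna: NucleotideSequence,
    anchor_length: int = 30,
    max_mismatches: int = 0,
    chromosome: "str | None" = None,
) -> TssAnnotation:
    """Map the TSS by placing the mRNA's 5' anchor on either genomic strand.

    Parameters
    ----------
    genome, mrna:
        Genomic record (absolute position 1 at its first base) and transcript.
    anchor_length:
        Number of 5'-terminal mRNA bases used as the anchor. 30 keeps the
        search space (4^30) effectively unique while tolerating short reads.
    max_mismatches:
        Hamming mismatches allowed within the anchor.

    Returns the unique placement's first transcribed base as the TSS; for a
    minus-strand placement that is the highest absolute coordinate covered by
    the anchor. Zero placements raise :class:`NoAnchorError`; more than one,
    :class:`AmbiguousTssError` listing all of them.
    """
    if len(mrna) < anchor_length:
        raise TssMappingError(
            f"mRNA {mrna.identifier!r} shorter ({len(mrna)}) than anchor {anchor_length}"
        )
    if len(genome) < anchor_length:
        raise TssMappingError(
            f"genome {genome.identifier!r} shorter ({len(genome)}) than anchor {anchor_length}"
        )
    chrom = chromosome if chromosome is not None else genome.identifier
    anchor = mrna.residues[:anchor_length]

    placements: list[TssAnnotation] = []
    plus_hits = _hamming_hits(genome.residues, anchor, max_mismatches)
    for start in plus_hits:
        locus = StrandedLocus(chrom, int(start) + 1, Strand.PLUS)
        mm = sum(
            1
            for a, b in zip(anchor, genome.residues[start : start + anchor_length])
            if a != b or a == "N" or b == "N"
        )
        placements.append(TssAnnotation(locus, mrna.identifier, anchor_length, mm))
    rc_anchor = reverse_complement(anchor)
    minus_hits = _hamming_hits(genome.residues, rc_anchor, max_mismatches)
    for start in minus_hits:
        # anchor covers absolute start+1 .. start+anchor_length; on the minus
        # strand transcription runs right-to-left, so the 5' base is the
        # highest absolute coordinate.
        locus = StrandedLocus(chrom, int(start) + anchor_length, Strand.MINUS)
        mm = sum(
            1
            for a, b in zip(rc_anchor, genome.residues[start : start + anchor_length])
            if a != b or a == "N" or b == "N"
        )
        placements.append(TssAnnotation(locus, mrna.identifier, anchor_length, mm))

    if not placements:
        raise NoAnchorError(
            f"no placement of the {anchor_length}-base 5' anchor of "
            f"{mrna.identifier!r} within {max_mismatches} mismatches"
        )
    if len(placements) > 1:
        raise AmbiguousTssError(placements)
    return placements[0]
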