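"""Nucleotide sequences, strand operations and the TSS-relative coordinate system.

Every genomic module in the package works on a strand-aware, zero-free
coordinate axis anchored at the transcription start site (TSS): the TSS base
is +1, the base immediately upstream is -1, and 0 does not exist. This is the
unique convention consistent with a window running from -6765 to +4234 around
a minus-strand TSS at 27230845 whose absolute bounds are 27237610..27226612
(27230845 - 27226612 + 1 = 4234 and 27230845 - 27237610 = -6765).

Internal coordinates are 1-based inclusive; conversion to 0-based half-open
happens only at BED export (see :mod:`hbskit.hbs_scan`).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "SequenceError",
    "CoordinateError",
    "Strand",
    "NucleotideSequence",
    "StrandedLocus",
    "AnalysisWindow",
    "WindowExtraction",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "complement_base",
    "abs_to_rel",
    "rel_to_abs",
    "extract_window",
]

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Malformed FASTA input or illegal residue."""


class CoordinateError(ValueError):
    """Coordinate outside its contract (rel = 0, window overhang, ...)."""


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"

    @classmethod
    def parse(cls, value: "str | Strand") -> "Strand":
        if isinstance(value, Strand):
            return value
        token = str(value).strip().lower()
        if token in {"+", "plus", "1"}:
            return cls.PLUS
        if token in {"-", "minus", "-1"}:
            return cls.MINUS
        raise ValueError(f"unrecognized strand {value!r}")

    @property
    def opposite(self) -> "Strand":
        return Strand.MINUS if self is Strand.PLUS else Strand.PLUS


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}.

    Residues are uppercased on construction; soft-masking (lowercase) carries
    no meaning here. Any other character is rejected.
    """

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        upper = self.residues.upper()
        bad = set(upper) - VALID_BASES
        if bad:
            raise SequenceError(
                f"record {self.identifier!r} contains illegal characters: "
                f"{''.join(sorted(bad))}"
            )
        object.__setattr__(self, "residues", upper)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def base_at(self, position: int) -> str:
        """Base at a 1-based absolute position."""
        if not 1 <= position <= len(self.residues):
            raise CoordinateError(
                f"position {position} outside record {self.identifier!r} "
                f"(length {len(self.residues)})"
            )
        return self.residues[position - 1]


@dataclass(frozen=True)
class StrandedLocus:
    """A single 1-based genomic base with a strand."""

    chromosome: str
    position: int
    strand: Strand

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand", Strand.parse(self.strand))
        if self.position < 1:
            raise CoordinateError(f"position must be >= 1, got {self.position}")

    @classmethod
    def parse(cls, text: str) -> "StrandedLocus":
        """Parse ``CHR:POS:STRAND`` (strand as ``+``/``-``/``plus``/``minus``)."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"expected CHR:POS:STRAND, got {text!r}")
        return cls(parts[0], int(parts[1]), Strand.parse(parts[2]))

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.strand.value}"


@dataclass(frozen=True)
class AnalysisWindow:
    """TSS-relative scan window, e.g. (-6765, +4234).

    ``upstream_extent`` is the most upstream relative coordinate covered
    (<= -1) and ``downstream_extent`` the most downstream (>= +1). Because the
    axis has no zero, the window covers ``-upstream_extent +
    downstream_extent`` bases.
    """

    upstream_extent: int
    downstream_extent: int

    def __post_init__(self) -> None:
        if self.upstream_extent > -1:
            raise CoordinateError(
                f"upstream_extent must be <= -1, got {self.upstream_extent}"
            )
        if self.downstream_extent < 1:
            raise CoordinateError(
                f"downstream_extent must be >= +1, got {self.downstream_extent}"
            )

    @property
    def length(self) -> int:
        return -self.upstream_extent + self.downstream_extent

    @classmethod
    def parse(cls, text: str) -> "AnalysisWindow":
        """Parse ``-6765:+4234``."""
        up, down = text.split(":")
        return cls(int(up), int(down))

    def local_of_rel(self, rel: int) -> int:
        """0-based window index of a TSS-relative coordinate."""
        if rel == 0:
            raise CoordinateError("relative coordinate 0 does not exist")
        if not self.upstream_extent <= rel <= self.downstream_extent:
            raise CoordinateError(f"relative position {rel} outside window {self}")
        upstream_span = -self.upstream_extent
        return upstream_span + rel if rel < 0 else upstream_span + rel - 1

    def rel_of_local(self, index: int) -> int:
        """TSS-relative coordinate of a 0-based window index."""
        if not 0 <= index < self.length:
            raise CoordinateError(f"index {index} outside window of length {self.length}")
        upstream_span = -self.upstream_extent
        rel = index - upstream_span
        return rel if rel < 0 else rel + 1


def read_fasta(path: "str | Path") -> list[NucleotideSequence]:
    """Read a (multi-record) FASTA file into validated sequences.

    Order is preserved; residues are uppercased. Empty files, duplicate
    identifiers and illegal characters raise :class:`SequenceError` naming
    the offending record.
    """
    path = Path(path)
    records: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(NucleotideSequence(rec.id, str(rec.seq)))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences, path: "str | Path", width: int = 70) -> None:
    """Write sequences as wrapped FASTA."""
    if isinstance(sequences, NucleotideSequence):
        sequences = [sequences]
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.identifier}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: "NucleotideSequence | str") -> "NucleotideSequence | str":
    """Watson-Crick reverse complement; N maps to N. Involution."""
    if isinstance(seq, str):
        return seq.translate(_COMPLEMENT)[::-1]
    return NucleotideSequence(seq.identifier, seq.residues.translate(_COMPLEMENT)[::-1])


def abs_to_rel(position: int, tss: StrandedLocus) -> int:
    """Convert a 1-based absolute position to a TSS-relative coordinate.

    The TSS base maps to +1 and the base immediately upstream of it to -1;
    0 is never returned. Downstream means along the direction of
    transcription, so on the minus strand downstream positions have *lower*
    absolute coordinates.
    """
    if position < 1:
        raise CoordinateError(f"position must be >= 1, got {position}")
    if tss.strand is Strand.MINUS:
        if position <= tss.position:  # downstream of a minus-strand TSS
            return tss.position - position + 1
        return tss.position - position
    if position >= tss.position:  # downstream of a plus-strand TSS
        return position - tss.position + 1
    return position - tss.position


def rel_to_abs(rel: int, tss: StrandedLocus) -> int:
    """Exact inverse of :func:`abs_to_rel` for the same TSS."""
    if rel == 0:
        raise CoordinateError("relative coordinate 0 does not exist")
    if tss.strand is Strand.MINUS:
        position = tss.position - rel + 1 if rel > 0 else tss.position - rel
    else:
        position = tss.position + rel - 1 if rel > 0 else tss.position + rel
    if position < 1:
        raise CoordinateError(f"relative {rel} maps before the start of {tss}")
    return position


@dataclass(frozen=True)
class WindowExtraction:
    """Gene-sense window sequence plus its local/relative/absolute index maps."""

    sequence: NucleotideSequence
    tss: StrandedLocus
    window: AnalysisWindow

    def rel_of_local(self, index: int) -> int:
        return self.window.rel_of_local(index)

    def local_of_rel(self, rel: int) -> int:
        return self.window.local_of_rel(rel)

    def abs_of_local(self, index: int) -> int:
        return rel_to_abs(self.window.rel_of_local(index), self.tss)


def extract_window(
    genome: NucleotideSequence,
    tss: StrandedLocus,
    window: AnalysisWindow,
) -> WindowExtraction:
    """Extract the analysis window around a TSS in gene-sense orientation.

    For a minus-strand TSS the result is the reverse complement of the
    plus-strand genomic slice, so the returned sequence always reads 5'->3'
    along the gene. Local index 0 corresponds to the window's upstream
    extent. The genome record is taken to start at absolute position 1.
    """
    if tss.strand is Strand.MINUS:
        low = tss.position - window.downstream_extent + 1
        high = tss.position - window.upstream_extent
    else:
        low = tss.position + window.upstream_extent
        high = tss.position + window.downstream_extent - 1
    if low < 1 or high > len(genome):
        raise CoordinateError(
            f"window spans absolute {low}..{high} but record "
            f"{genome.identifier!r} covers 1..{len(genome)} "
            f"(overhang {max(0, 1 - low)} bp left, {max(0, high - len(genome))} bp right)"
        )
    raw = genome.residues[low - 1 : high]
    if tss.strand is Strand.MINUS:
        raw = reverse_complement(raw)
    name = f"{tss.chromosome}|tss={tss.position}{tss.strand.value}|{window.upstream_extent}:{window.downstream_extent}"
    return WindowExtraction(NucleotideSequence(name, raw), tss, window)
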