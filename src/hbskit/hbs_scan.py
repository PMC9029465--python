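"""Discovery and classification of candidate HIF-binding sites (HBSs).

HIF-1 binds hypoxia-response elements through a short conserved core,
written A0-C-G-T-G with the adenine indexed 0. Two flanking nucleotides —
G at position -2 and C at +5 relative to A0 — are known to raise the
probability that a core is actually bound in vivo, so candidates carrying
either flank (inclusive "and/or") are classified HIGH and bare cores
CORE_ONLY. The scanner composes window extraction, exact core search,
flank annotation, classification and coordinate resolution, and exports
BED6 / GFF3 / CSV.

The default scan covers the gene-sense strand only; antisense scanning is
an explicit flag. The optional degenerate mode accepts RCGTG (R = A or G).
"""

from __future__ import annotations

import csv as _csv
import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

from .sequences import (
    AnalysisWindow,
    NucleotideSequence,
    Strand,
    StrandedLocus,
    complement_base,
    extract_window,
    reverse_complement,
)
from .tss_mapping import TssAnnotation

__all__ = [
    "Confidence",
    "Location",
    "Orientation",
    "HbsCandidate",
    "find_cores",
    "annotate_flanks",
    "classify",
    "scan_region",
    "export_candidates",
    "read_candidates_csv",
]

UNKNOWN = "UNKNOWN"

# IUPAC letters the core motif may use; N in the *sequence* never matches.
_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "Y": "[CT]"}
_IUPAC_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R"}


class Confidence(str, Enum):
    HIGH = "HIGH"
    CORE_ONLY = "CORE_ONLY"


class Location(str, Enum):
    UPSTREAM = "UPSTREAM"
    INTRAGENIC = "INTRAGENIC"


class Orientation(str, Enum):
    """Orientation of a core hit relative to the scanned sequence."""

    SENSE = "sense"
    ANTISENSE = "antisense"


@dataclass(frozen=True)
class HbsCandidate:
    """One core match with flank annotation, confidence and position.

    ``offset`` is the 0-based index of the A0 base in the scanned (window)
    sequence. ``strand`` is the genomic strand of the match once resolved by
    :func:`scan_region`. Flanks are single bases in match orientation, or
    ``UNKNOWN`` where they fall outside the sequence.
    """

    core: str
    offset: int
    orientation: Orientation
    flank_minus2: str
    flank_plus5: str
    has_G_minus2: bool
    has_C_plus5: bool
    confidence: "Confidence | None" = None
    low_context: bool = False
    rel_position: "int | None" = None
    abs_position: "int | None" = None
    strand: "Strand | None" = None
    chromosome: "str | None" = None
    location: "Location | None" = None
    label: "str | None" = None


def _motif_regex(core: str) -> "re.Pattern[str]":
    try:
        body = "".join(_IUPAC[ch] for ch in core.upper())
    except KeyError as exc:
        raise ValueError(f"unsupported motif letter {exc.args[0]!r} in {core!r}") from exc
    return re.compile(f"(?=({body}))")


def _motif_revcomp(core: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[ch] for ch in core.upper())[::-1]


def find_cores(
    seq: "NucleotideSequence | str",
    core: str = "ACGTG",
    scan_antisense: bool = False,
) -> list[tuple[int, Orientation]]:
    """All occurrences of the core motif, in 5'->3' order of the A0 base.

    Offsets are 0-based indices into ``seq``. Antisense hits (when enabled)
    are reported at the offset of the sense-strand base that pairs with the
    core's A0, i.e. the last base of the reverse-complement pattern.
    Overlapping occurrences are all reported (a lookahead scan), although
    ACGTG itself cannot self-overlap.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    hits = [
        (m.start(), Orientation.SENSE)
        for m in _motif_regex(core).finditer(residues)
    ]
    if scan_antisense:
        span = len(core)
        hits.extend(
            (m.start() + span - 1, Orientation.ANTISENSE)
            for m in _motif_regex(_motif_revcomp(core)).finditer(residues)
        )
    hits.sort(key=lambda h: (h[0], h[1] is Orientation.ANTISENSE))
    return hits


def annotate_flanks(
    seq: "NucleotideSequence | str",
    hit: tuple[int, Orientation],
    core_length: int = 5,
) -> HbsCandidate:
    """Annotate the -2 and +5 flanking bases of a core hit (match orientation).

    Positions count from the A0 base of the core: -2 is two bases 5' of A0
    and +5 the base immediately 3' of the 5-mer. Flanks outside the sequence
    are ``UNKNOWN``.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    offset, orientation = hit

    def base(i: int) -> str:
        return residues[i] if 0 <= i < len(residues) else UNKNOWN

    if orientation is Orientation.SENSE:
        core = residues[offset : offset + core_length]
        f2 = base(offset - 2)
        f5 = base(offset + core_length)
    else:
        # A0 sits at `offset` on the sense axis and the match reads toward
        # decreasing sense indices on the complementary strand.
        core = reverse_complement(residues[offset - core_length + 1 : offset + 1])
        f2 = base(offset + 2)
        f2 = complement_base(f2) if f2 != UNKNOWN else UNKNOWN
        f5 = base(offset - core_length)
        f5 = complement_base(f5) if f5 != UNKNOWN else UNKNOWN

    return HbsCandidate(
        core=core,
        offset=offset,
        orientation=orientation,
        flank_minus2=f2,
        flank_plus5=f5,
        has_G_minus2=f2 == "G",
        has_C_plus5=f5 == "C",
    )


def classify(candidate: HbsCandidate) -> HbsCandidate:
    """Assign HIGH (G-2 and/or C+5 present) or CORE_ONLY confidence.

    ``UNKNOWN`` flanks count as absent; a candidate with any unknown flank
    additionally carries a low-context warning flag.
    """
    confidence = (
        Confidence.HIGH
        if candidate.has_G_minus2 or candidate.has_C_plus5
        else Confidence.CORE_ONLY
    )
    low_context = UNKNOWN in (candidate.flank_minus2, candidate.flank_plus5)
    return replace(candidate, confidence=confidence, low_context=low_context)


def _resolve_tss(tss: "TssAnnotation | StrandedLocus") -> StrandedLocus:
    return tss.locus if isinstance(tss, TssAnnotation) else tss


def scan_region(
    genome: NucleotideSequence,
    tss: "TssAnnotation | StrandedLocus",
    window: AnalysisWindow,
    scan_antisense: bool = False,
    core: str = "ACGTG",
) -> list[HbsCandidate]:
    """Scan the TSS-relative window for HBS candidates.

    Composes :func:`~hbskit.sequences.extract_window` -> :func:`find_cores`
    -> :func:`annotate_flanks` -> :func:`classify`, then resolves TSS-relative
    and absolute coordinates of each A0 base, tags genomic context (UPSTREAM
    iff rel <= -1) and labels candidates #1, #2, ... in 5'->3' window order.
    """
    locus = _resolve_tss(tss)
    extraction = extract_window(genome, locus, window)
    hits = find_cores(extraction.sequence, core=core, scan_antisense=scan_antisense)
    candidates: list[HbsCandidate] = []
    for ordinal, hit in enumerate(hits, start=1):
        cand = classify(annotate_flanks(extraction.sequence, hit, core_length=len(core)))
        rel = extraction.rel_of_local(cand.offset)
        abs_pos = extraction.abs_of_local(cand.offset)
        strand = (
            locus.strand
            if cand.orientation is Orientation.SENSE
            else locus.strand.opposite
        )
        candidates.append(
            replace(
                cand,
                rel_position=rel,
                abs_position=abs_pos,
                strand=strand,
                chromosome=locus.chromosome,
                location=Location.UPSTREAM if rel <= -1 else Location.INTRAGENIC,
                label=f"#{ordinal}",
            )
        )
    return candidates


_CSV_FIELDS = [
    "label",
    "chromosome",
    "rel_position",
    "abs_position",
    "strand",
    "core",
    "flank_minus2",
    "flank_plus5",
    "has_G_minus2",
    "has_C_plus5",
    "confidence",
    "location",
    "low_context",
    "offset",
    "orientation",
]


def _bed_span(candidate: HbsCandidate, core_length: int = 5) -> tuple[int, int]:
    """0-based half-open absolute span of the matched core bases.

    On the genomic minus strand the core extends toward decreasing absolute
    coordinates from A0.
    """
    a0 = candidate.abs_position
    if candidate.strand is Strand.MINUS:
        return a0 - core_length, a0
    return a0 - 1, a0 - 1 + core_length


def export_candidates(
    candidates: list[HbsCandidate],
    path: "str | Path",
    fmt: str = "CSV",
) -> None:
    """Write candidates as BED6, GFF3 or CSV.

    BED6 uses 0-based half-open absolute coordinates over the 5 matched core
    bases, with the label/confidence in the name column and score 1000 for
    HIGH vs 500 for CORE_ONLY. GFF3 is 1-based inclusive. CSV mirrors every
    candidate field and round-trips through :func:`read_candidates_csv`.
    """
    fmt = fmt.upper()
    path = Path(path)
    if any(c.abs_position is None for c in candidates):
        raise ValueError("candidates must have resolved coordinates before export")
    with open(path, "w", newline="") as fh:
        if fmt == "BED6":
            for c in candidates:
                start, end = _bed_span(c, len(c.core))
                score = 1000 if c.confidence is Confidence.HIGH else 500
                name = f"HBS{c.label}|{c.confidence.value}"
                fh.write(
                    f"{c.chromosome}\t{start}\t{end}\t{name}\t{score}\t{c.strand.value}\n"
                )
        elif fmt == "GFF3":
            fh.write("##gff-version 3\n")
            for c in candidates:
                start0, end0 = _bed_span(c, len(c.core))
                attrs = (
                    f"ID=HBS{c.label.lstrip('#')};confidence={c.confidence.value};"
                    f"rel_position={c.rel_position};location={c.location.value}"
                )
                fh.write(
                    f"{c.chromosome}\thbskit\tprotein_binding_site\t{start0 + 1}\t{end0}\t."
                    f"\t{c.strand.value}\t.\t{attrs}\n"
                )
        elif fmt == "CSV":
            writer = _csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
            writer.writeheader()
            for c in candidates:
                writer.writerow(
                    {
                        "label": c.label,
                        "chromosome": c.chromosome,
                        "rel_position": c.rel_position,
                        "abs_position": c.abs_position,
                        "strand": c.strand.value,
                        "core": c.core,
                        "flank_minus2": c.flank_minus2,
                        "flank_plus5": c.flank_plus5,
                        "has_G_minus2": c.has_G_minus2,
                        "has_C_plus5": c.has_C_plus5,
                        "confidence": c.confidence.value,
                        "location": c.location.value,
                        "low_context": c.low_context,
                        "offset": c.offset,
                        "orientation": c.orientation.value,
                    }
                )
        else:
            raise ValueError(f"unknown export format {fmt!r} (BED6, GFF3 or CSV)")


def read_candidates_csv(path: "str | Path") -> list[HbsCandidate]:
    """Read back a CSV written by :func:`export_candidates`."""
    out: list[HbsCandidate] = []
    with open(path, newline="") as fh:
        for row in _csv.DictReader(fh):
            out.append(
                HbsCandidate(
                    core=row["core"],
                    offset=int(row["offset"]),
                    orientation=Orientation(row["orientation"]),
                    flank_minus2=row["flank_minus2"],
                    flank_plus5=row["flank_plus5"],
                    has_G_minus2=row["has_G_minus2"] == "True",
                    has_C_plus5=row["has_C_plus5"] == "True",
                    confidence=Confidence(row["confidence"]),
                    low_context=row["low_context"] == "True",
                    rel_position=int(row["rel_position"]),
                    abs_position=int(row["abs_position"]),
                    strand=Strand(row["strand"]),
                    chromosome=row["chromosome"],
                    location=Location(row["location"]),
                    label=row["label"],
                )
            )
    return out
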