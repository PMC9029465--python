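"""Seeded generators with exact ground truth for every pipeline stage.

Each generator emulates one class of study input without any download:

* :func:`simulate_locus` — a genomic slice with a known TSS (either strand)
  and A0CGTG cores planted at chosen TSS-relative offsets with controlled
  G-2 / C+5 flanks. Background is drawn base-by-base (uniform composition by
  default); accidental core occurrences — on either strand — are destroyed
  by single-base substitution so the scanner's output is exactly the truth
  table.
* :func:`simulate_mrna` — a transcript whose 5' base is exactly the TSS
  base, for exercising anchor-based TSS mapping.
* :func:`simulate_ct_table` — qPCR plates with a chosen true enrichment or
  expression fold per condition and Gaussian Ct noise.
* :func:`simulate_trajectory` — multi-frame structures engineered so that
  the per-frame protein-DNA contact count equals a prescribed schedule
  exactly (contact pairs at 0.45 nm, non-contacts >= 0.9 nm, so counts are
  robust to PDB coordinate rounding) and chosen atoms oscillate with known
  fluctuation amplitudes about the mean structure.

All randomness flows from one explicit seed; identical seed and parameters
give byte-identical outputs. Ground truth is serialized as JSON alongside
each dataset.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import (
    AnalysisWindow,
    NucleotideSequence,
    Strand,
    StrandedLocus,
    complement_base,
    rel_to_abs,
)
from .structure import Moiety, Trajectory, _atoms_frame, AtomRecord

__all__ = [
    "GenerationError",
    "PlantedSite",
    "LocusTruth",
    "CtTruth",
    "TrajectoryTruth",
    "DEFAULT_WINDOW",
    "DEFAULT_MOUSE_SITES",
    "simulate_locus",
    "simulate_mrna",
    "simulate_ct_table",
    "simulate_trajectory",
]


class GenerationError(ValueError):
    """Requested synthetic dataset is infeasible."""


#: The analysis window used throughout: -6765 upstream to +4234 downstream.
DEFAULT_WINDOW = AnalysisWindow(-6765, 4234)

#: Default six-site layout mirroring the mouse locus: site #1 upstream at
#: -2186 with both favourable flanks; one further upstream site and four
#: intragenic sites, with sites #4 (both flanks) and #5 (C+5 only) completing
#: the high-probability set {#1, #4, #5}. Only the -2186 offset is an
#: externally printed position; the others are fixed representative choices.
DEFAULT_MOUSE_SITES = (
    (-2186, True, True),
    (-1200, False, False),
    (350, False, False),
    (1500, True, True),
    (2600, False, True),
    (3900, False, False),
)

_CORE = "ACGTG"
_CORE_RC = "CACGT"


@dataclass(frozen=True)
class PlantedSite:
    rel_position: int
    has_G_minus2: bool
    has_C_plus5: bool

    @property
    def confidence(self) -> str:
        return "HIGH" if self.has_G_minus2 or self.has_C_plus5 else "CORE_ONLY"

    @property
    def location(self) -> str:
        return "UPSTREAM" if self.rel_position <= -1 else "INTRAGENIC"


@dataclass(frozen=True)
class LocusTruth:
    """Ground truth of a simulated locus, sufficient to predict the scan."""

    seed: int
    chromosome: str
    tss_position: int
    strand: str
    window_upstream: int
    window_downstream: int
    sites: tuple[PlantedSite, ...]

    @property
    def tss(self) -> StrandedLocus:
        return StrandedLocus(self.chromosome, self.tss_position, Strand(self.strand))

    @property
    def window(self) -> AnalysisWindow:
        return AnalysisWindow(self.window_upstream, self.window_downstream)

    def expected_candidates(self) -> list[tuple[int, str, str]]:
        """(rel_position, confidence, location) in 5'->3' window order."""
        ordered = sorted(self.sites, key=lambda s: self.window.local_of_rel(s.rel_position))
        return [(s.rel_position, s.confidence, s.location) for s in ordered]

    def to_json(self, path: "str | Path") -> None:
        _dump_truth(self, path)

    @classmethod
    def from_json(cls, path: "str | Path") -> "LocusTruth":
        data = json.loads(Path(path).read_text())
        data.pop("kind", None)
        data["sites"] = tuple(PlantedSite(**s) for s in data["sites"])
        return cls(**data)


def _dump_truth(truth, path: "str | Path") -> None:
    payload = asdict(truth)
    payload["kind"] = type(truth).__name__
    Path(path).write_text(json.dumps(payload, indent=1, default=list) + "\n")


def _default_tss_position(window: AnalysisWindow, strand: Strand) -> int:
    # place the window flush with absolute position 1
    if strand is Strand.MINUS:
        return window.downstream_extent
    return -window.upstream_extent + 1


def simulate_locus(
    seed: int,
    length: "int | None" = None,
    tss_position: "int | None" = None,
    strand: "Strand | str" = Strand.MINUS,
    window: AnalysisWindow = DEFAULT_WINDOW,
    planted: "tuple | list" = DEFAULT_MOUSE_SITES,
    chromosome: str = "chr_synth",
    base_probs: "tuple[float, float, float, float] | None" = None,
) -> tuple[NucleotideSequence, LocusTruth]:
    """Generate a genomic slice with planted HBS cores and exact truth.

    ``planted`` holds ``(rel_position, has_G_minus2, has_C_plus5)`` triples
    (or :class:`PlantedSite` objects); A0 bases must be pairwise >= 8 bp
    apart and every -2..+5 footprint must lie inside the window. Accidental
    ACGTG / CACGT occurrences outside planted sites are destroyed by
    single-base substitution, so scanning the window recovers exactly the
    planted candidates.

    ``base_probs`` optionally skews background composition (A, C, G, T);
    genomic core density is GC-sensitive, but the truth table never depends
    on it.
    """
    strand = Strand.parse(strand)
    sites = tuple(
        s if isinstance(s, PlantedSite) else PlantedSite(*s) for s in planted
    )
    if tss_position is None:
        tss_position = _default_tss_position(window, strand)
    if length is None:
        length = window.length
    tss = StrandedLocus(chromosome, tss_position, strand)

    # feasibility: footprints inside window, plants >= 8 bp apart
    locals_ = []
    for s in sites:
        l0 = window.local_of_rel(s.rel_position)
        if l0 - 2 < 0 or l0 + 5 >= window.length:
            raise GenerationError(
                f"footprint of site at rel {s.rel_position} leaves the window"
            )
        locals_.append(l0)
    for i, a in enumerate(locals_):
        for b in locals_[i + 1 :]:
            if abs(a - b) < 8:
                raise GenerationError(
                    "planted sites closer than 8 bp (overlapping footprints)"
                )

    span_low = min(
        rel_to_abs(window.upstream_extent, tss), rel_to_abs(window.downstream_extent, tss)
    )
    span_high = max(
        rel_to_abs(window.upstream_extent, tss), rel_to_abs(window.downstream_extent, tss)
    )
    if span_low < 1 or span_high > length:
        raise GenerationError(
            f"window spans absolute {span_low}..{span_high} outside genome of length {length}"
        )

    rng = np.random.default_rng(seed)
    probs = None if base_probs is None else np.asarray(base_probs, dtype=float)
    if probs is not None:
        probs = probs / probs.sum()
    genome = list(rng.choice(list("ACGT"), size=length, p=probs))

    def abs_of_local(l: int) -> int:
        return rel_to_abs(window.rel_of_local(l), tss)

    protected: set[int] = set()
    planted_spans: set[tuple[int, str]] = set()
    for s, l0 in zip(sites, locals_):
        flank2 = "G" if s.has_G_minus2 else str(rng.choice(list("ACT")))
        # -1 base must not be C: a C here would form an accidental
        # reverse-strand core (CACGT) overlapping the plant
        flank1 = str(rng.choice(list("AGT")))
        flank5 = "C" if s.has_C_plus5 else str(rng.choice(list("AGT")))
        bases = flank2 + flank1 + _CORE + flank5  # gene-sense, A0 at index 2
        for k, base in enumerate(bases, start=-2):
            pos = abs_of_local(l0 + k)
            genome[pos - 1] = base if strand is Strand.PLUS else complement_base(base)
            protected.add(pos)
        a0_abs = abs_of_local(l0)
        if strand is Strand.PLUS:
            planted_spans.add((a0_abs - 1, _CORE))
        else:
            planted_spans.add((a0_abs - 5, _CORE_RC))

    # destroy accidental cores (either strand) outside planted spans
    for _ in range(200):
        text = "".join(genome)
        accidental = []
        for pattern in (_CORE, _CORE_RC):
            start = text.find(pattern)
            while start != -1:
                if (start, pattern) not in planted_spans:
                    accidental.append((start, pattern))
                start = text.find(pattern, start + 1)
        if not accidental:
            break
        for start, pattern in accidental:
            mutable = [
                i for i in range(start, start + len(pattern)) if (i + 1) not in protected
            ]
            if not mutable:
                raise GenerationError(
                    f"accidental core at {start + 1} lies fully inside planted footprints"
                )
            i = mutable[0]
            genome[i] = str(rng.choice([b for b in "ACGT" if b != genome[i]]))
    else:
        raise GenerationError("could not eliminate accidental cores in 200 passes")

    truth = LocusTruth(
        seed=seed,
        chromosome=chromosome,
        tss_position=tss_position,
        strand=strand.value,
        window_upstream=window.upstream_extent,
        window_downstream=window.downstream_extent,
        sites=sites,
    )
    return NucleotideSequence(chromosome, "".join(genome)), truth


def simulate_mrna(
    genome: NucleotideSequence,
    tss: StrandedLocus,
    exon_lengths: "list[int] | tuple[int, ...]",
    intron_lengths: "list[int] | None" = None,
    identifier: str = "mrna_synth",
) -> NucleotideSequence:
    """Build a spliced transcript whose 5' base is exactly the TSS base.

    Exons run gene-sense starting at the TSS, separated by introns (100 bp
    each unless given). For a minus-strand gene the transcript is the
    reverse complement of the genomic exon slices, read 5'->3'.
    """
    if not exon_lengths:
        raise GenerationError("at least one exon is required")
    if intron_lengths is None:
        intron_lengths = [100] * (len(exon_lengths) - 1)
    if len(intron_lengths) != len(exon_lengths) - 1:
        raise GenerationError(
            f"{len(exon_lengths)} exons need {len(exon_lengths) - 1} introns, "
            f"got {len(intron_lengths)}"
        )
    step = 1 if tss.strand is Strand.PLUS else -1
    pos = tss.position
    bases: list[str] = []
    for i, exon in enumerate(exon_lengths):
        for _ in range(exon):
            base = genome.base_at(pos)
            bases.append(base if tss.strand is Strand.PLUS else complement_base(base))
            pos += step
        if i < len(intron_lengths):
            pos += step * intron_lengths[i]
    return NucleotideSequence(identifier, "".join(bases))


@dataclass(frozen=True)
class CtTruth:
    """Ground truth of a simulated Ct table."""

    seed: int
    design: str  # "enrichment" | "expression"
    conditions: tuple[str, ...]
    true_folds: tuple[float, ...]
    base_ct: float
    noise_sd: float
    replicates: int
    targets: tuple[str, str]  # (sample-ish target, reference-ish target)
    calibrator: "str | None" = None

    def expected(self) -> dict[str, float]:
        """Noise-free summary value per condition."""
        folds = dict(zip(self.conditions, self.true_folds))
        if self.design == "enrichment":
            return folds
        cal = folds[self.calibrator]
        return {c: f / cal for c, f in folds.items()}

    def to_json(self, path: "str | Path") -> None:
        _dump_truth(self, path)

    @classmethod
    def from_json(cls, path: "str | Path") -> "CtTruth":
        data = json.loads(Path(path).read_text())
        data.pop("kind", None)
        for key in ("conditions", "true_folds", "targets"):
            data[key] = tuple(data[key])
        return cls(**data)


def simulate_ct_table(
    seed: int,
    conditions: tuple[str, ...] = ("normoxia", "hypoxia_12h"),
    true_folds: tuple[float, ...] = (5.8, 35.0),
    base_ct: float = 25.0,
    noise_sd: float = 0.2,
    replicates: int = 6,
    design: str = "enrichment",
    chip_target: str = "HBS1_ChIP",
    igg_target: str = "IgG",
    gene_target: str = "b3AR",
    housekeeping_target: str = "Rpl13a",
    calibrator: "str | None" = None,
) -> tuple[pd.DataFrame, CtTruth]:
    """Simulate a replicate Ct table with known true folds.

    For ``design="enrichment"`` each replicate draws an IgG Ct from
    Normal(base_ct, noise_sd) and sets the ChIP Ct to
    ``IgG - log2(true_fold) + Normal(0, noise_sd)``. The defaults mirror the
    study conditions: six replicates, a strong (35-fold) enrichment under
    extended hypoxia against a ~6x weaker normoxic control, and ~0.2-cycle
    instrument noise.

    For ``design="expression"`` the housekeeping Ct plays the reference
    role and ``true_folds`` are expression levels whose ratios to the
    calibrator condition (first condition unless given) are what the
    delta-delta-Ct summary recovers.
    """
    if len(conditions) != len(true_folds):
        raise GenerationError("conditions and true_folds must align")
    if any(f <= 0 for f in true_folds):
        raise GenerationError("true folds must be positive")
    if replicates < 1:
        raise GenerationError("at least one replicate required")
    if design not in ("enrichment", "expression"):
        raise GenerationError(f"unknown design {design!r}")
    if design == "expression" and calibrator is None:
        calibrator = conditions[0]
    if calibrator is not None and calibrator not in conditions:
        raise GenerationError(f"calibrator {calibrator!r} not among conditions")

    rng = np.random.default_rng(seed)
    sample_target, ref_target = (
        (chip_target, igg_target) if design == "enrichment" else (gene_target, housekeeping_target)
    )
    gene_offset = 5.0 if design == "expression" else 0.0  # fixed target-vs-ref Ct gap
    rows = []
    for condition, fold in zip(conditions, true_folds):
        for rep in range(1, replicates + 1):
            ref_ct = rng.normal(base_ct, noise_sd) if noise_sd > 0 else base_ct
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            sample_ct = ref_ct + gene_offset - math.log2(fold) + noise
            sample_id = f"{condition}_s{rep}"
            rows.append((sample_id, condition, sample_target, rep, sample_ct))
            rows.append((sample_id, condition, ref_target, rep, ref_ct))
    table = pd.DataFrame(
        rows, columns=["sample_id", "condition", "target", "replicate", "ct"]
    )
    truth = CtTruth(
        seed=seed,
        design=design,
        conditions=tuple(conditions),
        true_folds=tuple(float(f) for f in true_folds),
        base_ct=base_ct,
        noise_sd=noise_sd,
        replicates=replicates,
        targets=(sample_target, ref_target),
        calibrator=calibrator,
    )
    return table, truth


@dataclass(frozen=True)
class TrajectoryTruth:
    """Ground truth of a simulated trajectory."""

    seed: int
    contact_schedule: tuple[int, ...]
    fluctuation_amplitudes: tuple[float, ...]  # per protein atom, nm
    contact_distance: float = 0.45
    separation_distance: float = 1.5
    cutoff: float = 0.6

    def expected_rmsf(self, n_dna: int) -> np.ndarray:
        """Expected per-atom RMSF (mean-structure reference, even window)."""
        return np.concatenate(
            [np.asarray(self.fluctuation_amplitudes, dtype=float), np.zeros(n_dna)]
        )

    def to_json(self, path: "str | Path") -> None:
        _dump_truth(self, path)

    @classmethod
    def from_json(cls, path: "str | Path") -> "TrajectoryTruth":
        data = json.loads(Path(path).read_text())
        data.pop("kind", None)
        data["contact_schedule"] = tuple(data["contact_schedule"])
        data["fluctuation_amplitudes"] = tuple(data["fluctuation_amplitudes"])
        return cls(**data)


def simulate_trajectory(
    seed: int,
    n_protein: int = 12,
    n_dna: int = 10,
    n_frames: int = 10,
    contact_schedule: "list[int] | None" = None,
    fluctuation_amplitudes: "list[float] | None" = None,
    frame_spacing: "float | None" = None,
) -> tuple[Trajectory, TrajectoryTruth]:
    """Engineer a trajectory with exact per-frame contact counts.

    Protein atom ``k`` and DNA atom ``k`` form a designated pair 0.45 nm
    apart when pair ``k`` is scheduled "in contact" in a frame, and 1.5 nm
    apart otherwise; distinct pairs sit 3 nm apart along x, so the 0.6 nm
    protein-DNA contact count of frame ``t`` is exactly
    ``contact_schedule[t]``. The schedule maximum must not exceed
    ``min(n_protein, n_dna)``.

    The last ``len(fluctuation_amplitudes)`` protein atoms (which must not be
    contact-pair atoms) oscillate along z as +/- amplitude on alternating
    frames, far from all DNA, so their RMSF about the mean structure over any
    even trailing window equals the amplitude exactly; all other atoms are
    static.
    """
    if contact_schedule is None:
        contact_schedule = [min(n_protein, n_dna)] * n_frames
    if len(contact_schedule) != n_frames:
        raise GenerationError(
            f"schedule length {len(contact_schedule)} != {n_frames} frames"
        )
    if any(c < 0 for c in contact_schedule):
        raise GenerationError("contact counts must be non-negative")
    m = max(contact_schedule) if contact_schedule else 0
    if m > min(n_protein, n_dna):
        raise GenerationError(
            f"schedule needs {m} simultaneous pairs but only "
            f"{min(n_protein, n_dna)} protein/DNA pairs exist"
        )
    amplitudes = list(fluctuation_amplitudes or [])
    if m + len(amplitudes) > n_protein:
        raise GenerationError(
            f"{len(amplitudes)} fluctuating atoms do not fit beside {m} contact "
            f"pairs in {n_protein} protein atoms"
        )

    records = [
        AtomRecord("CA", "GLY", k + 1, "A", Moiety.PROTEIN) for k in range(n_protein)
    ] + [AtomRecord("P", "DA", j + 1, "B", Moiety.DNA) for j in range(n_dna)]
    atoms = _atoms_frame(records)

    per_atom_amp = np.zeros(n_protein)
    fluct_start = n_protein - len(amplitudes)
    for i, a in enumerate(amplitudes):
        per_atom_amp[fluct_start + i] = a

    coords = np.zeros((n_frames, n_protein + n_dna, 3))
    for t in range(n_frames):
        for k in range(n_protein):
            y = 0.0 if k < m else 20.0
            z = per_atom_amp[k] * (1.0 if t % 2 == 0 else -1.0)
            coords[t, k] = (3.0 * k, y, z)
        for j in range(n_dna):
            d = 0.45 if j < contact_schedule[t] else 1.5
            coords[t, n_protein + j] = (3.0 * j, d, 0.0)

    truth = TrajectoryTruth(
        seed=seed,
        contact_schedule=tuple(int(c) for c in contact_schedule),
        fluctuation_amplitudes=tuple(float(a) for a in per_atom_amp),
    )
    return Trajectory(atoms, coords, frame_spacing), truth
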