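"""Protein-DNA interface metrics on multi-frame structures.

A "contact" is an atom pair — one atom from each selection, by default
protein vs DNA — whose Euclidean distance is at most a cutoff (0.6 nm by
default, the distance below which amino-acid/nucleotide interactions are
considered effective). Counting is inclusive at the boundary so results are
bit-reproducible; the boundary set has measure zero for real coordinates.
Pair counting is grid-accelerated (k-d trees) and exactly equals the O(n^2)
enumeration.

Trajectory metrics: RMSD between frames (optionally after least-squares
Kabsch superposition) and per-atom / per-residue RMSF over a trailing
window, relative either to the window-mean structure (the standard
definition) or to the window's first frame. No periodic-boundary handling:
coordinates are treated as whole molecules in open space.

All lengths are nm internally; PDB angstroms are converted on read (x0.1)
and on write (x10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Moiety",
    "AtomRecord",
    "Frame",
    "Trajectory",
    "ContactParameters",
    "ContactSeries",
    "StructureError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "count_contacts",
    "contact_series",
    "residue_contact_map",
    "kabsch_rotation",
    "rmsd",
    "rmsf",
]

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common force-field protonation/bond variants
    "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "CYX", "ASH", "GLH", "LYN",
}
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DN"}

ANGSTROM_PER_NM = 10.0


class StructureError(ValueError):
    """Malformed structure file or inconsistent frames."""


class SelectionError(ValueError):
    """Empty or overlapping atom selections."""


class Moiety:
    PROTEIN = "PROTEIN"
    DNA = "DNA"
    OTHER = "OTHER"


def moiety_of(residue_name: str) -> str:
    name = residue_name.strip().upper()
    if name in PROTEIN_RESIDUES:
        return Moiety.PROTEIN
    if name in DNA_RESIDUES:
        return Moiety.DNA
    return Moiety.OTHER


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    residue_name: str
    residue_index: int
    chain: str
    moiety: str


ATOM_COLUMNS = ["atom_name", "residue_name", "residue_index", "chain", "moiety"]


@dataclass(frozen=True)
class Frame:
    """One coordinate set (nm) over a fixed atom table."""

    atoms: pd.DataFrame
    coords: np.ndarray  # (n_atoms, 3), nm

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed atom table (lengths in nm)."""

    atoms: pd.DataFrame
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_spacing: "float | None" = None  # ns per frame, optional

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.atoms):
            raise StructureError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{len(self.atoms)} atoms"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, index: int) -> Frame:
        return Frame(self.atoms, self.coords[index])

    def select(self, moiety: "str | None" = None, chain: "str | None" = None) -> np.ndarray:
        """Indices of atoms matching the given moiety and/or chain."""
        mask = np.ones(len(self.atoms), dtype=bool)
        if moiety is not None:
            mask &= (self.atoms["moiety"] == moiety).to_numpy()
        if chain is not None:
            mask &= (self.atoms["chain"] == chain).to_numpy()
        return np.nonzero(mask)[0]


def _atoms_frame(records: list[AtomRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.atom_name, a.residue_name, a.residue_index, a.chain, a.moiety) for a in records],
        columns=ATOM_COLUMNS,
    )


def read_structure(path: "str | Path", frame_spacing: "float | None" = None) -> Trajectory:
    """Read a (multi-MODEL) PDB file into a trajectory in nm.

    A file without MODEL records is a single frame. Models must all contain
    the same number of atoms; a violation is reported with the offending
    model number, and unparseable ATOM/HETATM lines with their line number.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    atom_tables: list[list[AtomRecord]] = []
    current_coords: list[list[float]] = []
    current_atoms: list[AtomRecord] = []
    model_numbers: list[int] = []
    in_model = False
    saw_model_record = False

    def close_model() -> None:
        nonlocal current_coords, current_atoms
        if current_atoms:
            atom_tables.append(current_atoms)
            frames.append(np.asarray(current_coords, dtype=float) / ANGSTROM_PER_NM)
        current_coords, current_atoms = [], []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                saw_model_record = True
                in_model = True
                try:
                    model_numbers.append(int(line[6:].split()[0]))
                except (IndexError, ValueError):
                    model_numbers.append(len(model_numbers) + 1)
            elif record == "ENDMDL":
                in_model = False
                close_model()
            elif record in ("ATOM", "HETATM"):
                try:
                    atom_name = line[12:16].strip()
                    residue_name = line[17:20].strip()
                    chain = line[21].strip() or "?"
                    residue_index = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise StructureError(
                        f"unparseable ATOM record at line {lineno} of {path}: {exc}"
                    ) from exc
                current_atoms.append(
                    AtomRecord(atom_name, residue_name, residue_index, chain,
                               moiety_of(residue_name))
                )
                current_coords.append([x, y, z])
    close_model()

    if not frames:
        raise StructureError(f"no ATOM records found in {path}")
    if saw_model_record and not model_numbers:
        model_numbers = list(range(1, len(frames) + 1))
    if not model_numbers:
        model_numbers = [1]

    n_atoms = len(atom_tables[0])
    for i, table in enumerate(atom_tables):
        if len(table) != n_atoms:
            model = model_numbers[i] if i < len(model_numbers) else i + 1
            raise StructureError(
                f"model {model} has {len(table)} atoms, expected {n_atoms} "
                f"(all frames must share one atom table)"
            )

    atoms = _atoms_frame(atom_tables[0])
    coords = np.stack(frames)
    return Trajectory(atoms, coords, frame_spacing)


def write_structure(traj: Trajectory, path: "str | Path") -> None:
    """Write a trajectory as a multi-MODEL PDB (coordinates nm -> angstrom)."""
    with open(path, "w") as fh:
        multi = traj.n_frames > 1
        for f in range(traj.n_frames):
            if multi:
                fh.write(f"MODEL     {f + 1:>4d}\n")
            for i, atom in enumerate(traj.atoms.itertuples(index=False), start=1):
                x, y, z = traj.coords[f, i - 1] * ANGSTROM_PER_NM
                name = atom.atom_name if len(atom.atom_name) == 4 else f" {atom.atom_name:<3s}"
                fh.write(
                    f"ATOM  {i:>5d} {name:<4s} {atom.residue_name:<3s} "
                    f"{atom.chain:1s}{atom.residue_index:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


@dataclass(frozen=True)
class ContactParameters:
    """Cutoff (nm) and the two atom selections being paired.

    ``group_a``/``group_b`` are either moiety names (``"PROTEIN"``,
    ``"DNA"``) resolved against the frame's atom table, or explicit index
    arrays.
    """

    cutoff: float = 0.6
    group_a: "str | np.ndarray" = Moiety.PROTEIN
    group_b: "str | np.ndarray" = Moiety.DNA

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be > 0, got {self.cutoff}")


def _resolve_group(frame: Frame, group: "str | np.ndarray", side: str) -> np.ndarray:
    if isinstance(group, str):
        idx = np.nonzero((frame.atoms["moiety"] == group).to_numpy())[0]
    else:
        idx = np.asarray(group, dtype=int)
    if idx.size == 0:
        raise SelectionError(f"empty selection for group_{side}")
    return idx


def _resolve_groups(frame: Frame, params: ContactParameters) -> tuple[np.ndarray, np.ndarray]:
    idx_a = _resolve_group(frame, params.group_a, "a")
    idx_b = _resolve_group(frame, params.group_b, "b")
    if np.intersect1d(idx_a, idx_b).size:
        raise SelectionError("contact groups must be disjoint")
    return idx_a, idx_b


def count_contacts(frame: Frame, params: ContactParameters = ContactParameters()) -> int:
    """Number of cross-group atom pairs within the cutoff (inclusive)."""
    idx_a, idx_b = _resolve_groups(frame, params)
    tree_a = cKDTree(frame.coords[idx_a])
    tree_b = cKDTree(frame.coords[idx_b])
    return int(tree_a.count_neighbors(tree_b, params.cutoff))


@dataclass(frozen=True)
class ContactSeries:
    """Per-frame contact counts plus the mean over a trailing window."""

    per_frame_counts: np.ndarray
    trailing_window: int
    window_mean: float = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.per_frame_counts, dtype=int)
        object.__setattr__(self, "per_frame_counts", counts)
        if not 1 <= self.trailing_window <= len(counts):
            raise ValueError(
                f"trailing window {self.trailing_window} invalid for "
                f"{len(counts)} frames"
            )
        object.__setattr__(
            self, "window_mean", float(counts[-self.trailing_window :].mean())
        )


def contact_series(
    traj: Trajectory,
    params: ContactParameters = ContactParameters(),
    trailing_window: "int | None" = None,
) -> ContactSeries:
    """Contact counts for every frame and their trailing-window mean."""
    if trailing_window is None:
        trailing_window = traj.n_frames
    counts = np.array(
        [count_contacts(traj.frame(f), params) for f in range(traj.n_frames)],
        dtype=int,
    )
    return ContactSeries(counts, trailing_window)


def residue_contact_map(
    frame: Frame, params: ContactParameters = ContactParameters()
) -> pd.DataFrame:
    """Contact counts aggregated by residue on each side of the interface.

    Returns columns ``chain_a, residue_index_a, residue_name_a, chain_b,
    residue_index_b, residue_name_b, contacts``; the column sum of
    ``contacts`` equals :func:`count_contacts` on the same frame.
    """
    idx_a, idx_b = _resolve_groups(frame, params)
    tree_a = cKDTree(frame.coords[idx_a])
    tree_b = cKDTree(frame.coords[idx_b])
    neighbor_lists = tree_a.query_ball_tree(tree_b, params.cutoff)
    atoms = frame.atoms
    counts: dict[tuple, int] = {}
    for local_a, partners in enumerate(neighbor_lists):
        if not partners:
            continue
        a = atoms.iloc[idx_a[local_a]]
        key_a = (a["chain"], int(a["residue_index"]), a["residue_name"])
        for local_b in partners:
            b = atoms.iloc[idx_b[local_b]]
            key = key_a + (b["chain"], int(b["residue_index"]), b["residue_name"])
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "chain_a": k[0],
            "residue_index_a": k[1],
            "residue_name_a": k[2],
            "chain_b": k[3],
            "residue_index_b": k[4],
            "residue_name_b": k[5],
            "contacts": v,
        }
        for k, v in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chain_a", "residue_index_a", "residue_name_a",
            "chain_b", "residue_index_b", "residue_name_b", "contacts",
        ],
    )


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal least-squares rotation aligning centered ``mobile`` onto
    centered ``reference`` (Kabsch algorithm, reflection-corrected)."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    return vt.T @ correction @ u.T


def _frame_coords(frame: "Frame | np.ndarray") -> np.ndarray:
    return frame.coords if isinstance(frame, Frame) else np.asarray(frame, dtype=float)


def rmsd(
    frame: "Frame | np.ndarray",
    reference_frame: "Frame | np.ndarray",
    selection: "np.ndarray | None" = None,
    superpose: bool = True,
) -> float:
    """Root-mean-square deviation between two frames, in nm.

    With ``superpose`` the optimal rigid rotation+translation is applied
    first, making the result invariant under rigid motions; without it, the
    raw displacement RMS is returned.
    """
    a = _frame_coords(frame)
    b = _frame_coords(reference_frame)
    if selection is not None:
        a = a[np.asarray(selection, dtype=int)]
        b = b[np.asarray(selection, dtype=int)]
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise SelectionError(
            f"mismatched selections: shapes {a.shape} vs {b.shape}"
        )
    if len(a) == 0:
        raise SelectionError("empty selection")
    if superpose:
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        a = a @ kabsch_rotation(a, b).T
    diff = a - b
    return float(np.sqrt((diff * diff).sum() / len(a)))


def rmsf(
    traj: Trajectory,
    trailing_window: "int | None" = None,
    reference: str = "mean_structure",
    per: str = "atom",
    selection: "np.ndarray | None" = None,
):
    """Per-atom (or per-residue) RMS fluctuation over a trailing window, nm.

    ``reference="mean_structure"`` (default) measures displacement from the
    window-mean coordinates — the standard fluctuation definition;
    ``reference="first_frame"`` measures it from the window's first frame.
    No superposition is applied: frames are assumed already aligned (the
    synthetic generator produces them that way; align externally otherwise).

    Per-residue values are means over each residue's atoms and are returned
    as a DataFrame (``chain, residue_index, residue_name, rmsf``); per-atom
    values as an ndarray ordered like the atom table.
    """
    if trailing_window is None:
        trailing_window = traj.n_frames
    if trailing_window < 2:
        raise ValueError(f"trailing window must cover >= 2 frames, got {trailing_window}")
    if trailing_window > traj.n_frames:
        raise ValueError(
            f"trailing window {trailing_window} exceeds {traj.n_frames} frames"
        )
    window = traj.coords[-trailing_window:]
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        window = window[:, sel]
        atoms = traj.atoms.iloc[sel].reset_index(drop=True)
    else:
        atoms = traj.atoms
    if reference == "mean_structure":
        ref = window.mean(axis=0)
    elif reference == "first_frame":
        ref = window[0]
    else:
        raise ValueError(
            f"reference must be 'mean_structure' or 'first_frame', got {reference!r}"
        )
    sq = ((window - ref) ** 2).sum(axis=2)  # (frames, atoms)
    per_atom = np.sqrt(sq.mean(axis=0))
    if per == "atom":
        return per_atom
    if per != "residue":
        raise ValueError(f"per must be 'atom' or 'residue', got {per!r}")
    table = atoms.copy()
    table["rmsf"] = per_atom
    grouped = (
        table.groupby(["chain", "residue_index", "residue_name"], sort=True)["rmsf"]
        .mean()
        .reset_index()
    )
    return grouped
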