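"""PDB reading, contact counting, residue maps, RMSD and RMSF."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from hbskit.structure import (
    ContactParameters,
    ContactSeries,
    Frame,
    Moiety,
    SelectionError,
    StructureError,
    Trajectory,
    contact_series,
    count_contacts,
    kabsch_rotation,
    read_structure,
    residue_contact_map,
    rmsd,
    rmsf,
    write_structure,
)
from hbskit.synthetic import simulate_trajectory

SINGLE_FRAME_PDB = """\
ATOM      1  CA  ASP A  24      10.000  10.000  10.000  1.00  0.00
ATOM      2  P   DA  C  10      15.000  10.000  10.000  1.00  0.00
END
"""


def brute_force_contacts(coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float) -> int:
    """O(n^2) oracle: enumerate every cross pair."""
    count = 0
    for a in coords_a:
        for b in coords_b:
            if np.sqrt(((a - b) ** 2).sum()) <= cutoff:
                count += 1
    return count


def random_frame(seed: int, n_a: int = 50, n_b: int = 50, box: float = 3.0) -> Frame:
    rng = np.random.default_rng(seed)
    atoms = pd.DataFrame(
        {
            "atom_name": ["CA"] * n_a + ["P"] * n_b,
            "residue_name": ["GLY"] * n_a + ["DA"] * n_b,
            "residue_index": list(range(1, n_a + 1)) + list(range(1, n_b + 1)),
            "chain": ["A"] * n_a + ["B"] * n_b,
            "moiety": [Moiety.PROTEIN] * n_a + [Moiety.DNA] * n_b,
        }
    )
    return Frame(atoms, rng.uniform(0, box, size=(n_a + n_b, 3)))


class TestReadStructure:
    def test_single_frame_two_atoms(self, pdb_file):
        traj = read_structure(pdb_file(SINGLE_FRAME_PDB))
        assert traj.n_frames == 1
        assert traj.n_atoms == 2
        # angstrom -> nm
        assert traj.coords[0, 0] == pytest.approx([1.0, 1.0, 1.0])

    def test_moiety_assignment(self, pdb_file):
        traj = read_structure(pdb_file(SINGLE_FRAME_PDB))
        assert list(traj.atoms["moiety"]) == [Moiety.PROTEIN, Moiety.DNA]

    def test_atom_count_mismatch_names_model(self, pdb_file):
        text = (
            "MODEL        1\n"
            "ATOM      1  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00\n"
            "ATOM      2  CA  GLY A   2       2.000   0.000   0.000  1.00  0.00\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00\n"
            "ENDMDL\n"
            "MODEL        3\n"
            "ATOM      1  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00\n"
            "ATOM      2  CA  GLY A   2       2.000   0.000   0.000  1.00  0.00\n"
            "ENDMDL\n"
        )
        with pytest.raises(StructureError, match="model 2"):
            read_structure(pdb_file(text))

    def test_unparseable_atom_line_reports_line_number(self, pdb_file):
        text = "ATOM      1  CA  GLY A   1       1.000   x.000   0.000  1.00  0.00\n"
        with pytest.raises(StructureError, match="line 1"):
            read_structure(pdb_file(text))

    def test_write_read_round_trip(self, tmp_path):
        traj, _ = simulate_trajectory(3, n_frames=4, contact_schedule=[2, 3, 1, 0])
        path = tmp_path / "t.pdb"
        write_structure(traj, path)
        back = read_structure(path)
        assert back.n_frames == traj.n_frames
        assert np.allclose(back.coords, traj.coords, atol=1e-4)  # 0.001 A rounding
        assert list(back.atoms["moiety"]) == list(traj.atoms["moiety"])

    def test_matches_mdanalysis_parsing(self, tmp_path):
        """Independent reference parser agrees on coordinates (A vs nm)."""
        mda = pytest.importorskip("MDAnalysis")
        traj, _ = simulate_trajectory(4, n_frames=3)
        path = tmp_path / "t.pdb"
        write_structure(traj, path)
        ours = read_structure(path)
        universe = mda.Universe(str(path))
        assert len(universe.atoms) == ours.n_atoms
        for i, ts in enumerate(universe.trajectory):
            assert np.allclose(ts.positions * 0.1, ours.coords[i], atol=1e-4)


class TestCountContacts:
    def _two_atom_frame(self, separation_nm: float) -> Frame:
        atoms = pd.DataFrame(
            {
                "atom_name": ["CA", "P"],
                "residue_name": ["ASP", "DT"],
                "residue_index": [24, 10],
                "chain": ["A", "C"],
                "moiety": [Moiety.PROTEIN, Moiety.DNA],
            }
        )
        coords = np.array([[0.0, 0.0, 0.0], [separation_nm, 0.0, 0.0]])
        return Frame(atoms, coords)

    def test_pair_inside_cutoff(self):
        assert count_contacts(self._two_atom_frame(0.5)) == 1

    def test_pair_outside_cutoff(self):
        assert count_contacts(self._two_atom_frame(0.7)) == 0

    def test_inclusive_boundary(self):
        assert count_contacts(self._two_atom_frame(0.6)) == 1

    def test_grid_equals_brute_force_seed7(self):
        frame = random_frame(7)
        expected = brute_force_contacts(frame.coords[:50], frame.coords[50:], 0.6)
        assert count_contacts(frame) == expected

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("box", [1.0, 3.0, 10.0])
    def test_grid_equals_brute_force_sparse_and_dense(self, seed, box):
        frame = random_frame(seed, n_a=30, n_b=30, box=box)
        expected = brute_force_contacts(frame.coords[:30], frame.coords[30:], 0.6)
        assert count_contacts(frame) == expected

    def test_monotone_in_cutoff_and_symmetric(self):
        frame = random_frame(11)
        counts = [
            count_contacts(frame, ContactParameters(cutoff=c))
            for c in (0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert counts == sorted(counts)
        swapped = ContactParameters(group_a=Moiety.DNA, group_b=Moiety.PROTEIN)
        assert count_contacts(frame, swapped) == count_contacts(frame)

    def test_empty_group_rejected(self):
        frame = random_frame(1)
        only_protein = Frame(frame.atoms[frame.atoms["moiety"] == Moiety.PROTEIN].reset_index(drop=True),
                             frame.coords[:50])
        with pytest.raises(SelectionError, match="empty"):
            count_contacts(only_protein)

    def test_overlapping_groups_rejected(self):
        frame = random_frame(2)
        params = ContactParameters(group_a=np.arange(10), group_b=np.arange(5, 15))
        with pytest.raises(SelectionError, match="disjoint"):
            count_contacts(frame, params)


class TestContactSeries:
    def test_constant_geometry(self):
        traj, _ = simulate_trajectory(0, n_frames=10, contact_schedule=[4] * 10)
        series = contact_series(traj, trailing_window=10)
        assert (series.per_frame_counts == 4).all()
        assert series.window_mean == 4.0

    def test_engineered_schedule_and_trailing_mean(self):
        traj, truth = simulate_trajectory(1, n_frames=5, contact_schedule=[5, 5, 5, 9, 9])
        series = contact_series(traj, trailing_window=2)
        assert list(series.per_frame_counts) == list(truth.contact_schedule)
        assert series.window_mean == 9.0

    def test_window_equal_to_all_frames(self):
        traj, _ = simulate_trajectory(2, n_frames=4, contact_schedule=[1, 2, 3, 4])
        series = contact_series(traj)
        assert series.window_mean == 2.5

    def test_window_mean_bounded_by_windowed_counts(self):
        series = ContactSeries(np.array([5, 5, 5, 9, 9]), trailing_window=3)
        windowed = series.per_frame_counts[-3:]
        assert windowed.min() <= series.window_mean <= windowed.max()

    def test_oversized_window_rejected(self):
        traj, _ = simulate_trajectory(3, n_frames=3, contact_schedule=[1, 1, 1])
        with pytest.raises(ValueError, match="trailing window"):
            contact_series(traj, trailing_window=4)


class TestResidueContactMap:
    def test_single_pair_row(self, pdb_file):
        traj = read_structure(pdb_file(SINGLE_FRAME_PDB))
        table = residue_contact_map(traj.frame(0))
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["residue_name_a"], row["residue_index_a"]) == ("ASP", 24)
        assert (row["residue_name_b"], row["residue_index_b"]) == ("DA", 10)
        assert row["contacts"] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_total_equals_count_contacts(self, seed):
        frame = random_frame(seed)
        table = residue_contact_map(frame)
        assert table["contacts"].sum() == count_contacts(frame)

    def test_empty_when_no_contacts(self):
        frame = random_frame(0)
        table = residue_contact_map(frame, ContactParameters(cutoff=1e-6))
        assert len(table) == 0


class TestRmsd:
    def test_identical_frames_zero(self):
        frame = random_frame(0)
        assert rmsd(frame, frame, superpose=False) == 0.0
        assert rmsd(frame, frame, superpose=True) < 1e-12  # SVD float noise

    def test_rigid_motion_invariance(self):
        coords = np.random.default_rng(5).normal(size=(30, 3))
        rotation = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = coords @ rotation.T + np.array([1.0, -2.0, 0.5])
        assert rmsd(moved, coords, superpose=True) < 1e-9
        assert rmsd(moved, coords, superpose=False) > 0.1

    def test_single_displacement_closed_form(self):
        a = np.zeros((4, 3))
        b = a.copy()
        b[0, 0] = 0.2
        assert rmsd(a, b, superpose=False) == pytest.approx(0.2 / 2.0)  # d / sqrt(N)

    @pytest.mark.parametrize("seed", range(5))
    def test_superposed_never_exceeds_raw(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(20, 3))
        assert rmsd(a, b, superpose=True) <= rmsd(a, b, superpose=False) + 1e-12

    def test_kabsch_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(25, 3))
        b = rng.normal(size=(25, 3))
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        _, rssd = Rotation.align_vectors(bc, ac)
        assert rmsd(a, b, superpose=True) == pytest.approx(rssd / np.sqrt(25), rel=1e-9)

    def test_mismatched_selection_rejected(self):
        with pytest.raises(SelectionError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


def brute_force_rmsf(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Direct per-atom loop over frames."""
    n_frames, n_atoms, _ = coords.shape
    out = np.zeros(n_atoms)
    for i in range(n_atoms):
        total = 0.0
        for t in range(n_frames):
            d = coords[t, i] - reference[i]
            total += (d * d).sum()
        out[i] = np.sqrt(total / n_frames)
    return out


class TestRmsf:
    def test_static_trajectory_all_zero(self):
        traj, _ = simulate_trajectory(0, n_frames=6, contact_schedule=[3] * 6)
        assert np.allclose(rmsf(traj), 0.0)

    def test_oscillator_amplitude_with_mean_reference(self):
        traj, truth = simulate_trajectory(
            1, n_frames=8, contact_schedule=[2] * 8, fluctuation_amplitudes=[0.05, 0.12]
        )
        values = rmsf(traj, reference="mean_structure")
        expected = truth.expected_rmsf(n_dna=10)
        assert np.allclose(values, expected)

    def test_first_frame_reference_matches_brute_force(self):
        traj, _ = simulate_trajectory(
            2, n_frames=6, contact_schedule=[2] * 6, fluctuation_amplitudes=[0.07]
        )
        window = 4
        values = rmsf(traj, trailing_window=window, reference="first_frame")
        expected = brute_force_rmsf(traj.coords[-window:], traj.coords[-window])
        assert np.allclose(values, expected)
        # +/-a oscillator whose window starts at an extreme: half the frames
        # sit 2a away -> RMSF = a * sqrt(2)
        osc = traj.atoms.index[traj.atoms["atom_name"] == "CA"][-1]
        assert values[osc] == pytest.approx(0.07 * np.sqrt(2))

    def test_per_residue_aggregation(self):
        traj, _ = simulate_trajectory(
            3, n_frames=4, contact_schedule=[1] * 4, fluctuation_amplitudes=[0.1]
        )
        table = rmsf(traj, per="residue")
        assert set(table.columns) == {"chain", "residue_index", "residue_name", "rmsf"}
        fluct = table[(table["chain"] == "A") & (table["residue_index"] == 12)]
        assert fluct["rmsf"].iloc[0] == pytest.approx(0.1)

    def test_too_small_window_rejected(self):
        traj, _ = simulate_trajectory(4, n_frames=5, contact_schedule=[1] * 5)
        with pytest.raises(ValueError, match=">= 2"):
            rmsf(traj, trailing_window=1)
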