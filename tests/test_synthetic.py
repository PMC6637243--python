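import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from puckertools import (
    MockComplexSpec,
    PuckerPathSpec,
    build_mock_complex,
    classify,
    cremer_pople,
    frames_from_structure,
    inverse_cp,
    occupancy,
    per_frame_conformers,
    rmsd_series,
    simulate_pucker_path,
)
from puckertools import io as ptio


class TestInverseCP:
    def test_zero_amplitude_is_planar_hexagon(self):
        ring = inverse_cp(0.0, 37.0, 123.0)
        assert np.allclose(ring.positions[:, 2], 0.0)
        sides = np.linalg.norm(
            ring.positions - np.roll(ring.positions, -1, axis=0), axis=1)
        assert np.allclose(sides, 1.54, atol=1e-12)

    def test_pure_chair_alternates(self):
        ring = inverse_cp(0.6, 0.0, 0.0)
        expected = (-1.0) ** np.arange(6) * 0.6 / math.sqrt(6)
        assert np.allclose(ring.positions[:, 2], expected, atol=1e-12)

    def test_round_trip_all_38(self, library):
        for c in library:
            p = cremer_pople(inverse_cp(0.6, c.theta_ref, c.phi_ref))
            assert classify(p, library).conformer == c.label

    @given(q_amp=st.floats(0.2, 0.8), theta=st.floats(0, 180),
           phi=st.floats(0, 360))
    def test_bond_lengths_within_ten_percent(self, q_amp, theta, phi):
        ring = inverse_cp(q_amp, theta, phi)
        sides = np.linalg.norm(
            ring.positions - np.roll(ring.positions, -1, axis=0), axis=1)
        assert np.all(np.abs(sides - 1.54) / 1.54 < 0.10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            inverse_cp(-0.1, 0, 0)
        with pytest.raises(ValueError):
            inverse_cp(2.0, 0, 0)
        with pytest.raises(ValueError):
            inverse_cp(0.6, 0, 0, bond_length=0.0)


class TestSimulatePath:
    def test_single_waypoint_zero_noise_is_constant(self):
        spec = PuckerPathSpec(waypoints=("4C1",), dwell_fractions=(1.0,),
                              n_frames=20, angular_noise_sigma=0.0,
                              q_noise_sigma=0.0, seed=0)
        path = simulate_pucker_path(spec)
        first = path.trajectory.frames[0].positions
        for f in path.trajectory.frames:
            assert np.allclose(f.positions, first, atol=1e-12)

    def test_dwell_fractions_recovered_within_3se(self):
        spec = PuckerPathSpec(waypoints=("4C1", "1S3"),
                              dwell_fractions=(0.9, 0.1),
                              n_frames=500, angular_noise_sigma=3.0, seed=42)
        path = simulate_pucker_path(spec)
        table = occupancy(per_frame_conformers(path.trajectory))
        for label, p in (("4C1", 0.9), ("1S3", 0.1)):
            se = 100 * math.sqrt(p * (1 - p) / 500)
            assert abs(table.get(label) - 100 * p) <= 3 * se

    def test_same_seed_reproduces_coordinates(self):
        spec = PuckerPathSpec(waypoints=("4C1", "1,4B"),
                              dwell_fractions=(0.7, 0.3), n_frames=30, seed=9)
        a = simulate_pucker_path(spec)
        b = simulate_pucker_path(spec)
        for fa, fb in zip(a.trajectory.frames, b.trajectory.frames):
            assert np.array_equal(fa.positions, fb.positions)

    def test_ground_truth_labels_cover_all_frames(self):
        spec = PuckerPathSpec(waypoints=("4C1", "1S5"),
                              dwell_fractions=(0.5, 0.5), n_frames=21, seed=1)
        path = simulate_pucker_path(spec)
        assert len(path.intended_conformers) == 21
        assert set(path.intended_conformers) == {"4C1", "1S5"}
        assert path.intended_conformers.count("4C1") in (10, 11)

    def test_explicit_coordinate_waypoints(self):
        spec = PuckerPathSpec(waypoints=((0.6, 90.0, 210.0),),
                              dwell_fractions=(1.0,), n_frames=5,
                              angular_noise_sigma=0.0, q_noise_sigma=0.0,
                              seed=0)
        path = simulate_pucker_path(spec)
        p = cremer_pople(path.trajectory.frames[0])
        assert p.theta == pytest.approx(90.0, abs=1e-9)
        assert p.phi == pytest.approx(210.0, abs=1e-9)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            PuckerPathSpec(waypoints=("4C1", "1S3"),
                           dwell_fractions=(0.5, 0.4))
        with pytest.raises(ValueError):
            PuckerPathSpec(waypoints=("4C1",), dwell_fractions=(1.0,),
                           n_frames=0)
        with pytest.raises(ValueError):
            PuckerPathSpec(waypoints=(), dwell_fractions=())


class TestMockComplex:
    def test_rigid_everything_yields_zero_profile(self):
        spec = MockComplexSpec(
            n_protein_residues=6,
            pucker_spec=PuckerPathSpec(waypoints=("4C1",),
                                       dwell_fractions=(1.0,), n_frames=6,
                                       angular_noise_sigma=0.0,
                                       q_noise_sigma=0.0, seed=0),
            ligand_subsites=(("-1", True), ("+1", True)),
            jitter_sigma=0.0, seed=0)
        mock = build_mock_complex(spec)
        profile = rmsd_series(frames_from_structure(mock.structure),
                              mock.subsite_map)
        for series in profile.series.values():
            assert np.max(series) < 1e-6

    def test_puckering_minus1_exceeds_rigid_plus1(self):
        spec = MockComplexSpec(
            n_protein_residues=6,
            pucker_spec=PuckerPathSpec(waypoints=("4C1", "1S3"),
                                       dwell_fractions=(0.5, 0.5),
                                       n_frames=30, seed=5),
            seed=5)
        mock = build_mock_complex(spec)
        profile = rmsd_series(frames_from_structure(mock.structure),
                              mock.subsite_map)
        assert profile.mean("-1") > profile.mean("+1")

    def test_subsite_map_round_trips_through_tsv(self, tmp_path):
        spec = MockComplexSpec(
            n_protein_residues=4,
            ligand_subsites=(("-1", False), ("+1", True), ("+2", True),
                             ("+3", True), ("+2'", True)),
            pucker_spec=PuckerPathSpec(waypoints=("4C1",),
                                       dwell_fractions=(1.0,), n_frames=3,
                                       seed=0),
            seed=0)
        mock = build_mock_complex(spec)
        path = tmp_path / "subsites.tsv"
        ptio.write_subsite_map(mock.subsite_map, path)
        assert ptio.read_subsite_map(path) == mock.subsite_map

    def test_byte_identical_pdb_for_same_seed(self, tmp_path):
        spec = MockComplexSpec(
            n_protein_residues=5,
            pucker_spec=PuckerPathSpec(waypoints=("4C1", "B2,5"),
                                       dwell_fractions=(0.6, 0.4),
                                       n_frames=8, seed=17),
            seed=17)
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        ptio.write_multimodel_pdb(build_mock_complex(spec).structure, p1)
        ptio.write_multimodel_pdb(build_mock_complex(spec).structure, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_no_hydrogens_generated(self):
        mock = build_mock_complex(MockComplexSpec(
            n_protein_residues=4,
            pucker_spec=PuckerPathSpec(waypoints=("4C1",),
                                       dwell_fractions=(1.0,), n_frames=2,
                                       seed=0),
            seed=0))
        assert not np.any(np.asarray(mock.structure.element) == "H")

    def test_requires_exactly_one_minus1(self):
        with pytest.raises(ValueError, match="-1 subsite"):
            MockComplexSpec(ligand_subsites=(("+1", True), ("+2", True)))
        with pytest.raises(ValueError):
            MockComplexSpec(ligand_subsites=(("-1", False), ("-1", False)))


def test_full_stack_round_trip_gh42_style_mixture(tmp_path, library):
    """Write a 5-equatorial-conformer mixture to PDB, re-read, and recover
    the programmed dwell fractions within 3 binomial SE."""
    waypoints = ("4C1", "B3,O", "1S3", "1,4B", "1S5", "B2,5")
    dwell = (0.70, 0.05, 0.05, 0.06, 0.08, 0.06)
    spec = PuckerPathSpec(waypoints=waypoints, dwell_fractions=dwell,
                          n_frames=600, angular_noise_sigma=2.5, seed=33)
    path = simulate_pucker_path(spec)
    pdb = tmp_path / "mix.pdb"
    ptio.write_multimodel_pdb(ptio.trajectory_to_structure(path.trajectory),
                              pdb)
    traj = ptio.extract_ring_trajectory(ptio.read_multimodel_pdb(pdb))
    table = occupancy(per_frame_conformers(traj))
    for label, p in zip(waypoints, dwell):
        se = 100 * math.sqrt(p * (1 - p) / 600)
        assert abs(table.get(label) - 100 * p) <= 3 * se, label
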