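import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_min_rmsd
from conftest import rigid_transform
from kitcd import synthetic
from kitcd.core import ALL, CA, AtomSelection, Trajectory, make_ca_structure
from kitcd.geometry import (
    MetricSeries,
    d_series,
    end_to_end_distance,
    kabsch_fit,
    radius_of_gyration,
    ramachandran_fraction,
    rmsd100,
    rmsd_series,
    rmsf,
)


class TestKabsch:
    def test_self_fit_is_identity(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        sup = kabsch_fit(x, x)
        assert sup.rmsd < 1e-10
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rigid_invariance(self, seed):
        x = np.random.default_rng(seed).normal(size=(8, 3))
        moved = rigid_transform(x, seed=seed)
        sup = kabsch_fit(moved, x)
        assert sup.rmsd < 1e-8
        np.testing.assert_allclose(sup.transform(moved), x, atol=1e-7)

    def test_rotations_are_proper(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            sup = kabsch_fit(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
            assert abs(np.linalg.det(sup.rotation) - 1.0) < 1e-8
            np.testing.assert_allclose(
                sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-8
            )

    def test_symmetry_of_optimal_rmsd(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        assert kabsch_fit(a, b).rmsd == pytest.approx(kabsch_fit(b, a).rmsd, abs=1e-8)

    def test_matches_rotation_space_brute_force(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(4, 3))
        noisy = rigid_transform(base, seed=7) + rng.normal(scale=0.3, size=(4, 3))
        ours = kabsch_fit(noisy, base).rmsd
        oracle = brute_force_min_rmsd(noisy, base)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_fit(line, line + 1.0)


class TestRmsdSeries:
    def test_constant_trajectory_is_zero(self, bead_protein):
        structure, _ = bead_protein
        traj = Trajectory(np.repeat(structure.coords[None], 5, axis=0), structure)
        series = rmsd_series(traj, CA)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-7)

    def test_rigid_motion_only_is_zero(self, bead_protein):
        structure, _ = bead_protein
        frames = np.stack(
            [rigid_transform(structure.coords, seed=s) for s in range(4)]
        )
        traj = Trajectory(frames, structure)
        series = rmsd_series(traj, CA)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-6)

    def test_two_frame_displacement_matches_hand_formula(self):
        coords = np.array(
            [[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 3.8], [5, 5, 5]]
        )
        structure = make_ca_structure(coords)
        moved = coords.copy()
        # displace one atom without any net rigid component removable by a
        # fit on the displaced frame: compare against the optimal-fit value
        moved[4] += [0.0, 0.0, 1.0]
        traj = Trajectory(np.stack([coords, moved]), structure)
        series = rmsd_series(traj, CA)
        sup = kabsch_fit(moved, coords)
        expected = np.sqrt(np.mean(np.sum((sup.transform(moved) - coords) ** 2, axis=1)))
        assert series.values[1] == pytest.approx(expected, abs=1e-10)
        # and the unfitted formula bounds it from above
        assert series.values[1] <= np.sqrt(1.0 / 5) + 1e-10


class TestRmsf:
    def test_constant_trajectory_zero(self, bead_protein):
        structure, _ = bead_protein
        traj = Trajectory(np.repeat(structure.coords[None], 4, axis=0), structure)
        np.testing.assert_allclose(rmsf(traj, CA), 0.0, atol=1e-8)

    def test_single_oscillating_atom_closed_form(self):
        rng = np.random.default_rng(8)
        base = rng.normal(scale=5.0, size=(12, 3))
        structure = make_ca_structure(base)
        amp = 0.7
        frames = []
        for sign in (1, -1) * 5:
            f = base.copy()
            f[0, 0] += sign * amp
            frames.append(f)
        traj = Trajectory(np.stack(frames), structure)
        # fit on the static atoms so no rigid component leaks in
        static = AtomSelection(atom_names={"CA"}, first_residue=2)
        values = rmsf(traj, CA, fit_region=static)
        assert values[0] == pytest.approx(amp, abs=1e-8)
        np.testing.assert_allclose(values[1:], 0.0, atol=1e-8)

    def test_planted_variance_recovery(self, gaussian_traj):
        traj, truth, _ = gaussian_traj
        values = rmsf(traj, ALL)
        expected = np.sqrt(truth["per_atom_msf"])
        rel = np.abs(values - expected) / np.maximum(expected, 1e-12)
        assert np.max(rel) < 0.05

    def test_burn_in_must_leave_frames(self, gaussian_traj):
        traj, _, _ = gaussian_traj
        with pytest.raises(ValueError):
            rmsf(traj, CA, burn_in=traj.n_frames)


class TestRadiusOfGyration:
    def test_two_equal_masses(self):
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(1.0)

    def test_unit_square(self):
        square = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert radius_of_gyration(square) == pytest.approx(np.sqrt(0.5))

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(deadline=None, max_examples=25)
    def test_homogeneity_under_scaling(self, scale):
        coords = np.random.default_rng(9).normal(size=(20, 3))
        rg = radius_of_gyration(coords)
        assert radius_of_gyration(coords * scale) == pytest.approx(
            scale * rg, rel=1e-9
        )

    def test_translation_invariance(self):
        coords = np.random.default_rng(10).normal(size=(15, 3))
        assert radius_of_gyration(coords + 100.0) == pytest.approx(
            radius_of_gyration(coords), abs=1e-8
        )

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.ones((2, 3)), masses=np.array([1.0, 0.0]))


class TestRmsd100:
    @given(st.floats(min_value=0.0, max_value=50.0))
    @settings(deadline=None, max_examples=25)
    def test_identity_at_100_residues(self, x):
        assert rmsd100(x, 100) == x

    def test_hand_evaluated_example(self):
        assert rmsd100(2.0, 400) == pytest.approx(2.0 / (1 + np.log(2.0)), abs=1e-9)

    def test_monotone_decreasing_above_100(self):
        values = [rmsd100(3.0, n) for n in (100, 150, 200, 400, 800)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_small_domains_rejected(self):
        with pytest.raises(ValueError):
            rmsd100(1.0, 13)


class TestEndToEnd:
    def test_hand_placed_pair(self, bead_protein):
        _, scheme = bead_protein
        res_a, res_b = scheme.reference_pair
        n = 40
        coords = np.random.default_rng(11).normal(size=(n, 3))
        coords[res_a - 1] = [0, 0, 0]
        coords[res_b - 1] = [0, 0, 9.9]
        structure = make_ca_structure(coords)
        assert end_to_end_distance(structure, scheme) == pytest.approx(9.9)

    def test_rigid_invariance(self, bead_protein):
        structure, scheme = bead_protein
        d0 = end_to_end_distance(structure, scheme)
        moved = structure.with_coords(rigid_transform(structure.coords, seed=12))
        assert end_to_end_distance(moved, scheme) == pytest.approx(d0, abs=1e-5)

    def test_missing_residue_named_in_error(self, bead_protein):
        structure, scheme = bead_protein
        trimmed = make_ca_structure(structure.coords[:5])
        with pytest.raises(ValueError, match=str(scheme.reference_pair[0])):
            end_to_end_distance(trimmed, scheme)

    def test_d_series_tracks_frames(self, bead_protein):
        structure, scheme = bead_protein
        frames = np.repeat(structure.coords[None], 3, axis=0)
        series = d_series(Trajectory(frames, structure), scheme)
        d0 = end_to_end_distance(structure, scheme)
        np.testing.assert_allclose(series.values, d0, atol=1e-5)


class TestRamachandran:
    def test_ideal_helix_fully_allowed(self, ideal_helix_12):
        assert ramachandran_fraction(ideal_helix_12) == pytest.approx(1.0)

    def test_disallowed_conformation_counted_outside(self):
        # phi=+60, psi=-60 on non-Gly residues is outside the allowed map
        s = synthetic.build_peptide_backbone([(60.0, -60.0)] * 5)
        assert ramachandran_fraction(s) == pytest.approx(0.0)

    def test_fraction_bounded(self, antiparallel_sheet):
        f = ramachandran_fraction(antiparallel_sheet)
        assert 0.0 <= f <= 1.0

    def test_gly_pro_only_region_is_error(self):
        helix = synthetic.ideal_helix(6)
        gly = helix.atoms.copy()
        gly.res_name = np.full(gly.array_length(), "GLY")
        from kitcd.core import Structure

        with pytest.raises(ValueError):
            ramachandran_fraction(Structure(gly))


def test_metric_series_summary_string():
    series = MetricSeries(values=np.array([12.4, 12.6, 12.8]))
    assert series.summary_string() == "12.6 (2)"
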