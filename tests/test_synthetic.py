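import numpy as np
import pytest
from biotite.structure import dihedral_backbone
from scipy.spatial.distance import pdist

from kitcd.synthetic import (
    CA_SPACING,
    MIN_NONCONSECUTIVE,
    CovarianceSpec,
    EnsembleSpec,
    build_peptide_backbone,
    generate_bead_protein,
    generate_candidate_ensemble,
    generate_gaussian_trajectory,
    generate_transition_trajectory,
    ideal_helix,
    ideal_strand,
    random_covariance_spec,
    rigid_body_subspace,
)


class TestBeadProtein:
    def test_bond_lengths_and_self_avoidance(self, bead_protein):
        structure, _ = bead_protein
        coords = structure.coords
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        np.testing.assert_allclose(steps, CA_SPACING, atol=1e-6)
        d = pdist(coords)
        # all non-consecutive pairs respect the avoidance floor
        n = len(coords)
        idx = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
        nonconsec = idx[:, 1] - idx[:, 0] > 1
        assert d[nonconsec].min() >= MIN_NONCONSECUTIVE - 1e-9

    def test_scheme_matches_domain_sizes(self, bead_protein):
        _, scheme = bead_protein
        assert scheme["N-lobe"] == (1, 10)
        assert scheme["KID"] == (11, 30)
        assert scheme["C-lobe"] == (31, 40)
        assert scheme.reference_pair == (10, 31)

    def test_seed_reproducibility(self):
        s1, _ = generate_bead_protein((5, 5), seed=3)
        s2, _ = generate_bead_protein((5, 5), seed=3)
        np.testing.assert_array_equal(s1.coords, s2.coords)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            generate_bead_protein((5, 0, 5), seed=0)


class TestCovarianceSpec:
    def test_covariance_reconstruction(self):
        spec = random_covariance_spec(10, np.array([4.0, 1.0]), seed=0)
        c = spec.covariance
        np.testing.assert_allclose(c, c.T)
        eigs = np.sort(np.linalg.eigvalsh(c))[::-1]
        np.testing.assert_allclose(eigs[:2], [4.0, 1.0], atol=1e-10)
        np.testing.assert_allclose(eigs[2:], 0.0, atol=1e-10)

    def test_non_orthonormal_directions_rejected(self):
        bad = np.ones((2, 6))
        with pytest.raises(ValueError):
            CovarianceSpec(eigenvalues=np.array([1.0, 1.0]), directions=bad)

    def test_negative_eigenvalues_rejected(self):
        d = np.eye(2, 6)
        with pytest.raises(ValueError):
            CovarianceSpec(eigenvalues=np.array([1.0, -1.0]), directions=d)

    def test_rigid_subspace_orthonormal_and_rigid(self, bead_protein):
        structure, _ = bead_protein
        basis = rigid_body_subspace(structure.coords)
        assert basis.shape == (6, 3 * structure.n_atoms)
        np.testing.assert_allclose(basis @ basis.T, np.eye(6), atol=1e-10)
        # translation rows: a uniform x-shift lies in the span
        shift = np.tile([1.0, 0.0, 0.0], structure.n_atoms)
        proj = basis.T @ (basis @ shift)
        np.testing.assert_allclose(proj, shift, atol=1e-8)

    def test_planted_directions_orthogonal_to_rigid_subspace(self, bead_protein):
        structure, _ = bead_protein
        spec = random_covariance_spec(
            structure.n_atoms, np.array([2.0, 1.0]), seed=5, structure=structure
        )
        basis = rigid_body_subspace(structure.coords)
        overlap = basis @ spec.directions.T
        np.testing.assert_allclose(overlap, 0.0, atol=1e-8)


class TestGaussianTrajectory:
    def test_truth_is_self_consistent(self, gaussian_traj):
        _, truth, _ = gaussian_traj
        c = truth["covariance"]
        np.testing.assert_allclose(
            np.trace(c), truth["eigenvalues"].sum(), atol=1e-9
        )
        np.testing.assert_allclose(
            truth["per_atom_msf"].sum(), truth["eigenvalues"].sum(), atol=1e-9
        )

    def test_sample_mean_near_input_structure(self, bead_protein, gaussian_traj):
        structure, _ = bead_protein
        traj, _, _ = gaussian_traj
        mean = traj.coords.mean(axis=0)
        # fluctuations average out; tolerance scales as sigma/sqrt(F)
        assert np.abs(mean - structure.coords).max() < 0.2

    def test_seed_reproducibility(self, bead_protein):
        structure, _ = bead_protein
        spec = random_covariance_spec(
            structure.n_atoms, np.array([1.0]), seed=6, structure=structure
        )
        t1, _ = generate_gaussian_trajectory(structure, spec, 50, seed=7)
        t2, _ = generate_gaussian_trajectory(structure, spec, 50, seed=7)
        np.testing.assert_array_equal(t1.coords, t2.coords)


class TestTransitionTrajectory:
    def test_labels_and_window(self, bead_protein):
        structure, _ = bead_protein
        a = structure.coords
        b = a + [5.0, 0, 0]
        traj, truth = generate_transition_trajectory(
            structure, a, b, switch_start=40, switch_len=10,
            noise_sigma=0.0, n_frames=100, seed=8,
        )
        labels = truth["labels"]
        assert np.all(labels[:40] == 0)
        # the ramp reaches state B on the final window frame, so that frame
        # already carries label 1
        assert np.all(labels[40:49] == -1)
        assert np.all(labels[49:] == 1)
        # noise-free endpoints sit exactly on the states
        np.testing.assert_allclose(traj.coords[0], a, atol=1e-9)
        np.testing.assert_allclose(traj.coords[-1], b, atol=1e-9)
        # ramp is monotone along the displacement axis
        x = traj.coords[:, 0, 0]
        assert np.all(np.diff(x[39:51]) >= -1e-12)

    def test_mismatched_states_rejected(self, bead_protein):
        structure, _ = bead_protein
        with pytest.raises(ValueError):
            generate_transition_trajectory(
                structure, structure.coords, structure.coords[:-1],
                switch_start=10, switch_len=5, noise_sigma=0.1,
                n_frames=50, seed=0,
            )


class TestCandidateEnsemble:
    def test_planted_d_is_exact(self, candidate_ensemble):
        models, scheme, truth = candidate_ensemble
        res_a, res_b = scheme.reference_pair
        for m, d_true in zip(models[:20], truth["d_values"][:20]):
            coords = m.structure.coords
            d = np.linalg.norm(coords[res_b - 1] - coords[res_a - 1])
            # structures store float32 coordinates
            assert d == pytest.approx(d_true, abs=1e-4)
            assert m.d == pytest.approx(d_true, abs=1e-9)

    def test_d_distribution_covers_the_band(self, candidate_ensemble):
        _, _, truth = candidate_ensemble
        ds = truth["d_values"]
        assert ds.min() >= 7.0 and ds.max() <= 13.0
        assert np.sum(np.abs(ds - 9.9) <= 1.0) > 10

    def test_ss_strings_close_to_templates(self, candidate_ensemble):
        models, _, truth = candidate_ensemble
        spec = EnsembleSpec()
        for m, g in zip(models, truth["group_labels"]):
            template = truth["templates"][g]
            identity = np.mean(
                [a == b for a, b in zip(m.ss, template)]
            )
            # flip noise is 5% per position; allow generous slack
            assert identity > 1.0 - 4 * spec.ss_flip_noise

    def test_templates_mutually_distinct(self, candidate_ensemble):
        _, _, truth = candidate_ensemble
        t = truth["templates"]
        for i in range(len(t)):
            for j in range(i + 1, len(t)):
                identity = np.mean([a == b for a, b in zip(t[i], t[j])])
                assert identity < 0.8

    def test_seed_reproducibility(self):
        spec = EnsembleSpec(n_models=5)
        m1, _, _ = generate_candidate_ensemble(spec, seed=9)
        m2, _, _ = generate_candidate_ensemble(spec, seed=9)
        for a, b in zip(m1, m2):
            assert a.d == b.d and a.ss == b.ss
            np.testing.assert_array_equal(a.structure.coords, b.structure.coords)


class TestBackboneBuilders:
    def test_bond_lengths_standard(self, ideal_helix_12):
        coords = ideal_helix_12.coords
        names = ideal_helix_12.atom_names
        n_idx = np.flatnonzero(names == "N")
        ca_idx = np.flatnonzero(names == "CA")
        c_idx = np.flatnonzero(names == "C")
        n_ca = np.linalg.norm(coords[ca_idx] - coords[n_idx], axis=1)
        ca_c = np.linalg.norm(coords[c_idx] - coords[ca_idx], axis=1)
        np.testing.assert_allclose(n_ca, 1.458, atol=1e-3)
        np.testing.assert_allclose(ca_c, 1.525, atol=1e-3)

    @pytest.mark.parametrize(
        "builder,phi_ref,psi_ref",
        [(ideal_helix, -57.0, -47.0), (ideal_strand, -139.0, 135.0)],
    )
    def test_requested_dihedrals_realised(self, builder, phi_ref, psi_ref):
        s = builder(10)
        phi, psi, _ = dihedral_backbone(s.atoms)
        np.testing.assert_allclose(
            np.degrees(phi[1:-1]), phi_ref, atol=0.5
        )
        np.testing.assert_allclose(
            np.degrees(psi[1:-1]), psi_ref, atol=0.5
        )

    def test_custom_dihedral_list(self):
        angles = [(-57.0, -47.0)] * 4 + [(-139.0, 135.0)] * 4
        s = build_peptide_backbone(angles)
        phi, psi, _ = dihedral_backbone(s.atoms)
        np.testing.assert_allclose(np.degrees(phi[1]), -57.0, atol=0.5)
        np.testing.assert_allclose(np.degrees(psi[6]), 135.0, atol=0.5)

    def test_sheet_has_two_strands_with_sequence_gap(self, antiparallel_sheet):
        res = np.unique(antiparallel_sheet.residue_numbers)
        gaps = np.diff(np.sort(res))
        assert (gaps > 1).sum() == 1
        assert gaps.max() >= 10
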