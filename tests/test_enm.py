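"""Elastic-network model: Hessian structure, spectra, derived profiles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lidkit.enm import (
    ENMParams,
    build_enm,
    enm_covariance_map,
    normal_modes,
    normalized_mobility,
    predicted_bfactors,
)
from lidkit.io import select
from lidkit.traj import rmsf
from lidkit.io import Trajectory

from conftest import ca_only_structure

TETRAHEDRON = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
)


def independent_hessian(coords, resids, params):
    """Oracle Hessian assembly: scalar loops, no shared code path."""
    n = len(coords)
    H = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rij = np.asarray(coords[j]) - np.asarray(coords[i])
            d = np.sqrt(np.sum(rij**2))
            s = max(abs(int(resids[j]) - int(resids[i])), 1)
            if s <= params.seq_neighbor_cutoff:
                k = params.k_seq / s**2
            else:
                k = params.k_cart * d ** (-params.cart_exponent)
            e = rij / d
            block = k * np.outer(e, e)
            H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= block
            H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += block
    return H


class TestBuildENM:
    def test_two_node_analytic_blocks(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        params = ENMParams(k_seq=1.0)
        model = build_enm(coords, np.array([1, 2]), params)
        assert len(model.springs) == 1
        i, j, k = model.springs[0]
        assert k == pytest.approx(1.0)
        rr = np.outer([1.0, 0, 0], [1.0, 0, 0])
        np.testing.assert_allclose(model.hessian[:3, :3], rr, atol=1e-12)
        np.testing.assert_allclose(model.hessian[:3, 3:], -rr, atol=1e-12)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            build_enm(np.zeros((1, 3)))

    def test_duplicate_nodes_rejected(self):
        coords = np.array([[0.0, 0, 0], [0.1, 0, 0], [5.0, 0, 0]])
        with pytest.raises(ValueError, match="min_distance"):
            build_enm(coords)

    def test_translation_invariance_block_row_sums(self):
        model = build_enm(TETRAHEDRON * 3.0)
        H = model.hessian.reshape(4, 3, 4, 3)
        row_sums = H.sum(axis=2)  # sum over j blocks
        np.testing.assert_allclose(row_sums, 0.0, atol=1e-12)

    def test_hessian_symmetric(self, toy_chain):
        ca = select(toy_chain, atom_names={"CA"})
        model = build_enm(ca.coords, ca.resids)
        H = model.hessian
        assert np.max(np.abs(H - H.T)) < 1e-10 * np.max(np.abs(H))

    def test_matches_independent_assembly(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(scale=5.0, size=(6, 3))
        resids = np.array([1, 2, 3, 5, 8, 9])
        params = ENMParams()
        model = build_enm(coords, resids, params)
        np.testing.assert_allclose(
            model.hessian, independent_hessian(coords, resids, params), atol=1e-10
        )


class TestNormalModes:
    def test_two_body_eigenvalue(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        model = build_enm(coords, params=ENMParams(k_seq=2.5))
        ms = normal_modes(model)
        nonzero = ms.eigenvalues[ms.eigenvalues > 1e-8]
        # single internal mode of a two-body spring: lambda = 2k
        assert nonzero.size == 1
        assert nonzero[0] == pytest.approx(2 * 2.5, rel=1e-12)

    def test_six_zero_modes_generic_3d(self, toy_chain):
        ca = select(toy_chain, atom_names={"CA"})
        ms = normal_modes(build_enm(ca.coords, ca.resids))
        assert ms.n_zero == 6
        assert np.all(ms.eigenvalues[6:] > 0)

    def test_collinear_geometry_rejected(self):
        line = np.column_stack([np.arange(5.0) * 3.8, np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            normal_modes(build_enm(line))

    def test_eigenvalues_match_dense_diagonalization_oracle(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(scale=4.0, size=(5, 3))
        resids = np.arange(1, 6)
        params = ENMParams()
        ms = normal_modes(build_enm(coords, resids, params))
        oracle = np.linalg.eigvalsh(independent_hessian(coords, resids, params))
        oracle = np.clip(oracle, 0.0, None)
        scale = oracle.max()
        np.testing.assert_allclose(ms.eigenvalues, oracle, atol=1e-9 * scale)

    def test_eigenvectors_orthonormal(self, toy_chain):
        ca = select(toy_chain, atom_names={"CA"})
        ms = normal_modes(build_enm(ca.coords[:20], ca.resids[:20]))
        G = ms.eigenvectors.T @ ms.eigenvectors
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)


class TestDerivedProfiles:
    def test_tetrahedron_symmetry(self):
        # uniform springs: all pairs in the distance-decay regime, and all
        # pair distances are equal in a regular tetrahedron
        uniform = ENMParams(seq_neighbor_cutoff=0)
        ms = normal_modes(build_enm(TETRAHEDRON * 3.0, params=uniform))
        b = predicted_bfactors(ms)
        np.testing.assert_allclose(b, b[0], rtol=1e-9)
        np.testing.assert_allclose(normalized_mobility(ms), 1.0, rtol=1e-9)

    def test_mobility_max_is_one(self, toy_chain):
        ca = select(toy_chain, atom_names={"CA"})
        mob = normalized_mobility(normal_modes(build_enm(ca.coords, ca.resids)))
        assert mob.max() == pytest.approx(1.0, abs=1e-15)
        assert np.all(mob > 0)

    def test_rigid_body_invariance(self, toy_chain):
        ca = select(toy_chain, atom_names={"CA"})
        coords = ca.coords
        rot = Rotation.from_euler("xyz", [10, 70, -30], degrees=True).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -3.0, 11.0])
        ms_a = normal_modes(build_enm(coords, ca.resids))
        ms_b = normal_modes(build_enm(moved, ca.resids))
        scale = ms_a.eigenvalues.max()
        np.testing.assert_allclose(
            ms_a.eigenvalues, ms_b.eigenvalues, atol=1e-8 * scale
        )
        np.testing.assert_allclose(
            predicted_bfactors(ms_a), predicted_bfactors(ms_b), rtol=1e-8
        )
        np.testing.assert_allclose(
            enm_covariance_map(ms_a), enm_covariance_map(ms_b), atol=1e-8
        )

    def test_covariance_map_structure(self, toy_chain):
        ca = select(toy_chain, atom_names={"CA"})
        corr = enm_covariance_map(normal_modes(build_enm(ca.coords, ca.resids)))
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-12)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        assert np.all(corr <= 1 + 1e-12) and np.all(corr >= -1 - 1e-12)

    def test_two_node_covariance_analytic(self):
        # a single spring: the only internal mode moves the nodes in
        # antiphase, so the normalized cross-correlation is exactly -1
        model = build_enm(np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        corr = enm_covariance_map(normal_modes(model))
        assert corr[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_bfactors_match_mode_gaussian_sampling(self):
        """Monte-Carlo oracle: sample the mode Gaussians directly."""
        rng = np.random.default_rng(7)
        coords = rng.normal(scale=4.0, size=(8, 3))
        ms = normal_modes(build_enm(coords))
        b = predicted_bfactors(ms)
        lam = ms.eigenvalues[ms.n_zero :]
        V = ms.eigenvectors[:, ms.n_zero :]
        draws = rng.normal(size=(100_000, lam.size)) / np.sqrt(lam)[None, :]
        disp = draws @ V.T  # (draws, 3n)
        msf = (disp.reshape(-1, 8, 3) ** 2).sum(axis=2).mean(axis=0)
        r = np.corrcoef(b, msf)[0, 1]
        assert r > 0.999

    def test_bfactor_profile_tracks_sampled_trajectory_rmsf(self):
        """Trajectory drawn from the mode Gaussians reproduces the ENM
        fluctuation profile (squared-RMSF vs B, Pearson r > 0.99)."""
        rng = np.random.default_rng(8)
        coords = make_coords_for_rmsf(rng)
        ms = normal_modes(build_enm(coords))
        b = predicted_bfactors(ms)
        lam = ms.eigenvalues[ms.n_zero :]
        V = ms.eigenvectors[:, ms.n_zero :]
        amps = rng.normal(size=(10_000, lam.size)) / np.sqrt(lam)[None, :]
        frames = coords[None] + (amps @ V.T).reshape(-1, coords.shape[0], 3)
        traj = Trajectory(topology=ca_only_structure(coords), frames=frames)
        prof = rmsf(traj, superpose=False)
        r = np.corrcoef(b, prof**2)[0, 1]
        assert r > 0.99


def make_coords_for_rmsf(rng):
    from lidkit.synthetic import make_toy_chain
    from lidkit.io import select as _select

    chain = make_toy_chain(20, seed=int(rng.integers(1000)))
    return _select(chain, atom_names={"CA"}).coords
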