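"""GNM/ANM construction, eigenanalysis, fluctuations and correlations.

The path-3 chain and the two-bead pair have fully analytic spectra, so the
expected values here are exact; larger structures are checked against the
dense pseudo-inverse as an independent route.
"""

import subprocess
import sys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import enmpair as ep
from enmpair.enm import DisconnectedNetworkError

from conftest import random_rigid_motion


def random_structure(rng: np.random.Generator, n: int) -> ep.CalphaStructure:
    """Connected random blob: jittered helix keeps the chain connected."""
    s = ep.make_chain(n, geometry="helix")
    return ep.jitter(s, 0.5, seed=int(rng.integers(2**31)))


class TestKirchhoff:
    def test_single_residue_zero_matrix(self):
        g = ep.build_kirchhoff(ep.make_chain(1, 3.8), 7.3)
        np.testing.assert_array_equal(g.kirchhoff, [[0.0]])

    def test_two_residue_spring(self):
        g = ep.build_kirchhoff(ep.make_chain(2, 3.8), 7.3)
        np.testing.assert_array_equal(g.kirchhoff, [[1, -1], [-1, 1]])

    def test_path3_matrix(self, path3):
        g = ep.build_kirchhoff(path3, 7.3)
        np.testing.assert_array_equal(
            g.kirchhoff, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]]
        )

    def test_cutoff_is_inclusive(self):
        g = ep.build_kirchhoff(ep.make_chain(2, 7.3), 7.3)
        assert g.kirchhoff[0, 1] == -1

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(5, 40))
    def test_laplacian_structure(self, seed, n):
        """Rows sum to zero; off-diagonals in {0, −1}; diagonal = degree."""
        rng = np.random.default_rng(seed)
        s = random_structure(rng, n)
        g = ep.build_kirchhoff(s, 7.3)
        k = g.kirchhoff
        np.testing.assert_allclose(k, k.T)
        np.testing.assert_allclose(k.sum(axis=1), 0.0, atol=1e-9)
        off = k[~np.eye(n, dtype=bool)]
        assert set(np.unique(off)) <= {0.0, -1.0}
        np.testing.assert_array_equal(np.diag(k), -(k - np.diag(np.diag(k))).sum(1))


class TestContactNumbers:
    def test_path3_counts(self, path3):
        cn = ep.contact_numbers(path3, 7.3)
        np.testing.assert_array_equal(cn, [1, 2, 1])
        assert cn.mean() == pytest.approx(4 / 3)

    def test_single_residue(self):
        np.testing.assert_array_equal(ep.contact_numbers(ep.make_chain(1, 3.8)), [0])

    def test_matches_kirchhoff_diagonal(self):
        s, _ = ep.make_dumbbell(ep.DumbbellSpec(seed=6))
        for rc in (7.3, 9.0):
            np.testing.assert_array_equal(
                ep.contact_numbers(s, rc), np.diag(ep.build_kirchhoff(s, rc).kirchhoff)
            )


class TestDecompose:
    def test_path3_eigenvalues(self, path3):
        g = ep.build_kirchhoff(path3, 7.3)
        np.testing.assert_allclose(g.eigenvalues, [0.0, 1.0, 3.0], atol=1e-9)
        assert g.n_zero == 1

    def test_eigenvectors_orthonormal(self):
        s, _ = ep.make_dumbbell(ep.DumbbellSpec(seed=2))
        g = ep.build_kirchhoff(s, 7.3)
        u = g.eigenvectors
        np.testing.assert_allclose(u.T @ u, np.eye(s.n_residues), atol=1e-8)

    def test_connected_gnm_has_one_zero_mode(self):
        for seed in (1, 2, 3):
            s, _ = ep.make_dumbbell(ep.DumbbellSpec(seed=seed))
            assert ep.build_kirchhoff(s, 7.3).n_zero == 1

    def test_disconnected_graph_flagged_with_component_count(self):
        s = ep.make_chain(6, spacing=8.0)  # no pair within 7.3 Å
        g = ep.build_kirchhoff(s, 7.3)
        with pytest.warns(UserWarning, match="disconnected"):
            dec = g.decompose()
        assert dec.n_zero == 6
        assert g.n_components() == 6

    def test_zero_mode_count_equals_component_count(self):
        # two separated fragments
        a = ep.make_chain(5, 3.8)
        coords = np.vstack([a.coords, a.coords + [100.0, 0, 0]])
        s = ep.CalphaStructure(
            residue_id=[("A", i + 1, "") for i in range(10)],
            residue_name=["ALA"] * 10,
            coords=coords,
        )
        g = ep.build_kirchhoff(s, 7.3)
        with pytest.warns(UserWarning):
            assert g.decompose().n_zero == 2
        assert g.n_components() == 2

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ep.decompose(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestGnmFluctuations:
    def test_path3_full_msf(self, path3):
        g = ep.build_kirchhoff(path3, 7.3)
        np.testing.assert_allclose(
            ep.gnm_msf(g).msf, [5 / 3, 2 / 3, 5 / 3], atol=1e-9
        )

    def test_path3_slowest_mode_only(self, path3):
        g = ep.build_kirchhoff(path3, 7.3)
        # slowest mode λ=1, u=(1,0,−1)/√2 → 3·(1/2, 0, 1/2)
        np.testing.assert_allclose(
            ep.gnm_msf(g, modes=[1]).msf, [1.5, 0.0, 1.5], atol=1e-9
        )

    def test_msf_linear_in_scale(self, path3):
        g = ep.build_kirchhoff(path3, 7.3)
        np.testing.assert_allclose(
            ep.gnm_msf(g, scale=2.0).msf, 2.0 * ep.gnm_msf(g).msf, rtol=1e-12
        )

    def test_out_of_range_mode_rejected(self, path3):
        g = ep.build_kirchhoff(path3, 7.3)
        with pytest.raises(ValueError, match="mode 0"):
            ep.gnm_msf(g, modes=[0])
        with pytest.raises(ValueError, match="mode 3"):
            ep.gnm_msf(g, modes=[3])

    def test_mode_sum_equals_pseudo_inverse_diagonal(self):
        rng = np.random.default_rng(11)
        for n in (20, 60, 200):
            s = random_structure(rng, n)
            g = ep.build_kirchhoff(s, 7.3)
            oracle = 3.0 * np.diag(np.linalg.pinv(g.kirchhoff, rcond=1e-8))
            np.testing.assert_allclose(ep.gnm_msf(g).msf, oracle, rtol=1e-8)


class TestBfactorConversion:
    @pytest.mark.parametrize(
        "msf, expected",
        [(0.0, 0.0), (1.0, 8 * np.pi**2 / 3), (5 / 3, 40 * np.pi**2 / 9)],
    )
    def test_conversion_values(self, msf, expected):
        assert ep.msf_to_bfactor(np.array([msf]))[0] == pytest.approx(expected, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ep.msf_to_bfactor(np.array([-0.1]))


class TestCrossCorrelation:
    def test_path3_values(self, path3):
        c = ep.cross_correlation(ep.build_kirchhoff(path3, 7.3)).c
        assert c[0, 2] == pytest.approx(-0.8, abs=1e-9)
        assert c[0, 1] == pytest.approx(-1 / np.sqrt(10), abs=1e-9)

    def test_unit_diagonal_symmetry_and_bounds(self):
        s, _ = ep.make_dumbbell(ep.DumbbellSpec(seed=3))
        c = ep.cross_correlation(ep.build_kirchhoff(s, 7.3)).c
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-9)
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        assert np.max(np.abs(c)) <= 1 + 1e-9

    def test_disconnected_network_refused(self):
        s = ep.make_chain(6, spacing=8.0)
        g = ep.build_kirchhoff(s, 7.3)
        with pytest.warns(UserWarning):
            g.decompose()
        with pytest.raises(DisconnectedNetworkError):
            ep.cross_correlation(g)


class TestHessian:
    def test_two_bead_superelements(self, two_beads):
        a = ep.build_hessian(two_beads, 15.0)
        h = a.hessian
        xx = h[np.ix_([0, 3], [0, 3])]
        np.testing.assert_allclose(xx, [[1, -1], [-1, 1]], atol=1e-12)
        mask = np.ones((6, 6), dtype=bool)
        mask[np.ix_([0, 3], [0, 3])] = False
        np.testing.assert_allclose(h[mask], 0.0, atol=1e-12)

    def test_two_bead_spectrum(self, two_beads):
        a = ep.build_hessian(two_beads, 15.0)
        assert a.n_zero == 5
        np.testing.assert_allclose(a.eigenvalues[5], 2.0, atol=1e-9)

    def test_translation_in_null_space(self):
        s, _ = ep.make_dumbbell(ep.DumbbellSpec(seed=5))
        a = ep.build_hessian(s, 15.0)
        t = np.tile([1.0, 0.0, 0.0], s.n_residues)
        np.testing.assert_allclose(a.hessian @ t, 0.0, atol=1e-9)

    def test_positive_semidefinite(self):
        s, _ = ep.make_dumbbell(ep.DumbbellSpec(seed=5))
        a = ep.build_hessian(s, 15.0)
        assert a.eigenvalues[0] >= -1e-8 * a.eigenvalues[-1]

    def test_coincident_residues_rejected(self):
        s = ep.CalphaStructure(
            residue_id=[("A", 1, ""), ("A", 2, "")],
            residue_name=["ALA", "ALA"],
            coords=np.zeros((2, 3)),
        )
        with pytest.raises(ValueError, match="coincident"):
            ep.build_hessian(s, 15.0)

    def test_spectrum_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(7)
        s = random_structure(rng, 30)
        r, t = random_rigid_motion(rng)
        s2 = s.with_coords(s.coords @ r.T + t)
        for build, cutoff in ((ep.build_kirchhoff, 7.3), (ep.build_hessian, 15.0)):
            ev1 = build(s, cutoff).eigenvalues
            ev2 = build(s2, cutoff).eigenvalues
            np.testing.assert_allclose(ev1, ev2, atol=1e-8 * max(1, ev1[-1]))


class TestAnmFluctuations:
    def test_two_bead_msf(self, two_beads):
        a = ep.build_hessian(two_beads, 15.0)
        np.testing.assert_allclose(ep.anm_msf(a).msf, [0.75, 0.75], atol=1e-9)

    def test_symmetric_beads_symmetric_msf(self, two_beads):
        a = ep.build_hessian(two_beads, 15.0)
        msf = ep.anm_msf(a).msf
        assert msf[0] == pytest.approx(msf[1], rel=1e-12)

    def test_mode_sum_equals_pseudo_inverse_trace(self):
        rng = np.random.default_rng(13)
        s = random_structure(rng, 20)
        a = ep.build_hessian(s, 15.0)
        pinv = np.linalg.pinv(a.hessian, rcond=1e-8)
        oracle = 3.0 * np.diag(pinv).reshape(-1, 3).sum(axis=1)
        np.testing.assert_allclose(ep.anm_msf(a).msf, oracle, rtol=1e-8)


class TestAnmModeFluctuation:
    def test_two_bead_directions_antiparallel_along_bond(self, two_beads):
        a = ep.build_hessian(two_beads, 15.0)
        msf, dirs = ep.anm_mode_fluctuation(a, 1)
        # bond is along x: both direction vectors on the x axis, opposite sense
        np.testing.assert_allclose(dirs[:, 1:], 0.0, atol=1e-9)
        assert dirs[0, 0] * dirs[1, 0] < 0

    def test_squared_components_sum_to_one(self):
        s, _ = ep.make_dumbbell(ep.DumbbellSpec(seed=2))
        a = ep.build_hessian(s, 15.0)
        for k in (1, 2, 3):
            _, dirs = ep.anm_mode_fluctuation(a, k)
            assert np.sum(dirs**2) == pytest.approx(1.0, abs=1e-8)

    def test_slowest_mode_domain_anticorrelation(self):
        for seed in (1, 2, 3):
            s, labels = ep.make_dumbbell(ep.DumbbellSpec(seed=seed))
            a = ep.build_hessian(s, 15.0)
            _, dirs = ep.anm_mode_fluctuation(a, 1)
            da = dirs[labels.domain_a].mean(axis=0)
            db = dirs[labels.domain_b].mean(axis=0)
            assert float(da @ db) < 0

    def test_mode_out_of_range(self, two_beads):
        a = ep.build_hessian(two_beads, 15.0)
        with pytest.raises(ValueError):
            ep.anm_mode_fluctuation(a, 2)


class TestAgainstBio3d:
    def test_gnm_fluctuations_match_bio3d_up_to_scale(self, tmp_path):
        """Independent cross-check: bio3d's GNM on the same synthetic PDB
        yields fluctuations proportional to ours (its normalization differs
        by a constant factor only)."""
        s, _ = ep.make_dumbbell(ep.DumbbellSpec(seed=9))
        path = tmp_path / "dumbbell.pdb"
        ep.write_calpha_pdb(s, path)
        rscript = (
            "suppressMessages(library(bio3d));"
            f"pdb <- read.pdb('{path}');"
            "m <- gnm(pdb, cutoff=7.3);"
            "cat(m$fluctuations, sep=',')"
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        ref = np.array([float(v) for v in out.stdout.strip().split(",")])
        mine = ep.gnm_msf(ep.build_kirchhoff(ep.read_calpha(path), 7.3)).msf
        assert ref.size == mine.size
        ratio = mine / ref
        np.testing.assert_allclose(ratio, ratio.mean(), rtol=1e-4)


class TestMatrixExport:
    def test_sparse_and_dense_round_trip(self, tmp_path, path3):
        g = ep.build_kirchhoff(path3, 7.3)
        from enmpair.enm import write_matrix_csv, write_matrix_sparse

        dense = tmp_path / "k.csv"
        write_matrix_csv(g.kirchhoff, dense)
        back = np.loadtxt(dense, delimiter=",")
        np.testing.assert_array_equal(back, g.kirchhoff)

        sparse = tmp_path / "k.txt"
        write_matrix_sparse(g.kirchhoff, sparse)
        rebuilt = np.zeros((3, 3))
        for line in sparse.read_text().splitlines():
            i, j, v = line.split(",")
            rebuilt[int(i) - 1, int(j) - 1] = float(v)
        np.testing.assert_array_equal(rebuilt, g.kirchhoff)
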