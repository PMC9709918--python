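"""Superposition RMSD, dihedrals, and distance matrices against independent oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from confbench import (
    RepresentativeSelection,
    dihedral_angle,
    kabsch_rmsd,
    pairwise_distance_matrix,
    subset_rmsd,
    torsion_features,
)
from confbench.geometry import circular_difference

from conftest import chain_conformer


def grid_search_rmsd(P, Q, n_coarse=24):
    """Brute-force minimum RMSD over rotations: nested Euler-angle grids.

    Independent of the closed-form path: centers both sets, scans a coarse
    rotation grid, then refines twice around the best orientation.
    """
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)

    def rmsd_for(rots):
        rotated = np.einsum("rij,nj->rni", rots.as_matrix(), Q)
        return np.sqrt(np.mean(np.sum((rotated - P) ** 2, axis=2), axis=1))

    center = np.zeros(3)
    span = 180.0
    best = np.inf
    for _ in range(4):
        axes = [np.linspace(c - span, c + span, n_coarse) for c in center]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        rots = Rotation.from_euler("zyz", grid, degrees=True)
        vals = rmsd_for(rots)
        i = int(np.argmin(vals))
        best = min(best, vals[i])
        center = grid[i]
        span /= n_coarse / 2.5
    return float(best)


class TestKabschRmsd:
    def test_identity_and_rigid_motion_invariance(self, rng):
        """RMSD is 0 against any rotated + translated copy, to 1e-6 Å."""
        P = rng.normal(size=(7, 3))
        for _ in range(20):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(size=3) * 10
            assert kabsch_rmsd(P, P @ R.T + t) < 1e-6

    def test_simple_triangles(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        assert kabsch_rmsd(P, P) == 0.0
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        assert kabsch_rmsd(P, P @ Rz.T + 5.0) < 1e-12

    def test_matches_grid_search_oracle(self, rng):
        """Closed form equals brute-force rotation-grid minimization to 1e-3 Å."""
        for _ in range(50):
            P = rng.normal(size=(5, 3)) * 2
            Q = rng.normal(size=(5, 3)) * 2
            assert kabsch_rmsd(P, Q) == pytest.approx(grid_search_rmsd(P, Q), abs=1e-3)

    def test_not_larger_than_unsuperposed_rmsd(self, rng):
        for _ in range(20):
            P = rng.normal(size=(6, 3))
            Q = rng.normal(size=(6, 3))
            plain = np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1)))
            assert kabsch_rmsd(P, Q) <= plain + 1e-12

    def test_symmetric_in_arguments(self, rng):
        P, Q = rng.normal(size=(2, 8, 3))
        assert kabsch_rmsd(P, Q) == pytest.approx(kabsch_rmsd(Q, P), abs=1e-12)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestSubsetRmsd:
    def test_identical_conformers(self, chain_selection):
        a = chain_conformer([60.0, -60.0, 180.0])
        assert subset_rmsd(a, a, chain_selection) == 0.0

    def test_only_non_selected_atoms_perturbed(self):
        """Perturbing atoms outside the selection leaves the subset RMSD at 0."""
        a = chain_conformer([60.0, -60.0, 180.0], n_atoms=8)
        b = chain_conformer([60.0, -60.0, 180.0], n_atoms=8)
        b.coords[7] += 3.0
        sel = RepresentativeSelection(atom_indices=tuple(range(6)))
        assert subset_rmsd(a, b, sel) < 1e-12

    def test_out_of_bounds_selection_errors(self):
        a = chain_conformer([60.0, -60.0, 180.0])
        sel = RepresentativeSelection(atom_indices=(0, 1, 99))
        with pytest.raises(ValueError):
            subset_rmsd(a, a, sel)


class TestDihedralAngle:
    @pytest.mark.parametrize(
        "p4,expected",
        [((1, -1, 0), 180.0), ((1, 1, 0), 0.0)],
        ids=["planar-trans", "planar-cis"],
    )
    def test_planar_references(self, p4, expected):
        assert dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), p4) == pytest.approx(expected)

    def test_mirror_flips_sign(self, rng):
        """A mirror image negates the torsion but preserves its magnitude."""
        for _ in range(10):
            pts = rng.normal(size=(4, 3)) * 2
            try:
                a = dihedral_angle(*pts)
            except ValueError:
                continue
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            b = dihedral_angle(*mirrored)
            if abs(abs(a) - 180.0) > 1e-9:
                assert b == pytest.approx(-a, abs=1e-9)
            else:
                assert abs(b) == pytest.approx(abs(a), abs=1e-9)

    def test_degenerate_geometry_errors(self):
        with pytest.raises(ValueError):
            dihedral_angle((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        with pytest.raises(ValueError):  # collinear triple
            dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestTorsionFeatures:
    def test_constructed_chain_round_trip(self, chain_selection):
        c = chain_conformer([60.0, 60.0, 60.0])
        np.testing.assert_allclose(torsion_features(c, chain_selection), 60.0, atol=1e-9)
        c2 = chain_conformer([180.0, -60.0, 45.0])
        np.testing.assert_allclose(
            torsion_features(c2, chain_selection), [180.0, -60.0, 45.0], atol=1e-9
        )

    def test_empty_quad_list_errors(self):
        c = chain_conformer([60.0, 60.0, 60.0])
        sel = RepresentativeSelection(atom_indices=(0, 1, 2, 3))
        with pytest.raises(ValueError):
            torsion_features(c, sel)


class TestDistanceMatrix:
    def test_torsion_metric_wraps_around(self):
        """170° vs -170° differ by 20°, not 340°."""
        sel = RepresentativeSelection(
            atom_indices=tuple(range(4)), dihedral_quads=((0, 1, 2, 3),)
        )
        a = chain_conformer([170.0], conformer_id="a")
        b = chain_conformer([-170.0], conformer_id="b")
        dist = pairwise_distance_matrix([a, b], sel, metric="torsion")
        assert dist.values[0, 1] == pytest.approx(20.0, abs=1e-6)

    def test_duplicates_give_zero_offdiagonal(self, chain_selection):
        a = chain_conformer([60.0, -60.0, 180.0], conformer_id="a")
        b = chain_conformer([60.0, -60.0, 180.0], conformer_id="b")
        for metric in ("subset_rmsd", "torsion", "blended"):
            dist = pairwise_distance_matrix([a, b, a], chain_selection, metric=metric)
            assert dist.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_on_random_ensembles(self, chain_selection, rng):
        confs = [
            chain_conformer(rng.uniform(-180, 180, 3), conformer_id=f"c{i}")
            for i in range(6)
        ]
        for metric in ("subset_rmsd", "torsion", "blended"):
            dist = pairwise_distance_matrix(confs, chain_selection, metric=metric)
            np.testing.assert_allclose(dist.values, dist.values.T, atol=1e-9)
            assert np.all(np.diag(dist.values) == 0)

    def test_angle_periodicity(self):
        """theta and theta - 360 are the same feature."""
        np.testing.assert_allclose(circular_difference(350.0, -10.0), 0.0)
        np.testing.assert_allclose(circular_difference([10.0], [370.0]), [0.0])

    def test_single_conformer_errors(self, chain_selection):
        with pytest.raises(ValueError):
            pairwise_distance_matrix([chain_conformer([60.0, 0.0, 0.0])], chain_selection)
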