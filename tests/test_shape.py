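"""Shape scoring: embedding, Gaussian overlap, superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from brs3d import shape
from brs3d.shape import (
    KAPPA,
    P_AMP,
    Molecule3D,
    Pose,
    embed_molecule,
    pose_score,
    superimpose,
)

from conftest import make_single_atom


def grid_overlap(mol_a, mol_b, spacing=0.1, pad=4.0):
    """Numerical oracle: integrate rho_A * rho_B on a dense 3D grid."""
    pts = np.vstack([mol_a.coords, mol_b.coords])
    lo, hi = pts.min(axis=0) - pad, pts.max(axis=0) + pad
    axes = [np.arange(lo[d], hi[d], spacing) for d in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def density(mol):
        rho = np.zeros(len(grid))
        for c, r in zip(mol.coords, mol.radii):
            d2 = np.sum((grid - c) ** 2, axis=1)
            rho += P_AMP * np.exp(-(KAPPA / r**2) * d2)
        return rho

    return float(np.sum(density(mol_a) * density(mol_b)) * spacing**3)


class TestEmbedding:
    def test_methane(self):
        m = embed_molecule("C", seed=0, mol_id="methane")
        assert m.n_heavy == 1
        assert m.rdmol.GetNumAtoms() == 5  # C + 4 H
        assert abs(float(np.sum(m.charges))) < 0.5  # heavy-atom partial charges

    def test_benzene_planar(self):
        m = embed_molecule("c1ccccc1", seed=0)
        centered = m.coords - m.coords.mean(axis=0)
        # smallest singular value = extent off the best-fit plane
        assert np.linalg.svd(centered, compute_uv=False)[-1] < 0.1

    def test_deterministic(self):
        a = embed_molecule("CCOc1ccccc1", seed=5)
        b = embed_molecule("CCOc1ccccc1", seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_unparseable_raises(self):
        with pytest.raises(ValueError, match="unparseable"):
            embed_molecule("not_a_smiles(((", seed=0)

    def test_feature_flags_detected(self):
        m = embed_molecule("c1ccccc1C(=O)[O-]", seed=0)
        assert m.flags["ACCEPTOR"].sum() >= 1
        assert m.flags["NEG"].sum() >= 1


class TestPoseScore:
    def test_exact_copy_scores_one(self, small_molecules):
        m = small_molecules["phenol"]
        assert pose_score(m, m) == pytest.approx(1.0, abs=1e-12)

    def test_distant_molecules_score_zero(self, small_molecules):
        m = small_molecules["ethanol"]
        far = m.transformed(np.eye(3), np.array([100.0, 0.0, 0.0]))
        assert pose_score(far, m) < 1e-6

    def test_score_bounded(self, small_molecules):
        mols = list(small_molecules.values())
        for a in mols:
            for b in mols:
                assert 0.0 <= pose_score(a, b) <= 1.0

    @pytest.mark.parametrize("d", [0.0, 0.8, 1.6, 2.5])
    def test_single_atom_closed_form_vs_grid_quadrature(self, d):
        """The two-Gaussian overlap Tanimoto must match 3D grid integration."""
        a = make_single_atom("a", (0.0, 0.0, 0.0))
        b = make_single_atom("b", (d, 0.0, 0.0))
        o_ab = grid_overlap(a, b)
        o_aa = grid_overlap(a, a)
        expected = o_ab / (2 * o_aa - o_ab)
        assert pose_score(a, b) == pytest.approx(expected, rel=0.01)

    def test_single_atom_analytic_formula(self):
        # V_12 = p^2 (pi/(2a))^(3/2) exp(-a d^2 / 2) with a = kappa/r^2
        d = 1.3
        a = make_single_atom("a", (0.0, 0.0, 0.0))
        b = make_single_atom("b", (d, 0.0, 0.0))
        alpha = KAPPA
        v12 = P_AMP**2 * (np.pi / (2 * alpha)) ** 1.5 * np.exp(-alpha * d**2 / 2)
        v11 = P_AMP**2 * (np.pi / (2 * alpha)) ** 1.5
        assert pose_score(a, b) == pytest.approx(v12 / (2 * v11 - v12), rel=1e-9)


class TestSuperimpose:
    def test_self_overlay_reaches_one(self, small_molecules):
        m = small_molecules["pyridine"]
        poses = superimpose(m, m, seed=0)
        assert poses[0].score == pytest.approx(1.0, abs=1e-3)

    def test_sorted_non_increasing(self, small_molecules):
        poses = superimpose(small_molecules["phenol"], small_molecules["toluene"], seed=0)
        scores = [p.score for p in poses]
        assert scores == sorted(scores, reverse=True)

    def test_single_atom_vs_translation_grid(self):
        """Optimized single-atom alignment equals brute-force grid search."""
        a = make_single_atom("a", (1.0, -2.0, 0.5))
        b = make_single_atom("b", (4.0, 0.0, -1.0), radius=1.4)
        best = superimpose(a, b, seed=0)[0].score
        grid = np.linspace(-3, 3, 13)
        brute = max(
            pose_score(a, b, np.eye(3), np.array([tx, ty, tz]) - a.coords[0] + b.coords[0])
            for tx in grid
            for ty in grid
            for tz in grid
        )
        assert best >= brute - 1e-6
        # global optimum is coincident centres
        coincident = pose_score(a, b, np.eye(3), b.coords[0] - a.coords[0])
        assert best == pytest.approx(coincident, abs=1e-6)

    def test_rigid_motion_invariance(self, small_molecules):
        q, t = small_molecules["phenol"], small_molecules["pyridine"]
        base = superimpose(q, t, seed=0)[0].score
        rot = Rotation.from_rotvec([0.4, -1.2, 0.8]).as_matrix()
        moved = q.transformed(rot, np.array([3.0, -7.0, 2.0]))
        assert abs(superimpose(moved, t, seed=3)[0].score - base) < 1e-3

    def test_symmetry_of_best_score(self, small_molecules):
        a, b = small_molecules["phenol"], small_molecules["toluene"]
        s_ab = superimpose(a, b, seed=0)[0].score
        s_ba = superimpose(b, a, seed=0)[0].score
        assert abs(s_ab - s_ba) < 1e-2

    def test_inflation_decreases_score(self, small_molecules):
        m = small_molecules["benzene"]
        inflated = Molecule3D(
            "inflated",
            m.elements,
            m.coords * 2.0,
            m.charges,
            m.radii,
            {ch: v.copy() for ch, v in m.flags.items()},
        )
        assert superimpose(inflated, m, seed=0)[0].score < superimpose(m, m, seed=0)[0].score

    def test_pose_transform_reproduces_score(self, small_molecules):
        q, t = small_molecules["ethanol"], small_molecules["phenol"]
        pose = superimpose(q, t, seed=0)[0]
        posed = shape.apply_pose(q, pose)
        assert pose_score(posed, t) == pytest.approx(pose.score, abs=1e-9)

    def test_deterministic(self, small_molecules):
        q, t = small_molecules["ethanol"], small_molecules["phenol"]
        p1 = superimpose(q, t, seed=4)[0]
        p2 = superimpose(q, t, seed=4)[0]
        assert p1.score == p2.score
        np.testing.assert_array_equal(p1.rotation, p2.rotation)


class TestPoseValidation:
    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError, match="proper rotation"):
            Pose(rotation=np.diag([1.0, 1.0, -1.0]), translation=np.zeros(3), score=0.5)

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="score"):
            Pose(rotation=np.eye(3), translation=np.zeros(3), score=1.5)


def test_rotation_jacobian_matches_finite_differences():
    rng = np.random.default_rng(0)
    for w in [np.zeros(3), rng.normal(size=3), 1e-9 * rng.normal(size=3)]:
        r, jacs = shape._rot_and_jac(w)
        for k in range(3):
            eps = 1e-7
            wp, wm = w.copy(), w.copy()
            wp[k] += eps
            wm[k] -= eps
            num = (shape._rodrigues(wp) - shape._rodrigues(wm)) / (2 * eps)
            np.testing.assert_allclose(jacs[k], num, atol=1e-6)


def test_sdf_roundtrip(tmp_path, small_molecules):
    mols = [small_molecules["ethanol"], small_molecules["phenol"]]
    path = tmp_path / "out.sdf"
    shape.write_sdf(mols, path)
    back = shape.read_sdf(path)
    assert [m.mol_id for m in back] == ["ethanol", "phenol"]
    # SDF stores 4 decimal places
    np.testing.assert_allclose(back[0].coords, mols[0].coords, atol=1e-3)
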