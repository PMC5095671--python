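"""3D conformer handling, rigid superposition and morphological similarity scoring.

A molecule is modelled as a sum of atom-centred spherical Gaussians
(Grant-Pickup parametrization: amplitude ``p`` = 2.7, exponent
``alpha = kappa / r_vdw**2`` with ``kappa ~ 2.344`` chosen so each Gaussian
integrates to the hard-sphere van der Waals volume).  Similarity between two
rigid conformers is the volume-overlap Tanimoto

    T_shape = O_AB / (O_AA + O_BB - O_AB),   O_XY = integral rho_X * rho_Y dV,

blended 50/50 with an analogous Tanimoto over matching pharmacophoric
feature centres (donor-donor, acceptor-acceptor, positive-positive,
negative-negative), so the score reflects both surface shape and charge
characteristics and always lies in [0, 1].

Superposition maximises this score over rigid motions of the query with a
quasi-Newton optimizer on a rotation-vector + translation parameterization
(analytic gradients), started from centroid-aligned principal-axes
orientations plus seeded random rotations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, ChemicalFeatures

__all__ = [
    "Molecule3D",
    "Pose",
    "embed_molecule",
    "pose_score",
    "superimpose",
    "best_score",
    "apply_pose",
    "read_sdf",
    "write_sdf",
    "FEATURE_CHANNELS",
]

# Gaussian-sphere parametrization (amplitude and width constant).
P_AMP = 2.7
KAPPA = np.pi * (3.0 * P_AMP / (4.0 * np.pi)) ** (2.0 / 3.0)  # ~2.344
#: radius (Angstrom) of the Gaussian placed on each pharmacophore centre
FEATURE_RADIUS = 1.0

FEATURE_CHANNELS = ("DONOR", "ACCEPTOR", "POS", "NEG")
_FAMILY_TO_CHANNEL = {
    "Donor": "DONOR",
    "Acceptor": "ACCEPTOR",
    "PosIonizable": "POS",
    "NegIonizable": "NEG",
}

_FEATURE_FACTORY = None


def _feature_factory():
    global _FEATURE_FACTORY
    if _FEATURE_FACTORY is None:
        fdef = os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        _FEATURE_FACTORY = ChemicalFeatures.BuildFeatureFactory(fdef)
    return _FEATURE_FACTORY


@dataclass
class Molecule3D:
    """A single minimized 3D conformer, heavy atoms only.

    ``flags`` maps each pharmacophore channel to a boolean mask over the
    heavy atoms; a flagged atom contributes a unit-radius Gaussian to that
    channel during feature scoring.
    """

    mol_id: str
    elements: tuple
    coords: np.ndarray  # (n_heavy, 3) Angstrom
    charges: np.ndarray  # Gasteiger partial charges, e
    radii: np.ndarray  # vdW radii, Angstrom
    flags: dict = field(default_factory=dict)
    rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) < 1:
            raise ValueError(f"{self.mol_id}: need >= 1 heavy atom with 3D coordinates")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.mol_id}: non-finite coordinates")
        if np.any(self.radii <= 0):
            raise ValueError(f"{self.mol_id}: vdW radii must be positive")
        for ch in FEATURE_CHANNELS:
            self.flags.setdefault(ch, np.zeros(len(self.coords), dtype=bool))

    @property
    def n_heavy(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def feature_coords(self, channel: str) -> np.ndarray:
        return self.coords[self.flags[channel]]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule3D":
        """Return a copy with coordinates mapped through x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_coords = self.coords @ rotation.T + translation
        rd = None
        if self.rdmol is not None:
            rd = Chem.Mol(self.rdmol)
            conf = rd.GetConformer()
            pos = conf.GetPositions() @ rotation.T + translation
            for i, p in enumerate(pos):
                conf.SetAtomPosition(i, p.tolist())
        return Molecule3D(
            mol_id=self.mol_id,
            elements=self.elements,
            coords=new_coords,
            charges=self.charges.copy(),
            radii=self.radii.copy(),
            flags={ch: m.copy() for ch, m in self.flags.items()},
            rdmol=rd,
        )


@dataclass
class Pose:
    """Rigid motion of a query into a template frame plus its similarity score."""

    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # (3,) Angstrom
    score: float

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("pose rotation must be a proper rotation (det +1)")
        if not (-1e-9 <= self.score <= 1.0 + 1e-9):
            raise ValueError("pose score must lie in [0, 1]")
        self.score = float(min(max(self.score, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Embedding / IO
# ---------------------------------------------------------------------------


def _derived_seed(seed: int, salt: int = 0) -> int:
    return int((int(seed) * 2654435761 + 97 + salt * 40503) % (2**31 - 1)) + 1


def _from_rdkit(mol: Chem.Mol, mol_id: str) -> Molecule3D:
    if mol.GetNumConformers() == 0:
        raise ValueError(f"{mol_id}: molecule has no 3D conformer")
    AllChem.ComputeGasteigerCharges(mol)
    pt = Chem.GetPeriodicTable()
    conf = mol.GetConformer()
    pos = conf.GetPositions()

    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if not heavy:
        raise ValueError(f"{mol_id}: no heavy atoms")
    idx_map = {a: i for i, a in enumerate(heavy)}

    flags = {ch: np.zeros(len(heavy), dtype=bool) for ch in FEATURE_CHANNELS}
    for feat in _feature_factory().GetFeaturesForMol(mol):
        ch = _FAMILY_TO_CHANNEL.get(feat.GetFamily())
        if ch is None:
            continue
        for a in feat.GetAtomIds():
            if a in idx_map:
                flags[ch][idx_map[a]] = True
    # formal charges always count as ionizable centres
    for a in mol.GetAtoms():
        if a.GetIdx() in idx_map and a.GetFormalCharge() != 0:
            ch = "POS" if a.GetFormalCharge() > 0 else "NEG"
            flags[ch][idx_map[a.GetIdx()]] = True

    charges = np.array(
        [float(mol.GetAtomWithIdx(a).GetProp("_GasteigerCharge")) for a in heavy]
    )
    charges = np.nan_to_num(charges)
    return Molecule3D(
        mol_id=mol_id,
        elements=tuple(mol.GetAtomWithIdx(a).GetSymbol() for a in heavy),
        coords=pos[heavy],
        charges=charges,
        radii=np.array([pt.GetRvdw(mol.GetAtomWithIdx(a).GetAtomicNum()) for a in heavy]),
        flags=flags,
        rdmol=mol,
    )


def embed_molecule(source, seed: int = 0, mol_id: str | None = None) -> Molecule3D:
    """Parse a SMILES string (or take an RDKit mol), embed one minimized 3D
    conformer (distance geometry + MMFF/UFF minimization) and assign Gasteiger
    charges and pharmacophore flags.  Deterministic for a fixed seed."""
    if isinstance(source, Chem.Mol):
        mol = Chem.Mol(source)
        if mol_id is None:
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else "mol"
        if mol.GetNumConformers() > 0:
            mol = Chem.AddHs(mol, addCoords=True)
            return _from_rdkit(mol, mol_id)
    else:
        mol = Chem.MolFromSmiles(str(source))
        if mol is None:
            raise ValueError(f"unparseable structure: {source!r}")
        if mol_id is None:
            mol_id = str(source)
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = _derived_seed(seed)
    ok = AllChem.EmbedMolecule(mol, params)
    attempts = 1
    while ok != 0 and attempts < 5:
        params.randomSeed = _derived_seed(seed, attempts)
        params.useRandomCoords = True
        ok = AllChem.EmbedMolecule(mol, params)
        attempts += 1
    if ok != 0:
        raise ValueError(f"{mol_id}: 3D embedding failed after {attempts} attempts")
    try:
        if AllChem.MMFFHasAllMoleculeParams(mol):
            AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
        else:
            AllChem.UFFOptimizeMolecule(mol, maxIters=500)
    except Exception:  # minimization failure leaves the raw embedding
        pass
    mol.SetProp("_Name", mol_id)
    return _from_rdkit(mol, mol_id)


def read_sdf(path) -> list:
    """Read a V2000 SDF into Molecule3D records (coordinates taken as-is)."""
    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparseable SDF record #{i} in {path}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        mol = Chem.AddHs(mol, addCoords=True)
        out.append(_from_rdkit(mol, name))
    return out


def write_sdf(mols, path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            if m.rdmol is None:
                raise ValueError(f"{m.mol_id}: no underlying structure to write")
            rd = Chem.Mol(m.rdmol)
            rd.SetProp("_Name", m.mol_id)
            writer.write(rd)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Gaussian overlap machinery
# ---------------------------------------------------------------------------


def _alphas(mol: Molecule3D) -> np.ndarray:
    return KAPPA / mol.radii**2


def _pair_consts(alpha_a: np.ndarray, alpha_b: np.ndarray):
    """Distance-independent constants of the pairwise Gaussian product integral."""
    s = alpha_a[:, None] + alpha_b[None, :]
    gamma = alpha_a[:, None] * alpha_b[None, :] / s
    pref = P_AMP * P_AMP * (np.pi / s) ** 1.5
    return gamma, pref


def _overlap(coords_a, alpha_a, coords_b, alpha_b) -> float:
    """O_AB = integral rho_A rho_B dV for two Gaussian atom clouds."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0.0
    gamma, pref = _pair_consts(alpha_a, alpha_b)
    d2 = cdist(coords_a, coords_b, "sqeuclidean")
    return float(np.sum(pref * np.exp(-gamma * d2)))


def _tanimoto(o_ab: float, o_aa: float, o_bb: float) -> float:
    denom = o_aa + o_bb - o_ab
    if denom <= 0:
        return 0.0
    return o_ab / denom


class _PairContext:
    """Precomputed quantities for scoring one (query, template) pair.

    Works in centroid-centred frames; only inter-molecular squared distances
    change with the pose, so all pair prefactors are computed once.
    """

    def __init__(self, query: Molecule3D, template: Molecule3D, w_shape: float = 0.5):
        self.w_shape = float(w_shape)
        self.q_center = query.centroid
        self.t_center = template.centroid
        qa, ta = _alphas(query), _alphas(template)
        self.qc = query.coords - self.q_center
        self.tc = template.coords - self.t_center
        self.gamma_s, self.pref_s = _pair_consts(qa, ta)
        self.o_qq = _overlap(self.qc, qa, self.qc, qa)
        self.o_tt = _overlap(self.tc, ta, self.tc, ta)

        af = KAPPA / FEATURE_RADIUS**2
        self.alpha_f = af
        self.gamma_f = af / 2.0
        self.pref_f = P_AMP * P_AMP * (np.pi / (2.0 * af)) ** 1.5
        self.fpairs = []  # (query feature coords centered, template feature coords)
        o_ff_q = o_ff_t = 0.0
        self.n_feat_q = self.n_feat_t = 0
        for ch in FEATURE_CHANNELS:
            fq = query.feature_coords(ch) - self.q_center
            ft = template.feature_coords(ch) - self.t_center
            self.n_feat_q += len(fq)
            self.n_feat_t += len(ft)
            alph = np.full(max(len(fq), len(ft), 1), af)
            o_ff_q += _overlap(fq, alph[: len(fq)], fq, alph[: len(fq)])
            o_ff_t += _overlap(ft, alph[: len(ft)], ft, alph[: len(ft)])
            if len(fq) and len(ft):
                self.fpairs.append((fq, ft))
        self.o_ff_self = o_ff_q + o_ff_t
        self.use_features = (self.n_feat_q + self.n_feat_t) > 0

    # -- scoring ------------------------------------------------------------

    def score(self, qc_posed: np.ndarray, fq_posed: list) -> float:
        d2 = cdist(qc_posed, self.tc, "sqeuclidean")
        o_ab = float(np.sum(self.pref_s * np.exp(-self.gamma_s * d2)))
        t_shape = _tanimoto(o_ab, self.o_qq, self.o_tt)
        if not self.use_features:
            return t_shape
        o_f = 0.0
        for fq, (_, ft) in zip(fq_posed, self.fpairs):
            d2f = cdist(fq, ft, "sqeuclidean")
            o_f += float(np.sum(self.pref_f * np.exp(-self.gamma_f * d2f)))
        t_feat = _tanimoto(o_f, 0.0, self.o_ff_self)
        return self.w_shape * t_shape + (1.0 - self.w_shape) * t_feat

    def score_and_coord_grad(self, qc_posed: np.ndarray, fq_posed: list):
        """Score plus its gradient w.r.t. the posed query coordinates."""
        d2 = (
            np.einsum("ik,ik->i", qc_posed, qc_posed)[:, None]
            + np.einsum("jk,jk->j", self.tc, self.tc)[None, :]
            - 2.0 * qc_posed @ self.tc.T
        )
        e = self.pref_s * np.exp(-self.gamma_s * d2)
        o_ab = float(e.sum())
        denom = self.o_qq + self.o_tt - o_ab
        t_shape = o_ab / denom if denom > 0 else 0.0
        # dT/dO = (O_AA + O_BB) / denom**2
        dt_do = (self.o_qq + self.o_tt) / denom**2 if denom > 0 else 0.0
        ge = self.gamma_s * e
        # sum_j ge_ij (x_i - y_j) = x_i * rowsum(ge) - ge @ y
        g_shape = -2.0 * dt_do * (
            qc_posed * ge.sum(axis=1)[:, None] - ge @ self.tc
        )

        if not self.use_features:
            return t_shape, g_shape, []

        o_f = 0.0
        pieces = []
        for fq, (_, ft) in zip(fq_posed, self.fpairs):
            d2f = (
                np.einsum("ik,ik->i", fq, fq)[:, None]
                + np.einsum("jk,jk->j", ft, ft)[None, :]
                - 2.0 * fq @ ft.T
            )
            ef = self.pref_f * np.exp(-self.gamma_f * d2f)
            o_f += float(ef.sum())
            pieces.append((fq, ft, ef))
        denf = self.o_ff_self - o_f
        t_feat = o_f / denf if denf > 0 else 0.0
        dtf_do = self.o_ff_self / denf**2 if denf > 0 else 0.0
        g_feat = []
        for fq, ft, ef in pieces:
            g_feat.append(
                -2.0 * self.gamma_f * dtf_do * (1.0 - self.w_shape)
                * (fq * ef.sum(axis=1)[:, None] - ef @ ft)
            )
        score = self.w_shape * t_shape + (1.0 - self.w_shape) * t_feat
        return score, self.w_shape * g_shape, g_feat

    def batch_local_step(self, V, VF, Rcur, T):
        """Vectorized score and local-frame gradient over many starts at once.

        V: (s, n, 3) start-rotated centred query coords; VF: per feature-pair
        (s, nf, 3); Rcur: (s, 3, 3) current rotations; T: (s, 3) translations.
        Returns scores (s,), the torque dOmega (s, 3) — the gradient w.r.t. an
        infinitesimal left-composed rotation — and dT (s, 3).
        """
        n_s = len(T)
        dOm = np.zeros((n_s, 3))
        dT = np.zeros((n_s, 3))

        def cloud_terms(base, target, gamma, pref):
            x = np.einsum("sab,snb->sna", Rcur, base) + T[:, None, :]
            d2 = (
                np.einsum("snk,snk->sn", x, x)[:, :, None]
                + np.einsum("mk,mk->m", target, target)[None, None, :]
                - 2.0 * np.einsum("sna,ma->snm", x, target)
            )
            e = pref * np.exp(-gamma * d2)
            return x, e

        x, e = cloud_terms(V, self.tc, self.gamma_s, self.pref_s)
        o_ab = e.sum(axis=(1, 2))
        denom = np.maximum(self.o_qq + self.o_tt - o_ab, 1e-300)
        t_shape = o_ab / denom
        dt_do = (self.o_qq + self.o_tt) / denom**2
        ge = self.gamma_s * e
        g = -2.0 * dt_do[:, None, None] * (
            x * ge.sum(axis=2)[:, :, None] - np.einsum("snm,ma->sna", ge, self.tc)
        )
        scores = self.w_shape * t_shape if self.use_features else t_shape
        g = g * (self.w_shape if self.use_features else 1.0)
        dT += g.sum(axis=1)
        # d score / d omega_k = sum_i (y_i x g_i)_k with y the rotated coords
        dOm += _batch_cross_sum(x - T[:, None, :], g)

        if self.use_features:
            o_f = np.zeros(n_s)
            feat_pieces = []
            for vf, (_, ft) in zip(VF, self.fpairs):
                xf, ef = cloud_terms(vf, ft, self.gamma_f, self.pref_f)
                o_f += ef.sum(axis=(1, 2))
                feat_pieces.append((xf, ft, ef))
            denf = np.maximum(self.o_ff_self - o_f, 1e-300)
            t_feat = o_f / denf
            dtf_do = self.o_ff_self / denf**2
            scores = scores + (1.0 - self.w_shape) * t_feat
            for xf, ft, ef in feat_pieces:
                gf = (
                    -2.0
                    * self.gamma_f
                    * (1.0 - self.w_shape)
                    * dtf_do[:, None, None]
                    * (xf * ef.sum(axis=2)[:, :, None] - np.einsum("snm,ma->sna", ef, ft))
                )
                dT += gf.sum(axis=1)
                dOm += _batch_cross_sum(xf - T[:, None, :], gf)
        return scores, dOm, dT


def _batch_cross_sum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """sum_n a_sn x b_sn for (s, n, 3) arrays -> (s, 3)."""
    return np.stack(
        [
            (a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]).sum(axis=1),
            (a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]).sum(axis=1),
            (a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]).sum(axis=1),
        ],
        axis=1,
    )


def _cross_mat(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


def _cross(a, b):
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def _rodrigues(w: np.ndarray) -> np.ndarray:
    theta2 = float(w @ w)
    wx = _cross_mat(w)
    if theta2 < 1e-16:
        return np.eye(3) + wx + 0.5 * (wx @ wx)
    theta = np.sqrt(theta2)
    return (
        np.eye(3)
        + (np.sin(theta) / theta) * wx
        + ((1.0 - np.cos(theta)) / theta2) * (wx @ wx)
    )


def _rot_and_jac(w: np.ndarray):
    """Rotation matrix of a rotation vector and the three matrices dR/dw_k."""
    theta2 = float(w @ w)
    R = _rodrigues(w)
    jacs = []
    eye = np.eye(3)
    if theta2 < 1e-16:
        for k in range(3):
            jacs.append(_cross_mat(eye[k]) @ R)
    else:
        wx = _cross_mat(w)
        imr = eye - R
        for k in range(3):
            a = w[k] * wx + _cross_mat(_cross(w, imr[:, k]))
            jacs.append(a @ R / theta2)
    return R, jacs


def _rodrigues_batch(W: np.ndarray) -> np.ndarray:
    """Rotation matrices for a batch of rotation vectors, shape (s, 3, 3)."""
    s = len(W)
    theta2 = np.einsum("sk,sk->s", W, W)
    theta = np.sqrt(theta2)
    small = theta < 1e-8
    a = np.where(small, 1.0 - theta2 / 6.0, np.sin(theta) / np.where(small, 1.0, theta))
    b = np.where(
        small, 0.5 - theta2 / 24.0, (1.0 - np.cos(theta)) / np.where(small, 1.0, theta2)
    )
    WX = np.zeros((s, 3, 3))
    WX[:, 0, 1], WX[:, 0, 2] = -W[:, 2], W[:, 1]
    WX[:, 1, 0], WX[:, 1, 2] = W[:, 2], -W[:, 0]
    WX[:, 2, 0], WX[:, 2, 1] = -W[:, 1], W[:, 0]
    WX2 = WX @ WX
    return np.eye(3)[None] + a[:, None, None] * WX + b[:, None, None] * WX2


def _rotvec_jacobians_batch(W: np.ndarray, R: np.ndarray) -> np.ndarray:
    """dR/dw_k for a batch of rotation vectors; result shape (s, 3, 3, 3)."""
    s = len(W)
    theta2 = np.einsum("sk,sk->s", W, W)
    out = np.zeros((s, 3, 3, 3))
    eye = np.eye(3)
    small = theta2 < 1e-16
    for k in range(3):
        ek_cross = _cross_mat(eye[k])
        out[:, k] = ek_cross[None] @ R
    big = ~small
    if np.any(big):
        Wb, Rb, t2 = W[big], R[big], theta2[big]
        WX = np.zeros((len(Wb), 3, 3))
        WX[:, 0, 1], WX[:, 0, 2] = -Wb[:, 2], Wb[:, 1]
        WX[:, 1, 0], WX[:, 1, 2] = Wb[:, 2], -Wb[:, 0]
        WX[:, 2, 0], WX[:, 2, 1] = -Wb[:, 1], Wb[:, 0]
        imr = eye[None] - Rb
        res = np.zeros((len(Wb), 3, 3, 3))
        for k in range(3):
            u = np.cross(Wb, imr[:, :, k])
            UX = np.zeros((len(Wb), 3, 3))
            UX[:, 0, 1], UX[:, 0, 2] = -u[:, 2], u[:, 1]
            UX[:, 1, 0], UX[:, 1, 2] = u[:, 2], -u[:, 0]
            UX[:, 2, 0], UX[:, 2, 1] = -u[:, 1], u[:, 0]
            A = Wb[:, k, None, None] * WX + UX
            res[:, k] = (A @ Rb) / t2[:, None, None]
        out[big] = res
    return out


def pose_score(
    a: Molecule3D,
    b: Molecule3D,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    w_shape: float = 0.5,
) -> float:
    """Morphological similarity of ``a`` (optionally posed through x -> R x + t)
    against ``b``, in [0, 1]."""
    if rotation is None:
        rotation = np.eye(3)
    if translation is None:
        translation = np.zeros(3)
    posed = a.transformed(rotation, translation)
    ctx = _PairContext(posed, b, w_shape=w_shape)
    fq_posed = [fq for fq, _ in ctx.fpairs]
    # _PairContext centres both molecules; shift the query cloud into the
    # template-centred frame so relative geometry is preserved.
    shift = ctx.q_center - ctx.t_center
    return float(ctx.score(ctx.qc + shift, [fq + shift for fq in fq_posed]))


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=True)
    axes = vt.T
    if np.linalg.det(axes) < 0:
        axes[:, -1] *= -1
    return axes


_SIGN_COMBOS = [np.diag(d) for d in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))]


def superimpose(
    query: Molecule3D,
    template: Molecule3D,
    n_poses: int = 10,
    seed: int = 0,
    n_starts: int = 24,
    max_iter: int = 200,
    score_tol: float = 1e-4,
    dedup_rmsd: float = 0.25,
    w_shape: float = 0.5,
) -> list:
    """Rigidly superimpose ``query`` onto ``template`` maximizing the
    morphological similarity; return up to ``n_poses`` distinct local optima
    sorted by score descending.

    Starts are the 4 proper principal-axes sign combinations at centroid
    alignment plus seeded random rotations up to ``n_starts``.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    ctx = _PairContext(query, template, w_shape=w_shape)
    axes_q = _principal_axes(query.coords)
    axes_t = _principal_axes(template.coords)
    starts = [axes_t @ d @ axes_q.T for d in _SIGN_COMBOS]
    n_rand = max(n_starts - len(starts), 0)
    if n_rand:
        rng = np.random.default_rng(_derived_seed(seed))
        starts.extend(Rotation.random(n_rand, random_state=rng).as_matrix())

    fq0 = [fq for fq, _ in ctx.fpairs]
    n_all = len(starts)
    starts_arr = np.stack(starts)
    V = np.einsum("sab,nb->sna", starts_arr, ctx.qc)
    VF = [np.einsum("sab,nb->sna", starts_arr, fq) for fq in fq0]

    # phase 1: coarse vectorized ascent (Adam in local frames) over all starts
    Rcur = np.repeat(np.eye(3)[None], n_all, axis=0)
    T = np.zeros((n_all, 3))
    m_w = np.zeros((n_all, 3))
    v_w = np.zeros((n_all, 3))
    m_t = np.zeros((n_all, 3))
    v_t = np.zeros((n_all, 3))
    lr, b1, b2, eps = 0.1, 0.9, 0.999, 1e-8
    scores1 = np.zeros(n_all)
    for it in range(1, 31):
        scores1, dOm, dT = ctx.batch_local_step(V, VF, Rcur, T)
        m_w = b1 * m_w + (1 - b1) * dOm
        v_w = b2 * v_w + (1 - b2) * dOm * dOm
        step_w = lr * (m_w / (1 - b1**it)) / (np.sqrt(v_w / (1 - b2**it)) + eps)
        Rcur = _rodrigues_batch(step_w) @ Rcur
        m_t = b1 * m_t + (1 - b1) * dT
        v_t = b2 * v_t + (1 - b2) * dT * dT
        T += lr * (m_t / (1 - b1**it)) / (np.sqrt(v_t / (1 - b2**it)) + eps)

    # merge starts that have already fallen into the same basin, then polish
    # one representative per basin with a quasi-Newton local optimizer
    posed1 = np.einsum("sab,snb->sna", Rcur, V) + T[:, None, :]
    pre_tol = max(0.3, dedup_rmsd)
    order = sorted(range(n_all), key=lambda i: (-scores1[i], i))
    reps = []
    for i in order:
        if all(
            float(np.sqrt(np.mean(np.sum((posed1[i] - posed1[j]) ** 2, axis=1))))
            >= pre_tol
            for j in reps
        ):
            reps.append(i)

    results = []
    for start_idx in reps:
        v = Rcur[start_idx] @ V[start_idx].T
        v = v.T
        vf = [(Rcur[start_idx] @ f[start_idx].T).T for f in VF]

        def objective(params):
            w, t = params[:3], params[3:]
            R, jacs = _rot_and_jac(w)
            x = v @ R.T + t
            xf = [f @ R.T + t for f in vf]
            score, g_shape, g_feat = ctx.score_and_coord_grad(x, xf)
            grads = [(g_shape, v)] + list(zip(g_feat, vf))
            dt = np.zeros(3)
            dw = np.zeros(3)
            for g, base in grads:
                if len(g) == 0:
                    continue
                dt += g.sum(axis=0)
                for k in range(3):
                    dw[k] += float(np.sum(g * (base @ jacs[k].T)))
            return -score, -np.concatenate([dw, dt])

        res = minimize(
            objective,
            np.concatenate([np.zeros(3), T[start_idx]]),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": score_tol, "gtol": 1e-7},
        )
        w_opt, t_opt = res.x[:3], res.x[3:]
        r_full = _rodrigues(w_opt) @ Rcur[start_idx] @ starts_arr[start_idx]
        results.append((-float(res.fun), start_idx, r_full, t_opt))

    # deduplicate near-identical optima, keep the best-scoring representative
    results.sort(key=lambda r: (-r[0], r[1]))
    kept = []
    for score, start_idx, r_full, t_opt in results:
        posed = ctx.qc @ r_full.T + t_opt
        dup = False
        for _, _, pr, pt in kept:
            other = ctx.qc @ pr.T + pt
            rmsd = float(np.sqrt(np.mean(np.sum((posed - other) ** 2, axis=1))))
            if rmsd < dedup_rmsd:
                dup = True
                break
        if not dup:
            kept.append((score, start_idx, r_full, t_opt))
        if len(kept) >= n_poses:
            break

    poses = []
    for score, _, r_full, t_opt in kept:
        translation = ctx.t_center + t_opt - r_full @ ctx.q_center
        poses.append(Pose(rotation=r_full, translation=translation, score=score))
    return poses


def best_score(a: Molecule3D, b: Molecule3D, seed: int = 0, **kwargs) -> float:
    """Best superposition score of ``a`` onto ``b``."""
    return superimpose(a, b, n_poses=1, seed=seed, **kwargs)[0].score


def apply_pose(mol: Molecule3D, pose: Pose) -> Molecule3D:
    return mol.transformed(pose.rotation, pose.translation)
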