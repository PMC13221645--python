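"""Anisotropic network model (ANM) normal modes and ensemble RMSF.

The ANM coarse-grains a protein to its Cα atoms connected by uniform
harmonic springs within a distance cutoff (default 15 Å, spring constant
gamma = 1).  The 3N x 3N Hessian has super-elements

    H_ij = -(gamma / d_ij^2) (r_ij ⊗ r_ij)   for contacting pairs i != j,
    H_ii = -sum_{j != i} H_ij,

whose low-frequency eigenvectors approximate collective motions.  Six
eigenvalues vanish for a generic structure (rigid translations and
rotations; five for exactly collinear point sets).  "Mode 1" is the lowest
non-trivial mode; per-residue mobility is the Euclidean amplitude of its
unit eigenvector on each Cα — no 1/sqrt(eigenvalue) scaling is applied.

The ensemble side mirrors the standard trajectory protocol: frames are
superposed onto the first frame with a proper Kabsch rotation (removing
global translation/rotation), then the per-residue root mean square
fluctuation about the time-average position is computed in Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg
from sklearn.base import BaseEstimator

__all__ = [
    "StructureModel",
    "Trajectory",
    "ModeSet",
    "ResidueProfile",
    "AnisotropicNetworkModel",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "build_anm_hessian",
    "compute_modes",
    "mode_mobility",
    "superpose_to_first",
    "kabsch_rotation",
    "compute_rmsf",
]

DEFAULT_CUTOFF = 15.0
DEFAULT_N_MODES = 10
N_RIGID_GENERIC = 6
N_RIGID_COLLINEAR = 5

_BACKBONE_NAMES = ("N", "CA", "C")


@dataclass
class StructureModel:
    """Cα (plus optional backbone) coordinates of one structure.

    ``residue_ids`` is an ordered list of (chain, residue number, residue
    name) tuples; ``ca_coords`` is (N, 3) in Å; ``backbone_coords`` is an
    optional (N, 3, 3) array of N/CA/C positions per residue.
    """

    residue_ids: list
    ca_coords: np.ndarray
    backbone_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        n = len(self.residue_ids)
        if self.ca_coords.shape != (n, 3):
            raise ValueError(f"ca_coords must be ({n}, 3)")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("non-finite coordinates")
        if len(set(map(tuple, self.residue_ids))) != n:
            raise ValueError("residue_ids must be unique")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


@dataclass
class Trajectory:
    """Ordered frames over a fixed atom set (F, A, 3), Å."""

    frames: np.ndarray
    residue_ids: list
    atom_names: list | None = None
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, A, 3)")
        if self.frames.shape[0] < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if self.frames.shape[1] != len(self.residue_ids):
            raise ValueError("residue_ids must match atom count")
        if self.atom_names is None:
            self.atom_names = ["CA"] * self.frames.shape[1]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class ModeSet:
    """Non-trivial ANM eigenpairs plus rigid-mode bookkeeping.

    ``eigenvalues`` ascend and exclude the rigid-body (zero) modes;
    ``eigenvectors`` has one orthonormal 3N-vector per column.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero_modes: int
    cutoff_angstrom: float = DEFAULT_CUTOFF
    gamma: float = 1.0
    n_requested: int = DEFAULT_N_MODES

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def truncated(self) -> bool:
        """True when fewer non-trivial modes exist than were requested."""
        return self.n_modes < self.n_requested


@dataclass
class ResidueProfile:
    """Per-residue non-negative scalar profile (mobility: dimensionless
    eigenvector amplitude; RMSF: Å)."""

    residue_ids: list
    values: np.ndarray
    kind: str = "mobility"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.residue_ids):
            raise ValueError("values must match residue_ids length")
        if np.any(self.values < -1e-12):
            raise ValueError("profile values must be >= 0")


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _structure_from_atoms(atoms, backbone: bool) -> StructureModel:
    import biotite.structure as struc

    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValueError("no amino-acid atoms in file")
    ids, ca, bb = [], [], []
    skipped = []
    for start in struc.get_residue_starts(atoms):
        chain = atoms.chain_id[start]
        res_id = int(atoms.res_id[start])
        res_name = atoms.res_name[start]
        res_mask = (
            (atoms.chain_id == chain)
            & (atoms.res_id == res_id)
            & (atoms.res_name == res_name)
        )
        res = atoms[res_mask]
        ca_mask = res.atom_name == "CA"
        if not ca_mask.any():
            skipped.append((chain, res_id, res_name))
            continue
        ids.append((str(chain), res_id, str(res_name)))
        ca.append(res.coord[ca_mask][0])
        if backbone:
            triple = []
            ok = True
            for name in _BACKBONE_NAMES:
                m = res.atom_name == name
                if not m.any():
                    ok = False
                    break
                triple.append(res.coord[m][0])
            bb.append(np.asarray(triple) if ok else np.full((3, 3), np.nan))
    if skipped:
        warnings.warn(f"skipped {len(skipped)} residue(s) without CA: {skipped[:5]}")
    if not ids:
        raise ValueError("no residues with CA atoms")
    return StructureModel(
        residue_ids=ids,
        ca_coords=np.asarray(ca),
        backbone_coords=np.asarray(bb) if backbone and bb else None,
    )


def read_structure(path, chain: str | None = None, backbone: bool = False) -> StructureModel:
    """Read Cα (and optionally N/CA/C backbone) atoms from a PDB file.

    Model 1 is used; alternate locations resolve to the first (blank/'A')
    conformer.  Residues lacking a Cα atom are skipped with a warning.
    """
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    atoms = f.get_structure(model=1, altloc="first")
    if chain is not None:
        atoms = atoms[atoms.chain_id == chain]
        if atoms.array_length() == 0:
            raise ValueError(f"no atoms for chain {chain!r}")
    return _structure_from_atoms(atoms, backbone)


def read_trajectory(path, selection: str = "ca") -> Trajectory:
    """Read a multi-model PDB ensemble (MODEL/ENDMDL records).

    ``selection`` is ``"ca"`` (Cα only) or ``"backbone"`` (N, CA, C).
    All models must share one atom set.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure(altloc="first")
    stack = stack[:, struc.filter_amino_acids(stack)]
    if selection == "ca":
        mask = stack.atom_name == "CA"
    elif selection == "backbone":
        mask = np.isin(stack.atom_name, _BACKBONE_NAMES)
    else:
        raise ValueError("selection must be 'ca' or 'backbone'")
    stack = stack[:, mask]
    if stack.array_length() == 0:
        raise ValueError("selection matched no atoms")
    ids = [
        (str(c), int(r), str(n))
        for c, r, n in zip(stack.chain_id, stack.res_id, stack.res_name)
    ]
    return Trajectory(
        frames=np.asarray(stack.coord, dtype=float),
        residue_ids=ids,
        atom_names=[str(a) for a in stack.atom_name],
    )


def _to_atom_array(structure: StructureModel):
    import biotite.structure as struc

    n = structure.n_residues
    arr = struc.AtomArray(n)
    arr.coord = structure.ca_coords.astype(np.float32)
    arr.chain_id = np.array([r[0] for r in structure.residue_ids])
    arr.res_id = np.array([r[1] for r in structure.residue_ids])
    arr.res_name = np.array([r[2] for r in structure.residue_ids])
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_structure(structure: StructureModel, path) -> None:
    """Write a Cα-only structure as a standard PDB file."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile()
    f.set_structure(_to_atom_array(structure))
    f.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write an ensemble as a multi-model (MODEL/ENDMDL) PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    ref = StructureModel(residue_ids=traj.residue_ids, ca_coords=traj.frames[0])
    template = _to_atom_array(ref)
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = traj.frames.astype(np.float32)
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


# ---------------------------------------------------------------------------
# ANM core
# ---------------------------------------------------------------------------

def build_anm_hessian(coords, cutoff: float = DEFAULT_CUTOFF, gamma: float = 1.0) -> np.ndarray:
    """Assemble the 3N x 3N ANM Hessian from Cα coordinates.

    Pairs with d_ij <= cutoff (inclusive) interact through a spring of
    uniform constant gamma; the matrix is symmetric positive semidefinite
    with zero row sums per axis.

    Raises on coincident coordinates; warns on isolated (contact-free)
    nodes.
    """
    coords = np.asarray(coords, dtype=float)
    if isinstance(coords, np.ndarray) and coords.ndim != 2:
        raise ValueError("coords must be (N, 3)")
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = np.sum(diff**2, axis=-1)
    iu = np.triu_indices(n, k=1)
    if np.any(d2[iu] == 0.0):
        raise ValueError("duplicate coordinates (zero inter-node distance)")
    contact = (d2 <= cutoff**2)
    np.fill_diagonal(contact, False)
    if np.any(~contact.any(axis=1)):
        isolated = np.nonzero(~contact.any(axis=1))[0]
        warnings.warn(f"isolated nodes without contacts: {isolated.tolist()}")

    h = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(contact, k=1))
    for i, j in zip(ii, jj):
        rij = diff[j, i]  # r_j - r_i
        block = -gamma * np.outer(rij, rij) / d2[i, j]
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return h


def _zero_threshold(eigenvalues: np.ndarray) -> float:
    largest = float(np.max(eigenvalues)) if len(eigenvalues) else 0.0
    return max(1e-8, 1e-10 * largest)


def compute_modes(
    hessian,
    n_nontrivial: int = DEFAULT_N_MODES,
    solver: str = "dense",
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = 1.0,
) -> ModeSet:
    """Eigendecompose an ANM Hessian and return the lowest non-trivial modes.

    Rigid-body (zero) modes are detected with a spectrum-relative floor,
    ``max(1e-8, 1e-10 * lambda_max)``.  ``solver="dense"`` uses a full
    symmetric eigendecomposition; ``solver="sparse"`` a shift-invert
    Lanczos iteration on the sparse matrix.  If fewer non-trivial modes
    exist than requested, the available ones are returned (``truncated``
    set on the ModeSet).
    """
    if solver == "dense":
        h = np.asarray(hessian.todense()) if scipy.sparse.issparse(hessian) else np.asarray(hessian)
        evals, evecs = scipy.linalg.eigh(h)
        lam_max = float(evals[-1])
    elif solver == "sparse":
        h = scipy.sparse.csr_matrix(hessian)
        dim = h.shape[0]
        k = min(N_RIGID_GENERIC + n_nontrivial + 2, dim - 1)
        evals, evecs = scipy.sparse.linalg.eigsh(h, k=k, sigma=-1e-4, which="LM")
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
        lam_max = float(
            scipy.sparse.linalg.eigsh(h, k=1, which="LA", return_eigenvectors=False)[0]
        )
    else:
        raise ValueError("solver must be 'dense' or 'sparse'")

    thr = max(1e-8, 1e-10 * lam_max)
    nonzero = evals > thr
    n_zero = int(np.sum(~nonzero))
    keep = np.nonzero(nonzero)[0][:n_nontrivial]
    return ModeSet(
        eigenvalues=np.asarray(evals[keep], dtype=float),
        eigenvectors=np.asarray(evecs[:, keep], dtype=float),
        n_zero_modes=n_zero,
        cutoff_angstrom=cutoff,
        gamma=gamma,
        n_requested=n_nontrivial,
    )


def mode_mobility(modes: ModeSet, mode_index: int = 1, residue_ids=None) -> ResidueProfile:
    """Per-residue displacement amplitude along one non-trivial mode.

    ``mode_index`` counts from 1 (= lowest non-trivial mode).  The value
    for residue i is the Euclidean norm of the (x, y, z) components of the
    unit eigenvector — unscaled, so the squared values sum to one.
    """
    if not 1 <= mode_index <= modes.n_modes:
        raise ValueError(
            f"mode_index must be in [1, {modes.n_modes}], got {mode_index}"
        )
    v = modes.eigenvectors[:, mode_index - 1].reshape(-1, 3)
    values = np.linalg.norm(v, axis=1)
    if residue_ids is None:
        residue_ids = [("A", i + 1, "UNK") for i in range(len(values))]
    return ResidueProfile(residue_ids=list(residue_ids), values=values, kind="mobility")


class AnisotropicNetworkModel(BaseEstimator):
    """scikit-learn-style estimator for ANM normal modes.

    Fit on an (N, 3) Cα coordinate array (or a StructureModel); exposes
    the Hessian, the non-trivial eigenpairs and per-residue mobilities as
    fitted attributes.

    Parameters
    ----------
    cutoff : float
        Contact cutoff in Å (pairs at d <= cutoff interact).  Default 15.
    gamma : float
        Uniform spring constant.  Default 1.
    n_modes : int
        Number of non-trivial modes to retain.  Default 10.
    solver : {"dense", "sparse"}
        Eigensolver backend.
    """

    def __init__(self, cutoff: float = DEFAULT_CUTOFF, gamma: float = 1.0,
                 n_modes: int = DEFAULT_N_MODES, solver: str = "dense"):
        self.cutoff = cutoff
        self.gamma = gamma
        self.n_modes = n_modes
        self.solver = solver

    def fit(self, X, y=None):
        if isinstance(X, StructureModel):
            coords = X.ca_coords
            self.residue_ids_ = list(X.residue_ids)
        else:
            coords = np.asarray(X, dtype=float)
            self.residue_ids_ = [("A", i + 1, "UNK") for i in range(len(coords))]
        if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) < 3:
            raise ValueError("X must be an (N>=3, 3) coordinate array")
        self.hessian_ = build_anm_hessian(coords, self.cutoff, self.gamma)
        modes = compute_modes(
            self.hessian_, n_nontrivial=self.n_modes, solver=self.solver,
            cutoff=self.cutoff, gamma=self.gamma,
        )
        self.modes_ = modes
        self.eigenvalues_ = modes.eigenvalues
        self.eigenvectors_ = modes.eigenvectors
        self.n_zero_modes_ = modes.n_zero_modes
        return self

    def mobility(self, mode_index: int = 1) -> ResidueProfile:
        """Per-residue amplitude profile of one fitted mode (1-based)."""
        if not hasattr(self, "modes_"):
            raise AttributeError("call fit first")
        return mode_mobility(self.modes_, mode_index, residue_ids=self.residue_ids_)


# ---------------------------------------------------------------------------
# superposition and RMSF
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper least-squares rotation (det = +1) mapping centred ``mobile``
    onto centred ``target``."""
    cov = mobile.T @ target
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def _selection_mask(traj: Trajectory, selection: str) -> np.ndarray:
    names = np.asarray(traj.atom_names)
    if selection == "all":
        return np.ones(traj.n_atoms, dtype=bool)
    if selection == "ca":
        return names == "CA"
    if selection == "backbone":
        return np.isin(names, _BACKBONE_NAMES)
    raise ValueError("selection must be 'all', 'ca' or 'backbone'")


def superpose_to_first(traj: Trajectory, selection: str = "backbone") -> Trajectory:
    """Rigid-body align every frame onto frame 1 (Kabsch, proper rotation).

    The least-squares rotation/translation is computed on the selection
    atoms (falling back to all atoms if the selection is empty) and
    applied to the whole frame.  Collinear selections leave the rotation
    underdetermined and raise.
    """
    mask = _selection_mask(traj, selection)
    if not mask.any():
        mask = np.ones(traj.n_atoms, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need at least 3 selection atoms for superposition")
    ref_sel = traj.frames[0][mask]
    ref_centroid = ref_sel.mean(axis=0)
    centred_ref = ref_sel - ref_centroid
    s = np.linalg.svd(centred_ref, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("collinear selection: rotation is underdetermined")

    aligned = np.empty_like(traj.frames)
    aligned[0] = traj.frames[0]
    for f in range(1, traj.n_frames):
        sel = traj.frames[f][mask]
        centroid = sel.mean(axis=0)
        rot = kabsch_rotation(sel - centroid, centred_ref)
        aligned[f] = (traj.frames[f] - centroid) @ rot.T + ref_centroid
    return Trajectory(
        frames=aligned,
        residue_ids=list(traj.residue_ids),
        atom_names=list(traj.atom_names),
        frame_times=traj.frame_times,
    )


def compute_rmsf(traj: Trajectory, atoms: str = "ca") -> ResidueProfile:
    """Per-residue RMSF (Å) of an aligned ensemble.

    RMSF_i = sqrt(mean_f |r_i(f) - r̄_i|^2) with r̄_i the time-average
    position.  The trajectory must already be superposed; a single frame
    has no defined fluctuation and raises.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF undefined for a single frame")
    mask = _selection_mask(traj, atoms)
    if not mask.any():
        raise ValueError("selection matched no atoms")
    xyz = traj.frames[:, mask, :]
    mean_pos = xyz.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((xyz - mean_pos) ** 2, axis=2), axis=0))
    ids = [rid for rid, m in zip(traj.residue_ids, mask) if m]
    return ResidueProfile(residue_ids=ids, values=rmsf, kind="rmsf")
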