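"""Macromolecular structure handling for receptor preparation.

Reading and writing of fixed-column PDB files, least-squares rigid backbone
superposition (Kabsch), and grafting of a single residue from a donor
structure into a target structure.  The motivating use case is building a
screening-compatible AdoMetDC model by replacing the catalytic pyruvoyl
group (residue 68) of an active structure with the unprocessed Ser68 of a
mutant structure, after aligning the two protein backbones.

Non-standard residues such as the pyruvoyl group are treated as opaque
HETATM residues; no chemical perception is attempted.  Coordinates are kept
in Angstroms exactly as read, with no re-centering.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Superposition",
    "read_pdb",
    "write_pdb",
    "superpose_backbone",
    "apply_superposition",
    "graft_residue",
    "BACKBONE_ATOMS",
]

#: Default backbone atom set used for superposition.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

_MAX_SERIAL = 99999


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure model.

    ``hetero`` preserves the ATOM/HETATM distinction so that non-standard
    residues (e.g. a pyruvoyl group) survive a write/read round trip.
    """

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    alt_loc: str = ""
    occupancy: float = 1.0
    hetero: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy must lie in [0, 1], got {self.occupancy}")
        object.__setattr__(self, "position", (float(pos[0]), float(pos[1]), float(pos[2])))


@dataclasses.dataclass
class StructureModel:
    """An ordered collection of atoms from one model of a structure file.

    Residue numbering is *not* assumed monotone within a chain; residues are
    addressed by ``(chain_id, residue_number)`` keys.
    """

    atoms: list[AtomRecord]
    source_id: str = ""
    model_index: int = 1

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("StructureModel must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureModel):
            return NotImplemented
        return self.atoms == other.atoms

    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Angstroms."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[int]:
        """Indices of the atoms belonging to one residue, in file order."""
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Copy of the model with ``x -> R x + t`` applied to every atom."""
        new_xyz = self.coords() @ np.asarray(rotation).T + np.asarray(translation)
        atoms = [
            dataclasses.replace(a, position=tuple(xyz))
            for a, xyz in zip(self.atoms, new_xyz)
        ]
        return StructureModel(atoms, source_id=self.source_id, model_index=self.model_index)


@dataclasses.dataclass(frozen=True)
class Superposition:
    """A proper rigid transform ``x -> rotation @ x + translation``.

    ``rmsd`` is the post-fit RMSD over the ``n_atoms_used`` paired atoms.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms_used: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be a 3x3 matrix with determinant +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ np.asarray(self.rotation).T + np.asarray(self.translation)


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    # Keep, per (chain, residue, atom name), the highest-occupancy alt-loc;
    # ties go to the first-listed record.  Atoms without alt-locs pass through.
    best: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        key = (a.chain_id, a.residue_number, a.atom_name)
        if key not in best or atoms[best[key]].occupancy < a.occupancy:
            best[key] = i
    keep = set(best.values())
    return [a for i, a in enumerate(atoms) if i in keep]


def read_pdb(path: str | Path, model: int = 1) -> StructureModel:
    """Read one model of a PDB file into a :class:`StructureModel`.

    Alt-locs are resolved by highest occupancy (first-listed on ties).

    Parameters
    ----------
    path:
        PDB file containing ATOM/HETATM records.
    model:
        1-based model number (MODEL record); files without MODEL records
        count as a single model 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no parsable ATOM/HETATM records")
    if not (1 <= model <= n_models):
        raise ValueError(f"{path}: model {model} absent (file has {n_models})")
    arr = pdb.get_structure(
        model=model, altloc="all", extra_fields=["occupancy", "b_factor"]
    )
    if arr.array_length() == 0:
        raise ValueError(f"{path}: no parsable ATOM/HETATM records")
    altloc_id = (
        arr.get_annotation("altloc_id")
        if "altloc_id" in arr.get_annotation_categories()
        else [""] * arr.array_length()
    )
    atoms = []
    for i in range(arr.array_length()):
        loc = str(altloc_id[i]).strip().replace(".", "")
        atoms.append(
            AtomRecord(
                chain_id=str(arr.chain_id[i]),
                residue_number=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]),
                atom_name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                position=tuple(np.asarray(arr.coord[i], dtype=float)),
                alt_loc=loc,
                occupancy=float(arr.occupancy[i]),
                hetero=bool(arr.hetero[i]),
            )
        )
    atoms = _resolve_altlocs(atoms)
    # after resolution the surviving conformer is the canonical one
    atoms = [dataclasses.replace(a, alt_loc="") for a in atoms]
    return StructureModel(atoms, source_id=path.stem, model_index=model)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model as a fixed-column PDB file that round-trips through
    :func:`read_pdb`."""
    if len(model) > _MAX_SERIAL:
        raise ValueError(
            f"cannot encode {len(model)} atoms: PDB serial numbers overflow at {_MAX_SERIAL}"
        )
    for a in model.atoms:
        if len(a.atom_name) > 4:
            raise ValueError(f"atom name {a.atom_name!r} exceeds 4 characters")
        if len(a.residue_name) > 3:
            raise ValueError(f"residue name {a.residue_name!r} exceeds 3 characters")
        if len(a.chain_id) > 1:
            raise ValueError(f"chain id {a.chain_id!r} exceeds 1 character")
    n = len(model)
    arr = bst.AtomArray(n)
    arr.coord = model.coords().astype(np.float32)
    arr.chain_id = np.array([a.chain_id for a in model.atoms])
    arr.res_id = np.array([a.residue_number for a in model.atoms])
    arr.res_name = np.array([a.residue_name for a in model.atoms])
    arr.atom_name = np.array([a.atom_name for a in model.atoms])
    arr.element = np.array([a.element for a in model.atoms])
    arr.hetero = np.array([a.hetero for a in model.atoms])
    arr.set_annotation("occupancy", np.array([a.occupancy for a in model.atoms]))
    arr.set_annotation("b_factor", np.zeros(n))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def _paired_coords(
    mobile: StructureModel, reference: StructureModel, atom_names: Iterable[str]
) -> tuple[np.ndarray, np.ndarray]:
    names = set(atom_names)
    ref_index = {
        (a.chain_id, a.residue_number, a.atom_name): a.position
        for a in reference.atoms
        if a.atom_name in names
    }
    mob, ref = [], []
    for a in mobile.atoms:
        key = (a.chain_id, a.residue_number, a.atom_name)
        if a.atom_name in names and key in ref_index:
            mob.append(a.position)
            ref.append(ref_index[key])
    return np.asarray(mob, dtype=float), np.asarray(ref, dtype=float)


def kabsch(mobile_xyz: np.ndarray, reference_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rigid transform mapping ``mobile_xyz`` onto
    ``reference_xyz`` (paired points), by the Kabsch SVD construction.

    Returns ``(rotation, translation, rmsd)`` with the transform
    ``x -> R x + t`` minimizing the RMSD over all rotations+translations.
    """
    P = np.asarray(mobile_xyz, dtype=float)
    Q = np.asarray(reference_xyz, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def superpose_backbone(
    mobile: StructureModel,
    reference: StructureModel,
    atom_names: Iterable[str] = BACKBONE_ATOMS,
) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Atoms are paired by exact ``(chain_id, residue_number, atom_name)``
    identity restricted to ``atom_names`` (protein backbone N, CA, C, O by
    default).  At least 3 non-collinear paired atoms are required.
    """
    P, Q = _paired_coords(mobile, reference, atom_names)
    if len(P) < 3:
        raise ValueError(f"only {len(P)} paired atoms; at least 3 required")
    # collinear point sets leave a rotation degree of freedom unresolved
    sing = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
    if sing[1] < 1e-8 * max(sing[0], 1.0):
        raise ValueError("degenerate (collinear) atom set: superposition not unique")
    R, t, rmsd = kabsch(P, Q)
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms_used=len(P))


def apply_superposition(model: StructureModel, sp: Superposition) -> StructureModel:
    """Return ``model`` with the superposition transform applied."""
    return model.transformed(sp.rotation, sp.translation)


def graft_residue(
    target: StructureModel,
    donor: StructureModel,
    target_residue: tuple[str, int],
    donor_residue: tuple[str, int],
    atom_names: Iterable[str] = BACKBONE_ATOMS,
) -> StructureModel:
    """Replace one residue of ``target`` with a residue taken from ``donor``.

    The donor structure is first rigidly superposed onto the target over the
    shared backbone; the donor residue's atoms (in donor order, transformed
    into the target frame) are then inserted at the target residue's slot and
    renumbered/rechained to the target's chain and residue number.  All other
    target atoms are untouched.

    This implements pyruvoyl -> Ser68 substitution: graft the Ser68 of an
    unprocessed mutant structure into the active structure's residue-68 slot
    (or vice versa).
    """
    t_chain, t_num = target_residue
    d_chain, d_num = donor_residue
    t_idx = target.residue_atoms(t_chain, t_num)
    if not t_idx:
        raise ValueError(f"target residue {t_chain}:{t_num} not found")
    d_idx = donor.residue_atoms(d_chain, d_num)
    if not d_idx:
        raise ValueError(f"donor residue {d_chain}:{d_num} not found")
    if len(d_idx) < 4:
        raise ValueError(
            f"donor residue {d_chain}:{d_num} has only {len(d_idx)} atoms; suspect fragment"
        )
    # Align on the shared frame EXCLUDING the residue being swapped: its
    # atoms differ between the structures by construction (pyruvoyl vs Ser)
    # and would bias the fit; with them excluded, grafting a residue back
    # restores the original coordinates exactly.
    t_excl = set(t_idx)
    d_excl = set(d_idx)
    ref_sub = StructureModel([a for i, a in enumerate(target.atoms) if i not in t_excl])
    mob_sub = StructureModel([a for i, a in enumerate(donor.atoms) if i not in d_excl])
    sp = superpose_backbone(mob_sub, ref_sub, atom_names)
    donor_aligned = apply_superposition(donor, sp)
    grafted = [
        dataclasses.replace(
            donor_aligned.atoms[i], chain_id=t_chain, residue_number=t_num, alt_loc=""
        )
        for i in d_idx
    ]
    insert_at = t_idx[0]
    keep = [a for i, a in enumerate(target.atoms) if i not in set(t_idx)]
    # t_idx positions before insert_at are all >= insert_at by construction
    # (residue atoms are contiguous in practice, but we do not rely on it)
    n_removed_before = sum(1 for i in t_idx if i < insert_at)
    pos = insert_at - n_removed_before
    atoms = keep[:pos] + grafted + keep[pos:]
    return StructureModel(atoms, source_id=f"{target.source_id}+{donor.source_id}", model_index=target.model_index)
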