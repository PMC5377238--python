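"""Shared fixtures: tiny hand-written PDB texts and pose builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from samdcscreen.pose_triage import DockingResult, LigandPose

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def pdb_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_num: int,
    x: float,
    y: float,
    z: float,
    occ: float = 1.0,
    alt: str = " ",
    element: str = "C",
    record: str = "ATOM",
) -> str:
    return (
        f"{record:<6s}{serial:5d} {name:^4s}{alt}{res_name:>3s} {chain}{res_num:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def three_atom_pdb(tmp_path):
    text = "\n".join(
        [
            pdb_line(1, "N", "ALA", "A", 1, 11.104, 6.134, -6.504, element="N"),
            pdb_line(2, "CA", "ALA", "A", 1, 11.639, 6.071, -5.147),
            pdb_line(3, "C", "ALA", "A", 1, 12.685, 7.147, -4.925),
            "END",
        ]
    )
    p = tmp_path / "three.pdb"
    p.write_text(text + "\n")
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    text = "\n".join(
        [
            pdb_line(1, "CA", "LEU", "A", 1, 10.0, 1.0, 1.0, occ=0.6, alt="A"),
            pdb_line(2, "CA", "LEU", "A", 1, 20.0, 2.0, 2.0, occ=0.4, alt="B"),
            pdb_line(3, "CB", "LEU", "A", 1, 1.0, 1.0, 1.0, occ=0.5, alt="A"),
            pdb_line(4, "CB", "LEU", "A", 1, 2.0, 2.0, 2.0, occ=0.5, alt="B"),
            "END",
        ]
    )
    p = tmp_path / "altloc.pdb"
    p.write_text(text + "\n")
    return p


def residue_lines(
    chain: str, res_num: int, res_name: str, offset: np.ndarray, serial0: int = 1,
    record: str = "ATOM", n_extra: int = 0,
) -> list[str]:
    """Backbone N/CA/C/O (plus optional CB-like extras) for one toy residue."""
    base = {
        "N": (0.0, 0.0, 0.0),
        "CA": (1.46, 0.0, 0.0),
        "C": (2.0, 1.42, 0.0),
        "O": (1.3, 2.4, 0.2),
    }
    names = list(base) + [f"C{i+1}" for i in range(n_extra)]
    lines = []
    for i, name in enumerate(names):
        xyz = np.array(base.get(name, (1.5 + 0.8 * i, -1.2, 0.5 * i))) + offset
        element = name[0]
        lines.append(
            pdb_line(serial0 + i, name, res_name, chain, res_num, *xyz, element=element, record=record)
        )
    return lines


def write_chain(tmp_path, fname: str, residues: list[tuple], record="ATOM") -> "Path":
    """residues: list of (chain, num, name, offset, n_extra)."""
    lines, serial = [], 1
    for chain, num, name, offset, n_extra in residues:
        rl = residue_lines(chain, num, name, np.asarray(offset, float), serial, record, n_extra)
        lines.extend(rl)
        serial += len(rl)
    p = tmp_path / fname
    p.write_text("\n".join(lines + ["END"]) + "\n")
    return p


def make_result(
    molecule_id: str,
    scores: list[float],
    offsets: list[float],
    n_atoms: int = 5,
    seed: int = 0,
) -> DockingResult:
    """Poses displaced rigidly along x by the given offsets from a common
    reference conformation, so RMSD to pose i equals |offset_i - offset_ref|."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_atoms, 3))
    poses = [
        LigandPose(i + 1, s, base + np.array([d, 0.0, 0.0]))
        for i, (s, d) in enumerate(zip(scores, offsets))
    ]
    return DockingResult(molecule_id, n_atoms, poses)
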