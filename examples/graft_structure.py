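"""Graft a residue between two structures after backbone superposition.

Builds two small synthetic protein fragments (stand-ins for an active
AdoMetDC structure with a pyruvoyl group at position 68 and a mutant with
Ser68 intact), superposes their backbones, and swaps residue 68 of the
target for the donor's — the same operation used to build a
screening-compatible receptor model with a standard serine in the
catalytic slot.
"""

import numpy as np

from samdcscreen.structio import graft_residue, read_pdb, superpose_backbone, write_pdb
from samdcscreen.structio import AtomRecord, StructureModel

def fragment(res68_name: str, n_res68_atoms: int, offset: np.ndarray) -> StructureModel:
    atoms = []
    rng = np.random.default_rng(abs(hash(res68_name)) % 2**31)
    for resnum, resname in [(66, "GLY"), (67, "PHE"), (68, res68_name), (69, "ALA")]:
        n_atoms = n_res68_atoms if resnum == 68 else 4
        base = np.array([3.8 * (resnum - 66), 0.0, 0.0])
        for i, name in enumerate(["N", "CA", "C", "O", "CB", "CG", "OD1"][:n_atoms]):
            xyz = base + offset + np.array([0.3 * i, 0.5 * (i % 2), 0.2 * i])
            atoms.append(AtomRecord("A", resnum, resname, name, name[0], tuple(xyz)))
    return StructureModel(atoms, source_id=res68_name)

# active-form stand-in: 5-atom pyruvoyl-like residue 68 (synthetic)
target = fragment("PYR", 5, np.zeros(3))
# mutant stand-in: full Ser68, displaced and to be aligned (synthetic)
donor = fragment("SER", 6, np.array([10.0, 5.0, -3.0]))

sp = superpose_backbone(donor, target)
print(f"backbone superposition over {sp.n_atoms_used} atoms, rmsd = {sp.rmsd:.3f} A")

chimera = graft_residue(target, donor, ("A", 68), ("A", 68))
res68 = [a for a in chimera.atoms if a.residue_number == 68]
print(f"target had {len(target)} atoms; chimera has {len(chimera)}")
print(f"residue 68 is now {res68[0].residue_name} with {len(res68)} atoms")
write_pdb(chimera, "chimera.pdb")
print("wrote chimera.pdb — a single continuous model, renumbered to the target's chain")
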