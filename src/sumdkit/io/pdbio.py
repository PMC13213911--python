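"""PDB coordinate I/O (via biotite).

PDB carries names, residues, chains and coordinates only; masses, charges,
LJ parameters and bonded terms live in the sidecar topology file.  Reading
therefore yields a *skeleton* system (placeholder parameters) that
:func:`~sumdkit.io.sidecar.read_topology_sidecar` completes.  1-based PDB
serial numbers are mapped to 0-based contiguous atom ids at this boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from ..topology import AtomRecord, Component, Frame, MolecularSystem

_PLACEHOLDER_MASS = 1.0

#: chain → component mapping used when none is recorded; the toy generator
#: writes receptor atoms to chain R and binder atoms to chain P.
_DEFAULT_COMPONENTS = {"R": Component.RECEPTOR, "P": Component.LIGAND}


def _infer_element(name: str) -> str:
    """First alphabetic character of the atom name (documented rule)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_pdb(
    path: str | Path,
    component_of_chain: dict[str, Component | str] | None = None,
) -> tuple[MolecularSystem, Frame]:
    """Read ATOM/HETATM records into a skeleton system plus a frame.

    Raises on unparseable records (with the offending line number) and on
    duplicate serial numbers.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    try:
        arr = pdb.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:
        line = _find_bad_line(path)
        raise ValueError(f"{path.name}: malformed ATOM record near line {line}: {exc}") from exc
    serials = arr.get_annotation("atom_id")
    if len(set(serials.tolist())) != len(serials):
        dupes = sorted({int(s) for s in serials if (serials == s).sum() > 1})
        raise ValueError(f"{path.name}: duplicate atom serial number(s) {dupes[:5]}")
    comp_map = dict(_DEFAULT_COMPONENTS)
    for k, v in (component_of_chain or {}).items():
        comp_map[k] = Component(v)
    atoms = []
    for i in range(arr.array_length()):
        chain = str(arr.chain_id[i])
        atoms.append(
            AtomRecord(
                atom_id=i,
                name=str(arr.atom_name[i]),
                mass=_PLACEHOLDER_MASS,
                charge=0.0,
                lj_rmin_half=0.0,
                lj_epsilon=0.0,
                residue_index=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]),
                chain_id=chain,
                component=comp_map.get(chain, Component.OTHER),
            )
        )
    system = MolecularSystem(atoms=atoms)
    frame = Frame(coordinates=np.asarray(arr.coord, dtype=float))
    return system, frame


def _find_bad_line(path: Path) -> int:
    """Best-effort line number of the first malformed ATOM/HETATM record."""
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError:
                    return n
    return -1


def write_pdb(path: str | Path, system: MolecularSystem, frame: Frame) -> None:
    """Write one model; atom ids become 1-based serials."""
    if frame.n_atoms != system.n_atoms:
        raise ValueError("frame/system atom count mismatch")
    n = system.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(frame.coordinates, dtype=np.float32)
    arr.chain_id = np.array([a.chain_id for a in system.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_index for a in system.atoms])
    arr.res_name = np.array([a.residue_name for a in system.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in system.atoms], dtype="U6")
    arr.element = np.array([_infer_element(a.name) for a in system.atoms], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
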