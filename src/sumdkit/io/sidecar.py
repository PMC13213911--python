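"""Sidecar topology format: the parameters PDB cannot carry.

A plain-text, whitespace-tabular format with bracketed sections::

    # sumdkit topology sidecar v1
    [atoms]            # atom_id mass charge lj_rmin_half lj_epsilon component
    0 50.0 -1.0 2.0 0.15 receptor
    ...
    [bonds]            # i j k r0      (harmonic, E = 0.5 k (r-r0)^2)
    0 1 20.0 3.8
    [elastic]          # i j k r0      (elastic-network pairs)
    ...
    [box]              # lx ly lz  (optional, orthorhombic, Å)

Atom ids are the internal 0-based ids, i.e. PDB serial − 1 of the paired
coordinate file.  The atom count must match the PDB skeleton exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..topology import AtomRecord, Component, MolecularSystem


def write_topology_sidecar(path: str | Path, system: MolecularSystem) -> None:
    lines = ["# sumdkit topology sidecar v1", "[atoms]"]
    for a in system.atoms:
        lines.append(
            f"{a.atom_id} {a.mass!r} {a.charge!r} "
            f"{a.lj_rmin_half!r} {a.lj_epsilon!r} {a.component.value}"
        )
    lines.append("[bonds]")
    for i, j, k, r0 in system.bonds:
        lines.append(f"{i} {j} {k!r} {r0!r}")
    lines.append("[elastic]")
    for i, j, k, r0 in system.elastic_pairs:
        lines.append(f"{i} {j} {k!r} {r0!r}")
    if system.box is not None:
        lines.append("[box]")
        lines.append(" ".join(f"{v:.6f}" for v in system.box))
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology_sidecar(path: str | Path, skeleton: MolecularSystem) -> MolecularSystem:
    """Attach masses/charges/LJ/bonded terms to a PDB-derived skeleton.

    The sidecar must describe exactly the skeleton's atom count.
    """
    path = Path(path)
    section = None
    per_atom: dict[int, tuple[float, float, float, float, str]] = {}
    bonds: list[tuple[int, int, float, float]] = []
    elastic: list[tuple[int, int, float, float]] = []
    box = None
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]").lower()
            if section not in ("atoms", "bonds", "elastic", "box"):
                raise ValueError(f"{path.name}:{ln}: unknown section [{section}]")
            continue
        parts = line.split()
        try:
            if section == "atoms":
                aid = int(parts[0])
                if aid in per_atom:
                    raise ValueError(f"duplicate atom id {aid}")
                per_atom[aid] = (
                    float(parts[1]),
                    float(parts[2]),
                    float(parts[3]),
                    float(parts[4]),
                    parts[5] if len(parts) > 5 else "other",
                )
            elif section in ("bonds", "elastic"):
                term = (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]))
                (bonds if section == "bonds" else elastic).append(term)
            elif section == "box":
                box = np.array([float(v) for v in parts[:3]])
            else:
                raise ValueError("data before any section header")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path.name}:{ln}: bad record {raw!r}: {exc}") from exc
    n = skeleton.n_atoms
    if len(per_atom) != n:
        raise ValueError(
            f"sidecar describes {len(per_atom)} atoms but coordinates have {n}"
        )
    atoms = []
    for a in skeleton.atoms:
        if a.atom_id not in per_atom:
            raise ValueError(f"sidecar missing atom id {a.atom_id}")
        mass, charge, rmh, eps, comp = per_atom[a.atom_id]
        atoms.append(
            AtomRecord(
                atom_id=a.atom_id,
                name=a.name,
                mass=mass,
                charge=charge,
                lj_rmin_half=rmh,
                lj_epsilon=eps,
                residue_index=a.residue_index,
                residue_name=a.residue_name,
                chain_id=a.chain_id,
                component=Component(comp),
            )
        )
    return MolecularSystem(atoms=atoms, bonds=bonds, elastic_pairs=elastic, box=box)
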