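"""Core domain types: atoms, systems, selections, frames, trajectories.

Indexing convention: atoms are identified by a 0-based contiguous
``atom_id``; 1-based serial numbers from file formats are mapped at the
I/O boundary and never appear internally.  Residue identity is the pair
``(chain_id, residue_index)``; display numbering offsets (e.g. to match a
reference sequence numbering) are applied only when labelling output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np


class Component(str, enum.Enum):
    """Which binding partner an atom belongs to."""

    RECEPTOR = "receptor"
    LIGAND = "ligand"
    OTHER = "other"


@dataclass(frozen=True)
class AtomRecord:
    """One atom (or coarse-grained bead) of the topology.

    Parameters use the rmin/2 + epsilon Lennard-Jones convention
    (Lorentz–Berthelot combining: rmin_ij = rmin_half_i + rmin_half_j,
    eps_ij = sqrt(eps_i * eps_j)).
    """

    atom_id: int
    name: str
    mass: float  # amu, > 0
    charge: float  # e
    lj_rmin_half: float  # Å, >= 0
    lj_epsilon: float  # kcal/mol, >= 0
    residue_index: int
    residue_name: str
    chain_id: str
    component: Component = Component.OTHER

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.atom_id}: mass must be > 0, got {self.mass}")
        if self.lj_epsilon < 0 or self.lj_rmin_half < 0:
            raise ValueError(f"atom {self.atom_id}: negative LJ parameter")


# (i, j, k [kcal/mol/Å²], r0 [Å])
BondTerm = tuple[int, int, float, float]


@dataclass
class MolecularSystem:
    """Topology of a molecular system: atoms, bonded terms, optional box.

    ``bonds`` are harmonic bonds; ``elastic_pairs`` are the same functional
    form but represent elastic-network restraints holding structured cores
    rigid (kept separate so they can be listed/serialised apart).  The box,
    when present, is orthorhombic: three edge lengths in Å.
    """

    atoms: list[AtomRecord]
    bonds: list[BondTerm] = field(default_factory=list)
    elastic_pairs: list[BondTerm] = field(default_factory=list)
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if ids != list(range(len(self.atoms))):
            raise ValueError("atom_id values must be 0..N-1, contiguous, in order")
        n = len(self.atoms)
        for tag, terms in (("bond", self.bonds), ("elastic pair", self.elastic_pairs)):
            for i, j, k, r0 in terms:
                if not (0 <= i < n and 0 <= j < n):
                    raise ValueError(f"{tag} ({i},{j}) references a missing atom")
                if i == j:
                    raise ValueError(f"{tag} ({i},{j}) is a self-bond")
                if r0 <= 0:
                    raise ValueError(f"{tag} ({i},{j}): r0 must be > 0, got {r0}")
        # residue_index non-decreasing within a chain
        last: dict[str, int] = {}
        for a in self.atoms:
            prev = last.get(a.chain_id)
            if prev is not None and a.residue_index < prev:
                raise ValueError(
                    f"residue_index decreases within chain {a.chain_id!r} at atom {a.atom_id}"
                )
            last[a.chain_id] = a.residue_index
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or not np.all(self.box > 0):
                raise ValueError("box must be three positive orthorhombic edge lengths")
        self._cache: dict[str, np.ndarray] = {}

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def _array(self, key: str, getter) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = np.array([getter(a) for a in self.atoms], dtype=float)
        return self._cache[key]

    @property
    def masses(self) -> np.ndarray:
        return self._array("masses", lambda a: a.mass)

    @property
    def charges(self) -> np.ndarray:
        return self._array("charges", lambda a: a.charge)

    @property
    def lj_rmin_half(self) -> np.ndarray:
        return self._array("rmin_half", lambda a: a.lj_rmin_half)

    @property
    def lj_epsilon(self) -> np.ndarray:
        return self._array("epsilon", lambda a: a.lj_epsilon)

    def component_ids(self, component: Component | str) -> np.ndarray:
        """Atom ids belonging to one component, ascending."""
        component = Component(component)
        return np.array(
            [a.atom_id for a in self.atoms if a.component is component], dtype=int
        )

    def residue_keys(self, component: Component | str | None = None) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_index) keys, optionally per component."""
        seen: dict[tuple[str, int], None] = {}
        comp = Component(component) if component is not None else None
        for a in self.atoms:
            if comp is None or a.component is comp:
                seen.setdefault((a.chain_id, a.residue_index), None)
        return list(seen)


@dataclass(frozen=True)
class Selection:
    """An ordered set of atom ids plus the rule that produced it."""

    atom_ids: np.ndarray
    label: str
    expression: str

    def __post_init__(self) -> None:
        ids = np.asarray(self.atom_ids, dtype=int)
        if ids.ndim != 1 or ids.size == 0:
            raise ValueError(f"selection {self.label!r} is empty")
        if np.any(np.diff(ids) <= 0):
            raise ValueError(f"selection {self.label!r}: ids must be strictly ascending")
        object.__setattr__(self, "atom_ids", ids)

    def __len__(self) -> int:
        return int(self.atom_ids.size)

    def validate_for(self, system: MolecularSystem) -> None:
        if self.atom_ids[-1] >= system.n_atoms or self.atom_ids[0] < 0:
            raise ValueError(
                f"selection {self.label!r} references atoms outside the system"
            )


@dataclass
class Frame:
    """One snapshot: coordinates in Å, optional velocities in Å/ps, time in ps."""

    coordinates: np.ndarray
    time: float = 0.0
    velocities: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be N×3")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.time < 0:
            raise ValueError("frame time must be >= 0")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coordinates.shape:
                raise ValueError("velocities shape must match coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """An ordered sequence of frames over one topology."""

    system: MolecularSystem
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.system.n_atoms
        times = []
        for f in self.frames:
            if f.n_atoms != n:
                raise ValueError(
                    f"frame has {f.n_atoms} atoms, topology has {n}"
                )
            times.append(f.time)
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def coordinates_array(self) -> np.ndarray:
        """All coordinates stacked, shape (n_frames, n_atoms, 3)."""
        if not self.frames:
            return np.zeros((0, self.system.n_atoms, 3))
        return np.stack([f.coordinates for f in self.frames])


def center_of_mass(
    frame: Frame, system: MolecularSystem, sel: Selection
) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms, Å."""
    sel.validate_for(system)
    m = system.masses[sel.atom_ids]
    x = frame.coordinates[sel.atom_ids]
    return (m[:, None] * x).sum(axis=0) / m.sum()


def com_distance(
    frame: Frame,
    system: MolecularSystem,
    sel_a: Selection,
    sel_b: Selection,
    periodic: bool = False,
) -> float:
    """Distance between two selection centres of mass, Å.

    With ``periodic=True`` the minimum-image convention is applied to the
    COM difference vector componentwise (orthorhombic box); the box is taken
    from the frame if present, else from the system.
    """
    d = center_of_mass(frame, system, sel_a) - center_of_mass(frame, system, sel_b)
    if periodic:
        box = frame.box if frame.box is not None else system.box
        if box is None:
            raise ValueError("periodic distance requested but no box is defined")
        box = np.asarray(box, dtype=float)
        d = d - box * np.round(d / box)
    return float(np.linalg.norm(d))
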