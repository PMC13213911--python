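"""Shared fixtures: tiny hand-built systems and the default toy complex."""

from __future__ import annotations

import numpy as np
import pytest

from sumdkit import (
    AtomRecord,
    Component,
    Frame,
    MolecularSystem,
    make_toy_complex,
)


def make_beads(
    n: int,
    masses=None,
    charges=None,
    rmin_half=2.0,
    epsilon=0.15,
    bonds=(),
    elastic=(),
    chain="A",
    resname="BEA",
    name="CA",
    component=Component.OTHER,
    box=None,
) -> MolecularSystem:
    """A bare n-bead system, one residue per bead."""
    masses = np.full(n, 12.0) if masses is None else np.asarray(masses, float)
    charges = np.zeros(n) if charges is None else np.asarray(charges, float)
    atoms = [
        AtomRecord(
            atom_id=i,
            name=name,
            mass=float(masses[i]),
            charge=float(charges[i]),
            lj_rmin_half=rmin_half,
            lj_epsilon=epsilon,
            residue_index=i + 1,
            residue_name=resname,
            chain_id=chain,
            component=component,
        )
        for i in range(n)
    ]
    return MolecularSystem(
        atoms=atoms, bonds=list(bonds), elastic_pairs=list(elastic), box=box
    )


@pytest.fixture(scope="session")
def toy_complex():
    """Default synthetic receptor/binder complex (deterministic)."""
    return make_toy_complex()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_system(rng, n, charged=True, bonded=True):
    """Random small system for force-consistency oracles."""
    charges = rng.choice([-1.0, 0.0, 1.0], size=n) if charged else np.zeros(n)
    masses = rng.uniform(12.0, 60.0, size=n)
    bonds = []
    elastic = []
    if bonded:
        for i in range(n - 1):
            bonds.append((i, i + 1, float(rng.uniform(5, 30)), float(rng.uniform(3, 4.5))))
        for _ in range(n // 3):
            i, j = rng.choice(n, size=2, replace=False)
            if abs(i - j) > 1:
                elastic.append(
                    (int(min(i, j)), int(max(i, j)), float(rng.uniform(2, 15)), float(rng.uniform(4, 8)))
                )
    return make_beads(n, masses=masses, charges=charges, bonds=bonds, elastic=elastic)


def random_coords(rng, n, spread=12.0, min_dist=2.5):
    """Random coordinates with no pair closer than min_dist (placed one at
    a time so large n stays feasible)."""
    pts = [rng.uniform(-spread, spread, size=3)]
    while len(pts) < n:
        cand = rng.uniform(-spread, spread, size=3)
        if min(np.linalg.norm(cand - q) for q in pts) > min_dist:
            pts.append(cand)
    return np.array(pts)


@pytest.fixture()
def two_bead_frame():
    system = make_beads(2, masses=[1.0, 3.0])
    frame = Frame(coordinates=np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]]))
    return system, frame
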