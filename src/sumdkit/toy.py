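"""Synthetic coarse-grained receptor/binder complexes.

The generator emulates the geometry of RNA–IDR recognition at bead
resolution: the receptor is a rigid polyanionic double-strand arc (one
bead per "nucleotide", each strand bead carrying −1e by default, plus a
neutral backing ridge giving the molecule body) whose concave face forms
a groove; the binder is a neutral elastic-network core (the folded
domain) plus a flexible, linear, bonded tail whose alternating beads
carry +1e — the disordered, arginine-rich segment that leads
recognition.  The start frame displaces the binder until its nearest
bead is 30 Å from the nearest receptor bead; the bound reference lays
the tail along the groove midline and docks the core against the
concave face at the arc bottom, constructed geometrically (never by
simulation) for use as an RMSD/threshold fixture.

These systems make no attempt at realistic RNA geometry, base pairing or
sequence effects; they exist so the supervision and analysis machinery can
be exercised end-to-end on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import EngineConfig, EngineState, ForceFieldTerms, ToyEngine
from .selections import build_selection
from .supervision import SuMDProtocol, SupervisionPhase
from .topology import (
    AtomRecord,
    Component,
    Frame,
    MolecularSystem,
    Trajectory,
    center_of_mass,
    com_distance,
)

_BEAD_SPACING = 3.8  # Å, Cα-like
_STRAND_HALF_GAP = 2.75  # Å, strands at z = ±2.75
#: radial depth of the groove midline below the strand radius, chosen so a
#: binder bead on the midline touches both strands at LJ-contact distance
#: (sqrt(3.6² + 2.75²) ≈ 4.5 Å for the mixed receptor/binder contact)
_GROOVE_DEPTH = 3.6


@dataclass
class ToyComplexParams:
    """Recipe for one synthetic receptor/binder complex."""

    n_receptor_beads: int = 32  # split over two strands
    n_core_beads: int = 12
    n_tail_beads: int = 6  # short motif, proportionate to an RGG-type tail
    receptor_charge: float = -1.0  # e per receptor bead
    tail_charge: float = +1.0  # e per charged tail bead
    tail_charged_fraction: float = 0.5  # alternating beads charged
    #: number of charged "lysine-like" core beads; 0 (the default) keeps
    #: the folded core neutral so that recognition is tail-led, as it is
    #: in RGG-type binders — the core then docks through the tether and
    #: short-range contacts rather than by its own electrostatic capture
    core_charged_beads: int = 0
    #: beads of a backing ridge behind the arc bottom, giving the receptor
    #: body thickness there (a thin two-strand shell would let the dock
    #: site be approached from the convex back side)
    n_backing_beads: int = 6
    bond_k: float = 20.0  # kcal/mol/Å²
    bond_r0: float = _BEAD_SPACING
    elastic_k: float = 10.0
    receptor_elastic_cutoff: float = 6.5  # Å
    core_elastic_cutoff: float = 7.0  # Å
    bead_mass: float = 50.0  # amu
    #: nucleotide beads are bulkier than residue beads; the softer, wider
    #: receptor contact keeps surface sliding possible at 310 K
    receptor_lj_rmin_half: float = 2.5  # Å
    lj_rmin_half: float = 2.0  # Å (binder beads)
    lj_epsilon: float = 0.15  # kcal/mol
    initial_separation: float = 30.0  # Å, binder to nearest receptor atom
    #: band of allowed cosines between the (random) displacement direction
    #: and the groove axis.  The default keeps the binder on the open face
    #: (not behind the receptor) but off the funnel axis, reproducing the
    #: regime the protocol is for: displaced away from the binding site,
    #: where plain dynamics does not simply fall back into the bound pose.
    #: (-1, 1) allows any direction.
    approach_cone_min_cos: float = 0.2
    approach_cone_max_cos: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_receptor_beads, self.n_core_beads, self.n_tail_beads) < 2:
            raise ValueError("bead counts must be >= 2")
        if self.initial_separation <= 0:
            raise ValueError("initial separation must be > 0")
        if not (0 <= self.tail_charged_fraction <= 1):
            raise ValueError("tail_charged_fraction must be in [0, 1]")


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return radius * np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _receptor_coords(n_beads: int, n_backing: int) -> np.ndarray:
    """Two parallel semicircular strands (concave face toward +x) plus a
    backing ridge behind the arc bottom."""
    n_s = n_beads // 2
    radius = _BEAD_SPACING * (n_s - 1) / math.pi
    ang = np.pi / 2 + np.linspace(0.0, np.pi, n_s)
    arc = np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n_s)], axis=1)
    top = arc + [0.0, 0.0, _STRAND_HALF_GAP]
    bottom = arc - [0.0, 0.0, _STRAND_HALF_GAP]
    parts = [top, bottom]
    if n_backing:
        r_back = radius + 4.5
        dphi = _BEAD_SPACING / r_back
        back_ang = np.pi + ((np.arange(n_backing) - (n_backing - 1) / 2) * dphi)
        parts.append(
            np.stack(
                [r_back * np.cos(back_ang), r_back * np.sin(back_ang), np.zeros(n_backing)],
                axis=1,
            )
        )
    return np.concatenate(parts), radius


def make_toy_complex(
    params: ToyComplexParams | None = None,
) -> tuple[MolecularSystem, Frame, Frame]:
    """Build (system, start frame, bound-reference frame).

    The start frame displaces the binder along a random (seeded) direction
    on the groove-facing cone until its nearest bead is
    ``initial_separation`` Å from the nearest receptor bead — displacement
    away from the binding site, measured as surface clearance.
    """
    p = params or ToyComplexParams()
    rng = np.random.default_rng(p.seed)

    rec_xyz, radius = _receptor_coords(p.n_receptor_beads, p.n_backing_beads)
    n_rec = rec_xyz.shape[0]
    n_s = p.n_receptor_beads // 2

    # ---- binder: core cluster + linear tail (built in local frame) ----
    core_radius = math.sqrt(p.n_core_beads * _BEAD_SPACING**2 / (4 * math.pi))
    core_local = _fibonacci_sphere(p.n_core_beads, max(core_radius, 2.5))
    # anchor = core bead with most negative x; tail extends along -x
    anchor = int(np.argmin(core_local[:, 0]))
    t_idx = np.arange(1, p.n_tail_beads + 1)
    tail_local = core_local[anchor] + np.stack(
        [-_BEAD_SPACING * t_idx, np.zeros_like(t_idx, dtype=float), np.zeros_like(t_idx, dtype=float)],
        axis=1,
    )
    binder_local = np.concatenate([core_local, tail_local])

    # ---- topology ----
    atoms: list[AtomRecord] = []
    n_strand = 2 * n_s
    for i in range(n_rec):
        # strand beads model the phosphate backbone and carry the charge;
        # backing-ridge beads are the neutral body of the molecule
        is_strand = i < n_strand
        atoms.append(
            AtomRecord(
                atom_id=i,
                name="P" if is_strand else "C4'",
                mass=p.bead_mass,
                charge=p.receptor_charge if is_strand else 0.0,
                lj_rmin_half=p.receptor_lj_rmin_half,
                lj_epsilon=p.lj_epsilon,
                residue_index=i + 1,  # 1-based, PDB-friendly
                residue_name="RNB" if is_strand else "BDY",
                chain_id="R",
                component=Component.RECEPTOR,
            )
        )
    # charged core beads: those nearest the tail anchor (basic patch)
    d_to_anchor = np.linalg.norm(core_local - core_local[anchor], axis=1)
    basic = set(np.argsort(d_to_anchor)[: p.core_charged_beads].tolist())
    n_charged_tail = int(round(p.tail_charged_fraction * p.n_tail_beads))
    # alternating beads first (0, 2, 4, ...), then fill odds if more needed
    interleaved = list(range(0, p.n_tail_beads, 2)) + list(range(1, p.n_tail_beads, 2))
    charged_tail = set(interleaved[:n_charged_tail])
    for j in range(p.n_core_beads + p.n_tail_beads):
        is_core = j < p.n_core_beads
        if is_core:
            q = p.tail_charge if j in basic else 0.0
        else:
            q = p.tail_charge if (j - p.n_core_beads) in charged_tail else 0.0
        atoms.append(
            AtomRecord(
                atom_id=n_rec + j,
                name="CA",
                mass=p.bead_mass,
                charge=q,
                lj_rmin_half=p.lj_rmin_half,
                lj_epsilon=p.lj_epsilon,
                residue_index=j + 1,  # 1-based, PDB-friendly
                residue_name="COR" if is_core else "TAL",
                chain_id="P",
                component=Component.LIGAND,
            )
        )

    bonds = []
    elastic = []
    # receptor strand backbones + elastic cross-links
    for s in range(2):
        for k in range(n_s - 1):
            i = s * n_s + k
            bonds.append((i, i + 1, p.bond_k, p.bond_r0))
    for k in range(p.n_backing_beads - 1):
        i = 2 * n_s + k
        bonds.append((i, i + 1, p.bond_k, p.bond_r0))
    bonded = {(min(i, j), max(i, j)) for i, j, *_ in bonds}
    for i in range(n_rec):
        for j in range(i + 1, n_rec):
            if (i, j) in bonded:
                continue
            r = float(np.linalg.norm(rec_xyz[i] - rec_xyz[j]))
            if r < p.receptor_elastic_cutoff:
                elastic.append((i, j, p.elastic_k, r))
    # core elastic network
    for a in range(p.n_core_beads):
        for b in range(a + 1, p.n_core_beads):
            r = float(np.linalg.norm(core_local[a] - core_local[b]))
            if r < p.core_elastic_cutoff:
                elastic.append((n_rec + a, n_rec + b, p.elastic_k, r))
    # tail chain, anchored to the core
    first_tail = n_rec + p.n_core_beads
    bonds.append((n_rec + anchor, first_tail, p.bond_k, p.bond_r0))
    for k in range(p.n_tail_beads - 1):
        bonds.append((first_tail + k, first_tail + k + 1, p.bond_k, p.bond_r0))

    system = MolecularSystem(atoms=atoms, bonds=bonds, elastic_pairs=elastic)

    # ---- start frame ----
    masses = system.masses
    com_rec = (masses[:n_rec, None] * rec_xyz).sum(0) / masses[:n_rec].sum()
    m_b = masses[n_rec:]
    # random direction on the hemisphere facing the groove (+x)
    # sample a displacement direction on the groove-facing cone, then move
    # the binder out along it until its nearest atom is exactly
    # initial_separation from the nearest receptor atom (displacement away
    # from the binding site is specified as surface clearance, not a COM
    # distance).  The tail is oriented perpendicular to the approach
    # direction so it has to locate the groove itself.
    while True:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        if p.approach_cone_min_cos <= direction[0] <= p.approach_cone_max_cos:
            break
    perp = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(direction, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    oriented = binder_local @ _rotation_from_to(np.array([-1.0, 0.0, 0.0]), perp).T
    oriented = oriented - (m_b[:, None] * oriented).sum(0) / m_b.sum()
    d_com = p.initial_separation  # starting guess; corrected iteratively
    for _ in range(50):
        binder = oriented + com_rec + d_com * direction
        gap = np.linalg.norm(rec_xyz[:, None, :] - binder[None, :, :], axis=-1).min()
        err = p.initial_separation - gap
        if abs(err) < 0.01:
            break
        d_com += err
    else:
        raise ValueError(
            f"binder placement did not converge for initial_separation "
            f"{p.initial_separation} Å (beads would overlap the receptor)"
        )
    if gap < 2.0:
        raise ValueError(
            f"initial_separation {p.initial_separation} Å leaves the binder "
            "overlapping the receptor; increase it"
        )
    start_xyz = np.concatenate([rec_xyz, binder])

    # ---- bound reference frame (geometric construction) ----
    # the core nestles against the concave face at the arc bottom; the
    # tail drapes from the core's edge sideways along the groove midline
    groove_r = radius - _GROOVE_DEPTH
    dphi = _BEAD_SPACING / groove_r
    r_core_center = radius - _GROOVE_DEPTH - core_radius + 1.5
    core_center = np.array([-r_core_center, 0.0, 0.0])
    core_bound = core_local - core_local.mean(0) + core_center
    ang = np.pi + (core_radius + _BEAD_SPACING) / groove_r + np.arange(p.n_tail_beads) * dphi
    tail_bound = np.stack(
        [groove_r * np.cos(ang), groove_r * np.sin(ang), np.zeros_like(ang)], axis=1
    )
    bound_xyz = np.concatenate([rec_xyz, core_bound, tail_bound])

    # beads with rmin ≈ 4 Å closer than half-contact are unphysical
    for name, xyz in (("start", start_xyz), ("bound reference", bound_xyz)):
        dmin = _min_pair_distance(xyz)
        if dmin < 2.0:
            raise ValueError(
                f"{name} frame has overlapping beads (min distance {dmin:.2f} Å); "
                "adjust the parameters"
            )

    return system, Frame(coordinates=start_xyz), Frame(coordinates=bound_xyz)


def _min_pair_distance(xyz: np.ndarray) -> float:
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def _rotation_from_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180°: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


# ---------------------------------------------------------------------------
# ready-made supervision setup


def site_expression(
    system: MolecularSystem, bound_reference: Frame, group_expr: str, n_site: int = 6
) -> str:
    """Receptor beads nearest a bound group's COM — a supervision 'site'.

    Mirrors how supervision residues are picked for real systems: from the
    contact hotspots of the bound/reference state.  Returns a resid-list
    expression so the choice is replayable from its textual form.
    """
    group = build_selection(system, group_expr)
    com = center_of_mass(bound_reference, system, group)
    rec = system.component_ids(Component.RECEPTOR)
    d = np.linalg.norm(bound_reference.coordinates[rec] - com, axis=1)
    nearest = rec[np.argsort(d)[:n_site]]
    resids = sorted({system.atoms[i].residue_index for i in nearest})
    return "chain R and resid " + " ".join(str(r) for r in resids)


def default_protocol(
    system: MolecularSystem,
    bound_reference: Frame,
    master_seed: int = 0,
    step_length: float = 300.0,
    max_retries_per_step: int = 20,
    max_productive_steps: int = 40,
) -> SuMDProtocol:
    """Two-phase protocol with selections and thresholds derived from the
    bound reference.

    Each phase supervises its mobile group against the receptor beads
    nearest that group's *bound* position (distinct sites, as when phase 1
    targets groove nucleotides near the tail and phase 2 a nucleotide at
    the folded domain's own dock region).  Phase 1 ends once half of a
    productive step's frames are within the bound tail–site distance plus
    a 4 Å margin; phase 2 supervises the core against the whole receptor
    and terminates at the bound core–receptor-COM distance plus a 2 Å
    margin.
    """
    tail = build_selection(system, "chain P and resname TAL", label="tail")
    core = build_selection(system, "chain P and resname COR", label="core")
    # each phase supervises against the receptor beads nearest its group's
    # *bound* position: phase 1 the groove site beside the draped tail,
    # phase 2 the dock site under the bound core at the arc bottom (the
    # backing ridge keeps that site unreachable from the convex back)
    groove_site = build_selection(
        system,
        site_expression(system, bound_reference, "chain P and resname TAL"),
        label="groove-site",
    )
    dock_site = build_selection(
        system,
        site_expression(system, bound_reference, "chain P and resname COR"),
        label="dock-site",
    )
    d_tail = com_distance(bound_reference, system, tail, groove_site)
    d_core = com_distance(bound_reference, system, core, dock_site)
    return SuMDProtocol(
        phases=[
            SupervisionPhase(
                name="step1-idr",
                ligand_sel=tail,
                receptor_sel=groove_site,
                step_length=step_length,
                switch_distance=d_tail + 4.0,
                switch_fraction=0.5,
            ),
            SupervisionPhase(
                name="step2-core",
                ligand_sel=core,
                receptor_sel=dock_site,
                step_length=step_length,
                target_distance=d_core + 2.0,
            ),
        ],
        max_retries_per_step=max_retries_per_step,
        max_productive_steps=max_productive_steps,
        master_seed=master_seed,
    )


def toy_run_config(seed: int = 0) -> EngineConfig:
    """Engine settings for the bundled coarse-grained systems: 310 K,
    20 fs timestep (the stiffest bond period is ~340 fs and the strongly
    overdamped update tolerates that ratio comfortably), friction
    30 ps⁻¹ (an implicit-water collision frequency, standing in for the
    solvent viscosity the model otherwise lacks), snapshots every 10 ps."""
    return EngineConfig(
        timestep_fs=20.0,
        temperature=310.0,
        friction=30.0,
        seed=seed,
        snapshot_interval_ps=10.0,
    )


def toy_run_terms() -> ForceFieldTerms:
    """Force-field settings for the bundled systems: dielectric 10 plus an
    8 Å Debye screening length (the value for 0.154 M monovalent salt at
    310 K), which keeps the approach diffusive beyond ~1-2 screening
    lengths as it is in solvated systems."""
    return ForceFieldTerms(dielectric=10.0, debye_length=8.0)


def toy_engine(
    system: MolecularSystem,
    seed: int = 0,
    terms: ForceFieldTerms | None = None,
) -> ToyEngine:
    return ToyEngine(system, terms or toy_run_terms(), toy_run_config(seed))


# ---------------------------------------------------------------------------
# deterministic stub engines (test doubles for the supervision logic)


class StubEngine:
    """Physics-free engine: rigidly translates the ligand toward, away
    from, or not at all relative to the receptor, at a fixed rate."""

    def __init__(
        self,
        system: MolecularSystem,
        mode: str,
        rate: float = 0.02,  # Å/ps
        snapshot_interval: float = 10.0,  # ps
    ) -> None:
        if mode not in ("approaching", "retreating", "frozen"):
            raise ValueError(f"unknown stub mode {mode!r}")
        self.system = system
        self.mode = mode
        self.rate = rate
        self.snapshot_interval = snapshot_interval
        self._lig = system.component_ids(Component.LIGAND)
        self._rec = system.component_ids(Component.RECEPTOR)

    def resample_velocities(self, state: EngineState, seed: int) -> EngineState:
        return EngineState(
            coordinates=state.coordinates.copy(),
            velocities=state.velocities.copy(),
            time=state.time,
            rng_token=seed,
        )

    def advance(
        self, state: EngineState, duration: float, seed: int
    ) -> tuple[Trajectory, EngineState]:
        n_snap = int(round(duration / self.snapshot_interval))
        if n_snap <= 0:
            raise ValueError("duration must cover at least one snapshot interval")
        m = self.system.masses
        x = state.coordinates.copy()
        com_l = (m[self._lig, None] * x[self._lig]).sum(0) / m[self._lig].sum()
        com_r = (m[self._rec, None] * x[self._rec]).sum(0) / m[self._rec].sum()
        u = com_r - com_l
        u = u / np.linalg.norm(u)
        if self.mode == "frozen":
            step_vec = np.zeros(3)
        else:
            sign = 1.0 if self.mode == "approaching" else -1.0
            step_vec = sign * self.rate * self.snapshot_interval * u
        frames = []
        for k in range(1, n_snap + 1):
            x = x.copy()
            x[self._lig] += step_vec
            frames.append(Frame(coordinates=x.copy(), time=state.time + k * self.snapshot_interval))
        final = EngineState(
            coordinates=x,
            velocities=state.velocities.copy(),
            time=state.time + n_snap * self.snapshot_interval,
        )
        return Trajectory(system=self.system, frames=frames), final


def make_stub_engine(
    system: MolecularSystem, mode: str, rate: float = 0.02, snapshot_interval: float = 10.0
) -> StubEngine:
    return StubEngine(system, mode, rate, snapshot_interval)
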