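"""Coarse-grained Langevin dynamics engine and the abstract engine contract.

The integrator is the BAOAB splitting of Langevin dynamics
(Leimkuhler & Matthews):

    B: v <- v + (dt/2) F/m
    A: x <- x + (dt/2) v
    O: v <- c1 v + c2 sqrt(kB T / m) xi,   c1 = exp(-gamma dt), c2 = sqrt(1-c1^2)
    A: x <- x + (dt/2) v
    B: v <- v + (dt/2) F(x)/m

with one force evaluation per step.  With friction gamma -> 0 the O step
becomes the identity and the scheme reduces exactly to velocity Verlet
(NVE), which is how energy-conservation tests drive it.

There is no explicit solvent: the Langevin thermostat plus a relative
dielectric (default 10) stand in for aqueous screening, which keeps
binding events of the bundled coarse-grained complexes at desk scale.
Cutoffs are optional and off by default (direct O(N²) sums are exact for
these system sizes); when enabled, LJ uses a 7.5/9.0 Å switched scheme and
Coulomb is truncated at the cutoff (no Ewald).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Protocol, runtime_checkable

import numpy as np

from . import _kernels
from .topology import Frame, MolecularSystem, Trajectory
from .units import FS, KB, KCAL_TO_AKMA, COULOMB_K


class EngineError(RuntimeError):
    """Raised on physical singularities or numerical blow-up."""


# (atom_id, k kcal/mol/Å², reference 3-vector Å)
Restraint = tuple[int, float, np.ndarray]


@dataclass
class ForceFieldTerms:
    """Potential-energy terms beyond what the topology already carries.

    Bonds and elastic pairs come from the MolecularSystem; this object adds
    the nonbonded treatment and optional positional restraints.
    """

    coulomb_constant: float = COULOMB_K
    dielectric: float = 10.0
    #: optional Debye screening length λ_D (Å): electrostatics become
    #: qq·exp(-r/λ_D)/(ε_r·r), standing in for dissolved salt; None = bare
    debye_length: float | None = None
    use_cutoffs: bool = False
    lj_switch_start: float = 7.5  # Å
    nonbonded_cutoff: float = 9.0  # Å
    restraints: list[Restraint] = field(default_factory=list)

    @property
    def kappa(self) -> float:
        return 0.0 if self.debye_length is None else 1.0 / self.debye_length

    def __post_init__(self) -> None:
        if self.dielectric < 1.0:
            raise ValueError("relative dielectric must be >= 1")
        if self.debye_length is not None and self.debye_length <= 0:
            raise ValueError("debye_length must be positive")
        if self.use_cutoffs and not (0 < self.lj_switch_start < self.nonbonded_cutoff):
            raise ValueError("need 0 < lj_switch_start < nonbonded_cutoff")


@dataclass
class EngineConfig:
    """Integrator settings.  Times in fs/ps as named; temperature in K."""

    timestep_fs: float = 2.0
    temperature: float = 310.0
    friction: float = 1.0  # ps^-1
    seed: int = 0
    snapshot_interval_ps: float = 10.0

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")


@dataclass
class EngineState:
    """Coordinates (Å), velocities (Å/ps) and clock (ps) of a running system."""

    coordinates: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    rng_token: int | None = None  # seed of the last stochastic operation

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.coordinates.shape != self.velocities.shape:
            raise ValueError("coordinates/velocities shape mismatch")
        if not (
            np.all(np.isfinite(self.coordinates)) and np.all(np.isfinite(self.velocities))
        ):
            raise ValueError("non-finite state")

    def as_frame(self) -> Frame:
        return Frame(
            coordinates=self.coordinates.copy(),
            velocities=self.velocities.copy(),
            time=self.time,
        )

    @classmethod
    def from_frame(cls, frame: Frame) -> "EngineState":
        v = frame.velocities if frame.velocities is not None else np.zeros_like(frame.coordinates)
        return cls(coordinates=frame.coordinates.copy(), velocities=v.copy(), time=frame.time)


def _nonbonded_pairs(system: MolecularSystem) -> tuple[np.ndarray, ...]:
    """All i<j pairs minus directly bonded ones, with combined parameters."""
    key = "nb_pairs"
    if key in system._cache:
        return system._cache[key]  # type: ignore[return-value]
    n = system.n_atoms
    iu, ju = np.triu_indices(n, k=1)
    excluded = {(min(i, j), max(i, j)) for i, j, _, _ in system.bonds}
    if excluded:
        keep = np.array([(i, j) not in excluded for i, j in zip(iu, ju)])
        iu, ju = iu[keep], ju[keep]
    q = system.charges
    rmh = system.lj_rmin_half
    eps = system.lj_epsilon
    pack = (
        iu.astype(np.int64),
        ju.astype(np.int64),
        (q[iu] * q[ju]),
        (rmh[iu] + rmh[ju]),
        np.sqrt(eps[iu] * eps[ju]),
    )
    system._cache[key] = pack  # type: ignore[assignment]
    return pack


def _restraint_arrays(terms: ForceFieldTerms) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not terms.restraints:
        z = np.zeros(0)
        return z.astype(np.int64), z, np.zeros((0, 3))
    idx = np.array([r[0] for r in terms.restraints], dtype=np.int64)
    ks = np.array([r[1] for r in terms.restraints], dtype=float)
    refs = np.array([np.asarray(r[2], dtype=float) for r in terms.restraints])
    return idx, ks, refs


def _bond_arrays(system: MolecularSystem) -> tuple[np.ndarray, ...]:
    """Bonds + elastic pairs concatenated into flat arrays, cached."""
    key = "bond_arrays"
    if key in system._cache:
        return system._cache[key]  # type: ignore[return-value]
    terms = list(system.bonds) + list(system.elastic_pairs)
    if not terms:
        z = np.zeros(0)
        pack = (z.astype(np.int64), z.astype(np.int64), z, z)
    else:
        arr = np.array([[i, j, k, r0] for i, j, k, r0 in terms], dtype=float)
        pack = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2].copy(),
            arr[:, 3].copy(),
        )
    system._cache[key] = pack  # type: ignore[assignment]
    return pack


def compute_forces(
    state: EngineState | Frame | np.ndarray,
    system: MolecularSystem,
    terms: ForceFieldTerms,
) -> tuple[np.ndarray, float]:
    """Forces (kcal/mol/Å) and potential energy (kcal/mol).

    Forces are the exact negative gradient of the returned potential:
    harmonic bonds + elastic-network pairs + positional restraints +
    (switched) 12-6 LJ + (truncated) Coulomb over all non-bonded pairs.
    """
    coords = state if isinstance(state, np.ndarray) else state.coordinates
    coords = np.ascontiguousarray(coords, dtype=float)
    forces = np.zeros_like(coords)
    pe = 0.0

    bi, bj, bk, br0 = _bond_arrays(system)
    if bi.size:
        pe += _kernels.harmonic_terms(coords, bi, bj, bk, br0, forces)

    ridx, rks, rrefs = _restraint_arrays(terms)
    if ridx.size:
        pe += _kernels.restraint_terms(coords, ridx, rks, rrefs, forces)

    iu, ju, qq, rmin, eps = _nonbonded_pairs(system)
    if iu.size:
        qq_scaled = qq * (terms.coulomb_constant / terms.dielectric)
        e_el, e_vdw, bad = _kernels.nonbonded_terms(
            coords,
            iu,
            ju,
            qq_scaled,
            rmin,
            eps,
            terms.use_cutoffs,
            terms.lj_switch_start,
            terms.nonbonded_cutoff,
            terms.kappa,
            forces,
        )
        if bad >= 0:
            raise EngineError(
                f"overlapping atoms {iu[bad]} and {ju[bad]} (r < 1e-6 Å): force singularity"
            )
        pe += e_el + e_vdw
    return forces, float(pe)


def resample_velocities(
    state: EngineState,
    system: MolecularSystem,
    temperature: float,
    seed: int,
) -> EngineState:
    """Draw fresh Maxwell–Boltzmann velocities at the given temperature.

    Per-atom, mass-dependent: each Cartesian component ~ N(0, kB T / m).
    Deterministic given the seed.  T -> 0 gives zero velocities.
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB * temperature * KCAL_TO_AKMA / system.masses)  # Å/ps
    v = rng.standard_normal(state.coordinates.shape) * sigma[:, None]
    return EngineState(
        coordinates=state.coordinates.copy(),
        velocities=v,
        time=state.time,
        rng_token=seed,
    )


def _baoab_constants(system: MolecularSystem, config: EngineConfig):
    dt = config.timestep_fs * FS  # ps
    m = system.masses[:, None]
    c1 = math.exp(-config.friction * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma = np.sqrt(KB * config.temperature * KCAL_TO_AKMA / m)  # Å/ps
    return dt, m, c1, c2, sigma


def langevin_step(
    state: EngineState,
    system: MolecularSystem,
    terms: ForceFieldTerms,
    config: EngineConfig,
    rng: np.random.Generator | None = None,
) -> EngineState:
    """One BAOAB step.  With friction = 0 the O-step is the identity and the
    scheme is exactly velocity Verlet."""
    rng = rng or np.random.default_rng(config.seed)
    dt, m, c1, c2, sigma = _baoab_constants(system, config)
    x = state.coordinates.copy()
    v = state.velocities.copy()
    f, _ = compute_forces(x, system, terms)
    acc = f * KCAL_TO_AKMA / m
    v += 0.5 * dt * acc
    x += 0.5 * dt * v
    if c2 > 0.0:
        v = c1 * v + c2 * sigma * rng.standard_normal(v.shape)
    x += 0.5 * dt * v
    f, _ = compute_forces(x, system, terms)
    v += 0.5 * dt * f * KCAL_TO_AKMA / m
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
        raise EngineError("non-finite coordinates after integration step (blow-up)")
    return EngineState(coordinates=x, velocities=v, time=state.time + dt)


def advance(
    state: EngineState,
    system: MolecularSystem,
    terms: ForceFieldTerms,
    config: EngineConfig,
    duration: float,
    seed: int,
) -> tuple[Trajectory, EngineState]:
    """Integrate ``duration`` ps, snapshotting every ``snapshot_interval_ps``.

    The returned segment's first frame is the state after the first snapshot
    interval — the caller already holds the starting frame.  Bitwise
    reproducible given (state, seed).
    """
    dt, m, c1, c2, sigma = _baoab_constants(system, config)
    snap_every = int(round(config.snapshot_interval_ps / dt))
    n_steps = int(round(duration / dt))
    if n_steps <= 0 or snap_every <= 0 or n_steps % snap_every != 0:
        raise ValueError(
            "duration must be a positive multiple of snapshot_interval "
            f"(duration={duration} ps, interval={config.snapshot_interval_ps} ps)"
        )
    x = np.ascontiguousarray(state.coordinates, dtype=float).copy()
    v = np.ascontiguousarray(state.velocities, dtype=float).copy()
    t0 = state.time
    bi, bj, bk, br0 = _bond_arrays(system)
    ridx, rks, rrefs = _restraint_arrays(terms)
    iu, ju, qq, rmin, eps = _nonbonded_pairs(system)
    qq_scaled = qq * (terms.coulomb_constant / terms.dielectric)
    n_snaps = n_steps // snap_every
    snaps_x = np.empty((n_snaps, system.n_atoms, 3))
    snaps_v = np.empty_like(snaps_x)
    # thermostat noise is pre-drawn from numpy's seeded PCG64 stream; the
    # kernel just consumes it, which keeps the (state, seed) -> trajectory
    # map bit-reproducible and the inner loop branch-free
    if config.friction > 0.0:
        noise = np.random.default_rng(seed).standard_normal(
            (n_steps, 3 * system.n_atoms)
        )
    else:
        noise = np.zeros((1, 3 * system.n_atoms))
    status, at_step = _kernels.integrate_baoab(
        x,
        v,
        (KCAL_TO_AKMA / m).ravel(),
        sigma.ravel(),
        bi, bj, bk, br0,
        ridx, rks, rrefs,
        iu, ju, qq_scaled, rmin, eps,
        terms.use_cutoffs, terms.lj_switch_start, terms.nonbonded_cutoff,
        terms.kappa,
        dt, c1, c2,
        n_steps, snap_every,
        noise,
        snaps_x, snaps_v,
    )
    if status == 1:
        raise EngineError(f"step {at_step}: overlapping atoms (force singularity)")
    if status == 2:
        raise EngineError(f"non-finite coordinates at step {at_step} (blow-up)")
    frames = [
        Frame(
            coordinates=snaps_x[k].copy(),
            velocities=snaps_v[k].copy(),
            time=t0 + (k + 1) * snap_every * dt,
        )
        for k in range(n_snaps)
    ]
    final = EngineState(coordinates=x, velocities=v, time=t0 + n_steps * dt, rng_token=seed)
    return Trajectory(system=system, frames=frames), final


def equilibrate(
    state: EngineState,
    system: MolecularSystem,
    terms: ForceFieldTerms,
    config: EngineConfig,
    restraint_k: float = 5.0,
    duration: float = 1000.0,
    seed: int = 0,
) -> EngineState:
    """Restrained NVT relaxation: every atom harmonically tethered to its
    input position with ``restraint_k`` (kcal/mol/Å²), then restraints
    dropped.  ``duration`` 0 returns the state unchanged."""
    if restraint_k < 0:
        raise ValueError("restraint_k must be >= 0")
    if duration == 0:
        return state
    restrained = replace(
        terms,
        restraints=[
            (i, restraint_k, state.coordinates[i].copy()) for i in range(system.n_atoms)
        ]
        if restraint_k > 0
        else [],
    )
    _, final = advance(state, system, restrained, config, duration, seed)
    return final


@runtime_checkable
class DynamicsEngine(Protocol):
    """The engine contract the supervision loop drives.

    Any backend (this toy engine, or an adapter wrapping an all-atom
    package) must provide these two operations with exactly the snapshot
    semantics of :func:`advance`.  Note the contract deliberately has no
    equilibration or barostat surface: pressure coupling belongs to system
    preparation on the backend's side.
    """

    system: MolecularSystem

    def advance(
        self, state: EngineState, duration: float, seed: int
    ) -> tuple[Trajectory, EngineState]: ...

    def resample_velocities(self, state: EngineState, seed: int) -> EngineState: ...


class ToyEngine:
    """The bundled coarse-grained Langevin backend, bound to one system."""

    def __init__(
        self,
        system: MolecularSystem,
        terms: ForceFieldTerms | None = None,
        config: EngineConfig | None = None,
    ) -> None:
        self.system = system
        self.terms = terms or ForceFieldTerms()
        self.config = config or EngineConfig()

    def advance(
        self, state: EngineState, duration: float, seed: int
    ) -> tuple[Trajectory, EngineState]:
        return advance(state, self.system, self.terms, self.config, duration, seed)

    def resample_velocities(self, state: EngineState, seed: int) -> EngineState:
        return resample_velocities(state, self.system, self.config.temperature, seed)

    def equilibrate(
        self,
        state: EngineState,
        restraint_k: float = 5.0,
        duration: float = 1000.0,
        seed: int = 0,
    ) -> EngineState:
        return equilibrate(
            state, self.system, self.terms, self.config, restraint_k, duration, seed
        )
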