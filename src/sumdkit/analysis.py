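"""Trajectory analytics: superposition RMSD, COM-distance profiles,
interaction energies and their per-residue decomposition, contact
fingerprints, and replica stability ranking.

Interaction energies are the sum of van der Waals (12-6 LJ,
Lorentz–Berthelot combining) and electrostatic (Coulomb over a relative
dielectric) contributions between the two components, in kcal/mol.  By
default the double sum is exact (no cutoff); a switched-cutoff mode
consistent with the engine's 7.5/9.0 Å scheme is available for
comparability with dynamics settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .engine import ForceFieldTerms
from .topology import (
    Component,
    Frame,
    MolecularSystem,
    Selection,
    Trajectory,
)

ResidueKey = tuple[str, int]  # (chain_id, residue_index)


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition: x_aligned = (x - com_mobile) @ rotation + shift.

    ``rotation`` acts on row vectors; it is proper (det = +1, reflections
    excluded by the Kabsch determinant correction).
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation + self.translation


@dataclass
class EnergySeries:
    """Per-frame interaction energy between the two components."""

    times: np.ndarray
    electrostatic: np.ndarray
    vdw: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.electrostatic + self.vdw

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ps": self.times,
                "electrostatic_kcal_mol": self.electrostatic,
                "vdw_kcal_mol": self.vdw,
                "total_kcal_mol": self.total,
            }
        )


@dataclass
class PerResidueEnergyMatrix:
    """Residues × frames interaction energy of one component vs the partner."""

    residue_keys: list[ResidueKey]
    residue_labels: list[str]
    times: np.ndarray
    matrix: np.ndarray  # (n_residues, n_frames), kcal/mol

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.residue_labels, columns=self.times
        )


@dataclass
class ContactTable:
    """Per-residue contact frequencies (fraction of frames with >= 1 atom
    pair of that residue within ``cutoff`` of the partner component)."""

    receptor: dict[ResidueKey, float]
    ligand: dict[ResidueKey, float]
    cutoff: float
    labels: dict[ResidueKey, str] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"component": comp, "residue": self.labels.get(k, str(k)), "frequency": v}
            for comp, table in (("receptor", self.receptor), ("ligand", self.ligand))
            for k, v in table.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class ReplicaMetrics:
    replica_id: str
    mean_rmsd: float
    sd_rmsd: float
    mean_energy: float
    sd_energy: float


def residue_label(
    system: MolecularSystem,
    key: ResidueKey,
    numbering_offsets: dict[str, int] | None = None,
) -> str:
    """Display label like ``A:ARG:788``; display numbering may be shifted
    per chain to match a reference (e.g. UniProt) numbering."""
    chain, resid = key
    offset = (numbering_offsets or {}).get(chain, 0)
    name = next(
        (a.residue_name for a in system.atoms if a.chain_id == chain and a.residue_index == resid),
        "UNK",
    )
    return f"{chain}:{name}:{resid + offset}"


# ---------------------------------------------------------------------------
# superposition


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``
    (Kabsch algorithm, SVD with determinant correction)."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching N×3 arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    cm = w @ mobile
    cr = w @ reference
    p = mobile - cm
    q = reference - cr
    if np.linalg.matrix_rank(p * w[:, None], tol=1e-10) < 2:
        raise ValueError("degenerate (collinear or coincident) point set")
    h = p.T @ (w[:, None] * q)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt  # row-vector convention: aligned = p @ rot
    aligned = p @ rot
    rmsd = float(np.sqrt((w * ((aligned - q) ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rotation=rot, translation=cr - cm @ rot, rmsd=rmsd)


def cross_rmsd(
    trajectory: Trajectory | Frame,
    reference: Frame,
    align_sel: Selection,
    measure_sel: Selection,
) -> np.ndarray:
    """Per-frame RMSD of ``measure_sel`` after superposing each frame onto
    the reference over ``align_sel`` (e.g. align on the nucleic-acid
    backbone, measure the protein backbone).  Unweighted."""
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else [trajectory]
    ref_align = reference.coordinates[align_sel.atom_ids]
    ref_meas = reference.coordinates[measure_sel.atom_ids]
    out = np.empty(len(frames))
    for i, f in enumerate(frames):
        if f.n_atoms != reference.n_atoms:
            raise ValueError(
                f"frame has {f.n_atoms} atoms, reference has {reference.n_atoms}: "
                "selections cannot be matched"
            )
        sup = superpose(f.coordinates[align_sel.atom_ids], ref_align)
        moved = sup.apply(f.coordinates[measure_sel.atom_ids])
        out[i] = np.sqrt(((moved - ref_meas) ** 2).sum(axis=1).mean())
    return out


# ---------------------------------------------------------------------------
# energetics


def _cross_pairs(system: MolecularSystem, ids_a: np.ndarray, ids_b: np.ndarray):
    ia, ib = np.meshgrid(ids_a, ids_b, indexing="ij")
    ia = ia.ravel().astype(np.int64)
    ib = ib.ravel().astype(np.int64)
    q = system.charges
    rmh = system.lj_rmin_half
    eps = system.lj_epsilon
    return ia, ib, q[ia] * q[ib], rmh[ia] + rmh[ib], np.sqrt(eps[ia] * eps[ib])


def interaction_energy(
    frame: Frame,
    system: MolecularSystem,
    group_a: Selection | np.ndarray,
    group_b: Selection | np.ndarray,
    terms: ForceFieldTerms | None = None,
) -> tuple[float, float]:
    """(electrostatic, vdw) interaction energy between two disjoint groups."""
    terms = terms or ForceFieldTerms()
    ids_a = group_a.atom_ids if isinstance(group_a, Selection) else np.asarray(group_a)
    ids_b = group_b.atom_ids if isinstance(group_b, Selection) else np.asarray(group_b)
    if np.intersect1d(ids_a, ids_b).size:
        raise ValueError("groups must be disjoint")
    ia, ib, qq, rmin, eps = _cross_pairs(system, ids_a, ids_b)
    e_el = np.zeros(ia.size)
    e_vdw = np.zeros(ia.size)
    bad = _kernels.nonbonded_pair_energies(
        np.ascontiguousarray(frame.coordinates),
        ia,
        ib,
        qq * (terms.coulomb_constant / terms.dielectric),
        rmin,
        eps,
        terms.use_cutoffs,
        terms.lj_switch_start,
        terms.nonbonded_cutoff,
        terms.kappa,
        e_el,
        e_vdw,
    )
    if bad >= 0:
        raise ValueError(
            f"overlapping atoms {ia[bad]} and {ib[bad]} across groups"
        )
    return float(e_el.sum()), float(e_vdw.sum())


def interaction_energy_series(
    trajectory: Trajectory,
    system: MolecularSystem,
    terms: ForceFieldTerms | None = None,
) -> EnergySeries:
    """Receptor–ligand interaction energy along a trajectory."""
    rec = system.component_ids(Component.RECEPTOR)
    lig = system.component_ids(Component.LIGAND)
    el = np.empty(len(trajectory))
    vdw = np.empty(len(trajectory))
    for i, f in enumerate(trajectory):
        el[i], vdw[i] = interaction_energy(f, system, rec, lig, terms)
    return EnergySeries(times=trajectory.times, electrostatic=el, vdw=vdw)


def per_residue_profile(
    trajectory: Trajectory,
    system: MolecularSystem,
    component: Component | str,
    terms: ForceFieldTerms | None = None,
    numbering_offsets: dict[str, int] | None = None,
) -> PerResidueEnergyMatrix:
    """Time-resolved per-residue decomposition of the interaction energy.

    Entry (r, f) = total (elec + vdW) energy between residue r of the
    chosen component and the entire partner component at frame f.  Rows
    sum to the component's total interaction energy per frame (exactly,
    when cutoffs are disabled).
    """
    terms = terms or ForceFieldTerms()
    component = Component(component)
    partner = Component.LIGAND if component is Component.RECEPTOR else Component.RECEPTOR
    ids_c = system.component_ids(component)
    ids_p = system.component_ids(partner)
    if ids_c.size == 0:
        raise ValueError(f"component {component.value!r} has no atoms")
    if ids_p.size == 0:
        raise ValueError(f"partner component {partner.value!r} has no atoms")
    keys = system.residue_keys(component)
    key_index = {k: i for i, k in enumerate(keys)}
    # residue bin of each cross pair, computed once
    ia, ib, qq, rmin, eps = _cross_pairs(system, ids_c, ids_p)
    res_of_pair = np.array(
        [key_index[(system.atoms[i].chain_id, system.atoms[i].residue_index)] for i in ia]
    )
    qq_scaled = qq * (terms.coulomb_constant / terms.dielectric)
    mat = np.zeros((len(keys), len(trajectory)))
    e_el = np.zeros(ia.size)
    e_vdw = np.zeros(ia.size)
    for f_idx, f in enumerate(trajectory):
        bad = _kernels.nonbonded_pair_energies(
            np.ascontiguousarray(f.coordinates),
            ia, ib, qq_scaled, rmin, eps,
            terms.use_cutoffs, terms.lj_switch_start, terms.nonbonded_cutoff,
            terms.kappa, e_el, e_vdw,
        )
        if bad >= 0:
            raise ValueError(
                f"overlapping atoms {ia[bad]} and {ib[bad]} at frame {f_idx}"
            )
        mat[:, f_idx] = np.bincount(res_of_pair, weights=e_el + e_vdw, minlength=len(keys))
    labels = [residue_label(system, k, numbering_offsets) for k in keys]
    return PerResidueEnergyMatrix(
        residue_keys=keys, residue_labels=labels, times=trajectory.times, matrix=mat
    )


# ---------------------------------------------------------------------------
# contacts


def contact_table(
    trajectory: Trajectory,
    system: MolecularSystem,
    cutoff: float = 4.5,
    top_k: int = 25,
    numbering_offsets: dict[str, int] | None = None,
) -> ContactTable:
    """Contact frequency per residue of both components.

    A residue is "in contact" in a frame when at least one of its atoms
    lies within ``cutoff`` Å of any partner-component atom; the frequency
    is the fraction of frames in contact.  Output keeps the ``top_k`` most
    frequently contacting residues of each component.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    rec = system.component_ids(Component.RECEPTOR)
    lig = system.component_ids(Component.LIGAND)
    res_rec = system.residue_keys(Component.RECEPTOR)
    res_lig = system.residue_keys(Component.LIGAND)
    idx_rec = {k: i for i, k in enumerate(res_rec)}
    idx_lig = {k: i for i, k in enumerate(res_lig)}
    rr = np.array([idx_rec[(system.atoms[i].chain_id, system.atoms[i].residue_index)] for i in rec])
    rl = np.array([idx_lig[(system.atoms[i].chain_id, system.atoms[i].residue_index)] for i in lig])
    count_rec = np.zeros(len(res_rec))
    count_lig = np.zeros(len(res_lig))
    nf = len(trajectory)
    for f in trajectory:
        d = np.linalg.norm(
            f.coordinates[rec][:, None, :] - f.coordinates[lig][None, :, :], axis=-1
        )
        close = d <= cutoff
        hit_rec_atom = close.any(axis=1)
        hit_lig_atom = close.any(axis=0)
        count_rec[np.unique(rr[hit_rec_atom])] += 1
        count_lig[np.unique(rl[hit_lig_atom])] += 1
    freq_rec = count_rec / max(nf, 1)
    freq_lig = count_lig / max(nf, 1)

    def top(keys, freqs):
        order = sorted(range(len(keys)), key=lambda i: (-freqs[i], i))[:top_k]
        return {keys[i]: float(freqs[i]) for i in order}

    labels = {
        k: residue_label(system, k, numbering_offsets) for k in (*res_rec, *res_lig)
    }
    return ContactTable(
        receptor=top(res_rec, freq_rec),
        ligand=top(res_lig, freq_lig),
        cutoff=cutoff,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# replica ranking


def replica_metrics(
    trajectory: Trajectory,
    system: MolecularSystem,
    align_sel: Selection,
    measure_sel: Selection,
    terms: ForceFieldTerms | None = None,
    replica_id: str = "run",
    reference: Frame | None = None,
) -> ReplicaMetrics:
    """Mean ± sd of RMSD-from-start and of total interaction energy.

    The RMSD reference defaults to the trajectory's own first frame
    ("RMSD from the initial state"), the convention of stability analyses
    of classical-MD extensions; pass ``reference`` explicitly to compare
    against an experimental structure instead.  sd is the population
    standard deviation (ddof = 0).
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    ref = reference or trajectory[0]
    rmsds = cross_rmsd(trajectory, ref, align_sel, measure_sel)
    energies = interaction_energy_series(trajectory, system, terms).total
    return ReplicaMetrics(
        replica_id=replica_id,
        mean_rmsd=float(rmsds.mean()),
        sd_rmsd=float(rmsds.std()),
        mean_energy=float(energies.mean()),
        sd_energy=float(energies.std()),
    )


def rank_replicas(metrics: list[ReplicaMetrics]) -> list[ReplicaMetrics]:
    """Order replicas best-first by composite stability rank.

    Each replica gets the sum of its within-set ranks of mean RMSD
    (ascending: lowest drift best) and mean interaction energy (ascending:
    most negative best).  Ties on the composite are broken by mean energy,
    then by input order (stable).
    """
    if not metrics:
        raise ValueError("need at least one replica")
    from scipy.stats import rankdata

    r_rmsd = rankdata([m.mean_rmsd for m in metrics], method="min")
    r_en = rankdata([m.mean_energy for m in metrics], method="min")
    score = r_rmsd + r_en
    order = sorted(
        range(len(metrics)), key=lambda i: (score[i], metrics[i].mean_energy, i)
    )
    return [metrics[i] for i in order]


def com_distance_series(
    trajectory: Trajectory,
    system: MolecularSystem,
    sel_a: Selection,
    sel_b: Selection,
    periodic: bool = False,
) -> np.ndarray:
    """Supervised-style COM distance profile along a trajectory, Å."""
    from .topology import com_distance

    return np.array(
        [com_distance(f, system, sel_a, sel_b, periodic) for f in trajectory]
    )
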