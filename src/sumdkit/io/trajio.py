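"""Trajectory I/O in the XTC container (via mdtraj).

XTC stores coordinates in nm with ~1e-3 nm fixed-point precision and a
per-frame time stamp in ps; this package's Å coordinates are converted at
this boundary (Å = 10 × nm), so the documented roundtrip precision is
0.01 Å.  A zero-frame trajectory writes a valid empty file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from mdtraj.formats import XTCTrajectoryFile

from ..topology import Frame, MolecularSystem, Trajectory

_NM_PER_ANGSTROM = 0.1


def write_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    path = str(path)
    with XTCTrajectoryFile(path, "w") as fh:
        if len(trajectory) == 0:
            return
        xyz = trajectory.coordinates_array() * _NM_PER_ANGSTROM
        times = trajectory.times
        fh.write(
            xyz.astype(np.float32),
            time=times.astype(np.float32),
            step=np.arange(1, len(trajectory) + 1),
        )


def read_trajectory(path: str | Path, system: MolecularSystem) -> Trajectory:
    path = Path(path)
    if path.stat().st_size == 0:
        return Trajectory(system=system, frames=[])
    with XTCTrajectoryFile(str(path), "r") as fh:
        xyz, times, _, _ = fh.read()
    if xyz.shape[0] and xyz.shape[1] != system.n_atoms:
        raise ValueError(
            f"trajectory has {xyz.shape[1]} atoms, topology has {system.n_atoms}"
        )
    frames = [
        Frame(coordinates=np.asarray(xyz[i], dtype=float) / _NM_PER_ANGSTROM, time=float(times[i]))
        for i in range(xyz.shape[0])
    ]
    return Trajectory(system=system, frames=frames)
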