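"""YAML run configuration.

The config file names everything a run needs: input paths, engine and
force-field settings, the supervision phases (with selection expressions),
and analysis settings.  Unknown keys are rejected — a typo in a threshold
name must fail, not silently fall back to a default.  The ``run``
subcommand echoes the fully resolved config next to its outputs; re-running
from the echo reproduces the step log exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class PathsConfig:
    topology: str = "system.top"
    coordinates: str = "system.pdb"
    output_dir: str = "sumd_out"


@dataclass
class EngineSection:
    timestep_fs: float = 2.0
    temperature: float = 310.0
    friction: float = 1.0
    snapshot_interval_ps: float = 10.0


@dataclass
class ForceFieldSection:
    dielectric: float = 10.0
    debye_length: float | None = None  # Å; null = bare Coulomb
    use_cutoffs: bool = False
    lj_switch_start: float = 7.5
    nonbonded_cutoff: float = 9.0


@dataclass
class EquilibrationSection:
    restraint_k: float = 5.0  # kcal/mol/Å²
    duration_ps: float = 1000.0
    seed: int = 0


@dataclass
class PhaseSection:
    name: str
    ligand: str  # selection expression
    receptor: str
    step_length_ps: float = 300.0
    slope_threshold: float = 0.0
    switch_distance: float | None = None
    switch_fraction: float = 1.0
    target_distance: float | None = None


@dataclass
class ProtocolSection:
    phases: list[PhaseSection] = field(default_factory=list)
    max_retries_per_step: int = 20
    max_productive_steps: int = 100
    master_seed: int = 0


@dataclass
class AnalysisSection:
    contact_cutoff: float = 4.5  # Å
    top_k: int = 25
    align: str = "component receptor"  # selection for RMSD alignment
    measure: str = "component ligand"  # selection for RMSD measurement
    numbering_offsets: dict[str, int] = field(default_factory=dict)


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    engine: EngineSection = field(default_factory=EngineSection)
    forcefield: ForceFieldSection = field(default_factory=ForceFieldSection)
    equilibration: EquilibrationSection = field(default_factory=EquilibrationSection)
    protocol: ProtocolSection = field(default_factory=ProtocolSection)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        _check_keys(
            data,
            {"paths", "engine", "forcefield", "equilibration", "protocol", "analysis"},
            "config",
        )
        cfg = cls()
        for section, typ in (
            ("paths", PathsConfig),
            ("engine", EngineSection),
            ("forcefield", ForceFieldSection),
            ("equilibration", EquilibrationSection),
            ("analysis", AnalysisSection),
        ):
            if section in data:
                sub = data[section] or {}
                _check_keys(sub, {f for f in typ.__dataclass_fields__}, section)
                setattr(cfg, section, typ(**sub))
        if "protocol" in data:
            sub = dict(data["protocol"] or {})
            _check_keys(sub, {f for f in ProtocolSection.__dataclass_fields__}, "protocol")
            phases = []
            for i, ph in enumerate(sub.pop("phases", []) or []):
                _check_keys(
                    ph, {f for f in PhaseSection.__dataclass_fields__}, f"protocol.phases[{i}]"
                )
                phases.append(PhaseSection(**ph))
            cfg.protocol = ProtocolSection(phases=phases, **sub)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
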