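"""YAML project configuration for the command-line workflow.

A project file collects per-species template settings (frequency
limits, window size), the score-cut-off sweep parameters, evaluation
paths and the master seed, so a whole campaign re-runs from one
document.  CLI flags override config values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SpeciesConfig", "SweepConfig", "ProjectConfig", "load_config"]


@dataclass(frozen=True)
class SpeciesConfig:
    name: str
    freq_limits: tuple[float, float]
    window_size: int = 512
    template_paths: tuple[str, ...] = ()


@dataclass(frozen=True)
class SweepConfig:
    start: float = 3.0
    step: float = 0.2
    stop: float | None = None


@dataclass(frozen=True)
class ProjectConfig:
    species: tuple[SpeciesConfig, ...] = ()
    sweep: SweepConfig = field(default_factory=SweepConfig)
    annotations: str | None = None
    audio_dir: str | None = None
    output_dir: str = "chorusmatch_out"
    seed: int = 0


_TOP_KEYS = {"species", "sweep", "annotations", "audio_dir", "output_dir", "seed"}
_SPECIES_KEYS = {"name", "freq_limits", "window_size", "template_paths"}
_SWEEP_KEYS = {"start", "step", "stop"}


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ValueError(f"invalid config key '{key}' in {where}")


def load_config(path: str | Path) -> ProjectConfig:
    """Parse and validate a project YAML file; unknown keys are errors."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a mapping")
    _check_keys(doc, _TOP_KEYS, "project config")

    species = []
    for entry in doc.get("species", []) or []:
        _check_keys(entry, _SPECIES_KEYS, f"species entry {entry.get('name', '?')!r}")
        species.append(SpeciesConfig(
            name=entry["name"],
            freq_limits=tuple(entry["freq_limits"]),
            window_size=int(entry.get("window_size", 512)),
            template_paths=tuple(entry.get("template_paths", ())),
        ))

    sweep_doc = doc.get("sweep", {}) or {}
    _check_keys(sweep_doc, _SWEEP_KEYS, "sweep section")
    sweep = SweepConfig(
        start=float(sweep_doc.get("start", 3.0)),
        step=float(sweep_doc.get("step", 0.2)),
        stop=None if sweep_doc.get("stop") is None else float(sweep_doc["stop"]),
    )

    return ProjectConfig(
        species=tuple(species),
        sweep=sweep,
        annotations=doc.get("annotations"),
        audio_dir=doc.get("audio_dir"),
        output_dir=str(doc.get("output_dir", "chorusmatch_out")),
        seed=int(doc.get("seed", 0)),
    )
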