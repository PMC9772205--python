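"""Run configuration: one validated YAML document for a whole pipeline run.

A ``RunConfig`` bundles the cohort description, crop geometry,
hyperparameter grids, consensus-architecture overrides, experiment
protocol, paths and the global seed.  Unknown keys anywhere in the
document are rejected before any computation starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import ExperimentConfig
from .models import DEFAULT_C_GRID, DEFAULT_COMPONENTS_GRID
from .roi import CropGeometry
from .signs import SignKind
from .synthetic import CohortSpec, RaterProfile


def _build(cls, payload: dict, context: str):
    """Instantiate a dataclass from a dict, rejecting unknown keys."""
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**payload)


def _cohort_from_dict(payload: dict) -> CohortSpec:
    payload = dict(payload)
    for key in ("prevalence", "pain_prevalence"):
        if key in payload:
            payload[key] = {SignKind(k): float(v) for k, v in payload[key].items()}
    if "raters" in payload:
        payload["raters"] = tuple(
            _build(RaterProfile, r, "cohort.raters") for r in payload["raters"]
        )
    if "intensity_range" in payload:
        payload["intensity_range"] = tuple(payload["intensity_range"])
    return _build(CohortSpec, payload, "cohort")


@dataclass(frozen=True)
class RunConfig:
    data_dir: str | None = None
    model_dir: str | None = None
    report_dir: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    geometry: CropGeometry = field(default_factory=CropGeometry)
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_components_grid: tuple[int, ...] = DEFAULT_COMPONENTS_GRID
    #: sign -> "voting" | "aggregating", overriding the default assignment
    consensus_overrides: dict[SignKind, str] = field(default_factory=dict)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for sign, kind in self.consensus_overrides.items():
            if kind not in ("voting", "aggregating"):
                raise ValueError(
                    f"consensus override for {sign} must be voting/aggregating, got {kind!r}"
                )

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload or {})
        if "cohort" in payload:
            payload["cohort"] = _cohort_from_dict(payload["cohort"])
        if "geometry" in payload:
            payload["geometry"] = _build(CropGeometry, payload["geometry"], "geometry")
        if "experiment" in payload:
            payload["experiment"] = _build(
                ExperimentConfig, payload["experiment"], "experiment"
            )
        if "consensus_overrides" in payload:
            payload["consensus_overrides"] = {
                SignKind(k): v for k, v in payload["consensus_overrides"].items()
            }
        for key in ("C_grid", "n_components_grid"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return _build(cls, payload, "run config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if payload is None:
            payload = {}
        if not isinstance(payload, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        return cls.from_dict(payload)

    def assignment(self) -> dict[SignKind, str]:
        from .models import default_consensus_assignment

        out = default_consensus_assignment()
        out.update(self.consensus_overrides)
        return out
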