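"""Pipeline configuration: every tunable threshold, grouped by stage.

Config files are YAML mappings mirroring this model; unknown keys are
rejected (``extra="forbid"``) and all defaults are materialised, so the
echoed config in a run log is complete and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .dose_response import CRCThresholds
from .triage import TriageConfig

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


def _seven_doses() -> list[float]:
    # 7-dose confirmation design: 57 µM top, 1:3 dilutions
    return [57.0 / 3.0**k for k in range(7)]


class SynthSection(_Strict):
    noise_cv: float = 0.05
    n_inactive: int = 1387
    n_true: int = 8
    n_counter_fp: int = 30
    n_promiscuous: int = 15
    true_ic50_range_um: tuple[float, float] = (0.03, 3.0)
    true_efficacy_range_pct: tuple[float, float] = (85.0, 100.0)
    counter_ic50_range_um: tuple[float, float] = (0.1, 50.0)
    promiscuous_ic50_range_um: tuple[float, float] = (1.0, 30.0)
    primary_doses_um: list[float] = Field(default_factory=lambda: [57.0, 11.4, 2.28, 0.456])
    confirmation_doses_um: list[float] = Field(default_factory=_seven_doses)
    control_ic50_um: float = 27.0
    control_top_um: float = 285.0
    control_n_doses: int = 16


class QCSection(_Strict):
    positional_threshold: float = 0.2
    z_prime_min: float = 0.5


class DoseResponseSection(_Strict):
    high_efficacy: float = 80.0
    partial_floor: float = 30.0
    r2_min: float = 0.9
    asymptote_slope_tol: float = 10.0
    baseline_prox_tol: float = 10.0
    single_dose_activity: float = 50.0
    extrapolation_logs: float = 1.0

    def thresholds(self) -> CRCThresholds:
        return CRCThresholds(**self.model_dump())


class TriageSection(_Strict):
    top_dose_response_min: float = 50.0
    counter_inactive_rule: str = "class"
    counter_inactive_floor: float = 30.0
    differential_pic50_gap: float = 1.0
    differential_counter_efficacy: float = 50.0
    potency_gate_um: float = 10.0

    def triage_config(self) -> TriageConfig:
        return TriageConfig(**self.model_dump())


class KineticsSection(_Strict):
    ambiguity_delta: float = 2.0


class PKSection(_Strict):
    trapezoid_method: str = "linuplogdown"
    lambda_z_points: int = 3
    lambda_z_select: str = "last"


class BiomarkersSection(_Strict):
    reduction_uncertainty: str = "delta"  # or "bootstrap"
    alpha: float = 0.05


class PipelineConfig(_Strict):
    """Root configuration; section names match the pipeline stages."""

    seed: int = 0
    synth: SynthSection = Field(default_factory=SynthSection)
    qc: QCSection = Field(default_factory=QCSection)
    dose_response: DoseResponseSection = Field(default_factory=DoseResponseSection)
    triage: TriageSection = Field(default_factory=TriageSection)
    kinetics: KineticsSection = Field(default_factory=KineticsSection)
    pk: PKSection = Field(default_factory=PKSection)
    biomarkers: BiomarkersSection = Field(default_factory=BiomarkersSection)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; missing file fields fall back to defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True))


def config_hash(config: PipelineConfig) -> str:
    """Stable digest of the fully materialised configuration."""
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
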