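"""Experiment configuration: validated schema, YAML round-trip, presets.

The defaults reproduce the published parameter sets: the parameter-
evaluation polymerase (R_max 0.5, |b| 1, C_0 0, 2 s mean pauses over a
Gamma(1, 10 ms) extension -- an effective ~100 Hz recorder spending ~17%
of its time paused -- and 10,000 bp records) with parameter-evaluation
alignment settings (k = 2000 ms, omega = 1/100, 50 ms calcium bins,
100-nt DNA bins), and a center-out preset (12,000 bp, omega = 1/240,
25-nt DNA bins, cosine tuning with rates in [10, 150] spikes/s).

Sign note: the error sigmoid is implemented exactly as written, which
decreases with calcium for positive b; the presets store b = -1 so error
rates rise with calcium, as the experiments assume, with |b| from the
published table.
"""

from __future__ import annotations

import hashlib
import json
import math
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .align import AlignmentConfig
from .dnap import ErrorFunction, KineticModel
from .neural import CosineTuning, LinearTuning

__all__ = [
    "DnapBlock",
    "AlignmentBlock",
    "NeuralBlock",
    "SweepBlock",
    "ExperimentConfig",
    "parse_config",
    "write_config",
    "parameter_evaluation_config",
    "center_out_config",
]

SWEEP_AXES = ("record_length", "incorporation_rate", "sensitivity_b", "r_max")


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DnapBlock(_Block):
    """Polymerase parameters (error transfer function + kinetics)."""

    R_max: float = Field(0.5, gt=0, le=1)
    b: float = -1.0
    C_0: float = 0.0
    # 0.001 gives the ~100 Hz effective rate and ~17% paused time the
    # experiments assume (2 s mean pauses over a Gamma(1, 10 ms) extension)
    p_pause: float = Field(0.001, ge=0, le=1)
    lambda_p: float = Field(2000.0, gt=0, description="pause mean, ms")
    alpha: float = Field(1.0, gt=0)
    beta: float = Field(10.0, gt=0, description="extension Gamma scale, ms")
    n_basepairs: int = Field(10000, ge=1)

    def error_function(self) -> ErrorFunction:
        return ErrorFunction(r_max=self.R_max, b=self.b, c0=self.C_0)

    def kinetic_model(self) -> KineticModel:
        return KineticModel(
            p_pause=self.p_pause,
            pause_mean_ms=self.lambda_p,
            gamma_shape=self.alpha,
            gamma_scale_ms=self.beta,
        )


class AlignmentBlock(_Block):
    k: float = Field(2000.0, gt=0, description="backward search window, ms")
    omega: float = Field(1.0 / 100.0, ge=0, le=1)
    ca_downsample: float = Field(50.0, gt=0, description="L_C, ms/sample")
    dna_downsample: int = Field(100, ge=1, description="L_D, nt/bin")
    extend_search_window: bool = True

    def alignment_config(self) -> AlignmentConfig:
        return AlignmentConfig(
            omega=self.omega,
            k_ms=self.k,
            calcium_downsample_ms=self.ca_downsample,
            dna_downsample=self.dna_downsample,
            extend_search_window=self.extend_search_window,
        )


class NeuralBlock(_Block):
    tuning: Literal["linear", "cosine"] = "linear"
    m: float = 0.05  # spikes/ms per unit stimulus (linear)
    lambda_min: float = 0.0  # spikes/ms (linear)
    lambda_min_hz: float = 10.0  # spikes/s (cosine)
    lambda_max_hz: float = 150.0
    theta: float = math.pi / 4  # true preferred direction (cosine)
    tau: float = Field(200.0, gt=0, description="calcium decay, ms")
    # stimulus design (linear experiments)
    n_blocks: int = Field(400, ge=1)
    block_len_s: float = Field(5.0, gt=0)
    # kinematics design (center-out experiments)
    n_reaches: int = Field(384, ge=1)
    directions: int = Field(8, ge=2)
    reach_dur_ms: float = Field(600.0, gt=0)
    hold_dur_ms: float = Field(400.0, ge=0)
    peak_speed: float = Field(0.5, gt=0)
    speed_lo: float = Field(0.05, ge=0)
    speed_hi: float = Field(0.4, gt=0)

    def tuning_model(self):
        if self.tuning == "linear":
            return LinearTuning(m=self.m, lambda_min=self.lambda_min)
        return CosineTuning(
            theta=self.theta,
            lambda_min_hz=self.lambda_min_hz,
            lambda_max_hz=self.lambda_max_hz,
            ref_speed=self.peak_speed,
        )


class SweepBlock(_Block):
    axis: Literal["record_length", "incorporation_rate", "sensitivity_b", "r_max"] = (
        "record_length"
    )
    grid: list[float] = Field(default_factory=lambda: [1000, 2500, 5000])


class ExperimentConfig(_Block):
    kind: Literal["sweep", "center_out"] = "sweep"
    dnap: DnapBlock = Field(default_factory=DnapBlock)
    alignment: AlignmentBlock = Field(default_factory=AlignmentBlock)
    neural: NeuralBlock = Field(default_factory=NeuralBlock)
    sweep: Optional[SweepBlock] = None
    n_trials: int = Field(20, ge=1)
    seed: int = 0
    full: bool = False  # restore publication-scale trial counts (50/100)

    @model_validator(mode="after")
    def _fill_sweep(self):
        if self.kind == "sweep" and self.sweep is None:
            self.sweep = SweepBlock()
        return self

    @property
    def effective_trials(self) -> int:
        if not self.full:
            return self.n_trials
        return 50 if self.kind == "sweep" else 100

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def parse_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config; empty file -> all defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ExperimentConfig.model_validate(raw or {})


def write_config(path, cfg: ExperimentConfig) -> None:
    """Serialize a config back to YAML (normalized field order)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)


def parameter_evaluation_config(**overrides) -> ExperimentConfig:
    """The parameter-evaluation experiment with its published defaults."""
    return ExperimentConfig.model_validate({"kind": "sweep", **overrides})


def center_out_config(**overrides) -> ExperimentConfig:
    """The synthetic center-out experiment with its published defaults."""
    base = {
        "kind": "center_out",
        "dnap": {"p_pause": 0.001, "n_basepairs": 12000},
        "alignment": {"omega": 1.0 / 240.0, "dna_downsample": 25},
        "neural": {"tuning": "cosine"},
    }
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            base[key] = {**base[key], **val}
        else:
            base[key] = val
    return ExperimentConfig.model_validate(base)
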