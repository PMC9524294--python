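"""Run configuration: every tunable parameter with its documented default.

The configuration is flat (YAML with scalar keys).  Unknown keys are
rejected so typos fail loudly.  ``SimulationConfig`` is the single source
of defaults for the oscillators, the trial engine, the learning rule and
the paradigm generators.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .engine import EngineConfig
from .oscillator import ControlState, coupling_for_frequency

__all__ = ["SimulationConfig", "load_config"]


@dataclass(frozen=True)
class SimulationConfig:
    """All model parameters.

    Oscillators: ``C_theta`` / ``C_gamma`` are radians of phase advance per
    step (0.07 -> 5.57 Hz theta, 0.578 -> 46 Hz gamma at ``dt_ms = 2``);
    ``phase_noise_sd`` desynchronizes untagged columns; ``kappa`` pulls
    column radii back to ``r_target`` after burst kicks.

    Control: the MFC amplitude starts at ``baseline_radius``, grows by
    ``grow_rate`` per pre-response step up to ``amplitude_cap`` when
    synchronization is enabled, and decays by ``decay_rate`` after a
    response; bursts kick tagged columns by ``+-burst_gain``.

    Engine: leaky accumulator dynamics and the calibrated response
    ``threshold`` (see EngineConfig).

    Learning/paradigms: ``beta_learn`` is the learning-variant rate;
    initial weights are U(0, ``init_weight_max_extensive``) for the
    extensive task and U(0, ``init_weight_max``) elsewhere; ``w_word`` >
    ``w_color`` hard-codes the Stroop reading advantage.
    """

    # oscillator
    C_theta: float = 0.07
    C_gamma: float = coupling_for_frequency(46.0, 2.0)
    dt_ms: float = 2.0
    r_target: float = 1.0
    kappa: float = 0.1
    phase_noise_sd: float = 0.1
    # control module
    grow_rate: float = 0.015
    decay_rate: float = 0.05
    baseline_radius: float = 0.01
    amplitude_cap: float = 1.0
    burst_gain: float = 0.5
    # engine
    threshold: float = 250.0
    max_steps: int = 500
    leak: float = 0.1
    input_drive: float = 1.0
    rate_noise_sd: float = 0.01
    backend: str = "numba"
    # learning
    beta_learn: float = 0.4
    # paradigm generators
    init_weight_max_extensive: float = 0.1
    init_weight_max: float = 0.01
    w_word: float = 0.3
    w_color: float = 0.1

    def engine_config(self) -> EngineConfig:
        return EngineConfig(
            threshold=self.threshold,
            max_steps=self.max_steps,
            leak=self.leak,
            input_drive=self.input_drive,
            rate_noise_sd=self.rate_noise_sd,
            C_gamma=self.C_gamma,
            C_theta=self.C_theta,
            dt_ms=self.dt_ms,
            r_target=self.r_target,
            kappa=self.kappa,
            phase_noise_sd=self.phase_noise_sd,
            backend=self.backend,
        )

    def control_state(self, sync_enabled: bool) -> ControlState:
        return ControlState(
            grow_rate=self.grow_rate,
            decay_rate=self.decay_rate,
            baseline_radius=self.baseline_radius,
            amplitude_cap=self.amplitude_cap,
            burst_gain=self.burst_gain,
            sync_enabled=sync_enabled,
        )

    def generator_kwargs(self, paradigm: str) -> dict[str, Any]:
        if paradigm == "extensive":
            return {"init_weight_max": self.init_weight_max_extensive}
        if paradigm == "stroop":
            return {
                "w_word": self.w_word,
                "w_color": self.w_color,
                "init_weight_max": self.init_weight_max,
            }
        if paradigm == "wcst":
            return {"init_weight_max": self.init_weight_max}
        raise ValueError(f"unknown paradigm: {paradigm!r}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path | None) -> SimulationConfig:
    """Load a YAML config file; ``None`` yields the defaults."""
    if path is None:
        return SimulationConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping of parameter keys")
    return SimulationConfig.from_dict(data)
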