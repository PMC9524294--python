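"""Trial execution: phase-gated transmission, LFC tagging, accumulation.

A trial couples three pieces: gamma-oscillating processing columns (one
per input and output unit), the theta-oscillating MFC whose amplitude-
dependent bursts synchronize the columns the LFC has tagged, and a leaky
accumulator per output unit that triggers the response when it crosses a
threshold.

Per timestep: all phases advance; a burst may deliver a common signed kick
to tagged input columns and every output column; active input rates are
clamped to ``input_drive``; each output rate integrates the weighted input
through the phase gate (open only when sender and receiver excitatory
phases are both positive) with leak and additive noise; rates feed the
accumulators; the first accumulator to reach threshold ends the trial.  If
none does within ``max_steps`` the trial is an omission, scored by the
argmax accumulator.  Theta power is the mean squared MFC amplitude over
the pre-response window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernel import get_kernel
from .oscillator import ControlState, coupling_for_frequency
from .paradigms import TrialRecord

__all__ = ["EngineConfig", "TrialResult", "gate", "make_tags", "run_trial"]


@dataclass(frozen=True)
class EngineConfig:
    """Rate/accumulator dynamics plus the shared gamma phase parameters.

    ``threshold`` is a calibrated constant: low enough that association
    weights of ~0.4 drive a response well before the step limit, high
    enough that untrained near-zero weights time out.  ``max_steps = 500``
    is the trial length; at the default 2 ms step a trial spans 1 s.
    """

    threshold: float = 250.0
    max_steps: int = 500
    leak: float = 0.1
    input_drive: float = 1.0
    rate_noise_sd: float = 0.01
    C_gamma: float = coupling_for_frequency(46.0, 2.0)
    C_theta: float = 0.07
    dt_ms: float = 2.0
    r_target: float = 1.0
    kappa: float = 0.1
    phase_noise_sd: float = 0.1
    backend: str = "numba"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not 0.0 <= self.leak <= 1.0:
            raise ValueError("leak must lie in [0, 1]")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated trial."""

    rt: int
    response: int
    omission: bool
    correct: bool
    theta_power: float
    x_in_max: np.ndarray
    x_out_max: np.ndarray
    accumulators: np.ndarray


def gate(E_sender: float, E_receiver: float) -> int:
    """Phase gate: transmission passes only when both phases are positive.

    Time-averaged over a full cycle this makes in-phase sender/receiver
    pairs maximally effective and anti-phase pairs silent.
    """
    return 1 if (E_sender > 0.0 and E_receiver > 0.0) else 0


_TAG_SLICES = {"word": (0, 4), "color": (0, 4), "number": (4, 8), "shape": (8, 12)}


def make_tags(
    paradigm: str,
    trial: TrialRecord,
    sync_enabled: bool,
    n_inputs: int,
) -> np.ndarray:
    """Binary LFC tag vector: which input columns receive the bursts.

    extensive: the 4 input units of the current block's stimulus set;
    stroop: the 4 units of the relevant dimension (words 0-3 / colors 4-7),
    selected by the active task unit; wcst: the 4 units of the relevant
    dimension (hard-coded schedule).  All zeros when synchronization is
    disabled.  Output columns are always burst recipients and need no tag.
    """
    tags = np.zeros(n_inputs, dtype=np.uint8)
    if not sync_enabled:
        return tags
    if paradigm == "extensive":
        tags[list(trial.labels["block_units"])] = 1
    elif paradigm == "stroop":
        lo = 0 if trial.labels["relevant_dimension"] == "word" else 4
        tags[lo : lo + 4] = 1
    elif paradigm == "wcst":
        dim = trial.labels["relevant_dimension"]
        lo = {"color": 0, "number": 4, "shape": 8}[dim]
        tags[lo : lo + 4] = 1
    else:
        raise ValueError(f"unknown paradigm: {paradigm!r}")
    return tags


def run_trial(
    W: np.ndarray,
    trial: TrialRecord,
    tags: np.ndarray,
    ctrl: ControlState,
    cfg: EngineConfig,
    rng: np.random.Generator,
) -> TrialResult:
    """Simulate one trial from stimulus onset to response or timeout."""
    W = np.ascontiguousarray(W, dtype=np.float64)
    if not np.isfinite(W).all():
        raise ValueError("weight matrix must be finite")
    n_in, n_out = W.shape
    active = np.asarray(trial.active_inputs, dtype=np.int64)
    if active.size == 0 or active.min() < 0 or active.max() >= n_in:
        raise ValueError("active input indices out of range for the weight matrix")
    tags = np.ascontiguousarray(tags, dtype=np.uint8)
    if tags.shape != (n_in,):
        raise ValueError("tag vector length must equal the number of inputs")

    n_cols = n_in + n_out
    T = cfg.max_steps
    # Pre-draw every variate the loop can consume (fixed count per trial, so
    # variant switches never desynchronize the stream).
    init_angles = rng.uniform(0.0, 2.0 * np.pi, size=n_cols + 1)
    jitter = cfg.phase_noise_sd * rng.standard_normal((T, n_cols))
    angles = cfg.C_gamma + jitter
    burst_u = rng.random(T)
    burst_sign = np.where(rng.random(T) < 0.5, 1.0, -1.0)
    rate_noise = rng.standard_normal((T, n_out))

    theta_angle = cfg.C_theta
    kernel = get_kernel(cfg.backend)
    rt, response, omission, theta_power, x_out_max, acc = kernel(
        W,
        active,
        tags,
        ctrl.sync_enabled,
        cfg.threshold,
        T,
        cfg.leak,
        cfg.input_drive,
        cfg.rate_noise_sd,
        cfg.kappa,
        cfg.r_target,
        ctrl.grow_rate,
        ctrl.baseline_radius,
        ctrl.amplitude_cap,
        ctrl.burst_gain,
        np.cos(theta_angle),
        np.sin(theta_angle),
        init_angles,
        np.cos(angles),
        np.sin(angles),
        burst_u,
        burst_sign,
        rate_noise,
    )
    x_in_max = np.zeros(n_in)
    x_in_max[active] = cfg.input_drive
    return TrialResult(
        rt=int(rt),
        response=int(response),
        omission=bool(omission),
        correct=int(response) == trial.target_output,
        theta_power=float(theta_power),
        x_in_max=x_in_max,
        x_out_max=np.clip(x_out_max, 0.0, 1.0),
        accumulators=np.asarray(acc),
    )
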