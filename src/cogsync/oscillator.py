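"""Phase dynamics of cortical columns and the medial-frontal (MFC) theta unit.

Every oscillating unit in the model is a *cortical column*: one rate-code
neuron plus an excitatory/inhibitory pair of phase-code neurons ``(E, I)``.
The undriven phase update is a pure rotation of ``(E, I)`` by a coupling
angle ``C`` per timestep, so the emergent oscillation frequency is

    f = C / (2 * pi * dt_seconds)

which, at the default 2 ms timestep, maps C = 0.05, 0.07, 0.10 to 3.97,
5.57 and 8 Hz (the theta range probed for the MFC) and C ~= 0.578 to the
46 Hz gamma rhythm shared by all processing columns.

The MFC unit carries a trial-varying amplitude: while no response has been
given its radius grows geometrically toward a cap (more synchronization
events late in a trial); after a response it relaxes back to a near-zero
baseline.  Bursts are emitted stochastically on the positive half-cycle of
the MFC excitatory phase with probability equal to the (clamped) phase
value; each burst is a signed kick shared by all recipient columns, the
common input that produces noise-induced synchronization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhaseState",
    "OscillatorParams",
    "ControlState",
    "step_phase",
    "dominant_frequency",
    "mfc_step",
    "sample_burst",
    "coupling_for_frequency",
    "frequency_for_coupling",
]


@dataclass(frozen=True)
class PhaseState:
    """Excitatory/inhibitory phase pair of one cortical column."""

    E: float
    I: float

    @property
    def radius(self) -> float:
        return math.hypot(self.E, self.I)

    @property
    def angle(self) -> float:
        return math.atan2(self.I, self.E)


@dataclass(frozen=True)
class OscillatorParams:
    """Parameters of the per-step phase update.

    Parameters
    ----------
    C : float
        Coupling parameter: radians of phase advance per timestep.
    dt_ms : float
        Timestep duration in milliseconds (default 2 ms).
    r_target : float
        Radius toward which the phase pair is attracted (0 disables any
        preferred amplitude together with ``kappa = 0``).
    kappa : float
        Radius-attraction strength per step, in [0, 1].  The attraction is
        multiplicative, ``r' = r * (1 + kappa * (r_target - r))``, so the
        origin remains a fixed point of the undriven update.
    phase_noise_sd : float
        Standard deviation (radians) of independent per-step jitter added
        to the rotation angle.
    """

    C: float
    dt_ms: float = 2.0
    r_target: float = 1.0
    kappa: float = 0.0
    phase_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.C, self.dt_ms, self.r_target, self.kappa, self.phase_noise_sd)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("oscillator parameters must be finite")
        if self.C <= 0:
            raise ValueError("coupling parameter C must be > 0")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")
        if self.r_target < 0:
            raise ValueError("r_target must be >= 0")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")

    @property
    def frequency_hz(self) -> float:
        """Emergent oscillation frequency implied by the rotation angle."""
        return frequency_for_coupling(self.C, self.dt_ms)


def frequency_for_coupling(C: float, dt_ms: float = 2.0) -> float:
    """Frequency (Hz) of a column rotating by ``C`` radians per ``dt_ms`` step."""
    return C / (2.0 * math.pi * dt_ms * 1e-3)


def coupling_for_frequency(freq_hz: float, dt_ms: float = 2.0) -> float:
    """Coupling parameter producing ``freq_hz`` at timestep ``dt_ms``."""
    return 2.0 * math.pi * freq_hz * dt_ms * 1e-3


def step_phase(
    state: PhaseState,
    params: OscillatorParams,
    kick: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PhaseState:
    """Advance a phase pair one timestep.

    Rotates ``(E, I)`` by ``C`` (plus optional angular jitter), applies the
    multiplicative radius attraction toward ``r_target``, then adds ``kick``
    to the excitatory phase.  With ``kappa = 0``, no noise and no kick the
    update is an exact rotation and conserves the radius.
    """
    if not (np.isfinite(state.E) and np.isfinite(state.I) and np.isfinite(kick)):
        raise ValueError("phase state and kick must be finite")
    angle = params.C
    if params.phase_noise_sd > 0.0:
        if rng is None:
            raise ValueError("phase_noise_sd > 0 requires an rng")
        angle += params.phase_noise_sd * rng.standard_normal()
    ca, sa = math.cos(angle), math.sin(angle)
    e = ca * state.E - sa * state.I
    i = sa * state.E + ca * state.I
    if params.kappa > 0.0:
        r = math.hypot(e, i)
        factor = 1.0 + params.kappa * (params.r_target - r)
        if factor < 0.0:
            factor = 0.0
        e *= factor
        i *= factor
    return PhaseState(E=e + kick, I=i)


def dominant_frequency(
    trace: np.ndarray,
    dt_ms: float,
    method: str = "zero_crossing",
) -> float:
    """Dominant oscillation frequency (Hz) of an excitatory-phase trace.

    ``method="zero_crossing"`` uses the mean interval between positive-going
    zero crossings; ``method="spectral"`` uses the periodogram peak.  On a
    clean sinusoid the two agree to well within 2%.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 8:
        raise ValueError("trace must be a 1-d sequence of at least 8 samples")
    if np.ptp(trace) == 0.0:
        raise ValueError("constant trace has no defined dominant frequency")
    dt_s = dt_ms * 1e-3
    if method == "zero_crossing":
        sign = trace > 0.0
        up = np.flatnonzero(~sign[:-1] & sign[1:])
        if up.size < 2:
            raise ValueError("trace too short: fewer than two zero-crossing cycles")
        mean_period = (up[-1] - up[0]) / (up.size - 1) * dt_s
        return 1.0 / mean_period
    if method == "spectral":
        from scipy.signal import periodogram

        freqs, power = periodogram(trace - trace.mean(), fs=1.0 / dt_s)
        return float(freqs[np.argmax(power)])
    raise ValueError(f"unknown method: {method!r}")


@dataclass(frozen=True)
class ControlState:
    """MFC theta oscillator with trial-varying amplitude, plus burst settings.

    ``mfc_phase`` always has radius ``mfc_radius``.  While ``sync_enabled``
    and no response has been given, the radius grows by a factor
    ``1 + grow_rate`` per step up to ``amplitude_cap``; after the response it
    decays toward ``baseline_radius`` by a factor ``1 - decay_rate``.  With
    ``sync_enabled = False`` the radius is pinned at ``baseline_radius``, so
    burst emission stays vanishingly rare.
    """

    mfc_phase: PhaseState = field(default_factory=lambda: PhaseState(0.01, 0.0))
    mfc_radius: float = 0.01
    grow_rate: float = 0.01
    decay_rate: float = 0.05
    baseline_radius: float = 0.01
    amplitude_cap: float = 1.0
    burst_gain: float = 0.5
    sync_enabled: bool = True

    def __post_init__(self) -> None:
        vals = (
            self.mfc_phase.E,
            self.mfc_phase.I,
            self.mfc_radius,
            self.grow_rate,
            self.decay_rate,
            self.baseline_radius,
            self.amplitude_cap,
            self.burst_gain,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("control-state fields must be finite")
        if self.baseline_radius < 0 or self.amplitude_cap < self.baseline_radius:
            raise ValueError("need 0 <= baseline_radius <= amplitude_cap")
        if not 0.0 <= self.decay_rate <= 1.0:
            raise ValueError("decay_rate must lie in [0, 1]")


def mfc_step(
    ctrl: ControlState,
    params: OscillatorParams,
    responded: bool = False,
) -> ControlState:
    """Advance the MFC unit one timestep at its theta coupling.

    Pre-response (and with synchronization enabled) the amplitude grows
    geometrically toward the cap; post-response it relaxes toward the
    baseline.  The phase pair is rescaled to the updated radius.
    """
    phase = step_phase(ctrl.mfc_phase, params)
    radius = ctrl.mfc_radius
    if responded:
        radius = ctrl.baseline_radius + (radius - ctrl.baseline_radius) * (
            1.0 - ctrl.decay_rate
        )
    elif ctrl.sync_enabled:
        radius = min(radius * (1.0 + ctrl.grow_rate), ctrl.amplitude_cap)
    r_now = phase.radius
    scale = radius / r_now if r_now > 0.0 else 0.0
    phase = PhaseState(E=phase.E * scale, I=phase.I * scale)
    return replace(ctrl, mfc_phase=phase, mfc_radius=radius)


def sample_burst(
    ctrl: ControlState, rng: np.random.Generator
) -> tuple[bool, float]:
    """Draw one burst event from the MFC.

    The emission probability is the positive part of the MFC excitatory
    phase, clamped to [0, 1] (bursts are theta-locked: silent on the
    negative half-cycle, near-certain at peak amplitude).  The magnitude is
    ``burst_gain`` with a random sign shared by every recipient of the
    event.  The uniform and sign variates are consumed on every call so
    that burst emission never desynchronizes a seeded random stream.
    """
    p = min(max(ctrl.mfc_phase.E, 0.0), 1.0)
    u = rng.random()
    sign = 1.0 if rng.random() < 0.5 else -1.0
    if u < p:
        return True, sign * ctrl.burst_gain
    return False, 0.0
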