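"""Single-trial simulation loop, written once and optionally numba-compiled.

All randomness is drawn *outside* the loop with a numpy Generator and
passed in as arrays, so the compiled and interpreted paths consume exactly
the same variates and produce identical trajectories, and seeds fully
determine every trial.
"""

from __future__ import annotations

import math

import numpy as np

try:  # compiled lazily at first use; falls back to the interpreted twin
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


def _simulate_trial(
    W,  # (n_in, n_out) float64
    active,  # (k,) int64 indices of driven inputs
    tags,  # (n_in,) uint8 LFC tags
    sync_enabled,  # bool
    threshold,
    max_steps,
    leak,
    input_drive,
    rate_noise_sd,
    kappa,
    r_target,
    grow_rate,
    baseline_radius,
    amplitude_cap,
    burst_gain,
    cos_theta,
    sin_theta,  # scalar MFC rotation per step
    init_angles,  # (n_cols + 1,) initial phase angles, last one is the MFC
    cos_rot,
    sin_rot,  # (max_steps, n_cols) per-step column rotation incl. jitter
    burst_u,  # (max_steps,) uniforms for burst emission
    burst_sign,  # (max_steps,) +-1.0 signs
    rate_noise,  # (max_steps, n_out) standard normals
):
    n_in, n_out = W.shape
    n_cols = n_in + n_out

    E = np.empty(n_cols)
    I = np.empty(n_cols)
    for j in range(n_cols):
        E[j] = r_target * math.cos(init_angles[j])
        I[j] = r_target * math.sin(init_angles[j])
    mfc_E = baseline_radius * math.cos(init_angles[n_cols])
    mfc_I = baseline_radius * math.sin(init_angles[n_cols])
    mfc_r = baseline_radius

    x_out = np.zeros(n_out)
    acc = np.zeros(n_out)
    x_out_max = np.zeros(n_out)
    theta_sq = 0.0
    rt = max_steps
    omission = True

    for t in range(max_steps):
        # (1) advance all column phases (gamma) and the MFC (theta)
        for j in range(n_cols):
            ca = cos_rot[t, j]
            sa = sin_rot[t, j]
            e = ca * E[j] - sa * I[j]
            i = sa * E[j] + ca * I[j]
            if kappa > 0.0:
                r = math.sqrt(e * e + i * i)
                f = 1.0 + kappa * (r_target - r)
                if f < 0.0:
                    f = 0.0
                e *= f
                i *= f
            E[j] = e
            I[j] = i
        e = cos_theta * mfc_E - sin_theta * mfc_I
        i = sin_theta * mfc_E + cos_theta * mfc_I
        if sync_enabled:
            new_r = mfc_r * (1.0 + grow_rate)
            if new_r > amplitude_cap:
                new_r = amplitude_cap
            if mfc_r > 0.0:
                s = new_r / mfc_r
                e *= s
                i *= s
            mfc_r = new_r
        mfc_E = e
        mfc_I = i
        theta_sq += mfc_r * mfc_r

        # (2) theta-locked burst: common kick to tagged inputs + all outputs
        p = mfc_E
        if p < 0.0:
            p = 0.0
        elif p > 1.0:
            p = 1.0
        if burst_u[t] < p:
            kick = burst_sign[t] * burst_gain
            for j in range(n_in):
                if tags[j] != 0:
                    E[j] += kick
            for o in range(n_out):
                E[n_in + o] += kick

        # (3)-(4) clamp input rates, update leaky output rates through the
        # phase gate (transmission only when sender and receiver E > 0)
        for o in range(n_out):
            drive = 0.0
            if E[n_in + o] > 0.0:
                for a in range(active.shape[0]):
                    ia = active[a]
                    if E[ia] > 0.0:
                        drive += W[ia, o] * input_drive
            xo = (1.0 - leak) * x_out[o] + drive + rate_noise_sd * rate_noise[t, o]
            if xo < 0.0:
                xo = 0.0
            x_out[o] = xo
            if xo > x_out_max[o]:
                x_out_max[o] = xo
            acc[o] += xo

        # (5)-(6) accumulate-to-threshold stopping rule
        amax = acc[0]
        for o in range(1, n_out):
            if acc[o] > amax:
                amax = acc[o]
        if amax >= threshold:
            rt = t + 1
            omission = False
            break

    response = 0
    best = acc[0]
    for o in range(1, n_out):
        if acc[o] > best:  # strict: ties resolve to the lowest index
            best = acc[o]
            response = o
    theta_power = theta_sq / rt
    return rt, response, omission, theta_power, x_out_max, acc


_compiled = None


def get_kernel(backend: str = "numba"):
    """Return the trial loop for ``backend`` in {"numba", "python"}."""
    global _compiled
    if backend == "python":
        return _simulate_trial
    if backend != "numba":
        raise ValueError(f"unknown backend: {backend!r}")
    if njit is None:  # pragma: no cover
        return _simulate_trial
    if _compiled is None:
        _compiled = njit(cache=False, fastmath=False)(_simulate_trial)
    return _compiled
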