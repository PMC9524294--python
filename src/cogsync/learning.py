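"""Trial-level Rescorla-Wagner weight update (modified form).

The association weights between input and output columns change once per
trial, after feedback, according to

    dW[i, o] = beta * (Target[o] - Xo[o]) * Xi[i] * Xo[o]

where ``Xi`` is the maximal rate activation of input unit ``i`` over the
trial, ``Xo`` the maximal rate activation of output unit ``o`` clipped to
[0, 1], and ``Target`` the one-hot desired response.  The trailing ``Xo``
factor (absent from the classic delta rule) restricts learning to unit
pairs that were simultaneously active within the trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RWParams", "rw_update"]


@dataclass(frozen=True)
class RWParams:
    """Learning rate and one-hot target for a single trial.

    ``beta = 0`` yields the non-learning model variants; learning variants
    use ``beta = 0.4``.
    """

    beta: float
    target: np.ndarray

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        target = np.asarray(self.target)
        if not np.array_equal(np.sort(target), np.r_[np.zeros(target.size - 1), 1.0]):
            raise ValueError("target must be one-hot over the outputs")


def rw_update(
    W: np.ndarray,
    x_in_max: np.ndarray,
    x_out_max: np.ndarray,
    params: RWParams,
) -> np.ndarray:
    """Return the updated weight matrix (the input is left untouched).

    Weights are neither clipped nor bounded; the rule's own
    ``(Target - Xo) * Xo`` factor drives each active pathway toward an
    output activation equal to its target and then stops.
    """
    W = np.asarray(W, dtype=float)
    x_in = np.asarray(x_in_max, dtype=float)
    x_out = np.asarray(x_out_max, dtype=float)
    target = np.asarray(params.target, dtype=float)
    if W.shape != (x_in.size, x_out.size) or target.size != x_out.size:
        raise ValueError("shape mismatch between weights, activations and target")
    if not (np.isfinite(x_in).all() and np.isfinite(x_out).all()):
        raise ValueError("activations must be finite")
    if (x_out < 0).any() or (x_out > 1).any():
        raise ValueError("x_out_max must lie in [0, 1]")
    delta = params.beta * np.outer(x_in, (target - x_out) * x_out)
    return W + delta
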