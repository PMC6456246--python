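"""Deterministic synchronous dynamics of the sigmoid network map.

Every neuron has zero bias and the logistic output function.  One time step
maps the network state ``y(t-1)`` in ``(0, 1)^n`` to

    z_i(t) = sum_j W[i, j] * y_j(t - 1)
    y_i(t) = 1 / (1 + exp(-z_i(t)))

with all neurons updated simultaneously, so the network is a deterministic
autonomous map on ``(0, 1)^n``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.special import expit

__all__ = [
    "sigmoid",
    "update_state",
    "simulate",
    "random_initial_state",
    "network_map",
]

# Smallest open-interval clamp: expit underflows to exactly 0.0 for
# z < ~-745 and rounds to exactly 1.0 for z > ~37; both would leave the
# open interval (0, 1), so outputs are clamped to the nearest interior
# representable values.
_LO = np.nextafter(0.0, 1.0)
_HI = np.nextafter(1.0, 0.0)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function, clamped into the open (0, 1)."""
    return np.clip(expit(z), _LO, _HI)


def update_state(W: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One synchronous update; the input state is left unmodified."""
    W = np.asarray(W)
    y = np.asarray(y, dtype=float)
    if y.shape != (W.shape[0],):
        raise ValueError(
            f"state length {y.shape} does not match matrix dimension {W.shape[0]}")
    z = W @ y
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite input sum encountered")
    return sigmoid(z)


def simulate(W: np.ndarray, y0: np.ndarray, steps: int,
             observer: Callable[[int, np.ndarray], None] | None = None,
             keep_states: bool = True) -> np.ndarray:
    """Iterate the network map for ``steps`` updates.

    Returns the trajectory as a ``(steps + 1, n)`` array whose first row is
    ``y0``.  With ``keep_states=False`` only the final state is returned
    (shape ``(n,)``); combined with ``observer(t, y)``, called after every
    update, long runs need not retain the full history.

    Raises ``FloatingPointError`` naming the step at which a non-finite
    state would be produced.
    """
    if steps < 0:
        raise ValueError(f"steps must be >= 0, got {steps}")
    W = np.asarray(W)
    y = np.asarray(y0, dtype=float).copy()
    out = np.empty((steps + 1, W.shape[0])) if keep_states else None
    if keep_states:
        out[0] = y
    for t in range(1, steps + 1):
        try:
            y = update_state(W, y)
        except FloatingPointError as exc:
            raise FloatingPointError(f"{exc} at step {t}") from None
        if keep_states:
            out[t] = y
        if observer is not None:
            observer(t, y)
    return out if keep_states else y


def random_initial_state(n: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. Uniform(0, 1) initial state of length ``n``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return rng.uniform(size=n)


def network_map(W: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """The update map ``y -> sigmoid(W @ y)`` as a plain callable.

    Useful wherever a generic iterated map is expected (e.g. the Lyapunov
    estimator, which is also exercised on scalar textbook maps).
    """
    W = np.asarray(W)
    return lambda y: sigmoid(W @ y)
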