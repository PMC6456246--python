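"""Per-network dynamical measures.

Three quantities characterize a free-running network:

* the maximum Lyapunov exponent ``lambda``, estimated by the Benettin
  two-trajectory method (positive => chaos);
* the attractor period ``T``, the first recurrence time of the (quantized)
  network state — ``T = 1`` is a stationary fixed point, and a run with no
  recurrence within the horizon is reported censored at ``t_max``;
* ``rho_rms``, the root mean square of all pairwise (and self) Pearson
  correlations between neuron time series over a post-transient window,
  with constant series assigned correlation 1.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np

from .dynamics import network_map, simulate, update_state

__all__ = [
    "LyapunovSettings",
    "DynamicsSummary",
    "max_lyapunov",
    "network_lyapunov",
    "fraction_positive",
    "detect_period",
    "brute_force_period",
    "average_period",
    "PeriodAverage",
    "pearson_correlation",
    "correlation_rms",
    "summarize_network",
]

#: below this standard deviation (in state units) a series counts as constant
SIGMA_FLOOR = 1e-12

#: default state-quantization step for period hashing
QUANTUM = 1e-12


@dataclasses.dataclass(frozen=True)
class LyapunovSettings:
    """Parameters of the Benettin estimator.

    ``eps`` is the perturbation magnitude, kept far above float quantization
    noise (~1e-16) and far below the O(1) state scale; ``transient`` steps
    are discarded before averaging the per-step log stretch factors over
    ``horizon`` steps; ``floor`` is the value reported when the separation
    collapses to exactly zero (infinitely contracting, e.g. a constant map).
    """

    eps: float = 1e-8
    transient: int = 1000
    horizon: int = 10_000
    floor: float = -50.0

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")
        if self.transient < 0:
            raise ValueError(f"transient must be >= 0, got {self.transient}")


@dataclasses.dataclass(frozen=True)
class DynamicsSummary:
    """Measured quantities of one network run."""

    lyapunov: float
    period: int
    censored: bool
    rho_rms: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def max_lyapunov(step_fn: Callable[[np.ndarray], np.ndarray],
                 y0: np.ndarray | float,
                 settings: LyapunovSettings = LyapunovSettings()) -> float:
    """Benettin estimate of the maximum Lyapunov exponent of an iterated map.

    A reference trajectory and a companion displaced by ``eps`` (along the
    first coordinate initially) are co-evolved; after every step the log of
    the separation growth ``ln(|y* - y| / eps)`` is recorded and the
    companion is pulled back to distance ``eps`` along the current
    separation direction.  The estimate is the mean log stretch over
    ``horizon`` steps after a ``transient``; if the separation ever
    underflows to exactly zero the map is contracting below resolution and
    ``settings.floor`` is returned.

    ``step_fn`` may be any deterministic map of a real vector (or scalar),
    which allows validating the estimator on textbook maps such as the
    logistic map.
    """
    y = np.atleast_1d(np.asarray(y0, dtype=float)).copy()
    for _ in range(settings.transient):
        y = step_fn(y)
    yp = y.copy()
    yp[0] += settings.eps

    eps = settings.eps
    total = 0.0
    for _ in range(settings.horizon):
        y = step_fn(y)
        yp = step_fn(yp)
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yp))):
            raise FloatingPointError("non-finite trajectory in Lyapunov estimate")
        d = yp - y
        sep = float(np.linalg.norm(d))
        if sep == 0.0:
            return settings.floor
        total += math.log(sep / eps)
        yp = y + d * (eps / sep)
    return max(total / settings.horizon, settings.floor)


def network_lyapunov(W: np.ndarray, y0: np.ndarray,
                     settings: LyapunovSettings = LyapunovSettings()) -> float:
    """Maximum Lyapunov exponent of the sigmoid network map defined by ``W``."""
    return max_lyapunov(network_map(W), y0, settings)


def fraction_positive(lambdas: Sequence[float]) -> float:
    """Fraction of strictly positive values — the chaotic-phase order parameter."""
    lam = np.asarray(list(lambdas), dtype=float)
    if lam.size == 0:
        raise ValueError("need at least one Lyapunov exponent")
    return float((lam > 0).sum() / lam.size)


def _qkey(y: np.ndarray, quantum: float) -> bytes:
    return np.rint(y / quantum).astype(np.int64).tobytes()


def detect_period(W: np.ndarray, y0: np.ndarray, t_max: int,
                  quantum: float = QUANTUM) -> tuple[int, bool]:
    """First recurrence time of the quantized network state.

    Simulates forward, hashing each state with every component rounded to
    the nearest multiple of ``quantum`` (bare float states never repeat for
    attractors approached asymptotically).  On a hash hit at times
    ``t0 < t`` the putative cycle of length ``T = t - t0`` is verified by
    re-simulating one full period from the current state and requiring
    quantized equality with the recorded trajectory at every step, which
    eliminates hash/quantization coincidences.

    Returns ``(T, False)`` on a confirmed repeat (``T = 1`` is a fixed
    point) or ``(t_max, True)`` — censored — if no repeat occurs.
    """
    if t_max < 1:
        raise ValueError(f"t_max must be >= 1, got {t_max}")
    if quantum <= 0:
        raise ValueError(f"quantum must be > 0, got {quantum}")
    W = np.asarray(W)
    y = np.asarray(y0, dtype=float).copy()

    k = _qkey(y, quantum)
    keys = [k]
    seen: dict[bytes, list[int]] = {k: [0]}
    for t in range(1, t_max + 1):
        y = update_state(W, y)
        k = _qkey(y, quantum)
        times = seen.get(k)
        if times is not None:
            # earliest occurrence first; a quantization coincidence on the
            # transient fails verification and the next pass is tried
            for t0 in times:
                if _verify_cycle(W, y, k, keys, t0, t - t0, quantum):
                    return t - t0, False
            times.append(t)
        else:
            seen[k] = [t]
        keys.append(k)
    return t_max, True


def _verify_cycle(W: np.ndarray, y: np.ndarray, k: bytes, keys: list[bytes],
                  t0: int, T: int, quantum: float) -> bool:
    """Re-simulate one putative period, checking quantized equality stepwise."""
    yv = y.copy()
    for s in range(1, T + 1):
        yv = update_state(W, yv)
        expected = k if t0 + s == len(keys) else keys[t0 + s]
        if _qkey(yv, quantum) != expected:
            return False
    return True


def brute_force_period(W: np.ndarray, y0: np.ndarray, t_max: int,
                       quantum: float = QUANTUM) -> tuple[int, bool]:
    """All-pairs quantized-state comparison; oracle for :func:`detect_period`.

    Quadratic in ``t_max`` — only sensible for tiny networks and horizons.
    """
    W = np.asarray(W)
    traj = simulate(W, np.asarray(y0, dtype=float), t_max)
    q = np.rint(traj / quantum).astype(np.int64)
    for t in range(1, t_max + 1):
        for t0 in range(t):
            if not np.array_equal(q[t], q[t0]):
                continue
            T = t - t0
            # confirm one full putative period by re-simulation
            yv = traj[t].copy()
            ok = True
            for s in range(1, T + 1):
                yv = update_state(W, yv)
                if not np.array_equal(np.rint(yv / quantum).astype(np.int64),
                                      q[t0 + s]):
                    ok = False
                    break
            if ok:
                return T, False
    return t_max, True


class PeriodAverage(NamedTuple):
    t_av: float
    censored_fraction: float


def average_period(results: Iterable[tuple[int, bool]]) -> PeriodAverage:
    """Ensemble mean period, censored runs contributing their horizon ``t_max``.

    Chaotic members therefore inflate the mean — the intended signature of a
    chaotic cell is a diverging ``t_av`` — and the censored fraction is
    reported alongside so the two effects can be separated.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one period measurement")
    periods = np.array([T for T, _ in results], dtype=float)
    cens = np.array([c for _, c in results], dtype=bool)
    return PeriodAverage(float(periods.mean()), float(cens.mean()))


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Population-moment Pearson coefficient with the degenerate-series rule.

    If either series has (numerically) zero standard deviation the
    correlation is defined as exactly 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    sa, sb = a.std(), b.std()
    if sa < SIGMA_FLOOR or sb < SIGMA_FLOOR:
        return 1.0
    r = float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))
    return min(1.0, max(-1.0, r))


def correlation_rms(window: np.ndarray) -> float:
    """RMS of all ordered-pair Pearson correlations over a trajectory window.

    ``window`` has shape ``(t, n)`` with ``t >= 2``.  All ``n^2`` ordered
    pairs enter, the diagonal included, so the value lies in ``(0, 1]``:
    independent series give about ``1/sqrt(n)`` (diagonal only), a constant
    (fixed-point) window gives exactly 1 via the degenerate rule.
    """
    X = np.asarray(window, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("window must contain at least 2 time steps")
    sd = X.std(axis=0)
    Z = X - X.mean(axis=0)
    cov = (Z.T @ Z) / X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = cov / np.outer(sd, sd)
    degenerate = sd < SIGMA_FLOOR
    rho[degenerate, :] = 1.0
    rho[:, degenerate] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.clip(rho, -1.0, 1.0, out=rho)
    return float(np.sqrt(np.mean(rho ** 2)))


def summarize_network(W: np.ndarray, y0: np.ndarray, t_max: int,
                      lyapunov: LyapunovSettings = LyapunovSettings(),
                      corr_window: int = 10_000, corr_transient: int = 1000,
                      quantum: float = QUANTUM,
                      measures: tuple[str, ...] = ("lyapunov", "period",
                                                   "correlation"),
                      ) -> DynamicsSummary:
    """All three measures for one network from one initial state.

    ``measures`` restricts which quantities are computed (the others are
    reported as NaN / censored-at-zero placeholders); useful in sweeps that
    only need a subset.
    """
    lam = float("nan")
    period, censored = 0, False
    rho = float("nan")
    if "lyapunov" in measures:
        lam = network_lyapunov(W, y0, lyapunov)
    if "period" in measures:
        period, censored = detect_period(W, y0, t_max, quantum)
    if "correlation" in measures:
        traj = simulate(W, y0, corr_transient + corr_window)
        rho = correlation_rms(traj[corr_transient + 1:])
    return DynamicsSummary(lyapunov=lam, period=period,
                           censored=censored, rho_rms=rho)
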