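"""Random weight matrices with prescribed density, balance and symmetry.

A network of ``n`` neurons is described by an ``n x n`` real matrix ``W``
where ``W[i, j]`` is the strength of the connection from neuron ``j`` to
neuron ``i``.  Self-connections are forbidden (zero diagonal), leaving
``n (n - 1)`` admissible entries.  Writing ``m`` for the number of nonzero
entries, ``m+`` / ``m-`` for the positive / negative counts and ``m_s`` for
the number of nonzero entries whose mirror image is exactly equal
(``W[j, i] == W[i, j]``), the three statistics controlled here are

* density   ``d = m / (n (n - 1))``          in [0, 1],
* balance   ``b = (m+ - m-) / m``            in [-1, 1],
* symmetry  ``s = m_s / m``                  in [0, 1].

Nonzero magnitudes are log-normal, mimicking the heavy-tailed synaptic
strength distributions reported for cortex; a fraction ``(1 - b)/2`` of them
is negated to set the excitation/inhibition balance.  Symmetric networks are
built by mirroring the upper triangle and then randomly swapping
lower-triangle cells until the prescribed symmetry is reached.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

__all__ = [
    "WeightConfig",
    "GenerationError",
    "ConvergenceError",
    "sample_magnitudes",
    "generate_weight_matrix",
    "connection_counts",
    "measure_density",
    "measure_balance",
    "measure_symmetry",
    "desymmetrize_by_swaps",
    "save_matrix",
    "load_matrix",
]


class GenerationError(ValueError):
    """Requested statistics cannot be realized (e.g. the density rounds to zero)."""


class ConvergenceError(RuntimeError):
    """Swap desymmetrization failed to reach the target within ``max_iter``."""

    def __init__(self, message: str, best_symmetry: float):
        super().__init__(message)
        self.best_symmetry = best_symmetry


@dataclasses.dataclass(frozen=True)
class WeightConfig:
    """Prescription for one random network.

    Parameters
    ----------
    n : int
        Number of neurons, at least 2 (with the diagonal excluded, ``n = 1``
        admits no connections at all).
    density, balance, symmetry : float
        Target statistics ``d`` in [0, 1], ``b`` in [-1, 1], ``s`` in [0, 1].
    loc, scale : float
        Location mu and scale sigma of the log-normal magnitude law, i.e.
        ``ln |w| ~ Normal(mu, sigma)``.  Defaults mu=0, sigma=1.
    seed : int
        Master seed; every random sub-step (support, magnitudes, signs,
        swaps) draws from the single stream it defines, in that fixed order.
    """

    n: int
    density: float
    balance: float
    symmetry: float = 0.0
    loc: float = 0.0
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"density must lie in [0, 1], got {self.density}")
        if not -1.0 <= self.balance <= 1.0:
            raise ValueError(f"balance must lie in [-1, 1], got {self.balance}")
        if not 0.0 <= self.symmetry <= 1.0:
            raise ValueError(f"symmetry must lie in [0, 1], got {self.symmetry}")
        if self.scale < 0:
            raise ValueError(f"scale must be >= 0, got {self.scale}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def sample_magnitudes(count: int, loc: float, scale: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw ``count`` strictly positive log-normal weight magnitudes.

    ``ln`` of the returned values is Normal(loc, scale); ``scale = 0``
    degenerates to the constant ``exp(loc)``.
    """
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    if scale < 0:
        raise ValueError(f"scale must be >= 0, got {scale}")
    return rng.lognormal(mean=loc, sigma=scale, size=count)


def connection_counts(W: np.ndarray) -> tuple[int, int, int, int]:
    """Return ``(m, m_plus, m_minus, m_s)`` for a weight matrix.

    ``m_s`` counts nonzero entries ``W[i, j]`` with ``W[j, i]`` *exactly*
    equal (bitwise float equality); both members of a matched pair count.
    """
    W = np.asarray(W)
    nz = W != 0
    m = int(nz.sum())
    m_plus = int((W > 0).sum())
    m_s = int((nz & (W == W.T)).sum())
    return m, m_plus, m - m_plus, m_s


def measure_density(W: np.ndarray) -> float:
    """Fraction of realized connections, ``m / (n (n - 1))``."""
    W = np.asarray(W)
    n = W.shape[0]
    m, _, _, _ = connection_counts(W)
    return m / (n * (n - 1))


def measure_balance(W: np.ndarray) -> float:
    """Signed excess of excitation, ``(m+ - m-) / m``.  Undefined for m = 0."""
    m, m_plus, m_minus, _ = connection_counts(W)
    if m == 0:
        raise ValueError("balance is undefined for a matrix with no connections")
    return (m_plus - m_minus) / m


def measure_symmetry(W: np.ndarray) -> float:
    """Fraction of nonzero entries with an exactly equal mirror, ``m_s / m``."""
    m, _, _, m_s = connection_counts(W)
    if m == 0:
        raise ValueError("symmetry is undefined for a matrix with no connections")
    return m_s / m


def _check_zero_diagonal(W: np.ndarray) -> None:
    if np.any(np.diagonal(W) != 0):
        raise ValueError("weight matrix must have a zero diagonal")


def generate_weight_matrix(config: WeightConfig) -> np.ndarray:
    """Generate a random weight matrix realizing ``config``.

    Construction, all draws from one generator seeded with ``config.seed``:

    1. target counts: ``m = round(d n(n-1))`` (asymmetric path) or
       ``m_upper = round(d n(n-1)/2)`` on the upper triangle (symmetric path);
    2. support cells drawn uniformly without replacement;
    3. log-normal magnitudes assigned to the support;
    4. a uniformly chosen fraction ``(1 - b)/2`` of them negated;
    5. for ``s > 0``: mirror the upper triangle (value and sign) onto the
       lower, then swap random lower-triangle cells until the measured
       symmetry is within the counting tolerance ``4/m`` of ``s``.

    Raises
    ------
    GenerationError
        If the target counts round to zero connections.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    total = n * (n - 1)

    if config.symmetry == 0.0:
        m = int(round(config.density * total))
        if m == 0:
            raise GenerationError(
                f"density {config.density} rounds to zero connections at n={n}")
        # off-diagonal cells enumerated row-major, skipping the diagonal
        flat = rng.choice(total, size=m, replace=False)
        rows, cols = np.divmod(flat, n - 1)
        cols = cols + (cols >= rows)  # reinsert the skipped diagonal column
        values = sample_magnitudes(m, config.loc, config.scale, rng)
        m_minus = int(round(m * (1.0 - config.balance) / 2.0))
        neg = rng.choice(m, size=m_minus, replace=False)
        values[neg] *= -1.0
        W = np.zeros((n, n))
        W[rows, cols] = values
        return W

    # symmetric path: build on the upper triangle, mirror, then desymmetrize
    tri = total // 2
    m_upper = int(round(config.density * tri))
    if m_upper == 0:
        raise GenerationError(
            f"density {config.density} rounds to zero symmetric pairs at n={n}; "
            "a nonzero symmetry target cannot be realized")
    iu, ju = np.triu_indices(n, k=1)
    sel = rng.choice(tri, size=m_upper, replace=False)
    values = sample_magnitudes(m_upper, config.loc, config.scale, rng)
    m_minus_u = int(round(m_upper * (1.0 - config.balance) / 2.0))
    neg = rng.choice(m_upper, size=m_minus_u, replace=False)
    values[neg] *= -1.0
    W = np.zeros((n, n))
    W[iu[sel], ju[sel]] = values
    W = W + W.T  # mirror: w_ji = w_ij, value and sign
    if config.symmetry < 1.0:
        W = desymmetrize_by_swaps(W, config.symmetry, rng)
    return W


def desymmetrize_by_swaps(W: np.ndarray, s_target: float,
                          rng: np.random.Generator,
                          max_iter: int | None = None,
                          tol: float | None = None) -> np.ndarray:
    """Reduce the symmetry of an exactly symmetric matrix to ``s_target``.

    Pairs of below-diagonal cells (zero cells included — necessary to reach
    low symmetry at low density) are chosen uniformly and their values
    exchanged; a swap that would increase the symmetric-match count is
    undone, so the count decreases monotonically toward the target.  The
    value multiset of the lower triangle — hence ``m``, ``m+``, ``m-``,
    density and balance — is preserved exactly.

    Stops when ``|s_measured - s_target| <= tol`` (default ``4/m``, the
    granularity of a single swap).  Raises :class:`ConvergenceError`,
    reporting the best symmetry achieved, if ``max_iter`` swaps do not
    suffice.
    """
    W = np.asarray(W, dtype=float)
    if not np.array_equal(W, W.T):
        raise ValueError("input matrix must be exactly symmetric")
    _check_zero_diagonal(W)
    if not 0.0 <= s_target <= 1.0:
        raise ValueError(f"s_target must lie in [0, 1], got {s_target}")

    n = W.shape[0]
    il, jl = np.tril_indices(n, k=-1)
    tri = il.size
    upper = W[jl, il].copy()      # mirrored partners, never touched
    vals = W[il, jl].copy()       # lower-triangle values, permuted by swaps

    m, _, _, m_s = connection_counts(W)
    if m == 0:
        raise ValueError("cannot desymmetrize a matrix with no connections")
    if tol is None:
        tol = 4.0 / m
    if max_iter is None:
        max_iter = max(100_000, 100 * tri)

    if abs(m_s / m - s_target) <= tol or s_target == 1.0:
        return W.copy()

    def match(k: int) -> bool:
        # plain bool: numpy bools add as logical OR, which would miscount
        return bool(vals[k] != 0 and vals[k] == upper[k])

    target_ms = s_target * m
    for _ in range(max_iter):
        a = int(rng.integers(tri))
        b = int(rng.integers(tri))
        if a == b:
            continue
        was = 2 * (match(a) + match(b))
        vals[a], vals[b] = vals[b], vals[a]
        now = 2 * (match(a) + match(b))
        if now > was:           # swap would raise symmetry: undo
            vals[a], vals[b] = vals[b], vals[a]
            continue
        m_s += now - was
        if abs(m_s - target_ms) <= tol * m:
            break
    else:
        raise ConvergenceError(
            f"symmetry {m_s / m:.4f} not within {tol:.4g} of target "
            f"{s_target} after {max_iter} swaps", best_symmetry=m_s / m)

    out = np.zeros_like(W)
    out[jl, il] = upper
    out[il, jl] = vals
    return out


def save_matrix(W: np.ndarray, path: str | Path,
                metadata: dict | None = None) -> None:
    """Write ``W`` in MatrixMarket coordinate format (real, general).

    If ``metadata`` is given it is written as a JSON sidecar next to the
    matrix (same stem, ``.json`` suffix).
    """
    path = Path(path)
    _check_zero_diagonal(np.asarray(W))
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(W))
    if metadata is not None:
        path.with_suffix(".json").write_text(json.dumps(metadata, indent=2))


def load_matrix(path: str | Path) -> np.ndarray:
    """Read a square weight matrix from a MatrixMarket file."""
    M = scipy.io.mmread(str(path))
    W = np.asarray(M.todense() if scipy.sparse.issparse(M) else M, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {W.shape}")
    _check_zero_diagonal(W)
    return W
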