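"""Ensemble sweeps over the (balance, density, symmetry) control space.

For every grid cell an ensemble of networks with the prescribed weight
statistics is generated, each is run from a random initial state, and the
cell is summarized by

* ``f_pos``       — fraction of members with a positive Lyapunov exponent,
* ``t_av``        — mean attractor period (censored runs at ``t_max``),
* ``censored_frac`` — fraction of members with no recurrence found,
* ``rho_rms_mean`` — ensemble mean of the cross-correlation RMS.

Cells are mutually independent and deterministic given the master seed, so
sweeps can be re-run (or resumed) cell by cell in any order.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import weights
from .dynamics import random_initial_state
from .measures import (LyapunovSettings, QUANTUM, average_period,
                       fraction_positive, summarize_network)

__all__ = [
    "EnsembleSpec",
    "PhaseCell",
    "PhaseGrid",
    "member_seed_sequence",
    "run_ensemble",
    "sweep_grid",
    "grid_to_frame",
    "export_grid",
    "plot_heatmaps",
]

ALL_MEASURES = ("lyapunov", "period", "correlation")


@dataclasses.dataclass(frozen=True)
class EnsembleSpec:
    """Full prescription of one phase-diagram sweep.

    The reference study conditions are ensembles of 100 networks simulated
    for 10^6 steps per cell of an 11 x 10 balance-density grid; both are
    kept as defaults here and scaled down explicitly where desk-scale runs
    are wanted.
    """

    n: int
    balance_values: tuple[float, ...] = tuple(np.round(np.linspace(-1.0, 1.0, 11), 10))
    density_values: tuple[float, ...] = tuple(np.round(np.linspace(0.1, 1.0, 10), 10))
    symmetry_values: tuple[float, ...] = (0.0,)
    ensemble_size: int = 100
    master_seed: int = 0
    t_max: int = 1_000_000
    loc: float = 0.0
    scale: float = 1.0
    lyapunov: LyapunovSettings = LyapunovSettings()
    corr_window: int = 10_000
    corr_transient: int = 1000
    quantum: float = QUANTUM
    measures: tuple[str, ...] = ALL_MEASURES

    def __post_init__(self):
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        for name, vals, lo, hi in (("balance", self.balance_values, -1.0, 1.0),
                                   ("density", self.density_values, 0.0, 1.0),
                                   ("symmetry", self.symmetry_values, 0.0, 1.0)):
            if len(vals) == 0:
                raise ValueError(f"{name}_values must be non-empty")
            if any(not lo <= v <= hi for v in vals):
                raise ValueError(f"{name}_values must lie in [{lo}, {hi}]")
        unknown = set(self.measures) - set(ALL_MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")

    def grid_points(self) -> list[tuple[float, float, float]]:
        """Cells as (symmetry, density, balance) in deterministic order."""
        return [(s, d, b)
                for s in self.symmetry_values
                for d in self.density_values
                for b in self.balance_values]


@dataclasses.dataclass(frozen=True)
class PhaseCell:
    """Ensemble aggregates for one grid point."""

    n: int
    balance: float
    density: float
    symmetry: float
    ensemble_size: int
    f_pos: float
    t_av: float
    censored_frac: float
    rho_rms_mean: float
    seed: int
    failed: bool = False
    reason: str | None = None


@dataclasses.dataclass(frozen=True)
class PhaseGrid:
    spec: EnsembleSpec
    cells: tuple[PhaseCell, ...]


def member_seed_sequence(master_seed: int, cell_index: int,
                         member_index: int) -> np.random.SeedSequence:
    """Splittable per-member seed: SeedSequence keyed on (master, cell, member)."""
    return np.random.SeedSequence((master_seed, cell_index, member_index))


def run_ensemble(n: int, balance: float, density: float, symmetry: float,
                 ensemble_size: int, master_seed: int, cell_index: int = 0,
                 *, t_max: int = 100_000, loc: float = 0.0, scale: float = 1.0,
                 lyapunov: LyapunovSettings = LyapunovSettings(),
                 corr_window: int = 10_000, corr_transient: int = 1000,
                 quantum: float = QUANTUM,
                 measures: tuple[str, ...] = ALL_MEASURES) -> PhaseCell:
    """Generate, simulate and measure one ensemble; aggregate into a PhaseCell.

    Member ``k`` derives its matrix seed and initial state from
    ``SeedSequence((master_seed, cell_index, k))``, so any cell is
    reproducible in isolation.  An infeasible weight prescription marks the
    cell failed (with the reason) instead of raising.
    """
    summaries = []
    try:
        for k in range(ensemble_size):
            ss = member_seed_sequence(master_seed, cell_index, k)
            ss_w, ss_y = ss.spawn(2)
            cfg = weights.WeightConfig(
                n=n, density=density, balance=balance, symmetry=symmetry,
                loc=loc, scale=scale,
                seed=int(ss_w.generate_state(1, np.uint32)[0]))
            W = weights.generate_weight_matrix(cfg)
            y0 = random_initial_state(n, np.random.default_rng(ss_y))
            summaries.append(summarize_network(
                W, y0, t_max, lyapunov=lyapunov, corr_window=corr_window,
                corr_transient=corr_transient, quantum=quantum,
                measures=measures))
    except (weights.GenerationError, weights.ConvergenceError) as exc:
        return PhaseCell(n=n, balance=balance, density=density,
                         symmetry=symmetry, ensemble_size=ensemble_size,
                         f_pos=float("nan"), t_av=float("nan"),
                         censored_frac=float("nan"), rho_rms_mean=float("nan"),
                         seed=master_seed, failed=True, reason=str(exc))

    f_pos = (fraction_positive([s.lyapunov for s in summaries])
             if "lyapunov" in measures else float("nan"))
    if "period" in measures:
        t_av, censored = average_period([(s.period, s.censored)
                                         for s in summaries])
    else:
        t_av, censored = float("nan"), float("nan")
    rho = (float(np.mean([s.rho_rms for s in summaries]))
           if "correlation" in measures else float("nan"))
    return PhaseCell(n=n, balance=balance, density=density, symmetry=symmetry,
                     ensemble_size=ensemble_size, f_pos=f_pos, t_av=t_av,
                     censored_frac=censored, rho_rms_mean=rho,
                     seed=master_seed)


def sweep_grid(spec: EnsembleSpec, progress: bool = False) -> PhaseGrid:
    """One PhaseCell per grid point; per-cell failures do not abort the sweep."""
    points = spec.grid_points()
    if progress:
        from tqdm import tqdm
        points_iter: Iterable = tqdm(list(enumerate(points)), desc="cells")
    else:
        points_iter = enumerate(points)
    cells = []
    for idx, (s, d, b) in points_iter:
        cells.append(run_ensemble(
            spec.n, b, d, s, spec.ensemble_size, spec.master_seed,
            cell_index=idx, t_max=spec.t_max, loc=spec.loc, scale=spec.scale,
            lyapunov=spec.lyapunov, corr_window=spec.corr_window,
            corr_transient=spec.corr_transient, quantum=spec.quantum,
            measures=spec.measures))
    return PhaseGrid(spec=spec, cells=tuple(cells))


_CSV_COLUMNS = ["n", "balance", "density", "symmetry", "ensemble_size",
                "f_pos", "t_av", "censored_frac", "rho_rms_mean", "seed",
                "failed", "reason"]


def grid_to_frame(grid: PhaseGrid) -> pd.DataFrame:
    """Long-format table, one row per cell."""
    return pd.DataFrame([dataclasses.asdict(c) for c in grid.cells],
                        columns=_CSV_COLUMNS)


def export_grid(grid: PhaseGrid, out_dir: str | Path,
                heatmaps: bool = False) -> Path:
    """Write ``phase_grid.csv`` and ``metadata.json`` (and optional heatmaps).

    Returns the path of the CSV.  Re-exporting the same grid is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "phase_grid.csv"
    grid_to_frame(grid).to_csv(csv_path, index=False)
    meta = dataclasses.asdict(grid.spec)
    meta["lyapunov"] = dataclasses.asdict(grid.spec.lyapunov)
    (out_dir / "metadata.json").write_text(json.dumps(meta, indent=2,
                                                      sort_keys=True))
    if heatmaps:
        plot_heatmaps(grid, out_dir)
    return csv_path


def load_grid_frame(path: str | Path) -> pd.DataFrame:
    """Read back an exported ``phase_grid.csv``."""
    return pd.read_csv(path)


def plot_heatmaps(grid: PhaseGrid, out_dir: str | Path,
                  measures: Sequence[str] = ("f_pos", "t_av",
                                             "rho_rms_mean")) -> list[Path]:
    """Balance-density heatmap per measure and symmetry value (PNG files)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = grid_to_frame(grid)
    paths = []
    for s_val, sub in df.groupby("symmetry"):
        for meas in measures:
            pivot = sub.pivot(index="density", columns="balance", values=meas)
            fig, ax = plt.subplots(figsize=(6, 4.5))
            data = pivot.values
            if meas == "t_av":
                data = np.log10(np.maximum(data, 1.0))
            ext = [pivot.columns.min(), pivot.columns.max(),
                   pivot.index.min(), pivot.index.max()]
            if ext[0] == ext[1]:
                ext[0], ext[1] = ext[0] - 0.05, ext[1] + 0.05
            if ext[2] == ext[3]:
                ext[2], ext[3] = ext[2] - 0.05, ext[3] + 0.05
            im = ax.imshow(data, origin="lower", aspect="auto", extent=ext)
            ax.set_xlabel("balance")
            ax.set_ylabel("density")
            title = f"{meas} (log10)" if meas == "t_av" else meas
            ax.set_title(f"{title}, symmetry={s_val}, n={grid.spec.n}")
            fig.colorbar(im, ax=ax)
            p = Path(out_dir) / f"{meas}_s{s_val}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths.append(p)
    return paths
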