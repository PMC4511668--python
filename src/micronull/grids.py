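"""Replicated parameter sweeps over the acquisition x environment plane.

A :class:`GridSpec` crosses a list of parental-acquisition fractions x with a
list of pooled-environment fractions y, runs several independent replicate
simulations per cell, and aggregates the end-of-run alpha/beta/gamma
diversities into matrices suitable for heatmaps or tables.

Replicate seeds are derived deterministically from (base seed, cell index,
replicate index), so cells can be computed in any order — or re-run
individually — with identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .simulation import diversity_record, run_simulation

__all__ = [
    "GridSpec",
    "GridResult",
    "preset_grids",
    "cell_seed",
    "run_grid",
    "write_grid_tables",
    "read_grid_table",
    "plot_heatmap",
]

logger = logging.getLogger(__name__)

_METRICS = ("alpha", "beta", "gamma")


@dataclass(frozen=True)
class GridSpec:
    x_values: tuple[float, ...]
    y_values: tuple[float, ...]
    replicates: int
    base_config: SimulationConfig
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("x_values", "y_values"):
            vals = getattr(self, name)
            if len(vals) == 0 or any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"{name} must be a non-empty list of values in [0,1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class GridResult:
    x_values: tuple[float, ...]
    y_values: tuple[float, ...]
    mean: dict[str, np.ndarray]       # metric -> |x| x |y| matrix
    sd: dict[str, np.ndarray]
    generations: np.ndarray           # mean generations actually run per cell


def preset_grids(name: str) -> tuple[float, ...]:
    """Named x/y-axis presets.

    * ``linear`` — 0.0 to 1.0 in steps of 0.1 (11 values);
    * ``power_small`` — {0} plus powers 0.5^j for j = 10..0, probing the
      near-zero end;
    * ``power_large`` — 1 - 0.5^j for j = 0..20, probing the near-one end
      (contains e.g. 0.984375 = 98.4% parental acquisition).
    """
    if name == "linear":
        return tuple(np.round(np.arange(0, 11) * 0.1, 10))
    if name == "power_small":
        return (0.0,) + tuple(0.5**j for j in range(10, -1, -1))
    if name == "power_large":
        return tuple(1.0 - 0.5**j for j in range(0, 21))
    raise ValueError(f"unknown preset {name!r}; expected linear, power_small "
                     "or power_large")


def cell_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-replicate seed, independent of execution order."""
    ss = np.random.SeedSequence([base_seed, cell_index, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def run_grid(spec: GridSpec, progress: bool = False) -> GridResult:
    """Run every (x, y) cell with independent replicates and aggregate.

    Per cell, the mean and sample sd (NaN for a single replicate) of the
    final-state alpha, beta and gamma are recorded, along with the mean
    number of generations each replicate actually ran (relevant when early
    stopping is enabled).
    """
    nx, ny = len(spec.x_values), len(spec.y_values)
    mean = {metric: np.zeros((nx, ny)) for metric in _METRICS}
    sd = {metric: np.zeros((nx, ny)) for metric in _METRICS}
    generations = np.zeros((nx, ny))
    for ix, x in enumerate(spec.x_values):
        for iy, y in enumerate(spec.y_values):
            cell = ix * ny + iy
            finals = {metric: [] for metric in _METRICS}
            gens = []
            for rep in range(spec.replicates):
                config = spec.base_config.replace(
                    parental_fraction=float(x),
                    pooled_env_fraction=float(y),
                    seed=cell_seed(spec.base_seed, cell, rep),
                )
                try:
                    result = run_simulation(config)
                except Exception as exc:  # re-raise with cell coordinates
                    raise RuntimeError(
                        f"simulation failed at grid cell x={x}, y={y}, "
                        f"replicate {rep}"
                    ) from exc
                record = diversity_record(result.final_state, config.richness_mode)
                finals["alpha"].append(record.alpha_mean)
                finals["beta"].append(record.beta)
                finals["gamma"].append(record.gamma)
                gens.append(result.final_state.generation)
            for metric in _METRICS:
                vals = np.array(finals[metric])
                mean[metric][ix, iy] = vals.mean()
                sd[metric][ix, iy] = (
                    vals.std(ddof=1) if len(vals) > 1 else float("nan")
                )
            generations[ix, iy] = float(np.mean(gens))
            if progress:
                logger.info("cell x=%.6g y=%.6g done (%d replicates)", x, y,
                            spec.replicates)
    return GridResult(spec.x_values, spec.y_values, mean, sd, generations)


def _frame(result: GridResult, matrix: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        matrix,
        index=pd.Index(list(result.x_values), name="x"),
        columns=pd.Index(list(result.y_values), name="y"),
    )


def write_grid_tables(result: GridResult, out_dir: str | Path) -> list[Path]:
    """Write alpha/beta/gamma mean and sd matrices (plus generations) as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for metric in _METRICS:
        for kind, source in (("mean", result.mean), ("sd", result.sd)):
            path = out / f"{metric}_{kind}.csv"
            _frame(result, source[metric]).to_csv(path)
            written.append(path)
    path = out / "generations.csv"
    _frame(result, result.generations).to_csv(path)
    written.append(path)
    return written


def read_grid_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def plot_heatmap(result: GridResult, metric: str, path: str | Path) -> None:
    """Convenience PNG heatmap of one metric's per-cell means."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    fig, ax = plt.subplots(figsize=(6, 5))
    mat = result.mean[metric].T  # y on the vertical axis, increasing upward
    im = ax.imshow(mat, origin="lower", aspect="auto", vmin=0, vmax=1,
                   cmap="viridis")
    ax.set_xticks(range(len(result.x_values)))
    ax.set_xticklabels([f"{v:.3g}" for v in result.x_values], rotation=90)
    ax.set_yticks(range(len(result.y_values)))
    ax.set_yticklabels([f"{v:.3g}" for v in result.y_values])
    ax.set_xlabel("parental acquisition fraction x")
    ax.set_ylabel("pooled environment fraction y")
    ax.set_title(f"{metric}-diversity (replicate means)")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
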