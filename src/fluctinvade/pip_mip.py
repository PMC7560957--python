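"""Pairwise (PIP) and mutual (MIP) invasibility grids over a 1-d strategy
slice.

For stochastic models, all mutants in one grid row are averaged along a
single simulated resident trajectory — the fitness of a rare mutant only
depends on the resident's environment, so one resident path serves every
mutant column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .invasion import MethodError, _fitness_evaluator
from .model_core import as_strategy
from .simulate import SimulationConfig

__all__ = ["InvasibilityGrid", "pip_grid", "mip_grid", "grid_to_csv"]


@dataclass
class InvasibilityGrid:
    x_grid: np.ndarray  # residents (rows)
    y_grid: np.ndarray  # mutants (columns)
    S_values: np.ndarray  # S[i, j] = fitness of mutant y_j in resident x_i
    se_values: np.ndarray
    region: np.ndarray  # 'plus' | 'minus' | 'neutral_band' | 'missing'
    method: str = ""


def pip_grid(spec, x_range, n_grid: int, method: str = "closed_form",
             config: Optional[SimulationConfig] = None,
             strategy_slice: Optional[Callable] = None,
             dead_band: Optional[float] = None, **kwargs) -> InvasibilityGrid:
    """Fitness sign grid S(x, y) over ``x_range = (lo, hi)``.

    ``strategy_slice`` maps a grid scalar to a full strategy vector (for
    multi-dimensional strategy spaces); default is the identity. The region
    is 'plus'/'minus' by sign outside a neutral dead-band of 3 SE (ergodic)
    or ``dead_band`` (default 1e-10) for deterministic methods; diagonal
    cells are classified 'neutral_band'. Failing cells are marked 'missing'.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    lo, hi = float(x_range[0]), float(x_range[1])
    grid = np.linspace(lo, hi, n_grid)
    to_strategy = strategy_slice or (lambda u: np.array([u]))
    band = 1e-10 if dead_band is None else dead_band

    S = np.full((n_grid, n_grid), np.nan)
    SE = np.zeros((n_grid, n_grid))
    region = np.full((n_grid, n_grid), "missing", dtype=object)
    for i, xv in enumerate(grid):
        x = as_strategy(to_strategy(xv))
        try:
            evaluate = _fitness_evaluator(spec, [x], method, config, **kwargs)
        except (MethodError, ValueError):
            continue
        for j, yv in enumerate(grid):
            y = as_strategy(to_strategy(yv))
            try:
                res = evaluate(y)
            except (MethodError, ValueError):
                continue
            S[i, j] = res.value
            SE[i, j] = res.se
            cell_band = 3.0 * res.se if method == "ergodic" else band
            if i == j or abs(res.value) <= cell_band:
                region[i, j] = "neutral_band"
            elif res.value > 0:
                region[i, j] = "plus"
            else:
                region[i, j] = "minus"
    return InvasibilityGrid(x_grid=grid, y_grid=grid.copy(), S_values=S,
                            se_values=SE, region=region, method=method)


def mip_grid(pip: InvasibilityGrid) -> np.ndarray:
    """Mutual-invasibility regions from a square PIP.

    Cell (i, j) combines S(x_i, y_j) and S(x_j, y_i): 'mutual' when both are
    plus, 'one_way' when exactly one is, 'none' when neither, 'missing' when
    either cell is missing.
    """
    n = len(pip.x_grid)
    if pip.S_values.shape != (n, n):
        raise ValueError("PIP grid must be square")
    out = np.full((n, n), "none", dtype=object)
    for i in range(n):
        for j in range(n):
            a, b = pip.region[i, j], pip.region[j, i]
            if a == "missing" or b == "missing":
                out[i, j] = "missing"
            elif a == "plus" and b == "plus":
                out[i, j] = "mutual"
            elif a == "plus" or b == "plus":
                out[i, j] = "one_way"
    return out


def grid_to_csv(pip: InvasibilityGrid, path, mip: Optional[np.ndarray] = None):
    """Long-format CSV export: x, y, S, se, region (and mip region)."""
    import pandas as pd

    rows = []
    n = len(pip.x_grid)
    for i in range(n):
        for j in range(n):
            row = {
                "x": pip.x_grid[i],
                "y": pip.y_grid[j],
                "S": pip.S_values[i, j],
                "se": pip.se_values[i, j],
                "region": pip.region[i, j],
            }
            if mip is not None:
                row["mip_region"] = mip[i, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
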