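"""Ancestral effective population size from LD at chosen genetic distances.

Inverting Sved's expectation E(r^2) = 1/(1 + 4*N*c) gives

    N_T(t) = (1 / (4c)) * (1 / r2_c - 1),   with  c = 1/(2t),

where r2_c is the mean r^2 of SNP pairs about c morgans apart and
N_T(t) is the effective size t generations before present: LD between
distant markers reflects recent Ne, LD between tight markers reflects
ancient Ne.  Pairs are pooled across autosomes, and the mean r^2 is
sample-size corrected (r^2 - 1/(2n)) by default because the 1/(2n)
sampling inflation dominates the small r^2 values at large distances.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default generation grid: log-spaced, 10 to 100,000 generations, 40 points.
DEFAULT_GRID = np.unique(np.round(np.logspace(1, 5, 40)).astype(int))

DEFAULT_MIN_PAIRS = 100
DEFAULT_REL_WINDOW = 0.2


class InfiniteNeError(ValueError):
    """Mean r^2 <= 0: the implied effective size is infinite."""


def ne_at_generation(t: float, mean_r2: float) -> float:
    """N_T(t) = (t/2) * (1/mean_r2 - 1) via c = 1/(2t).

    ``mean_r2`` = 1 implies Ne = 0 (complete LD); ``mean_r2`` <= 0 (for
    example after over-correction) implies infinite Ne and raises.
    """
    if t <= 0:
        raise ValueError("t must be a positive number of generations")
    if mean_r2 <= 0:
        raise InfiniteNeError("mean r^2 <= 0 implies an infinite effective size")
    if mean_r2 > 1:
        raise ValueError("mean r^2 cannot exceed 1")
    c = 1.0 / (2.0 * t)
    return (1.0 / (4.0 * c)) * (1.0 / mean_r2 - 1.0)


def build_trajectory(
    table: pd.DataFrame,
    generation_grid=None,
    bin_policy: tuple[str, float] = ("relative", DEFAULT_REL_WINDOW),
    min_pairs: int = DEFAULT_MIN_PAIRS,
    correction: bool = True,
) -> pd.DataFrame:
    """Ne trajectory over a grid of past generations, pooled across autosomes.

    For each generation t the target recombination distance is
    c = 1/(2t); the pairs averaged are those with genetic distance inside
    the bin the policy defines:

    ``("relative", w)``
        distances within c*(1-w) .. c*(1+w) (default w = 0.2);
    ``("nearest", m)``
        the m pairs with distance closest to c.

    Points whose bin holds fewer than ``min_pairs`` pairs, or whose mean
    r^2 is non-positive after correction, are dropped with a log line.
    Returns columns (t, c, c_lo, c_hi, n_pairs, mean_r2, nt), sorted by t.
    """
    if generation_grid is None:
        generation_grid = DEFAULT_GRID
    grid = np.asarray(generation_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("generation grid is empty")
    if table.empty:
        raise ValueError("LD pair table is empty")
    policy, param = bin_policy
    if policy not in ("relative", "nearest"):
        raise ValueError(f"unknown bin policy {policy!r}")

    value_col = "r2_corrected" if correction else "r2"
    d = table["dist_morgans"].to_numpy()
    y = table[value_col].to_numpy()
    order = np.argsort(d)
    d, y = d[order], y[order]

    rows = []
    for t in np.sort(grid):
        c = 1.0 / (2.0 * t)
        if policy == "relative":
            lo, hi = c * (1.0 - param), c * (1.0 + param)
            i0, i1 = np.searchsorted(d, [lo, hi])
        else:
            m = int(param)
            center = np.searchsorted(d, c)
            i0 = max(0, center - m // 2)
            i1 = min(len(d), i0 + m)
            i0 = max(0, i1 - m)
            lo, hi = (d[i0], d[i1 - 1]) if i1 > i0 else (c, c)
        n_pairs = i1 - i0
        if n_pairs < min_pairs:
            logger.info("t=%g: only %d pairs in bin, point dropped", t, n_pairs)
            continue
        mean_r2 = float(np.mean(y[i0:i1]))
        if mean_r2 <= 0:
            logger.info("t=%g: non-positive mean r^2 (%.3g), point dropped", t, mean_r2)
            continue
        rows.append(
            {
                "t": float(t),
                "c": c,
                "c_lo": float(lo),
                "c_hi": float(hi),
                "n_pairs": int(n_pairs),
                "mean_r2": mean_r2,
                "nt": ne_at_generation(float(t), mean_r2),
            }
        )
    if not rows:
        logger.warning("build_trajectory: no generation produced an occupied bin")
    return pd.DataFrame(rows, columns=["t", "c", "c_lo", "c_hi", "n_pairs", "mean_r2", "nt"])


def reduction_percent(nt_recent: float, nt_ancient: float) -> float:
    """Percentage decline from the ancient to the recent estimate, 1 decimal."""
    if nt_ancient <= 0:
        raise ValueError("ancient Ne must be positive")
    return round(100.0 * (1.0 - nt_recent / nt_ancient), 1)
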