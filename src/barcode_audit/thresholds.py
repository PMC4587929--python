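"""Data-driven identification thresholds.

Two complementary procedures, both operating on the K2P matrix:

1. **Cumulative-error minimization** — over a grid of candidate
   thresholds, count per threshold the *false positives* (queries with
   no conspecific match strictly within the threshold) and *false
   negatives* (queries whose within-threshold matches span two or more
   species); the optimum minimizes their sum, ties resolved to the
   smallest threshold.
2. **Density local minimum** — a Gaussian KDE of all pairwise distances
   typically shows an intraspecific bump near zero and an interspecific
   bulk further out; the first interior local minimum of the density is
   taken as the transition between intra- and interspecific distances.
   A unimodal density yields an explicit "no transition found" result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .distance import DistanceMatrix

DEFAULT_GRID = np.round(np.arange(0.1, 10.0001, 0.1), 4)  # percent


def _per_query_species_mins(dm: DistanceMatrix):
    """Per query: nearest-conspecific distance and per-species minima.

    Returns (nearest_conspecific, second_smallest_species_min), both in
    proportions with inf where undefined/absent.
    """
    species = np.asarray(dm.species)
    if species.size == 0:
        raise ValueError("distance matrix carries no species labels")
    order = np.argsort(species, kind="stable")
    sp_sorted = species[order]
    starts = np.flatnonzero(np.r_[True, sp_sorted[1:] != sp_sorted[:-1]])
    uniq = sp_sorted[starts]
    sp_col = {s: k for k, s in enumerate(uniq)}

    d = dm.d.copy()
    np.fill_diagonal(d, np.inf)
    d[np.isnan(d)] = np.inf
    d_sorted = d[:, order]
    mins = np.minimum.reduceat(d_sorted, starts, axis=1)  # (n_queries, n_species)

    own = np.array([sp_col[s] for s in species])
    nearest_consp = mins[np.arange(len(dm)), own]
    if mins.shape[1] < 2:
        second_species_min = np.full(len(dm), np.inf)
    else:
        second_species_min = np.partition(mins, 1, axis=1)[:, 1]
    return nearest_consp, second_species_min


@dataclass(frozen=True)
class ThresholdScan:
    """Per-threshold false positive/negative counts and the optimum."""

    grid: np.ndarray  # percent, ascending
    false_positive: np.ndarray
    false_negative: np.ndarray

    @property
    def cumulative_error(self) -> np.ndarray:
        return self.false_positive + self.false_negative

    @property
    def optimum(self) -> float:
        return float(self.grid[int(np.argmin(self.cumulative_error))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_pct": self.grid,
                "false_positive": self.false_positive,
                "false_negative": self.false_negative,
                "cumulative_error": self.cumulative_error,
            }
        )


def cumulative_error_scan(
    dm: DistanceMatrix, grid=DEFAULT_GRID
) -> ThresholdScan:
    """Scan candidate thresholds (percent) for cumulative identification error.

    Every sequence acts as a leave-one-out query. False positives
    decrease and false negatives increase monotonically in the
    threshold, which the scan verifies by construction.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly ascending")
    nearest_consp, second_species_min = _per_query_species_mins(dm)
    t = grid[None, :] / 100.0
    fp = (nearest_consp[:, None] >= t).sum(axis=0)
    fn = (second_species_min[:, None] < t).sum(axis=0)
    return ThresholdScan(grid=grid, false_positive=fp, false_negative=fn)


@dataclass(frozen=True)
class DensityMinimum:
    """KDE of all pairwise distances and its interior local minima."""

    grid: np.ndarray  # percent
    density: np.ndarray
    local_minima: tuple[float, ...]  # percent
    threshold: float | None  # selected transition; None if unimodal
    bandwidth: float

    @property
    def found(self) -> bool:
        return self.threshold is not None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_pct": self.grid, "density": self.density})


def density_local_minimum(
    dm: DistanceMatrix,
    bandwidth_policy: str | float = "silverman",
    n_grid: int = 512,
    max_pairs: int | None = None,
    seed: int | None = None,
) -> DensityMinimum:
    """Gaussian KDE over all defined pairwise distances; first interior
    local minimum selected as the intra/inter transition.

    ``bandwidth_policy`` is passed to :class:`scipy.stats.gaussian_kde`
    (``"silverman"``, ``"scott"`` or a numeric factor). ``max_pairs``
    optionally subsamples very large distance multisets (seeded) before
    density estimation.
    """
    vals = dm.condensed(drop_undefined=True) * 100.0  # percent
    if vals.size < 10:
        raise ValueError("need at least 10 defined pairwise distances")
    if max_pairs is not None and vals.size > max_pairs:
        rng = np.random.default_rng(seed)
        vals = rng.choice(vals, size=max_pairs, replace=False)
    if np.allclose(vals, vals[0]):
        grid = np.linspace(vals[0] - 1, vals[0] + 1, n_grid)
        return DensityMinimum(
            grid=grid,
            density=np.zeros_like(grid),
            local_minima=(),
            threshold=None,
            bandwidth=float("nan"),
        )
    kde = gaussian_kde(vals, bw_method=bandwidth_policy)
    lo, hi = float(vals.min()), float(vals.max())
    grid = np.linspace(lo, hi, n_grid)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] < dens[:-2]) & (dens[1:-1] < dens[2:])
    ) + 1
    minima = tuple(float(grid[i]) for i in interior)
    return DensityMinimum(
        grid=grid,
        density=dens,
        local_minima=minima,
        threshold=minima[0] if minima else None,
        bandwidth=float(kde.factor),
    )
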