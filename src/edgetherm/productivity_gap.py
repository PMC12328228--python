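"""Observed T_surf versus the thermal optimum for ecosystem productivity.

The thermal-optimum surface (T_opt) lives on a coarse regular grid (1/12
degree cells in the source data; metres-scale cells in synthetic mode).
Each sample point receives the T_opt of the cell containing it, and the gap
T_surf - T_opt is modelled against distance-from-edge with the same
additive-model machinery as the raw edge curves, on in-forest points only,
for scenes that satisfy the eligibility rules (>=500 observations, >=2
overpasses, >=1 observation at >=800 m into the forest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curve_model import (EdgeContrast, EdgeCurveModel, edge_interior_contrast,
                          fit_edge_curve, predict_partial)
from .raster import RasterGrid
from .synthetic_landscape import SyntheticStudy

ToptGrid = RasterGrid  # coarse T_opt surface; same container, coarser cells


class CoverageError(ValueError):
    """The T_opt grid does not cover any of the points."""


@dataclass
class GapCurve:
    """Fitted gap curve on 0..500 m with its edge-interior contrast."""

    curve: pd.DataFrame          # columns d, fit, se (gap scale, deg C)
    contrast: EdgeContrast       # 30 m vs 500 m on the gap scale
    model: EdgeCurveModel
    n_points: int


def attach_topt(points: pd.DataFrame, grid: ToptGrid
                ) -> tuple[pd.DataFrame, int]:
    """Assign each point the T_opt of the coarse cell containing it.

    Cells are half-open: a point on a shared vertical boundary belongs to
    the cell to its east, on a horizontal boundary to the cell to its south.
    Points outside the grid or in nodata cells are dropped; the count of
    dropped points is returned alongside the augmented table.
    """
    x0, y0 = grid.origin
    cell = grid.pixel_size
    nrows, ncols = grid.shape
    col = np.floor((points["x"].to_numpy(dtype=float) - x0) / cell).astype(int)
    row = np.floor((y0 - points["y"].to_numpy(dtype=float)) / cell).astype(int)
    inside = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
    if not inside.any():
        raise CoverageError("T_opt grid covers none of the points")
    topt = np.full(len(points), np.nan)
    topt[inside] = grid.values[row[inside], col[inside]]
    defined = inside & (topt != grid.nodata) & np.isfinite(topt)
    out = points.loc[defined].copy()
    out["topt_c"] = topt[defined]
    return out.reset_index(drop=True), int((~defined).sum())


def filter_eligible_scenes(points: pd.DataFrame, *, min_obs: int = 500,
                           min_overpasses: int = 2, min_deep: float = 800.0,
                           max_dist: float = 1000.0
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep in-forest points of scenes meeting the three eligibility rules.

    Working on in-forest points up to ``max_dist`` (non-forest points are
    excluded), a scene is retained iff it has at least ``min_obs``
    observations, from at least ``min_overpasses`` distinct overpasses, with
    at least one observation ``min_deep`` m or farther into the forest (all
    thresholds inclusive).  The exclusion log names the failed criteria.
    """
    inside = points[(points["dist_m"] > 0)
                    & (points["dist_m"] <= max_dist)]
    rows = []
    for sid, grp in inside.groupby("scene_id", sort=True):
        n = len(grp)
        n_over = grp["overpass_id"].nunique()
        deep = float(grp["dist_m"].max()) if n else 0.0
        fails = []
        if n < min_obs:
            fails.append("observation count")
        if n_over < min_overpasses:
            fails.append("overpass count")
        if deep < min_deep:
            fails.append("no deep-interior observation")
        rows.append({"scene_id": sid, "n_obs": n, "n_overpasses": n_over,
                     "max_dist": deep, "eligible": not fails,
                     "failed": "; ".join(fails)})
    log = pd.DataFrame(rows)
    ok = set(log.loc[log["eligible"], "scene_id"]) if len(log) else set()
    return inside[inside["scene_id"].isin(ok)].reset_index(drop=True), log


def fit_gap_curve(points: pd.DataFrame, *, d_edge: float = 30.0,
                  d_interior: float = 500.0, se_rule: str = "as-printed",
                  knot_range: tuple[float, float] = (0.0, 1000.0),
                  **fit_kwargs) -> GapCurve:
    """Fit the additive model with T_surf - T_opt as the response.

    Expects eligible, in-forest points carrying ``topt_c``.  The prediction
    grid is every metre from 0 to 500 (501 values) with elevation at its
    mean and the SxO at the most frequent level, and the contrast defaults
    to (30 m, 500 m) on the gap scale.
    """
    if points["topt_c"].isna().any():
        raise ValueError("points are missing topt_c; run attach_topt first")
    if (points["dist_m"] <= 0).any():
        raise ValueError("gap curves use in-forest points only (dist_m > 0)")
    gap_points = points.assign(tsurf_c=points["tsurf_c"] - points["topt_c"])
    model = fit_edge_curve(gap_points, knot_range=knot_range, **fit_kwargs)
    curve = predict_partial(model, np.arange(0.0, 501.0))
    contrast = edge_interior_contrast(model, d_edge, d_interior, se_rule)
    return GapCurve(curve=curve, contrast=contrast, model=model,
                    n_points=len(points))


def synthetic_topt(study: SyntheticStudy, mode: str = "uniform", *,
                   value: float = 25.0, offset: float = 0.0) -> ToptGrid:
    """Coarse synthetic T_opt grid over a study's scene tiles.

    One cell per scene tile (cells therefore span many 30 m pixels).

    mode='uniform'
        Every cell takes ``value``.
    mode='offset-from-interior'
        Cell i takes the scene's deep-interior truth plus ``offset``:
        T_macro - A + offset.  ``offset`` < 0 yields a tropics-like scenario
        (observed T_surf above the optimum everywhere); ``offset = 0`` makes
        the deep interior sit at the optimum (temperate/boreal-like).
    """
    cfg = study.config
    extent = cfg.grid_size * cfg.pixel_size
    n = cfg.n_scenes
    vals = np.empty((1, n))
    for i in range(n):
        sid = f"S{i:04d}"
        truth = study.truths[sid]
        if mode == "uniform":
            vals[0, i] = value
        elif mode == "offset-from-interior":
            vals[0, i] = truth.t_macro - truth.amplitude + offset
        else:
            raise ValueError(f"unknown mode: {mode!r}")
    return RasterGrid(vals, origin=(0.0, 0.0), pixel_size=extent)
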