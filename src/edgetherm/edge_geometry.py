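"""Forest classification, signed distance to the forest edge, point sampling.

The classification rule is canopy cover >= 30 % (inclusive).  Signed distance
is the exact Euclidean distance between pixel centers to the nearest
opposite-class pixel: positive inside forest, negative outside.  Point
sampling draws uniformly without replacement within one scene-by-overpass
(SxO) and applies the study's inclusion filters *after* sampling (cloud,
nodata, |distance| <= 1000 m), logging a removal count per cause.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import RasterGrid

POINT_COLUMNS = ["scene_id", "overpass_id", "x", "y", "dist_m", "tsurf_c",
                 "elev_m", "season", "biome", "topt_c"]


class NoEdgeError(ValueError):
    """The mask contains a single class, so no edge (and no distance) exists."""


def classify_forest(canopy: RasterGrid, threshold: float = 30.0) -> RasterGrid:
    """Binary forest mask: 1 where canopy >= threshold, 0 below, nodata kept."""
    vals = canopy.values
    out = np.where(vals >= threshold, 1.0, 0.0)
    out[canopy.nodata_mask()] = canopy.nodata
    return canopy.like(out)


def signed_distance_to_edge(mask: RasterGrid) -> RasterGrid:
    """Signed Euclidean distance (m) from each pixel center to the edge.

    Forest pixels get +distance to the nearest non-forest pixel center,
    non-forest pixels -distance to the nearest forest pixel center.  Nodata
    pixels are excluded from both classes and stay nodata.  Uses the exact
    Euclidean distance transform (no approximation).
    """
    vals = mask.values
    nd = mask.nodata_mask()
    forest = (vals == 1.0) & ~nd
    nonforest = (vals == 0.0) & ~nd
    if not forest.any() or not nonforest.any():
        raise NoEdgeError("mask holds a single class; distance to edge is undefined")
    # EDT gives, per pixel, the distance to the nearest zero of its input.
    d_to_nonforest = ndimage.distance_transform_edt(~nonforest)
    d_to_forest = ndimage.distance_transform_edt(~forest)
    out = np.full(vals.shape, mask.nodata)
    out[forest] = d_to_nonforest[forest] * mask.pixel_size
    out[nonforest] = -d_to_forest[nonforest] * mask.pixel_size
    return mask.like(out)


@dataclass
class RemovalLog:
    """Per-cause accounting of points removed after sampling one SxO."""

    sampled: int
    cloud: int = 0
    nodata: int = 0
    distance: int = 0
    undersampled: bool = False  # fewer valid pixels than requested draws

    @property
    def kept(self) -> int:
        return self.sampled - self.cloud - self.nodata - self.distance

    def as_dict(self) -> dict:
        return {"sampled": self.sampled, "cloud": self.cloud,
                "nodata": self.nodata, "distance": self.distance,
                "kept": self.kept, "undersampled": self.undersampled}


def sample_scene_points(fields: dict[str, RasterGrid], mask: RasterGrid,
                        n: int = 1000, seed=None, *,
                        max_edge_distance: float = 1000.0,
                        scene_id: str = "S0", overpass_id: str = "O0",
                        season: str = "", biome: str = "",
                        ) -> tuple[pd.DataFrame, RemovalLog]:
    """Randomly sample pixels of one SxO and apply the inclusion filters.

    Parameters
    ----------
    fields : dict
        Rasters keyed ``tsurf``, ``elev``, ``cloud`` and optionally ``dist``
        (computed from ``mask`` when absent), all co-registered with ``mask``.
    n : int
        Number of points drawn uniformly *without replacement* over pixels.
    max_edge_distance : float
        Points farther than this from the edge (either side) are removed.

    Returns
    -------
    (points, log)
        ``points`` has the standard point-table schema; ``log`` records the
        per-cause removal counts, which sum exactly to sampled - kept.
    """
    rng = np.random.default_rng(seed)
    dist = fields.get("dist")
    if dist is None:
        dist = signed_distance_to_edge(mask)
    nrows, ncols = mask.shape
    npix = nrows * ncols
    take = min(n, npix)
    flat = rng.choice(npix, size=take, replace=False)
    log = RemovalLog(sampled=take, undersampled=take < n)
    rows, cols = np.divmod(flat, ncols)

    cloudy = fields["cloud"].values[rows, cols] != 0
    log.cloud = int(cloudy.sum())
    rows, cols = rows[~cloudy], cols[~cloudy]

    bad = np.zeros(rows.shape, dtype=bool)
    for key in ("tsurf", "elev"):
        g = fields[key]
        bad |= g.values[rows, cols] == g.nodata
    bad |= dist.values[rows, cols] == dist.nodata
    log.nodata = int(bad.sum())
    rows, cols = rows[~bad], cols[~bad]

    d = dist.values[rows, cols]
    far = np.abs(d) > max_edge_distance
    log.distance = int(far.sum())
    rows, cols, d = rows[~far], cols[~far], d[~far]

    xs, ys = mask.pixel_centers()
    points = pd.DataFrame({
        "scene_id": scene_id,
        "overpass_id": overpass_id,
        "x": xs[cols],
        "y": ys[rows],
        "dist_m": d,
        "tsurf_c": fields["tsurf"].values[rows, cols],
        "elev_m": fields["elev"].values[rows, cols],
        "season": season,
        "biome": biome,
        "topt_c": np.nan,
    })
    return points, log


def restrict_for_curve(points: pd.DataFrame, max_dist: float = 500.0) -> pd.DataFrame:
    """Keep points with dist_m <= 500 m (inclusive) for the edge-curve fits.

    Points outside the forest (negative distances, down to -1000 m) stay in;
    only the deep interior beyond ``max_dist`` is dropped.
    """
    return points[points["dist_m"] <= max_dist].reset_index(drop=True)
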