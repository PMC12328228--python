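"""Per-SxO edge slopes and the macroclimate meta-regression.

Each scene-by-overpass (SxO) contributes one ordinary-least-squares slope of
T_surf on log10(distance into the forest) with elevation as a covariate —
the per-scene edge-effect statistic dT/dD (deg C per log10 m).  Under this
module's sign convention distance increases into the forest, so cooling
toward the interior means a negative slope.  Slopes pass through a Hampel
outlier filter (median +- 3 MAD) and feed an inverse-variance-weighted
quadratic regression of dT/dD on the SxO's mean T_surf, the macroclimate
proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class InsufficientDataError(ValueError):
    """Fewer usable scenes than the analysis requires."""


@dataclass
class SceneSlope:
    """One SxO's dT/dD estimate with its sampling variance."""

    scene_id: str
    overpass_id: str
    beta: float
    var_beta: float
    n_obs: int
    scene_mean_t: float


@dataclass
class SlopeRejection:
    """Why an SxO produced no usable slope."""

    scene_id: str
    overpass_id: str
    n_obs: int
    reason: str


@dataclass
class MetaRegressionFit:
    """Inverse-variance-weighted quadratic fit of beta on scene-mean T_surf."""

    b0: float
    b1: float
    b2: float
    se_b0: float
    se_b1: float
    se_b2: float
    weighted_r2: float
    n_scenes: int
    cov: np.ndarray

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.b0, self.b1, self.b2])

    @property
    def se(self) -> np.ndarray:
        return np.array([self.se_b0, self.se_b1, self.se_b2])


def scene_slope(points: pd.DataFrame, *, min_obs: int = 4,
                scene_mean_t: float | None = None
                ) -> SceneSlope | SlopeRejection:
    """OLS slope of T_surf on log10(dist) + elevation for one SxO.

    ``points`` must already be restricted to in-forest distances
    (0 < dist_m <= 1000).  ``scene_mean_t`` defaults to the mean T_surf of
    the supplied points but callers normally pass the mean over *all*
    retained points of the SxO (inside and outside the forest), the
    macroclimate convention.  Returns a rejection record (never raises) for
    n < min_obs or a singular design.
    """
    sid = str(points["scene_id"].iloc[0]) if len(points) else "?"
    oid = str(points["overpass_id"].iloc[0]) if len(points) else "?"
    n = len(points)
    if n < min_obs:
        return SlopeRejection(sid, oid, n, f"fewer than {min_obs} observations")
    d = points["dist_m"].to_numpy(dtype=float)
    if (d <= 0).any():
        raise ValueError("scene_slope expects in-forest points (dist_m > 0)")
    y = points["tsurf_c"].to_numpy(dtype=float)
    logd = np.log10(d)
    elev = points["elev_m"].to_numpy(dtype=float)

    cols = [np.ones(n), logd]
    if np.ptp(elev) > 0:
        cols.append(elev)
    X = np.column_stack(cols)
    if np.ptp(logd) == 0 or np.linalg.matrix_rank(X) < X.shape[1]:
        return SlopeRejection(sid, oid, n, "singular design")
    p = X.shape[1]
    if n <= p:
        return SlopeRejection(sid, oid, n, "no residual degrees of freedom")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta_hat = xtx_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    sigma2 = float(resid @ resid) / (n - p)
    mean_t = float(y.mean()) if scene_mean_t is None else float(scene_mean_t)
    return SceneSlope(sid, oid, beta=float(beta_hat[1]),
                      var_beta=float(sigma2 * xtx_inv[1, 1]),
                      n_obs=n, scene_mean_t=mean_t)


def compute_scene_slopes(points: pd.DataFrame, *, min_obs: int = 4,
                         max_dist: float = 1000.0,
                         pool_overpasses: bool = False
                         ) -> tuple[list[SceneSlope], list[SlopeRejection]]:
    """Slopes for every SxO (or scene, when pooling overpasses) in a table.

    The regression uses in-forest points up to ``max_dist``; the
    macroclimate proxy ``scene_mean_t`` is the arithmetic mean T_surf of
    *all* the group's retained points, inside and outside the forest.
    """
    keys = ["scene_id"] if pool_overpasses else ["scene_id", "overpass_id"]
    slopes: list[SceneSlope] = []
    rejected: list[SlopeRejection] = []
    for _, grp in points.groupby(keys, sort=True):
        mean_t = float(grp["tsurf_c"].mean())
        inside = grp[(grp["dist_m"] > 0) & (grp["dist_m"] <= max_dist)]
        res = scene_slope(inside, min_obs=min_obs, scene_mean_t=mean_t) \
            if len(inside) else SlopeRejection(
                str(grp["scene_id"].iloc[0]), str(grp["overpass_id"].iloc[0]),
                0, f"fewer than {min_obs} observations")
        (slopes if isinstance(res, SceneSlope) else rejected).append(res)
    return slopes, rejected


def hampel_filter(slopes: list[SceneSlope], *, n_scale: float = 3.0,
                  scale: str = "mad"
                  ) -> tuple[list[SceneSlope], list[SceneSlope]]:
    """Hampel outlier filter on the betas: keep |beta - median| <= 3 * MAD.

    ``scale='mad'`` (default) uses the median absolute deviation, unscaled
    (no 1.4826 factor) — the standard Hampel construction; ``scale='mean'``
    uses the mean absolute deviation about the median for a literal reading
    of "mean absolute deviations".  One pass only.  With a degenerate scale
    (MAD = 0) every beta different from the median is removed.
    """
    if len(slopes) < 3:
        raise InsufficientDataError("Hampel filter needs at least 3 slopes")
    beta = np.array([s.beta for s in slopes])
    med = float(np.median(beta))
    dev = np.abs(beta - med)
    if scale == "mad":
        spread = float(np.median(dev))
    elif scale == "mean":
        spread = float(np.mean(dev))
    else:
        raise ValueError(f"unknown scale: {scale!r}")
    keep = dev <= n_scale * spread
    kept = [s for s, k in zip(slopes, keep) if k]
    removed = [s for s, k in zip(slopes, keep) if not k]
    return kept, removed


def ivw_quadratic(slopes: list[SceneSlope]) -> MetaRegressionFit:
    """Inverse-variance-weighted quadratic regression of beta on scene-mean T.

    Weighted least squares of beta on (1, t, t^2) with weights 1/var_beta;
    coefficient covariance is the weighted normal-equations inverse scaled
    by the weighted residual variance, and the weighted R^2 is
    1 - wRSS / wTSS with wTSS taken about the weighted mean.
    """
    m = len(slopes)
    if m < 4:
        raise InsufficientDataError(
            f"need at least 4 scenes for the quadratic fit, got {m}")
    beta = np.array([s.beta for s in slopes])
    t = np.array([s.scene_mean_t for s in slopes])
    var = np.array([s.var_beta for s in slopes])
    if (var <= 0).any():
        raise ValueError("all slope variances must be positive")
    w = 1.0 / var
    X = np.column_stack([np.ones(m), t, t * t])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ beta)
    resid = beta - X @ coef
    wrss = float(w @ resid ** 2)
    scale = wrss / (m - 3)
    cov = cov_unscaled * scale
    se = np.sqrt(np.diag(cov))
    wmean = float(w @ beta) / float(w.sum())
    wtss = float(w @ (beta - wmean) ** 2)
    r2 = 1.0 - wrss / wtss if wtss > 0 else np.nan
    return MetaRegressionFit(b0=float(coef[0]), b1=float(coef[1]),
                             b2=float(coef[2]), se_b0=float(se[0]),
                             se_b1=float(se[1]), se_b2=float(se[2]),
                             weighted_r2=float(r2), n_scenes=m, cov=cov)


def subset_cooling(slopes: list[SceneSlope]) -> list[SceneSlope]:
    """SxOs where temperature decreases toward the interior (beta < 0).

    scene_mean_t is left untouched — the macroclimate proxy keeps using all
    sampled points of the scene, inside and outside the forest.
    """
    return [s for s in slopes if s.beta < 0]


def no_outlier_variant(slopes: list[SceneSlope]) -> MetaRegressionFit:
    """The meta-regression without any outlier filter (robustness variant)."""
    return ivw_quadratic(slopes)


def slopes_to_frame(slopes: list[SceneSlope],
                    rejected: list[SlopeRejection] | None = None,
                    removed: list[SceneSlope] | None = None) -> pd.DataFrame:
    """Slope table with kept flags and rejection reasons, ready for CSV."""
    rows = []
    removed_keys = {(s.scene_id, s.overpass_id) for s in (removed or [])}
    for s in slopes:
        rows.append({"scene_id": s.scene_id, "overpass_id": s.overpass_id,
                     "beta": s.beta, "var_beta": s.var_beta, "n_obs": s.n_obs,
                     "scene_mean_t": s.scene_mean_t,
                     "kept": (s.scene_id, s.overpass_id) not in removed_keys,
                     "reject_reason": ""})
    for s in (removed or []):
        for row in rows:
            if (row["scene_id"], row["overpass_id"]) == (s.scene_id, s.overpass_id):
                row["reject_reason"] = "hampel outlier"
    for r in (rejected or []):
        rows.append({"scene_id": r.scene_id, "overpass_id": r.overpass_id,
                     "beta": np.nan, "var_beta": np.nan, "n_obs": r.n_obs,
                     "scene_mean_t": np.nan, "kept": False,
                     "reject_reason": r.reason})
    return pd.DataFrame(rows)
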