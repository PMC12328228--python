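"""Synthetic fragmented-forest landscapes with known edge-effect ground truth.

Every downstream stage (edge geometry, curve model, slope meta-regression,
productivity gap) is exercised on landscapes generated here, where the true
edge temperature profile, elevation lapse, per-SxO offsets and noise levels
are known exactly.

Ground-truth temperature model
------------------------------
At signed distance-to-edge d (m, positive inside forest) the noise-free
surface temperature is

    T(d) = T_macro - A * S(d),      S(d) = 1 / (1 + exp(-d / lam)),

so T(-inf) = T_macro outside the forest and T(+inf) = T_macro - A deep in
the interior.  A > 0 means the interior is cooler than the surroundings
(the common case); A < 0 encodes the boreal-winter reversal where dark
canopy is warmer than snow-covered open land.  An elevation lapse is applied
relative to the scene-mean elevation so that elevation and edge effects are
separable by construction, and each scene-by-overpass (SxO) carries an
additive offset with SD ``sigma_scene`` on top of i.i.d. noise with SD
``sigma_noise``.

The edge amplitude may be linked to the scene's macroclimate through
A = a0 + a1*T_macro + a2*T_macro**2, the relationship the slope
meta-regression stage is designed to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .edge_geometry import (POINT_COLUMNS, RemovalLog, classify_forest,
                            sample_scene_points, signed_distance_to_edge)
from .raster import NODATA, RasterGrid

# days per month, non-leap year
_MONTH_DAYS = np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class EdgeEffectTruth:
    """Ground-truth parameters of one scene's edge temperature profile.

    t_macro : scene baseline temperature outside the forest (deg C)
    amplitude : edge amplitude A, non-forest minus deep-interior (deg C;
        negative for winter-reversal scenarios)
    lam : sigmoid length scale (m); the profile saturates within ~5*lam
    lapse : elevation lapse rate (deg C per m), applied about the scene mean
    sigma_noise : per-point noise SD (deg C)
    sigma_scene : SD of additive per-SxO offsets (deg C)
    a0, a1, a2 : optional coefficients of the macroclimate link
        A = a0 + a1*T_macro + a2*T_macro**2 that produced ``amplitude``
    """

    t_macro: float
    amplitude: float
    lam: float = 90.0
    lapse: float = -0.0065
    sigma_noise: float = 1.4
    sigma_scene: float = 2.0
    a0: float | None = None
    a1: float | None = None
    a2: float | None = None

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lam must be positive")
        if self.sigma_noise < 0 or self.sigma_scene < 0:
            raise ValueError("noise SDs must be non-negative")

    def temperature(self, dist_m) -> np.ndarray:
        """Noise-free temperature at signed distance(s), at mean elevation."""
        return self.t_macro - self.amplitude * sigmoid(np.asarray(dist_m) / self.lam)

    def contrast(self, d_edge: float, d_interior: float) -> float:
        """Analytic T(d_edge) - T(d_interior) contrast."""
        return float(self.temperature(d_edge) - self.temperature(d_interior))


@dataclass
class StudyConfig:
    """Sampling design of one synthetic study (the study conditions)."""

    n_scenes: int
    n_overpasses: int = 2
    grid_size: int = 64
    pixel_size: float = 30.0
    n_points_per_sxo: int = 1000
    canopy_threshold: float = 30.0
    max_edge_distance: float = 1000.0
    cloud_fraction: float = 0.1
    seed: int = 0
    n_patches: int = 3
    patch_scale: float = 300.0
    lat_range: tuple[float, float] = (-60.0, 70.0)
    biome_bands: dict = field(
        default_factory=lambda: {"tropical": 23.5, "temperate": 50.0})

    def __post_init__(self) -> None:
        for name in ("n_scenes", "n_overpasses", "grid_size", "n_points_per_sxo"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.cloud_fraction < 1:
            raise ValueError("cloud_fraction must lie in [0, 1)")


def biome_of(lat: float, bands: dict | None = None) -> str:
    """Latitude-band biome label (|lat|<=23.5 tropical, <=50 temperate, else boreal)."""
    bands = bands or {"tropical": 23.5, "temperate": 50.0}
    a = abs(lat)
    for name, limit in sorted(bands.items(), key=lambda kv: kv[1]):
        if a <= limit:
            return name
    return "boreal"


def season_of(day_of_year: int, lat: float) -> str:
    """Hemisphere-flipped meteorological season for a day-of-year (1..365)."""
    month = int(np.searchsorted(_MONTH_DAYS, ((day_of_year - 1) % 365) + 1)) + 1
    north = {12: "winter", 1: "winter", 2: "winter",
             3: "spring", 4: "spring", 5: "spring",
             6: "summer", 7: "summer", 8: "summer"}.get(month, "autumn")
    if lat >= 0:
        return north
    return {"winter": "summer", "summer": "winter",
            "spring": "autumn", "autumn": "spring"}[north]


def overpass_days(n_overpasses: int) -> list[int]:
    """Days-of-year of the overpasses, spread evenly across the year."""
    return [int((j + 0.5) * 365 / n_overpasses) + 1 for j in range(n_overpasses)]


def generate_forest_mask(grid_size: int, n_patches: int, patch_scale: float,
                         seed=None, *, pixel_size: float = 30.0,
                         patches: list[tuple] | None = None,
                         max_tries: int = 25) -> RasterGrid:
    """Canopy-cover raster (%) from a union of random elliptical patches.

    A pixel belongs to a patch iff its *center* falls inside the ellipse
    (pixel-center inclusion).  Forest pixels draw canopy in [60, 100], the
    matrix in [0, 25), so the 30 % threshold separates the classes cleanly.

    Parameters
    ----------
    patches : optional list of (row_c, col_c, semi_major_px, semi_minor_px,
        angle_rad) overriding the random draw (used for deterministic
        geometries in tests and scenarios).
    """
    if grid_size < 16:
        raise ValueError("grid_size must be at least 16 pixels")
    if n_patches < 0:
        raise ValueError("n_patches must be non-negative")
    rng = _as_rng(seed)
    g = grid_size
    ii, jj = np.indices((g, g)) + 0.5  # pixel centers, pixel units

    def rasterize(plist):
        inside = np.zeros((g, g), dtype=bool)
        for (ci, cj, a, b, th) in plist:
            di, dj = ii - ci, jj - cj
            u = np.cos(th) * dj + np.sin(th) * di
            v = -np.sin(th) * dj + np.cos(th) * di
            inside |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
        return inside

    if patches is not None:
        inside = rasterize(patches)
    elif n_patches == 0:
        inside = np.zeros((g, g), dtype=bool)
    else:
        scale_px = patch_scale / pixel_size
        for _ in range(max_tries):
            plist = []
            for _ in range(n_patches):
                ci, cj = rng.uniform(0.1 * g, 0.9 * g, size=2)
                a = scale_px * rng.uniform(0.7, 1.3)
                b = a * rng.uniform(0.6, 1.0)
                th = rng.uniform(0, np.pi)
                plist.append((ci, cj, a, b, th))
            inside = rasterize(plist)
            if inside.any() and not inside.all():
                break
        else:
            raise RuntimeError(
                "could not draw a mask containing both classes; "
                "reduce patch_scale or n_patches")

    canopy = np.where(inside, 60.0 + 40.0 * rng.random((g, g)),
                      25.0 * rng.random((g, g)))
    return RasterGrid(canopy, pixel_size=pixel_size)


def generate_elevation(grid_size: int, seed=None, *, pixel_size: float = 30.0,
                       base: float = 300.0, relief: float = 120.0,
                       corr_px: float | None = None) -> RasterGrid:
    """Smooth low-frequency elevation field (m), mean ~ base, SD ~ relief."""
    rng = _as_rng(seed)
    corr_px = corr_px if corr_px is not None else grid_size / 8
    z = ndimage.gaussian_filter(rng.standard_normal((grid_size, grid_size)),
                                sigma=corr_px, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = z / sd
    return RasterGrid(base + relief * z, pixel_size=pixel_size)


def generate_scene_fields(mask: RasterGrid, truth: EdgeEffectTruth, seed=None, *,
                          threshold: float = 30.0, cloud_fraction: float = 0.0,
                          scene_offset: float = 0.0,
                          elevation: RasterGrid | None = None,
                          ) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Surface-temperature, elevation and cloud rasters for one SxO.

    The noise-free component at a pixel with signed distance d and elevation
    e is ``T_macro - A*S(d) + lapse*(e - mean e) + scene_offset``; i.i.d.
    noise with SD ``sigma_noise`` is added on top, and a ``cloud_fraction``
    share of pixels is cloud-flagged.

    Raises :class:`~edgetherm.edge_geometry.NoEdgeError` when the classified
    mask holds a single class.
    """
    rng = _as_rng(seed)
    binary = classify_forest(mask, threshold)
    dist = signed_distance_to_edge(binary)
    if elevation is None:
        elevation = generate_elevation(mask.shape[0], rng,
                                       pixel_size=mask.pixel_size)
    elev = elevation.values
    tsurf = (truth.temperature(dist.values)
             + truth.lapse * (elev - elev.mean())
             + scene_offset)
    if truth.sigma_noise > 0:
        tsurf = tsurf + rng.normal(0.0, truth.sigma_noise, size=tsurf.shape)
    cloud = (rng.random(tsurf.shape) < cloud_fraction).astype(float)
    return (mask.like(tsurf), elevation, mask.like(cloud))


def default_truth_sampler(a0: float = -0.5, a1: float = 0.05, a2: float = 0.003,
                          lam: float = 90.0, lapse: float = -0.0065,
                          sigma_noise: float = 1.4, sigma_scene: float = 2.0):
    """Truth rule linking edge amplitude to a latitude-driven macroclimate.

    T_macro = 28 - 0.4*|lat| + N(0, 2) and A = a0 + a1*T + a2*T^2; the
    defaults give A ~ 4.9 deg C at T_macro = 35 (tropical summer) and a mild
    reversal (A < 0) at cold macroclimates, mirroring the qualitative
    biome/season structure of the edge effect.
    """

    def sampler(scene_index: int, lat: float, rng: np.random.Generator
                ) -> EdgeEffectTruth:
        t = 28.0 - 0.4 * abs(lat) + rng.normal(0.0, 2.0)
        amp = a0 + a1 * t + a2 * t * t
        return EdgeEffectTruth(t_macro=t, amplitude=amp, lam=lam, lapse=lapse,
                               sigma_noise=sigma_noise, sigma_scene=sigma_scene,
                               a0=a0, a1=a1, a2=a2)

    return sampler


@dataclass
class SyntheticStudy:
    """A generated study: point table plus the ground truth that made it."""

    points: pd.DataFrame
    truths: dict
    sxo_offsets: dict
    scene_meta: pd.DataFrame
    removal_log: pd.DataFrame
    config: StudyConfig


def generate_study(config: StudyConfig, truth_sampler=None,
                   mask_patches=None) -> SyntheticStudy:
    """Generate a full multi-scene, multi-overpass study.

    Each scene occupies its own tile in a shared coordinate frame (scene i
    starts at x = i * grid extent), has a latitude drawn from
    ``config.lat_range``, a forest mask and elevation field fixed across
    overpasses, and per-SxO additive offsets and noise.  Points are returned
    already filtered for cloud, nodata and |dist| <= max_edge_distance, with
    per-cause removal counts in ``removal_log``.

    ``mask_patches``, when given, is a callable scene_index -> explicit
    patch list (row_c, col_c, semi_major_px, semi_minor_px, angle_rad)
    overriding the random patch draw (used for deterministic geometries).

    All randomness flows from ``config.seed`` through per-scene and per-SxO
    derived streams, so scenes are independently reproducible.
    """
    truth_sampler = truth_sampler or default_truth_sampler()
    extent = config.grid_size * config.pixel_size
    days = overpass_days(config.n_overpasses)

    frames, logs = [], []
    truths: dict = {}
    offsets: dict = {}
    meta_rows = []
    for i in range(config.n_scenes):
        scene_id = f"S{i:04d}"
        scene_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, i]))
        lat = scene_rng.uniform(*config.lat_range)
        truth = truth_sampler(i, lat, scene_rng)
        if not isinstance(truth, EdgeEffectTruth):
            raise TypeError("truth_sampler must return an EdgeEffectTruth")
        truths[scene_id] = truth
        mask = generate_forest_mask(
            config.grid_size, config.n_patches, config.patch_scale, scene_rng,
            pixel_size=config.pixel_size,
            patches=mask_patches(i) if mask_patches is not None else None)
        mask.origin = (i * extent, 0.0)
        elev = generate_elevation(config.grid_size, scene_rng,
                                  pixel_size=config.pixel_size)
        elev.origin = mask.origin
        binary = classify_forest(mask, config.canopy_threshold)
        dist = signed_distance_to_edge(binary)
        biome = biome_of(lat, config.biome_bands)
        meta_rows.append({"scene_id": scene_id, "lat": lat, "biome": biome,
                          "origin_x": mask.origin[0], "origin_y": 0.0,
                          "t_macro": truth.t_macro,
                          "amplitude": truth.amplitude,
                          "elev_mean": float(elev.values.mean())})
        for j in range(config.n_overpasses):
            overpass_id = f"O{j:02d}"
            rng_o = np.random.default_rng(
                np.random.SeedSequence([config.seed, i, j]))
            off = rng_o.normal(0.0, truth.sigma_scene) if truth.sigma_scene else 0.0
            offsets[(scene_id, overpass_id)] = off
            tsurf, _, cloud = generate_scene_fields(
                mask, truth, rng_o, threshold=config.canopy_threshold,
                cloud_fraction=config.cloud_fraction, scene_offset=off,
                elevation=elev)
            season = season_of(days[j], lat)
            pts, log = sample_scene_points(
                {"tsurf": tsurf, "elev": elev, "cloud": cloud, "dist": dist},
                binary, n=config.n_points_per_sxo, seed=rng_o,
                max_edge_distance=config.max_edge_distance,
                scene_id=scene_id, overpass_id=overpass_id,
                season=season, biome=biome)
            frames.append(pts)
            logs.append({"scene_id": scene_id, "overpass_id": overpass_id,
                         **log.as_dict()})

    points = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=POINT_COLUMNS))
    return SyntheticStudy(points=points, truths=truths, sxo_offsets=offsets,
                          scene_meta=pd.DataFrame(meta_rows),
                          removal_log=pd.DataFrame(logs), config=config)


def simulate_slope_study(n_scenes: int, a0: float = 0.6, a1: float = -0.22,
                         a2: float = 0.004, *, seed=None,
                         t_range: tuple[float, float] = (0.0, 35.0),
                         n_points_range: tuple[int, int] = (100, 600),
                         dist_range: tuple[float, float] = (30.0, 1000.0),
                         sigma_noise: float = 1.4,
                         elev_sd: float = 80.0, lapse: float = -0.0065,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Point table whose per-scene ground truth is a log-linear edge slope.

    For scene s with macroclimate T_s ~ U(t_range) the in-forest profile is

        T(d) = T_s + beta_s * (log10 d - mean log10 d) + lapse*(e - mean e)

    with beta_s = a0 + a1*T_s + a2*T_s**2 exactly: the per-SxO regression of
    T_surf on log10(distance) recovers beta_s, and the inverse-variance-
    weighted quadratic meta-regression recovers (a0, a1, a2) directly.  This
    complements the sigmoid field generator, whose log10-distance slope is
    only a scaled projection of the edge amplitude (see docs/methods.md).

    Returns (points, truth) where truth has one row per scene with columns
    scene_id, t_macro, beta_true, n_obs.
    """
    rng = _as_rng(seed)
    lo, hi = np.log10(dist_range[0]), np.log10(dist_range[1])
    center = 0.5 * (lo + hi)
    frames, rows = [], []
    for i in range(n_scenes):
        scene_id = f"S{i:04d}"
        t = rng.uniform(*t_range)
        beta = a0 + a1 * t + a2 * t * t
        n = int(rng.integers(n_points_range[0], n_points_range[1] + 1))
        logd = rng.uniform(lo, hi, size=n)
        elev = rng.normal(300.0, elev_sd, size=n)
        tsurf = (t + beta * (logd - center) + lapse * (elev - elev.mean())
                 + rng.normal(0.0, sigma_noise, size=n))
        frames.append(pd.DataFrame({
            "scene_id": scene_id, "overpass_id": "O00",
            "x": np.nan, "y": np.nan, "dist_m": 10.0 ** logd,
            "tsurf_c": tsurf, "elev_m": elev,
            "season": "summer", "biome": "", "topt_c": np.nan}))
        rows.append({"scene_id": scene_id, "t_macro": t, "beta_true": beta,
                     "n_obs": n})
    return pd.concat(frames, ignore_index=True), pd.DataFrame(rows)
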