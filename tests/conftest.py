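import numpy as np
import pandas as pd
import pytest

from edgetherm.raster import RasterGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def three_by_three_mask():
    """Only the center pixel is forest; pixel size 30 m."""
    return RasterGrid(np.array([[0, 0, 0], [0, 1, 0], [0, 0, 0]], dtype=float),
                      pixel_size=30.0)


def make_points(rng, n_scenes=4, n_per_scene=200, dist_range=(-400.0, 400.0),
                tsurf_fn=None, offsets=None, elev_sd=50.0):
    """Small synthetic point table with a caller-supplied response rule."""
    frames = []
    for s in range(n_scenes):
        d = rng.uniform(*dist_range, size=n_per_scene)
        elev = rng.normal(300.0, elev_sd, size=n_per_scene)
        off = offsets[s] if offsets is not None else 0.0
        y = (tsurf_fn(d, elev) if tsurf_fn is not None
             else np.full(n_per_scene, 20.0)) + off
        frames.append(pd.DataFrame({
            "scene_id": f"S{s:02d}", "overpass_id": "O00",
            "x": rng.uniform(0, 5000, n_per_scene),
            "y": rng.uniform(0, 5000, n_per_scene),
            "dist_m": d, "tsurf_c": y, "elev_m": elev,
            "season": "summer", "biome": "tropical", "topt_c": np.nan}))
    return pd.concat(frames, ignore_index=True)
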