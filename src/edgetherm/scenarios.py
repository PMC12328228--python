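"""Canonical study scenarios shared by examples, tests and the pipeline.

Each function builds a :class:`~edgetherm.synthetic_landscape.StudyConfig`
(and where needed a truth sampler) encoding one named study condition:

* ``curve_recovery`` — 50 scenes x 1000 points with a fixed sigmoid truth
  (A = 3 deg C, lam = 50 m, noise SD 1 deg C), the condition under which the
  fitted partial-residual curve and the 30 m/500 m contrast are checked
  against the analytic profile.
* ``winter_reversal`` — boreal scenes in winter with A < 0 (dark canopy
  warmer than snow-covered open land), producing a negative edge-interior
  contrast.
* ``deep_forest`` — scenes built around one large elliptical core so that
  interiors reach beyond 800 m and the productivity-gap eligibility rules
  are satisfiable by construction.
"""

from __future__ import annotations

import numpy as np

from .synthetic_landscape import (EdgeEffectTruth, StudyConfig, generate_study,
                                  SyntheticStudy)


def fixed_truth_sampler(amplitude: float, *, t_macro: float = 25.0,
                        lam: float = 50.0, lapse: float = -0.0065,
                        sigma_noise: float = 1.0, sigma_scene: float = 2.0):
    """Truth rule assigning every scene the same edge-effect parameters."""

    def sampler(scene_index: int, lat: float, rng: np.random.Generator
                ) -> EdgeEffectTruth:
        return EdgeEffectTruth(t_macro=t_macro, amplitude=amplitude, lam=lam,
                               lapse=lapse, sigma_noise=sigma_noise,
                               sigma_scene=sigma_scene)

    return sampler


def curve_recovery_study(seed: int, *, n_scenes: int = 50,
                         amplitude: float = 3.0, lam: float = 50.0,
                         sigma_noise: float = 1.0) -> SyntheticStudy:
    """Sigmoid-truth study for curve and contrast recovery checks.

    One overpass per scene (so 50 SxO), no cloud dropout, patches large
    enough that in-forest distances cover the full 0-500 m curve range.
    """
    config = StudyConfig(n_scenes=n_scenes, n_overpasses=1, grid_size=64,
                         n_points_per_sxo=1000, cloud_fraction=0.0,
                         seed=seed, n_patches=2, patch_scale=650.0,
                         lat_range=(20.0, 40.0))
    sampler = fixed_truth_sampler(amplitude, lam=lam, sigma_noise=sigma_noise)
    return generate_study(config, sampler)


def winter_reversal_study(seed: int, *, n_scenes: int = 12,
                          amplitude: float = -2.0) -> SyntheticStudy:
    """Boreal-winter scenario: negative edge amplitude (edge colder)."""
    config = StudyConfig(n_scenes=n_scenes, n_overpasses=1, grid_size=64,
                         n_points_per_sxo=1000, cloud_fraction=0.0,
                         seed=seed, n_patches=2, patch_scale=650.0,
                         lat_range=(55.0, 65.0))
    sampler = fixed_truth_sampler(amplitude, t_macro=-5.0, lam=90.0,
                                  sigma_noise=1.0, sigma_scene=1.0)
    return generate_study(config, sampler)


def deep_forest_study(seed: int, *, n_scenes: int = 8, n_overpasses: int = 2,
                      amplitude: float = 3.0, t_macro: float = 28.0,
                      lam: float = 90.0, sigma_scene: float = 0.25
                      ) -> SyntheticStudy:
    """Large-core scenario whose scenes pass the gap eligibility rules.

    The forest mask is one ellipse with a 900 m semi-minor axis, so the
    deepest interior pixels lie ~870 m from the edge and every scene can
    contribute >=800 m observations.
    """
    config = StudyConfig(n_scenes=n_scenes, n_overpasses=n_overpasses,
                         grid_size=64, n_points_per_sxo=1000,
                         cloud_fraction=0.0, seed=seed, n_patches=1,
                         patch_scale=900.0, lat_range=(5.0, 15.0))

    sampler = fixed_truth_sampler(amplitude, t_macro=t_macro, lam=lam,
                                  sigma_noise=1.0, sigma_scene=sigma_scene)
    r = config.patch_scale / config.pixel_size
    g = config.grid_size

    def core(_scene_index: int):
        return [(g / 2, g / 2, r, r, 0.0)]

    return generate_study(config, sampler, mask_patches=core)
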