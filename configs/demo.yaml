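# Demo study configuration — the full default set, spelled out.
# Any key not present in the defaults is rejected (silent misconfiguration
# is worse than failure).

study:
  n_scenes: 12            # satellite scenes (one tile each)
  n_overpasses: 8         # overpass dates, spread over the year (2/season)
  grid_size: 64           # pixels per tile side (64 x 30 m = 1920 m)
  pixel_size: 30.0        # m
  n_points_per_sxo: 1000  # random draws per scene-by-overpass
  canopy_threshold: 30.0  # % canopy cover, inclusive forest threshold
  max_edge_distance: 1000.0   # m, |distance| retention window
  cloud_fraction: 0.1
  seed: 42
  n_patches: 2
  patch_scale: 900.0      # m; large cores so >=800 m interiors occur
  lat_range: [-30.0, 65.0]

truth:                    # macroclimate-linked sigmoid edge profile
  a0: -0.5                # A = a0 + a1*T_macro + a2*T_macro^2 (deg C)
  a1: 0.05
  a2: 0.003
  lam: 90.0               # sigmoid length scale (m)
  lapse: -0.0065          # deg C per m, about the scene-mean elevation
  sigma_noise: 1.4        # per-point noise SD (deg C)
  sigma_scene: 2.0        # per-SxO offset SD (deg C)

curve:
  group_by: [biome, season]
  edge: 30.0              # m, edge evaluation point
  interior: 500.0         # m, interior evaluation point
  variant_edge: 50.0
  variant_interior: 1000.0
  se_rule: as-printed     # or: quadrature
  nbasis_dist: 20
  nbasis_elev: 10
  criterion: gcv          # or: reml
  moran_max_points: 1500
  moran_permutations: 99

meta:
  min_obs: 4
  max_dist: 1000.0
  pool_overpasses: false
  hampel_scale: mad       # or: mean

gap:
  season: summer
  topt_mode: offset-from-interior   # or: uniform
  topt_value: 25.0        # used by mode: uniform
  topt_offset: -2.0       # deg C below the deep-interior truth
  min_obs: 500
  min_overpasses: 2
  min_deep: 800.0
  group_by: [biome]

output:
  write_rasters: false
  figures: false
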