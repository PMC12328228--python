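# Methods

`edgetherm` re-implements, as a tested pipeline, an inference chain for
forest-edge surface-temperature (T_surf) effects: how T_surf changes with
distance from the forest edge, how the strength of that edge effect scales
with macroclimate, and how edge versus interior temperatures compare with
the thermal optimum for ecosystem productivity (T_opt). Because the
original inputs are continental-scale satellite products, every stage is
exercised on a synthetic-landscape generator with known ground truth; this
note records the model, the generator, and the numerical choices.

## Edge geometry

Forest is classified from canopy cover at an inclusive 30 % threshold.
Signed distance to the edge is the exact Euclidean distance between pixel
centers to the nearest opposite-class pixel — positive inside forest,
negative outside — computed with the exact Euclidean distance transform
(`scipy.ndimage.distance_transform_edt`); no approximate transform is used,
and the test suite checks exact agreement with a brute-force all-pairs
search. Measuring between pixel centers makes the minimum attainable
in-forest distance one pixel (30 m), which is also the edge evaluation
point of the contrasts. Nodata pixels belong to neither class and receive
nodata distances.

Point sampling draws uniformly **without replacement** over the pixels of
one scene-by-overpass (SxO), then filters — cloud, nodata, |distance| >
1000 m — in that order, logging one removal count per cause. Sampling
without replacement avoids duplicate coordinates that would distort the
Moran's I diagnostic within an SxO (duplicates can still occur across
overpasses of one scene and are handled by the Moran weight rule below).
For the curve fits, points are further restricted to distances of at most
500 m into the forest (inclusive); points outside the forest stay in.

## The edge-curve model

T_surf is modelled additively:

    T_surf_i = f_d(dist_i) + f_e(elev_i) + g_{sxo(i)} + eps_i

* `f_d`: cubic B-spline smooth of signed distance, 20 basis functions over
  a fixed [-1000, 1000] m support, second-difference penalty. The fixed
  support keeps the 500 m and 1000 m contrast points inside the basis even
  for the 500 m-restricted fit; regions without data are filled by
  penalized extrapolation and carry correspondingly wide standard errors.
* `f_e`: the same construction for elevation, 10 basis functions over the
  data range. A constant-elevation input drops the term.
* `g`: one coefficient per SxO with a ridge penalty — the standard
  mixed-model representation of an additive random effect. It absorbs
  everything that makes one SxO's level different from another's
  (overpass weather, season, scene offset), so the distance smooth is
  estimated strictly within-SxO.

Each spline block is reparameterised through the null space of its basis
column means (sum-to-zero over the sample), which removes the confounding
with the intercept exactly.

Smoothing parameters minimise GCV on a 20-point log-spaced grid per term
(distance/elevation: 1e-2..1e10; scene ridge: 1e-6..1e8) by coordinate
descent, normally converging in two sweeps. GCV uses an effective-dof
inflation of gamma = 1.4: with gamma = 1 the selected distance penalty hit
the grid floor and the curve showed pure-variance excursions of ~0.3 °C in
the data-sparse 400–500 m band; 1.4 is the standard remedy for GCV
undersmoothing in the penalized-regression literature. An approximate REML
criterion (profiled variance with penalty pseudo-determinants) is
selectable. The low floor of the scene-ridge grid is what lets noiseless
per-SxO offsets be absorbed to below 1e-6 °C.

The coefficient covariance is `sigma2 * (X'X + P)^-1` with
`sigma2 = RSS / (n - edf)` — the usual Bayesian covariance of penalized
splines.

**Partial prediction.** Curves are predicted every metre from -200 to 500
(701 values) with elevation fixed at its sample mean and the SxO at the
most frequent level. Absolute curve levels therefore inherit that
reference SxO's own offset and the difference between the global mean
elevation and the reference scene's mean; contrasts between two distances
cancel both and are the level-free quantities.

**Contrast standard errors.** Three variants are always computed for the
edge-minus-interior contrast: the source convention
`sqrt(SE_edge + SE_interior)` (no squaring; the "as-printed" fidelity
default), conventional quadrature `sqrt(SE_edge^2 + SE_interior^2)`, and a
covariance-aware SE propagating the full coefficient covariance through
the difference row. The covariance-aware SE is the statistically honest
one and is what the recovery tests calibrate against; the as-printed rule
is typically ~3-5x larger and thus conservative.

**Moran's I.** Residual spatial autocorrelation is assessed on a random
subset (default cap 75 000 points) with row-standardised inverse-distance
weights, zero diagonal; coincident pairs get weight 1/(half the minimum
nonzero pairwise distance). The null expectation is -1/(n-1) and p-values
come from 999 permutations of residuals over locations (one-sided for
positive autocorrelation). Computation is chunked so no n x n matrix is
materialised; the permutation test is O(n^2 * n_perm) and is meant for
subsets of a few thousand points.

## Per-scene slopes and the macroclimate meta-regression

For each SxO, T_surf is regressed by OLS on log10(distance) and elevation
using in-forest points up to 1000 m; the log10-distance coefficient is the
scene's edge-effect statistic dT/dD (°C per log10 m) with its sampling
variance. SxOs with fewer than 4 observations or a singular design are
rejected with a recorded reason, never an exception. Distance increases
into the forest, so interior cooling means a negative slope; this sign
convention is a documented choice, not a claim about any particular
figure's axis orientation. The macroclimate proxy `scene_mean_t` is the
arithmetic mean T_surf of **all** the SxO's retained points, inside and
outside the forest.

The Hampel filter removes slopes outside median ± 3·MAD, where MAD is the
median absolute deviation, unscaled (no 1.4826 factor) — the standard
Hampel construction; a `scale="mean"` switch provides the mean absolute
deviation about the median for a literal reading of "mean absolute
deviations". With MAD = 0 the interval is degenerate and everything off
the median is removed. One caveat the synthetic studies expose: when a
strong true trend spreads the slopes, median ± 3·MAD can clip genuine
extremes (about 20 % of scenes in the recovery study), slightly flattening
the fitted curvature. The recovery benchmarks therefore run the
meta-regression unfiltered; the filtered and cooling-only variants are
reported alongside.

The meta-regression is weighted least squares of dT/dD on
(1, t, t^2) with t = scene_mean_t and weights 1/var(dT/dD), as in
meta-analysis. Coefficient SEs scale the weighted normal-equations inverse
by the weighted residual variance (wRSS/(m-3)), and the weighted R^2 is
1 - wRSS/wTSS with wTSS about the weighted mean — stated explicitly since
R^2 under weighting is convention-dependent. Weights are relative:
rescaling every variance by a constant leaves the coefficients unchanged.

## Productivity gap

T_opt lives on a coarse grid (one value per cell spanning many pixels;
1/12° in the source data, scene-tile-sized cells in synthetic mode). Each
point takes the value of the cell containing it — containment, not
interpolation — with half-open cells: a point on a shared boundary belongs
to the cell to its east/south. Points in undefined cells are dropped with
a count.

Scenes enter the gap analysis only with >= 500 in-forest observations from
>= 2 distinct overpasses and >= 1 observation at >= 800 m into the forest
(all thresholds inclusive); non-forest points are excluded throughout. The
gap curve reuses the additive model with response T_surf - T_opt, distance
support [0, 1000] m, prediction grid 0..500 m, and the same contrast
machinery. When T_opt is globally uniform the gap contrast equals the raw
T_surf contrast exactly (a conservation identity in the test suite).

## The synthetic generator: what it emulates, and what it does not

Ground truth per scene: `T(d) = T_macro - A * S(d)` with
`S(d) = 1/(1+exp(-d/lam))`, so T_surf rises smoothly from the deep
interior (T_macro - A) through the edge (half the amplitude at d = 0) to
the open surroundings (T_macro), saturating within ~5·lam. Defaults:
`lam = 90 m` (curves flatten within ~500 m, matching the distance at which
edge influence is no longer detectable), elevation lapse -0.0065 °C/m
applied about the scene-mean elevation (the standard environmental lapse
rate; centering makes elevation and edge effects separable by
construction), per-point noise SD 1.4 °C (the retrieval error reported for
the 30 m Landsat T_surf product), per-SxO offset SD 2 °C, cloud dropout
10 %. The amplitude links to macroclimate through
`A = a0 + a1*T_macro + a2*T_macro^2` (defaults -0.5, 0.05, 0.003): ~5 °C
edge warming at tropical macroclimates and a mild reversal (A < 0) at cold
ones — the boreal-winter sign flip where dark canopy absorbs more than
snow-covered open land. Scene macroclimate is latitude-driven
(`28 - 0.4|lat|` °C plus scatter); seasons are hemisphere-flipped
meteorological quarters over evenly spread overpass days; biomes are
latitude bands (|lat| <= 23.5° tropical, <= 50° temperate, else boreal).

Landscapes are unions of random ellipses rasterised by pixel-center
inclusion on a 64x64, 30 m grid; elevation is a smoothed Gaussian field
(mean 300 m, SD 120 m). All randomness flows from one root seed through
per-scene and per-SxO derived streams, so scenes are independently
reproducible and studies are byte-identical across runs.

**The slope-study generator.** The per-SxO log10-distance slope of a
sigmoid profile is a scaled projection of the amplitude (beta ≈ -c·A with
c > 0 set by the distance distribution), so a quadratic amplitude link
cannot be recovered coefficient-for-coefficient from sigmoid fields.
`simulate_slope_study` therefore generates scenes whose ground truth *is*
the log-linear slope, `beta(T) = a0 + a1*T + a2*T^2` exactly (defaults
0.6, -0.22, 0.004: cooling over ~85 % of the 0-35 °C macroclimate range,
strongest near the hot end, positive curvature), with 100-600 in-forest
points per scene — the in-forest share of a 1000-point SxO draw. This is
the direct test bed for the meta-regression's calibration.

What the generator does **not** emulate: radiative transfer or energy
balance, diurnal/sunrise timing, geographic projections (a flat local
frame in metres), spatially correlated retrieval noise, real landscape
pattern (edges are elliptical arcs), cloud spatial structure (dropout is
i.i.d.), or any difference between edge and interior T_opt. Passing tests
therefore demonstrate that the inference chain recovers known truths under
its own assumptions — not that those assumptions hold for real Landsat
scenes.

## Study sizes used by the tests and the acceptance script

Curve recovery runs 50 scenes x 1000 points per replicate (about 45 000
retained points) with patch scale 650 m so sampled distances support the
whole evaluated range; 100 replicates for the contrast-coverage check.
Slope recovery runs 300 scenes x 200 replicates. The gap scenarios use
8 scenes built around a single 900 m-core ellipse, which guarantees
>= 800 m interiors and makes every scene eligible by construction. The
demo pipeline (12 scenes x 8 overpasses, 64x64 grid) is a smoke-scale
configuration: its per-group contrasts are well resolved, but 96 SxO give
the meta-regression little power — the quadratic link needs hundreds of
scenes, as the recovery study shows.

## Known limitations

* Absolute curve levels are anchored at the most frequent SxO and carry
  its offset; only contrasts are level-free.
* The approximate REML criterion uses penalty pseudo-determinants with a
  profiled variance; it is adequate for selection but is not a drop-in
  replacement for a full Laplace REML.
* The Moran permutation test is quadratic in the subset size; caps above
  ~20 000 points are computationally unreasonable.
* Scene effects are exchangeable ridge effects; spatial correlation
  *between* scenes is neither simulated nor modelled.
* The "as-printed" SE rule is dimensionally inconsistent (it adds SEs, not
  variances, under the root); it is provided for fidelity and flagged in
  every report next to the quadrature and covariance-aware values.
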