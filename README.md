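# edgetherm

Forests buffer local climate, but fragmentation turns interior forest into
edge habitat. `edgetherm` quantifies the **surface-temperature edge
effect** — how satellite-sensed surface temperature (T_surf) changes with
distance from the forest edge — how that effect **scales with
macroclimate**, and how edge versus interior temperatures compare with the
**thermal optimum for ecosystem productivity** (T_opt). It is written for
spatial ecologists and remote-sensing researchers who want the full
inference chain as tested, reusable code, exercised end-to-end on
synthetic fragmented landscapes with known ground truth (the original
30 m satellite inputs are continental-scale and not desk-reproducible).

The chain has four stages:

1. **Edge geometry** — classify forest (canopy cover >= 30 %), compute the
   signed Euclidean distance to the edge between pixel centers (positive
   inside forest, negative outside, exact transform), sample 1000 points
   per scene-by-overpass (SxO) and filter for cloud and |d| <= 1000 m.
2. **Edge curves** — a penalized additive model
   `T_surf ~ f(dist) + f(elev) + SxO ridge effect`, partial-residual
   curves predicted every metre from -200 to 500 m, and the
   edge-interior contrast `delta = T(30 m) - T(500 m)` with three SE
   propagation rules; Moran's I on the residuals as the spatial
   diagnostic.
3. **Slope meta-regression** — per-SxO OLS slope of T_surf on
   log10(distance) (`dT/dD`, °C per log10 m), Hampel outlier filter
   (median ± 3 MAD), and an inverse-variance-weighted quadratic regression
   of `dT/dD` on the scene's mean T_surf: the macroclimate scaling of the
   edge effect.
4. **Productivity gap** — attach a coarse T_opt surface by cell
   containment, keep scenes with >= 500 in-forest observations, >= 2
   overpasses and >= 1 observation at >= 800 m, and model
   `T_surf - T_opt` against distance into the forest.

See `docs/methods.md` for the model, the generator's ground truth
`T(d) = T_macro - A / (1 + exp(-d/lam))`, and all numerical choices.

## Worked example

```python
from edgetherm import (fit_edge_curve, predict_partial,
                       edge_interior_contrast, restrict_for_curve)
from edgetherm.scenarios import curve_recovery_study

study = curve_recovery_study(seed=5, n_scenes=20)   # sigmoid truth: A=3 C, lam=50 m
model = fit_edge_curve(restrict_for_curve(study.points))
curve = predict_partial(model)                      # every metre, -200..500
c = edge_interior_contrast(model, 30.0, 500.0, se_rule="quadrature")
print(c.delta_c, c.se_quadrature)
```

This prints (examples/02_edge_curve.py shows the full script):

```
n = 18532 points, 20 SxO levels
  T(-200 m) = 28.577 +- 0.039 C
  T(  +0 m) = 27.099 +- 0.037 C
  T( +30 m) = 26.692 +- 0.038 C
  T(+500 m) = 25.653 +- 0.076 C
edge-interior contrast (30 vs 500 m): 1.040 C (analytic truth 1.063 C)
  SE quadrature 0.085, as-printed 0.338, covariance-aware 0.071
```

The curve falls from the open surroundings (-200 m) through the edge to
the interior; the contrast of 1.04 °C recovers the analytic truth
`A*(S(500/lam) - S(30/lam)) = 1.063` °C within one SE. The three SEs are
the conventional quadrature rule, the source convention that adds SEs
without squaring (conservative), and the full covariance propagation.

Each capability has a narrative script under `examples/` (landscape
generation, edge curves, slope meta-regression, productivity gap, full
pipeline). The pipeline is also a CLI:

```bash
fet run --config configs/demo.yaml --out demo_run --seed 42
```

which writes point tables, per-biome/season curves and contrasts, the
slope table and meta-regression variants, gap curves, report tables, and
a `manifest.json` with per-stage counts and file digests; runs are
byte-identical for a fixed (config, seed) and each stage can be re-run
individually.

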