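"""End-to-end orchestration: synthesize -> curves -> meta -> gap -> report.

Stages communicate through CSV/JSON files in an output directory, so each
stage can be re-run individually from the previous stage's outputs.  A run
manifest records the configuration snapshot, the root seed, per-stage row
counts, filter-removal counts and SHA-256 digests of every output file;
runs are deterministic given (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from copy import deepcopy
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curve_model import (edge_interior_contrast, fit_edge_curve, morans_i,
                          predict_partial, variant_contrast)
from .edge_geometry import restrict_for_curve
from .productivity_gap import (attach_topt, filter_eligible_scenes,
                               fit_gap_curve, synthetic_topt)
from .raster import write_ascii_grid
from .slope_meta import (compute_scene_slopes, hampel_filter, ivw_quadratic,
                         no_outlier_variant, slopes_to_frame, subset_cooling,
                         InsufficientDataError)
from .synthetic_landscape import (StudyConfig, SyntheticStudy,
                                  default_truth_sampler, generate_study)

STAGES = ("synth", "curve", "meta", "gap", "report")

DEFAULT_CONFIG: dict = {
    "study": {
        "n_scenes": 12,
        "n_overpasses": 8,
        "grid_size": 64,
        "pixel_size": 30.0,
        "n_points_per_sxo": 1000,
        "canopy_threshold": 30.0,
        "max_edge_distance": 1000.0,
        "cloud_fraction": 0.1,
        "seed": 42,
        "n_patches": 2,
        "patch_scale": 900.0,
        "lat_range": [-30.0, 65.0],
    },
    "truth": {
        "a0": -0.5,
        "a1": 0.05,
        "a2": 0.003,
        "lam": 90.0,
        "lapse": -0.0065,
        "sigma_noise": 1.4,
        "sigma_scene": 2.0,
    },
    "curve": {
        "group_by": ["biome", "season"],
        "edge": 30.0,
        "interior": 500.0,
        "variant_edge": 50.0,
        "variant_interior": 1000.0,
        "se_rule": "as-printed",
        "nbasis_dist": 20,
        "nbasis_elev": 10,
        "criterion": "gcv",
        "moran_max_points": 1500,
        "moran_permutations": 99,
    },
    "meta": {
        "min_obs": 4,
        "max_dist": 1000.0,
        "pool_overpasses": False,
        "hampel_scale": "mad",
    },
    "gap": {
        "season": "summer",
        "topt_mode": "offset-from-interior",
        "topt_value": 25.0,
        "topt_offset": -2.0,
        "min_obs": 500,
        "min_overpasses": 2,
        "min_deep": 800.0,
        "group_by": ["biome"],
    },
    "output": {
        "write_rasters": False,
        "figures": False,
    },
}


class ConfigError(ValueError):
    """Unknown or malformed configuration key."""


def _merge_checked(defaults: dict, user: dict, path: str = "") -> dict:
    out = deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {path}{key}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge_checked(defaults[key], val, f"{path}{key}.")
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Full configuration: file values merged over the checked-in defaults.

    Any key absent from the default set is an error — silent
    misconfiguration is worse than failure.
    """
    if path is None:
        return deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("configuration file must hold a mapping")
    return _merge_checked(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()


def _study_from_config(config: dict) -> SyntheticStudy:
    sc = dict(config["study"])
    sc["lat_range"] = tuple(sc["lat_range"])
    tr = config["truth"]
    sampler = default_truth_sampler(
        a0=tr["a0"], a1=tr["a1"], a2=tr["a2"], lam=tr["lam"],
        lapse=tr["lapse"], sigma_noise=tr["sigma_noise"],
        sigma_scene=tr["sigma_scene"])
    return generate_study(StudyConfig(**sc), sampler)


# ---------------------------------------------------------------------------
# stages


def stage_synth(config: dict, out: Path) -> dict:
    study = _study_from_config(config)
    study.points.to_csv(out / "points.csv", index=False)
    study.scene_meta.to_csv(out / "scene_meta.csv", index=False)
    study.removal_log.to_csv(out / "removal_log.csv", index=False)
    truths = {sid: asdict(t) for sid, t in study.truths.items()}
    offsets = {f"{s}|{o}": v for (s, o), v in study.sxo_offsets.items()}
    (out / "truths.json").write_text(
        json.dumps({"scenes": truths, "sxo_offsets": offsets},
                   indent=1, sort_keys=True))
    removal = study.removal_log[["sampled", "cloud", "nodata",
                                 "distance", "kept"]].sum()
    return {"rows": int(len(study.points)),
            "removals": {k: int(v) for k, v in removal.items()}}


def _fit_group(points, config):
    cc = config["curve"]
    restricted = restrict_for_curve(points)
    model = fit_edge_curve(restricted, nbasis_dist=cc["nbasis_dist"],
                           nbasis_elev=cc["nbasis_elev"],
                           criterion=cc["criterion"])
    full_model = fit_edge_curve(points, nbasis_dist=cc["nbasis_dist"],
                                nbasis_elev=cc["nbasis_elev"],
                                criterion=cc["criterion"])
    return model, full_model


def stage_curve(config: dict, out: Path) -> dict:
    cc = config["curve"]
    points = pd.read_csv(out / "points.csv")
    curves, contrasts, morans, skipped = [], [], [], []
    rule = cc["se_rule"]
    for gi, (key, grp) in enumerate(points.groupby(cc["group_by"], sort=True)):
        label = "/".join(str(k) for k in np.atleast_1d(np.asarray(key, dtype=object)))
        try:
            model, full_model = _fit_group(grp, config)
        except (ValueError, KeyError) as exc:
            skipped.append({"group": label, "reason": str(exc)})
            continue
        curve = predict_partial(model)
        curve.insert(0, "group", label)
        curves.append(curve)
        for mdl, (de, di) in ((model, (cc["edge"], cc["interior"])),
                              (full_model, (cc["variant_edge"],
                                            cc["variant_interior"]))):
            c = edge_interior_contrast(mdl, de, di, rule)
            contrasts.append({"group": label, "n": mdl.n_obs, **asdict(c)})
        if model.coords is not None:
            mi = morans_i(model.residuals, model.coords,
                          max_points=cc["moran_max_points"],
                          seed=config["study"]["seed"] + 1000 + gi,
                          n_permutations=cc["moran_permutations"])
            morans.append({"group": label, **asdict(mi)})
    pd.concat(curves, ignore_index=True).to_csv(out / "curves.csv", index=False)
    pd.DataFrame(contrasts).to_csv(out / "contrasts.csv", index=False)
    pd.DataFrame(morans).to_csv(out / "moran.csv", index=False)
    return {"groups": len(curves), "skipped": skipped}


def stage_meta(config: dict, out: Path) -> dict:
    mc = config["meta"]
    points = pd.read_csv(out / "points.csv")
    slopes, rejected = compute_scene_slopes(
        points, min_obs=mc["min_obs"], max_dist=mc["max_dist"],
        pool_overpasses=mc["pool_overpasses"])
    fits = []

    def record(variant, slope_list):
        try:
            fit = ivw_quadratic(slope_list)
        except (InsufficientDataError, ValueError) as exc:
            fits.append({"variant": variant, "error": str(exc)})
            return
        row = {k: v for k, v in asdict(fit).items() if k != "cov"}
        fits.append({"variant": variant, **row})

    kept, removed = (hampel_filter(slopes, scale=mc["hampel_scale"])
                     if len(slopes) >= 3 else (slopes, []))
    record("hampel", kept)
    record("no_filter", slopes)
    record("cooling_only", subset_cooling(kept))
    slopes_to_frame(slopes, rejected, removed).to_csv(
        out / "slopes.csv", index=False)
    pd.DataFrame(fits).to_csv(out / "meta_fits.csv", index=False)
    return {"slopes": len(slopes), "rejected": len(rejected),
            "hampel_removed": len(removed)}


def _study_shell(config: dict, out: Path) -> SyntheticStudy:
    """Reconstruct the truth record of a run from truths.json (no rasters)."""
    from .synthetic_landscape import EdgeEffectTruth

    data = json.loads((out / "truths.json").read_text())
    truths = {sid: EdgeEffectTruth(**vals)
              for sid, vals in data["scenes"].items()}
    offsets = {tuple(k.split("|")): v for k, v in data["sxo_offsets"].items()}
    sc = dict(config["study"])
    sc["lat_range"] = tuple(sc["lat_range"])
    return SyntheticStudy(points=pd.DataFrame(), truths=truths,
                          sxo_offsets=offsets, scene_meta=pd.DataFrame(),
                          removal_log=pd.DataFrame(), config=StudyConfig(**sc))


def stage_gap(config: dict, out: Path) -> dict:
    gc = config["gap"]
    points = pd.read_csv(out / "points.csv")
    study = _study_shell(config, out)  # truths needed for the synthetic T_opt
    grid = synthetic_topt(study, gc["topt_mode"], value=gc["topt_value"],
                          offset=gc["topt_offset"])
    write_ascii_grid(grid, out / "topt.asc")
    pts = points[points["season"] == gc["season"]]
    pts, n_undefined = attach_topt(pts, grid)
    eligible, log = filter_eligible_scenes(
        pts, min_obs=gc["min_obs"], min_overpasses=gc["min_overpasses"],
        min_deep=gc["min_deep"])
    log.to_csv(out / "gap_eligibility.csv", index=False)
    curves, contrasts, skipped = [], [], []
    groups = (eligible.groupby(gc["group_by"], sort=True)
              if len(eligible) else [])
    for key, grp in groups:
        label = "/".join(str(k) for k in np.atleast_1d(np.asarray(key, dtype=object)))
        try:
            gap = fit_gap_curve(grp, se_rule=config["curve"]["se_rule"])
        except (ValueError, KeyError) as exc:
            skipped.append({"group": label, "reason": str(exc)})
            continue
        curve = gap.curve.copy()
        curve.insert(0, "group", label)
        curves.append(curve)
        contrasts.append({"group": label, "n": gap.n_points,
                          **asdict(gap.contrast)})
    (pd.concat(curves, ignore_index=True) if curves
     else pd.DataFrame(columns=["group", "d", "fit", "se"])
     ).to_csv(out / "gap_curves.csv", index=False)
    contrast_cols = ["group", "n", "d_edge", "d_interior", "delta_c",
                     "se_rule", "se_delta", "se_as_printed", "se_quadrature",
                     "se_cov", "se_edge", "se_interior"]
    (pd.DataFrame(contrasts) if contrasts
     else pd.DataFrame(columns=contrast_cols)
     ).to_csv(out / "gap_contrasts.csv", index=False)
    return {"season_points": int(len(pts)), "topt_undefined": n_undefined,
            "eligible_points": int(len(eligible)),
            "eligible_scenes": int(log["eligible"].sum()) if len(log) else 0,
            "groups": len(curves), "skipped": skipped}


def stage_report(config: dict, out: Path) -> dict:
    contrasts = pd.read_csv(out / "contrasts.csv")
    main = contrasts[contrasts["d_edge"] == config["curve"]["edge"]]
    cols = ["group", "n", "d_edge", "d_interior", "delta_c",
            "se_as_printed", "se_quadrature", "se_cov"]
    main[cols].to_csv(out / "report_contrasts.csv", index=False)
    pd.read_csv(out / "meta_fits.csv").to_csv(out / "report_meta.csv",
                                              index=False)
    gap = pd.read_csv(out / "gap_contrasts.csv")
    gap_cols = [c for c in cols if c in gap.columns]
    gap[gap_cols].to_csv(out / "report_gap.csv", index=False)
    if config["output"]["figures"]:
        _make_figures(out)
    return {"contrast_rows": int(len(main)), "gap_rows": int(len(gap))}


def _make_figures(out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = pd.read_csv(out / "curves.csv")
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, grp in curves.groupby("group"):
        ax.plot(grp["d"], grp["fit"], label=label)
        ax.fill_between(grp["d"], grp["fit"] - grp["se"],
                        grp["fit"] + grp["se"], alpha=0.2)
    ax.set_xlabel("distance to forest edge (m)")
    ax.set_ylabel("partial T_surf (deg C)")
    ax.legend(fontsize=7)
    fig.savefig(out / "fig_curves.png", dpi=120)
    plt.close(fig)

    slopes = pd.read_csv(out / "slopes.csv")
    kept = slopes[slopes["kept"] == True]  # noqa: E712
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(kept["scene_mean_t"], kept["beta"],
               s=10 / np.sqrt(kept["var_beta"].clip(lower=1e-6)), alpha=0.5)
    ax.set_xlabel("scene mean T_surf (deg C)")
    ax.set_ylabel("dT/dD (deg C per log10 m)")
    fig.savefig(out / "fig_meta.png", dpi=120)
    plt.close(fig)

    gap = pd.read_csv(out / "gap_curves.csv")
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, grp in gap.groupby("group"):
        ax.plot(grp["d"], grp["fit"], label=label)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("distance into forest (m)")
    ax.set_ylabel("T_surf - T_opt (deg C)")
    ax.legend(fontsize=7)
    fig.savefig(out / "fig_gap.png", dpi=120)
    plt.close(fig)


_STAGE_FUNCS = {"synth": stage_synth, "curve": stage_curve,
                "meta": stage_meta, "gap": stage_gap, "report": stage_report}

_STAGE_OUTPUTS = {
    "synth": ["points.csv", "scene_meta.csv", "removal_log.csv", "truths.json"],
    "curve": ["curves.csv", "contrasts.csv", "moran.csv"],
    "meta": ["slopes.csv", "meta_fits.csv"],
    "gap": ["topt.asc", "gap_eligibility.csv", "gap_curves.csv",
            "gap_contrasts.csv"],
    "report": ["report_contrasts.csv", "report_meta.csv", "report_gap.csv"],
}


def run_stage(stage: str, config: dict, out_dir) -> dict:
    """Run one named stage against an output directory (restartable)."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage: {stage!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _STAGE_FUNCS[stage](config, out)
    except Exception as exc:
        raise RuntimeError(
            json.dumps({"stage": stage, "error": type(exc).__name__,
                        "detail": str(exc)})) from exc


def run_pipeline(config: dict | None = None, out_dir=".", seed=None) -> dict:
    """Run all stages and write manifest.json; returns the manifest dict."""
    config = deepcopy(config) if config is not None else load_config()
    if seed is not None:
        config["study"]["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config["study"]["seed"],
        "config": config,
        "config_digest": _config_digest(config),
        "stages": {},
    }
    for stage in STAGES:
        info = run_stage(stage, config, out)
        files = {name: _sha256(out / name) for name in _STAGE_OUTPUTS[stage]
                 if (out / name).exists()}
        manifest["stages"][stage] = {"info": info, "files": files}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
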