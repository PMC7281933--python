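"""End-to-end orchestration: simulate -> preprocess -> fit -> compare -> associate.

A run is driven by a single declarative YAML config (all keys validated
against the schema below; unknown keys are rejected before any computation).
Every stage writes into its own subdirectory of ``out_dir`` and the run
manifest records the package version, config hash, seeds and a checksum for
every artifact, so identical configs reproduce identical manifests for the
deterministic stages.

Config schema (all sections optional; defaults shown)::

    out_dir: run            # output directory
    seed: 0                 # master seed for every stochastic stage
    log_level: INFO
    stages: [simulate, preprocess, fit, compare, associate]
    phantom:                # PhantomSpec overrides (see phantom module)
      n_per_group: 11
      noise_sigma: 0.02
      ...
    preprocess:
      fwhm_mm: 8.0
      order: smooth_then_fit   # or fit_then_smooth
    fit:
      method: segmented        # or full_nls
      b_cut: 200.0
    compare:
      thresholds: {vbw: 2.0, dstar: 2.0, d: 1.8, flow: 1.7}
      directions: {vbw: B>A, d: A>B, dstar: A>B, flow: A>B}  # A = patient
      connectivity: 18
      correction: rft          # or perm
      n_perm: 500
      alpha: 0.05
    associate:
      group: patient
      method: pearson
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .association import run_association_battery
from .inference import compare_groups, intersect_significant_clusters
from .io import (
    check_common_grid,
    load_dwi,
    load_nifti,
    read_bvals,
    read_cohort_table,
    save_nifti,
    sha256_file,
    sha256_of,
    write_bvals,
    write_cohort_table,
)
from .ivim import PARAM_NAMES, FitOptions, IVIMParams, fit_ivim_volume
from .phantom import CovariateModel, EllipsoidRegion, PhantomSpec, generate_cohort
from .preprocess import DWISeries, gaussian_smooth_masked, preprocess_series

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "preprocess", "fit", "compare", "associate")

_DEFAULTS = {
    "out_dir": "run",
    "seed": 0,
    "log_level": "INFO",
    "stages": list(ALL_STAGES),
    "phantom": {},
    "preprocess": {"fwhm_mm": 8.0, "order": "smooth_then_fit"},
    "fit": {"method": "full_nls", "b_cut": 200.0},
    "compare": {
        "thresholds": {"vbw": 2.0, "dstar": 2.0, "d": 1.8, "flow": 1.7},
        "directions": {"vbw": "B>A", "d": "A>B", "dstar": "A>B", "flow": "A>B"},
        "connectivity": 18,
        "correction": "rft",
        "n_perm": 500,
        "alpha": 0.05,
    },
    "associate": {"group": "patient", "method": "pearson"},
}

_PHANTOM_KEYS = {
    "grid_shape",
    "voxel_size_mm",
    "b_values",
    "n_per_group",
    "effect_region",
    "baseline",
    "effect_deltas",
    "between_subject_sd",
    "noise_sigma",
    "s0",
    "field_smooth_fwhm_mm",
    "n_directions",
    "noise_model",
    "covariates",
    "seed",
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and key not in ("thresholds", "directions"):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {path + key!r} must be a mapping")
            out[key] = dict(defaults[key], **value) if key != "phantom" else dict(value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load, merge with defaults, and validate a run configuration."""
    user: dict = {}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict):
                user[k] = dict(user.get(k, {}), **v)
            else:
                user[k] = v
    cfg = _merge(_DEFAULTS, user)
    unknown_phantom = set(cfg["phantom"]) - _PHANTOM_KEYS
    if unknown_phantom:
        raise ConfigError(f"unknown phantom config keys: {sorted(unknown_phantom)}")
    for stage in cfg["stages"]:
        if stage not in ALL_STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
    return cfg


def build_phantom_spec(cfg: dict) -> PhantomSpec:
    """Construct a PhantomSpec from the (validated) phantom config section."""
    p = dict(cfg["phantom"])
    kwargs: dict = {}
    for key in ("grid_shape", "voxel_size_mm", "b_values"):
        if key in p:
            kwargs[key] = tuple(p.pop(key))
    if "baseline" in p:
        kwargs["baseline"] = IVIMParams(**p.pop("baseline"))
    if "effect_region" in p:
        er = p.pop("effect_region")
        kwargs["effect_region"] = EllipsoidRegion(
            center_frac=tuple(er.get("center_frac", (0.5, 0.72, 0.5))),
            radii_mm=tuple(er.get("radii_mm", (28.0, 22.0, 18.0))),
        )
    if "covariates" in p:
        kwargs["covariates"] = {
            name: CovariateModel(**model) for name, model in p.pop("covariates").items()
        }
    kwargs.update(p)
    kwargs.setdefault("seed", cfg["seed"])
    return PhantomSpec(**kwargs)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the {stage!r} stage first"
        )
    return path


def _subject_ids(out: Path) -> list[str]:
    table = read_cohort_table(_require(out / "simulate" / "cohort.tsv", "simulate"))
    return list(table["subject_id"])


def stage_simulate(cfg: dict, out: Path) -> list[Path]:
    spec = build_phantom_spec(cfg)
    cohort = generate_cohort(spec)
    sdir = out / "simulate"
    paths = [write_bvals(spec.b_values, sdir / "bvals.txt")]
    paths.append(write_cohort_table(cohort.table, sdir / "cohort.tsv"))
    paths.append(
        save_nifti(
            cohort.truth.region_mask.astype(float), sdir / "region_mask.nii.gz", spec.voxel_size_mm
        )
    )
    for subj, dwi in zip(cohort.truth.subjects, cohort.dwi):
        paths.append(
            save_nifti(dwi.signal, sdir / f"{subj.subject_id}_dwi.nii.gz", spec.voxel_size_mm)
        )
        for param, fld in subj.fields.items():
            paths.append(
                save_nifti(
                    fld, sdir / "truth" / f"{subj.subject_id}_{param}.nii.gz", spec.voxel_size_mm
                )
            )
    (sdir / "phantom_spec.json").write_text(
        json.dumps(dataclasses.asdict(spec), default=lambda o: list(o) if isinstance(o, tuple) else str(o), indent=2)
    )
    paths.append(sdir / "phantom_spec.json")
    return paths


def stage_preprocess(cfg: dict, out: Path) -> list[Path]:
    sdir = out / "simulate"
    pdir = out / "preprocess"
    bvals = _require(sdir / "bvals.txt", "simulate")
    paths = []
    shapes = {}
    for sid in _subject_ids(out):
        dwi = load_dwi(_require(sdir / f"{sid}_dwi.nii.gz", "simulate"), bvals)
        shapes[sid] = dwi.grid_shape
        norm = preprocess_series(
            dwi, fwhm_mm=cfg["preprocess"]["fwhm_mm"], order=cfg["preprocess"]["order"]
        )
        paths.append(save_nifti(norm.signal, pdir / f"{sid}_norm.nii.gz", norm.voxel_size_mm))
        paths.append(
            save_nifti(norm.brain_mask.astype(float), pdir / f"{sid}_mask.nii.gz", norm.voxel_size_mm)
        )
    check_common_grid(shapes)
    return paths


def stage_fit(cfg: dict, out: Path) -> list[Path]:
    pdir = out / "preprocess"
    mdir = out / "maps"
    bvals = read_bvals(_require(out / "simulate" / "bvals.txt", "simulate"))
    opts = FitOptions(b_cut=cfg["fit"]["b_cut"])
    report = {"method": cfg["fit"]["method"], "b_cut": cfg["fit"]["b_cut"], "subjects": {}}
    paths = []
    for sid in _subject_ids(out):
        data, _aff, voxel = load_nifti(_require(pdir / f"{sid}_norm.nii.gz", "preprocess"))
        mask_data, _, _ = load_nifti(_require(pdir / f"{sid}_mask.nii.gz", "preprocess"))
        series = DWISeries(
            signal=data, b_values=bvals, voxel_size_mm=voxel, brain_mask=mask_data > 0.5
        )
        maps = fit_ivim_volume(series, method=cfg["fit"]["method"], options=opts)
        for name in PARAM_NAMES:
            vol = maps[name]
            if cfg["preprocess"]["order"] == "fit_then_smooth":
                # sensitivity path: raw series were fitted, smooth the maps
                vol = gaussian_smooth_masked(
                    vol, cfg["preprocess"]["fwhm_mm"], voxel, maps.mask
                )
            paths.append(save_nifti(vol, mdir / f"{sid}_{name}.nii.gz", voxel))
        report["subjects"][sid] = {"n_invalid": maps.n_invalid}
    rpath = mdir / "fit_report.json"
    rpath.write_text(json.dumps(report, indent=2))
    paths.append(rpath)
    return paths


def _load_group_maps(out: Path, param: str):
    table = read_cohort_table(_require(out / "simulate" / "cohort.tsv", "simulate"))
    mdir = out / "maps"
    groups: dict[str, list[np.ndarray]] = {"patient": [], "control": []}
    voxel = None
    for _, row in table.iterrows():
        data, _aff, voxel = load_nifti(_require(mdir / f"{row.subject_id}_{param}.nii.gz", "fit"))
        groups[row.group].append(data)
    return groups["patient"], groups["control"], voxel


def stage_compare(cfg: dict, out: Path) -> list[Path]:
    import pandas as pd

    ccfg = cfg["compare"]
    cdir = out / "compare"
    cdir.mkdir(parents=True, exist_ok=True)
    rows = []
    sig_masks = []
    paths = []
    for param in PARAM_NAMES:
        pats, ctrls, voxel = _load_group_maps(out, param)
        threshold = float(ccfg["thresholds"].get(param, 2.0))
        direction = ccfg["directions"].get(param, "A>B")
        tmap, clusters = compare_groups(
            pats,
            ctrls,
            threshold,
            direction=direction,
            connectivity=int(ccfg["connectivity"]),
            correction=ccfg["correction"],
            voxel_size_mm=voxel,
            n_perm=int(ccfg["n_perm"]),
            seed=int(cfg["seed"]),
        )
        contrast = "patient>control" if direction == "A>B" else "patient<control"
        paths.append(save_nifti(tmap.t, cdir / f"tmap_{param}.nii.gz", voxel))
        for i, c in enumerate(clusters):
            rows.append(
                {
                    "parameter": param,
                    "contrast": contrast,
                    "peak_x_mm": c.peak_mm[0],
                    "peak_y_mm": c.peak_mm[1],
                    "peak_z_mm": c.peak_mm[2],
                    "threshold": threshold,
                    "size_voxels": c.size_voxels,
                    "p_fwe": c.p_fwe,
                }
            )
            paths.append(
                save_nifti(c.mask.astype(float), cdir / f"cluster_{param}_{i:02d}.nii.gz", voxel)
            )
        sig = [c for c in clusters if c.p_fwe is not None and c.p_fwe < ccfg["alpha"]]
        if sig:
            sig_masks.append(sig[0].mask)
    table = pd.DataFrame(
        rows,
        columns=[
            "parameter",
            "contrast",
            "peak_x_mm",
            "peak_y_mm",
            "peak_z_mm",
            "threshold",
            "size_voxels",
            "p_fwe",
        ],
    )
    tpath = cdir / "cluster_table.tsv"
    table.to_csv(tpath, sep="\t", index=False)
    paths.append(tpath)
    if len(sig_masks) >= 2:
        inter = intersect_significant_clusters(sig_masks)
    else:
        inter = np.zeros(load_nifti(cdir / f"tmap_{PARAM_NAMES[0]}.nii.gz")[0].shape, dtype=bool)
    paths.append(save_nifti(inter.astype(float), cdir / "intersection.nii.gz", voxel))
    return paths


def stage_associate(cfg: dict, out: Path) -> list[Path]:
    table = read_cohort_table(_require(out / "simulate" / "cohort.tsv", "simulate"))
    region, _aff, _vox = load_nifti(_require(out / "compare" / "intersection.nii.gz", "compare"))
    region = region > 0.5
    if not region.any():
        logger.warning("associate: empty intersection region; falling back to largest "
                       "significant cluster is not attempted — writing empty table")
        import pandas as pd

        apath = out / "associate" / "assoc.tsv"
        apath.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            columns=["parameter", "covariate", "n", "r", "p", "p_bh", "slope", "intercept",
                     "sig_p05", "trend_p10"]
        ).to_csv(apath, sep="\t", index=False)
        return [apath]
    mdir = out / "maps"
    subject_maps = {
        sid: {p: load_nifti(_require(mdir / f"{sid}_{p}.nii.gz", "fit"))[0] for p in PARAM_NAMES}
        for sid in table["subject_id"]
    }
    assoc = run_association_battery(
        subject_maps,
        region,
        table,
        group=cfg["associate"]["group"],
        method=cfg["associate"]["method"],
    )
    apath = out / "associate" / "assoc.tsv"
    apath.parent.mkdir(parents=True, exist_ok=True)
    assoc.to_csv(apath, sep="\t", index=False)
    return [apath]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "fit": stage_fit,
    "compare": stage_compare,
    "associate": stage_associate,
}


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    cfg = config if isinstance(config, dict) else load_config(config)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    config_hash = sha256_of(cfg)
    logger.info("run config hash %s (ivimpipe %s, seed %s)", config_hash, __version__, cfg["seed"])
    artifacts: dict[str, str] = {}
    for stage in ALL_STAGES:
        if stage not in cfg["stages"]:
            continue
        logger.info("running stage %s", stage)
        for path in _STAGE_FUNCS[stage](cfg, out):
            artifacts[str(Path(path).relative_to(out))] = sha256_file(path)
    manifest = {
        "package_version": __version__,
        "config_hash": config_hash,
        "seed": cfg["seed"],
        "stages": list(cfg["stages"]),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
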