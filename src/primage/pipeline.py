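"""End-to-end orchestration: simulate -> template -> preprocess -> brainage -> stats.

A :class:`RunConfig` holds every stage's parameters plus a single master
seed; :func:`run_pipeline` executes the enabled stages in flowchart order,
fans the master seed out to per-stage child seeds by stable spawning, writes
all numeric outputs under the run directory and appends a manifest recording
inputs, parameters, seeds and output hashes.  Two runs with the same config
and seed reproduce every numeric output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brainage import apply_trained_model, loocv_brainage
from .image import TissueProbabilityMap, VolumeImage
from .preprocess import preprocess_subject
from .stats import anova_from_summary, brainage_group_difference, fit_trajectory, GroupSummary
from .synthetic import (AgingModelParams, generate_cohort,
                        generate_experiment_cohort)
from .template import initialize_template, iterate_template, synthetic_reference_tpm

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("primage")

_STAGES = ("simulate", "template", "preprocess", "brainage", "stats")


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    out_dir: str = "primage_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    # simulate
    n_per_sex: tuple = (15, 14)
    experiment_cells: tuple = (5, 5, 7, 6)
    grid_shape: tuple = (48, 48, 48)
    voxel_size_mm: float = 2.0
    write_images: bool = False
    # template
    template_target_volume_ml: float = 200.0
    template_fwhm_mm: float = 2.0
    template_max_iter: int = 3
    template_stop_tol: float = 1e-3
    template_n_subjects: int = 6
    template_path: str = ""
    # preprocess
    slice_axis: int = 2
    register_dof: str = "full-affine"
    # brainage
    smoothing_fwhm_mm: float = 3.0
    resample_mm: float = 3.0
    refit_reduction_per_fold: bool = True
    # misc
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for key in ("n_per_sex", "experiment_cells", "grid_shape"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("n_per_sex", "experiment_cells", "grid_shape"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def validate_config(cfg: RunConfig) -> list:
    """Check types, ranges and stage dependencies; returns violations.

    Never raises and never mutates: an empty list means the config is ok.
    """
    v = []
    stages = cfg.stages
    unknown = set(stages) - set(_STAGES)
    if unknown:
        v.append(f"stages: unknown stage names {sorted(unknown)}")
    if not isinstance(cfg.seed, (int, np.integer)) or cfg.seed < 0:
        v.append("seed: must be a non-negative integer")
    for name in ("smoothing_fwhm_mm", "resample_mm", "template_fwhm_mm"):
        if getattr(cfg, name) <= 0:
            v.append(f"{name}: must be positive")
    if cfg.voxel_size_mm <= 0:
        v.append("voxel_size_mm: must be positive")
    if min(cfg.n_per_sex) < 0 or sum(cfg.n_per_sex) < 1:
        v.append("n_per_sex: need at least one subject")
    if cfg.template_target_volume_ml <= 0:
        v.append("template_target_volume_ml: must be positive")
    if cfg.template_max_iter < 1:
        v.append("template_max_iter: must be >= 1")
    if cfg.slice_axis not in (0, 1, 2):
        v.append("slice_axis: must be 0, 1 or 2")
    if cfg.register_dof not in ("scale-only", "rigid", "full-affine"):
        v.append("register_dof: must be scale-only, rigid or full-affine")
    # dependency rules
    if stages.get("preprocess") and not stages.get("template") and not cfg.template_path:
        v.append("preprocess: requires the template stage or a template_path")
    if stages.get("brainage") and not stages.get("simulate"):
        v.append("brainage: requires the simulate stage (no external cohort input)")
    if stages.get("stats") and not stages.get("brainage"):
        v.append("stats: requires the brainage stage")
    if cfg.template_path and not Path(cfg.template_path).exists():
        v.append(f"template_path: {cfg.template_path} does not exist")
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    Stage failures halt the run with the stage name (and subject id where
    applicable) in the exception message.  The manifest (also appended to
    ``manifest.json`` in the run directory) records the config, per-stage
    seeds, package versions, and a sha256 per written file.
    """
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "master_seed": int(cfg.seed),
        "stage_seeds": {},
        "stages_completed": [],
        "outputs": {},
    }
    written = {}

    params = AgingModelParams(grid_shape=cfg.grid_shape,
                              voxel_size_mm=cfg.voxel_size_mm)
    state = {}

    def record(name, path):
        written[name] = Path(path)

    # ---- simulate ----------------------------------------------------------
    if cfg.stages.get("simulate"):
        stage = "simulate"
        seed = _stage_seed(cfg.seed, stage)
        manifest["stage_seeds"][stage] = seed
        log.info("stage %s (seed %d)", stage, seed)
        lifespan = generate_cohort(params, n_per_sex=cfg.n_per_sex, master_seed=seed)
        experiment = generate_experiment_cohort(params,
                                                n_per_cell=cfg.experiment_cells,
                                                master_seed=seed + 1)
        state["lifespan"], state["experiment"] = lifespan, experiment
        cols = ["id", "sex", "age", "group", "birth_weight", "weight_at_scan"]
        p = out / "lifespan_metadata.csv"
        lifespan.metadata[cols].to_csv(p, index=False)
        record("lifespan_metadata", p)
        p = out / "experiment_metadata.csv"
        experiment.metadata[cols].to_csv(p, index=False)
        record("experiment_metadata", p)
        if cfg.write_images:
            for name, cohort in (("lifespan", lifespan), ("experiment", experiment)):
                paths = cohort.write(out / name)
                for img_path in paths["images"]:
                    record(f"{name}/{img_path.name}", img_path)
        manifest["stages_completed"].append(stage)

    # ---- template ----------------------------------------------------------
    if cfg.stages.get("template"):
        stage = "template"
        manifest["stage_seeds"][stage] = _stage_seed(cfg.seed, stage)
        log.info("stage %s", stage)
        if "lifespan" not in state:
            raise RuntimeError("stage template: requires simulated cohort in-run")
        reference = synthetic_reference_tpm(grid_shape=cfg.grid_shape,
                                            voxel_size_mm=2 * cfg.voxel_size_mm)
        tset = initialize_template(reference, cfg.template_target_volume_ml,
                                   cfg.voxel_size_mm)
        subset = state["lifespan"].images[:cfg.template_n_subjects]
        tset = iterate_template(subset, tset, fwhm_mm=cfg.template_fwhm_mm,
                                max_iter=cfg.template_max_iter,
                                stop_tol=cfg.template_stop_tol,
                                register_dof=cfg.register_dof)
        state["template"] = tset
        for name, path in tset.write(out / "template").items():
            record(f"template/{Path(path).name}", path)
        manifest["stages_completed"].append(stage)
    elif cfg.template_path:
        tdir = Path(cfg.template_path)
        state["template"] = None
        state["template_tpm"] = TissueProbabilityMap.from_nifti(tdir / "tpm.nii")
        state["template_t1"] = VolumeImage.from_nifti(tdir / "t1_average.nii")

    # ---- preprocess --------------------------------------------------------
    if cfg.stages.get("preprocess"):
        stage = "preprocess"
        manifest["stage_seeds"][stage] = _stage_seed(cfg.seed, stage)
        log.info("stage %s", stage)
        tset = state.get("template")
        tpm = tset.tpm if tset is not None else state["template_tpm"]
        t1 = tset.t1_average if tset is not None else state["template_t1"]
        rows = []
        for cname in ("lifespan", "experiment"):
            cohort = state.get(cname)
            if cohort is None:
                continue
            for sid, img in zip(cohort.metadata["id"], cohort.images):
                try:
                    seg, _ = preprocess_subject(img, tpm, t1,
                                                slice_axis=cfg.slice_axis,
                                                register_dof=cfg.register_dof)
                except Exception as exc:
                    raise RuntimeError(
                        f"stage preprocess failed for subject {sid}: {exc}") from exc
                rows.append({"cohort": cname, "id": sid,
                             "gm_ml": seg.volumes_ml["gm"],
                             "wm_ml": seg.volumes_ml["wm"],
                             "csf_ml": seg.volumes_ml["csf"],
                             "tiv_ml": seg.tiv_ml,
                             "gm_frac": seg.fractions["gm"],
                             "wm_frac": seg.fractions["wm"],
                             "csf_frac": seg.fractions["csf"]})
        vol = pd.DataFrame(rows)
        p = out / "segmented_volumes.csv"
        vol.to_csv(p, index=False)
        record("segmented_volumes", p)
        state["volumes"] = vol
        manifest["stages_completed"].append(stage)

    # ---- brainage ----------------------------------------------------------
    if cfg.stages.get("brainage"):
        stage = "brainage"
        seed = _stage_seed(cfg.seed, stage)
        manifest["stage_seeds"][stage] = seed
        log.info("stage %s", stage)
        from .synthetic import noisy_gm_maps
        lifespan, experiment = state["lifespan"], state["experiment"]
        mask = np.ones(cfg.grid_shape, dtype=bool)
        train_maps = noisy_gm_maps(lifespan, seed=seed)
        test_maps = noisy_gm_maps(experiment, seed=seed + 1)
        loocv = loocv_brainage(train_maps, lifespan.metadata, mask,
                               (cfg.voxel_size_mm,) * 3,
                               fwhm_mm=cfg.smoothing_fwhm_mm,
                               resample_mm=cfg.resample_mm,
                               refit_reduction_per_fold=cfg.refit_reduction_per_fold)
        test_res, _ = apply_trained_model(train_maps, lifespan.metadata,
                                          test_maps, experiment.metadata, mask,
                                          (cfg.voxel_size_mm,) * 3,
                                          fwhm_mm=cfg.smoothing_fwhm_mm,
                                          resample_mm=cfg.resample_mm)
        state["loocv"], state["test_result"] = loocv, test_res
        p = out / "loocv_brainage.csv"
        loocv.write_csv(p)
        record("loocv_brainage", p)
        p = out / "experiment_brainage.csv"
        test_res.write_csv(p)
        record("experiment_brainage", p)
        p = out / "loocv_summary.json"
        p.write_text(json.dumps({"mae_years": loocv.mae, "pearson_r": loocv.r,
                                 "n": loocv.n, "seed": int(cfg.seed)}, indent=2))
        record("loocv_summary", p)
        manifest["stages_completed"].append(stage)

    # ---- stats -------------------------------------------------------------
    if cfg.stages.get("stats"):
        stage = "stats"
        manifest["stage_seeds"][stage] = _stage_seed(cfg.seed, stage)
        log.info("stage %s", stage)
        lifespan = state["lifespan"]
        test_res = state["test_result"]
        meta = lifespan.metadata

        # lifespan sex contrasts from cohort summaries (cohort-table shape)
        rows = []
        for var in ("gm_frac_true", "wm_frac_true", "csf_frac_true", "tiv_true_ml"):
            summ = {}
            for sex in ("female", "male"):
                x = meta.loc[meta["sex"] == sex, var]
                summ[sex] = GroupSummary(n=len(x), mean=float(x.mean()),
                                         sd=float(x.std(ddof=1)), label=sex)
            cmp_ = anova_from_summary(summ["female"], summ["male"], factor="sex")
            rows.append({"variable": var,
                         "female_mean": summ["female"].mean,
                         "female_sd": summ["female"].sd,
                         "male_mean": summ["male"].mean,
                         "male_sd": summ["male"].sd,
                         "F": cmp_.f_stat, "p": cmp_.p_value,
                         "partial_eta2": cmp_.partial_eta2})
        p = out / "lifespan_sex_contrasts.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        record("lifespan_sex_contrasts", p)

        # per-sex volume trajectories with linear/quadratic selection
        rows = []
        for sex in ("female", "male"):
            sub = meta[meta["sex"] == sex]
            orders = tuple(o for o in (1, 2) if len(sub) > o + 1)
            if not orders:
                continue
            for var in ("gm_frac_true", "wm_frac_true", "csf_frac_true"):
                fits = fit_trajectory(sub["age"], sub[var], orders=orders,
                                      response=var)
                for order, fit in fits.items():
                    rows.append({"sex": sex, "variable": var, "order": order,
                                 "adjusted_r2": fit.adjusted_r2, "F": fit.f_stat,
                                 "p": fit.p_value, "selected": fit.selected})
        p = out / "volume_trajectories.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        record("volume_trajectories", p)

        # female MNR vs CTR BrainAGE contrast (experiment-table shape)
        t = test_res.table
        fem = t[t["sex"] == "female"]
        diff, comp = brainage_group_difference(fem["score"].to_numpy(),
                                               fem["group"].to_numpy(),
                                               fem["age"].to_numpy())
        contrast = {"female_mnr_minus_ctr_years": diff}
        if comp is not None:
            contrast.update({"ancova_F": comp.f_stat, "ancova_p": comp.p_value,
                             "partial_eta2": comp.partial_eta2})
        p = out / "mnr_contrast.json"
        p.write_text(json.dumps(contrast, indent=2))
        record("mnr_contrast", p)
        manifest["stages_completed"].append(stage)

    manifest["outputs"] = {name: _sha256(path) for name, path in written.items()}

    manifest_path = out / "manifest.json"
    history = []
    if manifest_path.exists():
        try:
            history = json.loads(manifest_path.read_text())
            if not isinstance(history, list):
                history = [history]
        except json.JSONDecodeError:
            history = []
    history.append(manifest)   # append-only record of every run
    manifest_path.write_text(json.dumps(history, indent=2))
    return manifest
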