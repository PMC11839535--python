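"""End-to-end orchestration: inputs -> FD/FA feature tables -> group
statistics -> PLSC -> combined JSON report, from a single config.

Every stochastic stage derives its stream from one root seed, so a rerun
with the same config produces a byte-identical report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior, fa, fd, io, plsc, synthetic
from .exceptions import ValidationError

log = logging.getLogger("fractamorph")

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    masks_dir: str
    atlas_path: str
    fa_map_path: str
    labels_path: str
    behavior_csv: str
    cop_trials_dir: str
    output_dir: str
    fd_features: tuple[str, ...] = fd.FEATURES
    fd_size_schedule: str = "dyadic"
    fd_offset_policy: str = "corner"
    n_perm: int = 1000
    n_boot: int = 500
    bsr_threshold: float = 2.0
    seed: int = 0
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "fd_features" in raw:
            raw["fd_features"] = tuple(raw["fd_features"])
        return cls(**raw)

    def validate_paths(self) -> None:
        for attr in ("masks_dir", "atlas_path", "fa_map_path", "labels_path",
                     "behavior_csv", "cop_trials_dir"):
            if not Path(getattr(self, attr)).exists():
                raise ValidationError(
                    f"config path {attr} does not exist: "
                    f"{getattr(self, attr)}")


def _stage(name):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            start = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise ValidationError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.2f s", name,
                     time.perf_counter() - start)
            return result
        return wrapper
    return decorator


@_stage("fd")
def _run_fd(config: RunConfig, out_dir: Path) -> dict:
    masks = {}
    for path in sorted(Path(config.masks_dir).glob("*.nii*")):
        data, zooms = io.read_nifti(path)
        roi = path.name.split(".nii")[0]
        masks[roi] = fd.BinaryMask3D(data > 0, voxel_size_mm=zooms)
    if not masks:
        raise ValidationError(f"no NIfTI masks found in {config.masks_dir}")
    table = fd.roi_fd_features(masks, features=config.fd_features,
                               size_schedule=config.fd_size_schedule,
                               offset_policy=config.fd_offset_policy)
    out = out_dir / "fd_features.tsv"
    io.write_tidy_tsv(table, out)
    return {"output": out.name, "n_rois": len(masks),
            "n_rows": int(len(table))}


@_stage("fa")
def _run_fa(config: RunConfig, out_dir: Path) -> dict:
    atlas_data, _ = io.read_nifti(config.atlas_path)
    map_data, _ = io.read_nifti(config.fa_map_path)
    with open(config.labels_path) as fh:
        names = {int(k): str(v) for k, v in yaml.safe_load(fh).items()}
    atlas = fa.LabelAtlas(np.asarray(atlas_data).astype(np.int32), names)
    table = fa.mean_fa_by_roi(fa.ScalarMap(np.asarray(map_data, float)),
                              atlas)
    out = out_dir / "fa_means.tsv"
    io.write_tidy_tsv(table, out)
    return {"output": out.name, "n_rois": int(len(table)),
            "mean_fa": {row.roi: row.mean_fa
                        for row in table.itertuples(index=False)}}


@_stage("behavior")
def _run_behavior(config: RunConfig, out_dir: Path, cohort) -> dict:
    stats = behavior.compare_groups(cohort, alpha=config.alpha)
    out = out_dir / "group_stats.tsv"
    io.write_tidy_tsv(stats, out)
    trials = [io.read_cop_trial_csv(p)
              for p in sorted(Path(config.cop_trials_dir).glob("*.csv"))]
    if not trials:
        raise ValidationError(
            f"no COP trial CSVs found in {config.cop_trials_dir}")
    cop = behavior.cop_displacement(trials)
    return {"output": out.name,
            "cop_displacement_cm": cop,
            "n_trials": len(trials),
            "group_stats": [
                {"measure": row.measure, "t": row.t, "df": row.df,
                 "p": row.p, "effect_size": row.effect_size,
                 "significant": bool(row.significant)}
                for row in stats.itertuples(index=False)]}


@_stage("plsc")
def _run_plsc(config: RunConfig, out_dir: Path, cohort, seed: int) -> dict:
    model = plsc.plsc_analysis(cohort, n_perm=config.n_perm,
                               n_boot=config.n_boot, seed=seed,
                               bsr_threshold=config.bsr_threshold)
    doc = model.to_dict()
    doc["feature_names"] = list(cohort.feature_names)
    doc["measure_names"] = list(cohort.measure_names)
    out = out_dir / "plsc_results.json"
    with open(out, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
    import pandas as pd

    scores = pd.DataFrame(
        {"subject_id": cohort.subject_ids, "group": cohort.group})
    for comp in range(model.n_components):
        scores[f"imaging_score_{comp + 1}"] = model.scores_img[:, comp]
        scores[f"behavioral_score_{comp + 1}"] = model.scores_beh[:, comp]
    io.write_tidy_tsv(scores, out_dir / "plsc_scores.tsv")
    return {"output": out.name,
            "singular_values": doc["singular_values"],
            "cov_explained": doc["cov_explained"],
            "perm_p": doc["perm_p"],
            "n_stable_img": int(np.sum(model.stable_img[:, 0])),
            "n_stable_beh": int(np.sum(model.stable_beh[:, 0]))}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and write the combined JSON report."""
    config.validate_paths()
    out_dir = io.ensure_dir(config.output_dir)
    cohort = io.read_cohort_csv(config.behavior_csv)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {
            "fd": _run_fd(config, out_dir),
            "fa": _run_fa(config, out_dir),
            "behavior": _run_behavior(config, out_dir, cohort),
            "plsc": _run_plsc(config, out_dir, cohort, config.seed),
        },
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def validate_report(report: dict) -> None:
    """Structural check of the combined report against schema 1.0."""
    if report.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValidationError("unknown or missing report schema version")
    if not isinstance(report.get("seed"), int):
        raise ValidationError("report must record the root seed")
    stages = report.get("stages")
    if not isinstance(stages, dict):
        raise ValidationError("report must hold a stages mapping")
    for name in ("fd", "fa", "behavior", "plsc"):
        if name not in stages:
            raise ValidationError(f"report missing stage {name!r}")
        if "output" not in stages[name]:
            raise ValidationError(f"stage {name!r} missing its output path")
    plsc_stage = stages["plsc"]
    for key in ("singular_values", "cov_explained", "perm_p"):
        values = plsc_stage.get(key)
        if not isinstance(values, list) or not values:
            raise ValidationError(f"plsc stage missing {key}")
    if abs(sum(plsc_stage["cov_explained"]) - 1.0) > 1e-9:
        raise ValidationError("cov_explained must sum to 1")
    beh = stages["behavior"]
    if not isinstance(beh.get("cop_displacement_cm"), (int, float)):
        raise ValidationError("behavior stage missing the COP statistic")


def make_demo(out_dir, seed: int = 0) -> Path:
    """Populate a directory with synthetic inputs sized like the study
    (18 subjects: 8 HC / 10 TBI; 34 imaging features; 5 measures) plus a
    ready-to-run config.yaml."""
    out = io.ensure_dir(out_dir)
    root = np.random.SeedSequence(seed)
    cohort_seed, cop_seed, fa_seed = (int(s.generate_state(1)[0]) % 2**31
                                      for s in root.spawn(3))

    masks_dir = io.ensure_dir(out / "masks")
    phantoms = {
        "sponge": synthetic.PhantomSpec("menger_sponge", 2, pad=1),
        "cube": synthetic.PhantomSpec("solid_cube", 16, pad=1),
        "sheet": synthetic.PhantomSpec("plane_sheet", 16, pad=1),
    }
    for name, spec in phantoms.items():
        io.write_nifti(masks_dir / f"{name}.nii",
                       synthetic.make_phantom(spec).occupancy)

    rng = np.random.default_rng(fa_seed)
    boxes = [((2, 8), (2, 8), (2, 8)),
             ((10, 16), (2, 10), (2, 10)),
             ((2, 10), (12, 18), (12, 18))]
    values = np.round(rng.uniform(0.2, 0.8, size=len(boxes)), 3)
    labels, scalar = synthetic.make_labeled_volume((20, 20, 20), boxes,
                                                   values)
    io.write_nifti(out / "atlas.nii", labels)
    io.write_nifti(out / "fa_map.nii", scalar)
    with open(out / "labels.yaml", "w") as fh:
        yaml.safe_dump({k + 1: f"roi_{k + 1}" for k in range(len(boxes))},
                       fh)

    cohort = synthetic.make_cohort(synthetic.CohortSpec(
        effect=3.0, noise_sd=1.0, seed=cohort_seed))
    io.write_cohort_csv(cohort, out / "cohort.csv")

    cop_dir = io.ensure_dir(out / "cop_trials")
    for trial_idx in range(5):
        trial = synthetic.make_cop_trace(synthetic.COPTraceSpec(
            duration_s=8.0, sampling_rate_hz=100.0, perturb_onset_s=2.0,
            amplitude=2.0, drift_slope=0.1, noise_sd=0.05,
            seed=cop_seed + trial_idx))
        io.write_cop_trial_csv(cop_dir / f"trial_{trial_idx + 1:02d}.csv",
                               trial.samples, trial.sampling_rate_hz,
                               trial.onset_index)

    config = {
        "masks_dir": str(masks_dir),
        "atlas_path": str(out / "atlas.nii"),
        "fa_map_path": str(out / "fa_map.nii"),
        "labels_path": str(out / "labels.yaml"),
        "behavior_csv": str(out / "cohort.csv"),
        "cop_trials_dir": str(cop_dir),
        "output_dir": str(out / "results"),
        "n_perm": 200,
        "n_boot": 100,
        "seed": seed,
    }
    config_path = out / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
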