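"""Readers and writers for the on-disk formats used by the pipeline:
NIfTI-1 volumes, cohort CSV tables, COP trial CSVs, and tidy TSVs."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import ValidationError


def write_nifti(path, data: np.ndarray,
                voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    affine = np.diag([*voxel_size_mm, 1.0])
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asanyarray(img.dataobj), zooms


def write_cop_trial_csv(path, samples: np.ndarray, sampling_rate_hz: float,
                        onset_index: int) -> None:
    """One column per axis of the trace: time_s, cop.  The perturbation
    onset is stored as a commented header line so the CSV stays tidy."""
    t = np.arange(len(samples)) / sampling_rate_hz
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={sampling_rate_hz}\n")
        fh.write(f"# onset_index={onset_index}\n")
        pd.DataFrame({"time_s": t, "cop": samples}).to_csv(fh, index=False)


def read_cop_trial_csv(path):
    from .behavior import COPTrial

    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    if "cop" not in frame.columns:
        raise ValidationError(f"{path}: missing 'cop' column")
    if "sampling_rate_hz" in meta:
        rate = float(meta["sampling_rate_hz"])
    else:
        dt = np.diff(frame["time_s"].to_numpy())
        rate = 1.0 / float(np.median(dt))
    onset = int(meta.get("onset_index", 0))
    return COPTrial(samples=frame["cop"].to_numpy(dtype=float),
                    sampling_rate_hz=rate, onset_index=onset)


def write_cohort_csv(cohort, path) -> None:
    frame = pd.DataFrame(cohort.X, columns=list(cohort.feature_names))
    for j, name in enumerate(cohort.measure_names):
        frame[name] = cohort.Y[:, j]
    frame.insert(0, "group", list(cohort.group))
    frame.insert(0, "subject_id", list(cohort.subject_ids))
    frame.to_csv(path, index=False)


def read_cohort_csv(path, measure_names=("BBS", "COP", "TMT", "SDMT", "SCWT")):
    from .plsc import CohortMatrices

    frame = pd.read_csv(path)
    for required in ("subject_id", "group"):
        if required not in frame.columns:
            raise ValidationError(f"{path}: missing '{required}' column")
    measures = [m for m in measure_names if m in frame.columns]
    if not measures:
        raise ValidationError(f"{path}: no behavioral measure columns found")
    features = [c for c in frame.columns
                if c not in ("subject_id", "group", *measures)]
    return CohortMatrices(
        X=frame[features].to_numpy(dtype=float),
        Y=frame[measures].to_numpy(dtype=float),
        subject_ids=tuple(str(s) for s in frame["subject_id"]),
        group=tuple(str(g) for g in frame["group"]),
        feature_names=tuple(features),
        measure_names=tuple(measures),
    )


def write_tidy_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
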