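"""Synthetic inputs for every pipeline stage.

Generates fractal phantoms of known dimension, two-group cohorts with a
planted rank-1 cross-block covariance, sinusoid-perturbation COP traces,
and paired label-atlas / scalar-map volumes — all deterministic under a
single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .behavior import COPTrial
from .exceptions import ValidationError, VoxelBudgetError
from .fd import BinaryMask3D
from .plsc import CohortMatrices

PHANTOM_KINDS = ("menger_sponge", "solid_cube", "plane_sheet", "rod",
                 "single_voxel")

#: 18 white-matter tract ROI names for the FA block (bilateral tracts split
#: into left/right) plus 16 generic network-complexity feature names.
FA_ROI_NAMES = (
    "CST_L", "CST_R",
    "SLF_L", "SLF_R",
    "CC_body", "CC_genu", "CC_splenium",
    "caudate_L", "caudate_R",
    "cingulum_L", "cingulum_R",
    "inferiorOccF_L", "inferiorOccF_R",
    "corona_radiata_L", "corona_radiata_R",
    "inferiorLongF_L", "inferiorLongF_R",
    "MCP",
)
FD_FEATURE_NAMES = tuple(f"FD_{i + 1:02d}" for i in range(16))
BEHAVIOR_NAMES = ("BBS", "COP", "TMT", "SDMT", "SCWT")


@dataclass(frozen=True)
class PhantomSpec:
    """A deterministic voxel phantom of known fractal dimension."""

    kind: str
    level_or_side: int = 1
    pad: int = 0
    max_voxels: int = 100_000_000

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValidationError(f"unknown phantom kind {self.kind!r}")
        if self.level_or_side < 1:
            raise ValidationError("level_or_side must be >= 1")
        if self.pad < 0:
            raise ValidationError("pad must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Rank-1 latent-variable cohort: per subject a scalar latent t drives
    both blocks along fixed unit-norm salience directions, plus iid noise."""

    n_subjects: int = 18
    n_imaging: int = 34
    n_behavior: int = 5
    effect: float = 1.0
    noise_sd: float = 1.0
    salience_img: np.ndarray | None = None
    salience_beh: np.ndarray | None = None
    group_sizes: tuple[int, int] = (8, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_imaging < 1 or self.n_behavior < 1:
            raise ValidationError("cohort dimensions must be positive")
        if self.effect < 0:
            raise ValidationError("effect must be non-negative")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if min(self.group_sizes) < 1:
            raise ValidationError("group sizes must be positive")
        if sum(self.group_sizes) != self.n_subjects:
            raise ValidationError(
                f"group sizes {self.group_sizes} do not sum to "
                f"n_subjects={self.n_subjects}")
        for name, vec, dim in (("salience_img", self.salience_img,
                                self.n_imaging),
                               ("salience_beh", self.salience_beh,
                                self.n_behavior)):
            if vec is None:
                continue
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (dim,):
                raise ValidationError(f"{name} must have length {dim}")
            if abs(np.linalg.norm(arr) - 1.0) > 1e-8:
                raise ValidationError(f"{name} must have unit Euclidean norm")
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class COPTraceSpec:
    """Platform-perturbation trace: linear drift + a windowed sinusoid
    burst + Gaussian noise."""

    duration_s: float = 8.0
    sampling_rate_hz: float = 100.0
    perturb_onset_s: float = 2.0
    perturb_freq_hz: float = 0.5
    n_cycles: int = 2
    amplitude: float = 2.0
    drift_slope: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValidationError("duration and sampling rate must be positive")
        if self.sampling_rate_hz < 50:
            raise ValidationError(
                "sampling_rate_hz must be >= 50 so a 10 Hz low-pass is "
                "meaningful")
        if self.perturb_onset_s < 0:
            raise ValidationError("perturb_onset_s must be non-negative")
        if self.perturb_freq_hz <= 0 or self.n_cycles < 1:
            raise ValidationError("perturbation frequency and cycle count "
                                  "must be positive")
        if self.amplitude <= 0:
            raise ValidationError("amplitude must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.perturb_onset_s + self.n_cycles / self.perturb_freq_hz \
                > self.duration_s + 1e-12:
            raise ValidationError(
                "perturbation must end within the trace duration")


def _menger(level: int) -> np.ndarray:
    """Corner-anchored Menger sponge: a voxel survives iff at no base-3
    digit position do >= 2 of its coordinates have digit 1."""
    side = 3 ** level
    idx = np.arange(side)
    keep = np.ones((side, side, side), dtype=bool)
    for k in range(level):
        digit = (idx // 3 ** k) % 3 == 1
        dx = digit[:, None, None]
        dy = digit[None, :, None]
        dz = digit[None, None, :]
        keep &= ~((dx & dy) | (dx & dz) | (dy & dz))
    return keep


def make_phantom(spec: PhantomSpec) -> BinaryMask3D:
    """Build a deterministic phantom mask (padded with background margin).

    Foreground counts are closed-form: 20**L (sponge), s**3 (cube),
    s**2 (sheet), s (rod), 1 (single voxel).
    """
    s = spec.level_or_side
    if spec.kind == "menger_sponge":
        side = 3 ** s
        if side**3 > spec.max_voxels:
            raise VoxelBudgetError(
                f"menger_sponge level {s} needs {side**3} voxels "
                f"(budget {spec.max_voxels})")
        core = _menger(s)
    elif spec.kind == "solid_cube":
        if s**3 > spec.max_voxels:
            raise VoxelBudgetError(f"cube side {s} exceeds the voxel budget")
        core = np.ones((s, s, s), dtype=bool)
    elif spec.kind == "plane_sheet":
        if s * s > spec.max_voxels:
            raise VoxelBudgetError(f"sheet side {s} exceeds the voxel budget")
        core = np.ones((s, s, 1), dtype=bool)
    elif spec.kind == "rod":
        if s > spec.max_voxels:
            raise VoxelBudgetError(f"rod length {s} exceeds the voxel budget")
        core = np.ones((s, 1, 1), dtype=bool)
    else:  # single_voxel
        core = np.ones((1, 1, 1), dtype=bool)
    if spec.pad:
        core = np.pad(core, spec.pad, constant_values=False)
    return BinaryMask3D(core)


def _unit_vector(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def _default_names(n_imaging: int, n_behavior: int):
    if n_imaging == len(FA_ROI_NAMES) + len(FD_FEATURE_NAMES):
        features = FA_ROI_NAMES + FD_FEATURE_NAMES
    else:
        features = tuple(f"img_{i + 1:03d}" for i in range(n_imaging))
    if n_behavior == len(BEHAVIOR_NAMES):
        measures = BEHAVIOR_NAMES
    else:
        measures = tuple(f"beh_{j + 1:02d}" for j in range(n_behavior))
    return features, measures


def make_cohort(spec: CohortSpec) -> CohortMatrices:
    """Draw one cohort from the rank-1 model.

    effect = 0 yields independent blocks.  Salience directions default to
    random unit vectors drawn from a stream independent of the noise, so
    the planted directions are stable per seed.
    """
    root = np.random.SeedSequence(spec.seed)
    dir_rng, noise_rng = (np.random.default_rng(s) for s in root.spawn(2))
    sal_img = (spec.salience_img if spec.salience_img is not None
               else _unit_vector(dir_rng, spec.n_imaging))
    sal_beh = (spec.salience_beh if spec.salience_beh is not None
               else _unit_vector(dir_rng, spec.n_behavior))
    t = noise_rng.standard_normal(spec.n_subjects)
    X = (spec.effect * np.outer(t, sal_img)
         + spec.noise_sd * noise_rng.standard_normal(
             (spec.n_subjects, spec.n_imaging)))
    Y = (spec.effect * np.outer(t, sal_beh)
         + spec.noise_sd * noise_rng.standard_normal(
             (spec.n_subjects, spec.n_behavior)))
    n_hc, n_tbi = spec.group_sizes
    group = ("HC",) * n_hc + ("TBI",) * n_tbi
    features, measures = _default_names(spec.n_imaging, spec.n_behavior)
    return CohortMatrices(
        X=X, Y=Y,
        subject_ids=tuple(f"sub-{i + 1:03d}" for i in range(spec.n_subjects)),
        group=group, feature_names=features, measure_names=measures,
        latent=t, salience_img=sal_img, salience_beh=sal_beh,
    )


def make_cop_trace(spec: COPTraceSpec) -> COPTrial:
    """trace(t) = drift_slope*t + A*sin(2*pi*f*(t-onset)) on the
    perturbation window + N(0, noise_sd)."""
    n = int(round(spec.duration_s * spec.sampling_rate_hz))
    t = np.arange(n) / spec.sampling_rate_hz
    onset = spec.perturb_onset_s
    end = onset + spec.n_cycles / spec.perturb_freq_hz
    response = np.where(
        (t >= onset) & (t <= end),
        spec.amplitude * np.sin(2 * np.pi * spec.perturb_freq_hz * (t - onset)),
        0.0)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    noise = (rng.standard_normal(n) * spec.noise_sd if spec.noise_sd > 0
             else np.zeros(n))
    samples = spec.drift_slope * t + response + noise
    onset_index = int(round(onset * spec.sampling_rate_hz))
    return COPTrial(samples=samples, sampling_rate_hz=spec.sampling_rate_hz,
                    onset_index=onset_index)


def make_labeled_volume(
    shape: tuple[int, int, int],
    roi_boxes: Sequence[tuple[tuple[int, int], tuple[int, int],
                              tuple[int, int]]],
    roi_values: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Integer label atlas + scalar map from disjoint axis-aligned boxes.

    Box k (1-based label) spans half-open ranges ((x0,x1),(y0,y1),(z0,z1));
    the scalar map holds roi_values[k] inside box k and 0 elsewhere.
    """
    if len(roi_boxes) != len(roi_values):
        raise ValidationError("need one value per box")
    labels = np.zeros(shape, dtype=np.int16)
    scalar = np.zeros(shape, dtype=float)
    for k, (box, value) in enumerate(zip(roi_boxes, roi_values), start=1):
        sl = []
        for axis, (lo, hi) in enumerate(box):
            if not (0 <= lo < hi <= shape[axis]):
                raise ValidationError(
                    f"box {k} exceeds the volume along axis {axis}")
            sl.append(slice(lo, hi))
        sl = tuple(sl)
        if np.any(labels[sl] != 0):
            raise ValidationError(f"box {k} overlaps an earlier box")
        labels[sl] = k
        scalar[sl] = value
    return labels, scalar
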