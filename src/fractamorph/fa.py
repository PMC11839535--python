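"""ROI-mean scalar statistics on a label atlas.

Computes per-ROI mean fractional anisotropy (FA) from a precomputed
scalar map and an integer label volume sharing the same voxel grid.  No
resampling is performed — a grid mismatch is an error, never a silent
interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyROIError, ShapeMismatchError, ValidationError


@dataclass(frozen=True)
class LabelAtlas:
    """Integer label volume (0 = background) with label->name mapping."""

    labels: np.ndarray
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValidationError("atlas must be a 3-D volume")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("atlas labels must be integers")
        object.__setattr__(self, "labels", arr)
        present = set(np.unique(arr).tolist())
        missing = [k for k in self.names if k not in present]
        if missing:
            raise ValidationError(
                f"named labels absent from the atlas volume: {missing}")


@dataclass(frozen=True)
class ScalarMap:
    """A 3-D scalar volume; FA values are expected in [0, 1]."""

    values: np.ndarray
    in_valid_range: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3:
            raise ValidationError("scalar map must be a 3-D volume")
        object.__setattr__(self, "values", arr)
        finite = arr[np.isfinite(arr)]
        ok = bool(finite.size == 0
                  or ((finite >= 0).all() and (finite <= 1).all()))
        object.__setattr__(self, "in_valid_range", ok)
        if not ok:
            warnings.warn("scalar map holds values outside [0, 1]",
                          RuntimeWarning, stacklevel=2)


def mean_fa_by_roi(scalar_map: ScalarMap, atlas: LabelAtlas,
                   labels: Sequence[int] | None = None) -> pd.DataFrame:
    """Arithmetic mean of the map over each requested label.

    NaN voxels are excluded (counted and warned about).  Returns a tidy
    frame with columns roi, label, mean_fa, n_voxels.
    """
    if scalar_map.values.shape != atlas.labels.shape:
        raise ShapeMismatchError(
            f"map shape {scalar_map.values.shape} != atlas shape "
            f"{atlas.labels.shape}")
    if labels is None:
        labels = sorted(atlas.names)
    rows = []
    for label in labels:
        in_roi = atlas.labels == label
        n_total = int(in_roi.sum())
        if n_total == 0:
            name = atlas.names.get(label, str(label))
            raise EmptyROIError(
                f"label {label} ({name}) has no voxels in the atlas")
        values = scalar_map.values[in_roi]
        valid = np.isfinite(values)
        n_nan = int((~valid).sum())
        if n_nan:
            warnings.warn(
                f"label {label}: excluded {n_nan} non-finite voxels",
                RuntimeWarning, stacklevel=2)
        if not valid.any():
            raise EmptyROIError(
                f"label {label} has no finite voxels to average")
        rows.append((atlas.names.get(label, str(label)), int(label),
                     float(values[valid].mean()), n_total - n_nan))
    return pd.DataFrame(rows, columns=["roi", "label", "mean_fa", "n_voxels"])
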