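"""Balance and cognitive outcome statistics.

Covers the center-of-pressure (COP) displacement statistic computed from
force-platform traces and the between-group comparisons (Welch t-test and
pooled-SD standardized mean difference) for the behavioral measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .exceptions import UndefinedStatisticError, ValidationError


@dataclass(frozen=True)
class COPTrial:
    """One force-platform trial: anterior/posterior COP position (cm)."""

    samples: np.ndarray
    sampling_rate_hz: float
    onset_index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or len(arr) < 2:
            raise ValidationError("samples must be a 1-D sequence")
        if self.sampling_rate_hz < 50:
            raise ValidationError("sampling rate must be >= 50 Hz")
        if self.onset_index < 0:
            raise ValidationError("onset_index must be non-negative")
        if self.onset_index >= len(arr):
            raise ValidationError("onset_index beyond the end of the trial")
        object.__setattr__(self, "samples", arr)


@dataclass(frozen=True)
class GroupStats:
    """Two-sample comparison summary in the fixed order TBI - HC."""

    t: float
    df: float
    p: float
    effect_size: float


def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    # 4th-order zero-phase Butterworth (filtfilt); cutoff must stay
    # strictly below Nyquist
    wn = cutoff_hz / (fs / 2.0)
    if not 0 < wn < 1:
        raise ValidationError(
            f"cutoff {cutoff_hz} Hz invalid for sampling rate {fs} Hz")
    b, a = signal.butter(4, wn)
    return signal.filtfilt(b, a, x)


def cop_displacement(trials: Sequence[COPTrial], cutoff_hz: float = 10.0,
                     window_s: float = 2.0) -> float:
    """Cumulative distance traveled by the trial-averaged COP over the
    first ``window_s`` seconds after perturbation onset.

    Per-trial processing: epoch at onset, zero-phase low-pass at
    ``cutoff_hz``, remove the least-squares linear trend; epochs are then
    averaged sample-wise and the path length is the sum of absolute
    consecutive differences across the window.
    """
    if not trials:
        raise ValidationError("need at least one trial")
    fs = trials[0].sampling_rate_hz
    if any(tr.sampling_rate_hz != fs for tr in trials):
        raise ValidationError("all trials must share one sampling rate")
    epoch_len = min(len(tr.samples) - tr.onset_index for tr in trials)
    n_window = int(round(window_s * fs))
    if n_window + 1 > epoch_len:
        raise ValidationError(
            f"window of {window_s} s ({n_window + 1} samples) exceeds the "
            f"shortest epoch ({epoch_len} samples)")
    processed = []
    for tr in trials:
        epoch = tr.samples[tr.onset_index:tr.onset_index + epoch_len]
        filtered = _lowpass(epoch, fs, cutoff_hz)
        processed.append(signal.detrend(filtered, type="linear"))
    averaged = np.mean(processed, axis=0)
    window = averaged[:n_window + 1]
    return float(np.sum(np.abs(np.diff(window))))


def _welch_parts(mean1, sd1, n1, mean2, sd2, n2):
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be non-negative")
    se2 = sd1**2 / n1 + sd2**2 / n2
    if se2 == 0:
        if mean1 == mean2:
            raise UndefinedStatisticError(
                "zero variance in both groups with equal means")
        return np.inf * np.sign(mean2 - mean1), float(n1 + n2 - 2)
    t = (mean2 - mean1) / np.sqrt(se2)
    df = se2**2 / ((sd1**2 / n1)**2 / (n1 - 1)
                   + (sd2**2 / n2)**2 / (n2 - 1))
    return float(t), float(df)


def cohens_d(mean1: float, sd1: float, n1: int,
             mean2: float, sd2: float, n2: int) -> float:
    """(mean2 - mean1) / pooled SD, pooled with (n-1) weights."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2)
                     / (n1 + n2 - 2))
    if pooled == 0:
        raise UndefinedStatisticError("pooled SD is zero")
    return float((mean2 - mean1) / pooled)


def welch_t(mean1: float, sd1: float, n1: int,
            mean2: float, sd2: float, n2: int) -> GroupStats:
    """Welch two-sample t-test from summary statistics with Satterthwaite
    degrees of freedom; two-tailed p.  Effect size is the pooled-SD
    standardized mean difference (sign follows mean2 - mean1)."""
    t, df = _welch_parts(mean1, sd1, n1, mean2, sd2, n2)
    if np.isinf(t):
        p = float(np.finfo(float).tiny)
    else:
        p = float(min(2.0 * stats.t.sf(abs(t), df), 1.0))
        p = max(p, float(np.finfo(float).tiny))
    try:
        d = cohens_d(mean1, sd1, n1, mean2, sd2, n2)
    except UndefinedStatisticError:
        d = float(np.sign(mean2 - mean1)) * np.inf
    return GroupStats(t=t, df=df, p=p, effect_size=d)


def compare_groups(cohort, alpha: float = 0.05) -> pd.DataFrame:
    """Per-measure Welch t-test and effect size, TBI - HC, from a cohort's
    behavioral block.  No multiple-testing correction is applied."""
    group = np.asarray(cohort.group)
    present = set(group)
    if present != {"HC", "TBI"}:
        raise ValidationError(
            f"need exactly groups HC and TBI, found {sorted(present)}")
    hc = group == "HC"
    tbi = group == "TBI"
    if hc.sum() < 2 or tbi.sum() < 2:
        raise ValidationError("each group needs >= 2 subjects")
    rows = []
    for j, measure in enumerate(cohort.measure_names):
        y = np.asarray(cohort.Y[:, j], dtype=float)
        gs = welch_t(
            float(y[hc].mean()), float(y[hc].std(ddof=1)), int(hc.sum()),
            float(y[tbi].mean()), float(y[tbi].std(ddof=1)), int(tbi.sum()))
        rows.append((measure, gs.t, gs.df, gs.p, gs.effect_size,
                     gs.p <= alpha))
    return pd.DataFrame(
        rows, columns=["measure", "t", "df", "p", "effect_size",
                       "significant"])


def compare_groups_from_summary(summary: pd.DataFrame,
                                alpha: float = 0.05) -> pd.DataFrame:
    """Same comparison computed from printed per-group summary rows.

    ``summary`` needs columns: measure, mean_hc, sd_hc, n_hc, mean_tbi,
    sd_tbi, n_tbi.
    """
    required = {"measure", "mean_hc", "sd_hc", "n_hc",
                "mean_tbi", "sd_tbi", "n_tbi"}
    missing = required - set(summary.columns)
    if missing:
        raise ValidationError(f"summary table missing columns {sorted(missing)}")
    rows = []
    for rec in summary.itertuples(index=False):
        gs = welch_t(rec.mean_hc, rec.sd_hc, int(rec.n_hc),
                     rec.mean_tbi, rec.sd_tbi, int(rec.n_tbi))
        rows.append((rec.measure, gs.t, gs.df, gs.p, gs.effect_size,
                     gs.p <= alpha))
    return pd.DataFrame(
        rows, columns=["measure", "t", "df", "p", "effect_size",
                       "significant"])
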