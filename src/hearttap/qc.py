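"""Quality control and traditional comparison measures.

Cohort screening mirrors common practice for the heartbeat-tapping task:
subjects whose tone-condition statistic is an iterative-Grubbs outlier at
p < .01 are excluded (taken to reflect inattention or indiscriminate
tapping), as are recordings with too few beats or no taps in any condition.
The traditional Schandry-style counting-accuracy score is provided as the
comparison measure for the model-based parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def counting_accuracy(
    n_beats: int, n_taps: int, denominator: str = "recorded"
) -> float:
    """Schandry-style heartbeat counting accuracy, single trial, unclipped.

    Default form: 1 - |recorded - reported| / recorded.  The alternative
    averaged denominator (mean of recorded and reported) is available via
    ``denominator='mean'``.  Scores can be negative when the report
    overshoots badly; they are deliberately not clipped.
    """
    if n_beats <= 0:
        raise ValueError("n_beats must be positive")
    if n_taps < 0:
        raise ValueError("n_taps must be non-negative")
    if denominator == "recorded":
        denom = n_beats
    elif denominator == "mean":
        denom = 0.5 * (n_beats + n_taps)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 1.0 - abs(n_beats - n_taps) / denom


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t-distribution."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def iterative_grubbs(values, alpha: float = 0.01) -> np.ndarray:
    """Boolean outlier mask by repeated two-sided Grubbs testing.

    Repeatedly tests the most extreme remaining point at level ``alpha``
    and removes it if significant, until no outlier remains or fewer than
    three points are left.  A zero-variance sample has no outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D sample of at least 3 values")
    mask = np.zeros(x.size, dtype=bool)
    active = np.arange(x.size)
    while active.size >= 3:
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g > grubbs_critical(active.size, alpha):
            mask[active[i]] = True
            active = np.delete(active, i)
        else:
            break
    return mask


@dataclass
class QCReport:
    """Per-subject exclusion flags and conserved counts."""

    flags: pd.DataFrame  # subject_id, tone_outlier, insufficient_beats, no_taps, excluded
    n_total: int
    n_excluded: int

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_excluded

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_excluded": self.n_excluded,
            "n_retained": self.n_retained,
            "excluded_subjects": self.flags.loc[
                self.flags["excluded"], "subject_id"
            ].tolist(),
        }


def quality_control(
    summary: pd.DataFrame,
    tone_stat: pd.Series | None = None,
    alpha: float = 0.01,
    min_beats: int = 30,
) -> QCReport:
    """Screen a cohort.

    ``summary`` needs columns ``subject_id, condition, n_beats, n_taps``.
    ``tone_stat`` is the per-subject tone-condition statistic screened by
    iterative Grubbs (by default the tone-condition sensory-precision
    estimate; which statistic to screen is a configuration choice).
    """
    required = {"subject_id", "condition", "n_beats", "n_taps"}
    if not required <= set(summary.columns):
        raise ValueError(f"summary must have columns {sorted(required)}")
    subjects = summary["subject_id"].unique()
    flags = pd.DataFrame(
        {
            "subject_id": subjects,
            "tone_outlier": False,
            "insufficient_beats": False,
            "no_taps": False,
        }
    ).set_index("subject_id")
    if tone_stat is not None and len(tone_stat) >= 3:
        mask = iterative_grubbs(tone_stat.to_numpy(dtype=float), alpha=alpha)
        for sid in np.asarray(tone_stat.index)[mask]:
            if sid in flags.index:
                flags.loc[sid, "tone_outlier"] = True
    beats_min = summary.groupby("subject_id")["n_beats"].min()
    taps_max = summary.groupby("subject_id")["n_taps"].max()
    flags.loc[beats_min[beats_min < min_beats].index, "insufficient_beats"] = True
    flags.loc[taps_max[taps_max == 0].index, "no_taps"] = True
    flags["excluded"] = flags.any(axis=1)
    flags = flags.reset_index()
    return QCReport(
        flags=flags,
        n_total=int(len(subjects)),
        n_excluded=int(flags["excluded"].sum()),
    )
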