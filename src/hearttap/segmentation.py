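"""Event streams and trial segmentation for the heartbeat-tapping task.

Behavior on the task is modelled at the level of discrete trials: the span
between consecutive perceivable heartbeats is halved into an after-beat
(systole-present) window and a before-beat (diastole) window, and each window
becomes one trial on which the participant either tapped or did not.
Perceivable beats are EKG R-wave peak times shifted forward by the pulse
transit time (PTT, ~200 ms to the earlobe), the delay before the pressure
wave can actually be felt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hearttap")

#: Recognized event kinds for :class:`EventSeries`.
EVENT_KINDS = ("r_peak", "perceivable_beat", "tap", "tone", "ppg_onset")

#: Default pulse transit time (seconds): R-wave to earlobe pulse arrival.
DEFAULT_PTT = 0.200

#: Observation labels used throughout (systole = after-beat window).
SYSTOLE = "systole"
DIASTOLE = "diastole"

#: Response labels.
TAP = "tap"
NO_TAP = "no_tap"


# ---------------------------------------------------------------------------
# Event container
# ---------------------------------------------------------------------------

@dataclass
class EventSeries:
    """Timestamped events of a single kind within one recording window.

    Parameters
    ----------
    times
        Event times in seconds, strictly ascending, all within
        ``[0, duration]``.
    kind
        One of :data:`EVENT_KINDS`.
    duration
        Length of the recording window in seconds.
    subject_id, condition
        Optional provenance labels.
    """

    times: np.ndarray
    kind: str
    duration: float
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("event times must be strictly ascending")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise ValueError("event times must lie in [0, duration]")

    def __len__(self) -> int:
        return int(self.times.size)


def events_to_frame(series: Iterable[EventSeries]) -> pd.DataFrame:
    """Concatenate event series into the on-disk table (``time_s``, ``kind``)."""
    rows = [
        pd.DataFrame({"time_s": s.times, "kind": s.kind}) for s in series
    ]
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["time_s", "kind"]
    )
    return out.sort_values("time_s", kind="stable").reset_index(drop=True)


def write_events_csv(path, series: Iterable[EventSeries]) -> None:
    events_to_frame(series).to_csv(path, index=False)


def read_events_csv(
    path, duration: float, subject_id: str = "", condition: str = ""
) -> dict[str, EventSeries]:
    """Read an event CSV and split it into one :class:`EventSeries` per kind."""
    frame = pd.read_csv(path)
    if not {"time_s", "kind"} <= set(frame.columns):
        raise ValueError(f"{path}: expected columns time_s, kind")
    out: dict[str, EventSeries] = {}
    for kind, sub in frame.groupby("kind"):
        out[str(kind)] = EventSeries(
            times=np.sort(sub["time_s"].to_numpy(dtype=float)),
            kind=str(kind),
            duration=duration,
            subject_id=subject_id,
            condition=condition,
        )
    return out


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    """One systole/diastole window with its tap response."""

    index: int
    observation: str  # systole | diastole
    response: str  # tap | no_tap
    window_start: float
    window_end: float
    n_taps_in_window: int = 0


@dataclass
class TrialSequence:
    """Ordered trials for one subject-condition, plus provenance counts."""

    trials: list[Trial]
    subject_id: str = ""
    condition: str = ""
    n_beats: int = 0
    n_taps: int = 0
    n_taps_outside: int = 0

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def observations(self) -> list[str]:
        return [t.observation for t in self.trials]

    @property
    def responses(self) -> list[str]:
        return [t.response for t in self.trials]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "observation": self.observations,
                "response": self.responses,
                "window_start": [t.window_start for t in self.trials],
                "window_end": [t.window_end for t in self.trials],
                "n_taps": [t.n_taps_in_window for t in self.trials],
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, subject_id: str = "", condition: str = ""
    ) -> "TrialSequence":
        trials = [
            Trial(
                index=int(r["index"]),
                observation=str(r["observation"]),
                response=str(r["response"]),
                window_start=float(r["window_start"]),
                window_end=float(r["window_end"]),
                n_taps_in_window=int(r["n_taps"]),
            )
            for _, r in frame.iterrows()
        ]
        n_taps = int(sum(t.n_taps_in_window for t in trials))
        return cls(
            trials=trials,
            subject_id=subject_id,
            condition=condition,
            n_beats=len(trials) // 2 + 1 if trials else 0,
            n_taps=n_taps,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def perceivable_beats(r_peaks: EventSeries, ptt: float = DEFAULT_PTT) -> EventSeries:
    """Shift R-wave peaks by the pulse transit time.

    Events shifted past the end of the recording are dropped (a beat whose
    pressure wave arrives after the trial ended was never perceivable).
    """
    if r_peaks.kind != "r_peak":
        raise ValueError(f"expected r_peak series, got {r_peaks.kind!r}")
    if ptt < 0:
        raise ValueError("ptt must be non-negative")
    shifted = r_peaks.times + ptt
    shifted = shifted[shifted < r_peaks.duration] if ptt > 0 else shifted
    return EventSeries(
        times=shifted,
        kind="perceivable_beat",
        duration=r_peaks.duration,
        subject_id=r_peaks.subject_id,
        condition=r_peaks.condition,
    )


def segment_trials(beats: EventSeries) -> list[tuple[str, float, float]]:
    """Halve each inter-beat span into (observation, window_start, window_end).

    For consecutive perceivable beats ``e_i < e_{i+1}`` with midpoint ``m``:
    ``[e_i, m)`` is the after-beat window (systole signal present) and
    ``[m, e_{i+1})`` the before-beat window (diastole).  Beats 1 s apart thus
    give a 500 ms systole window.  Time before the first beat and after the
    last has no defined systole/diastole status and yields no trials.
    """
    t = beats.times
    if t.size < 2:
        raise ValueError("insufficient beats: need at least 2 perceivable beats")
    windows: list[tuple[str, float, float]] = []
    mids = (t[:-1] + t[1:]) / 2.0
    for start, mid, end in zip(t[:-1], mids, t[1:]):
        windows.append((SYSTOLE, float(start), float(mid)))
        windows.append((DIASTOLE, float(mid), float(end)))
    return windows


def assign_responses(
    windows: Sequence[tuple[str, float, float]],
    taps: EventSeries,
    subject_id: str = "",
    condition: str = "",
) -> TrialSequence:
    """Mark each window tapped/untapped.

    Windows are half-open ``[start, end)``; a tap exactly on a boundary
    belongs to the later window.  Multiple taps within one window collapse to
    a single tap response (each interval is one tap/no-tap choice); the count
    is kept for QC.  Taps outside every window are counted but unused.
    """
    if taps.kind != "tap":
        raise ValueError(f"expected tap series, got {taps.kind!r}")
    tap_times = taps.times
    trials: list[Trial] = []
    n_inside = 0
    for i, (obs, start, end) in enumerate(windows):
        n_in = int(np.count_nonzero((tap_times >= start) & (tap_times < end)))
        n_inside += n_in
        trials.append(
            Trial(
                index=i,
                observation=obs,
                response=TAP if n_in else NO_TAP,
                window_start=start,
                window_end=end,
                n_taps_in_window=n_in,
            )
        )
    return TrialSequence(
        trials=trials,
        subject_id=subject_id or taps.subject_id,
        condition=condition or taps.condition,
        n_beats=len(windows) // 2 + 1 if windows else 0,
        n_taps=int(tap_times.size),
        n_taps_outside=int(tap_times.size) - n_inside,
    )


def build_trial_sequence(
    r_peaks: EventSeries, taps: EventSeries, ptt: float = DEFAULT_PTT
) -> TrialSequence:
    """Full segmentation pipeline: PTT shift, interval halving, responses."""
    beats = perceivable_beats(r_peaks, ptt)
    windows = segment_trials(beats)
    return assign_responses(
        windows, taps, subject_id=r_peaks.subject_id, condition=r_peaks.condition
    )


@dataclass(frozen=True)
class PTTEstimate:
    """Median R-wave→PPG delay with pairing quality diagnostics."""

    ptt: float
    n_pairs: int
    n_r_peaks: int
    low_quality: bool

    @property
    def fraction_paired(self) -> float:
        return self.n_pairs / self.n_r_peaks if self.n_r_peaks else 0.0


def estimate_ptt(
    r_peaks: EventSeries,
    ppg_onsets: EventSeries,
    max_delay: float = 0.5,
) -> PTTEstimate:
    """Estimate PTT as the median R-wave→PPG-onset delay.

    Each R-peak pairs with the first PPG onset following it within
    ``max_delay`` seconds (a physiological upper bound that prevents pairing
    across beats).  If fewer than half the R-peaks pair, the estimate is
    flagged low quality and the 200 ms default should be preferred.
    """
    if not len(r_peaks) or not len(ppg_onsets):
        raise ValueError("both series must be non-empty")
    delays = []
    idx = np.searchsorted(ppg_onsets.times, r_peaks.times, side="left")
    for r, j in zip(r_peaks.times, idx):
        if j < ppg_onsets.times.size:
            d = ppg_onsets.times[j] - r
            if 0 <= d <= max_delay:
                delays.append(d)
    if not delays:
        raise ValueError("no usable pairs")
    n_pairs = len(delays)
    low = n_pairs < 0.5 * len(r_peaks)
    if low:
        logger.warning(
            "PTT estimate low quality: %d/%d R-peaks paired; "
            "consider the %.3f s default",
            n_pairs,
            len(r_peaks),
            DEFAULT_PTT,
        )
    return PTTEstimate(
        ptt=float(np.median(delays)),
        n_pairs=n_pairs,
        n_r_peaks=len(r_peaks),
        low_quality=low,
    )
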