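"""Doppler speed-signal conditioning for walking-session traces.

The raw 1-Hz Doppler speed of a walking session carries three artifact
classes: sporadic high-magnitude spikes, low-amplitude positive noise while
the wearer is at rest, and one-or-two-epoch spurious walking/stopping
flickers.  They are removed by a seven-pass cascade calibrated per session
from a representative window of steady walking:

1. *spike filter* — values above twice the calibration mean v̄ are replaced
   by the mean of the five following epochs;
2. *zero-threshold filter* — values below v̄ − K·σv are set to 0, where
   K = 2 if the calibration coefficient of variation CV(ν) ≥ 15% and K = 5
   otherwise;
3–7. *smoothing actions 1–5* — local rules that re-anchor the first epoch of
   a walking bout and erase isolated zeros inside walking (actions 2–3) and
   isolated positive epochs inside rest (actions 4–5).

Each pass sweeps the vector left to right in place, so within a pass later
epochs see already-updated earlier epochs; each pass starts from the output
of the previous one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_gpx import SpeedTrace

__all__ = [
    "CalibrationStats",
    "ProcessedTrace",
    "select_window",
    "calibration_stats",
    "spike_filter",
    "zero_filter",
    "smooth_actions",
    "process_speed",
    "suggest_calibration_window",
]

logger = logging.getLogger(__name__)

#: CV(ν) percentage at and above which the zero-threshold coefficient K is 2.
CV_K_BOUNDARY_PCT = 15.0
MAX_CALIBRATION_WINDOW_S = 120


@dataclass(frozen=True)
class CalibrationStats:
    """Speed statistics over the representative calibration window.

    v_bar, sigma_v are the mean and sample (n−1) standard deviation of raw
    speed in km/h; cv_v = 100·σv/v̄ in percent; K ∈ {2, 5} sets the
    zero-filter threshold v̄ − K·σv.
    """

    v_bar: float
    sigma_v: float
    cv_v: float
    K: int
    window: tuple[pd.Timestamp, pd.Timestamp]
    window_len_s: float

    @property
    def zero_threshold_kmh(self) -> float:
        return self.v_bar - self.K * self.sigma_v

    @property
    def spike_threshold_kmh(self) -> float:
        return 2.0 * self.v_bar


@dataclass
class ProcessedTrace:
    """A trace plus its fully conditioned speed vector.

    ``base`` keeps the raw speeds; ``speed_processed`` has the same length
    and is non-negative everywhere.
    """

    base: SpeedTrace
    speed_processed: np.ndarray
    calib: CalibrationStats
    stages_applied: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.base)

    def to_frame(self) -> pd.DataFrame:
        df = self.base.df.rename(columns={"speed_kmh": "speed_raw_kmh", "source": "stage_flags"}).copy()
        df["speed_processed_kmh"] = self.speed_processed
        cols = ["time", "lat", "lon", "ele_gps", "ele_corrected",
                "speed_raw_kmh", "speed_processed_kmh", "stage_flags"]
        return df[cols]


def select_window(trace: SpeedTrace, start, end) -> SpeedTrace:
    """Sub-trace on the closed interval [start, end].

    ``start``/``end`` may be timestamps or seconds offsets from the first
    epoch.  Mirrors the manual period-of-interest selection (a few seconds
    before the first walking bout to a few seconds after the last one).
    """
    return trace.slice_time(start, end)


def calibration_stats(trace: SpeedTrace, calib_window) -> CalibrationStats:
    """Compute v̄, σv, CV(ν) and K on raw speeds over the calibration window.

    The window must span at least two epochs and at most 120 s; K = 2 when
    CV(ν) ≥ 15% and K = 5 when CV(ν) < 15%.
    """
    start, end = calib_window
    sub = trace.slice_time(start, end)
    if len(sub) < 2:
        raise ValueError("calibration window must contain at least 2 epochs")
    window_len_s = len(sub) * trace.epoch_s
    if window_len_s > MAX_CALIBRATION_WINDOW_S:
        raise ValueError(
            f"calibration window spans {window_len_s:.0f}s; the representative period "
            f"is at most {MAX_CALIBRATION_WINDOW_S}s"
        )
    v = sub.speed
    v_bar = float(np.mean(v))
    if v_bar == 0:
        raise ValueError("calibration window contains no movement")
    sigma_v = float(np.std(v, ddof=1))
    cv_v = 100.0 * sigma_v / v_bar
    K = 2 if cv_v >= CV_K_BOUNDARY_PCT else 5
    return CalibrationStats(
        v_bar=v_bar, sigma_v=sigma_v, cv_v=cv_v, K=K,
        window=(sub.df["time"].iloc[0], sub.df["time"].iloc[-1]),
        window_len_s=float(window_len_s),
    )


def _mean_following(v: np.ndarray, i: int, k: int = 5) -> float | None:
    """Mean of up to k epochs following i; None when none exist."""
    if i + 1 >= len(v):
        return None
    return float(np.mean(v[i + 1 : i + 1 + k]))


def spike_filter(speed: np.ndarray, calib: CalibrationStats) -> np.ndarray:
    """Replace speed spikes above 2·v̄ by the mean of the five following epochs.

    The scan is left to right on the raw vector; replacement values are the
    raw following values (a left-to-right sweep has not yet visited them, so
    raw and current coincide).  Near the end of the vector fewer following
    epochs are used; a spike at the final epoch takes the last preceding
    non-spike value.
    """
    v = np.asarray(speed, float)
    out = v.copy()
    thr = calib.spike_threshold_kmh
    n = len(v)
    for i in range(n):
        if v[i] > thr:
            m = _mean_following(v, i)
            if m is not None:
                out[i] = m
            else:
                j = i - 1
                while j >= 0 and v[j] > thr:
                    j -= 1
                out[i] = v[j] if j >= 0 else calib.v_bar
    return out


def zero_filter(speed: np.ndarray, calib: CalibrationStats) -> np.ndarray:
    """Zero every value strictly below the threshold v̄ − K·σv.

    A non-positive threshold disables the filter (vector returned unchanged,
    with a logged warning): the calibration window was too noisy for a
    meaningful rest/walk separation.
    """
    v = np.asarray(speed, float).copy()
    T = calib.zero_threshold_kmh
    if T <= 0:
        logger.warning(
            "zero_filter disabled: threshold v̄-K·σv = %.3f km/h is not positive", T
        )
        return v
    v[v < T] = 0.0
    return v


def _action_1(v: np.ndarray) -> None:
    # First positive epoch after a zero is re-anchored to the local mean of
    # the five following epochs.  A final epoch with no followers is left
    # unchanged rather than fabricating a value from the zero before it.
    n = len(v)
    for i in range(1, n):
        if v[i - 1] == 0 and v[i] > 0:
            m = _mean_following(v, i)
            if m is not None:
                v[i] = m


def _action_2(v: np.ndarray) -> None:
    # Isolated zero inside walking -> mean of epochs i-2, i-1, i+2, i+3.
    n = len(v)
    for i in range(n):
        if (
            v[i] == 0
            and i - 2 >= 0
            and i + 3 < n
            and v[i - 2] > 0
            and v[i - 1] > 0
            and v[i + 2] > 0
            and v[i + 3] > 0
        ):
            v[i] = (v[i - 2] + v[i - 1] + v[i + 2] + v[i + 3]) / 4.0


def _action_4(v: np.ndarray) -> None:
    # Isolated positive epoch inside rest -> 0 (the mean of four zeros).
    n = len(v)
    for i in range(n):
        if (
            v[i] > 0
            and i - 2 >= 0
            and i + 3 < n
            and v[i - 2] == 0
            and v[i - 1] == 0
            and v[i + 2] == 0
            and v[i + 3] == 0
        ):
            v[i] = 0.0


_SMOOTHING_PASSES = (
    ("action_1", _action_1),
    ("action_2", _action_2),
    ("action_3", _action_2),
    ("action_4", _action_4),
    ("action_5", _action_4),
)


def smooth_actions(speed: np.ndarray) -> np.ndarray:
    """Apply smoothing actions 1–5, each as a full in-place left-to-right pass.

    Epochs whose neighbour indices fall outside the vector are left
    unchanged (no extrapolation at the boundaries).
    """
    v = np.asarray(speed, float).copy()
    for _, fn in _SMOOTHING_PASSES:
        fn(v)
    return v


def process_speed(trace: SpeedTrace, calib: CalibrationStats) -> ProcessedTrace:
    """Run the full seven-pass cascade on a trace's raw speed."""
    v = spike_filter(trace.speed, calib)
    v = zero_filter(v, calib)
    v = smooth_actions(v)
    stages = ["spike_filter", "zero_filter"] + [name for name, _ in _SMOOTHING_PASSES]
    return ProcessedTrace(base=trace, speed_processed=v, calib=calib, stages_applied=stages)


def suggest_calibration_window(
    trace: SpeedTrace,
    window_s: int = 120,
    movement_floor_kmh: float = 1.0,
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Heuristic helper: the ``window_s`` window of lowest CV among windows
    whose mean speed exceeds ``movement_floor_kmh``.

    The representative period is in principle a manual, visual choice; this
    helper only proposes a steady-walking candidate.  Note that minimising
    the *sample* CV over many overlapping windows biases the selected CV
    low, which can flip K from 2 to 5 — inspect the result before use.
    """
    n_win = min(int(window_s // trace.epoch_s), len(trace))
    if n_win < 2:
        raise ValueError("trace too short for a calibration window")
    s = pd.Series(trace.speed)
    roll = s.rolling(n_win)
    mean, sd = roll.mean(), roll.std(ddof=1)
    cv = (100.0 * sd / mean).where(mean > movement_floor_kmh)
    if cv.isna().all():
        raise ValueError("no window with mean speed above the movement floor")
    end_idx = int(cv.idxmin())
    start_idx = end_idx - n_win + 1
    t = trace.df["time"]
    return (t.iloc[start_idx], t.iloc[end_idx])
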