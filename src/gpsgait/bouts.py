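"""Walking/stopping bout segmentation with a minimum-bout-duration rule.

A processed speed vector is first cut into maximal runs of constant state
(walking: speed > 0; stopping: speed = 0).  Runs shorter than the minimum
bout duration (15 s by default) do not count as genuine state changes: each
sub-threshold run is absorbed into the bout currently open, so a walk
interrupted by a 10-s pause remains one walking bout.  A state shift is
validated only by a run of at least the minimum duration, after which the
open bout closes and a new one opens.  ``min_bout_s=0`` disables merging
(runs become bouts verbatim), which is the sensitivity-analysis setting.

Walking distance is integrated from the Doppler speed channel, not from
coordinates: absorbed zero epochs contribute 0 metres but full duration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .speed_processing import ProcessedTrace

__all__ = ["Bout", "detect_bouts", "bout_metrics", "bouts_to_frame"]

DEFAULT_MIN_BOUT_S = 15.0


@dataclass
class Bout:
    """One validated walking or stopping interval.

    ``start_idx``/``end_idx`` are inclusive epoch indices into the processed
    trace; ``index`` is the 1-based position among same-state bouts;
    ``n_absorbed_runs`` counts the sub-threshold opposite-state runs merged
    into this bout.
    """

    state: str  # "walking" | "stopping"
    start: pd.Timestamp
    end: pd.Timestamp
    start_idx: int
    end_idx: int
    duration_s: float
    distance_m: float = 0.0
    mean_speed_kmh: float = 0.0
    n_absorbed_runs: int = 0
    index: int = 0

    @property
    def n_epochs(self) -> int:
        return self.end_idx - self.start_idx + 1


def _runs(speed: np.ndarray) -> list[tuple[str, int, int]]:
    """Maximal constant-state runs as (state, start_idx, end_idx) inclusive."""
    walking = np.asarray(speed) > 0
    out = []
    start = 0
    for i in range(1, len(walking) + 1):
        if i == len(walking) or walking[i] != walking[start]:
            out.append(("walking" if walking[start] else "stopping", start, i - 1))
            start = i
    return out


def detect_bouts(processed: ProcessedTrace, min_bout_s: float = DEFAULT_MIN_BOUT_S) -> list[Bout]:
    """Segment a processed trace into validated, alternating bouts.

    The first run always opens a bout (a short leading rest is expected and
    is trimmed later, at the outcome stage).  Each subsequent run is absorbed
    into the open bout when it is shorter than ``min_bout_s`` or has the same
    state; otherwise it validates a state shift.  A sub-threshold run at the
    very end is absorbed like any interior one.  Returned bouts alternate in
    state, tile the span, and carry integrated distance and mean speed.
    """
    if min_bout_s < 0:
        raise ValueError("min_bout_s must be non-negative")
    if len(processed) == 0:
        raise ValueError("empty processed trace")
    epoch = float(processed.base.epoch_s)
    runs = _runs(processed.speed_processed)

    merged: list[list] = []  # [state, start_idx, end_idx, n_absorbed]
    for state, s, e in runs:
        dur = (e - s + 1) * epoch
        if merged and (dur < min_bout_s or state == merged[-1][0]):
            merged[-1][2] = e
            if state != merged[-1][0]:
                merged[-1][3] += 1
        else:
            merged.append([state, s, e, 0])

    times = processed.base.df["time"]
    bouts = []
    counters = {"walking": 0, "stopping": 0}
    for state, s, e, n_abs in merged:
        counters[state] += 1
        b = Bout(
            state=state,
            start=times.iloc[s],
            end=times.iloc[e],
            start_idx=s,
            end_idx=e,
            duration_s=(e - s + 1) * epoch,
            n_absorbed_runs=n_abs,
            index=counters[state],
        )
        bouts.append(bout_metrics(b, processed))
    return bouts


def bout_metrics(bout: Bout, processed: ProcessedTrace) -> Bout:
    """Complete a bout's distance and mean speed from the processed speeds.

    Distance integrates the processed speed over *all* epochs of the bout
    (absorbed zeros contribute nothing); mean speed is distance over the full
    bout duration, in km/h.  Stopping bouts carry 0 for both.
    """
    epoch = float(processed.base.epoch_s)
    if bout.state == "stopping":
        return replace(bout, distance_m=0.0, mean_speed_kmh=0.0)
    v = processed.speed_processed[bout.start_idx : bout.end_idx + 1]
    distance_m = float(np.sum(v / 3.6) * epoch)
    mean_speed_kmh = distance_m / bout.duration_s * 3.6
    return replace(bout, distance_m=distance_m, mean_speed_kmh=mean_speed_kmh)


def bouts_to_frame(bouts: list[Bout], session_id: str = "") -> pd.DataFrame:
    """Bout table with the export column layout."""
    return pd.DataFrame(
        {
            "session_id": session_id,
            "bout_no": range(1, len(bouts) + 1),
            "state": [b.state for b in bouts],
            "start": [b.start for b in bouts],
            "end": [b.end for b in bouts],
            "duration_s": [b.duration_s for b in bouts],
            "distance_m": [b.distance_m for b in bouts],
            "mean_speed_kmh": [b.mean_speed_kmh for b in bouts],
            "n_absorbed_runs": [b.n_absorbed_runs for b in bouts],
        }
    )
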