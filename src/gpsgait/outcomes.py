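"""Per-session walking-capacity outcomes from a validated bout sequence.

The session proper runs from the start of the first walking bout to the end
of the last walking bout; leading and trailing rest is trimmed before any
outcome is computed.  Session-level outcomes (duration, total walking time
and distance, time-weighted mean speed, number of interior stops) always use
every walking bout.  Capacity outcomes — maximal walking distance (MWD, the
greatest single-bout distance), per-bout distance/speed means and CVs, stop
duration statistics — optionally exclude the final walking bout: when a
session is ended by the protocol clock rather than by symptoms, its last
bout does not reflect walking capacity.  That judgement is human, so the
exclusion is a per-session flag, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .bouts import Bout

__all__ = ["SessionOutcomes", "session_outcomes", "batch_outcomes"]


def _cv_pct(values: np.ndarray) -> float:
    return 100.0 * float(np.std(values, ddof=1)) / float(np.mean(values))


@dataclass
class SessionOutcomes:
    """The full per-session outcome set.

    CV fields are ``None`` when fewer than two qualifying bouts (or stops)
    exist; stop-duration fields are ``None`` for stop-free sessions.
    """

    session_id: str
    session_duration_min: float
    total_walking_time_min: float
    total_walking_distance_m: float
    mean_speed_all_bouts_kmh: float
    n_stops: int
    mwd_m: float
    mwd_bout_index: int
    mwd_on_first_bout: bool
    mean_bout_distance_m: float
    cv_bout_distance_pct: float | None
    mean_bout_speed_kmh: float
    cv_bout_speed_pct: float | None
    mean_stop_duration_min: float | None
    cv_stop_duration_pct: float | None
    last_bout_excluded: bool

    def to_dict(self) -> dict:
        return asdict(self)


def session_outcomes(
    bouts: list[Bout],
    exclude_last: bool = False,
    session_id: str = "",
) -> SessionOutcomes:
    """Compute all session outcomes from an alternating bout sequence.

    When ``exclude_last`` is true and the session has at least two walking
    bouts, the final walking bout and the stop immediately before it are
    dropped from the capacity outcomes only; session duration, total walking
    time/distance and the session mean speed keep every bout.
    """
    walks_all = [b for b in bouts if b.state == "walking"]
    if not walks_all:
        raise ValueError("no walking detected")

    # Trim leading/trailing rest: session = first walk start -> last walk end.
    i0 = bouts.index(walks_all[0])
    i1 = bouts.index(walks_all[-1])
    session = bouts[i0 : i1 + 1]
    walks = [b for b in session if b.state == "walking"]
    stops = [b for b in session if b.state == "stopping"]  # interior by construction

    session_duration_s = sum(b.duration_s for b in session)
    total_walk_s = sum(b.duration_s for b in walks)
    total_dist_m = sum(b.distance_m for b in walks)
    mean_speed = total_dist_m / total_walk_s * 3.6

    excluded = bool(exclude_last) and len(walks) >= 2
    cap_walks = walks[:-1] if excluded else walks
    cap_stops = stops[:-1] if excluded and stops else stops

    dists = np.array([b.distance_m for b in cap_walks])
    speeds = np.array([b.mean_speed_kmh for b in cap_walks])
    mwd_pos = int(np.argmax(dists))
    mwd_bout_index = cap_walks[mwd_pos].index

    stop_durs_min = np.array([b.duration_s / 60.0 for b in cap_stops])

    return SessionOutcomes(
        session_id=session_id,
        session_duration_min=session_duration_s / 60.0,
        total_walking_time_min=total_walk_s / 60.0,
        total_walking_distance_m=total_dist_m,
        mean_speed_all_bouts_kmh=mean_speed,
        n_stops=len(stops),
        mwd_m=float(dists[mwd_pos]),
        mwd_bout_index=mwd_bout_index,
        mwd_on_first_bout=mwd_bout_index == 1,
        mean_bout_distance_m=float(np.mean(dists)),
        cv_bout_distance_pct=_cv_pct(dists) if len(dists) >= 2 else None,
        mean_bout_speed_kmh=float(np.mean(speeds)),
        cv_bout_speed_pct=_cv_pct(speeds) if len(speeds) >= 2 else None,
        mean_stop_duration_min=float(np.mean(stop_durs_min)) if len(stop_durs_min) else None,
        cv_stop_duration_pct=_cv_pct(stop_durs_min) if len(stop_durs_min) >= 2 else None,
        last_bout_excluded=excluded,
    )


def batch_outcomes(sessions) -> pd.DataFrame:
    """One outcome row per (bouts, config) session; failures become error rows.

    ``sessions`` yields ``(session_id, bouts, config)`` where config carries
    ``min_bout_s`` and ``exclude_last`` (echoed into the table).  A session
    that raises contributes a row with the error message instead of being
    silently dropped.
    """
    rows = []
    for session_id, bouts, config in sessions:
        min_bout_s = config.get("min_bout_s")
        exclude_last = bool(config.get("exclude_last", False))
        try:
            out = session_outcomes(bouts, exclude_last=exclude_last, session_id=session_id)
            row = out.to_dict()
            row["error"] = None
        except ValueError as exc:
            row = {"session_id": session_id, "error": str(exc)}
        row["min_bout_s"] = min_bout_s
        row["exclude_last"] = exclude_last
        rows.append(row)
    cols = [
        "session_id", "session_duration_min", "total_walking_time_min",
        "total_walking_distance_m", "mean_speed_all_bouts_kmh", "n_stops",
        "mwd_m", "mwd_bout_index", "mwd_on_first_bout", "mean_bout_distance_m",
        "cv_bout_distance_pct", "mean_bout_speed_kmh", "cv_bout_speed_pct",
        "mean_stop_duration_min", "cv_stop_duration_pct", "last_bout_excluded",
        "min_bout_s", "exclude_last", "error",
    ]
    return pd.DataFrame(rows, columns=cols)
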