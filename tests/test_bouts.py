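import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpsgait import detect_bouts, process_speed, bouts_to_frame
from gpsgait.speed_processing import CalibrationStats, ProcessedTrace

from conftest import make_trace


def processed_from(speeds):
    """Wrap a pre-conditioned speed vector as a ProcessedTrace."""
    tr = make_trace(speeds)
    c = CalibrationStats(3.0, 0.3, 10.0, 5, (None, None), 120.0)
    return ProcessedTrace(base=tr, speed_processed=np.asarray(speeds, float), calib=c)


# ---------------------------------------------------------------- oracle ---
def fixpoint_merge(states_durations, min_bout_s):
    """Independent oracle: repeatedly merge the first sub-threshold run
    (never the leading one) into its predecessor, coalescing same-state
    neighbours, until a fixed point."""
    runs = [list(r) for r in states_durations]  # [state, duration]
    changed = True
    while changed:
        changed = False
        # coalesce same-state neighbours first
        i = 1
        while i < len(runs):
            if runs[i][0] == runs[i - 1][0]:
                runs[i - 1][1] += runs[i][1]
                del runs[i]
                changed = True
            else:
                i += 1
        for i in range(1, len(runs)):
            if runs[i][1] < min_bout_s:
                runs[i - 1][1] += runs[i][1]
                del runs[i]
                changed = True
                break
    return [(s, d) for s, d in runs]


def speeds_from_runs(states_durations, walk_speed=3.6):
    parts = [
        np.full(int(d), walk_speed if s == "walking" else 0.0)
        for s, d in states_durations
    ]
    return np.concatenate(parts)


# -------------------------------------------------------------- examples ---
def test_short_interior_stop_is_absorbed_into_one_walking_bout():
    """walk 60 | stop 10 | walk 60 with the 15-s rule -> one 130-s walk."""
    runs = [("walking", 60), ("stopping", 10), ("walking", 60)]
    bouts = detect_bouts(processed_from(speeds_from_runs(runs)), 15)
    assert len(bouts) == 1
    b = bouts[0]
    assert (b.state, b.duration_s, b.n_absorbed_runs) == ("walking", 130.0, 1)


def test_long_stop_validates_a_state_shift():
    runs = [("walking", 60), ("stopping", 20), ("walking", 60)]
    bouts = detect_bouts(processed_from(speeds_from_runs(runs)), 15)
    assert [(b.state, b.duration_s) for b in bouts] == [
        ("walking", 60.0), ("stopping", 20.0), ("walking", 60.0),
    ]


def test_min_bout_zero_returns_maximal_runs_verbatim():
    runs = [("walking", 5), ("stopping", 2), ("walking", 9), ("stopping", 40)]
    bouts = detect_bouts(processed_from(speeds_from_runs(runs)), 0)
    assert [(b.state, b.duration_s) for b in bouts] == [
        (s, float(d)) for s, d in runs
    ]


def test_walking_distance_is_speed_integral():
    """100 epochs at 3.6 km/h (1 m/s) -> 100 m, mean speed 3.6 km/h."""
    bouts = detect_bouts(processed_from(np.full(100, 3.6)), 15)
    assert bouts[0].distance_m == pytest.approx(100.0)
    assert bouts[0].mean_speed_kmh == pytest.approx(3.6)


def test_stopping_bout_has_zero_distance_and_speed():
    bouts = detect_bouts(processed_from(np.zeros(30)), 15)
    assert (bouts[0].distance_m, bouts[0].mean_speed_kmh) == (0.0, 0.0)


def test_absorbed_zero_epochs_dilute_mean_speed():
    """130-s walk with a 10-s absorbed stop at 1 m/s: 120 m, ~3.32 km/h."""
    runs = [("walking", 60), ("stopping", 10), ("walking", 60)]
    b = detect_bouts(processed_from(speeds_from_runs(runs)), 15)[0]
    assert b.distance_m == pytest.approx(120.0)
    assert b.mean_speed_kmh == pytest.approx(120.0 / 130.0 * 3.6, abs=1e-9)
    assert b.mean_speed_kmh == pytest.approx(3.32, abs=0.005)


def test_trailing_subthreshold_run_is_absorbed():
    runs = [("walking", 60), ("stopping", 8)]
    bouts = detect_bouts(processed_from(speeds_from_runs(runs)), 15)
    assert len(bouts) == 1
    assert bouts[0].duration_s == 68.0


def test_bout_table_export_columns():
    runs = [("walking", 60), ("stopping", 20), ("walking", 30)]
    tbl = bouts_to_frame(detect_bouts(processed_from(speeds_from_runs(runs)), 15), "s1")
    assert list(tbl.columns) == [
        "session_id", "bout_no", "state", "start", "end",
        "duration_s", "distance_m", "mean_speed_kmh", "n_absorbed_runs",
    ]
    assert tbl["bout_no"].tolist() == [1, 2, 3]


# ------------------------------------------------------------ properties ---
@st.composite
def run_sequences(draw):
    n = draw(st.integers(1, 20))
    first = draw(st.booleans())
    runs = []
    for i in range(n):
        state = "walking" if (i % 2 == 0) == first else "stopping"
        runs.append((state, draw(st.integers(1, 40))))
    return runs


@settings(max_examples=80, deadline=None, derandomize=True)
@given(runs=run_sequences(), min_bout=st.integers(0, 20))
def test_merging_matches_fixpoint_oracle(runs, min_bout):
    bouts = detect_bouts(processed_from(speeds_from_runs(runs)), min_bout)
    assert [(b.state, b.duration_s) for b in bouts] == [
        (s, float(d)) for s, d in fixpoint_merge(runs, min_bout)
    ]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(runs=run_sequences())
def test_bouts_alternate_tile_span_and_conserve_distance(runs):
    speeds = speeds_from_runs(runs)
    p = processed_from(speeds)
    bouts = detect_bouts(p, 15)
    states = [b.state for b in bouts]
    assert all(a != b for a, b in zip(states, states[1:]))
    assert sum(b.duration_s for b in bouts) == pytest.approx(len(speeds))
    # walking-bout distance equals the speed integral over walking-bout
    # epochs (a walking flicker absorbed into a stopping bout carries none)
    walk_integral = sum(
        np.sum(speeds[b.start_idx : b.end_idx + 1] / 3.6)
        for b in bouts
        if b.state == "walking"
    )
    assert sum(b.distance_m for b in bouts) == pytest.approx(walk_integral)
    # interior bouts respect the minimum duration
    for b in bouts[1:-1]:
        assert b.duration_s >= 15


@settings(max_examples=40, deadline=None, derandomize=True)
@given(runs=run_sequences(), lo=st.integers(0, 15), hi=st.integers(0, 15))
def test_lowering_min_bout_never_decreases_bout_count(runs, lo, hi):
    lo, hi = min(lo, hi), max(lo, hi)
    p = processed_from(speeds_from_runs(runs))
    assert len(detect_bouts(p, lo)) >= len(detect_bouts(p, hi))
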