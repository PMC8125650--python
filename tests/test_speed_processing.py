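import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpsgait import (
    CalibrationStats,
    calibration_stats,
    process_speed,
    select_window,
    smooth_actions,
    spike_filter,
    suggest_calibration_window,
    zero_filter,
)

from conftest import make_trace


def calib(v_bar, sigma_v, window_len=120.0):
    """Hand-built calibration stats (K follows the 15% rule)."""
    cv = 100.0 * sigma_v / v_bar
    return CalibrationStats(
        v_bar=v_bar, sigma_v=sigma_v, cv_v=cv, K=2 if cv >= 15 else 5,
        window=(None, None), window_len_s=window_len,
    )


# ---------------------------------------------------------------- oracle ---
def naive_cascade(speed, v_bar, sigma_v, K):
    """Deliberately naive index-by-index reference of the seven passes."""
    v = [float(x) for x in speed]
    n = len(v)

    def mean_following(vec, i):
        window = vec[i + 1 : i + 6]
        return sum(window) / len(window) if window else None

    # pass 1: spike filter on the raw list
    raw = list(v)
    out = list(v)
    for i in range(n):
        if raw[i] > 2 * v_bar:
            m = mean_following(raw, i)
            if m is not None:
                out[i] = m
            else:
                j = i - 1
                while j >= 0 and raw[j] > 2 * v_bar:
                    j -= 1
                out[i] = raw[j] if j >= 0 else v_bar
    v = out
    # pass 2: zero threshold
    T = v_bar - K * sigma_v
    if T > 0:
        v = [0.0 if x < T else x for x in v]
    # passes 3-7: actions, each a full in-place left-to-right sweep
    for action in (1, 2, 3, 4, 5):
        for i in range(n):
            if action == 1:
                if i - 1 >= 0 and v[i - 1] == 0 and v[i] > 0:
                    m = mean_following(v, i)
                    if m is not None:
                        v[i] = m
            elif action in (2, 3):
                if (
                    v[i] == 0 and i - 2 >= 0 and i + 3 < n
                    and v[i - 2] > 0 and v[i - 1] > 0 and v[i + 2] > 0 and v[i + 3] > 0
                ):
                    v[i] = (v[i - 2] + v[i - 1] + v[i + 2] + v[i + 3]) / 4.0
            else:
                if (
                    v[i] > 0 and i - 2 >= 0 and i + 3 < n
                    and v[i - 2] == 0 and v[i - 1] == 0 and v[i + 2] == 0 and v[i + 3] == 0
                ):
                    v[i] = 0.0
    return np.array(v)


# ------------------------------------------------------------ window ops ---
def test_select_window_full_span_is_identity():
    tr = make_trace([1.0, 2.0, 3.0])
    assert select_window(tr, 0, 2).speed == pytest.approx(tr.speed)


def test_select_window_single_epoch():
    tr = make_trace([1.0, 2.0, 3.0])
    assert len(select_window(tr, 1, 1)) == 1


def test_select_window_closed_interval_epoch_count():
    """Minutes 1-31 of a 60-min trace: 1801 epochs (inclusive endpoints)."""
    tr = make_trace(np.ones(3600))
    assert len(select_window(tr, 60, 1860)) == 1801


def test_select_window_empty_selection_errors():
    tr = make_trace([1.0, 2.0])
    with pytest.raises(ValueError, match="empty selection"):
        tr.slice_time(10, 20)


# ----------------------------------------------------------- calibration ---
def test_calibration_constant_signal():
    tr = make_trace(np.full(120, 3.0))
    c = calibration_stats(tr, (0, 119))
    assert (c.v_bar, c.sigma_v, c.cv_v, c.K) == (3.0, 0.0, 0.0, 5)


def test_calibration_alternating_signal_uses_sample_sd():
    tr = make_trace([2.0, 4.0] * 60)
    c = calibration_stats(tr, (0, 119))
    assert c.v_bar == pytest.approx(3.0)
    assert c.sigma_v == pytest.approx(1.0042, abs=1e-4)  # divisor n-1
    assert c.cv_v == pytest.approx(33.47, abs=0.01)
    assert c.K == 2


def test_cv_boundary_of_exactly_15_percent_gives_K2():
    # mean 20, sample sd 3: CV is exactly 15.0 in floating point
    tr = make_trace([17.0, 20.0, 23.0])
    c = calibration_stats(tr, (0, 2))
    assert c.cv_v == 15.0
    assert c.K == 2


def test_calibration_rejects_no_movement_and_long_windows():
    with pytest.raises(ValueError, match="no movement"):
        calibration_stats(make_trace(np.zeros(10)), (0, 9))
    with pytest.raises(ValueError, match="at most 120"):
        calibration_stats(make_trace(np.ones(200)), (0, 125))


def test_suggest_calibration_window_prefers_steady_walking():
    v = np.concatenate([np.zeros(60), np.full(200, 3.0), np.full(100, 3.0) + 1.5])
    tr = make_trace(v)
    start, end = suggest_calibration_window(tr, window_s=120)
    idx0 = int((start - tr.start_time).total_seconds())
    assert 60 <= idx0 and idx0 + 119 < 260  # inside the constant stretch


# ---------------------------------------------------------------- stages ---
def test_spike_filter_replaces_with_mean_of_five_following():
    c = calib(2.5, 0.1)
    v = [2.5, 2.5, 6.0, 2.5, 2.5, 2.5, 2.5, 2.5]
    out = spike_filter(np.array(v), c)
    assert out[2] == pytest.approx(2.5)
    assert out == pytest.approx([2.5, 2.5, 2.5, 2.5, 2.5, 2.5, 2.5, 2.5])


def test_spike_filter_is_noop_without_spikes():
    c = calib(2.5, 0.1)
    v = np.array([2.0, 3.0, 4.9, 1.0])
    assert spike_filter(v, c) == pytest.approx(v)


def test_spike_filter_edge_uses_available_following_epochs():
    c = calib(2.0, 0.1)
    v = np.array([2.0, 2.0, 2.0, 5.0, 2.0, 2.2])
    assert spike_filter(v, c)[3] == pytest.approx(2.1)


def test_spike_filter_final_epoch_takes_last_non_spike_value():
    c = calib(2.0, 0.1)
    v = np.array([2.0, 1.8, 9.0])
    assert spike_filter(v, c)[2] == pytest.approx(1.8)


def test_zero_filter_thresholds_strictly_below():
    c = calib(3.0, 0.6)  # CV 20% -> K=2 -> T=1.8
    assert c.zero_threshold_kmh == pytest.approx(1.8)
    out = zero_filter(np.array([2.5, 1.0, 1.9, 1.8]), c)
    assert out == pytest.approx([2.5, 0.0, 1.9, 1.8])  # exactly-T value kept


def test_zero_filter_disabled_when_threshold_not_positive(caplog):
    c = CalibrationStats(3.0, 0.9, 30.0, 5, (None, None), 120.0)  # T = -1.5
    v = np.array([0.2, 3.0, 0.1])
    with caplog.at_level("WARNING", logger="gpsgait.speed_processing"):
        out = zero_filter(v, c)
    assert out == pytest.approx(v)
    assert any("disabled" in r.message for r in caplog.records)


def test_action2_fills_isolated_zero_inside_walking():
    out = smooth_actions(np.array([2.0, 2.0, 0.0, 2.0, 2.0, 2.0]))
    assert out == pytest.approx([2.0] * 6)


def test_isolated_positive_epoch_inside_rest_is_erased():
    out = smooth_actions(np.array([0, 0, 0, 3.0, 0, 0, 0, 0]))
    assert out == pytest.approx(np.zeros(8))


def test_all_zero_vector_is_a_fixed_point_of_smoothing():
    assert smooth_actions(np.zeros(50)) == pytest.approx(np.zeros(50))


def test_cascade_is_fixed_point_on_constant_positive_vector():
    tr = make_trace(np.full(300, 3.0))
    c = calibration_stats(tr, (0, 119))
    p = process_speed(tr, c)
    assert p.speed_processed == pytest.approx(tr.speed)
    assert p.stages_applied == [
        "spike_filter", "zero_filter",
        "action_1", "action_2", "action_3", "action_4", "action_5",
    ]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(1, 300),
    cv=st.floats(5.0, 40.0),
)
def test_cascade_matches_naive_oracle_on_random_vectors(seed, n, cv):
    """Pipelined implementation == index-by-index reference of all 7 passes."""
    rng = np.random.default_rng(seed)
    # mixture of rest, walking and spikes, like a real conditioned signal
    v = rng.choice([0.0, 1.0], size=n, p=[0.35, 0.65]) * rng.uniform(1.5, 4.5, n)
    v[rng.random(n) < 0.03] *= 3.0
    v_bar = 3.0
    sigma_v = v_bar * cv / 100.0
    c = calib(v_bar, sigma_v)
    tr = make_trace(v)
    got = process_speed(tr, c).speed_processed
    expected = naive_cascade(v, v_bar, sigma_v, c.K)
    assert got == pytest.approx(expected)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(1, 200))
def test_stage_invariants_on_random_vectors(seed, n):
    """Each stage preserves length and non-negativity; the zero filter never
    increases a value; smoothing never drives anything negative."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(0, 6, n) * (rng.random(n) < 0.7)
    c = calib(3.0, 0.6)
    s1 = spike_filter(v, c)
    s2 = zero_filter(s1, c)
    s3 = smooth_actions(s2)
    for s in (s1, s2, s3):
        assert len(s) == n
        assert np.min(s) >= 0 if n else True
    assert np.all(s2 <= s1)
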