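"""Event detection: confidence filtering, I-DT fixations, saccades, blinks."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import surgaze as sg
from surgaze import events as ev

from conftest import make_stream, stationary_stream


# ---------------------------------------------------------------- filtering

def test_filter_threshold_zero_is_identity():
    rng = np.random.default_rng(0)
    n = 50
    s = make_stream(np.arange(n) / 200, rng.normal(size=n), rng.normal(size=n),
                    conf=rng.uniform(0, 1, n))
    out = ev.filter_by_confidence(s, 0.0)
    assert len(out) == n
    np.testing.assert_array_equal(out.x, s.x)


def test_filter_threshold_one_empties_half_confidence_stream():
    n = 20
    s = make_stream(np.arange(n) / 200, np.zeros(n), np.zeros(n), conf=np.full(n, 0.5))
    assert len(ev.filter_by_confidence(s, 1.0)) == 0


def test_filter_count_matches_linear_scan_oracle():
    rng = np.random.default_rng(7)
    n = 500
    conf = rng.uniform(0, 1, n)
    s = make_stream(np.arange(n) / 200, np.zeros(n), np.zeros(n), conf=conf)
    out = ev.filter_by_confidence(s, 0.6)
    expected = sum(1 for c in conf if c >= 0.6)  # brute-force scan
    assert len(out) == expected
    assert np.all(np.diff(out.t) > 0)  # order preserved


def test_filter_rejects_out_of_range_threshold():
    s = stationary_stream(0.1)
    with pytest.raises(ValueError):
        ev.filter_by_confidence(s, 1.5)


# ---------------------------------------------------------- dispersion metric

def _brute_force_dispersion(x, y):
    best = 0.0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            best = max(best, math.hypot(x[i] - x[j], y[i] - y[j]))
    return best


def test_dispersion_single_sample_is_zero():
    assert ev.angular_dispersion([3.0], [4.0]) == 0.0


def test_dispersion_two_samples_one_axis():
    assert ev.angular_dispersion([0.0, 1.0], [2.0, 2.0]) == pytest.approx(1.0)


@pytest.mark.parametrize("n,seed", [(20, 0), (20, 1), (200, 2), (800, 3)])
def test_dispersion_equals_pairwise_maximum_oracle(n, seed):
    """The metric must equal the O(n^2) max over all pairs, incl. hull path."""
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=n), rng.normal(size=n)
    assert ev.angular_dispersion(x, y) == pytest.approx(_brute_force_dispersion(x, y))


@settings(max_examples=50, deadline=None)
@given(hst.lists(hst.tuples(hst.floats(-10, 10), hst.floats(-10, 10)),
                 min_size=2, max_size=30))
def test_dispersion_reorder_invariant(pts):
    x = [p[0] for p in pts]
    y = [p[1] for p in pts]
    d1 = ev.angular_dispersion(x, y)
    d2 = ev.angular_dispersion(list(reversed(x)), list(reversed(y)))
    assert d1 == pytest.approx(d2)


# ------------------------------------------------------------- I-DT detector

def test_stationary_200ms_dwell_is_one_fixation():
    s = stationary_stream(0.200)
    fx = ev.detect_fixations(s)
    assert len(fx) == 1
    assert fx[0].duration == pytest.approx(0.200, abs=1e-9)
    assert fx[0].dispersion == 0.0
    assert fx[0].centroid_x == pytest.approx(5.0)


def test_50ms_dwell_below_floor_yields_nothing():
    assert ev.detect_fixations(stationary_stream(0.050)) == []


def test_empty_stream_yields_empty_list():
    s = make_stream([], [], [], conf=[])
    assert ev.detect_fixations(s) == []


def test_long_dwell_splits_into_capped_fixations():
    """A 700 ms stationary dwell: one 420 ms fixation plus a >=80 ms remainder."""
    s = stationary_stream(0.700)
    fx = ev.detect_fixations(s)
    assert len(fx) == 2
    assert fx[0].duration == pytest.approx(0.420, abs=1e-9)
    assert fx[1].duration >= 0.080 - 1e-9
    assert fx[0].end < fx[1].start


def test_gap_breaks_window():
    """Two 150 ms dwells separated by a 4-sample hole are two fixations."""
    rate = 200.0
    n = 31
    t1 = np.arange(n) / rate
    t2 = t1[-1] + 4 / rate + np.arange(1, n + 1) / rate
    t = np.concatenate([t1, t2])
    x = np.full(len(t), 1.0)
    s = make_stream(t, x, x, rate=rate)
    fx = ev.detect_fixations(s)
    assert len(fx) == 2


def test_dispersion_threshold_rejects_wide_cloud():
    rate = 200.0
    n = 41
    t = np.arange(n) / rate
    x = np.where(np.arange(n) % 2 == 0, 0.0, 2.0)  # 2 deg alternation
    s = make_stream(t, x, np.zeros(n), rate=rate)
    assert ev.detect_fixations(s) == []


def test_detected_fixations_satisfy_bounds_on_synthetic_session(detected_short):
    fx, _ = detected_short
    assert fx, "expected fixations on a 60 s session"
    for f in fx:
        assert 0.080 - 1e-9 <= f.duration <= 0.420 + 1e-9
        assert f.dispersion <= 1.50


def test_detector_recovers_ground_truth_exactly_on_clean_stream(detected_short):
    """Confidence gaps delimit dwells: detected count equals the log exactly."""
    fx, log = detected_short
    gt = log.fixations
    assert len(fx) == len(gt)
    for f, g in zip(fx, gt):
        assert f.start == pytest.approx(g.start, abs=1e-9)
        assert f.duration == pytest.approx(g.duration, abs=1e-9)


def test_noise_free_profile_gives_zero_dispersion(geometry, surfaces, attending):
    prof = attending.with_(noise_sd=0.0)
    stream, log = sg.generate_session(prof, geometry, surfaces, 5.0, seed=3)
    fx = ev.detect_fixations(ev.filter_by_confidence(stream, 0.6))
    assert len(fx) == len(log.fixations)
    assert all(f.dispersion == 0.0 for f in fx)


def test_unsorted_timestamps_rejected():
    with pytest.raises(ValueError):
        make_stream([0.0, 0.01, 0.005], [0, 0, 0], [0, 0, 0])


@pytest.mark.parametrize("seed", range(6))
def test_raising_dispersion_absorbs_no_fewer_samples_single_window(seed):
    """Monotonicity holds in the single-window regime.

    (Globally, greedy I-DT absorption is not monotone in the threshold:
    a wider first window can strand a sub-80 ms tail that a narrower
    threshold would have split into two kept fixations.)
    """
    rng = np.random.default_rng(seed)
    rate = 200.0
    n = 30  # 145 ms: at most one window fits
    t = np.arange(n) / rate
    x = np.cumsum(rng.normal(0, 0.2, n))
    y = np.cumsum(rng.normal(0, 0.2, n))
    s = make_stream(t, x, y, rate=rate)
    prev = -1
    for disp in (0.3, 0.6, 1.0, 1.5, 2.5, 4.0):
        fx = ev.detect_fixations(s, max_dispersion=disp)
        absorbed = sum(f.n_samples for f in fx)
        assert absorbed >= prev
        prev = absorbed


# ------------------------------------------------------------------ saccades

def _fix(start, end, cx, cy):
    return ev.Fixation(start=start, end=end, centroid_x=cx, centroid_y=cy,
                       dispersion=0.0, n_samples=2)


def test_two_fixations_give_one_saccade_with_centroid_distance():
    fx = [_fix(0.0, 0.1, 0.0, 0.0), _fix(0.12, 0.2, 0.3, 0.0)]
    sac = ev.extract_saccades(fx)
    assert len(sac) == 1
    assert sac[0].amplitude == pytest.approx(0.3)
    assert sac[0].duration == pytest.approx(0.02)


def test_n_fixations_give_n_minus_one_saccades():
    fx = [_fix(0.15 * i, 0.15 * i + 0.1, 0.1 * i, 0.0) for i in range(7)]
    assert len(ev.extract_saccades(fx)) == 6
    assert len(ev.extract_saccades(fx, max_gap=None)) == 6


def test_fewer_than_two_fixations_give_empty():
    assert ev.extract_saccades([]) == []
    assert ev.extract_saccades([_fix(0, 0.1, 0, 0)]) == []


def test_long_gaps_are_not_saccades_unless_disabled():
    fx = [_fix(0.0, 0.1, 0.0, 0.0), _fix(0.5, 0.6, 1.0, 0.0)]  # 400 ms gap
    assert ev.extract_saccades(fx) == []
    assert len(ev.extract_saccades(fx, max_gap=None)) == 1


# -------------------------------------------------------------------- blinks

def test_constant_full_confidence_has_no_blinks():
    s = stationary_stream(1.0)
    assert ev.detect_blinks(s) == []


def test_single_200ms_dropout_is_one_blink():
    rate = 200.0
    n = 200
    conf = np.ones(n)
    conf[50:91] = 0.0  # 40 * 5 ms = 200 ms span
    s = make_stream(np.arange(n) / rate, np.zeros(n), np.zeros(n), conf=conf)
    blinks = ev.detect_blinks(s, confidence_floor=0.5, min_duration=0.1)
    assert len(blinks) == 1
    assert blinks[0].duration == pytest.approx(0.200, abs=1e-9)


def test_short_dropouts_ignored():
    rate = 200.0
    n = 100
    conf = np.ones(n)
    conf[10:13] = 0.0  # 10 ms
    s = make_stream(np.arange(n) / rate, np.zeros(n), np.zeros(n), conf=conf)
    assert ev.detect_blinks(s, 0.5, 0.1) == []


def test_generated_blink_rate_recovered(geometry, surfaces, attending):
    """Recovered blink rate within 3 SE of the profile rate over replicates."""
    rates = []
    for i in range(12):
        stream, _ = sg.generate_session(attending, geometry, surfaces, 60.0, seed=100 + i)
        blinks = ev.detect_blinks(stream)
        rates.append(len(blinks) / (stream.duration / 60.0))
    rates = np.asarray(rates)
    se = rates.std(ddof=1) / np.sqrt(len(rates))
    assert abs(rates.mean() - attending.blink_rate) <= 3 * se + 1e-12


# ----------------------------------------------------------- session metrics

def test_session_metrics_hand_computed():
    fx = [_fix(0.0, 0.1, 0, 0), _fix(0.2, 0.4, 1, 0), _fix(0.5, 0.65, 1, 1)]
    sac = ev.extract_saccades(fx, max_gap=None)
    m = ev.session_metrics(fx, sac, [ev.Blink(1.0, 1.2)], total_duration=30.0)
    assert m.fixation_count == 3
    assert m.mean_fixation_duration == pytest.approx((0.1 + 0.2 + 0.15) / 3)
    assert m.mean_saccade_amplitude == pytest.approx((1.0 + 1.0) / 2)
    assert m.blink_rate == pytest.approx(2.0)  # 1 blink / 0.5 min


def test_session_metrics_empty_uses_nan_sentinels():
    m = ev.session_metrics([], [], [], total_duration=10.0)
    assert m.fixation_count == 0
    assert math.isnan(m.mean_fixation_duration)
    assert math.isnan(m.mean_saccade_amplitude)
    assert m.blink_rate == 0.0


def test_session_metrics_rejects_zero_duration():
    with pytest.raises(ValueError):
        ev.session_metrics([], [], [], total_duration=0.0)


# ------------------------------------------------------------------- file IO

def test_gaze_csv_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    n = 64
    s = make_stream(np.arange(n) / 200, rng.normal(size=n), rng.normal(size=n),
                    conf=rng.uniform(0, 1, n))
    p = tmp_path / "stream.csv"
    ev.write_gaze_csv(s, p)
    back = ev.read_gaze_csv(p)
    np.testing.assert_allclose(back.x, s.x)
    np.testing.assert_allclose(back.confidence, s.confidence)


def test_events_csv_written_with_all_kinds(tmp_path, detected_short):
    fx, _ = detected_short
    sac = ev.extract_saccades(fx)
    p = tmp_path / "events.csv"
    ev.write_events_csv(fx, sac, [ev.Blink(0.5, 0.7)], p)
    df = ev.read_events_csv(p)
    assert set(df.kind) == {"fixation", "saccade", "blink"}
    assert (df.kind == "fixation").sum() == len(fx)
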