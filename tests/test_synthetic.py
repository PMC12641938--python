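"""Synthetic-data generator: determinism, moment fidelity, ground truth."""

from __future__ import annotations

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

import surgaze as sg
from surgaze import aoi as am
from surgaze import events as ev
from surgaze.sampling import truncated_normal_mean_matched, truncated_lognormal_mean_matched
from surgaze.synthetic import derive_seed


# ------------------------------------------------------------- determinism

def test_same_profile_and_seed_reproduce_identical_stream(attending, geometry, surfaces):
    s1, l1 = sg.generate_session(attending, geometry, surfaces, 10.0, seed=42)
    s2, l2 = sg.generate_session(attending, geometry, surfaces, 10.0, seed=42)
    np.testing.assert_array_equal(s1.t, s2.t)
    np.testing.assert_array_equal(s1.x, s2.x)
    np.testing.assert_array_equal(s1.y, s2.y)
    np.testing.assert_array_equal(s1.confidence, s2.confidence)
    assert l1.events == l2.events


def test_different_seeds_differ(attending, geometry, surfaces):
    s1, _ = sg.generate_session(attending, geometry, surfaces, 10.0, seed=1)
    s2, _ = sg.generate_session(attending, geometry, surfaces, 10.0, seed=2)
    assert not np.array_equal(s1.x, s2.x)


# ------------------------------------------------------------ stream shape

def test_stream_sampled_at_nominal_rate(short_session, geometry):
    stream, _ = short_session
    dt = np.diff(stream.t)
    assert np.allclose(dt, 1.0 / geometry.nominal_rate, atol=1e-12)
    assert stream.t[-1] <= 60.0


def test_subminimal_duration_yields_no_fixations(attending, geometry, surfaces):
    """A 50 ms recording is shorter than the 80 ms fixation floor."""
    stream, log = sg.generate_session(attending, geometry, surfaces, 0.05, seed=0)
    assert log.fixations == []
    assert ev.detect_fixations(ev.filter_by_confidence(stream, 0.6)) == []


def test_single_dwell_session_with_zero_noise(attending, geometry, surfaces):
    """Zero jitter: exactly one ground-truth fixation with zero dispersion."""
    prof = attending.with_(noise_sd=0.0, fixation_duration_sd=0.0)
    stream, log = sg.generate_session(prof, geometry, surfaces, 0.18, seed=5)
    assert len(log.fixations) == 1
    f = log.fixations[0]
    seg = (stream.t >= f.start - 1e-12) & (stream.t <= f.end + 1e-12) & (stream.confidence >= 0.6)
    assert ev.angular_dispersion(stream.x[seg], stream.y[seg]) == 0.0


def test_invalid_profile_parameter_named():
    with pytest.raises(ValueError, match="noise_sd"):
        sg.STUDY_PROFILES["attending"].with_(noise_sd=0.5)
    with pytest.raises(ValueError, match="mean_fixation_duration"):
        sg.STUDY_PROFILES["attending"].with_(mean_fixation_duration=0.5)
    with pytest.raises(ValueError, match="aoi_proportions"):
        sg.STUDY_PROFILES["attending"].with_(
            aoi_proportions={"HUD": 0.5, "instrument_field": 0.3, "peripheral": 0.1}
        )


# -------------------------------------------------------- ground-truth log

def test_ground_truth_fixations_satisfy_classification_bounds(short_session):
    stream, log = short_session
    t = stream.t
    for f in log.fixations:
        assert 0.080 - 1e-9 <= f.duration <= 0.420 + 1e-9
        seg = (t >= f.start - 1e-12) & (t <= f.end + 1e-12)
        d = ev.angular_dispersion(stream.x[seg], stream.y[seg])
        assert d <= 1.50
    # non-overlap per kind, times in session bounds
    for kind in ("fixation", "saccade", "blink"):
        evs = log.of_kind(kind)
        for a, b in zip(evs, evs[1:]):
            assert b.start >= a.end - 1e-12
        for e in evs:
            assert 0.0 <= e.start <= e.end <= 60.0 + 1e-9


def test_ground_truth_aoi_labels_match_surface_containment(short_session, surfaces, geometry):
    _, log = short_session
    polys = {s.label: Polygon(s.vertices) for s in surfaces}
    for f in log.fixations[::10]:
        px, py = geometry.deg_to_px(f.centroid_x, f.centroid_y)
        assert polys[f.aoi].buffer(1e-6).contains(Point(float(px), float(py)))


# ---------------------------------------------------------- moment fidelity

def test_dwell_duration_moment_fidelity(attending, geometry, surfaces):
    """Over >=50 seeds, mean generated dwell duration within 3 SE of profile."""
    means = []
    for i in range(50):
        _, log = sg.generate_session(attending, geometry, surfaces, 30.0, seed=500 + i)
        means.append(np.mean([f.duration for f in log.fixations]))
    means = np.asarray(means)
    se = means.std(ddof=1) / math.sqrt(len(means))
    assert abs(means.mean() - attending.mean_fixation_duration) <= 3 * se


def test_aoi_fidelity_of_ground_truth_fixations(pgy2, geometry, surfaces):
    """Empirical AOI fractions within 3 SE of the profile proportions."""
    shares = {lab: [] for lab in sg.AOI_LABELS}
    for i in range(40):
        _, log = sg.generate_session(pgy2, geometry, surfaces, 60.0, seed=900 + i)
        fx = log.fixations
        for lab in sg.AOI_LABELS:
            shares[lab].append(sum(1 for f in fx if f.aoi == lab) / len(fx))
    for lab in sg.AOI_LABELS:
        v = np.asarray(shares[lab])
        se = v.std(ddof=1) / math.sqrt(len(v))
        assert abs(v.mean() - pgy2.aoi_proportions[lab]) <= 3 * se + 1e-12, lab


# -------------------------------------------------------- surfaces & masks

def test_surfaces_tile_frame_disjointly(surfaces, geometry):
    polys = [Polygon(s.vertices) for s in surfaces]
    union = unary_union(polys)
    frame_area = geometry.width_px * geometry.height_px
    assert union.area == pytest.approx(frame_area)
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            assert polys[i].intersection(polys[j]).area == pytest.approx(0.0)


def test_surface_file_round_trip(surfaces, tmp_path):
    for ext in ("yaml", "json"):
        p = tmp_path / f"surfaces.{ext}"
        am.write_surfaces(surfaces, p)
        back = am.read_surfaces(p)
        assert [s.label for s in back] == [s.label for s in surfaces]
        for a, b in zip(back, surfaces):
            assert a.vertices == b.vertices


def test_mask_radius_zero_has_no_blue(geometry):
    mask = sg.generate_mask_image(geometry, ((640.0, 360.0), 0.0))
    assert int(mask.blue_mask().sum()) == 0


def test_mask_blue_area_matches_disk_formula(geometry):
    r = 150.0
    mask = sg.generate_mask_image(geometry, ((640.0, 360.0), r))
    count = int(mask.blue_mask().sum())
    assert abs(count - math.pi * r**2) <= 2 * math.pi * r + 10  # rasterization


def test_mask_png_round_trip_preserves_blue_exactly(geometry, tmp_path):
    from surgaze import coverage as cov

    mask = sg.generate_mask_image(geometry, ((300.0, 300.0), 80.0))
    p = tmp_path / "mask.png"
    cov.write_mask_png(mask, p)
    back = cov.read_mask_png(p)
    np.testing.assert_array_equal(back.blue_mask(), mask.blue_mask())


def test_mask_circle_outside_frame_rejected(geometry):
    with pytest.raises(ValueError):
        sg.generate_mask_image(geometry, ((10.0, 10.0), 50.0))


# ------------------------------------------------------- tear annotations

def test_tear_angle_exact_when_sd_zero():
    prof = sg.STUDY_PROFILES["PGY4"].with_(tear_angle_mean=45.0, tear_angle_sd=0.0)
    for seed in range(5):
        ann = sg.generate_tear_annotation(prof, seed=seed)
        assert sg.tear_angle(ann) == pytest.approx(45.0, abs=1e-9)


def test_tear_annotation_reproducible(attending):
    a1 = sg.generate_tear_annotation(attending, seed=9)
    a2 = sg.generate_tear_annotation(attending, seed=9)
    assert a1 == a2


@pytest.mark.parametrize("label,target", [("attending", 6.0), ("PGY2", 88.4)])
def test_tear_angle_group_means_recovered(label, target):
    prof = sg.STUDY_PROFILES[label]
    angles = [
        sg.tear_angle(sg.generate_tear_annotation(prof, seed=derive_seed(3, label, i)))
        for i in range(40)
    ]
    a = np.asarray(angles)
    se = a.std(ddof=1) / math.sqrt(len(a))
    assert abs(a.mean() - target) <= 3 * se


def test_tear_diameter_fraction_matches_profile(attending):
    fracs = [
        sg.diameter_fraction(sg.generate_tear_annotation(attending, seed=i))
        for i in range(40)
    ]
    f = np.asarray(fracs)
    se = f.std(ddof=1) / math.sqrt(len(f))
    assert abs(f.mean() - attending.diameter_fraction_mean) <= 3 * se + 1e-3


def test_tear_outline_expert_more_circular_than_novice():
    att = np.mean([
        sg.circularity(sg.generate_tear_outline(sg.STUDY_PROFILES["attending"], seed=i))
        for i in range(10)
    ])
    nov = np.mean([
        sg.circularity(sg.generate_tear_outline(sg.STUDY_PROFILES["PGY2"], seed=i))
        for i in range(10)
    ])
    assert att > nov
    assert att > 0.98


# ---------------------------------------------------------------- cohorts

def test_cohort_counts_and_manifest_determinism(geometry, surfaces):
    profiles = [sg.STUDY_PROFILES[g] for g in sg.GROUP_ORDER]
    rec1, man1 = sg.generate_cohort(profiles, 5, base_seed=7, geometry=geometry,
                                    surfaces=surfaces, duration=2.0)
    assert len(rec1) == 25
    _, man2 = sg.generate_cohort(profiles, 5, base_seed=7, geometry=geometry,
                                 surfaces=surfaces, duration=2.0)
    assert man1 == man2
    seeds = [s["seed"] for s in man1["sessions"]]
    assert len(set(seeds)) == len(seeds)
    assert all(0 <= s < 2**31 for s in seeds)


def test_cohort_n1_and_duplicate_labels(geometry, surfaces):
    profiles = [sg.STUDY_PROFILES["PGY2"], sg.STUDY_PROFILES["attending"]]
    rec, _ = sg.generate_cohort(profiles, 1, base_seed=1, geometry=geometry,
                                surfaces=surfaces, duration=2.0)
    assert len(rec) == 2
    with pytest.raises(ValueError, match="duplicate"):
        sg.generate_cohort([profiles[0], profiles[0]], 2, 1, geometry, surfaces, 2.0)


# ------------------------------------------------------ truncated samplers

@pytest.mark.parametrize(
    "target,sd,lo,hi",
    [(0.118, 0.016, 0.085, 0.415), (0.286, 0.152, 0.085, 0.415), (88.4, 14.3, 0.0, 180.0)],
)
def test_truncated_normal_mean_matching(target, sd, lo, hi):
    rng = np.random.default_rng(0)
    draws = truncated_normal_mean_matched(target, sd, lo, hi, rng, size=200_000)
    assert np.all((draws >= lo) & (draws <= hi))
    assert np.mean(draws) == pytest.approx(target, abs=4 * sd / math.sqrt(len(draws)))


@pytest.mark.parametrize("target", [0.09, 0.118, 0.286, 0.41])
def test_truncated_lognormal_mean_matching(target):
    rng = np.random.default_rng(1)
    draws = truncated_lognormal_mean_matched(target, 0.45, 0.08, 0.42, rng, size=200_000)
    assert np.all((draws >= 0.08) & (draws <= 0.42))
    se = draws.std() / math.sqrt(len(draws))
    assert np.mean(draws) == pytest.approx(target, abs=4 * se)
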