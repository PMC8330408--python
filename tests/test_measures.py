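"""Per-bolus measurement: timing grid, anatomical scaling, geometry,
hyoid kinematics, and the annotation -> parameter-record assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from swallowkit import (
    BolusAnnotation,
    ConfigurationError,
    ContourSet,
    EventFrames,
    EventOrderError,
    GeometryError,
    HyoidTrack,
    SpineLandmarks,
    anatomical_transform,
    compute_hyoid_kinematics,
    compute_timing,
    frames_to_ms,
    polygon_area,
    summarize_bolus,
)


# --- frame -> ms conversion ----------------------------------------------

@pytest.mark.parametrize(
    "start,end,fps,expected",
    [
        (0, 15, 30, 500),  # 15 frames at 30 fps
        (5, 5, 30, 0),
        (0, 1, 30, 34),
        (0, 2, 30, 67),
        (0, 4, 30, 134),
        (0, 11, 30, 367),
        (0, 14, 30, 467),
        (0, 16, 30, 534),
        (0, 19, 30, 634),
        (0, 30, 30, 1000),
        (0, 3, 25, 120),
    ],
)
def test_frames_to_ms_ceiling_grid(start, end, fps, expected):
    assert frames_to_ms(start, end, fps) == expected


def test_frames_to_ms_matches_ceiling_oracle():
    # independent closed form at 30 fps: ceil(k * 100 / 3)
    for k in range(200):
        assert frames_to_ms(0, k, 30) == math.ceil(k * 100 / 3)


def test_frames_to_ms_monotone_in_interval_length():
    vals = [frames_to_ms(0, k, 30) for k in range(100)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_frames_to_ms_errors_and_signed():
    with pytest.raises(EventOrderError):
        frames_to_ms(10, 5, 30)
    assert frames_to_ms(10, 5, 30, signed=True) == -frames_to_ms(5, 10, 30)
    with pytest.raises(ConfigurationError):
        frames_to_ms(0, 1, 0)
    with pytest.raises(ConfigurationError):
        frames_to_ms(0, 1, 30, convention="bogus")


def test_frames_to_ms_alternative_conventions():
    assert frames_to_ms(0, 2, 30, convention="floor") == 66
    assert frames_to_ms(0, 2, 30, convention="round") == 67
    assert frames_to_ms(0, 1, 30, convention="round") == 33


# --- anatomical transform -------------------------------------------------

def test_transform_c2_maps_to_unit_y():
    lm = SpineLandmarks(c2ai=(0.0, -30.0), c4ai=(0.0, 0.0))
    np.testing.assert_allclose(anatomical_transform(lm, (0.0, -30.0)), [0.0, 100.0])
    np.testing.assert_allclose(anatomical_transform(lm, (0.0, 0.0)), [0.0, 0.0])


def test_transform_rotated_frame_matches_rotation_oracle():
    # independent construction: place the spine at 37 degrees, length 25 px,
    # and a probe point 50 px along the anterior perpendicular from C4
    theta = math.radians(37.0)
    c4 = np.array([12.0, 7.0])
    u = np.array([math.cos(theta), math.sin(theta)])
    c2 = c4 + 25.0 * u
    anterior = np.array([u[1], -u[0]])  # left-facing projection
    probe = c4 + 50.0 * anterior
    lm = SpineLandmarks(c2ai=c2, c4ai=c4)
    np.testing.assert_allclose(
        anatomical_transform(lm, probe), [200.0, 0.0], atol=1e-9
    )


def test_transform_facing_flips_anterior_sign():
    lm = SpineLandmarks(c2ai=(0.0, -30.0), c4ai=(0.0, 0.0))
    left = anatomical_transform(lm, (-15.0, 0.0), facing="left")
    right = anatomical_transform(lm, (-15.0, 0.0), facing="right")
    np.testing.assert_allclose(left, [50.0, 0.0])
    np.testing.assert_allclose(right, [-50.0, 0.0])


def test_degenerate_landmarks_rejected():
    with pytest.raises(GeometryError):
        SpineLandmarks(c2ai=(1.0, 1.0), c4ai=(1.0, 1.0))


# --- polygon area ---------------------------------------------------------

def test_polygon_area_basics():
    square = [(0, 0), (1, 0), (1, 1), (0, 1)]
    assert polygon_area(square) == 1.0
    assert polygon_area([]) == 0.0
    assert polygon_area([(0, 0), (1, 1)]) == 0.0  # degenerate


@settings(deadline=None, max_examples=50, derandomize=True)
@given(hst.integers(min_value=0, max_value=2**31 - 1))
def test_polygon_area_vertex_order_invariance(seed):
    rng = np.random.default_rng(seed)
    # star-convex polygon: sorted angles guarantee simplicity
    n = rng.integers(3, 12)
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    rad = rng.uniform(1, 10, n)
    poly = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    a = polygon_area(poly)
    assert polygon_area(poly[::-1]) == pytest.approx(a)
    assert polygon_area(np.roll(poly, 3, axis=0)) == pytest.approx(a)


def test_polygon_area_matches_rasterization_oracle(rng):
    # Monte-Carlo grid-count oracle on a random star-convex 20-gon
    ang = np.sort(rng.uniform(0, 2 * np.pi, 20))
    rad = rng.uniform(5, 15, 20)
    poly = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    lo, hi = poly.min(axis=0) - 1, poly.max(axis=0) + 1
    pts = rng.uniform(lo, hi, size=(200_000, 2))
    # ray-casting point-in-polygon, vectorized over sample points
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    v = poly
    for i in range(len(v)):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % len(v)]
        crosses = (y1 > y) != (y2 > y)
        xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < xint)
    box = np.prod(hi - lo)
    mc_area = inside.mean() * box
    assert polygon_area(poly) == pytest.approx(mc_area, rel=0.01)


# --- timing parameters ----------------------------------------------------

def test_timing_interval_definitions():
    ev = EventFrames(
        bolus_past_mandible=94,
        hyoid_burst_onset=100,
        ues_open=103,
        ues_close=103,
        lvc_first_frame=105,
        lvc_offset=120,
        swallow_rest=130,
    )
    t = compute_timing(ev, fps=30)
    assert t["hyb_to_ueso"] == 100.0  # 3 frames
    assert t["ueso_duration"] == 0.0
    assert t["swallow_reaction_time"] == 200.0
    assert t["lvc_duration"] == 500.0
    assert math.isnan(t["hyoid_burst_duration"])  # no peak frame given


def test_timing_negative_reaction_time_and_missing_events():
    ev = EventFrames(bolus_past_mandible=100, hyoid_burst_onset=94, swallow_rest=130)
    t = compute_timing(ev, fps=30)
    assert t["swallow_reaction_time"] == -200.0
    assert math.isnan(t["ueso_duration"])  # missing events yield nan, not a crash


# --- hyoid kinematics -----------------------------------------------------

def _flat_landmarks():
    return SpineLandmarks(c2ai=(0.0, -100.0), c4ai=(0.0, 0.0))


def test_stationary_track_zero_speed():
    lm = _flat_landmarks()
    track = HyoidTrack(start_frame=90, positions=np.tile([0.0, -120.0], (60, 1)))
    ev = EventFrames(hyoid_burst_onset=100, swallow_rest=140)
    kin = compute_hyoid_kinematics(track, lm, ev, fps=30)
    assert kin["peak_xy_hyoid"] == pytest.approx(120.0)
    # peak is at the window start: zero-length burst leaves speed undefined
    assert math.isnan(kin["hyoid_xy_speed"])


def test_half_cosine_trajectory_closed_form():
    # radial rise 120 -> 176 %(C2-4) over 15 frames: burst duration 500 ms,
    # speed (176-120)/0.5 = 112 %(C2-4)/s
    lm = _flat_landmarks()
    frames = np.arange(90, 151)
    r = np.full(frames.shape, 120.0)
    rise = (frames >= 100) & (frames <= 115)
    r[rise] = 120 + 56 * 0.5 * (1 - np.cos(np.pi * (frames[rise] - 100) / 15))
    r[frames > 115] = 150.0
    track = HyoidTrack(start_frame=90, positions=np.column_stack([np.zeros_like(r), -r]))
    ev = EventFrames(hyoid_burst_onset=100, swallow_rest=145)
    kin = compute_hyoid_kinematics(track, lm, ev, fps=30)
    assert kin["peak_xy_hyoid"] == pytest.approx(176.0)
    assert kin["hyoid_burst_duration"] == 500.0
    assert kin["hyoid_xy_speed"] == pytest.approx(112.0)


# --- similarity invariance ------------------------------------------------

def _similarity(ann: BolusAnnotation, scale, theta, shift, flip_y=False):
    """Apply one similarity transform to every pixel coordinate of an
    annotation (the physical measures must not change)."""
    c, s = math.cos(theta), math.sin(theta)
    R = np.array([[c, -s], [s, c]]) * scale

    def tx(p):
        p = np.asarray(p, float)
        if flip_y:
            p = p * np.array([1.0, -1.0])
        return p @ R.T + shift

    return BolusAnnotation(
        participant_id=ann.participant_id,
        bolus_id=ann.bolus_id,
        rater_id=ann.rater_id,
        sip_volume=ann.sip_volume,
        n_swallows=ann.n_swallows,
        pas_initial=ann.pas_initial,
        pas_max=ann.pas_max,
        lvc_integrity=ann.lvc_integrity,
        events=ann.events,
        landmarks=SpineLandmarks(c2ai=tx(ann.landmarks.c2ai), c4ai=tx(ann.landmarks.c4ai)),
        hyoid=HyoidTrack(ann.hyoid.start_frame, tx(ann.hyoid.positions)),
        contours=ContourSet(
            **{
                n: tx(ann.contours.polygon(n))
                if ann.contours.polygon(n).size
                else np.empty((0, 2))
                for n in (
                    "pharynx_at_max_constriction",
                    "pharynx_at_rest",
                    "residue_valleculae",
                    "residue_pyriform",
                    "residue_other",
                )
            },
            ues_diameter_segment=tx(ann.contours.ues_diameter_segment),
        ),
        fps=ann.fps,
    )


SCALED_OUTPUTS = [
    "peak_xy_hyoid",
    "hyoid_xy_speed",
    "ues_diameter",
    "pa_max_constriction",
    "pa_rest",
    "residue_valleculae",
    "residue_pyriform",
    "residue_other",
    "residue_total",
]


@pytest.mark.parametrize("scale,theta,flip", [(2.5, 1.1, False), (0.4, -2.0, False), (1.3, 0.7, True)])
def test_scaled_measures_similarity_invariant(small_study, scale, theta, flip):
    ann = small_study.annotations[0]
    base = summarize_bolus(ann).as_dict()
    moved = summarize_bolus(_similarity(ann, scale, theta, np.array([55.0, -20.0]), flip))
    moved = moved.as_dict()
    for k in SCALED_OUTPUTS + ["swallow_reaction_time", "ueso_duration", "lvc_duration"]:
        assert moved[k] == pytest.approx(base[k], rel=1e-9, abs=1e-9), k


# --- assembly -------------------------------------------------------------

def test_summarize_single_and_multiple_swallows(small_study):
    ann = small_study.annotations[0]
    one = BolusAnnotation(
        **{
            **{f: getattr(ann, f) for f in (
                "participant_id", "bolus_id", "rater_id", "sip_volume",
                "lvc_integrity", "events", "landmarks", "hyoid", "contours", "fps",
            )},
            "n_swallows": 1,
            "pas_initial": 1,
            "pas_max": 1,
        }
    )
    rec = summarize_bolus(one)
    assert rec.pas_max == 1 and rec.multiple_swallows is False
    two = BolusAnnotation(
        **{
            **{f: getattr(ann, f) for f in (
                "participant_id", "bolus_id", "rater_id", "sip_volume",
                "lvc_integrity", "events", "landmarks", "hyoid", "contours", "fps",
            )},
            "n_swallows": 2,
            "pas_initial": 1,
            "pas_max": 2,
        }
    )
    rec = summarize_bolus(two)
    assert rec.pas_max == 2 and rec.multiple_swallows is True


def test_residue_total_is_component_sum(small_study):
    for ann in small_study.annotations[:6]:
        rec = summarize_bolus(ann)
        assert rec.residue_total == pytest.approx(
            rec.residue_valleculae + rec.residue_pyriform + rec.residue_other
        )
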