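"""Derivation of the per-bolus swallowing parameters from an annotation.

Three coordinate systems are involved:

* **image pixels** — raw annotation coordinates, x right, y down;
* **anatomical frame** — origin at the anterior-inferior corner of C4, the
  Y axis pointing superiorly along the C2-C4 spine, the X axis pointing
  anteriorly; both axes expressed in %(C2-4), i.e. percent of the
  individual's C2-C4 spine length. Anatomical scaling removes fluoroscopic
  magnification and body-size differences;
* **time** — 0-based frame indices converted to milliseconds at the
  recording frame rate (default 30 fps).

Durations are converted with the ceiling convention
``ceil((end - start) * 1000 / fps)``: at 30 fps every duration falls on the
millisecond grid {0, 34, 67, 100, 134, ...}.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np

from .annotations import (
    BolusAnnotation,
    ContourSet,
    EventFrames,
    HyoidTrack,
    ParameterRecord,
    SpineLandmarks,
)
from .exceptions import (
    ConfigurationError,
    EventOrderError,
    GeometryError,
    InputValidationError,
)

logger = logging.getLogger(__name__)

#: interval parameters as (name, start event, end event)
TIMING_INTERVALS = (
    ("swallow_reaction_time", "bolus_past_mandible", "hyoid_burst_onset"),
    ("hyb_to_ueso", "hyoid_burst_onset", "ues_open"),
    ("ueso_duration", "ues_open", "ues_close"),
    ("time_to_lvc", "hyoid_burst_onset", "lvc_first_frame"),
    ("lvc_duration", "lvc_first_frame", "lvc_offset"),
)


# --- timing ---------------------------------------------------------------

def frames_to_ms(
    start: int,
    end: int,
    fps: float = 30.0,
    *,
    signed: bool = False,
    convention: str = "ceil",
) -> int:
    """Convert a frame interval [start, end) to an integer duration in ms.

    The default ceiling convention maps k frames at 30 fps onto the grid
    ceil(k*100/3) = 0, 34, 67, 100, ... With ``signed=True`` an inverted
    interval returns the negated magnitude instead of raising (used for
    swallow reaction time, where the hyoid burst may precede bolus arrival).
    """
    if fps <= 0:
        raise ConfigurationError(f"fps must be positive, got {fps}")
    if end < start:
        if not signed:
            raise EventOrderError("start", "end", start, end)
        return -frames_to_ms(end, start, fps, convention=convention)
    k = int(end) - int(start)
    exact = k * 1000.0 / fps
    # guard against float representation tipping ceil for exact multiples
    exact = round(exact, 9)
    if convention == "ceil":
        return int(math.ceil(exact))
    if convention == "round":
        return int(round(exact))
    if convention == "floor":
        return int(math.floor(exact))
    raise ConfigurationError(f"unknown timing convention {convention!r}")


def ms_to_frames(ms: float, fps: float = 30.0) -> int:
    """Inverse of :func:`frames_to_ms` on the grid: the frame count whose
    ceiling-converted duration is nearest to ``ms`` (signed)."""
    if fps <= 0:
        raise ConfigurationError(f"fps must be positive, got {fps}")
    return int(round(ms * fps / 1000.0))


# --- geometry -------------------------------------------------------------

def anatomical_transform(
    landmarks: SpineLandmarks, points, facing: str = "left"
) -> np.ndarray:
    """Map pixel point(s) into the anatomical %(C2-4) frame.

    The origin is C4-AI; the Y unit vector points from C4-AI toward C2-AI
    (superior positive); the X axis is the Y axis rotated so that anterior is
    positive. ``facing`` names the direction the participant faces in the
    image ("left" or "right" lateral projection); with image y growing
    downward, a left-facing projection puts anterior toward image-left.
    Output coordinates are percent of the C2-C4 spine length.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 2 or not np.all(np.isfinite(pts)):
        raise InputValidationError("points must be finite (x, y) pairs")
    length = landmarks.length
    if length == 0.0:
        raise GeometryError("degenerate spine landmarks")
    u = (landmarks.c2ai - landmarks.c4ai) / length  # superior unit vector
    if facing == "left":
        x_hat = np.array([u[1], -u[0]])
    elif facing == "right":
        x_hat = np.array([-u[1], u[0]])
    else:
        raise ConfigurationError(f"facing must be 'left' or 'right', got {facing!r}")
    rel = pts - landmarks.c4ai
    out = np.stack([rel @ x_hat, rel @ u], axis=-1) * (100.0 / length)
    return out[0] if single else out


def polygon_area(vertices) -> float:
    """Area of a simple polygon by the shoelace formula, in squared input
    units. Empty or degenerate (<3 vertices) input gives 0. Invariant under
    vertex-order reversal and cyclic rotation."""
    v = np.asarray(vertices, dtype=float)
    if v.size == 0 or len(v) < 3:
        return 0.0
    if v.ndim != 2 or v.shape[1] != 2:
        raise InputValidationError("polygon must be an (n, 2) vertex array")
    if not np.all(np.isfinite(v)):
        raise InputValidationError("polygon contains non-finite vertices")
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


# --- hyoid kinematics -----------------------------------------------------

def radial_positions(
    hyoid: HyoidTrack, landmarks: SpineLandmarks, facing: str = "left"
) -> np.ndarray:
    """Radial XY hyoid position per tracked frame: the Euclidean norm of the
    anatomically transformed position, in %(C2-4)."""
    scaled = anatomical_transform(landmarks, hyoid.positions, facing=facing)
    return np.linalg.norm(scaled, axis=-1)


def compute_hyoid_kinematics(
    hyoid: Optional[HyoidTrack],
    landmarks: SpineLandmarks,
    events: EventFrames,
    fps: float = 30.0,
    facing: str = "left",
    context: str = "",
) -> dict:
    """Peak XY hyoid position, hyoid XY speed, and the hyoid burst duration.

    The analysis window is [hyoid_burst_onset, swallow_rest] clipped to the
    track. Peak = maximum radial position over the window; the hyoid burst
    duration is the interval from burst onset to the (first) frame of peak
    position; speed = (peak - minimum radial position between burst onset and
    the peak frame) / burst duration. A zero-length burst leaves speed
    missing and is logged.
    """
    out = {
        "peak_xy_hyoid": math.nan,
        "hyoid_xy_speed": math.nan,
        "hyoid_burst_duration": math.nan,
        "peak_frame": None,
    }
    burst, rest = events.hyoid_burst_onset, events.swallow_rest
    if hyoid is None or burst is None or rest is None:
        logger.warning("hyoid kinematics missing (no track or events) %s", context)
        return out
    lo = max(burst, hyoid.start_frame)
    hi = min(rest, hyoid.end_frame)
    if hi < lo:
        logger.warning("hyoid track does not cover analysis window %s", context)
        return out
    r = radial_positions(hyoid, landmarks, facing=facing)
    window = r[lo - hyoid.start_frame : hi - hyoid.start_frame + 1]
    peak_idx = int(np.argmax(window))
    peak = float(window[peak_idx])
    peak_frame = lo + peak_idx
    burst_ms = frames_to_ms(burst, peak_frame, fps)
    out["peak_xy_hyoid"] = peak
    out["peak_frame"] = peak_frame
    out["hyoid_burst_duration"] = float(burst_ms)
    if burst_ms <= 0:
        logger.warning("zero-length hyoid burst; speed undefined %s", context)
        return out
    lo_b = max(burst, hyoid.start_frame)
    rise_window = r[lo_b - hyoid.start_frame : peak_frame - hyoid.start_frame + 1]
    minimum = float(np.min(rise_window))
    out["hyoid_xy_speed"] = (peak - minimum) / (burst_ms / 1000.0)
    return out


# --- timing parameters ----------------------------------------------------

def compute_timing(
    events: EventFrames,
    fps: float = 30.0,
    peak_frame: Optional[int] = None,
    convention: str = "ceil",
    context: str = "",
) -> dict:
    """The five interval parameters (ms), plus the hyoid burst duration when
    the peak-position frame is supplied.

    All intervals are computed signed: swallow reaction time is negative when
    the hyoid burst precedes bolus arrival at the mandibular ramus, and noisy
    pre-consensus ratings can invert other short intervals — those are
    preserved (and logged) rather than crashed on. Missing events yield nan.
    """
    out = {}
    for name, start_name, end_name in TIMING_INTERVALS:
        start, end = events.get(start_name), events.get(end_name)
        if start is None or end is None:
            logger.warning("missing event for %s %s", name, context)
            out[name] = math.nan
            continue
        ms = frames_to_ms(start, end, fps, signed=True, convention=convention)
        if ms < 0 and name != "swallow_reaction_time":
            logger.warning("negative %s (%d ms) %s", name, ms, context)
        out[name] = float(ms)
    burst = events.hyoid_burst_onset
    if peak_frame is not None and burst is not None:
        out["hyoid_burst_duration"] = float(
            frames_to_ms(burst, peak_frame, fps, signed=True, convention=convention)
        )
    else:
        out["hyoid_burst_duration"] = math.nan
    return out


# --- scaled geometry ------------------------------------------------------

def compute_scaled_geometry(contours: ContourSet, landmarks: SpineLandmarks) -> dict:
    """UES diameter in %(C2-4) and region areas in %(C2-4)^2.

    Lengths scale as 100*d/L and areas as 100*A/L^2 where L is the pixel
    spine length; empty polygons contribute 0; a missing UES segment yields
    nan.
    """
    length = landmarks.length
    if length == 0.0:
        raise GeometryError("degenerate spine landmarks")
    out = {}
    seg = contours.ues_diameter_segment
    if seg is None:
        out["ues_diameter"] = math.nan
    else:
        out["ues_diameter"] = 100.0 * float(np.linalg.norm(seg[1] - seg[0])) / length
    scale = 100.0 / length**2
    out["pa_max_constriction"] = scale * polygon_area(
        contours.pharynx_at_max_constriction
    )
    out["pa_rest"] = scale * polygon_area(contours.pharynx_at_rest)
    for region in ("residue_valleculae", "residue_pyriform", "residue_other"):
        out[region] = scale * polygon_area(contours.polygon(region))
    out["residue_total"] = (
        out["residue_valleculae"] + out["residue_pyriform"] + out["residue_other"]
    )
    return out


# --- assembly -------------------------------------------------------------

def summarize_bolus(
    annotation: BolusAnnotation, facing: str = "left", convention: str = "ceil"
) -> ParameterRecord:
    """Derive the full per-bolus parameter record from a (consensus)
    annotation. Missing inputs propagate as missing parameters; nothing is
    imputed."""
    context = f"[{annotation.participant_id}/bolus {annotation.bolus_id}]"
    kin = compute_hyoid_kinematics(
        annotation.hyoid,
        annotation.landmarks,
        annotation.events,
        annotation.fps,
        facing=facing,
        context=context,
    )
    timing = compute_timing(
        annotation.events,
        annotation.fps,
        peak_frame=kin["peak_frame"],
        convention=convention,
        context=context,
    )
    geometry = compute_scaled_geometry(annotation.contours, annotation.landmarks)
    return ParameterRecord(
        participant_id=annotation.participant_id,
        bolus_id=annotation.bolus_id,
        sip_volume=annotation.sip_volume,
        n_swallows=annotation.n_swallows,
        pas_initial=annotation.pas_initial,
        pas_max=max(annotation.pas_max, annotation.pas_initial),
        lvc_integrity=annotation.lvc_integrity,
        peak_xy_hyoid=kin["peak_xy_hyoid"],
        hyoid_xy_speed=kin["hyoid_xy_speed"],
        hyoid_burst_duration=timing["hyoid_burst_duration"],
        multiple_swallows=annotation.n_swallows > 1,
        **{name: timing[name] for name, _, _ in TIMING_INTERVALS},
        **geometry,
    )
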