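"""Domain types for per-bolus videofluoroscopy annotations.

An annotation is what a trained rater produces from one recorded bolus:
frame numbers of the key swallowing events, a frame-by-frame pixel track of
the hyoid bone, pixel contours of the pharynx and residue regions, a UES
diameter line segment, cervical-spine landmarks used for anatomical scaling,
and per-bolus scalars (sip volume, swallow count, Penetration-Aspiration
scores, laryngeal-vestibule-closure integrity).

All pixel coordinates follow the standard image convention: x grows to the
right, y grows downward. Frame indices are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

from .exceptions import GeometryError, InputValidationError

# Fixed vocabularies -------------------------------------------------------

EVENT_NAMES = (
    "bolus_past_mandible",
    "hyoid_burst_onset",
    "ues_open",
    "ues_close",
    "lvc_first_frame",
    "lvc_offset",
    "max_ues_opening",
    "max_pharyngeal_constriction",
    "swallow_rest",
)

REGION_NAMES = (
    "pharynx_at_max_constriction",
    "pharynx_at_rest",
    "residue_valleculae",
    "residue_pyriform",
    "residue_other",
)

LVC_CATEGORIES = ("complete", "partial", "incomplete")

#: The 19 per-bolus parameters plus the auxiliary hyoid burst duration.
PARAMETER_NAMES = (
    "sip_volume",
    "n_swallows",
    "pas_initial",
    "pas_max",
    "lvc_integrity",
    "swallow_reaction_time",
    "hyb_to_ueso",
    "ueso_duration",
    "time_to_lvc",
    "lvc_duration",
    "peak_xy_hyoid",
    "hyoid_xy_speed",
    "ues_diameter",
    "pa_max_constriction",
    "pa_rest",
    "residue_valleculae",
    "residue_pyriform",
    "residue_other",
    "residue_total",
    "hyoid_burst_duration",
)

#: Continuous parameters (everything except swallow count, PAS and LVC class).
CONTINUOUS_PARAMETERS = (
    "sip_volume",
    "swallow_reaction_time",
    "hyb_to_ueso",
    "ueso_duration",
    "time_to_lvc",
    "lvc_duration",
    "hyoid_burst_duration",
    "peak_xy_hyoid",
    "hyoid_xy_speed",
    "ues_diameter",
    "pa_max_constriction",
    "pa_rest",
    "residue_valleculae",
    "residue_pyriform",
    "residue_other",
    "residue_total",
)


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,) or not np.all(np.isfinite(a)):
        raise InputValidationError(f"expected a finite (x, y) point, got {p!r}")
    return a


@dataclass(frozen=True)
class SpineLandmarks:
    """Anterior-inferior corners of the C2 and C4 vertebrae, in pixels.

    The segment from C4-AI to C2-AI defines the anatomical Y axis and its
    length is the scaling unit for all %(C2-4) measures.
    """

    c2ai: np.ndarray
    c4ai: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "c2ai", _as_point(self.c2ai))
        object.__setattr__(self, "c4ai", _as_point(self.c4ai))
        if self.length == 0.0:
            raise GeometryError("C2 and C4 landmarks coincide (zero spine length)")

    @property
    def length(self) -> float:
        """|C2-AI − C4-AI| in pixels."""
        return float(np.linalg.norm(self.c2ai - self.c4ai))


@dataclass(frozen=True)
class EventFrames:
    """Frame indices of the key swallow events; ``None`` marks a missing rating."""

    bolus_past_mandible: Optional[int] = None
    hyoid_burst_onset: Optional[int] = None
    ues_open: Optional[int] = None
    ues_close: Optional[int] = None
    lvc_first_frame: Optional[int] = None
    lvc_offset: Optional[int] = None
    max_ues_opening: Optional[int] = None
    max_pharyngeal_constriction: Optional[int] = None
    swallow_rest: Optional[int] = None

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InputValidationError(
                    f"event '{f.name}' must be a non-negative frame index, got {v!r}"
                )
            object.__setattr__(self, f.name, int(v))
        self._check_order("ues_open", "max_ues_opening")
        self._check_order("max_ues_opening", "ues_close")
        self._check_order("lvc_first_frame", "lvc_offset")
        self._check_order("hyoid_burst_onset", "swallow_rest")

    def _check_order(self, first: str, second: str):
        a, b = getattr(self, first), getattr(self, second)
        if a is not None and b is not None and a > b:
            raise InputValidationError(
                f"event ordering violated: {first}={a} > {second}={b}"
            )

    def get(self, name: str) -> Optional[int]:
        if name not in EVENT_NAMES:
            raise InputValidationError(f"unknown event name {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class HyoidTrack:
    """Frame-by-frame hyoid pixel positions starting at ``start_frame``."""

    start_frame: int
    positions: np.ndarray  # shape (n_frames, 2)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] == 0:
            raise InputValidationError("hyoid track must be a non-empty (n, 2) array")
        if not np.all(np.isfinite(pos)):
            raise InputValidationError("hyoid track contains non-finite coordinates")
        if self.start_frame < 0:
            raise InputValidationError("hyoid track start_frame must be >= 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "start_frame", int(self.start_frame))

    @property
    def end_frame(self) -> int:
        """Last covered frame (inclusive)."""
        return self.start_frame + len(self.positions) - 1

    def covers(self, frame: int) -> bool:
        return self.start_frame <= frame <= self.end_frame

    def at(self, frame: int) -> np.ndarray:
        if not self.covers(frame):
            raise InputValidationError(
                f"frame {frame} outside hyoid track "
                f"[{self.start_frame}, {self.end_frame}]"
            )
        return self.positions[frame - self.start_frame]


def _as_polygon(vertices) -> np.ndarray:
    a = np.asarray(vertices, dtype=float)
    if a.size == 0:
        return np.empty((0, 2), dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise InputValidationError("polygon must be an (n, 2) vertex array")
    if not np.all(np.isfinite(a)):
        raise InputValidationError("polygon contains non-finite vertices")
    if 0 < len(a) < 3:
        raise InputValidationError("polygon needs >= 3 vertices (or be empty)")
    return a


@dataclass(frozen=True)
class ContourSet:
    """Pixel contours measured on the confirmed frames, plus the UES diameter
    segment. Empty polygons denote an absent region (area 0)."""

    pharynx_at_max_constriction: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2))
    )
    pharynx_at_rest: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    residue_valleculae: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    residue_pyriform: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    residue_other: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    ues_diameter_segment: Optional[np.ndarray] = None  # shape (2, 2)

    def __post_init__(self):
        for name in REGION_NAMES:
            object.__setattr__(self, name, _as_polygon(getattr(self, name)))
        seg = self.ues_diameter_segment
        if seg is not None:
            seg = np.asarray(seg, dtype=float)
            if seg.shape != (2, 2) or not np.all(np.isfinite(seg)):
                raise InputValidationError(
                    "UES diameter segment must be a finite point pair"
                )
            object.__setattr__(self, "ues_diameter_segment", seg)

    def polygon(self, name: str) -> np.ndarray:
        if name not in REGION_NAMES:
            raise InputValidationError(f"unknown region name {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class BolusAnnotation:
    """One rater's (or the consensus) complete annotation of one bolus."""

    participant_id: str
    bolus_id: int
    rater_id: str
    sip_volume: float
    n_swallows: int
    pas_initial: int
    pas_max: int
    lvc_integrity: str
    events: EventFrames
    landmarks: SpineLandmarks
    hyoid: Optional[HyoidTrack] = None
    contours: ContourSet = field(default_factory=ContourSet)
    fps: float = 30.0

    def __post_init__(self):
        if self.fps <= 0:
            raise InputValidationError("fps must be positive")
        if self.sip_volume <= 0:
            raise InputValidationError("sip_volume must be positive (ml)")
        if self.n_swallows < 1:
            raise InputValidationError("n_swallows must be >= 1")
        for name in ("pas_initial", "pas_max"):
            v = getattr(self, name)
            if not 1 <= v <= 8:
                raise InputValidationError(f"{name} must be an integer 1-8, got {v!r}")
        if self.pas_max < self.pas_initial:
            raise InputValidationError("pas_max must be >= pas_initial")
        if self.lvc_integrity not in LVC_CATEGORIES:
            raise InputValidationError(
                f"lvc_integrity must be one of {LVC_CATEGORIES}, got "
                f"{self.lvc_integrity!r}"
            )

    def with_rater(self, rater_id: str) -> "BolusAnnotation":
        return replace(self, rater_id=rater_id)

    @property
    def key(self) -> tuple:
        return (self.participant_id, self.bolus_id)


@dataclass
class ParameterRecord:
    """The derived per-bolus parameter set (19 parameters plus the auxiliary
    hyoid burst duration). Missing values are ``nan``."""

    participant_id: str
    bolus_id: int
    sip_volume: float = math.nan
    n_swallows: int = 1
    pas_initial: int = 1
    pas_max: int = 1
    lvc_integrity: str = "complete"
    swallow_reaction_time: float = math.nan  # ms, signed
    hyb_to_ueso: float = math.nan  # ms
    ueso_duration: float = math.nan  # ms
    time_to_lvc: float = math.nan  # ms
    lvc_duration: float = math.nan  # ms
    hyoid_burst_duration: float = math.nan  # ms
    peak_xy_hyoid: float = math.nan  # %(C2-4)
    hyoid_xy_speed: float = math.nan  # %(C2-4)/s
    ues_diameter: float = math.nan  # %(C2-4)
    pa_max_constriction: float = math.nan  # %(C2-4)^2
    pa_rest: float = math.nan  # %(C2-4)^2
    residue_valleculae: float = math.nan  # %(C2-4)^2
    residue_pyriform: float = math.nan  # %(C2-4)^2
    residue_other: float = math.nan  # %(C2-4)^2
    residue_total: float = math.nan  # %(C2-4)^2
    multiple_swallows: bool = False

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
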