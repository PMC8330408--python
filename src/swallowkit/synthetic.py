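"""Synthetic cohort generator.

Emulates the study conditions end to end so the measurement, agreement and
statistics stages are all testable at desk scale without any recorded data:

* a sex-balanced cohort (default n=76, ages uniform on 21-82, 3 thin-liquid
  boluses per participant, 30 fps);
* per-bolus "true" parameter values built from linear effect models —
  intercepts anchored at age 70 to the older-cohort medians, the published
  age/sex/sip-volume slopes, and correlated residual noise whose standard
  deviations are calibrated so the age-only variance explained matches the
  printed values (via sigma^2 = slope^2 * Var(age) * (1-R^2)/R^2);
* raw annotations realizing those values exactly (event frames on the ms
  grid, a half-cosine hyoid trajectory, rectangles of prescribed area,
  a segment of prescribed length, all in a randomly rotated/translated
  pixel frame), so ``summarize_bolus`` round-trips the generator;
* noisy dual-rater copies with integer frame jitter, pixel coordinate
  jitter and occasional categorical disagreements, calibrated to the
  published pre-consensus agreement levels.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so every operation is deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .annotations import (
    BolusAnnotation,
    ContourSet,
    EventFrames,
    HyoidTrack,
    SpineLandmarks,
)
from .exceptions import ConfigurationError, SynthesisError
from .measures import frames_to_ms, ms_to_frames

logger = logging.getLogger(__name__)

#: order of parameters in the noise correlation matrix
NOISE_PARAMETERS = (
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
)

#: timing parameters snapped to the ms grid before annotation synthesis
_TIMING = (
    "swallow_reaction_time",
    "hyb_to_ueso",
    "ueso_duration",
    "time_to_lvc",
    "lvc_duration",
    "hyoid_burst_duration",
)

#: parameters that are physically non-negative (truncated at 0 when drawn
#: negative); swallow reaction time is signed and exempt.
_NON_NEGATIVE = tuple(p for p in NOISE_PARAMETERS if p != "swallow_reaction_time")

#: parameters whose real-world distribution has a mass at the zero floor;
#: for these truncation is the intended zero-inflation, not an error, and
#: they are excluded from the low-truncation-rate guarantee.
FLOOR_CENSORED = (
    "pa_max_constriction",
    "residue_valleculae",
    "residue_pyriform",
    "residue_other",
)


@dataclass(frozen=True)
class ParameterEffect:
    """Linear effect model for one continuous parameter:

    value = intercept + age_slope*(age - 70) + sex_effect*male
            + sip_slope*(sip - sip_center) + participant noise + bolus noise
    """

    intercept: float
    age_slope: float = 0.0
    sex_effect: float = 0.0
    sip_slope: float = 0.0
    sd_participant: float = 0.0
    sd_bolus: float = 0.0


def _sd_from_r2(slope: float, predictor_sd: float, r2: float) -> float:
    """Residual SD (at the participant-mean level) making an effect explain
    a target fraction of variance: sigma = |slope| * sd_x * sqrt((1-R2)/R2)."""
    return abs(slope) * predictor_sd * math.sqrt((1.0 - r2) / r2)


def _split_sd(sigma_pm: float, boluses: int = 3) -> tuple[float, float]:
    """Split a participant-mean residual SD into equal participant- and
    bolus-level components: sd_p^2 + sd_b^2/boluses = sigma_pm^2."""
    s = sigma_pm * math.sqrt(boluses / (boluses + 1.0))
    return s, s


def _iqr_sd(p25: float, p75: float) -> float:
    """Normal-distribution SD implied by an interquartile range."""
    return (p75 - p25) / 1.3489795003921634


def default_correlations() -> tuple[np.ndarray, tuple]:
    """Default cross-parameter residual correlation matrix (symmetric PD),
    reproducing the published sign/magnitude structure of the pairwise
    parameter correlations, plus moderate residue inter-correlations."""
    names = NOISE_PARAMETERS
    idx = {n: i for i, n in enumerate(names)}
    R = np.eye(len(names))
    pairs = [
        ("time_to_lvc", "hyb_to_ueso", 0.496),
        ("time_to_lvc", "lvc_duration", -0.599),
        ("lvc_duration", "ueso_duration", 0.405),
        ("lvc_duration", "ues_diameter", 0.29),
        ("ueso_duration", "ues_diameter", 0.311),
        ("ueso_duration", "peak_xy_hyoid", 0.265),
        ("peak_xy_hyoid", "ues_diameter", 0.549),
        ("peak_xy_hyoid", "hyoid_xy_speed", 0.283),
        ("peak_xy_hyoid", "pa_rest", 0.268),
        ("pa_max_constriction", "residue_valleculae", 0.492),
        ("pa_max_constriction", "residue_pyriform", 0.432),
        ("pa_max_constriction", "residue_other", 0.35),
        ("residue_valleculae", "residue_pyriform", 0.35),
        ("residue_valleculae", "residue_other", 0.35),
        ("residue_pyriform", "residue_other", 0.35),
    ]
    for a, b, r in pairs:
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return R, names


# age distribution: uniform on [21, 82]
_AGE_SD = (82.0 - 21.0) / math.sqrt(12.0)
# participant-mean sip-volume SD under the default sip noise (see below)
_SIP_PM_SD = math.sqrt(4.0**2 + 3.0**2 / 3.0)


def default_effects() -> dict[str, ParameterEffect]:
    """Default effect configuration.

    Intercepts are the older-cohort medians (anchored at age 70); age, sex
    and sip-volume slopes are the published effects; residual SDs come from
    the published variance-explained fractions where available (6% swallow
    reaction time, 12% UES opening duration, 8% LVC duration, 10% UES
    diameter and pharyngeal areas, 13% sip-volume share of the
    hyoid-burst-to-UES-opening interval) and otherwise from the printed
    interquartile ranges.
    """

    def cal(slope, r2, sd_x=_AGE_SD):
        return _split_sd(_sd_from_r2(slope, sd_x, r2))

    def iqr(p25, p75):
        s = _iqr_sd(p25, p75) / math.sqrt(2.0)
        return s, s

    eff = {}
    sp, sb = cal(4.0, 0.06)
    eff["swallow_reaction_time"] = ParameterEffect(
        200.0, age_slope=4.0, sd_participant=sp, sd_bolus=sb
    )
    sp, sb = cal(-2.4, 0.13, sd_x=_SIP_PM_SD)
    eff["hyb_to_ueso"] = ParameterEffect(
        100.0, sip_slope=-2.4, sd_participant=sp, sd_bolus=sb
    )
    sp, sb = cal(1.4, 0.12)
    eff["ueso_duration"] = ParameterEffect(
        500.0, age_slope=1.4, sd_participant=sp, sd_bolus=sb
    )
    sp, sb = iqr(67.0, 200.0)
    eff["time_to_lvc"] = ParameterEffect(134.0, sd_participant=sp, sd_bolus=sb)
    sp, sb = cal(2.4, 0.08)
    eff["lvc_duration"] = ParameterEffect(
        534.0, age_slope=2.4, sd_participant=sp, sd_bolus=sb
    )
    eff["hyoid_burst_duration"] = ParameterEffect(
        267.0, sd_participant=70.0, sd_bolus=70.0
    )
    sp, sb = iqr(161.0, 189.0)
    eff["peak_xy_hyoid"] = ParameterEffect(176.0, sd_participant=sp, sd_bolus=sb)
    sp, sb = iqr(99.0, 154.0)
    eff["hyoid_xy_speed"] = ParameterEffect(117.0, sd_participant=sp, sd_bolus=sb)
    sp, sb = cal(0.11, 0.10)
    eff["ues_diameter"] = ParameterEffect(
        23.0, age_slope=0.11, sip_slope=0.27, sd_participant=sp, sd_bolus=sb
    )
    sp, sb = cal(0.035, 0.10)
    eff["pa_max_constriction"] = ParameterEffect(
        2.0, age_slope=0.035, sd_participant=sp, sd_bolus=sb
    )
    sp, sb = cal(0.31, 0.10)
    eff["pa_rest"] = ParameterEffect(
        63.0, age_slope=0.31, sex_effect=11.0, sd_participant=sp, sd_bolus=sb
    )
    eff["residue_valleculae"] = ParameterEffect(
        0.5, sd_participant=0.5, sd_bolus=0.5
    )
    eff["residue_pyriform"] = ParameterEffect(0.2, sd_participant=0.3, sd_bolus=0.3)
    eff["residue_other"] = ParameterEffect(0.2, sd_participant=0.3, sd_bolus=0.3)
    return eff


@dataclass
class EffectConfig:
    """Generator effect structure: per-parameter linear models, the residual
    correlation matrix, the sip-volume model, and the multiple-swallow
    logistic model (log-odds slope per ml; intercept set so roughly 20% of
    boluses at the centring sip volume are multiple)."""

    effects: dict[str, ParameterEffect] = field(default_factory=default_effects)
    anchor_age: float = 70.0
    sip_center: float = 14.0
    sip_base: float = 11.24
    sip_sex_effect: float = 4.69
    sip_sd_participant: float = 4.0
    sip_sd_bolus: float = 3.0
    multiple_logodds_intercept: float = -1.386
    multiple_logodds_per_ml: float = 0.09
    pas_probs: tuple = (0.90, 0.08, 0.02)  # P(PAS = 1, 2, 3) per swallow
    lvc_partial_p: float = 0.03
    correlations: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.correlations is None:
            self.correlations, _ = default_correlations()
        R = np.asarray(self.correlations, dtype=float)
        n = len(NOISE_PARAMETERS)
        if R.shape != (n, n) or not np.allclose(R, R.T):
            raise ConfigurationError(
                f"correlation matrix must be symmetric {n}x{n} "
                f"(parameter order: {NOISE_PARAMETERS})"
            )
        if not np.allclose(np.diag(R), 1.0):
            raise ConfigurationError("correlation matrix diagonal must be 1")
        w = np.linalg.eigvalsh(R)
        if w.min() < -1e-10:
            raise ConfigurationError(
                "correlation matrix is not positive semi-definite "
                f"(min eigenvalue {w.min():.3g}); project to the nearest "
                "correlation matrix (e.g. Higham 2002) and retry"
            )
        for name, e in self.effects.items():
            if e.sd_participant < 0 or e.sd_bolus < 0:
                raise ConfigurationError(f"negative residual SD for {name!r}")

    def zeroed(self) -> "EffectConfig":
        """Copy with every age/sex/sip effect set to 0 (null configuration
        for type-I-error simulations); noise levels are retained."""
        eff = {
            k: replace(v, age_slope=0.0, sex_effect=0.0, sip_slope=0.0)
            for k, v in self.effects.items()
        }
        return replace(self, effects=eff, sip_sex_effect=0.0)


@dataclass
class CohortConfig:
    """Cohort and rater-noise settings."""

    n: int = 76
    n_male: int = 38
    age_min: float = 21.0
    age_max: float = 82.0
    boluses_per_participant: int = 3
    fps: float = 30.0
    spine_length_mean_px: float = 100.0
    spine_length_sd_px: float = 8.0
    frame_jitter_sd: float = 1.0
    coord_jitter_px: float = 1.0
    pas_flip_p: float = 0.03
    lvc_flip_p: float = 0.015

    def __post_init__(self):
        if self.n < 2 or not 0 <= self.n_male <= self.n:
            raise ConfigurationError("need n >= 2 and 0 <= n_male <= n")
        if self.boluses_per_participant < 1:
            raise ConfigurationError("boluses_per_participant must be >= 1")
        if self.fps <= 0:
            raise ConfigurationError("fps must be positive")
        for name in ("frame_jitter_sd", "coord_jitter_px", "pas_flip_p", "lvc_flip_p"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


# --- cohort ---------------------------------------------------------------

def generate_cohort(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Participant table (id, age, sex, spine length) with exact sex balance
    and ages uniform on the configured range. Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    n = config.n
    ages = rng.uniform(config.age_min, config.age_max, size=n)
    sexes = np.array(["male"] * config.n_male + ["female"] * (n - config.n_male))
    rng.shuffle(sexes)
    spine = rng.normal(config.spine_length_mean_px, config.spine_length_sd_px, size=n)
    spine = np.clip(spine, 20.0, None)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "male": (sexes == "male").astype(int),
            "spine_length_px": spine,
        }
    )


# --- true parameter values ------------------------------------------------

def _snap_ms(ms: np.ndarray, fps: float, minimum_frames: int = 0) -> np.ndarray:
    """Snap millisecond values onto the achievable frame grid (signed)."""
    k = np.round(np.asarray(ms, dtype=float) * fps / 1000.0).astype(int)
    k = np.maximum(k, minimum_frames) if minimum_frames is not None else k
    out = np.empty(k.shape, dtype=float)
    flat = k.ravel()
    res = np.array(
        [math.copysign(frames_to_ms(0, abs(int(v)), fps), v) for v in flat]
    )
    out.ravel()[:] = res
    return out


def generate_parameters(
    participants: pd.DataFrame,
    effects: EffectConfig,
    config: CohortConfig,
    seed: int,
) -> pd.DataFrame:
    """Per-bolus true parameter table realizing the configured effect and
    correlation structure.

    Sip volume gets participant- and bolus-level noise around a sex-shifted
    base; each continuous parameter follows its linear effect model with
    correlated multivariate-normal noise split into participant- and
    bolus-level components; timing values are snapped to the fps grid;
    non-negative quantities are truncated at 0 (rates logged and stored in
    ``df.attrs['truncation_rates']``); the multiple-swallow indicator is
    drawn from the logistic sip-volume model. Hyoid speed is stored
    consistently with the snapped burst duration and the derived minimum
    radial position so that annotation synthesis round-trips exactly.
    """
    rng = np.random.default_rng(seed)
    n = len(participants)
    b = config.boluses_per_participant
    total = n * b
    R = np.asarray(effects.correlations, dtype=float)
    chol = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))

    age = np.repeat(participants["age"].to_numpy(), b)
    male = np.repeat(participants["male"].to_numpy(), b)
    pid = np.repeat(participants["participant_id"].to_numpy(), b)
    spine = np.repeat(participants["spine_length_px"].to_numpy(), b)
    bolus_id = np.tile(np.arange(1, b + 1), n)

    sip_p = rng.normal(0.0, effects.sip_sd_participant, size=n)
    sip = (
        effects.sip_base
        + effects.sip_sex_effect * male
        + np.repeat(sip_p, b)
        + rng.normal(0.0, effects.sip_sd_bolus, size=total)
    )
    sip = np.clip(sip, 1.0, None)

    noise_p = rng.standard_normal((n, len(NOISE_PARAMETERS))) @ chol.T
    noise_b = rng.standard_normal((total, len(NOISE_PARAMETERS))) @ chol.T

    values = {}
    trunc_rates = {}
    for j, name in enumerate(NOISE_PARAMETERS):
        e = effects.effects[name]
        v = (
            e.intercept
            + e.age_slope * (age - effects.anchor_age)
            + e.sex_effect * male
            + e.sip_slope * (sip - effects.sip_center)
            + e.sd_participant * np.repeat(noise_p[:, j], b)
            + e.sd_bolus * noise_b[:, j]
        )
        if name in _NON_NEGATIVE:
            below = v < 0
            trunc_rates[name] = float(np.mean(below))
            v = np.where(below, 0.0, v)
        values[name] = v

    for name in _TIMING:
        minimum = None if name == "swallow_reaction_time" else 0
        if name == "hyoid_burst_duration":
            minimum = 1  # a zero-length burst leaves speed undefined
        values[name] = _snap_ms(values[name], config.fps, minimum_frames=minimum)

    # make peak / speed / burst duration mutually consistent: the minimum
    # radial hyoid position is derived, and the stored speed equals
    # (peak - minimum) / burst duration exactly.
    peak = np.clip(values["peak_xy_hyoid"], 5.0, None)
    values["peak_xy_hyoid"] = peak
    speed = np.clip(values["hyoid_xy_speed"], 1.0, None)
    dur_s = values["hyoid_burst_duration"] / 1000.0
    minimum = peak - speed * dur_s
    low = minimum < 1.0
    minimum = np.where(low, 1.0, minimum)
    speed = (peak - minimum) / dur_s
    values["hyoid_xy_speed"] = speed

    multiple_p = 1.0 / (
        1.0
        + np.exp(
            -(
                effects.multiple_logodds_intercept
                + effects.multiple_logodds_per_ml * (sip - effects.sip_center)
            )
        )
    )
    multiple = rng.uniform(size=total) < multiple_p
    n_swallows = np.where(multiple, 2, 1)

    pas_levels = np.arange(1, len(effects.pas_probs) + 1)
    pas_initial = rng.choice(pas_levels, size=total, p=effects.pas_probs)
    pas_second = rng.choice(pas_levels, size=total, p=effects.pas_probs)
    pas_max = np.where(multiple, np.maximum(pas_initial, pas_second), pas_initial)
    lvc_integrity = np.where(
        rng.uniform(size=total) < effects.lvc_partial_p, "partial", "complete"
    )

    df = pd.DataFrame(
        {
            "participant_id": pid,
            "bolus_id": bolus_id,
            "age": age,
            "male": male,
            "sex": np.where(male == 1, "male", "female"),
            "spine_length_px": spine,
            "sip_volume": sip,
            "n_swallows": n_swallows,
            "multiple_swallows": multiple,
            "pas_initial": pas_initial,
            "pas_max": pas_max,
            "lvc_integrity": lvc_integrity,
            **values,
            "hyoid_min_xy": minimum,
        }
    )
    df["residue_total"] = (
        df["residue_valleculae"] + df["residue_pyriform"] + df["residue_other"]
    )
    df.attrs["truncation_rates"] = trunc_rates
    reportable = {
        k: v for k, v in trunc_rates.items() if k not in FLOOR_CENSORED and v > 0
    }
    if reportable:
        logger.info("truncation rates (non-floor parameters): %s", reportable)
    return df


# --- annotation synthesis -------------------------------------------------

_BASE_FRAME = 120  # bolus-past-mandible frame; leaves room for negative SRT


def _rect(rng: np.random.Generator, area_px2: float) -> np.ndarray:
    """An axis-aligned rectangle of exactly the requested pixel area, at a
    random location (area is placement-invariant)."""
    if area_px2 <= 0:
        return np.empty((0, 2))
    w = math.sqrt(area_px2) * rng.uniform(0.5, 2.0)
    h = area_px2 / w
    x0, y0 = rng.uniform(50.0, 900.0, size=2)
    return np.array([[x0, y0], [x0 + w, y0], [x0 + w, y0 + h], [x0, y0 + h]])


def synthesize_annotations(
    record: pd.Series | dict,
    config: CohortConfig,
    seed: int,
    rater_id: str = "truth",
) -> BolusAnnotation:
    """Construct a raw annotation whose measured parameters equal the true
    record (timing exact; geometry to float precision).

    Event frames are laid out from the grid-snapped intervals; the hyoid
    track is a half-cosine radial trajectory from the derived minimum to the
    peak over the burst, relaxing afterwards; contours are rectangles of the
    prescribed scaled area and the UES segment has the prescribed scaled
    length. Everything is expressed in a randomly rotated and translated
    pixel frame with the participant's sampled spine length.
    """
    r = dict(record)
    rng = np.random.default_rng(seed)
    fps = config.fps

    def k(name):
        return ms_to_frames(float(r[name]), fps)

    for name in ("ueso_duration", "time_to_lvc", "lvc_duration", "hyoid_burst_duration"):
        if float(r[name]) < 0:
            raise SynthesisError(f"negative duration {name}={r[name]} not realizable")

    mandible = _BASE_FRAME
    burst = mandible + k("swallow_reaction_time")
    if burst < 11:
        raise SynthesisError("swallow reaction time too negative to lay out frames")
    ues_open = burst + k("hyb_to_ueso")
    if ues_open < 0:
        raise SynthesisError("hyoid-burst-to-UES-opening too negative to lay out")
    ues_close = ues_open + k("ueso_duration")
    lvc_first = burst + k("time_to_lvc")
    lvc_offset = lvc_first + k("lvc_duration")
    peak_frame = burst + k("hyoid_burst_duration")
    rest = max(ues_close, lvc_offset, peak_frame) + 5
    events = EventFrames(
        bolus_past_mandible=mandible,
        hyoid_burst_onset=burst,
        ues_open=ues_open,
        ues_close=ues_close,
        lvc_first_frame=lvc_first,
        lvc_offset=lvc_offset,
        max_ues_opening=(ues_open + ues_close) // 2,
        max_pharyngeal_constriction=ues_open + 1,
        swallow_rest=rest,
    )

    # anatomical frame: random rotation + translation, sampled spine length
    L = float(r["spine_length_px"])
    theta = rng.uniform(0.0, 2.0 * math.pi)
    u = np.array([math.cos(theta), math.sin(theta)])  # superior unit vector (px)
    x_hat = np.array([u[1], -u[0]])  # anterior for a left-facing projection
    c4 = rng.uniform(300.0, 700.0, size=2)
    c2 = c4 + L * u
    landmarks = SpineLandmarks(c2ai=c2, c4ai=c4)

    def to_px(x_a, y_a):
        return c4 + (L / 100.0) * (np.multiply.outer(y_a, u) + np.multiply.outer(x_a, x_hat))

    # hyoid radial trajectory (%(C2-4)): minimum at burst onset, half-cosine
    # rise to the peak, partial relaxation afterwards
    peak = float(r["peak_xy_hyoid"])
    minimum = float(r["hyoid_min_xy"])
    if not 0.0 <= minimum <= peak:
        raise SynthesisError(
            f"hyoid minimum {minimum} outside [0, peak={peak}]"
        )
    frames = np.arange(burst - 10, rest + 11)
    radial = np.full(frames.shape, minimum, dtype=float)
    rise = (frames >= burst) & (frames <= peak_frame)
    phase = (frames[rise] - burst) / max(peak_frame - burst, 1)
    radial[rise] = minimum + (peak - minimum) * 0.5 * (1.0 - np.cos(math.pi * phase))
    after = frames > peak_frame
    if np.any(after):
        span = max(rest + 10 - peak_frame, 1)
        decay = (frames[after] - peak_frame) / span
        radial[after] = peak - (peak - minimum) * 0.7 * np.minimum(decay, 1.0)
    phi = rng.uniform(0.3, 1.2)  # direction of the hyoid from C4, anterosuperior
    positions = to_px(radial * math.sin(phi), radial * math.cos(phi))
    hyoid = HyoidTrack(start_frame=int(frames[0]), positions=positions)

    area_scale = L * L / 100.0  # %(C2-4)^2 -> px^2
    contours = ContourSet(
        pharynx_at_max_constriction=_rect(rng, float(r["pa_max_constriction"]) * area_scale),
        pharynx_at_rest=_rect(rng, float(r["pa_rest"]) * area_scale),
        residue_valleculae=_rect(rng, float(r["residue_valleculae"]) * area_scale),
        residue_pyriform=_rect(rng, float(r["residue_pyriform"]) * area_scale),
        residue_other=_rect(rng, float(r["residue_other"]) * area_scale),
        ues_diameter_segment=np.stack(
            [
                p0 := rng.uniform(200.0, 800.0, size=2),
                p0
                + float(r["ues_diameter"])
                / 100.0
                * L
                * np.array([math.cos(a := rng.uniform(0, 2 * math.pi)), math.sin(a)]),
            ]
        ),
    )

    return BolusAnnotation(
        participant_id=str(r["participant_id"]),
        bolus_id=int(r["bolus_id"]),
        rater_id=rater_id,
        sip_volume=float(r["sip_volume"]),
        n_swallows=int(r["n_swallows"]),
        pas_initial=int(r["pas_initial"]),
        pas_max=int(r["pas_max"]),
        lvc_integrity=str(r["lvc_integrity"]),
        events=events,
        landmarks=landmarks,
        hyoid=hyoid,
        contours=contours,
        fps=fps,
    )


# --- rater simulation -----------------------------------------------------

def simulate_rater(
    annotation: BolusAnnotation,
    config: CohortConfig,
    seed: int,
    rater_id: str = "rater",
) -> BolusAnnotation:
    """A noisy copy of an annotation, emulating one blinded human rater:
    discretized-normal frame jitter on every event, normal pixel jitter on
    every annotated coordinate (including the spine landmarks), and small
    probabilities of a +-1 PAS disagreement or an LVC-integrity flip.
    Deterministic given the seed; all-zero noise returns an identical copy.
    """
    rng = np.random.default_rng(seed)
    ev = annotation.events

    def jit(frame):
        if frame is None:
            return None
        return max(int(frame) + int(round(rng.normal(0.0, config.frame_jitter_sd))), 0)

    e = {name: jit(ev.get(name)) for name in (
        "bolus_past_mandible",
        "hyoid_burst_onset",
        "ues_open",
        "ues_close",
        "lvc_first_frame",
        "lvc_offset",
        "max_ues_opening",
        "max_pharyngeal_constriction",
        "swallow_rest",
    )}
    # keep physically ordered events ordered after jitter
    if e["ues_open"] is not None and e["ues_close"] is not None:
        e["ues_close"] = max(e["ues_close"], e["ues_open"])
        if e["max_ues_opening"] is not None:
            e["max_ues_opening"] = int(
                np.clip(e["max_ues_opening"], e["ues_open"], e["ues_close"])
            )
    if e["lvc_first_frame"] is not None and e["lvc_offset"] is not None:
        e["lvc_offset"] = max(e["lvc_offset"], e["lvc_first_frame"])
    if e["hyoid_burst_onset"] is not None and e["swallow_rest"] is not None:
        e["swallow_rest"] = max(e["swallow_rest"], e["hyoid_burst_onset"])

    def jitter_points(points):
        if points is None or np.size(points) == 0:
            return points
        return points + rng.normal(0.0, config.coord_jitter_px, size=np.shape(points))

    landmarks = SpineLandmarks(
        c2ai=jitter_points(annotation.landmarks.c2ai),
        c4ai=jitter_points(annotation.landmarks.c4ai),
    )
    hyoid = annotation.hyoid
    if hyoid is not None:
        hyoid = HyoidTrack(
            start_frame=hyoid.start_frame, positions=jitter_points(hyoid.positions)
        )
    c = annotation.contours
    contours = ContourSet(
        pharynx_at_max_constriction=jitter_points(c.pharynx_at_max_constriction),
        pharynx_at_rest=jitter_points(c.pharynx_at_rest),
        residue_valleculae=jitter_points(c.residue_valleculae),
        residue_pyriform=jitter_points(c.residue_pyriform),
        residue_other=jitter_points(c.residue_other),
        ues_diameter_segment=jitter_points(c.ues_diameter_segment),
    )

    pas_initial = annotation.pas_initial
    if rng.uniform() < config.pas_flip_p:
        pas_initial = int(np.clip(pas_initial + rng.choice([-1, 1]), 1, 8))
    pas_max = annotation.pas_max
    if rng.uniform() < config.pas_flip_p:
        pas_max = int(np.clip(pas_max + rng.choice([-1, 1]), 1, 8))
    pas_max = max(pas_max, pas_initial)
    lvc = annotation.lvc_integrity
    if rng.uniform() < config.lvc_flip_p:
        lvc = "partial" if lvc == "complete" else "complete"

    return BolusAnnotation(
        participant_id=annotation.participant_id,
        bolus_id=annotation.bolus_id,
        rater_id=rater_id,
        sip_volume=annotation.sip_volume,
        n_swallows=annotation.n_swallows,
        pas_initial=pas_initial,
        pas_max=pas_max,
        lvc_integrity=lvc,
        events=EventFrames(**e),
        landmarks=landmarks,
        hyoid=hyoid,
        contours=contours,
        fps=annotation.fps,
    )


# --- one-call study simulation --------------------------------------------

@dataclass
class SimulatedStudy:
    participants: pd.DataFrame
    truth: pd.DataFrame
    annotations: list[BolusAnnotation]
    rater_a: list[BolusAnnotation]
    rater_b: list[BolusAnnotation]
    seed: int


def simulate_study(
    config: Optional[CohortConfig] = None,
    effects: Optional[EffectConfig] = None,
    seed: int = 0,
    raters: bool = True,
) -> SimulatedStudy:
    """Generate a full synthetic study: cohort, true per-bolus parameters,
    truth annotations, and (optionally) two noisy rater copies per bolus."""
    config = config or CohortConfig()
    effects = effects or EffectConfig()
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(3)
    participants = generate_cohort(config, int(seeds[0]))
    truth = generate_parameters(participants, effects, config, int(seeds[1]))
    child = np.random.SeedSequence(int(seeds[2])).spawn(len(truth))
    annotations, ra, rb = [], [], []
    for i, (_, row) in enumerate(truth.iterrows()):
        sub = child[i].generate_state(3)
        ann = synthesize_annotations(row, config, int(sub[0]))
        annotations.append(ann)
        if raters:
            ra.append(simulate_rater(ann, config, int(sub[1]), rater_id="rater_a"))
            rb.append(simulate_rater(ann, config, int(sub[2]), rater_id="rater_b"))
    return SimulatedStudy(
        participants=participants,
        truth=truth,
        annotations=annotations,
        rater_a=ra,
        rater_b=rb,
        seed=seed,
    )
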