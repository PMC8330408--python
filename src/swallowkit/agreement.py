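"""Inter-rater agreement and consensus for dual-rated bolus annotations.

The rating workflow assigns each bolus recording to two blinded raters.
Before any discrepancy is resolved, agreement is summarized per item as
percent absolute agreement (within a tolerance), mean absolute difference,
and the intraclass correlation ICC(2,1) (two-way random effects, absolute
agreement, single measures — the appropriate form when raters are randomly
drawn from a pool). Items whose disagreement exceeds a pre-specified
threshold are flagged; flagged items require an explicit resolution before
the pair can be merged into a consensus annotation.

Default thresholds: event frames +-3 frames; UES diameter +-4 %(C2-4);
pharyngeal areas +-10 %(C2-4)^2; residue +-1 %(C2-4)^2; categorical items
(PAS, LVC integrity, swallow count) exact match. All are configurable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    BolusAnnotation,
    ContourSet,
    EventFrames,
    EVENT_NAMES,
    HyoidTrack,
    SpineLandmarks,
)
from .exceptions import ConfigurationError, ConsensusError, UndefinedStatisticError
from .measures import compute_scaled_geometry

logger = logging.getLogger(__name__)

CATEGORICAL_ITEMS = ("n_swallows", "pas_initial", "pas_max", "lvc_integrity")
GEOMETRY_ITEMS = (
    "ues_diameter",
    "pa_max_constriction",
    "pa_rest",
    "residue_valleculae",
    "residue_pyriform",
    "residue_other",
)

#: default discrepancy thresholds (absolute difference strictly above flags)
DEFAULT_THRESHOLDS = {
    "event_frames": 3.0,
    "ues_diameter": 4.0,
    "pa_max_constriction": 10.0,
    "pa_rest": 10.0,
    "residue_valleculae": 1.0,
    "residue_pyriform": 1.0,
    "residue_other": 1.0,
    "n_swallows": 0.0,
    "pas_initial": 0.0,
    "pas_max": 0.0,
    "lvc_integrity": 0.0,
}

_KNOWN_ITEMS = (
    set(EVENT_NAMES) | set(GEOMETRY_ITEMS) | set(CATEGORICAL_ITEMS) | {"event_frames"}
)


# --- statistics -----------------------------------------------------------

def percent_agreement(a: Sequence, b: Sequence, tolerance: float = 0.0) -> float:
    """Percent of paired ratings agreeing within ``tolerance`` (exact match
    for categorical data, tolerance 0)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.size == 0 or a.shape != b.shape:
        raise UndefinedStatisticError("percent agreement needs non-empty paired data")
    if tolerance < 0:
        raise ConfigurationError("tolerance must be >= 0")
    if a.dtype.kind in "UOS" or b.dtype.kind in "UOS":
        hits = a == b
    else:
        hits = np.abs(a.astype(float) - b.astype(float)) <= tolerance
    return 100.0 * float(np.mean(hits))


def mean_absolute_difference(a: Sequence[float], b: Sequence[float]) -> float:
    """Mean |a_i - b_i| in the item's native units."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise UndefinedStatisticError(
            "mean absolute difference needs non-empty paired data"
        )
    return float(np.mean(np.abs(a - b)))


def icc(a: Sequence[float], b: Sequence[float]) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares for n targets x 2 raters:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC and MSE are the row (target), column (rater) and residual
    mean squares. Returns nan with a warning on zero total variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise UndefinedStatisticError("icc needs equal-length 1-d vectors")
    n = a.size
    if n < 3:
        raise UndefinedStatisticError("icc needs at least 3 paired ratings")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        return math.nan
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        warnings.warn("degenerate variance decomposition: ICC undefined", stacklevel=2)
        return math.nan
    return float((msr - mse) / denom)


# --- item extraction ------------------------------------------------------

def _item_values(ann: BolusAnnotation, facing: str = "left") -> dict:
    """All compared item values for one annotation: event frames, categorical
    scalars, and the anatomically scaled geometry measures."""
    values = {name: ann.events.get(name) for name in EVENT_NAMES}
    for name in CATEGORICAL_ITEMS:
        values[name] = getattr(ann, name)
    values.update(
        {
            k: v
            for k, v in compute_scaled_geometry(ann.contours, ann.landmarks).items()
            if k in GEOMETRY_ITEMS
        }
    )
    return values


def _threshold_for(item: str, thresholds: dict) -> float:
    if item in EVENT_NAMES:
        key = item if item in thresholds else "event_frames"
    else:
        key = item
    if key not in thresholds:
        raise ConfigurationError(f"no threshold configured for item {item!r}")
    return float(thresholds[key])


def _is_categorical(item: str) -> bool:
    return item in CATEGORICAL_ITEMS


@dataclass(frozen=True)
class DiscrepancyFlag:
    """One inter-rater disagreement exceeding its threshold."""

    key: tuple
    item: str
    value_a: object
    value_b: object
    abs_difference: float
    threshold: float


def flag_discrepancies(
    rater_a: BolusAnnotation,
    rater_b: BolusAnnotation,
    thresholds: Optional[dict] = None,
    facing: str = "left",
) -> list[DiscrepancyFlag]:
    """Compare two ratings of the same bolus item by item; return one flag
    per exceedance (continuous: |a-b| > threshold; categorical: a != b),
    ordered deterministically by item."""
    if rater_a.key != rater_b.key:
        raise ConfigurationError(
            f"ratings refer to different boluses: {rater_a.key} vs {rater_b.key}"
        )
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    unknown = set(thresholds) - _KNOWN_ITEMS
    if unknown:
        raise ConfigurationError(f"unknown items in thresholds map: {sorted(unknown)}")
    va, vb = _item_values(rater_a, facing), _item_values(rater_b, facing)
    flags = []
    for item in list(EVENT_NAMES) + list(CATEGORICAL_ITEMS) + list(GEOMETRY_ITEMS):
        a, b = va[item], vb[item]
        threshold = _threshold_for(item, thresholds)
        if a is None or b is None:
            if (a is None) != (b is None):
                flags.append(
                    DiscrepancyFlag(rater_a.key, item, a, b, math.nan, threshold)
                )
            continue
        if _is_categorical(item) and item != "n_swallows":
            if isinstance(a, str) or isinstance(b, str):
                if a != b:
                    flags.append(
                        DiscrepancyFlag(rater_a.key, item, a, b, math.nan, threshold)
                    )
                continue
        diff = abs(float(a) - float(b))
        if diff > threshold:
            flags.append(DiscrepancyFlag(rater_a.key, item, a, b, diff, threshold))
    return flags


def flags_to_frame(flags: Sequence[DiscrepancyFlag]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": f.key[0],
            "bolus_id": f.key[1],
            "item": f.item,
            "value_a": f.value_a,
            "value_b": f.value_b,
            "abs_difference": f.abs_difference,
            "threshold": f.threshold,
        }
        for f in flags
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "bolus_id",
            "item",
            "value_a",
            "value_b",
            "abs_difference",
            "threshold",
        ],
    )


# --- agreement report -----------------------------------------------------

def agreement_report(
    pairs: Sequence[tuple[BolusAnnotation, BolusAnnotation]],
    thresholds: Optional[dict] = None,
    facing: str = "left",
) -> pd.DataFrame:
    """Pre-consensus agreement statistics per item across all rating pairs.

    Percent absolute agreement uses each item's flag threshold as its
    tolerance; ICC and mean absolute difference are reported for numeric
    items (ICC requires >= 3 complete pairs and non-zero variance).
    """
    if not pairs:
        raise UndefinedStatisticError("agreement report needs at least one pair")
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    values_a = [_item_values(a, facing) for a, _ in pairs]
    values_b = [_item_values(b, facing) for _, b in pairs]
    flag_counts: dict[str, int] = {}
    for a, b in pairs:
        for f in flag_discrepancies(a, b, thresholds, facing):
            flag_counts[f.item] = flag_counts.get(f.item, 0) + 1
    rows = []
    for item in list(EVENT_NAMES) + list(CATEGORICAL_ITEMS) + list(GEOMETRY_ITEMS):
        av = [v[item] for v in values_a]
        bv = [v[item] for v in values_b]
        keep = [i for i, (x, y) in enumerate(zip(av, bv)) if x is not None and y is not None]
        av = [av[i] for i in keep]
        bv = [bv[i] for i in keep]
        row = {
            "item": item,
            "n_pairs": len(av),
            "tolerance": _threshold_for(item, thresholds),
            "percent_agreement": math.nan,
            "mean_abs_difference": math.nan,
            "icc": math.nan,
            "n_flagged": flag_counts.get(item, 0),
        }
        if av:
            row["percent_agreement"] = percent_agreement(
                av, bv, tolerance=row["tolerance"]
            )
            if item != "lvc_integrity":
                row["mean_abs_difference"] = mean_absolute_difference(av, bv)
                if len(av) >= 3:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        row["icc"] = icc(av, bv)
        rows.append(row)
    return pd.DataFrame(rows)


# --- consensus ------------------------------------------------------------

def _round_half_even(x: float) -> int:
    return int(np.round(x))


def auto_resolutions(flags: Sequence[DiscrepancyFlag]) -> dict:
    """Default automatic resolution policy used by the pipeline (the study
    resolves flags in consensus meetings, which cannot be automated): event
    frames take the rounded mean, categorical items rater A's value, and
    geometry items rater A's contour."""
    res = {}
    for f in flags:
        if f.item in EVENT_NAMES:
            if f.value_a is None or f.value_b is None:
                res[f.item] = f.value_a if f.value_a is not None else f.value_b
            else:
                res[f.item] = _round_half_even((f.value_a + f.value_b) / 2.0)
        elif f.item in CATEGORICAL_ITEMS:
            res[f.item] = f.value_a
        else:
            res[f.item] = "a"
    return res


def _merge_polygon(pa: np.ndarray, pb: np.ndarray, context: str) -> np.ndarray:
    if pa.shape == pb.shape:
        return (pa + pb) / 2.0
    logger.warning("polygon vertex counts differ %s; keeping rater A", context)
    return pa


def consensus_merge(
    rater_a: BolusAnnotation,
    rater_b: BolusAnnotation,
    resolutions: Optional[dict] = None,
    thresholds: Optional[dict] = None,
    facing: str = "left",
) -> BolusAnnotation:
    """Merge two ratings of a bolus into a consensus annotation.

    Every flagged item must have a resolution (event items: an integer
    frame; categorical: the chosen label/count; geometry: "a" or "b"
    selecting that rater's pixel contour). Unflagged event frames merge to
    the rounded mean (round-half-to-even), unflagged categorical items take
    rater A's value, and pixel data (landmarks, track, contours) merge by
    coordinate-wise averaging.
    """
    flags = flag_discrepancies(rater_a, rater_b, thresholds, facing)
    resolutions = dict(resolutions or {})
    pending = [f.item for f in flags if f.item not in resolutions]
    if pending:
        raise ConsensusError(pending)
    flagged = {f.item for f in flags}
    context = f"[{rater_a.participant_id}/bolus {rater_a.bolus_id}]"
    if rater_a.fps != rater_b.fps:
        raise ConfigurationError("rating pair has mismatched fps")

    # events
    merged_events = {}
    for name in EVENT_NAMES:
        a, b = rater_a.events.get(name), rater_b.events.get(name)
        if name in flagged:
            merged_events[name] = resolutions[name]
        elif a is None or b is None:
            merged_events[name] = a if a is not None else b
        else:
            merged_events[name] = _round_half_even((a + b) / 2.0)
    # enforce event-order invariants that independent rounding can break
    if (
        merged_events.get("max_ues_opening") is not None
        and merged_events.get("ues_open") is not None
        and merged_events.get("ues_close") is not None
    ):
        merged_events["max_ues_opening"] = int(
            np.clip(
                merged_events["max_ues_opening"],
                merged_events["ues_open"],
                merged_events["ues_close"],
            )
        )
    for lo, hi in (
        ("ues_open", "ues_close"),
        ("lvc_first_frame", "lvc_offset"),
        ("hyoid_burst_onset", "swallow_rest"),
    ):
        if (
            merged_events.get(lo) is not None
            and merged_events.get(hi) is not None
            and merged_events[lo] > merged_events[hi]
        ):
            logger.warning("clamping %s to %s after merge %s", hi, lo, context)
            merged_events[hi] = merged_events[lo]

    # categorical scalars
    merged_cat = {}
    for name in CATEGORICAL_ITEMS:
        merged_cat[name] = (
            resolutions[name] if name in flagged else getattr(rater_a, name)
        )
    merged_cat["pas_max"] = max(merged_cat["pas_max"], merged_cat["pas_initial"])

    # pixel data
    landmarks = SpineLandmarks(
        c2ai=(rater_a.landmarks.c2ai + rater_b.landmarks.c2ai) / 2.0,
        c4ai=(rater_a.landmarks.c4ai + rater_b.landmarks.c4ai) / 2.0,
    )
    hyoid = rater_a.hyoid
    if rater_a.hyoid is not None and rater_b.hyoid is not None:
        if (
            rater_a.hyoid.start_frame == rater_b.hyoid.start_frame
            and len(rater_a.hyoid.positions) == len(rater_b.hyoid.positions)
        ):
            hyoid = HyoidTrack(
                start_frame=rater_a.hyoid.start_frame,
                positions=(rater_a.hyoid.positions + rater_b.hyoid.positions) / 2.0,
            )
        else:
            logger.warning("hyoid track extents differ %s; keeping rater A", context)
    elif rater_a.hyoid is None:
        hyoid = rater_b.hyoid

    def pick(item: str, pa, pb):
        if item in flagged:
            choice = resolutions[item]
            if choice not in ("a", "b"):
                raise ConfigurationError(
                    f"geometry resolution for {item!r} must be 'a' or 'b'"
                )
            return pa if choice == "a" else pb
        return None  # signal: merge by averaging

    contour_kwargs = {}
    region_to_item = {
        "pharynx_at_max_constriction": "pa_max_constriction",
        "pharynx_at_rest": "pa_rest",
        "residue_valleculae": "residue_valleculae",
        "residue_pyriform": "residue_pyriform",
        "residue_other": "residue_other",
    }
    for region, item in region_to_item.items():
        pa = rater_a.contours.polygon(region)
        pb = rater_b.contours.polygon(region)
        chosen = pick(item, pa, pb)
        contour_kwargs[region] = (
            chosen if chosen is not None else _merge_polygon(pa, pb, context)
        )
    sa = rater_a.contours.ues_diameter_segment
    sb = rater_b.contours.ues_diameter_segment
    if sa is None or sb is None:
        seg = sa if sa is not None else sb
    else:
        chosen = pick("ues_diameter", sa, sb)
        seg = chosen if chosen is not None else (sa + sb) / 2.0
    contour_kwargs["ues_diameter_segment"] = seg

    return BolusAnnotation(
        participant_id=rater_a.participant_id,
        bolus_id=rater_a.bolus_id,
        rater_id="consensus",
        sip_volume=(rater_a.sip_volume + rater_b.sip_volume) / 2.0,
        events=EventFrames(**merged_events),
        landmarks=landmarks,
        hyoid=hyoid,
        contours=ContourSet(**contour_kwargs),
        fps=rater_a.fps,
        **merged_cat,
    )
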