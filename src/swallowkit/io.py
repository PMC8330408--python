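"""File formats and configuration.

Annotations travel as JSON (one document holding a list of annotation
objects — nested event maps, coordinate arrays and scalars); derived
parameter records as tidy UTF-8 comma-separated CSV with a mandatory header
row and an optional units row; configuration as a single human-editable YAML
file. Schema violations are reported with record/field context and never
silently coerced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotations import (
    BolusAnnotation,
    ContourSet,
    EVENT_NAMES,
    EventFrames,
    HyoidTrack,
    ParameterRecord,
    REGION_NAMES,
    SpineLandmarks,
)
from .exceptions import InputValidationError
from .synthetic import CohortConfig, EffectConfig, ParameterEffect

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: units of each parameter column, written on the optional units row
PARAMETER_UNITS = {
    "sip_volume": "ml",
    "n_swallows": "count",
    "pas_initial": "score 1-8",
    "pas_max": "score 1-8",
    "lvc_integrity": "category",
    "swallow_reaction_time": "ms",
    "hyb_to_ueso": "ms",
    "ueso_duration": "ms",
    "time_to_lvc": "ms",
    "lvc_duration": "ms",
    "hyoid_burst_duration": "ms",
    "peak_xy_hyoid": "%(C2-4)",
    "hyoid_xy_speed": "%(C2-4)/s",
    "ues_diameter": "%(C2-4)",
    "pa_max_constriction": "%(C2-4)^2",
    "pa_rest": "%(C2-4)^2",
    "residue_valleculae": "%(C2-4)^2",
    "residue_pyriform": "%(C2-4)^2",
    "residue_other": "%(C2-4)^2",
    "residue_total": "%(C2-4)^2",
}


# --- annotation JSON ------------------------------------------------------

def annotation_to_dict(ann: BolusAnnotation) -> dict:
    d = {
        "participant_id": ann.participant_id,
        "bolus_id": ann.bolus_id,
        "rater_id": ann.rater_id,
        "fps": ann.fps,
        "sip_volume_ml": ann.sip_volume,
        "n_swallows": ann.n_swallows,
        "pas_initial": ann.pas_initial,
        "pas_max": ann.pas_max,
        "lvc_integrity": ann.lvc_integrity,
        "events": {k: ann.events.get(k) for k in EVENT_NAMES},
        "landmarks": {
            "c2ai": ann.landmarks.c2ai.tolist(),
            "c4ai": ann.landmarks.c4ai.tolist(),
        },
        "contours": {
            name: ann.contours.polygon(name).tolist() for name in REGION_NAMES
        },
    }
    seg = ann.contours.ues_diameter_segment
    d["contours"]["ues_diameter_segment"] = None if seg is None else seg.tolist()
    if ann.hyoid is None:
        d["hyoid_track"] = None
    else:
        d["hyoid_track"] = {
            "start_frame": ann.hyoid.start_frame,
            "positions": ann.hyoid.positions.tolist(),
        }
    return d


def annotation_from_dict(d: dict, context: str = "") -> BolusAnnotation:
    required = (
        "participant_id",
        "bolus_id",
        "rater_id",
        "sip_volume_ml",
        "n_swallows",
        "pas_initial",
        "pas_max",
        "lvc_integrity",
        "events",
        "landmarks",
    )
    missing = [k for k in required if k not in d]
    if missing:
        raise InputValidationError(f"{context}: missing required fields {missing}")
    events = d["events"]
    unknown = set(events) - set(EVENT_NAMES)
    if unknown:
        raise InputValidationError(
            f"{context}: unknown event names {sorted(unknown)}; "
            f"allowed: {list(EVENT_NAMES)}"
        )
    contours_in = d.get("contours") or {}
    unknown = set(contours_in) - set(REGION_NAMES) - {"ues_diameter_segment"}
    if unknown:
        raise InputValidationError(f"{context}: unknown contour regions {sorted(unknown)}")
    track_in = d.get("hyoid_track")
    hyoid = None
    if track_in is not None:
        hyoid = HyoidTrack(
            start_frame=track_in["start_frame"],
            positions=np.asarray(track_in["positions"], dtype=float),
        )
    else:
        logger.warning("%s: no hyoid track; kinematic parameters will be missing",
                       context or "annotation")
    seg = contours_in.get("ues_diameter_segment")
    try:
        return BolusAnnotation(
            participant_id=str(d["participant_id"]),
            bolus_id=int(d["bolus_id"]),
            rater_id=str(d["rater_id"]),
            sip_volume=float(d["sip_volume_ml"]),
            n_swallows=int(d["n_swallows"]),
            pas_initial=int(d["pas_initial"]),
            pas_max=int(d["pas_max"]),
            lvc_integrity=str(d["lvc_integrity"]),
            events=EventFrames(**{k: v for k, v in events.items() if v is not None}),
            landmarks=SpineLandmarks(
                c2ai=np.asarray(d["landmarks"]["c2ai"], dtype=float),
                c4ai=np.asarray(d["landmarks"]["c4ai"], dtype=float),
            ),
            hyoid=hyoid,
            contours=ContourSet(
                **{
                    name: np.asarray(contours_in.get(name, []), dtype=float).reshape(-1, 2)
                    for name in REGION_NAMES
                },
                ues_diameter_segment=None if seg is None else np.asarray(seg, dtype=float),
            ),
            fps=float(d.get("fps", 30.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise InputValidationError(f"{context}: malformed annotation: {exc}") from exc


def write_annotations(
    annotations: Sequence[BolusAnnotation], path: str | Path, seed: Optional[int] = None
) -> Path:
    path = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "annotations": [annotation_to_dict(a) for a in annotations],
    }
    path.write_text(json.dumps(doc))
    return path


def read_annotations(path: str | Path) -> list[BolusAnnotation]:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputValidationError(f"{path}: not valid JSON: {exc}") from exc
    if isinstance(doc, list):  # bare list accepted
        items = doc
    elif isinstance(doc, dict) and "annotations" in doc:
        items = doc["annotations"]
    else:
        raise InputValidationError(
            f"{path}: expected an annotation list or an object with 'annotations'"
        )
    out = []
    for i, item in enumerate(items):
        context = f"{path.name}[{i}]"
        out.append(annotation_from_dict(item, context=context))
    return out


# --- parameter record CSV -------------------------------------------------

def records_to_frame(records: Sequence[ParameterRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


def write_records_csv(
    records: pd.DataFrame | Sequence[ParameterRecord],
    path: str | Path,
    units_row: bool = False,
) -> Path:
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if units_row:
        units = pd.DataFrame(
            [{c: PARAMETER_UNITS.get(c, "") for c in df.columns}]
        )
        df = pd.concat([units, df], ignore_index=True)
    df.to_csv(path, index=False)
    return path


def read_records_csv(path: str | Path, units_row: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, skiprows=[1] if units_row else None)
    return df


# --- configuration --------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Everything the pipeline needs: timing and orientation conventions,
    agreement thresholds, Bonferroni families, and generator settings.
    Round-trips losslessly through YAML."""

    fps: float = 30.0
    timing_convention: str = "ceil"
    facing: str = "left"
    base_alpha: float = 0.05
    families: Optional[dict] = None
    thresholds: Optional[dict] = None
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    effects: EffectConfig = dataclasses.field(default_factory=EffectConfig)
    seed: int = 0
    sip_cut_ml: float = 16.0
    min_minority_participants: int = 5


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["effects"]["correlations"] = np.asarray(
        cfg.effects.correlations
    ).tolist()
    d["effects"]["effects"] = {
        k: dataclasses.asdict(v) for k, v in cfg.effects.effects.items()
    }
    d["effects"]["pas_probs"] = list(cfg.effects.pas_probs)
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "cohort" in d and isinstance(d["cohort"], dict):
        d["cohort"] = CohortConfig(**d["cohort"])
    if "effects" in d and isinstance(d["effects"], dict):
        e = dict(d["effects"])
        if "effects" in e:
            e["effects"] = {
                k: ParameterEffect(**v) if isinstance(v, dict) else v
                for k, v in e["effects"].items()
            }
        if e.get("correlations") is not None:
            e["correlations"] = np.asarray(e["correlations"], dtype=float)
        if "pas_probs" in e:
            e["pas_probs"] = tuple(e["pas_probs"])
        d["effects"] = EffectConfig(**e)
    return PipelineConfig(**d)


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
    return path


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise InputValidationError(f"{path}: config must be a YAML mapping")
    try:
        return config_from_dict(data)
    except TypeError as exc:
        raise InputValidationError(f"{path}: invalid config: {exc}") from exc
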