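"""End-to-end pipeline and the effect-recovery simulation harness.

``run_pipeline`` executes the full study workflow on a set of dual-rated
annotations (simulated or read from disk): pre-consensus agreement,
discrepancy flagging and automatic consensus, per-bolus measurement,
participant means, descriptives, the correlation screen, hierarchical
age/sex/sip-volume regressions against Bonferroni family alphas, the
bolus-level multiple-swallow logistic model and the dichotomized sip-volume
odds ratio. Every stage logs one structured line with its record count, and
all randomness flows from the single configured seed.

``effect_recovery_study`` repeats cohort simulation + regression many times
to estimate the mean recovered effects — the calibration check that the
generator and the statistical stage are mutually consistent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import agreement as agr
from . import stats as st
from .exceptions import InputValidationError, SwallowKitError, UndefinedStatisticError
from .io import (
    PipelineConfig,
    config_to_dict,
    records_to_frame,
    write_records_csv,
)
from .measures import summarize_bolus
from .synthetic import SimulatedStudy, simulate_study
from .stats import family_alpha_map, hierarchical_linear, participant_means

logger = logging.getLogger(__name__)


def configure_logging(level: int = logging.INFO, logfile: Optional[str] = None):
    """Structured logging to console (and optionally a file)."""
    handlers = [logging.StreamHandler()]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class PipelineResult:
    records: pd.DataFrame
    participants: pd.DataFrame
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    agreement: Optional[pd.DataFrame]
    flags: Optional[pd.DataFrame]
    regressions: dict
    regression_summary: pd.DataFrame
    logistic: Optional[pd.DataFrame]
    sip_odds_ratio: Optional[st.OddsRatioResult]
    metadata: dict = field(default_factory=dict)


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config_to_dict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _stage(name: str, count: int):
    logger.info("stage=%s records=%d", name, count)


#: outcomes analysed in the regression stage (the swallow count, PAS and LVC
#: integrity go through the logistic/odds-ratio route instead)
REGRESSION_OUTCOMES = (
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
    "residue_total",
)


def analyze_records(
    records: pd.DataFrame, config: Optional[PipelineConfig] = None
) -> dict:
    """The statistical stage on a bolus-level parameter table (needs age and
    male columns). Returns participant means, descriptives, correlations,
    hierarchical regressions keyed by outcome, a compact effect-flag summary,
    the multiple-swallow logistic fit and the dichotomized-sip odds ratio."""
    config = config or PipelineConfig()
    if "age" not in records.columns or "male" not in records.columns:
        raise InputValidationError("records need 'age' and 'male' covariate columns")
    means = participant_means(records)
    _stage("participant_means", len(means))
    desc = st.descriptives_table(records)
    corr = st.correlation_screen(means)
    alphas = family_alpha_map(config.families, base=config.base_alpha)
    regressions = {}
    summary_rows = []
    for outcome in REGRESSION_OUTCOMES:
        if outcome not in means.columns:
            continue
        alpha = alphas.get(outcome, config.base_alpha)
        try:
            res = hierarchical_linear(
                outcome if outcome != "sip_volume" else "sip_volume",
                means,
                alpha=alpha,
                include_sip=(
                    False
                    if outcome in ("sip_volume",) + st.REST_OUTCOMES
                    else None
                ),
            )
        except (UndefinedStatisticError, SwallowKitError) as exc:
            logger.warning("regression for %s skipped: %s", outcome, exc)
            continue
        regressions[outcome] = res
        row = {
            "outcome": outcome,
            "family_alpha": alpha,
            "age_effect": res.stages[0].significant,
            "age_coef": res.stages[0].coef["age"],
            "age_r2": res.stages[0].r2,
            "age_r2_adj": res.stages[0].r2_adj,
            "sex_effect": res.stages[1].significant if len(res.stages) > 1 else None,
            "sex_coef": res.stages[1].coef.get("male") if len(res.stages) > 1 else None,
            "sip_effect": res.stages[2].significant if len(res.stages) > 2 else None,
            "sip_coef": (
                res.stages[2].coef.get("sip_volume") if len(res.stages) > 2 else None
            ),
        }
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    _stage("regressions", len(summary))

    logistic = None
    sip_or = None
    if "multiple_swallows" in records.columns:
        try:
            logistic = st.binary_logistic(records)
        except SwallowKitError as exc:
            logger.warning("multiple-swallow logistic model skipped: %s", exc)
        try:
            table = st.dichotomize_sip(records, cut=config.sip_cut_ml)
            sip_or = st.two_by_two_or(*table)
        except SwallowKitError as exc:
            logger.warning("sip-volume odds ratio skipped: %s", exc)

    # PAS / LVC-integrity logistic models are run only when the minority
    # class is represented by enough participants; the study found too few
    # unsafe swallows or incomplete closures to model.
    extra_logistic = {}
    for outcome_col, label in (("pas_impaired", "pas"), ("lvc_impaired", "lvc")):
        if outcome_col == "pas_impaired":
            records = records.assign(pas_impaired=records["pas_max"] > 2)
        else:
            records = records.assign(
                lvc_impaired=records["lvc_integrity"] != "complete"
            )
        minority = (
            records.groupby("participant_id")[outcome_col].any().sum()
        )
        minority = min(int(minority), len(means) - int(minority))
        if minority < config.min_minority_participants:
            logger.info(
                "%s logistic model skipped: minority class has %d participants",
                label,
                minority,
            )
            continue
        try:
            extra_logistic[label] = st.binary_logistic(records, outcome=outcome_col)
        except SwallowKitError as exc:
            logger.warning("%s logistic model skipped: %s", label, exc)

    return {
        "participant_means": means,
        "descriptives": desc,
        "correlations": corr,
        "regressions": regressions,
        "regression_summary": summary,
        "logistic": logistic,
        "extra_logistic": extra_logistic,
        "sip_odds_ratio": sip_or,
    }


def run_pipeline(
    config: Optional[PipelineConfig] = None,
    study: Optional[SimulatedStudy] = None,
    rating_pairs: Optional[list] = None,
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Measure -> agree/consensus -> participant means -> statistics.

    Input is either a :class:`SimulatedStudy` (default: simulated from the
    config seed), or explicit ``rating_pairs`` — a list of
    ``(rater_a, rater_b)`` annotation pairs. Outputs are written to
    ``out_dir`` when given; numeric outputs are byte-identical under a fixed
    config and seed.
    """
    config = config or PipelineConfig()
    if rating_pairs is None:
        if study is None:
            study = simulate_study(
                config.cohort, config.effects, seed=config.seed, raters=True
            )
        rating_pairs = list(zip(study.rater_a, study.rater_b))
    if not rating_pairs:
        raise InputValidationError("no annotations supplied to the measure stage")
    _stage("input_pairs", len(rating_pairs))

    report = agr.agreement_report(rating_pairs, config.thresholds, config.facing)
    all_flags = []
    consensus = []
    for a, b in rating_pairs:
        flags = agr.flag_discrepancies(a, b, config.thresholds, config.facing)
        all_flags.extend(flags)
        resolutions = agr.auto_resolutions(flags)
        consensus.append(
            agr.consensus_merge(a, b, resolutions, config.thresholds, config.facing)
        )
    flags_df = agr.flags_to_frame(all_flags)
    _stage("consensus", len(consensus))

    records = records_to_frame(
        [
            summarize_bolus(ann, facing=config.facing, convention=config.timing_convention)
            for ann in consensus
        ]
    )
    _stage("measures", len(records))

    covariates = None
    if study is not None:
        covariates = study.participants[["participant_id", "age", "male", "sex"]]
    if covariates is not None:
        records = records.merge(covariates, on="participant_id", how="left")
    if "age" not in records.columns:
        raise InputValidationError(
            "participant covariates (age, male) are required for the "
            "statistical stage"
        )

    analysis = analyze_records(records, config)

    meta = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_pairs": len(rating_pairs),
        "n_flags": len(flags_df),
        "n_participants": len(analysis["participant_means"]),
    }
    logger.info("pipeline complete: %s", meta)

    result = PipelineResult(
        records=records,
        participants=analysis["participant_means"],
        descriptives=analysis["descriptives"],
        correlations=analysis["correlations"],
        agreement=report,
        flags=flags_df,
        regressions=analysis["regressions"],
        regression_summary=analysis["regression_summary"],
        logistic=analysis["logistic"],
        sip_odds_ratio=analysis["sip_odds_ratio"],
        metadata=meta,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records_csv(result.records, out / "parameter_records.csv")
        result.participants.to_csv(out / "participant_means.csv", index=False)
        result.descriptives.to_csv(out / "descriptives.csv", index=False)
        result.correlations.to_csv(out / "correlations.csv", index=False)
        result.agreement.to_csv(out / "agreement.csv", index=False)
        result.flags.to_csv(out / "flags.csv", index=False)
        result.regression_summary.to_csv(out / "regression_summary.csv", index=False)
        (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    return result


# --- effect recovery harness ----------------------------------------------

#: recovered quantities: name -> (outcome, stage predictors, coefficient)
RECOVERY_TARGETS = {
    "srt_age_ms_per_year": ("swallow_reaction_time", 1, "age"),
    "sip_sex_ml": ("sip_volume", 2, "male"),
    "ueso_age_ms_per_year": ("ueso_duration", 1, "age"),
    "lvc_age_ms_per_year": ("lvc_duration", 1, "age"),
    "ues_diameter_age_pct_per_year": ("ues_diameter", 1, "age"),
    "hyb_sip_ms_per_ml": ("hyb_to_ueso", 3, "sip_volume"),
    "ues_diameter_sip_pct_per_ml": ("ues_diameter", 3, "sip_volume"),
    "pa_rest_age_pct2_per_year": ("pa_rest", 1, "age"),
    "pa_rest_sex_pct2": ("pa_rest", 2, "male"),
    "pa_maxc_age_pct2_per_year": ("pa_max_constriction", 1, "age"),
}


def _cohort_estimates(means: pd.DataFrame) -> dict:
    """One cohort's recovered coefficients and the age-only variance
    explained for UES opening duration."""
    out = {}
    for key, (outcome, stage, term) in RECOVERY_TARGETS.items():
        if outcome == "sip_volume":
            # sex model for sip volume: volume on the male indicator
            fit = hierarchical_linear("sip_volume", means, include_sip=False)
            out[key] = fit.stages[1].coef["male"]
            continue
        fit = hierarchical_linear(outcome, means)
        out[key] = fit.stages[stage - 1].coef[term]
        if outcome == "ueso_duration":
            out["ueso_age_r2"] = fit.stages[0].r2
            out["ueso_age_r2_adj"] = fit.stages[0].r2_adj
    return out


def effect_recovery_study(
    n_cohorts: int = 200,
    base_seed: int = 1,
    cohort: Optional["CohortConfig"] = None,
    effects: Optional["EffectConfig"] = None,
    full_pipeline: bool = False,
) -> pd.DataFrame:
    """Simulate ``n_cohorts`` cohorts (seeds ``base_seed .. base_seed +
    n_cohorts - 1``) and fit the hierarchical models per cohort, returning
    one row of recovered effects per cohort.

    With ``full_pipeline=False`` the regressions run on the generator's true
    parameter tables (the recovery of the effect structure itself); with
    ``full_pipeline=True`` each cohort additionally passes through
    annotation synthesis, two simulated raters, automatic consensus and
    measurement, so rater noise and consensus rounding are included.
    """
    from .synthetic import CohortConfig, EffectConfig, generate_cohort, generate_parameters

    cohort = cohort or CohortConfig()
    effects = effects or EffectConfig()
    rows = []
    for i in range(n_cohorts):
        seed = base_seed + i
        if full_pipeline:
            study = simulate_study(cohort, effects, seed=seed, raters=True)
            config = PipelineConfig(cohort=cohort, effects=effects, seed=seed)
            result = run_pipeline(config, study=study)
            means = result.participants
        else:
            participants = generate_cohort(cohort, seed)
            truth = generate_parameters(participants, effects, cohort, seed + 500_000)
            means = participant_means(truth)
        rows.append({"seed": seed, **_cohort_estimates(means)})
    return pd.DataFrame(rows)


def recovery_summary(estimates: pd.DataFrame) -> pd.DataFrame:
    """Mean, Monte-Carlo standard error and n over the per-cohort effect
    estimates."""
    cols = [c for c in estimates.columns if c != "seed"]
    rows = []
    for c in cols:
        v = estimates[c].dropna()
        rows.append(
            {
                "quantity": c,
                "mean": float(v.mean()),
                "mc_se": float(v.std(ddof=1) / np.sqrt(len(v))),
                "n_cohorts": int(len(v)),
            }
        )
    return pd.DataFrame(rows)
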