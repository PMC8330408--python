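"""Statistical stage: descriptives, correlation screening with Bonferroni
families, hierarchical age/sex/sip-volume regression, bolus-level logistic
regression for multiple swallows, and 2x2 odds ratios.

Linear models run on participant means (one row per participant); the
multiple-swallow logistic model runs on bolus-level rows because sip volume
varies per bolus. The hierarchical models add predictors stepwise — stage 1:
age; stage 2: + sex (male indicator, so the coefficient is the male-female
difference); stage 3: + sip volume — and test each added predictor against a
Bonferroni-corrected family alpha. Parameters measured at rest skip the
sip-volume stage.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .annotations import CONTINUOUS_PARAMETERS
from .exceptions import (
    ConfigurationError,
    InputValidationError,
    SeparationError,
    SingularDesignError,
    UndefinedStatisticError,
)

logger = logging.getLogger(__name__)

#: Bonferroni families: members are analysed at alpha = round(0.05/m, 3).
#: Family membership is declarative (the correlation screen is advisory:
#: connected components of the r > 0.25 graph would merge the first two
#: families because LVC duration links them).
DEFAULT_FAMILIES = {
    "burst_timing": ["hyb_to_ueso", "hyoid_burst_duration", "time_to_lvc"],
    "valve_kinematics": [
        "ueso_duration",
        "lvc_duration",
        "ues_diameter",
        "peak_xy_hyoid",
        "hyoid_xy_speed",
    ],
    "pharyngeal_geometry": [
        "pa_rest",
        "pa_max_constriction",
        "residue_valleculae",
        "residue_pyriform",
        "residue_other",
    ],
}

#: outcomes analysed at rest: the sip-volume stage is not applicable.
REST_OUTCOMES = ("pa_rest",)


# --- descriptives ---------------------------------------------------------

def descriptives(values: Sequence[float]) -> tuple[float, float, float]:
    """(25th percentile, median, 75th percentile) by linear interpolation
    between closest order statistics."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise UndefinedStatisticError("descriptives need at least one finite value")
    p25, p50, p75 = np.percentile(v, [25, 50, 75], method="linear")
    return float(p25), float(p50), float(p75)


def descriptives_table(
    records: pd.DataFrame, parameters: Sequence[str] = CONTINUOUS_PARAMETERS
) -> pd.DataFrame:
    """Median and interquartile-range boundaries per continuous parameter."""
    rows = []
    for name in parameters:
        if name not in records.columns:
            continue
        try:
            p25, p50, p75 = descriptives(records[name])
        except UndefinedStatisticError:
            p25 = p50 = p75 = math.nan
        rows.append({"parameter": name, "p25": p25, "median": p50, "p75": p75})
    return pd.DataFrame(rows)


# --- correlation screen ---------------------------------------------------

def correlation_screen(
    table: pd.DataFrame,
    parameters: Optional[Sequence[str]] = None,
    threshold: float = 0.25,
) -> pd.DataFrame:
    """Pearson correlations over all pairwise combinations of continuous
    parameters; returns the pairs with |r| > threshold, sorted by |r|
    descending. Constant columns are skipped with a warning."""
    if parameters is None:
        parameters = [p for p in CONTINUOUS_PARAMETERS if p in table.columns]
    usable = []
    for p in parameters:
        col = pd.to_numeric(table[p], errors="coerce")
        if col.nunique(dropna=True) <= 1:
            logger.warning("constant column %r skipped in correlation screen", p)
            continue
        usable.append(p)
    rows = []
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            sub = table[[a, b]].dropna()
            if len(sub) < 3:
                logger.warning("fewer than 3 complete pairs for (%s, %s)", a, b)
                continue
            r, p_val = sps.pearsonr(sub[a], sub[b])
            if abs(r) > threshold:
                rows.append({"parameter_a": a, "parameter_b": b, "r": r, "p": p_val})
    out = pd.DataFrame(rows, columns=["parameter_a", "parameter_b", "r", "p"])
    if len(out):
        out = out.reindex(
            out["r"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    return out


def family_alpha(m: int, base: float = 0.05, decimals: int = 3) -> float:
    """Bonferroni-corrected alpha for a family of m related parameters,
    rounded to the reported precision: m=3 -> 0.017, m=5 -> 0.01."""
    if m < 1:
        raise ConfigurationError(f"family size must be >= 1, got {m}")
    return round(base / m, decimals)


def family_alpha_map(
    families: Optional[dict] = None, base: float = 0.05
) -> dict[str, float]:
    """Outcome -> corrected alpha for every family member; outcomes not in
    any family get the base alpha."""
    families = DEFAULT_FAMILIES if families is None else families
    out = {}
    for members in families.values():
        alpha = family_alpha(len(members), base=base)
        for m in members:
            out[m] = alpha
    return out


# --- hierarchical linear regression ---------------------------------------

@dataclass
class StageResult:
    predictors: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    r2: float
    r2_adj: float
    delta_r2: float
    added: Optional[str]
    added_p: float
    significant: bool


@dataclass
class RegressionResult:
    outcome: str
    n: int
    family_alpha: float
    stages: list[StageResult] = field(default_factory=list)

    @property
    def age_significant(self) -> bool:
        return self.stages[0].significant

    def stage(self, i: int) -> StageResult:
        return self.stages[i - 1]


def _check_design(X: np.ndarray, names: Sequence[str]):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"rank-deficient design; collinear predictors among {list(names)}"
        )


def hierarchical_linear(
    outcome: str,
    participants: pd.DataFrame,
    alpha: float = 0.05,
    include_sip: Optional[bool] = None,
    sip_column: str = "sip_volume",
) -> RegressionResult:
    """Hierarchical OLS of a participant-mean outcome on age, then + sex,
    then + sip volume.

    ``participants`` needs columns ``age``, ``male`` (0/1) and the outcome
    (plus ``sip_volume`` unless the sip stage is skipped). Each stage's added
    predictor is tested at the supplied (family) alpha; R^2 is raw (monotone
    across stages) and adjusted R^2 is also reported as the unbiased
    variance-explained estimate. Sip volume is skipped for rest measures.
    """
    if include_sip is None:
        include_sip = outcome not in REST_OUTCOMES
    cols = ["age", "male", outcome] + ([sip_column] if include_sip else [])
    missing = [c for c in cols if c not in participants.columns]
    if missing:
        raise InputValidationError(f"missing columns for regression: {missing}")
    data = participants[list(dict.fromkeys(cols))].dropna()
    if len(data) < 10:
        raise UndefinedStatisticError(
            f"hierarchical regression needs >= 10 participants, got {len(data)}"
        )
    y = data[outcome].to_numpy(dtype=float)
    stage_predictors = [["age"], ["age", "male"]]
    if include_sip and sip_column != outcome:
        stage_predictors.append(["age", "male", sip_column])
    result = RegressionResult(
        outcome=outcome, n=len(data), family_alpha=alpha, stages=[]
    )
    prev_r2 = 0.0
    for preds in stage_predictors:
        X = sm.add_constant(data[preds].to_numpy(dtype=float))
        _check_design(X, ["const"] + preds)
        fit = sm.OLS(y, X).fit()
        names = ["const"] + preds
        added = preds[-1]
        stage = StageResult(
            predictors=list(preds),
            coef=dict(zip(names, fit.params)),
            se=dict(zip(names, fit.bse)),
            p=dict(zip(names, fit.pvalues)),
            r2=float(fit.rsquared),
            r2_adj=float(fit.rsquared_adj),
            delta_r2=float(fit.rsquared) - prev_r2,
            added=added,
            added_p=float(fit.pvalues[names.index(added)]),
            significant=bool(fit.pvalues[names.index(added)] < alpha),
        )
        prev_r2 = stage.r2
        result.stages.append(stage)
    return result


# --- logistic regression --------------------------------------------------

def binary_logistic(
    boluses: pd.DataFrame,
    outcome: str = "multiple_swallows",
    predictors: Sequence[str] = ("age", "male", "sip_volume"),
) -> pd.DataFrame:
    """Maximum-likelihood logistic regression on bolus-level rows.

    Returns one row per predictor with the log-odds coefficient, odds ratio,
    standard error and Wald p-value. Raises on a single-class outcome or
    complete separation (a penalized fit is suggested, never applied
    silently).
    """
    cols = [outcome] + list(predictors)
    missing = [c for c in cols if c not in boluses.columns]
    if missing:
        raise InputValidationError(f"missing columns for logistic model: {missing}")
    data = boluses[cols].dropna()
    y = data[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise InputValidationError(
            f"outcome {outcome!r} has a single class; logistic model undefined"
        )
    X = sm.add_constant(data[list(predictors)].to_numpy(dtype=float))
    _check_design(X, ["const"] + list(predictors))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            "complete separation detected; consider a penalized (Firth/ridge) "
            "fit — not applied by default"
        ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError(
            "logistic fit failed to converge (quasi-separation likely); "
            "consider a penalized fit"
        )
    names = ["const"] + list(predictors)
    return pd.DataFrame(
        {
            "term": names,
            "coef": fit.params,
            "se": fit.bse,
            "odds_ratio": np.exp(fit.params),
            "p": fit.pvalues,
        }
    )


# --- 2x2 odds ratio -------------------------------------------------------

@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool
    table: tuple


def two_by_two_or(a: float, b: float, c: float, d: float) -> OddsRatioResult:
    """Odds ratio ad/bc for a 2x2 table [[a, b], [c, d]] with a Woolf
    log-normal 95% CI. Zero cells receive the Haldane-Anscombe 0.5
    correction (recorded in the result); an all-zero margin is undefined."""
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise InputValidationError("2x2 counts must be non-negative")
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise UndefinedStatisticError("a 2x2 margin is zero; odds ratio undefined")
    corrected = bool(np.any(counts == 0))
    if corrected:
        counts = counts + 0.5
    a_, b_, c_, d_ = counts
    or_ = (a_ * d_) / (b_ * c_)
    log_se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = 1.959963984540054
    return OddsRatioResult(
        odds_ratio=float(or_),
        ci_low=float(math.exp(math.log(or_) - z * log_se)),
        ci_high=float(math.exp(math.log(or_) + z * log_se)),
        continuity_corrected=corrected,
        table=(a, b, c, d),
    )


def dichotomize_sip(
    boluses: pd.DataFrame,
    cut: float = 16.0,
    sip_column: str = "sip_volume",
    outcome: str = "multiple_swallows",
) -> tuple[int, int, int, int]:
    """2x2 counts of (sip volume > cut) x (multiple swallows): returns
    (a, b, c, d) = (large & multiple, large & single, small & multiple,
    small & single), with 'small' meaning sip <= cut."""
    data = boluses[[sip_column, outcome]].dropna()
    large = data[sip_column] > cut
    multiple = data[outcome].astype(bool)
    a = int((large & multiple).sum())
    b = int((large & ~multiple).sum())
    c = int((~large & multiple).sum())
    d = int((~large & ~multiple).sum())
    return a, b, c, d


# --- participant means ----------------------------------------------------

def participant_means(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse bolus-level parameter records to one row per participant:
    the mean of each continuous parameter, covariates carried through, and
    an any-multiple-swallows indicator."""
    if "participant_id" not in records.columns:
        raise InputValidationError("records need a participant_id column")
    continuous = [p for p in CONTINUOUS_PARAMETERS if p in records.columns]
    agg = {p: "mean" for p in continuous}
    for c in ("age", "male", "sex"):
        if c in records.columns:
            agg[c] = "first"
    grouped = records.groupby("participant_id", sort=True).agg(agg).reset_index()
    if "multiple_swallows" in records.columns:
        anym = records.groupby("participant_id", sort=True)["multiple_swallows"].any()
        grouped["any_multiple_swallows"] = anym.to_numpy()
    return grouped
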