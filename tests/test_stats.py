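"""Descriptives, Bonferroni families, hierarchical and logistic regression,
odds ratios."""

import math

import numpy as np
import pandas as pd
import pytest

from swallowkit import (
    CohortConfig,
    ConfigurationError,
    EffectConfig,
    InputValidationError,
    SingularDesignError,
    UndefinedStatisticError,
    binary_logistic,
    correlation_screen,
    descriptives,
    dichotomize_sip,
    family_alpha,
    family_alpha_map,
    generate_cohort,
    generate_parameters,
    hierarchical_linear,
    participant_means,
    two_by_two_or,
)


# --- descriptives ---------------------------------------------------------

def test_descriptives_examples(rng):
    assert descriptives([1, 2, 3, 4, 5]) == (2.0, 3.0, 4.0)
    assert descriptives([7.0] * 9) == (7.0, 7.0, 7.0)
    v = rng.normal(size=101)
    p25, p50, p75 = descriptives(v)
    # independent sort-and-interpolate oracle
    s = np.sort(v)
    for got, q in ((p25, 0.25), (p50, 0.5), (p75, 0.75)):
        h = q * (len(s) - 1)
        lo = int(math.floor(h))
        expected = s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])
        assert got == pytest.approx(expected)
    with pytest.raises(UndefinedStatisticError):
        descriptives([])


# --- family alphas --------------------------------------------------------

@pytest.mark.parametrize("m,expected", [(3, 0.017), (5, 0.01), (1, 0.05), (2, 0.025)])
def test_family_alpha_rounding(m, expected):
    assert family_alpha(m) == expected


def test_family_alpha_monotone_and_errors():
    vals = [family_alpha(m) for m in range(1, 12)]
    assert all(b <= a for a, b in zip(vals, vals[1:]))
    assert vals[0] == 0.05
    with pytest.raises(ConfigurationError):
        family_alpha(0)


def test_family_alpha_map_defaults():
    alphas = family_alpha_map()
    assert alphas["hyb_to_ueso"] == 0.017
    assert alphas["time_to_lvc"] == 0.017
    assert alphas["ueso_duration"] == 0.01
    assert alphas["pa_rest"] == 0.01


# --- correlation screen ---------------------------------------------------

def test_correlation_screen_reports_perfect_pair(rng):
    x = rng.normal(size=50)
    df = pd.DataFrame({"ues_diameter": x, "peak_xy_hyoid": x, "pa_rest": rng.normal(size=50)})
    out = correlation_screen(df)
    top = out.iloc[0]
    assert {top["parameter_a"], top["parameter_b"]} == {"ues_diameter", "peak_xy_hyoid"}
    assert top["r"] == pytest.approx(1.0)


def test_correlation_screen_skips_constant_columns(rng):
    df = pd.DataFrame({"ues_diameter": np.ones(30), "pa_rest": rng.normal(size=30)})
    out = correlation_screen(df)
    assert len(out) == 0


def test_correlation_screen_null_report_rate(rng):
    # independent columns at n=76: P(|r| > 0.25) from the exact null
    # distribution of Pearson r; compare the observed report rate
    from scipy import stats as sps

    n, trials = 76, 400
    hits = 0
    for _ in range(trials):
        a, b = rng.normal(size=n), rng.normal(size=n)
        r, _p = sps.pearsonr(a, b)
        hits += abs(r) > 0.25
    # null P(|r|>t) via the t transform
    t = 0.25 * math.sqrt((n - 2) / (1 - 0.25**2))
    p_null = 2 * sps.t.sf(t, df=n - 2)
    se = math.sqrt(p_null * (1 - p_null) / trials)
    assert hits / trials == pytest.approx(p_null, abs=max(3 * se, 0.02))


def test_generated_timing_correlation_near_printed_value():
    # the generator's default correlation structure links time-to-LVC with
    # the hyoid-burst-to-UES-opening interval at r ~ 0.5
    cfg, eff = CohortConfig(n=500), EffectConfig()
    cohort = generate_cohort(cfg, 7)
    truth = generate_parameters(cohort, eff, cfg, 7)
    r = truth["time_to_lvc"].corr(truth["hyb_to_ueso"])
    assert 0.35 < r < 0.62


# --- hierarchical linear regression ---------------------------------------

def _toy_participants(rng, n=60):
    age = rng.uniform(21, 82, n)
    male = rng.integers(0, 2, n)
    sip = rng.normal(14, 4, n)
    return pd.DataFrame({"age": age, "male": male, "sip_volume": sip})


def test_deterministic_outcome_recovers_exactly(rng):
    df = _toy_participants(rng)
    df["y"] = 2.0 * df["age"]
    res = hierarchical_linear("y", df)
    assert res.stages[0].coef["age"] == pytest.approx(2.0)
    assert res.stages[0].r2 == pytest.approx(1.0)


def test_r2_monotone_and_delta_r2_nonnegative(rng):
    df = _toy_participants(rng)
    df["y"] = 3 * df["age"] - 5 * df["male"] + rng.normal(0, 40, len(df))
    res = hierarchical_linear("y", df)
    r2s = [s.r2 for s in res.stages]
    assert len(r2s) == 3
    assert all(b >= a for a, b in zip(r2s, r2s[1:]))
    assert all(s.delta_r2 >= 0 for s in res.stages)


def test_ols_matches_least_squares_oracle(rng):
    df = _toy_participants(rng)
    df["y"] = 1.5 * df["age"] + 4 * df["male"] - 2 * df["sip_volume"] + rng.normal(
        0, 10, len(df)
    )
    res = hierarchical_linear("y", df)
    X = np.column_stack(
        [np.ones(len(df)), df["age"], df["male"], df["sip_volume"]]
    )
    beta, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
    stage3 = res.stages[2]
    for name, b in zip(["const", "age", "male", "sip_volume"], beta):
        assert stage3.coef[name] == pytest.approx(b, rel=1e-6, abs=1e-9)


def test_singular_design_detected(rng):
    df = _toy_participants(rng)
    df["sip_volume"] = df["age"] * 2.0  # collinear with age
    df["y"] = rng.normal(size=len(df))
    with pytest.raises(SingularDesignError):
        hierarchical_linear("y", df)


def test_rest_measure_skips_sip_stage(rng):
    df = _toy_participants(rng)
    df["pa_rest"] = 0.3 * df["age"] + rng.normal(0, 15, len(df))
    res = hierarchical_linear("pa_rest", df)
    assert len(res.stages) == 2
    assert res.stages[-1].predictors == ["age", "male"]


def test_too_few_participants_rejected(rng):
    df = _toy_participants(rng, n=6)
    df["y"] = rng.normal(size=6)
    with pytest.raises(UndefinedStatisticError):
        hierarchical_linear("y", df)


# --- logistic regression --------------------------------------------------

def _newton_logistic(X, y, iters=60):
    """Independent Newton-Raphson maximum-likelihood oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        H = X.T @ (X * W[:, None])
        g = X.T @ (y - p)
        beta = beta + np.linalg.solve(H, g)
    return beta


def test_logistic_matches_newton_oracle(rng):
    n = 400
    age = rng.uniform(21, 82, n)
    male = rng.integers(0, 2, n)
    sip = rng.normal(14, 4, n)
    eta = -1.4 + 0.09 * (sip - 14) + 0.01 * (age - 50)
    y = rng.uniform(size=n) < 1 / (1 + np.exp(-eta))
    df = pd.DataFrame(
        {"age": age, "male": male, "sip_volume": sip, "multiple_swallows": y}
    )
    fit = binary_logistic(df)
    X = np.column_stack([np.ones(n), age, male, sip])
    ref = _newton_logistic(X, y.astype(float))
    np.testing.assert_allclose(fit["coef"].to_numpy(), ref, rtol=1e-6, atol=1e-8)


def test_logistic_single_class_rejected(rng):
    df = pd.DataFrame(
        {
            "age": rng.uniform(21, 82, 30),
            "male": rng.integers(0, 2, 30),
            "sip_volume": rng.normal(14, 4, 30),
            "multiple_swallows": np.zeros(30, dtype=bool),
        }
    )
    with pytest.raises(InputValidationError):
        binary_logistic(df)


def test_logistic_null_coefficients_near_zero(rng):
    n = 3000
    df = pd.DataFrame(
        {
            "age": rng.uniform(21, 82, n),
            "male": rng.integers(0, 2, n),
            "sip_volume": rng.normal(14, 4, n),
            "multiple_swallows": rng.uniform(size=n) < 0.2,
        }
    )
    fit = binary_logistic(df).set_index("term")
    for term in ("age", "male", "sip_volume"):
        assert abs(fit.loc[term, "coef"]) < 3 * fit.loc[term, "se"] + 1e-9


# --- 2x2 odds ratios ------------------------------------------------------

def test_or_balanced_table_is_one():
    res = two_by_two_or(10, 10, 10, 10)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.ci_low < 1 < res.ci_high


def test_or_woolf_ci_hand_computed():
    res = two_by_two_or(20, 10, 10, 20)
    assert res.odds_ratio == pytest.approx(4.0)
    se = math.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20)
    assert res.ci_low == pytest.approx(math.exp(math.log(4) - 1.96 * se), rel=1e-3)
    assert res.ci_high == pytest.approx(math.exp(math.log(4) + 1.96 * se), rel=1e-3)


def test_or_row_swap_inverts():
    a = two_by_two_or(17, 6, 9, 22)
    b = two_by_two_or(9, 22, 17, 6)
    assert b.odds_ratio == pytest.approx(1.0 / a.odds_ratio)


def test_or_zero_cell_correction_and_margins():
    res = two_by_two_or(5, 0, 3, 10)
    assert res.continuity_corrected
    assert math.isfinite(res.odds_ratio)
    with pytest.raises(UndefinedStatisticError):
        two_by_two_or(0, 0, 5, 5)


# --- sip dichotomization --------------------------------------------------

def test_dichotomize_sip_hand_tally():
    df = pd.DataFrame(
        {
            "sip_volume": [10, 20, 17, 16, 5, 30, 18, 12],
            "multiple_swallows": [False, True, False, True, False, True, True, False],
        }
    )
    # sip > 16: rows 20, 17, 30, 18 -> multiple T,F,T,T
    assert dichotomize_sip(df, cut=16) == (3, 1, 1, 3)


def test_generator_defaults_favor_multiple_swallows_for_large_sips():
    cfg, eff = CohortConfig(n=400), EffectConfig()
    cohort = generate_cohort(cfg, 21)
    truth = generate_parameters(cohort, eff, cfg, 21)
    a, b, c, d = dichotomize_sip(truth)
    assert two_by_two_or(a, b, c, d).odds_ratio > 1.0


# --- participant means ----------------------------------------------------

def test_participant_means_shapes(small_study):
    means = participant_means(small_study.truth)
    assert len(means) == small_study.participants.shape[0]
    one = small_study.truth[small_study.truth.participant_id == means.participant_id[0]]
    assert means.loc[0, "ueso_duration"] == pytest.approx(one["ueso_duration"].mean())
    assert means.loc[0, "any_multiple_swallows"] == one["multiple_swallows"].any()
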