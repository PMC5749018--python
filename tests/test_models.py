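import math

import numpy as np
import pandas as pd
import pytest

from fishpanel.errors import RankDeficiencyError, ValidationError
from fishpanel.models import (
    Z_95,
    clinical_only_model,
    fish_clinical_model,
    fish_only_model,
    fit_logistic,
    fit_logistic_2x2,
    fit_logistic_2x2_batch,
    haldane_odds_ratio,
    stratified_analysis,
)


def test_2x2_closed_form_example():
    """a=19 case+, b=10 case-, c=6 control+, d=19 control-: OR = ad/bc."""
    fit = fit_logistic_2x2(19, 10, 6, 19)
    t = fit.term("FISH")
    assert fit.converged
    assert t.odds_ratio == pytest.approx((19 * 19) / (10 * 6), abs=1e-4)
    assert t.odds_ratio == pytest.approx(6.0167, abs=1e-4)
    se_expected = math.sqrt(1 / 19 + 1 / 10 + 1 / 6 + 1 / 19)
    assert t.standard_error == pytest.approx(se_expected, abs=1e-6)
    assert t.ci_low == pytest.approx(math.exp(t.coefficient - Z_95 * t.standard_error))
    assert t.ci_high == pytest.approx(math.exp(t.coefficient + Z_95 * t.standard_error))
    assert t.ci_low < t.odds_ratio < t.ci_high


def test_2x2_sweep_small():
    rng = np.random.default_rng(0)
    for _ in range(25):
        a, b, c, d = rng.integers(1, 31, size=4)
        fit = fit_logistic_2x2(a, b, c, d)
        t = fit.term("FISH")
        assert t.odds_ratio == pytest.approx(a * d / (b * c), rel=1e-6)
        assert t.standard_error == pytest.approx(
            math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), abs=1e-6
        )


def test_batch_agrees_with_per_table_fit():
    rng = np.random.default_rng(1)
    tables = rng.integers(1, 31, size=(50, 4))
    batch = fit_logistic_2x2_batch(*tables.T)
    for i, (a, b, c, d) in enumerate(tables):
        t = fit_logistic_2x2(a, b, c, d).term("FISH")
        assert batch["coef"][i] == pytest.approx(t.coefficient, abs=1e-8)
        assert batch["se"][i] == pytest.approx(t.standard_error, abs=1e-8)


def test_matches_statsmodels_on_continuous_design():
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    n = 120
    X = rng.normal(size=(n, 2))
    logit = -0.3 + 0.8 * X[:, 0] - 0.5 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    fit = fit_logistic(X, y, term_names=["x1", "x2"])
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    coefs = [t.coefficient for t in fit.terms]
    ses = [t.standard_error for t in fit.terms]
    assert coefs == pytest.approx(list(ref.params), abs=1e-6)
    assert ses == pytest.approx(list(ref.bse), abs=1e-6)
    assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)


def test_rank_deficiency_names_collinear_terms():
    X = np.column_stack([np.ones(10), np.ones(10)])
    y = np.array([1, 0] * 5)
    with pytest.raises(RankDeficiencyError) as exc:
        fit_logistic(X, y, term_names=["a", "b"])
    assert exc.value.collinear_terms  # at least one named


def test_separation_is_flagged_not_silently_fit():
    x = np.array([1.0] * 5 + [0.0] * 5)
    y = np.array([1] * 5 + [0] * 5)
    fit = fit_logistic(x[:, None], y, term_names=["x"])
    assert not fit.converged
    assert any("separation" in d for d in fit.diagnostics)


def test_final_log_likelihood_improves_on_null():
    rng = np.random.default_rng(3)
    x = rng.normal(size=40)
    y = (rng.random(40) < 1 / (1 + np.exp(-x))).astype(int)
    fit = fit_logistic(x[:, None], y, term_names=["x"])
    p0 = y.mean()
    ll_null = y.sum() * math.log(p0) + (len(y) - y.sum()) * math.log(1 - p0)
    assert fit.log_likelihood >= ll_null - 1e-9


def test_fit_invariant_to_row_order_and_label_swap():
    rng = np.random.default_rng(4)
    x = rng.normal(size=60)
    y = (rng.random(60) < 1 / (1 + np.exp(-x))).astype(int)
    fit = fit_logistic(x[:, None], y, term_names=["x"])
    perm = rng.permutation(60)
    fit_perm = fit_logistic(x[perm][:, None], y[perm], term_names=["x"])
    assert fit_perm.term("x").coefficient == pytest.approx(fit.term("x").coefficient, abs=1e-8)
    fit_swap = fit_logistic(x[:, None], 1 - y, term_names=["x"])
    assert fit_swap.term("x").coefficient == pytest.approx(-fit.term("x").coefficient, abs=1e-7)


# ---------------------------------------------------------------- model wrappers

def _calls_outcome(a, b, c, d):
    calls = ["positive"] * a + ["negative"] * b + ["positive"] * c + ["negative"] * d
    outcome = ["case"] * (a + b) + ["control"] * (c + d)
    return np.array(calls), np.array(outcome)


def test_fish_only_model_equals_2x2():
    calls, outcome = _calls_outcome(19, 10, 6, 19)
    fit = fish_only_model(calls, outcome)
    assert fit.n_cases == 29 and fit.n_controls == 25
    assert fit.term("FISH").odds_ratio == pytest.approx(6.0167, abs=1e-4)


def test_fish_only_constant_calls_is_rank_deficient():
    calls, outcome = _calls_outcome(29, 0, 25, 0)
    with pytest.raises(RankDeficiencyError):
        fish_only_model(calls, outcome)


def test_empty_cell_reports_haldane_auxiliary():
    calls, outcome = _calls_outcome(10, 0, 5, 12)
    fit = fish_only_model(calls, outcome)
    assert not fit.converged
    assert fit.haldane_or == pytest.approx(haldane_odds_ratio(10, 0, 5, 12))


def test_fish_clinical_constant_risk_reduces_to_fish_only():
    calls, outcome = _calls_outcome(19, 10, 6, 19)
    risk = np.array(["Intermediate"] * len(calls))
    both = fish_clinical_model(calls, risk, outcome)
    only = fish_only_model(calls, outcome)
    assert both.term("FISH").coefficient == pytest.approx(
        only.term("FISH").coefficient, abs=1e-8
    )
    assert any("constant" in d for d in both.diagnostics)


def test_orthogonal_risk_leaves_fish_or_unchanged_in_expectation():
    """When calls and risk group are independent, adjustment barely moves the
    FISH OR (averaged over seeds)."""
    rng = np.random.default_rng(5)
    diffs = []
    for _ in range(30):
        n = 160
        x = rng.random(n) < 0.4
        logit = -0.5 + 1.2 * x
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        risk = rng.choice(["Low", "Intermediate", "High"], n)
        calls = np.where(x, "positive", "negative")
        outcome = np.where(y, "case", "control")
        unadj = fish_only_model(calls, outcome).term("FISH").coefficient
        adj = fish_clinical_model(calls, risk, outcome).term("FISH").coefficient
        diffs.append(adj - unadj)
    assert abs(np.mean(diffs)) < 0.05


def test_confounded_risk_shifts_fish_or_in_planted_direction():
    """Positive calls concentrated in high-risk patients inflate the crude
    FISH OR; adjusting for risk deflates it toward the planted value."""
    rng = np.random.default_rng(6)
    crude_minus_adj = []
    for _ in range(30):
        n = 200
        risk_score = rng.integers(1, 5, n)  # 1..4 ordinal
        x = rng.random(n) < (0.1 + 0.15 * risk_score)  # call tracks risk
        logit = -2.0 + 0.7 * x + 0.6 * risk_score  # risk has its own effect
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        risk = np.array(["VeryLow", "Low", "Intermediate", "High"])[risk_score - 1]
        calls = np.where(x, "positive", "negative")
        outcome = np.where(y, "case", "control")
        crude = fish_only_model(calls, outcome).term("FISH").coefficient
        adj = fish_clinical_model(calls, risk, outcome).term("FISH").coefficient
        crude_minus_adj.append(crude - adj)
    assert np.mean(crude_minus_adj) > 0.1


def test_clinical_only_recovers_planted_risk_effect_and_null_age():
    rng = np.random.default_rng(7)
    risk_coefs, age_coefs = [], []
    for _ in range(30):
        n = 200
        risk_score = rng.integers(1, 5, n)
        age = rng.normal(64, 6, n)
        logit = -2.2 + 0.8 * risk_score  # age truly null
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        risk = np.array(["VeryLow", "Low", "Intermediate", "High"])[risk_score - 1]
        fit = clinical_only_model(risk, age, np.where(y, "case", "control"))
        risk_coefs.append(fit.term("NCCN").coefficient)
        age_coefs.append(fit.term("age").coefficient)
    assert np.mean(risk_coefs) == pytest.approx(0.8, abs=0.15)
    assert abs(np.mean(age_coefs)) < 0.01


def test_stratified_skips_stratum_without_controls():
    clinical = pd.DataFrame(
        {
            "specimen_id": [f"S{i}" for i in range(8)],
            "outcome": ["case", "case", "case", "control", "case", "control", "case", "control"],
            "risk_group": ["High", "High", "Low", "Low", "Intermediate", "Intermediate",
                           "VeryLow", "VeryLow"],
        }
    )
    calls = np.array(["positive", "negative"] * 4)
    out = stratified_analysis(calls, clinical)
    assert out["higher"].fit is None and "missing outcome class" in out["higher"].skipped_reason
    assert out["lower"].n_cases == 2 and out["lower"].n_controls == 2


def test_stratified_lower_stratum_merges_verylow_and_low():
    rng = np.random.default_rng(8)
    n = 120
    risk = rng.choice(["VeryLow", "Low", "Intermediate", "High"], n)
    calls = rng.choice(["positive", "negative"], n)
    outcome = rng.choice(["case", "control"], n)
    clinical = pd.DataFrame(
        {"specimen_id": [f"S{i}" for i in range(n)], "outcome": outcome, "risk_group": risk}
    )
    out = stratified_analysis(calls, clinical)
    mask = np.isin(risk, ["VeryLow", "Low"])
    direct = fish_only_model(calls[mask], outcome[mask])
    assert out["lower"].fit is not None
    assert out["lower"].fit.term("FISH").odds_ratio == pytest.approx(
        direct.term("FISH").odds_ratio, abs=1e-9
    )
    assert out["lower"].n_cases == int((outcome[mask] == "case").sum())
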