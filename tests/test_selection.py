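import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishpanel.errors import ValidationError
from fishpanel.probes import CANDIDATE_PARAMETERS
from fishpanel.selection import (
    auc_single,
    build_grid,
    combination_auc,
    dfi,
    enumerate_and_rank,
    evaluate_combination,
    optimize_cutoffs,
    panel_call,
)


# ---------------------------------------------------------------- oracles

def auc_bruteforce(values, labels):
    """Case-control pair counting with ties counted one half."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    cases = values[labels == 1]
    controls = values[labels == 0]
    wins = sum((c > k) + 0.5 * (c == k) for c in cases for k in controls)
    return wins / (len(cases) * len(controls))


def optimize_bruteforce(parameters, matrix, labels, grid):
    """Naive Cartesian enumeration with the documented tie-break: lowest DFI,
    then highest specificity, then lexicographically largest cut-off vector."""
    is_case = np.asarray(labels) == "case" if np.asarray(labels).dtype.kind not in "biu" else np.asarray(labels).astype(bool)
    best = None
    for vector in itertools.product(*(grid[p] for p in parameters)):
        cutoffs = dict(zip(parameters, vector))
        calls = np.array(
            [panel_call(row, cutoffs) == "positive" for _, row in matrix.iterrows()]
        )
        sens = calls[is_case].mean()
        spec = (~calls[~is_case]).mean()
        key = (dfi(sens, spec), -spec, tuple(-v for v in vector))
        if best is None or key < best[0]:
            best = (key, cutoffs, sens, spec)
    return best[1], best[2], best[3], best[0][0]


# ---------------------------------------------------------------- auc_single

def test_auc_perfect_separation_and_ties():
    assert auc_single([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0
    assert auc_single([3, 3, 3, 3], [1, 1, 0, 0]) == 0.5
    # brute-force pair counting: cases [5,3] vs controls [1,2,4] -> 5/6
    assert auc_single([5, 3, 1, 2, 4], [1, 1, 0, 0, 0]) == pytest.approx(5 / 6)


def test_auc_requires_both_classes():
    with pytest.raises(ValidationError):
        auc_single([1, 2], [1, 1])


def test_auc_matches_bruteforce_with_ties():
    rng = np.random.default_rng(0)
    for _ in range(30):
        n = int(rng.integers(4, 40))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        values = rng.integers(0, 6, n).astype(float)  # heavy ties
        assert auc_single(values, labels) == pytest.approx(
            auc_bruteforce(values, labels), abs=1e-12
        )


@given(st.data())
@settings(deadline=None, max_examples=50, derandomize=True)
def test_auc_invariant_under_monotone_transform(data):
    n = data.draw(st.integers(5, 25))
    values = np.array(data.draw(st.lists(st.integers(0, 30), min_size=n, max_size=n)), float)
    labels = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)), int)
    if labels.sum() in (0, n):
        labels[0], labels[-1] = 1, 0
    transformed = np.exp(values / 10.0) + 3.0
    assert auc_single(values, labels) == pytest.approx(
        auc_single(transformed, labels), abs=1e-12
    )


# ---------------------------------------------------------------- panel_call / dfi

def test_panel_call_any_positive_rule():
    assert panel_call({"MYC Gain": 5, "PTEN Homozygous": 0}, {"MYC Gain": 4, "PTEN Homozygous": 10}) == "positive"
    # boundary: equality counts as positive (inclusive >=)
    assert panel_call({"MYC Gain": 4}, {"MYC Gain": 4}) == "positive"
    assert panel_call({"MYC Gain": 3, "PTEN Homozygous": 9}, {"MYC Gain": 4, "PTEN Homozygous": 10}) == "negative"
    with pytest.raises(ValidationError, match="PTEN"):
        panel_call({"MYC Gain": 3}, {"MYC Gain": 4, "PTEN Homozygous": 10})


def test_dfi_closed_form():
    assert dfi(1, 1) == 0.0
    assert dfi(0, 0) == pytest.approx(math.sqrt(2), abs=1e-12)
    assert dfi(0.73, 0.70) == pytest.approx(0.40361, abs=1e-5)
    with pytest.raises(ValidationError):
        dfi(1.2, 0.5)


@given(st.floats(0, 1), st.floats(0, 1))
@settings(deadline=None, derandomize=True)
def test_dfi_symmetry_and_range(s, p):
    assert dfi(s, p) == pytest.approx(dfi(p, s), abs=1e-12)
    assert 0.0 <= dfi(s, p) <= math.sqrt(2) + 1e-12


# ---------------------------------------------------------------- optimize_cutoffs

def _random_instance(rng, n_params=3, n_spec=16, grid_size=3):
    params = [f"P{j}" for j in range(n_params)]
    matrix = pd.DataFrame(
        rng.integers(0, 25, size=(n_spec, n_params)).astype(float),
        columns=params,
        index=[f"S{i}" for i in range(n_spec)],
    )
    labels = np.array(["case"] * (n_spec // 2) + ["control"] * (n_spec - n_spec // 2))
    rng.shuffle(labels)
    grid = {
        p: sorted(rng.choice(np.arange(1, 25), size=grid_size, replace=False).astype(float))
        for p in params
    }
    return params, matrix, labels, grid


def test_perfect_separation_tie_break_prefers_largest_cutoff():
    matrix = pd.DataFrame(
        {"P": [20.0] * 4 + [0.0] * 4}, index=[f"S{i}" for i in range(8)]
    )
    labels = ["case"] * 4 + ["control"] * 4
    grid = {"P": [float(c) for c in range(2, 16)]}
    res = optimize_cutoffs(["P"], matrix, labels, grid)
    assert res.dfi == 0.0 and res.sensitivity == 1.0 and res.specificity == 1.0
    assert res.cutoffs["P"] == 15.0


def test_optimize_matches_bruteforce_triple_loop():
    rng = np.random.default_rng(12)
    for _ in range(10):
        params, matrix, labels, grid = _random_instance(rng)
        res = optimize_cutoffs(params, matrix, labels, grid)
        cutoffs, sens, spec, best_dfi = optimize_bruteforce(params, matrix, labels, grid)
        assert res.dfi == pytest.approx(best_dfi, abs=1e-12)
        assert res.cutoffs == cutoffs
        assert res.sensitivity == pytest.approx(sens) and res.specificity == pytest.approx(spec)


def test_singleton_grid_degenerate_search():
    rng = np.random.default_rng(5)
    params, matrix, labels, _ = _random_instance(rng, n_params=2)
    grid = {"P0": [10.0], "P1": [5.0]}
    res = optimize_cutoffs(params, matrix, labels, grid)
    cutoffs, sens, spec, best_dfi = optimize_bruteforce(params, matrix, labels, grid)
    assert res.cutoffs == cutoffs and res.dfi == pytest.approx(best_dfi)


def test_empty_grid_rejected():
    matrix = pd.DataFrame({"P": [1.0, 2.0]}, index=["a", "b"])
    with pytest.raises(ValidationError):
        optimize_cutoffs(["P"], matrix, ["case", "control"], {"P": []})


def test_calls_consistent_with_any_positive_rule():
    rng = np.random.default_rng(3)
    params, matrix, labels, grid = _random_instance(rng)
    res = optimize_cutoffs(params, matrix, labels, grid)
    for sid, row in matrix.iterrows():
        assert res.calls[sid] == panel_call(row, res.cutoffs)


# ---------------------------------------------------------------- monotonicity

def _sens_spec(matrix, labels, cutoffs):
    is_case = np.asarray(labels) == "case"
    calls = np.array([panel_call(r, cutoffs) == "positive" for _, r in matrix.iterrows()])
    return calls[is_case].mean(), (~calls[~is_case]).mean()


def test_raising_cutoff_monotonicity():
    """Raising any single cut-off never increases sensitivity nor decreases
    specificity under the any-positive rule."""
    rng = np.random.default_rng(21)
    for _ in range(20):
        params, matrix, labels, grid = _random_instance(rng, n_params=3)
        cutoffs = {p: float(rng.choice(grid[p])) for p in params}
        sens0, spec0 = _sens_spec(matrix, labels, cutoffs)
        for p in params:
            raised = dict(cutoffs)
            raised[p] = cutoffs[p] + float(rng.integers(1, 10))
            sens1, spec1 = _sens_spec(matrix, labels, raised)
            assert sens1 <= sens0 + 1e-12
            assert spec1 >= spec0 - 1e-12


def test_adding_parameter_monotonicity():
    """Adding a parameter never decreases sensitivity, never increases specificity."""
    rng = np.random.default_rng(22)
    for _ in range(20):
        params, matrix, labels, grid = _random_instance(rng, n_params=3)
        cutoffs = {p: float(rng.choice(grid[p])) for p in params}
        base = {p: cutoffs[p] for p in params[:2]}
        sens0, spec0 = _sens_spec(matrix, labels, base)
        sens1, spec1 = _sens_spec(matrix, labels, cutoffs)
        assert sens1 >= sens0 - 1e-12
        assert spec1 <= spec0 + 1e-12


# ---------------------------------------------------------------- combination AUC

def test_combination_auc_single_parameter_reduces_to_auc_single():
    rng = np.random.default_rng(9)
    labels = np.array([1] * 15 + [0] * 15)
    # a case-enriched marker (the orientation the candidate list assumes)
    values = rng.uniform(0, 20, 30) + 6.0 * labels
    matrix = pd.DataFrame({"P": values}, index=[f"S{i}" for i in range(30)])
    auc, fallback = combination_auc(["P"], matrix, labels)
    assert auc == pytest.approx(auc_single(matrix["P"], labels), abs=1e-9)


def test_combination_auc_duplicate_parameter_is_ignored():
    rng = np.random.default_rng(10)
    matrix = pd.DataFrame(
        {"P": rng.uniform(0, 20, 30), "Q": rng.uniform(0, 20, 30)},
        index=[f"S{i}" for i in range(30)],
    )
    labels = np.array([1] * 15 + [0] * 15)
    a1, _ = combination_auc(["P", "Q"], matrix, labels)
    a2, _ = combination_auc(["P", "Q", "P"], matrix, labels)
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_combination_auc_matches_mann_whitney_on_fitted_scores():
    from fishpanel.models import fit_logistic

    rng = np.random.default_rng(11)
    matrix = pd.DataFrame(
        {"P": rng.uniform(0, 20, 10), "Q": rng.uniform(0, 20, 10)},
        index=[f"S{i}" for i in range(10)],
    )
    labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
    auc, fallback = combination_auc(["P", "Q"], matrix, labels)
    assert not fallback
    fit = fit_logistic(matrix[["P", "Q"]].to_numpy(), labels, term_names=["P", "Q"])
    assert auc == pytest.approx(auc_bruteforce(fit.fitted, labels), abs=1e-12)


# ---------------------------------------------------------------- enumeration

def test_enumerate_and_rank_combination_counts(small_matrix, panel):
    matrix, labels, _ = small_matrix
    grid = build_grid(CANDIDATE_PARAMETERS, panel)
    ranked = enumerate_and_rank(CANDIDATE_PARAMETERS, matrix, labels, grid, 3, 6)
    assert len(ranked) == 35 + 35 + 21 + 7
    aucs = [r.auc for r in ranked]
    assert aucs == sorted(aucs, reverse=True)


def test_enumerate_three_of_three_is_single_combination(small_matrix, panel):
    matrix, labels, _ = small_matrix
    cands = ["MYC Gain", "PTEN Homozygous", "NMYC Gain"]
    grid = build_grid(cands, panel)
    ranked = enumerate_and_rank(cands, matrix, labels, grid, 3, 3)
    assert len(ranked) == 1
    assert set(ranked[0].parameters) == set(cands)


def test_grid_ranges_follow_probe_classes(panel):
    grid = build_grid(CANDIDATE_PARAMETERS, panel)
    assert grid["MYC Gain"] == [float(c) for c in range(2, 16)]
    assert grid["PTEN Loss"] == [float(c) for c in range(10, 21)]
    assert grid["ERG 2Edel"] == [float(c) for c in range(4, 11)]
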