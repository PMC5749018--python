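"""Combination search: ROC/AUC ranking and DFI-optimal cut-off selection.

The discovery algorithm at the centre of the pipeline. Candidate FISH
parameters (percent abnormal cells per specimen) are grouped into all
subsets of 3-6 parameters. For each subset, every vector in the Cartesian
product of per-parameter candidate cut-offs is evaluated under the
**any-positive rule** — a specimen is panel-positive iff any parameter in
the subset is greater than or equal to its cut-off — and the vector with
the lowest distance from ideal

    DFI = sqrt((1 - sensitivity)^2 + (1 - specificity)^2)

is kept. Subsets are then ranked by AUC (descending), ties by DFI.

Candidate cut-off ranges (percent of cells) by probe class:
amplification 2-15, deletion 10-20, break-apart 4-10, at integer steps
(with 100 enumerated cells per specimen, percent values are integers, so
step 1 exhausts the range).

The exhaustive search is evaluated by dominance counting: each specimen is
negative at a cut-off vector iff every parameter's cut-off exceeds its
value, so the per-vector negative count over the full grid is a suffix
cumulative sum of corner indicators — linear in grid size rather than
quadratic in specimens x vectors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .models import fit_logistic
from .probes import ProbePanel

#: integer cut-off search ranges (percent of abnormal cells) per probe class
CUTOFF_RANGES = {
    "amplification": (2, 15),
    "deletion": (10, 20),
    "break_apart": (4, 10),
}


def build_grid(
    parameters: Sequence[str], panel: ProbePanel, step: int = 1
) -> dict[str, list[float]]:
    """Candidate cut-off list per parameter, derived from its probe's class."""
    if step < 1:
        raise ValidationError("grid step must be >= 1")
    grid: dict[str, list[float]] = {}
    for param in parameters:
        probe = panel.probe_for_parameter(param)
        if probe.cutoff_class not in CUTOFF_RANGES:
            raise ValidationError(
                f"parameter {param!r}: probe {probe.probe_id} has no cut-off range "
                f"(class {probe.cutoff_class!r})"
            )
        lo, hi = CUTOFF_RANGES[probe.cutoff_class]
        grid[param] = [float(c) for c in range(lo, hi + 1, step)]
    return grid


def auc_single(values, labels) -> float:
    """Mann-Whitney AUC of one score against case/control labels.

    Equals the probability that a random case outscores a random control,
    with ties counted one half; identical to the trapezoidal area under the
    empirical ROC curve.
    """
    values = np.asarray(values, dtype=float)
    is_case = _case_mask(labels)
    n1, n0 = int(is_case.sum()), int((~is_case).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("need at least one case and one control")
    ranks = rankdata(values)
    u = ranks[is_case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _case_mask(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "biu":
        return arr.astype(bool)
    return arr == "case"


def panel_call(row: Mapping[str, float], cutoffs: Mapping[str, float]) -> str:
    """Apply the any-positive rule to one specimen.

    Positive iff any parameter value is greater than or equal to its
    cut-off (inclusive); negative iff all values fall below their cut-offs.
    """
    for param, cut in cutoffs.items():
        if param not in row or (isinstance(row[param], float) and math.isnan(row[param])):
            raise ValidationError(f"missing value for parameter {param!r}")
        if row[param] >= cut:
            return "positive"
    return "negative"


def dfi(sensitivity: float, specificity: float) -> float:
    """Euclidean distance from the ideal ROC corner (sens = spec = 1).

    Ranges from 0 (perfect classification) to sqrt(2) (both zero).
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValidationError(
            f"sensitivity/specificity must be in [0,1], got ({sensitivity}, {specificity})"
        )
    return math.hypot(1.0 - sensitivity, 1.0 - specificity)


@dataclass
class CombinationResult:
    """One parameter combination with its optimised operating point."""

    parameters: tuple[str, ...]
    cutoffs: dict[str, float]
    sensitivity: float
    specificity: float
    dfi: float
    auc: float = math.nan
    auc_method: str = ""
    auc_fallback: bool = False
    calls: dict[str, str] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return " & ".join(self.parameters)


def _dedupe(parameters: Sequence[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for p in parameters:
        seen.setdefault(p)
    return tuple(seen)


def optimize_cutoffs(
    parameters: Sequence[str],
    matrix: pd.DataFrame,
    labels,
    grid: Mapping[str, Sequence[float]],
) -> CombinationResult:
    """Exhaustive DFI minimisation over the Cartesian cut-off grid.

    Every cut-off vector in the product of the per-parameter candidate
    lists is evaluated under the any-positive rule. Ties on DFI are broken
    deterministically: prefer higher specificity (fewest false positives),
    then the lexicographically largest cut-off vector (which is the
    element-wise largest whenever one exists) — the most conservative
    operating point among equals.
    """
    parameters = _dedupe(parameters)
    for param in parameters:
        if param not in grid or len(grid[param]) == 0:
            raise ValidationError(f"empty cut-off grid for parameter {param!r}")
        g = list(grid[param])
        if any(b <= a for a, b in zip(g, g[1:])):
            raise ValidationError(f"cut-off grid for {param!r} must be strictly increasing")
    is_case = _case_mask(labels)
    n1, n0 = int(is_case.sum()), int((~is_case).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("need at least one case and one control")

    grids = [np.asarray(grid[p], dtype=float) for p in parameters]
    shape = tuple(len(g) for g in grids)
    values = matrix.loc[:, list(parameters)].to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = matrix.index[np.isnan(values).any(axis=1)][0]
        raise ValidationError(f"missing parameter value for specimen {bad}")

    # Specimen negative at index tuple c iff c_p >= start_p for all p, where
    # start_p is the first grid index whose cut-off exceeds the value.
    starts = np.stack(
        [np.searchsorted(g, values[:, j], side="right") for j, g in enumerate(grids)],
        axis=1,
    )
    never_negative = (starts >= np.asarray(shape)).any(axis=1)

    neg_cases = np.zeros(shape, dtype=np.int32)
    neg_controls = np.zeros(shape, dtype=np.int32)
    for i in range(values.shape[0]):
        if never_negative[i]:
            continue
        corner = tuple(starts[i])
        if is_case[i]:
            neg_cases[corner] += 1
        else:
            neg_controls[corner] += 1
    for axis in range(len(shape)):  # prefix sums accumulate each [start, end] rectangle
        neg_cases = np.cumsum(neg_cases, axis=axis)
        neg_controls = np.cumsum(neg_controls, axis=axis)

    sens = 1.0 - neg_cases / n1
    spec = neg_controls / n0
    dfi_grid = np.hypot(1.0 - sens, 1.0 - spec)

    best = dfi_grid.min()
    flat_ties = np.flatnonzero(dfi_grid.ravel() == best)
    spec_flat = spec.ravel()[flat_ties]
    flat_ties = flat_ties[spec_flat == spec_flat.max()]
    chosen = int(flat_ties.max())  # C-order max flat index == lex-largest tuple
    idx = np.unravel_index(chosen, shape)
    cutoffs = {p: float(g[i]) for p, g, i in zip(parameters, grids, idx)}

    calls = {
        str(sid): panel_call(row, cutoffs)
        for sid, row in matrix.loc[:, list(parameters)].iterrows()
    }
    return CombinationResult(
        parameters=parameters,
        cutoffs=cutoffs,
        sensitivity=float(sens[idx]),
        specificity=float(spec[idx]),
        dfi=float(dfi_grid[idx]),
        calls=calls,
    )


def _rank_standardized_max(values: np.ndarray) -> np.ndarray:
    ranks = np.column_stack(
        [rankdata(values[:, j]) / values.shape[0] for j in range(values.shape[1])]
    )
    return ranks.max(axis=1)


def combination_auc(
    parameters: Sequence[str],
    matrix: pd.DataFrame,
    labels,
    method: str = "logistic",
    result: CombinationResult | None = None,
) -> tuple[float, bool]:
    """AUC of a parameter combination; returns ``(auc, used_fallback)``.

    ``method='logistic'`` scores specimens by fitted probabilities of an
    unpenalised logistic model on the continuous parameter values and takes
    the Mann-Whitney AUC of that score (a one-parameter combination thus
    reduces to the single-parameter AUC). If the fit fails to converge, the
    fallback score is the row-wise maximum of rank-standardised parameters.

    ``method='single-point'`` instead reports (sens + spec) / 2 at the
    optimised cut-offs — the area of the one-point ROC polygon — and
    requires ``result``.
    """
    parameters = _dedupe(parameters)
    is_case = _case_mask(labels)
    if method == "single-point":
        if result is None:
            raise ValidationError("single-point AUC needs an optimised CombinationResult")
        return (result.sensitivity + result.specificity) / 2.0, False
    if method != "logistic":
        raise ValidationError(f"unknown AUC method {method!r}")
    values = matrix.loc[:, list(parameters)].to_numpy(dtype=float)
    fallback = False
    try:
        fit = fit_logistic(values, is_case.astype(int), term_names=list(parameters))
        if fit.converged:
            scores = fit.fitted
        else:
            fallback = True
            scores = _rank_standardized_max(values)
    except Exception:
        fallback = True
        scores = _rank_standardized_max(values)
    return auc_single(scores, is_case.astype(int)), fallback


def evaluate_combination(
    parameters: Sequence[str],
    matrix: pd.DataFrame,
    labels,
    grid: Mapping[str, Sequence[float]],
    auc_method: str = "logistic",
) -> CombinationResult:
    """Optimise cut-offs and attach the combination AUC."""
    res = optimize_cutoffs(parameters, matrix, labels, grid)
    auc, fallback = combination_auc(parameters, matrix, labels, auc_method, result=res)
    res.auc = auc
    res.auc_method = auc_method
    res.auc_fallback = fallback
    return res


def enumerate_and_rank(
    candidates: Sequence[str],
    matrix: pd.DataFrame,
    labels,
    grid: Mapping[str, Sequence[float]],
    k_min: int = 3,
    k_max: int = 6,
    auc_method: str = "logistic",
) -> list[CombinationResult]:
    """Evaluate every subset of ``k_min..k_max`` candidates and rank them.

    Ranking: AUC descending, then DFI ascending, then parameter names
    lexicographically — so the leader per subset size gives the report its
    per-size table rows.
    """
    candidates = list(_dedupe(candidates))
    if len(candidates) < k_min:
        raise ValidationError(
            f"need at least k_min={k_min} candidates, got {len(candidates)}"
        )
    results: list[CombinationResult] = []
    for k in range(k_min, min(k_max, len(candidates)) + 1):
        for combo in itertools.combinations(candidates, k):
            results.append(evaluate_combination(combo, matrix, labels, grid, auc_method))
    results.sort(key=lambda r: (-r.auc, r.dfi, r.parameters))
    return results


def per_size_leaders(results: Sequence[CombinationResult]) -> list[CombinationResult]:
    """Best combination (by the ranking key) at each subset size."""
    leaders: dict[int, CombinationResult] = {}
    for res in results:  # results already ranked
        leaders.setdefault(len(res.parameters), res)
    return [leaders[k] for k in sorted(leaders)]


def combinations_to_frame(results: Sequence[CombinationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "combination": [r.label for r in results],
            "n_parameters": [len(r.parameters) for r in results],
            "cutoffs": [
                "; ".join(f"{p}>={c:g}" for p, c in r.cutoffs.items()) for r in results
            ],
            "sensitivity": [r.sensitivity for r in results],
            "specificity": [r.specificity for r in results],
            "dfi": [r.dfi for r in results],
            "auc": [r.auc for r in results],
            "auc_method": [r.auc_method for r in results],
            "auc_fallback": [int(r.auc_fallback) for r in results],
        }
    )


def calls_to_frame(results: Sequence[CombinationResult]) -> pd.DataFrame:
    rows = []
    for combo_id, res in enumerate(results):
        for sid, call in res.calls.items():
            rows.append(
                {"specimen_id": sid, "combination_id": combo_id, "combination": res.label, "call": call}
            )
    return pd.DataFrame(rows)
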