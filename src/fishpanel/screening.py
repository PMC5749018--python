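"""Correlation screen of FISH parameters against clinical variables.

A FISH marker that tracks a clinical variable (age, Gleason score, PSA,
tumour stage) carries no information beyond the clinic and would confound
a combined model, so its probe is dropped before combination search. Each
parameter is screened by Pearson correlation against each clinical
variable; if any parameter of a probe reaches p < alpha against any
clinical variable, the whole probe (all of its parameters) is excluded.
Stage is coded ordinally (T1c=1, T2a=2, T2b=3, T2c=4). No multiplicity
correction is applied; the screen is deliberately conservative in what it
keeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError, ValidationError
from .probes import ProbePanel

CLINICAL_VARIABLES = ("age", "gleason", "psa", "stage")
STAGE_ORDINAL = {"T1c": 1, "T2a": 2, "T2b": 3, "T2c": 4}


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValidationError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ScreenResult:
    """One (parameter, clinical variable) correlation test."""

    parameter_name: str
    clinical_variable: str
    r: float
    p_value: float
    evaluable: bool
    excluded: bool  # probe-level exclusion flag, filled after the sweep


def screen_parameters(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    panel: ProbePanel,
    alpha: float = 0.05,
) -> tuple[list[ScreenResult], set[str]]:
    """Screen every scored parameter against every clinical variable.

    Returns the per-pair results and the set of excluded ``probe_id``.
    Constant parameters are reported as not evaluable and never trigger
    exclusion. Specimens are matched on ``specimen_id``.
    """
    clin = clinical.set_index("specimen_id").loc[matrix.index]
    covars = {
        "age": clin["age"].astype(float).to_numpy(),
        "gleason": clin["gleason"].astype(float).to_numpy(),
        "psa": clin["psa"].astype(float).to_numpy(),
        "stage": clin["stage"].map(STAGE_ORDINAL).astype(float).to_numpy(),
    }
    param_cols = [c for c in matrix.columns if c != "n_cells_enumerated"]
    results: list[ScreenResult] = []
    flagged_probes: set[str] = set()
    for param in param_cols:
        values = matrix[param].to_numpy(dtype=float)
        for var in CLINICAL_VARIABLES:
            mask = ~(np.isnan(values) | np.isnan(covars[var]))
            if mask.sum() < 3:
                raise ValidationError(
                    f"fewer than 3 complete pairs for {param} vs {var}"
                )
            try:
                r, p = pearson(values[mask], covars[var][mask])
                evaluable = True
            except UndefinedCorrelationError:
                r, p, evaluable = math.nan, math.nan, False
            results.append(ScreenResult(param, var, r, p, evaluable, False))
            if evaluable and p < alpha:
                flagged_probes.add(panel.probe_for_parameter(param).probe_id)
    excluded_params = {
        name
        for pid in flagged_probes
        for name in panel[pid].parameter_names()
    }
    for res in results:
        res.excluded = res.parameter_name in excluded_params
    return results, flagged_probes


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter_name": [r.parameter_name for r in results],
            "clinical_variable": [r.clinical_variable for r in results],
            "r": [r.r for r in results],
            "p_value": [r.p_value for r in results],
            "evaluable": [int(r.evaluable) for r in results],
            "excluded": [int(r.excluded) for r in results],
        }
    )


def write_screen(results: list[ScreenResult], path: str | Path) -> None:
    screen_to_frame(results).to_csv(path, sep="\t", index=False)
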