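"""Logistic regression with Wald inference for panel-outcome association.

Models the probability of disease progression (case vs control) from the
dichotomised panel call and clinical risk stratification:

- **FISH-only**: outcome ~ intercept + panel call (positive = 1);
- **FISH + clinical**: outcome ~ intercept + panel call + NCCN risk group
  (entered as one ordinal score VeryLow=1 .. High=4 by default, matching a
  single reported odds ratio; dummy coding available);
- **clinical-only**: outcome ~ intercept + NCCN ordinal + age (years);
- **risk-stratified**: the FISH-only model fitted separately within the
  lower (VeryLow+Low), intermediate and higher (High) risk strata.

Fitting is maximum likelihood by iteratively reweighted least squares
(Newton scoring), tolerance 1e-8 on the coefficient update, at most 50
iterations. Standard errors come from the inverse observed information;
odds ratios are exp(coefficient) with 95% Wald confidence limits
exp(coef +/- 1.959964 * SE) and Wald chi-square p-values. Quasi-complete
separation is flagged, never silently patched; for 2x2 layouts with an
empty cell a Haldane-Anscombe (+0.5) corrected odds ratio is reported as a
clearly labelled auxiliary value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.special import expit
from scipy.stats import chi2

from .errors import RankDeficiencyError, ValidationError

Z_95 = 1.959964  # two-sided 95% normal quantile, Wald limits
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 50

RISK_ORDINAL = {"VeryLow": 1, "Low": 2, "Intermediate": 3, "High": 4}
STRATUM_GROUPS = {
    "lower": ("VeryLow", "Low"),
    "intermediate": ("Intermediate",),
    "higher": ("High",),
}


@dataclass
class Term:
    name: str
    coefficient: float
    standard_error: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LogisticFit:
    terms: list[Term]
    converged: bool
    n_cases: int
    n_controls: int
    log_likelihood: float
    diagnostics: list[str] = field(default_factory=list)
    fitted: np.ndarray | None = None
    haldane_or: float | None = None

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _outcome_to_binary(outcome) -> np.ndarray:
    arr = np.asarray(outcome)
    if arr.dtype.kind in "biuf":
        return arr.astype(float)
    return (arr == "case").astype(float)


def _calls_to_binary(calls) -> np.ndarray:
    arr = np.asarray(calls)
    if arr.dtype.kind in "biu":
        return arr.astype(float)
    return (arr == "positive").astype(float)


def fit_logistic(
    X,
    y,
    term_names: Sequence[str] | None = None,
    add_intercept: bool = True,
    freq_weights=None,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS with Wald inference.

    ``X`` is the predictor matrix (without intercept unless
    ``add_intercept=False``); ``y`` binary outcome (1 = case). Raises
    :class:`RankDeficiencyError` naming the collinear columns if the design
    is not full rank; quasi-complete separation yields ``converged=False``
    with a diagnostic rather than an exception.
    """
    if isinstance(X, pd.DataFrame):
        term_names = term_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and len(np.asarray(y)) != 1:
        X = X.T
    y = _outcome_to_binary(y)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y disagree on the number of observations")
    w = np.ones_like(y) if freq_weights is None else np.asarray(freq_weights, dtype=float)
    n_cases = int(round((w * y).sum()))
    n_controls = int(round((w * (1 - y)).sum()))
    if n_cases == 0 or n_controls == 0:
        raise ValidationError("need at least one case and one control")

    names = list(term_names) if term_names else [f"x{j + 1}" for j in range(X.shape[1])]
    if add_intercept:
        design = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names
    else:
        design = X

    _check_rank(design, names, w)

    beta = np.zeros(design.shape[1])
    converged = False
    diagnostics: list[str] = []
    for _ in range(IRLS_MAX_ITER):
        eta = design @ beta
        p = expit(eta)
        wt = w * p * (1.0 - p)
        wt = np.maximum(wt, 1e-10)
        info = design.T @ (design * wt[:, None])
        score = design.T @ (w * (y - p))
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            diagnostics.append("information matrix singular during IRLS")
            break
        np.clip(delta, -5.0, 5.0, out=delta)  # damp early overshoot
        beta = beta + delta
        if np.max(np.abs(delta)) < IRLS_TOL:
            converged = True
            break

    p = expit(design @ beta)
    p_clip = np.clip(p, 1e-12, 1 - 1e-12)
    ll = float((w * (y * np.log(p_clip) + (1 - y) * np.log(1 - p_clip))).sum())
    if not converged or np.max(np.abs(beta)) > 15.0:
        sep = _is_separated(p, y, w)
        if sep:
            converged = False
            diagnostics.append(
                "quasi-complete separation: coefficients diverging, "
                "Wald statistics unreliable"
            )

    wt = np.maximum(w * p * (1.0 - p), 1e-10)
    info = design.T @ (design * wt[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(design.shape[1], np.inf)

    terms = []
    for name, b, s in zip(names, beta, se):
        with np.errstate(over="ignore"):
            or_ = float(np.exp(b))
            ci_low = float(np.exp(b - Z_95 * s))
            ci_high = float(np.exp(b + Z_95 * s))
        pv = float(chi2.sf((b / s) ** 2, 1)) if s > 0 and np.isfinite(s) else float("nan")
        terms.append(Term(name, float(b), float(s), or_, ci_low, ci_high, pv))
    return LogisticFit(
        terms=terms,
        converged=converged,
        n_cases=n_cases,
        n_controls=n_controls,
        log_likelihood=ll,
        diagnostics=diagnostics,
        fitted=p,
    )


def _check_rank(design: np.ndarray, names: list[str], w: np.ndarray) -> None:
    active = design[w > 0]
    _, r, piv = qr(active, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(active.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < design.shape[1]:
        collinear = [names[j] for j in sorted(piv[rank:])]
        raise RankDeficiencyError(collinear)


def _is_separated(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> bool:
    mask = w > 0
    return bool(
        np.all(p[mask & (y == 1)] > 1 - 1e-6) and np.all(p[mask & (y == 0)] < 1e-6)
    ) or bool(np.any(p[mask & (y == 1)] > 1 - 1e-10) or np.any(p[mask & (y == 0)] < 1e-10))


def fit_logistic_2x2(a: float, b: float, c: float, d: float) -> LogisticFit:
    """Logistic fit of the 2x2 table (a=case+, b=case-, c=control+, d=control-).

    The saturated single-binary-predictor model: the marker odds ratio
    equals the cross-product ratio ad/(bc) and the Wald SE equals
    sqrt(1/a + 1/b + 1/c + 1/d).
    """
    X = np.array([[1.0], [0.0], [1.0], [0.0]])
    y = np.array([1.0, 1.0, 0.0, 0.0])
    w = np.array([a, b, c, d], dtype=float)
    return fit_logistic(X, y, term_names=["FISH"], freq_weights=w)


def fit_logistic_2x2_batch(a, b, c, d, n_iter: int = 40):
    """Vectorised IRLS over many 2x2 tables at once.

    Same Newton update as :func:`fit_logistic`, specialised to the
    two-parameter 2x2 design and broadcast over table arrays. Returns a
    dict with ``coef`` (marker log-odds-ratio), ``se``, ``odds_ratio`` and
    ``max_delta`` (final update magnitude, for convergence checks).
    """
    a, b, c, d = (np.asarray(v, dtype=float) for v in (a, b, c, d))
    t0 = np.zeros_like(a)
    t1 = np.zeros_like(a)
    max_delta = np.zeros_like(a)
    for _ in range(n_iter):
        p1 = expit(t0 + t1)
        p0 = expit(t0)
        g1 = a - (a + c) * p1
        g0 = g1 + b - (b + d) * p0
        s1 = np.maximum((a + c) * p1 * (1 - p1), 1e-12)
        s0 = np.maximum((b + d) * p0 * (1 - p0), 1e-12)
        delta0 = (g0 - g1) / s0
        delta1 = -delta0 + g1 / s1
        np.clip(delta0, -5, 5, out=delta0)
        np.clip(delta1, -5, 5, out=delta1)
        t0 += delta0
        t1 += delta1
        max_delta = np.maximum(np.abs(delta0), np.abs(delta1))
    p1 = expit(t0 + t1)
    p0 = expit(t0)
    s1 = (a + c) * p1 * (1 - p1)
    s0 = (b + d) * p0 * (1 - p0)
    se = np.sqrt(1.0 / s0 + 1.0 / s1)
    return {"coef": t1, "se": se, "odds_ratio": np.exp(t1), "max_delta": max_delta}


def haldane_odds_ratio(a: float, b: float, c: float, d: float) -> float:
    """Haldane-Anscombe (+0.5 per cell) corrected odds ratio."""
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


def fish_only_model(calls, outcome) -> LogisticFit:
    """outcome ~ intercept + FISH(positive = 1)."""
    x = _calls_to_binary(calls)
    y = _outcome_to_binary(outcome)
    fit = fit_logistic(x[:, None], y, term_names=["FISH"])
    a = float(((x == 1) & (y == 1)).sum())
    b = float(((x == 0) & (y == 1)).sum())
    c = float(((x == 1) & (y == 0)).sum())
    d = float(((x == 0) & (y == 0)).sum())
    if min(a, b, c, d) == 0:
        fit.haldane_or = haldane_odds_ratio(a, b, c, d)
        fit.diagnostics.append(
            "empty 2x2 cell: Haldane-Anscombe corrected OR reported as auxiliary value"
        )
    return fit


def _risk_design(risk_groups, coding: str) -> tuple[np.ndarray, list[str]]:
    groups = pd.Series(list(risk_groups))
    unknown = set(groups) - set(RISK_ORDINAL)
    if unknown:
        raise ValidationError(f"unknown risk groups: {unknown}")
    if coding == "ordinal":
        return groups.map(RISK_ORDINAL).to_numpy(dtype=float)[:, None], ["NCCN"]
    if coding == "dummy":
        present = [g for g in ("Low", "Intermediate", "High") if (groups == g).any()]
        cols = np.column_stack([(groups == g).to_numpy(dtype=float) for g in present])
        return cols, [f"NCCN[{g}]" for g in present]
    raise ValidationError(f"unknown risk coding {coding!r}")


def fish_clinical_model(calls, risk_groups, outcome, risk_coding: str = "ordinal") -> LogisticFit:
    """outcome ~ intercept + FISH + NCCN risk group.

    A constant risk covariate is dropped with a diagnostic, so the model
    degrades gracefully to the FISH-only fit within a single risk stratum.
    """
    x = _calls_to_binary(calls)
    risk_cols, risk_names = _risk_design(risk_groups, risk_coding)
    keep = [j for j in range(risk_cols.shape[1]) if np.ptp(risk_cols[:, j]) > 0]
    dropped = [risk_names[j] for j in range(risk_cols.shape[1]) if j not in keep]
    design = np.column_stack([x] + [risk_cols[:, j] for j in keep])
    names = ["FISH"] + [risk_names[j] for j in keep]
    fit = fit_logistic(design, _outcome_to_binary(outcome), term_names=names)
    for name in dropped:
        fit.diagnostics.append(f"risk covariate {name} constant; dropped from model")
    return fit


def clinical_only_model(risk_groups, ages, outcome, risk_coding: str = "ordinal") -> LogisticFit:
    """outcome ~ intercept + NCCN risk + age (years, continuous)."""
    risk_cols, risk_names = _risk_design(risk_groups, risk_coding)
    ages = np.asarray(ages, dtype=float)
    design = np.column_stack([risk_cols, ages])
    return fit_logistic(design, _outcome_to_binary(outcome), term_names=risk_names + ["age"])


@dataclass
class StratumResult:
    stratum: str
    n_cases: int
    n_controls: int
    fit: LogisticFit | None
    skipped_reason: str | None = None


def stratified_analysis(calls, clinical: pd.DataFrame, outcome=None) -> dict[str, StratumResult]:
    """FISH-only model fitted within each clinical risk stratum.

    Strata: lower = VeryLow + Low, intermediate, higher = High. Strata with
    a missing outcome class or a constant call are skipped with a
    diagnostic; non-convergence within a stratum is reported on the fit,
    not fatal.
    """
    calls = np.asarray(calls)
    risk = clinical["risk_group"].to_numpy()
    y = _outcome_to_binary(clinical["outcome"] if outcome is None else outcome)
    out: dict[str, StratumResult] = {}
    for stratum, groups in STRATUM_GROUPS.items():
        mask = np.isin(risk, groups)
        n_cases = int(y[mask].sum())
        n_controls = int((1 - y[mask]).sum())
        if n_cases == 0 or n_controls == 0:
            out[stratum] = StratumResult(
                stratum, n_cases, n_controls, None,
                "missing outcome class in stratum",
            )
            continue
        try:
            fit = fish_only_model(calls[mask], y[mask].astype(int))
        except RankDeficiencyError:
            out[stratum] = StratumResult(
                stratum, n_cases, n_controls, None, "constant panel call in stratum"
            )
            continue
        out[stratum] = StratumResult(stratum, n_cases, n_controls, fit)
    return out
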