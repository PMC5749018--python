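"""Specimen-level FISH parameters from per-nucleus signal enumeration.

Six parameter kinds are computed from enumerated signal counts:

- **Gain**: percent of cells with more than 2 signals;
- **Loss**: percent of cells with fewer than 2 signals (includes zero);
- **Homozygous**: percent of cells with 0 signals;
- **Ratio**: mean probe signals per cell divided by mean signals of the
  same-chromosome centromeric control;
- **Split** (break-apart probes): percent of cells with at least one
  isolated red *and* one isolated green signal — a rearrangement;
- **2Edel** (ERG break-apart): percent of cells with two or more isolated
  red signals and fewer isolated green than red — rearrangement through
  interstitial deletion, which multiplies the red (3') signal while losing
  green (5') signals.

Signal separation ("isolated" vs "fused", the >= 1 signal-width criterion
at the microscope) is resolved at enumeration time and carried in the cell
records; Split and 2Edel are disjoint cell classes here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NotApplicableError, UndefinedRatioError, ValidationError
from .probes import ProbePanel


def _as_counts(cells) -> np.ndarray:
    arr = np.asarray(pd.array(cells).astype("Int64").to_numpy(dtype=float))
    if arr.size == 0:
        raise ValidationError("empty cell set")
    if np.isnan(arr).any():
        raise ValidationError("missing signal counts in cell set")
    if (arr < 0).any():
        raise ValidationError("negative signal counts")
    return arr


def pct_gain(n_signals) -> float:
    """Percent of cells with more than 2 signals."""
    counts = _as_counts(n_signals)
    return 100.0 * float((counts > 2).sum()) / counts.size


def pct_loss(n_signals) -> float:
    """Percent of cells with fewer than 2 signals (0 or 1)."""
    counts = _as_counts(n_signals)
    return 100.0 * float((counts < 2).sum()) / counts.size


def pct_homozygous(n_signals) -> float:
    """Percent of cells with no signal at all (homozygous deletion pattern)."""
    counts = _as_counts(n_signals)
    return 100.0 * float((counts == 0).sum()) / counts.size


def ratio(n_signals_probe, n_signals_control) -> float:
    """Mean probe copy number relative to its same-chromosome CEP control."""
    probe = _as_counts(n_signals_probe)
    control = _as_counts(n_signals_control)
    control_mean = control.mean()
    if control_mean == 0:
        raise UndefinedRatioError("control probe mean signal count is zero")
    return float(probe.mean() / control_mean)


def pct_split(n_single_red, n_single_green) -> float:
    """Percent of cells with separated red and green signals (rearrangement).

    A cell counts as Split when it shows at least one isolated red and at
    least one isolated green signal. Cells matching the 2Edel pattern
    (red multiplied, green lost) have no isolated green and are therefore
    not counted here.
    """
    red = _as_counts(n_single_red)
    green = _as_counts(n_single_green)
    if red.size != green.size:
        raise ValidationError("red/green count vectors differ in length")
    return 100.0 * float(((red >= 1) & (green >= 1)).sum()) / red.size


def pct_2edel(n_single_red, n_single_green) -> float:
    """Percent of cells with the rearrangement-plus-deletion (2Edel) pattern.

    Operationalised as: two or more isolated red signals (gain of the 3'
    signal) with fewer isolated green than red (loss of at least one 5'
    signal relative to the red multiplicity).
    """
    red = _as_counts(n_single_red)
    green = _as_counts(n_single_green)
    if red.size != green.size:
        raise ValidationError("red/green count vectors differ in length")
    return 100.0 * float(((red >= 2) & (green < red)).sum()) / red.size


@dataclass
class QCFailure:
    """A specimen excluded from the parameter matrix, and why."""

    specimen_id: str
    reason: str


def specimen_parameters(
    cells: pd.DataFrame, panel: ProbePanel
) -> dict[str, float]:
    """Compute all panel parameters for one specimen's cell records.

    Raises ``ValidationError`` if any panel probe has no cells.
    """
    out: dict[str, float] = {}
    by_probe = {pid: grp for pid, grp in cells.groupby("probe_id")}
    for probe in panel:
        grp = by_probe.get(probe.probe_id)
        if grp is None or len(grp) == 0:
            raise ValidationError(f"no cells for probe {probe.probe_id}")
        name = probe.display_name
        if probe.probe_class == "locus":
            counts = grp["n_signals"]
            for param in probe.parameter_names():
                kind = param.rsplit(" ", 1)[1]
                if kind == "Gain":
                    out[param] = pct_gain(counts)
                elif kind == "Loss":
                    out[param] = pct_loss(counts)
                elif kind == "Homozygous":
                    out[param] = pct_homozygous(counts)
                elif kind == "Ratio":
                    ctrl_grp = by_probe.get(probe.control_probe_id)
                    if ctrl_grp is None or len(ctrl_grp) == 0:
                        raise ValidationError(
                            f"no cells for control probe {probe.control_probe_id}"
                        )
                    try:
                        out[param] = ratio(counts, ctrl_grp["n_signals"])
                    except UndefinedRatioError:
                        out[param] = float("nan")
        elif probe.probe_class == "break_apart":
            red, green = grp["n_single_red"], grp["n_single_green"]
            out[f"{name} Split"] = pct_split(red, green)
            if probe.scores_2edel:
                out[f"{name} 2Edel"] = pct_2edel(red, green)
    return out


def build_parameter_matrix(
    cells: pd.DataFrame, panel: ProbePanel
) -> tuple[pd.DataFrame, list[QCFailure]]:
    """Build the specimens x parameters matrix.

    Returns the wide matrix (index ``specimen_id``, one column per scored
    parameter in panel order, plus ``n_cells_enumerated``) and a list of
    QC failures: specimens lacking cells for any required probe are
    excluded and reported, not fatal.
    """
    rows: dict[str, dict[str, float]] = {}
    failures: list[QCFailure] = []
    for specimen_id, grp in cells.groupby("specimen_id", sort=True):
        try:
            params = specimen_parameters(grp, panel)
        except (ValidationError, NotApplicableError) as exc:
            failures.append(QCFailure(str(specimen_id), str(exc)))
            continue
        params["n_cells_enumerated"] = float(
            grp.groupby(["mix_id", "probe_id"]).size().max()
        )
        rows[str(specimen_id)] = params
    columns = panel.parameter_names() + ["n_cells_enumerated"]
    matrix = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=columns)
    matrix.index.name = "specimen_id"
    return matrix, failures


def write_parameter_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_parameter_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="specimen_id")
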