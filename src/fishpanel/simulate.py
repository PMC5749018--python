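"""Seeded synthetic case-control cohort generator.

Emulates a nested case-control active-surveillance cohort of localised
prostate cancer: per-specimen clinical records (age, PSA, Gleason score,
tumour stage, NCCN risk group, progression outcome) plus per-nucleus FISH
signal enumeration tables for a multi-mix probe panel.

The enumeration model is a two-level exchangeable mixture: each specimen
draws, per probe and lesion type, an abnormal-cell fraction from a Beta
prior (case and control arms have separate priors); each enumerated nucleus
is then assigned a lesion i.i.d. given those fractions and emits true
signal counts by a deterministic lesion rule. Sectioning of FFPE nuclei
("truncation") is modelled as independent Bernoulli loss of each true
signal, which depresses observed centromere copy number to ``2 * (1 - p)``
(about 1.84 at the default ``p = 0.08``, the regime seen in thin tissue
sections).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .probes import ProbePanel, default_panel

STAGES = ("T1c", "T2a", "T2b", "T2c")
RISK_GROUPS = ("VeryLow", "Low", "Intermediate", "High")

#: lesion vocabulary by probe class
LOCUS_LESIONS = ("gain", "hemizygous", "homozygous")
BREAK_APART_LESIONS = ("split", "2edel")

_PARAM_TO_LESION = {
    "Gain": "gain",
    "Loss": "hemizygous",
    "Homozygous": "homozygous",
    "Split": "split",
    "2Edel": "2edel",
}


def assign_nccn_risk(stage: str, psa: float, gleason: int, *, very_low: bool = False) -> str:
    """Assign an NCCN-style clinical risk group from stage, PSA and Gleason.

    The rule is a deterministic simplification of the NCCN stratification for
    clinically localised disease (T1c-T2c): High if Gleason >= 8 or
    PSA > 20 ng/mL; else Intermediate if Gleason = 7, PSA in [10, 20] or
    stage T2b/T2c; else VeryLow when the caller asserts the very-low
    criteria (T1c, Gleason <= 6, PSA < 10 plus core-level findings the data
    model does not carry, hence the explicit flag); else Low.
    """
    if stage not in STAGES:
        raise ValidationError(f"stage must be one of {STAGES}, got {stage!r}")
    if not psa > 0:
        raise ValidationError(f"psa must be positive, got {psa}")
    if not 2 <= int(gleason) <= 10:
        raise ValidationError(f"gleason must be in 2..10, got {gleason}")
    if gleason >= 8 or psa > 20:
        return "High"
    if gleason == 7 or 10 <= psa <= 20 or stage in ("T2b", "T2c"):
        return "Intermediate"
    if stage == "T1c" and gleason <= 6 and psa < 10 and very_low:
        return "VeryLow"
    return "Low"


@dataclass(frozen=True)
class PlantedEffect:
    """Case-enrichment of one FISH parameter's abnormal-cell fraction.

    ``multiplier`` scales the control-arm prior mean for case specimens
    (same prior concentration). ``risk_stratum`` optionally restricts the
    enrichment to cases in one analysis stratum (``lower`` = VeryLow+Low,
    ``intermediate``, ``higher`` = High); cases outside the stratum draw
    from the control prior.
    """

    parameter: str
    multiplier: float = 1.4
    risk_stratum: str | None = None


@dataclass(frozen=True)
class BetaPrior:
    """Beta(a, b) prior on a specimen-level abnormal-cell fraction."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ConfigurationError(
                f"abnormality_priors: Beta parameters must be positive, got ({self.a}, {self.b})"
            )

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def with_mean(self, mean: float) -> "BetaPrior":
        """Same concentration (a+b), shifted mean (clipped to (0, 0.95])."""
        mean = float(np.clip(mean, 1e-6, 0.95))
        kappa = self.a + self.b
        return BetaPrior(mean * kappa, (1.0 - mean) * kappa)


#: baseline (control-arm) abnormal-cell fraction prior: mean 2.5%, weakly informative
DEFAULT_CONTROL_PRIOR = BetaPrior(1.5, 58.5)

DEFAULT_PLANTED_EFFECTS = tuple(
    PlantedEffect(p)
    for p in (
        "PTEN Homozygous",
        "MYC Gain",
        "FGFR1 Gain",
        "NMYC Gain",
        "ETV1 Split",
        "PTEN Loss",
        "ERG 2Edel",
    )
)

# Matched case-control design: cases and controls share the risk-group
# distribution (the cohort matches controls to cases on stage, grade and
# PSA), with composition ~22% High, ~27% Intermediate, ~50% Low+VeryLow.
DEFAULT_RISK_GROUP_PROBS = {
    "VeryLow": 0.20,
    "Low": 0.30,
    "Intermediate": 0.27,
    "High": 0.23,
}

# Case-tilted alternative for planting a clinical risk-group association
# (roughly log-linear in the ordinal score, about e^1.2 odds per step), e.g.
# to exercise the clinical-only and adjusted models on a confounded cohort.
CASE_TILTED_RISK_GROUP_PROBS = {
    "case": {"VeryLow": 0.06, "Low": 0.16, "Intermediate": 0.32, "High": 0.46},
    "control": {"VeryLow": 0.32, "Low": 0.38, "Intermediate": 0.22, "High": 0.08},
}


@dataclass
class SimulationConfig:
    """Configuration of a synthetic cohort run.

    Parameters
    ----------
    n_cases, n_controls :
        Specimens with progressive / non-progressive outcome.
    cells_per_specimen :
        Nuclei enumerated per specimen per hybridisation mix.
    truncation_prob :
        Probability that an individual true signal is lost to sectioning.
    abnormality_priors :
        Optional overrides: ``(probe_id, lesion) -> {"case": BetaPrior,
        "control": BetaPrior}``. Unlisted combinations use the baseline
        control prior in both arms, modified by ``planted_effects``.
    planted_effects :
        Case-enrichment of specific parameters, see :class:`PlantedEffect`.
    risk_group_probs :
        Either one distribution over risk groups applied to both arms
        (the matched-design default), or ``{"case": {...},
        "control": {...}}`` to plant a clinical risk-group association.
    nkx31_gleason_slope :
        Coupling of the NKX3.1 hemizygous-loss fraction to the Gleason
        score (fraction of cells per Gleason unit above 5). Emulates the
        marker-clinical confounding that the screening stage is built to
        catch; set to 0 for an unconfounded cohort.
    seed :
        RNG seed; identical config + seed reproduces byte-identical tables.
    """

    n_cases: int = 58
    n_controls: int = 49
    cells_per_specimen: int = 100
    truncation_prob: float = 0.08
    abnormality_priors: Mapping[tuple[str, str], Mapping[str, BetaPrior]] = field(
        default_factory=dict
    )
    planted_effects: Sequence[PlantedEffect] = DEFAULT_PLANTED_EFFECTS
    risk_group_probs: Mapping = field(
        default_factory=lambda: dict(DEFAULT_RISK_GROUP_PROBS)
    )
    nkx31_gleason_slope: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigurationError("n_cases/n_controls must be non-negative")
        if self.n_cases + self.n_controls == 0:
            raise ConfigurationError("n_cases + n_controls must be positive")
        if self.cells_per_specimen <= 0:
            raise ConfigurationError("cells_per_specimen must be positive")
        if not 0.0 <= self.truncation_prob < 1.0:
            raise ConfigurationError(
                f"truncation_prob must be in [0, 1), got {self.truncation_prob}"
            )
        for arm, probs in self._arm_risk_probs().items():
            if set(probs) - set(RISK_GROUPS):
                raise ConfigurationError(
                    f"risk_group_probs[{arm}]: unknown groups {set(probs) - set(RISK_GROUPS)}"
                )
            total = sum(probs.values())
            if not np.isclose(total, 1.0) or any(v < 0 for v in probs.values()):
                raise ConfigurationError(
                    f"risk_group_probs[{arm}] must be a distribution (sums to {total})"
                )
        for eff in self.planted_effects:
            if eff.multiplier <= 0:
                raise ConfigurationError(
                    f"planted_effects[{eff.parameter}]: multiplier must be positive"
                )
            if eff.risk_stratum not in (None, "lower", "intermediate", "higher"):
                raise ConfigurationError(
                    f"planted_effects[{eff.parameter}]: unknown risk_stratum "
                    f"{eff.risk_stratum!r}"
                )

    def _arm_risk_probs(self) -> dict[str, dict[str, float]]:
        if "case" in self.risk_group_probs or "control" in self.risk_group_probs:
            return {
                "case": dict(self.risk_group_probs["case"]),
                "control": dict(self.risk_group_probs["control"]),
            }
        shared = dict(self.risk_group_probs)
        return {"case": shared, "control": shared}

    def prior_for(self, probe_id: str, lesion: str, arm: str, stratum: str) -> BetaPrior:
        """Resolve the Beta prior for one (probe, lesion, arm, stratum)."""
        override = self.abnormality_priors.get((probe_id, lesion))
        if override is not None:
            return override[arm]
        prior = DEFAULT_CONTROL_PRIOR
        if arm == "case":
            for eff in self.planted_effects:
                probe_disp, param = eff.parameter.rsplit(" ", 1)
                if _PARAM_TO_LESION.get(param) != lesion:
                    continue
                if probe_disp != probe_id.removesuffix("_BA"):
                    continue
                if eff.risk_stratum is not None and eff.risk_stratum != stratum:
                    continue
                prior = prior.with_mean(prior.mean * eff.multiplier)
        return prior


def _stratum_of(risk_group: str) -> str:
    return {"VeryLow": "lower", "Low": "lower", "Intermediate": "intermediate", "High": "higher"}[
        risk_group
    ]


def _draw_clinical(rng: np.random.Generator, risk_group: str) -> tuple[str, float, int, bool]:
    """Sample (stage, psa, gleason, very_low flag) consistent with a risk group."""
    if risk_group == "High":
        if rng.random() < 0.6:
            gleason = int(rng.choice([8, 9]))
            psa = float(np.round(rng.uniform(4.0, 18.0), 1))
        else:
            gleason = int(rng.choice([6, 7]))
            psa = float(np.round(rng.uniform(20.5, 38.0), 1))
        stage = str(rng.choice(["T1c", "T2a", "T2b"]))
        return stage, psa, gleason, False
    if risk_group == "Intermediate":
        route = rng.choice(["gleason7", "psa", "stage"], p=[0.5, 0.3, 0.2])
        gleason, psa, stage = 6, float(np.round(rng.uniform(3.0, 9.5), 1)), str(
            rng.choice(["T1c", "T2a"])
        )
        if route == "gleason7":
            gleason = 7
        elif route == "psa":
            psa = float(np.round(rng.uniform(10.0, 19.5), 1))
        else:
            stage = str(rng.choice(["T2b", "T2c"]))
        return stage, psa, gleason, False
    gleason = int(rng.choice([5, 6], p=[0.2, 0.8]))
    psa = float(np.round(rng.uniform(2.0, 9.5), 1))
    if risk_group == "VeryLow":
        return "T1c", psa, gleason, True
    return str(rng.choice(["T1c", "T2a"])), psa, gleason, False


def simulate_cell(
    probe_class: str,
    lesion: str,
    truncation_prob: float,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Simulate one nucleus' observed signal pattern for one probe.

    True counts per lesion: a normal locus shows 2 signals; ``gain`` an
    integer in 3..6; ``hemizygous`` 1; ``homozygous`` 0. A normal
    break-apart locus shows 2 fusion signals; ``split`` 1 fusion +
    1 isolated red + 1 isolated green; ``2edel`` 1 fusion + k isolated red
    (k in 2..4) + 0 isolated green. Each true signal is then independently
    lost with probability ``truncation_prob``.

    Returns a dict with ``n_signals`` for locus/centromere probes, or
    ``n_fusion``/``n_single_red``/``n_single_green`` for break-apart probes.
    """
    keep = 1.0 - truncation_prob
    if probe_class in ("locus", "centromere_control"):
        if lesion == "normal":
            true = 2
        elif lesion == "gain":
            true = int(rng.integers(3, 7))
        elif lesion == "hemizygous":
            true = 1
        elif lesion == "homozygous":
            true = 0
        else:
            raise ValidationError(
                f"lesion {lesion!r} incompatible with probe class {probe_class!r}"
            )
        return {"n_signals": int(rng.binomial(true, keep)) if true else 0}
    if probe_class == "break_apart":
        if lesion == "normal":
            fusion, red, green = 2, 0, 0
        elif lesion == "split":
            fusion, red, green = 1, 1, 1
        elif lesion == "2edel":
            fusion, red, green = 1, int(rng.integers(2, 5)), 0
        else:
            raise ValidationError(
                f"lesion {lesion!r} incompatible with probe class {probe_class!r}"
            )
        return {
            "n_fusion": int(rng.binomial(fusion, keep)) if fusion else 0,
            "n_single_red": int(rng.binomial(red, keep)) if red else 0,
            "n_single_green": int(rng.binomial(green, keep)) if green else 0,
        }
    raise ValidationError(f"unknown probe class {probe_class!r}")


def _simulate_probe_cells(
    probe,
    n_cells: int,
    fractions: dict[str, float],
    truncation_prob: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorised per-probe cell simulation for one specimen."""
    keep = 1.0 - truncation_prob
    lesions = (
        LOCUS_LESIONS
        if probe.probe_class in ("locus", "centromere_control")
        else BREAK_APART_LESIONS
    )
    probs = np.array([fractions.get(les, 0.0) for les in lesions], dtype=float)
    total_abn = probs.sum()
    if total_abn > 1.0:  # renormalise degenerate draws
        probs /= total_abn
        total_abn = 1.0
    full = np.concatenate([[1.0 - total_abn], probs])
    codes = rng.choice(len(full), size=n_cells, p=full)  # 0 = normal

    if probe.probe_class in ("locus", "centromere_control"):
        true = np.full(n_cells, 2, dtype=np.int64)
        true[codes == 1] = rng.integers(3, 7, size=int((codes == 1).sum()))
        true[codes == 2] = 1
        true[codes == 3] = 0
        return {"n_signals": rng.binomial(true, keep)}

    fusion = np.full(n_cells, 2, dtype=np.int64)
    red = np.zeros(n_cells, dtype=np.int64)
    green = np.zeros(n_cells, dtype=np.int64)
    split_mask = codes == 1
    edel_mask = codes == 2
    fusion[split_mask | edel_mask] = 1
    red[split_mask] = 1
    green[split_mask] = 1
    red[edel_mask] = rng.integers(2, 5, size=int(edel_mask.sum()))
    return {
        "n_fusion": rng.binomial(fusion, keep),
        "n_single_red": rng.binomial(red, keep),
        "n_single_green": rng.binomial(green, keep),
    }


def generate_cohort(
    config: SimulationConfig,
    panel: ProbePanel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ProbePanel]:
    """Generate a synthetic cohort.

    Returns ``(clinical, cells, panel)``: the clinical table (one row per
    specimen), the cell enumeration table (one row per nucleus per probe),
    and the probe panel used. Specimens are ordered cases first, then
    controls; all randomness derives from ``config.seed``.
    """
    config.validate()
    panel = panel if panel is not None else default_panel()
    rng = np.random.default_rng(config.seed)
    arm_probs = config._arm_risk_probs()

    clinical_rows = []
    arms = ["case"] * config.n_cases + ["control"] * config.n_controls
    for i, arm in enumerate(arms):
        specimen_id = f"S{i + 1:04d}"
        probs = arm_probs[arm]
        groups = list(RISK_GROUPS)
        p = np.array([probs.get(g, 0.0) for g in groups])
        risk_group = str(rng.choice(groups, p=p / p.sum()))
        stage, psa, gleason, very_low = _draw_clinical(rng, risk_group)
        assert assign_nccn_risk(stage, psa, gleason, very_low=very_low) == risk_group
        age = int(np.clip(np.round(rng.normal(64.0, 6.0)), 50, 82))
        clinical_rows.append(
            {
                "specimen_id": specimen_id,
                "outcome": arm,
                "age": age,
                "psa": psa,
                "gleason": gleason,
                "stage": stage,
                "risk_group": risk_group,
            }
        )
    clinical = pd.DataFrame(clinical_rows)

    cell_chunks = []
    n = config.cells_per_specimen
    for row in clinical_rows:
        stratum = _stratum_of(row["risk_group"])
        for mix_id in panel.mix_ids:
            for probe in panel.in_mix(mix_id):
                lesions = (
                    LOCUS_LESIONS
                    if probe.probe_class in ("locus", "centromere_control")
                    else BREAK_APART_LESIONS
                )
                fractions: dict[str, float] = {}
                if probe.probe_class != "centromere_control":
                    for lesion in lesions:
                        prior = config.prior_for(probe.probe_id, lesion, row["outcome"], stratum)
                        fractions[lesion] = float(rng.beta(prior.a, prior.b))
                if probe.probe_id == "NKX3.1" and config.nkx31_gleason_slope:
                    fractions["hemizygous"] = float(
                        np.clip(
                            fractions.get("hemizygous", 0.0)
                            + config.nkx31_gleason_slope * (row["gleason"] - 5),
                            0.0,
                            0.9,
                        )
                    )
                sig = _simulate_probe_cells(probe, n, fractions, config.truncation_prob, rng)
                chunk = pd.DataFrame(
                    {
                        "specimen_id": row["specimen_id"],
                        "mix_id": mix_id,
                        "cell_index": np.arange(n),
                        "probe_id": probe.probe_id,
                    }
                )
                for col in ("n_signals", "n_fusion", "n_single_red", "n_single_green"):
                    chunk[col] = sig.get(col, pd.array([pd.NA] * n, dtype="Int64"))
                cell_chunks.append(chunk)

    cells = pd.concat(cell_chunks, ignore_index=True)
    for col in ("n_signals", "n_fusion", "n_single_red", "n_single_green"):
        cells[col] = cells[col].astype("Int64")
    return clinical, cells, panel


def write_cohort(
    outdir: str | Path,
    clinical: pd.DataFrame,
    cells: pd.DataFrame,
    panel: ProbePanel,
) -> dict[str, Path]:
    """Write ``clinical.tsv``, ``cells.tsv`` and ``probes.tsv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": outdir / "clinical.tsv",
        "cells": outdir / "cells.tsv",
        "probes": outdir / "probes.tsv",
    }
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    cells.to_csv(paths["cells"], sep="\t", index=False)
    panel.write_tsv(paths["probes"])
    return paths


def read_cells(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("n_signals", "n_fusion", "n_single_red", "n_single_green"):
        if col in df:
            df[col] = df[col].astype("Int64")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
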