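"""End-to-end pipeline orchestration.

Stage order mirrors the analysis workflow: simulate (optional) ->
parameter enumeration -> marker screening -> combination selection ->
association models. Each stage reads/writes plain TSV tables so it can be
run standalone; a JSON manifest (config hash, seed, timings, QC
exclusions) makes a run reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import enumeration, models, screening, selection, simulate
from .errors import ConfigurationError, EnumerationQCError, PipelineError
from .probes import CANDIDATE_PARAMETERS, ProbePanel, default_panel

log = logging.getLogger("fishpanel")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``simulation`` (generate a synthetic cohort) or the
    three input paths (``cells_path``, ``clinical_path``, ``probes_path``)
    must be supplied.
    """

    outdir: str = "results"
    simulation: simulate.SimulationConfig | None = None
    cells_path: str | None = None
    clinical_path: str | None = None
    probes_path: str | None = None
    candidates: Sequence[str] = CANDIDATE_PARAMETERS
    grid_step: int = 1
    alpha: float = 0.05
    k_min: int = 3
    k_max: int = 6
    auc_method: str = "logistic"
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        have_paths = all(
            p is not None for p in (self.cells_path, self.clinical_path, self.probes_path)
        )
        if (self.simulation is None) == (not have_paths):
            raise ConfigurationError(
                "supply exactly one of: a simulation config, or cells/clinical/probes paths"
            )
        if not 3 <= self.k_min <= self.k_max:
            raise ConfigurationError("need 3 <= k_min <= k_max")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["abnormality_priors"] = {
                f"{k[0]}|{k[1]}": {arm: dataclasses.asdict(p) for arm, p in v.items()}
                for k, v in self.simulation.abnormality_priors.items()
            }
            d["simulation"] = sim
        d["candidates"] = list(self.candidates)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML or JSON, mirroring the field names."""
    raw = yaml.safe_load(Path(path).read_text())
    sim = raw.pop("simulation", None)
    cfg = RunConfig(**raw)
    if sim is not None:
        planted = [
            simulate.PlantedEffect(**e) if isinstance(e, dict) else simulate.PlantedEffect(e)
            for e in sim.pop("planted_effects", simulate.DEFAULT_PLANTED_EFFECTS)
        ]
        cfg.simulation = simulate.SimulationConfig(planted_effects=planted, **sim)
    if cfg.seed is not None and cfg.simulation is not None:
        cfg.simulation.seed = cfg.seed
    return cfg


def stage_simulate(config: RunConfig, outdir: Path):
    sim = config.simulation
    if config.seed is not None:
        sim = dataclasses.replace(sim, seed=config.seed)
    clinical, cells, panel = simulate.generate_cohort(sim)
    simulate.write_cohort(outdir, clinical, cells, panel)
    return clinical, cells, panel


def stage_enumerate(cells: pd.DataFrame, panel: ProbePanel, outdir: Path):
    matrix, failures = enumeration.build_parameter_matrix(cells, panel)
    if len(matrix) == 0:
        raise EnumerationQCError([(f.specimen_id, f.reason) for f in failures])
    enumeration.write_parameter_matrix(matrix, outdir / "parameters.tsv")
    if failures:
        log.warning("enumeration QC excluded %d specimens", len(failures))
    return matrix, failures


def stage_screen(matrix, clinical, panel, alpha, outdir: Path):
    results, excluded_probes = screening.screen_parameters(matrix, clinical, panel, alpha)
    screening.write_screen(results, outdir / "screen.tsv")
    if excluded_probes:
        log.info("screening excluded probes: %s", sorted(excluded_probes))
    return results, excluded_probes


def stage_select(config: RunConfig, matrix, labels, panel, excluded_probes, outdir: Path):
    candidates = [
        p
        for p in config.candidates
        if panel.probe_for_parameter(p).probe_id not in excluded_probes
    ]
    if len(candidates) < config.k_min:
        raise PipelineError(
            f"selection stage: only {len(candidates)} candidate parameters survive "
            f"the screen ({candidates}), need k_min={config.k_min}"
        )
    grid = selection.build_grid(candidates, panel, step=config.grid_step)
    ranked = selection.enumerate_and_rank(
        candidates, matrix, labels, grid,
        k_min=config.k_min, k_max=min(config.k_max, len(candidates)),
        auc_method=config.auc_method,
    )
    selection.combinations_to_frame(ranked).to_csv(outdir / "combinations.tsv", sep="\t", index=False)
    selection.calls_to_frame(ranked).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    return ranked, candidates


def stage_fit(leaders, clinical, outdir: Path):
    """Table-2/3 shaped model reports for the per-size leading combinations."""
    clin = clinical.set_index("specimen_id")
    model_rows, strat_rows = [], []
    for res in leaders:
        sids = list(res.calls)
        calls = [res.calls[s] for s in sids]
        sub = clin.loc[sids]
        outcome = sub["outcome"].to_numpy()
        risk = sub["risk_group"].to_numpy()
        fish = models.fish_only_model(calls, outcome)
        both = models.fish_clinical_model(calls, risk, outcome)
        f, bf, bn = fish.term("FISH"), both.term("FISH"), both.term("NCCN")
        model_rows.append(
            {
                "combination": res.label,
                "n_cases": fish.n_cases,
                "n_controls": fish.n_controls,
                "fish_or": f.odds_ratio, "fish_ci_low": f.ci_low,
                "fish_ci_high": f.ci_high, "fish_p": f.p_value,
                "fish_converged": int(fish.converged),
                "adj_fish_or": bf.odds_ratio, "adj_fish_ci_low": bf.ci_low,
                "adj_fish_ci_high": bf.ci_high, "adj_fish_p": bf.p_value,
                "nccn_or": bn.odds_ratio, "nccn_ci_low": bn.ci_low,
                "nccn_ci_high": bn.ci_high, "nccn_p": bn.p_value,
                "adj_converged": int(both.converged),
            }
        )
        strat = models.stratified_analysis(
            calls, sub.reset_index()[["specimen_id", "outcome", "risk_group"]]
        )
        for name, sres in strat.items():
            row = {
                "combination": res.label,
                "stratum": name,
                "n_cases": sres.n_cases,
                "n_controls": sres.n_controls,
            }
            if sres.fit is not None:
                t = sres.fit.term("FISH")
                row.update(
                    odds_ratio=t.odds_ratio, p_value=t.p_value,
                    converged=int(sres.fit.converged),
                    haldane_or=sres.fit.haldane_or,
                )
            else:
                row.update(odds_ratio=float("nan"), p_value=float("nan"),
                           converged=0, haldane_or=None, skipped=sres.skipped_reason)
            strat_rows.append(row)
    models_df = pd.DataFrame(model_rows)
    strat_df = pd.DataFrame(strat_rows)
    models_df.to_csv(outdir / "models.tsv", sep="\t", index=False)
    strat_df.to_csv(outdir / "models_stratified.tsv", sep="\t", index=False)
    return models_df, strat_df


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a result bundle including the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "config": config.to_jsonable(),
        "config_hash": config.config_hash(),
        "seed": config.seed if config.seed is not None else (
            config.simulation.seed if config.simulation else None
        ),
    }

    t0 = time.perf_counter()
    if config.simulation is not None:
        clinical, cells, panel = stage_simulate(config, outdir)
    else:
        cells = simulate.read_cells(config.cells_path)
        clinical = simulate.read_clinical(config.clinical_path)
        panel = ProbePanel.read_tsv(config.probes_path)
    timings["load_or_simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        matrix, qc_failures = stage_enumerate(cells, panel, outdir)
    except EnumerationQCError as exc:
        raise PipelineError(f"enumeration stage: {exc}") from exc
    timings["enumerate"] = time.perf_counter() - t0
    clinical = clinical[clinical["specimen_id"].isin(matrix.index)].reset_index(drop=True)

    t0 = time.perf_counter()
    screen_results, excluded_probes = stage_screen(
        matrix, clinical, panel, config.alpha, outdir
    )
    timings["screen"] = time.perf_counter() - t0

    labels = clinical.set_index("specimen_id").loc[matrix.index, "outcome"].to_numpy()
    t0 = time.perf_counter()
    ranked, candidates = stage_select(config, matrix, labels, panel, excluded_probes, outdir)
    timings["select"] = time.perf_counter() - t0

    leaders = selection.per_size_leaders(ranked)
    t0 = time.perf_counter()
    models_df, strat_df = stage_fit(leaders, clinical, outdir)
    timings["fit"] = time.perf_counter() - t0

    manifest.update(
        {
            "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
            "qc_exclusions": [(f.specimen_id, f.reason) for f in qc_failures],
            "excluded_probes": sorted(excluded_probes),
            "candidates_after_screen": candidates,
            "n_combinations": len(ranked),
            "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
        }
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "manifest": manifest,
        "clinical": clinical,
        "matrix": matrix,
        "screen": screen_results,
        "excluded_probes": excluded_probes,
        "ranked": ranked,
        "leaders": leaders,
        "models": models_df,
        "models_stratified": strat_df,
    }
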