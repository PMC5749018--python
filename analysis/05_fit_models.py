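#!/usr/bin/env python
"""Logistic association models for the leading combinations.

For each per-size leader: the FISH-only model, the FISH + NCCN risk-group
model (is the panel additive to clinical stratification?), and the
risk-stratified FISH-only models. Writes results/models.tsv and
results/models_stratified.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from fishpanel.pipeline import stage_fit
from fishpanel.selection import CombinationResult
from fishpanel.simulate import read_clinical


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--combinations", type=Path, default=Path("results/combinations.tsv"))
    ap.add_argument("--calls", type=Path, default=Path("results/calls.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    comb = pd.read_csv(args.combinations, sep="\t")
    calls = pd.read_csv(args.calls, sep="\t")
    clinical = read_clinical(args.cohort / "clinical.tsv")

    leaders = []
    for _, grp in comb.groupby("n_parameters"):
        row = grp.sort_values(["auc", "dfi"], ascending=[False, True]).iloc[0]
        cc = calls[calls["combination"] == row["combination"]]
        leaders.append(
            CombinationResult(
                parameters=tuple(row["combination"].split(" & ")),
                cutoffs={}, sensitivity=row["sensitivity"],
                specificity=row["specificity"], dfi=row["dfi"], auc=row["auc"],
                calls=dict(zip(cc["specimen_id"], cc["call"])),
            )
        )

    models_df, strat_df = stage_fit(leaders, clinical, args.outdir)
    print("panel association models (per-size leading combinations):")
    print(models_df[["combination", "n_cases", "n_controls", "fish_or", "fish_p",
                     "adj_fish_or", "nccn_or"]].round(3).to_string(index=False))
    print("\nrisk-stratified FISH-only models:")
    print(strat_df[["combination", "stratum", "n_cases", "n_controls",
                    "odds_ratio", "p_value"]].round(3).to_string(index=False))
    print(f"wrote {args.outdir / 'models.tsv'} and {args.outdir / 'models_stratified.tsv'}")


if __name__ == "__main__":
    main()
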