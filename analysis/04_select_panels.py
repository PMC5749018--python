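#!/usr/bin/env python
"""Enumerate 3-6 parameter combinations, optimise cut-offs by minimum DFI
under the any-positive rule, and rank combinations by AUC.

Reads results/cohort/, results/parameters.tsv and results/screen.tsv,
writes results/combinations.tsv and results/calls.tsv, and prints the
per-size leading combinations (the discovery report's headline table).
"""

import argparse
from pathlib import Path

import pandas as pd

from fishpanel.enumeration import read_parameter_matrix
from fishpanel.probes import CANDIDATE_PARAMETERS, ProbePanel
from fishpanel.selection import (
    build_grid,
    calls_to_frame,
    combinations_to_frame,
    enumerate_and_rank,
    per_size_leaders,
)
from fishpanel.simulate import read_clinical


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--parameters", type=Path, default=Path("results/parameters.tsv"))
    ap.add_argument("--screen", type=Path, default=Path("results/screen.tsv"))
    ap.add_argument("--k-min", type=int, default=3)
    ap.add_argument("--k-max", type=int, default=6)
    ap.add_argument("--auc-method", choices=["logistic", "single-point"], default="logistic")
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    matrix = read_parameter_matrix(args.parameters)
    clinical = read_clinical(args.cohort / "clinical.tsv").set_index("specimen_id")
    panel = ProbePanel.read_tsv(args.cohort / "probes.tsv")
    labels = clinical.loc[matrix.index, "outcome"].to_numpy()

    excluded_params: set[str] = set()
    if args.screen.exists():
        sc = pd.read_csv(args.screen, sep="\t")
        excluded_params = set(sc.loc[sc["excluded"] == 1, "parameter_name"])
    candidates = [c for c in CANDIDATE_PARAMETERS if c not in excluded_params]
    print(f"candidates after screen: {candidates}")

    grid = build_grid(candidates, panel)
    ranked = enumerate_and_rank(
        candidates, matrix, labels, grid,
        k_min=args.k_min, k_max=min(args.k_max, len(candidates)),
        auc_method=args.auc_method,
    )
    combinations_to_frame(ranked).to_csv(args.outdir / "combinations.tsv", sep="\t", index=False)
    calls_to_frame(ranked).to_csv(args.outdir / "calls.tsv", sep="\t", index=False)

    print(f"{len(ranked)} combinations evaluated; per-size leaders:")
    leaders = combinations_to_frame(per_size_leaders(ranked))
    print(leaders[["n_parameters", "combination", "cutoffs", "sensitivity",
                   "specificity", "dfi", "auc"]].round(3).to_string(index=False))
    print(f"wrote {args.outdir / 'combinations.tsv'} and {args.outdir / 'calls.tsv'}")


if __name__ == "__main__":
    main()
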