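#!/usr/bin/env python
"""Convert per-nucleus signal counts into the specimen x parameter matrix.

Reads results/cohort/, writes results/parameters.tsv, and prints the
case-vs-control means of the seven candidate parameters.
"""

import argparse
from pathlib import Path

from fishpanel.enumeration import build_parameter_matrix, write_parameter_matrix
from fishpanel.probes import CANDIDATE_PARAMETERS, ProbePanel
from fishpanel.simulate import read_cells, read_clinical


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/parameters.tsv"))
    args = ap.parse_args()

    cells = read_cells(args.cohort / "cells.tsv")
    clinical = read_clinical(args.cohort / "clinical.tsv")
    panel = ProbePanel.read_tsv(args.cohort / "probes.tsv")
    matrix, failures = build_parameter_matrix(cells, panel)
    write_parameter_matrix(matrix, args.out)

    print(f"{len(matrix)} specimens enumerated, {len(failures)} excluded by QC")
    for f in failures:
        print(f"  QC excluded {f.specimen_id}: {f.reason}")
    outcome = clinical.set_index("specimen_id").loc[matrix.index, "outcome"]
    means = matrix.groupby(outcome.to_numpy())[list(CANDIDATE_PARAMETERS)].mean().round(2)
    print("candidate parameter means (percent abnormal cells):")
    print(means.T.to_string())
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
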