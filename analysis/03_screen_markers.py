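#!/usr/bin/env python
"""Screen FISH parameters against clinical variables (age, Gleason, PSA,
stage) by Pearson correlation and drop confounded probes.

Reads results/cohort/ and results/parameters.tsv, writes results/screen.tsv.
The generator couples NKX3.1 loss to the Gleason score by default, so the
NKX3.1 probe is expected to fall here.
"""

import argparse
from pathlib import Path

from fishpanel.enumeration import read_parameter_matrix
from fishpanel.probes import ProbePanel
from fishpanel.screening import screen_parameters, screen_to_frame, write_screen
from fishpanel.simulate import read_clinical


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--parameters", type=Path, default=Path("results/parameters.tsv"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--out", type=Path, default=Path("results/screen.tsv"))
    args = ap.parse_args()

    matrix = read_parameter_matrix(args.parameters)
    clinical = read_clinical(args.cohort / "clinical.tsv")
    panel = ProbePanel.read_tsv(args.cohort / "probes.tsv")
    results, excluded = screen_parameters(matrix, clinical, panel, alpha=args.alpha)
    write_screen(results, args.out)

    df = screen_to_frame(results)
    sig = df[df.p_value < args.alpha].sort_values("p_value")
    print(f"{len(df)} correlation tests at alpha {args.alpha}; "
          f"{len(sig)} significant pairs")
    if len(sig):
        print(sig[["parameter_name", "clinical_variable", "r", "p_value"]]
              .round(4).to_string(index=False))
    print("excluded probes:", sorted(excluded) or "none")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
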