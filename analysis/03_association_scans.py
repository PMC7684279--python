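#!/usr/bin/env python
"""Summarize the P_T-cutoff association scans produced by
02_run_pipeline.py: for each discovery trait, the cutoff maximizing the
variance explained for (a) the matching target smoking phenotype and
(b) the HC/FR/SCZ diagnosis trend, with its coefficient and uncorrected
p-value.

Writes results/scan_summary.tsv and prints the narrative table.
"""

import argparse
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
TRAITS = ("initiation", "age_initiation", "quantity", "cessation")


def best_row(path: Path):
    scan = pd.read_csv(path, sep="\t")
    return scan.loc[scan["variance_explained"].idxmax()]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--pipeline", type=Path,
                    default=ROOT / "results" / "pipeline")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "scan_summary.tsv")
    args = ap.parse_args()
    resdir = args.pipeline / "results"

    rows = []
    for trait in TRAITS:
        for kind, stem in (("smoking", f"assoc_{trait}"),
                           ("diagnosis", f"assoc_diagnosis_{trait}")):
            path = resdir / f"{stem}.tsv"
            if not path.exists():
                continue
            b = best_row(path)
            rows.append({"discovery_trait": trait, "outcome": kind,
                         "best_threshold": b["threshold"],
                         "model": b["model"],
                         "coefficient": b["coefficient"],
                         "variance_explained": b["variance_explained"],
                         "p_value": b["p_value"], "n": b["n"]})
    summary = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    summary.to_csv(args.out, sep="\t", index=False, float_format="%.6g")
    print("best cutoff per scan (p-values uncorrected across cutoffs):")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
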