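#!/usr/bin/env python
"""Airway-resistance AUC summary.

Integrates each mouse's Rrs vs methacholine curve (trapezoid, linear
concentration axis) and summarizes the AUC per group x HDM dose — the
readout whose slopes were too flat to carry the susceptibility analysis,
which is why the score is built on the cytokine/chemokine responses.
"""

import argparse
from pathlib import Path

from aai_score import auc_by_group, auc_table
from aai_score.io import read_ahr_table

root = Path(__file__).resolve().parent.parent / "results"
parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--ahr", type=Path, default=root / "data" / "ahr.csv")
parser.add_argument("--out", type=Path, default=root / "ahr_auc_summary.csv")
parser.add_argument("--per-mouse-out", type=Path, default=root / "ahr_auc_per_mouse.csv")
args = parser.parse_args()

curves = read_ahr_table(args.ahr)
auc_table(curves).to_csv(args.per_mouse_out, index=False)
summary = auc_by_group(curves)
summary.to_csv(args.out, index=False)

print(f"summarized {len(curves)} curves into {len(summary)} group x dose cells")
group_means = summary.groupby("group")["auc_mean"].mean().sort_values(ascending=False)
print("group mean AUC (cm H2O/mL x mg/mL), descending:")
for group, value in group_means.items():
    print(f"  {group:12s} {value:7.1f}")
print(f"wrote {args.out} and {args.per_mouse_out}")
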