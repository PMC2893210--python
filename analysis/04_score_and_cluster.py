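#!/usr/bin/env python
"""Composite susceptibility scores, classification and clustering.

Combines each group's slope p-values (IL-4, IL-13, CCL7, CCL11) into
S = 1/mean(-log10 p), classifies against the cutoff 1/(-log10 0.05) = 0.77,
and clusters the group scores (Euclidean, average linkage) into a
dendrogram written as Newick.
"""

import argparse
from pathlib import Path

import pandas as pd

from aai_score import cluster_scores, score_groups
from aai_score.io import frame_to_fits, scores_to_frame, write_newick

root = Path(__file__).resolve().parent.parent / "results"
parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--fits", type=Path, default=root / "slope_fits.csv")
parser.add_argument("--out", type=Path, default=root / "scores.csv")
parser.add_argument("--newick-out", type=Path, default=root / "dendrogram.nwk")
parser.add_argument("--alpha", type=float, default=0.05)
args = parser.parse_args()

fits = frame_to_fits(pd.read_csv(args.fits))
scores = score_groups(fits, alpha=args.alpha)
scores_to_frame(scores).to_csv(args.out, index=False)

print(f"cutoff = {scores[0].cutoff:.4f} (printed as {round(scores[0].cutoff, 2)})")
for s in sorted(scores, key=lambda s: s.score):
    print(f"  {s.group:12s} score={s.score:.3f}  -> {s.label}")

dend = cluster_scores(scores)
write_newick(dend.to_newick(), args.newick_out)
first_a, first_b, h = dend.merge_order()[0]
pair = sorted([next(iter(first_a)), next(iter(first_b))])
print(f"closest pair on the score line: {pair[0]} and {pair[1]} (gap {h:.3f})")
print(f"wrote {args.out} and {args.newick_out}")
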