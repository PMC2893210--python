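#!/usr/bin/env python
"""OLS dose-response slopes per group x analyte.

Fits fold change vs HDM dose (PBS points excluded: they are the
normalization anchor) and reports each slope with its two-sided p-value for
slope != 0 — the significance that feeds the susceptibility score — plus
the inverse slope, a resistance-like transform.
"""

import argparse
from pathlib import Path

from aai_score import fit_all
from aai_score.io import fits_to_frame, read_response_table

root = Path(__file__).resolve().parent.parent / "results"
parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--responses", type=Path, default=root / "data" / "responses.csv")
parser.add_argument("--out", type=Path, default=root / "slope_fits.csv")
args = parser.parse_args()

fits = fit_all(read_response_table(args.responses))
fits_to_frame(fits).to_csv(args.out, index=False)

print(f"fit {len(fits)} group x analyte cells (n = {fits[0].n} mice each)")
for f in fits:
    flag = "significant" if f.p_value < 0.05 else "not significant"
    print(f"  {f.group:12s} {f.analyte:6s} slope={f.slope:+.4f}/ug  p={f.p_value:.2e}  ({flag})")
print(f"wrote {args.out}")
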