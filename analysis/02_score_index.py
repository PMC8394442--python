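#!/usr/bin/env python
"""Score every rating of the simulated cohort with the CTD-IP index.

Reads results/synthetic/scores.csv, appends Z, P and the CTD-IP /
idiopathic label per (case, rater), and writes results/scored.csv.
"""

import argparse
from pathlib import Path

from ctdip import read_scores, score_table
from ctdip.io import write_scored

parser = argparse.ArgumentParser()
parser.add_argument("--scores", type=Path, default=Path("results/synthetic/scores.csv"))
parser.add_argument("--out", type=Path, default=Path("results/scored.csv"))
args = parser.parse_args()

scored = score_table(read_scores(args.scores))
write_scored(scored, args.out)

per_rater = scored.groupby("rater_id")["label"].apply(lambda s: (s == "CTD-IP").sum())
print(f"scored {len(scored)} ratings -> {args.out}")
print("CTD-IP votes per rater:")
for rater, n in per_rater.items():
    print(f"  {rater}: {n}/{scored['case_id'].nunique()}")
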