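#!/usr/bin/env python
"""Clinical comparison of the CTD vs idiopathic groups.

Fisher's exact test for the binary covariates (chi-squared as a
secondary column), pooled-variance t-tests on per-group summaries for
the continuous labs.  Writes results/table2.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ctdip import compare_groups, read_clinical

parser = argparse.ArgumentParser()
parser.add_argument("--clinical", type=Path,
                    default=Path("results/synthetic/clinical.csv"))
parser.add_argument("--groups", type=Path, default=Path("results/groups.csv"))
parser.add_argument("--out", type=Path, default=Path("results/table2.csv"))
args = parser.parse_args()

clinical = read_clinical(args.clinical)
groups = pd.read_csv(args.groups, dtype={"case_id": str})
table = compare_groups(clinical, groups)
args.out.parent.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out, index=False)

print(f"compared {len(table)} variables -> {args.out}")
binary = table[table["kind"] == "binary"]
for row in binary.itertuples():
    print(f"  {row.variable:14s} CTD {row.ctd_pos}/{row.ctd_n} vs "
          f"idiopathic {row.idio_pos}/{row.idio_n}  p = {row.p_display}")
signif = table[table["p_value"] < 0.05]["variable"].tolist()
print("p < 0.05:", ", ".join(signif) if signif else "none")
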