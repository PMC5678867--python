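"""Recompute statistics that follow directly from the published counts.

The published 72-patient validation cohort reports its classification
results as counts (non-metastatic / metastatic per score class).  Those
counts are inputs here: the script recomputes the association tests and
group proportions with this package's contingency machinery and writes
them to results/published_checks.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ppgl_grading import contingency_test

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/published_checks.csv"))
args = parser.parse_args()

# rows: score class (low/high risk), cols: (non-metastatic, metastatic)
TABLES = {
    "pass_dichotomy": [[35, 3], [22, 12]],  # PASS <4 vs >=4
    "mgapp_dichotomy": [[48, 5], [9, 10]],  # M-GAPP <3 vs >=3
    "gapp_dichotomy": [[29, 3], [28, 12]],  # WD vs MD+PD
    "gapp_classes": [[29, 3], [28, 8], [0, 4]],  # WD / MD / PD
    "sdhb_loss": [[51, 6], [10, 5]],  # staining retained vs lost
}

rows = []
for name, table in TABLES.items():
    for method in ("auto", "yates", "pearson", "fisher"):
        if len(table) > 2 and method != "auto" and method != "pearson":
            continue
        try:
            stat, p = contingency_test(table, method=method)
        except Exception:
            continue
        high = table[-1]
        rows.append(
            {
                "comparison": name,
                "method": method,
                "statistic": stat,
                "p": p,
                "high_risk_metastatic_pct": 100 * high[1] / (high[0] + high[1]),
            }
        )

frame = pd.DataFrame(rows)
args.out.parent.mkdir(parents=True, exist_ok=True)
frame.to_csv(args.out, index=False)
print(frame.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
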