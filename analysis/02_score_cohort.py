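"""Score every subject of the cohort with GAPP, PASS and M-GAPP.

Reads results/cohort.csv (written by 01_simulate_cohort.py, or any file in
the cohort schema), writes the per-subject score panel to
results/scores.csv and prints the score distributions by outcome group.
"""

import argparse
from pathlib import Path

from ppgl_grading import read_cohort
from ppgl_grading.pipeline_io import scores_frame

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
parser.add_argument("--out", type=Path, default=Path("results/scores.csv"))
args = parser.parse_args()

frame = scores_frame(read_cohort(args.cohort))
args.out.parent.mkdir(parents=True, exist_ok=True)
frame.to_csv(args.out, index=False)

print(f"scored {len(frame)} subjects -> {args.out}")
for col in ("gapp_score", "pass_score", "mgapp_score"):
    by = frame.groupby("metastasis")[col].median()
    print(
        f"  {col}: median {by.get(False, float('nan')):.1f} (non-metastatic) "
        f"vs {by.get(True, float('nan')):.1f} (metastatic)"
    )
print("  GAPP classes:", frame["gapp_class"].value_counts().to_dict())
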