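"""Run the full validation report on the cohort and print the headlines.

Produces every table under results/report/: baseline group comparisons,
Cox tables per scoring system, score distributions and classification
contingencies, the ROC/AUC comparison with DeLong tests, Kaplan-Meier
metastasis-free-survival curves with log-rank tests, and the score-vs-MFS
correlations.
"""

import argparse
from pathlib import Path

from ppgl_grading import read_cohort, run_validation

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
parser.add_argument("--out-dir", type=Path, default=Path("results/report"))
parser.add_argument("--ties", choices=["breslow", "efron"], default="breslow")
args = parser.parse_args()

report = run_validation(read_cohort(args.cohort), ties=args.ties)
report.write(args.out_dir)

print(f"report written to {args.out_dir}")
if not report.roc_table.empty:
    for _, row in report.roc_table.iterrows():
        print(
            f"  AUC {row['score']}: {row['auc']:.3f} "
            f"({row['ci_low']:.3f}-{row['ci_high']:.3f})"
        )
if not report.logrank_table.empty:
    for _, row in report.logrank_table.iterrows():
        print(f"  log-rank {row['system']}: chi2={row['chi2']:.2f}, P={row['p']:.4f}")
if not report.correlation_table.empty:
    for _, row in report.correlation_table.iterrows():
        print(f"  score-vs-MFS {row['score']}: r={row['pearson_r']:.3f}, P={row['p']:.3f}")
for reason in report.skipped:
    print(f"  skipped: {reason}")
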