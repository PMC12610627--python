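#!/usr/bin/env python
"""Statistical validation of the four trust measures against behavior.

Runs the dispersion battery (Shapiro-Wilk, variances, Kruskal-Wallis with
epsilon^2, Dunn-Bonferroni, ANOVA), the Pearson/Spearman/Kendall
correlation triad, and the three-level classification agreement analysis
(Cohen's kappa vs behavior, pairwise bootstrap kappa comparisons, the
EEG-vs-questionnaire confusion matrix). Writes results/report.json.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from trustfuse.pipeline import validate_scores


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--table", type=Path, default=Path("results/score_table_fused.csv"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/report.json"))
    args = ap.parse_args()

    table = pd.read_csv(args.table)
    report = validate_scores(table, seed=args.seed)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=1, sort_keys=True))

    kw = report["dispersion"]["kruskal"]
    print(f"Kruskal-Wallis: H = {kw['H']:.1f}, p = {kw['p']:.3g}, "
          f"epsilon^2 = {kw['epsilon_squared']:.2f}")
    print("variances:", {k: round(v, 2) for k, v in report["dispersion"]["variance"].items()})
    print("Spearman vs behavior:",
          {m: round(d["spearman_rho"], 2) for m, d in report["correlation_vs_behavior"].items()})
    print("kappa vs behavior:",
          {m: round(d["kappa"], 2) for m, d in report["classification"]["kappa_vs_behavior"].items()})
    print(f"report -> {args.out}")


if __name__ == "__main__":
    main()
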