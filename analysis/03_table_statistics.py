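#!/usr/bin/env python
"""Association statistics on the published suspicious-vs-metastatic 2x2.

The published node-level cross-tabulation (156 suspicious metastatic, 85
suspicious non-metastatic, 256 non-suspicious metastatic, 582
non-suspicious non-metastatic) is used as a literal input; this script
recomputes its chi-square decomposition (expected cells and per-cell
contributions), the odds ratio with Woolf interval, and the diagnostic
metrics, writing them to results/table_stats.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from lnconcord import (
    ContingencyTable2x2,
    diagnostic_metrics,
    odds_ratio,
    pearson_chi_square,
)
from lnconcord.reporting import render_chi_square

ROOT = Path(__file__).resolve().parents[1]
COUNTS = (156, 85, 256, 582)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "table_stats.csv")
    args = ap.parse_args()

    table = ContingencyTable2x2(*COUNTS)
    chi = pearson_chi_square(table)
    orr = odds_ratio(table)
    m = diagnostic_metrics(table)

    print("\n".join(render_chi_square(chi, COUNTS)))
    print(f"odds ratio {orr.odds_ratio:.4f} "
          f"(95% CI {orr.ci_low:.4f}-{orr.ci_high:.4f})")
    print(f"sensitivity {m.sensitivity:.3f}  specificity {m.specificity:.3f}  "
          f"PPV {m.ppv:.3f}  NPV {m.npv:.3f}")

    rows = [
        ("chi_square", chi.statistic),
        ("p_value", chi.p_value),
        ("expected_suspicious_lnm_pos", chi.expected[0, 0]),
        ("contribution_suspicious_lnm_pos", chi.contributions[0, 0]),
        ("odds_ratio", orr.odds_ratio),
        ("or_ci_low", orr.ci_low),
        ("or_ci_high", orr.ci_high),
        ("sensitivity", m.sensitivity),
        ("specificity", m.specificity),
        ("ppv", m.ppv),
        ("npv", m.npv),
    ]
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(args.out, index=False)
    print(f"\nwritten to {args.out}")


if __name__ == "__main__":
    main()
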