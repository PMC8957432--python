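#!/usr/bin/env python
"""Concordance analysis of the simulated cohort.

Reads results/cohort/ (produced by 01_simulate_cohort.py), matches CT and
histology nodes per patient-station, and writes the cohort summary
(band/site SPRs, LNR, four-way category counts, node- and patient-level
diagnostic metrics, per-pattern odds ratios) to results/concordance/.
"""

import argparse
from pathlib import Path

from lnconcord import (
    attach_station_outcome,
    cohort_summary,
    default_registry,
    pattern_association,
    station_concordance,
)
from lnconcord.io import read_cohort
from lnconcord.reporting import render_summary_text, summary_to_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "concordance")
    args = ap.parse_args()

    registry = default_registry()
    cohort = read_cohort(args.cohort)
    summary = cohort_summary(*cohort, registry)
    per_station = station_concordance(
        cohort.ct_nodes, cohort.histo_nodes, registry, by_patient=True
    )
    labelled = attach_station_outcome(cohort.ct_nodes, cohort.histo_nodes)
    ors = pattern_association(labelled[["pattern", "metastatic"]])

    args.out.mkdir(parents=True, exist_ok=True)
    summary_to_frame(summary).to_csv(args.out / "summary.csv", index=False)
    per_station.to_csv(args.out / "stations.csv", index=False)
    text = render_summary_text(summary, ors)
    (args.out / "report.txt").write_text(text)
    print(text)
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
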