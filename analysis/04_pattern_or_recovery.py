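#!/usr/bin/env python
"""Parameter-recovery study for the enhancement-pattern odds ratios.

Generates repeated calibrated cohorts at the study's size and re-estimates
the one-vs-rest pattern odds ratios from each, exactly as the concordance
pipeline estimates them from data.  Reports the median estimate per
pattern (the homogenous pattern additionally in its protective
orientation, odds of non-metastasis) and the realized node metastasis
rate, writing per-cohort estimates and the medians to results/recovery/.
"""

import argparse
import json
from pathlib import Path

from lnconcord import SimConfig, default_registry
from lnconcord.recovery import pattern_or_recovery, recovery_medians

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-cohorts", type=int, default=200)
    ap.add_argument("--seed", type=int, default=1,
                    help="first cohort seed; cohorts use seed..seed+n-1")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "recovery")
    args = ap.parse_args()

    seeds = range(args.seed, args.seed + args.n_cohorts)
    results = pattern_or_recovery(seeds, SimConfig(), default_registry())
    med = recovery_medians(results)

    args.out.mkdir(parents=True, exist_ok=True)
    results.to_csv(args.out / "per_cohort_ors.csv", index=False)
    (args.out / "medians.json").write_text(json.dumps(med, indent=2) + "\n")

    print(f"{len(results)} cohorts")
    print(f"median dotted OR (metastasis):            "
          f"{med['median_or_dotted']:.3f}   (generating target 7.84)")
    print(f"median homogenous OR (non-metastasis):    "
          f"{med['median_or_homogenous_nonmet']:.3f}   (generating target 1.99)")
    print(f"median linear OR: {med['median_or_linear']:.3f}  "
          f"central: {med['median_or_central']:.3f}  "
          f"peripheral: {med['median_or_peripheral']:.3f}")
    print(f"mean realized node metastasis rate:       "
          f"{med['mean_node_metastasis_rate']:.4f} (configured 0.0939)")
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
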