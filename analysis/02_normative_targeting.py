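#!/usr/bin/env python
"""Step 2 — normative targeting on the synthetic cohorts.

Simulates a healthy normative cohort, averages its denoised thalamic-seed
Fisher-z maps into a normative map, projects it to the cortical surface,
identifies the positive and negative peak sites (vertex + 6 mm geodesic
sphere), then evaluates those fixed sites in an independent patient/control
cohort: group t tests and FS14 correlations at vertex and sphere level.

Expected pattern: the negative site sits at (or next to) the planted
left-occipital-direction vertex, and patient FC there anticorrelates with
FS14 near the planted r = -0.3 (attenuated slightly by measurement noise).
"""

import argparse
from pathlib import Path

from thalatarget.pipeline import AnalysisConfig, run_analysis


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/02_normative"))
    ap.add_argument("--n", type=int, default=100,
                    help="subjects per cohort (normative, patients, controls)")
    args = ap.parse_args()

    cfg = AnalysisConfig(mode="normative", master_seed=args.seed,
                         n_patients=args.n, n_controls=args.n,
                         n_normative=args.n, out_dir=str(args.out))
    result = run_analysis(cfg)
    print(result.report_text)
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
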