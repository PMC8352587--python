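#!/usr/bin/env python
"""Insertion-centric H3K9me3 dynamics: lag and downstream asymmetry.

Builds per-timepoint IP coverage tracks, extracts oriented +/-10 kb signal
matrices around planted insertion junctions, and reports (i) the timepoint
of peak insertion-centric signal relative to the TE expression peak and
(ii) the median downstream/upstream asymmetry ratio under skew 3 vs skew 1.
Also annotates euchromatin from 10 kb IP/input enrichment windows.

Writes results/chromatin/{metaprofiles.tsv,asymmetry.tsv,euchromatin.bed}.
"""

import argparse
import os

import numpy as np
import pandas as pd

from burstchrom import assignquant, chromsig, simgen, studies
from burstchrom.orchestrate import PipelineConfig, StageParams, run_timecourse


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/chromatin")
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    summary = run_timecourse(
        PipelineConfig(sim=simgen.default_config(args.seed), params=StageParams(), seed=args.seed)
    )
    rows = [
        {"timepoint": tp, "central_rpm": summary["central_h3k9me3_rpm"][tp],
         "asymmetry_median": summary["asymmetry_median"][tp],
         "total_te_pct": summary["total_te_pct"][tp]}
        for tp in summary["timepoints"]
    ]
    pd.DataFrame(rows).to_csv(
        os.path.join(args.outdir, "metaprofiles.tsv"), sep="\t", index=False
    )
    print("per-timepoint central H3K9me3 rpm vs TE %:")
    for r in rows:
        print(f"  {r['timepoint']:>6}: {r['central_rpm']:6.1f} rpm | {r['total_te_pct']:5.2f}% TE")
    print(f"H3K9me3 peak {summary['chip_peak_timepoint']} trails "
          f"RNA peak {summary['rna_peak_timepoint']}: {summary['chip_trails_rna']}")

    asym = studies.asymmetry_study(args.seed)
    pd.DataFrame([asym]).to_csv(
        os.path.join(args.outdir, "asymmetry.tsv"), sep="\t", index=False
    )
    print(f"median asymmetry: skew 3 -> {asym['median_s3']:.3f}, "
          f"skew 1 -> {asym['median_s1']:.3f} "
          f"({asym['separation_sigma']:.1f} sigma apart)")

    eu = studies.euchromatin_study(args.seed)
    print(f"euchromatin boundaries recovered within {eu['boundary_error_bp']} bp "
          f"of the planted block (threshold-monotone: {eu['threshold_monotone']})")


if __name__ == "__main__":
    main()
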