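#!/usr/bin/env python
"""Build the two synthetic study genomes and write their ground truth.

Outputs (results/simulation/): reference and sample FASTA, the planted
insertion truth BED and the realized configuration, for both the
time-course strain (1 Mb, 100 insertions) and the sparser depletion strain
(2 Mb, 60 insertions).
"""

import argparse

from burstchrom import io, simgen


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/simulation")
    args = ap.parse_args()

    for name, cfg in (
        ("timecourse_strain", simgen.default_config(args.seed)),
        ("depletion_strain", simgen.depletion_config(args.seed)),
    ):
        reference, sample, truth = simgen.build_genome(cfg, args.seed)
        outdir = f"{args.outdir}/{name}"
        io.write_simulation(outdir, cfg, reference, sample, truth)
        n = len(truth.insertion_truth)
        by_fam = {}
        for ins in truth.insertion_truth:
            by_fam[ins.family] = by_fam.get(ins.family, 0) + 1
        print(f"{name}: {reference.total_length():,} bp reference, "
              f"{n} planted insertions {by_fam} -> {outdir}/")


if __name__ == "__main__":
    main()
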