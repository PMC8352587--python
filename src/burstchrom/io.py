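"""Plain-text readers/writers for the pipeline's standard formats.

FASTA goes through Biopython; FASTQ is written directly (fixed 'I' quality,
Phred+33) because the simulator has no per-base quality model. All interval
output is 0-based half-open (BED convention).
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import Insertion, ReadAssignment


def write_simulation(outdir, cfg, reference, sample, truth) -> None:
    """Write reference.fa / sample.fa, truth_insertions.bed and the realized
    configuration for one simulated genome build."""
    import dataclasses

    import yaml

    os.makedirs(outdir, exist_ok=True)
    write_fasta(os.path.join(outdir, "reference.fa"), reference.sequences)
    write_fasta(os.path.join(outdir, "sample.fa"), sample.sequences)
    write_insertions_bed(
        os.path.join(outdir, "truth_insertions.bed"), truth.insertion_truth
    )
    raw = dataclasses.asdict(cfg)
    raw["expression_profile"] = {
        f"{fam}@{tp}": v for (fam, tp), v in cfg.expression_profile.items()
    }
    with open(os.path.join(outdir, "realized_config.yaml"), "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def write_fasta(path: str | os.PathLike, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | os.PathLike, reads: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((header[1:].strip().split()[0], seq))
    return reads


def write_fastq_paired(
    path1: str | os.PathLike, path2: str | os.PathLike, pairs: Iterable[tuple[str, str, str]]
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, r1, r2 in pairs:
            f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def write_insertions_bed(path: str | os.PathLike, insertions: Iterable[Insertion]) -> None:
    """BED6 + support_left, support_right, midpoint columns."""
    with open(path, "w") as fh:
        for ins in insertions:
            score = ins.support_left + ins.support_right
            fh.write(
                f"{ins.chrom}\t{ins.start}\t{ins.end}\t{ins.family}\t{score}\t"
                f"{ins.strand}\t{ins.support_left}\t{ins.support_right}\t{ins.midpoint}\n"
            )


def read_insertions_bed(path: str | os.PathLike) -> list[Insertion]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sl = int(f[6]) if len(f) > 7 else 0
            sr = int(f[7]) if len(f) > 7 else 0
            out.append(
                Insertion(f[0], int(f[1]), int(f[2]), f[3], f[5], sl, sr)
            )
    return out


def write_assignments_tsv(
    path: str | os.PathLike, assignments: Iterable[ReadAssignment]
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmate\tcategory\ttarget\tpos\tstrand\tunique\tn_candidates\n")
        for a in assignments:
            fh.write(
                f"{a.read_id}\t{a.mate}\t{a.category}\t{a.target}\t{a.pos}\t"
                f"{a.strand}\t{int(a.unique)}\t{a.n_candidates}\n"
            )


def read_assignments_tsv(path: str | os.PathLike) -> list[ReadAssignment]:
    df = pd.read_csv(path, sep="\t", dtype={"target": str}, keep_default_na=False)
    return [
        ReadAssignment(
            r.read_id, str(r.mate), r.category, r.target, int(r.pos), r.strand,
            bool(r.unique), int(r.n_candidates),
        )
        for r in df.itertuples()
    ]


def write_bedgraph(
    path: str | os.PathLike, values_by_chrom: dict, bin_size: int
) -> None:
    """4-column bedGraph of a binned track (merges equal adjacent bins)."""
    with open(path, "w") as fh:
        for chrom, vals in values_by_chrom.items():
            run_start, run_val = 0, None
            for i, v in enumerate(vals):
                if run_val is None:
                    run_start, run_val = i, v
                elif v != run_val:
                    fh.write(
                        f"{chrom}\t{run_start * bin_size}\t{i * bin_size}\t{run_val:.6g}\n"
                    )
                    run_start, run_val = i, v
            if run_val is not None:
                fh.write(
                    f"{chrom}\t{run_start * bin_size}\t{len(vals) * bin_size}\t{run_val:.6g}\n"
                )
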