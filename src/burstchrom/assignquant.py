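"""Two-tier read assignment and rpm quantification.

Reads are resolved with the consensus-first policy used for TE
quantification: align to the TE consensus library first, allocating
multimappers randomly among equal-best families; only reads with no
consensus hit are aligned to the genome, where only unique hits are kept
(genome multimappers are discarded). The aligner is an exact k-mer
seed-and-verify surrogate (default k = 21, up to 2 mismatches over the full
read) — sufficient for synthetic reads and fully testable.

rpm normalisation divides by the library total = all TE-consensus plus
genome-mapped reads; the per-file scaling factor converts a per-file CPM
track onto that whole-library rpm scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GENOME, TE, UNMAPPED, ReadAssignment, revcomp


class SeqIndex:
    """Exact k-mer seed index over a set of named sequences (forward strand).

    Reverse-strand hits are found by querying the reverse complement of the
    read, so the index itself stores only forward k-mers.
    """

    def __init__(self, sequences: dict[str, str], k: int = 21):
        if k < 11:
            raise ValueError("k must be >= 11")
        if not sequences:
            raise ValueError("no sequences to index")
        names = list(sequences)
        if len(set(names)) != len(names):
            raise ValueError("duplicate sequence names")
        self.k = k
        self.names = names
        self.seqs = [sequences[n].upper() for n in names]
        index: dict[str, list[tuple[int, int]]] = {}
        for sid, seq in enumerate(self.seqs):
            for pos in range(0, len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((sid, pos))
        self.index = index

    def n_seed_positions(self) -> int:
        return sum(max(len(s) - self.k + 1, 0) for s in self.seqs)


def _count_mismatches(query: str, target: str, start: int, limit: int) -> int:
    sub = target[start : start + len(query)]
    if sub == query:
        return 0
    mm = 0
    for a, b in zip(query, sub):
        if a != b:
            mm += 1
            if mm > limit:
                return mm
    return mm


def find_hits(index: SeqIndex, seq: str, max_mismatches: int = 2):
    """All equal-best full-length hits of ``seq`` on both strands.

    Returns ``(hits, best_mm)`` with hits as ``(seq_id, start, strand)``.
    Seeds are taken every k bases; once a perfect (0-mismatch) hit is seen,
    later seeds cannot reveal further perfect hits and the scan stops.
    """
    k = index.k
    best = max_mismatches + 1
    hits: list[tuple[int, int, str]] = []
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        L = len(q)
        if L < k:
            continue
        seen: set[tuple[int, int]] = set()
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        for off in offsets:
            for sid, pos in index.index.get(q[off : off + k], ()):
                start = pos - off
                if start < 0 or start + L > len(index.seqs[sid]):
                    continue
                if (sid, start) in seen:
                    continue
                seen.add((sid, start))
                mm = _count_mismatches(q, index.seqs[sid], start, best)
                if mm < best:
                    best = mm
                    hits = [(sid, start, strand)]
                elif mm == best and mm <= max_mismatches:
                    hits.append((sid, start, strand))
            if best == 0:
                break
    if best > max_mismatches:
        return [], best
    return hits, best


def assign_read(
    seq: str,
    te_index: SeqIndex,
    genome_index: SeqIndex,
    max_mismatches: int,
    rng: np.random.Generator,
    read_id: str = "",
    mate: str = "single",
) -> ReadAssignment:
    """Resolve one read with the two-tier policy.

    Tier 1: any TE-consensus hit wins; equal-best families are broken by a
    uniform draw from ``rng`` (the generator state advances once per
    TE-assigned read, in input order). Tier 2: a single best genome locus is
    kept as a unique GENOME assignment. Everything else — no hit, or a
    genomic multimapper — is UNMAPPED.
    """
    te_hits, _ = find_hits(te_index, seq, max_mismatches)
    if te_hits:
        pick = te_hits[int(rng.integers(0, len(te_hits)))]
        sid, start, strand = pick
        fams = {h[0] for h in te_hits}
        return ReadAssignment(
            read_id, mate, TE, te_index.names[sid], start, strand,
            unique=len(fams) == 1, n_candidates=len(te_hits),
        )
    g_hits, _ = find_hits(genome_index, seq, max_mismatches)
    if len(g_hits) == 1:
        sid, start, strand = g_hits[0]
        return ReadAssignment(
            read_id, mate, GENOME, genome_index.names[sid], start, strand,
            unique=True, n_candidates=1,
        )
    return ReadAssignment(read_id, mate, UNMAPPED, "", -1, ".", False, len(g_hits))


def assign_reads(
    reads,
    te_index: SeqIndex,
    genome_index: SeqIndex,
    max_mismatches: int = 2,
    seed: int = 0,
) -> list[ReadAssignment]:
    """Assign single-end reads ``[(read_id, seq), ...]`` in input order."""
    rng = np.random.default_rng(seed)
    return [
        assign_read(seq, te_index, genome_index, max_mismatches, rng, rid)
        for rid, seq in reads
    ]


def assign_pairs(
    pairs,
    te_index: SeqIndex,
    genome_index: SeqIndex,
    max_mismatches: int = 2,
    seed: int = 0,
) -> list[tuple[ReadAssignment, ReadAssignment]]:
    """Assign paired-end reads ``[(read_id, r1, r2), ...]`` mate by mate."""
    rng = np.random.default_rng(seed)
    out = []
    for rid, r1, r2 in pairs:
        a1 = assign_read(r1, te_index, genome_index, max_mismatches, rng, rid, "1")
        a2 = assign_read(r2, te_index, genome_index, max_mismatches, rng, rid, "2")
        out.append((a1, a2))
    return out


# --------------------------------------------------------------------------
# counting and normalisation


@dataclass
class CountMatrix:
    """Feature x sample integer counts plus per-sample library totals.

    ``library_total`` is the rpm denominator: all TE-consensus plus
    genome-mapped reads of the sample (UNMAPPED reads are excluded).
    """

    counts: pd.DataFrame
    library_totals: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


def count_features(
    assignments, sample: str = "sample", all_features: list[str] | None = None
) -> CountMatrix:
    """Count assigned reads per TE family and per genome feature (chromosome).

    The library total is the number of TE plus GENOME assignments.
    """
    counts: dict[str, int] = dict.fromkeys(all_features or [], 0)
    total = 0
    for a in assignments:
        if a.category == UNMAPPED:
            continue
        counts[a.target] = counts.get(a.target, 0) + 1
        total += 1
    col = pd.Series(counts, dtype=int, name=sample).sort_index()
    return CountMatrix(col.to_frame(), pd.Series({sample: total}))


def combine_counts(matrices: list[CountMatrix]) -> CountMatrix:
    counts = pd.concat([m.counts for m in matrices], axis=1).fillna(0).astype(int)
    totals = pd.concat([m.library_totals for m in matrices])
    return CountMatrix(counts, totals)


def rpm_normalize(cm: CountMatrix) -> pd.DataFrame:
    """rpm(feature, sample) = count * 1e6 / library_total."""
    if (cm.library_totals <= 0).any():
        bad = cm.library_totals[cm.library_totals <= 0].index.tolist()
        raise ValueError(f"library total is zero for samples {bad}")
    return cm.counts * 1e6 / cm.library_totals


def scaling_factor(file_reads: int, library_total: int) -> float:
    """Multiplier converting a per-file CPM track onto the library rpm scale."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return file_reads / library_total


def te_fraction_timecourse(
    rpm_tables: dict[str, list[pd.Series] | pd.Series],
    te_families: list[str],
) -> pd.DataFrame:
    """Per-family and total TE transcriptome percentages per timepoint.

    ``rpm_tables`` maps timepoint -> rpm Series (or list of replicate
    Series). Output is tidy: one row per (timepoint, family) plus a
    ``total_TE`` row; percentages are rpm / 1e4 so that 17,000 rpm = 1.7%.
    Replicate mean and SD are reported when replicates are present.
    """
    rows = []
    for tp, tables in rpm_tables.items():
        reps = [tables] if isinstance(tables, pd.Series) else list(tables)
        mat = pd.concat(
            [t.reindex(te_families).fillna(0.0) for t in reps], axis=1
        )
        pct = mat / 1e4
        totals = pct.sum(axis=0)
        for fam in te_families:
            rows.append(
                {
                    "timepoint": tp,
                    "family": fam,
                    "rpm_mean": mat.loc[fam].mean(),
                    "pct_mean": pct.loc[fam].mean(),
                    "pct_sd": pct.loc[fam].std(ddof=1) if len(reps) > 1 else 0.0,
                }
            )
        rows.append(
            {
                "timepoint": tp,
                "family": "total_TE",
                "rpm_mean": mat.sum(axis=0).mean(),
                "pct_mean": totals.mean(),
                "pct_sd": totals.std(ddof=1) if len(reps) > 1 else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    fam_rows = df[df["family"] != "total_TE"]
    df["rank"] = fam_rows.groupby("timepoint")["pct_mean"].rank(
        ascending=False, method="first"
    )
    return df


def top_families(timecourse: pd.DataFrame, n: int = 30) -> list[str]:
    fam = timecourse[timecourse["family"] != "total_TE"]
    order = fam.groupby("family")["pct_mean"].max().sort_values(ascending=False)
    return order.index[:n].tolist()


# --------------------------------------------------------------------------
# SAM-subset ingestion (pre-aligned data bypassing the surrogate aligner)


def read_sam_assignments(path, te_names: set[str]) -> list[ReadAssignment]:
    """Minimal SAM reader: QNAME, FLAG, RNAME, POS, MAPQ.

    Category is TE when RNAME is a consensus name, else GENOME. Uniqueness
    follows the MAPQ=255 convention (255 codes a unique alignment); genomic
    multimappers are discarded as UNMAPPED per the two-tier policy. POS is
    converted from SAM 1-based to 0-based.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            qname, flag, rname, pos, mapq = f[0], int(f[1]), f[2], int(f[3]), int(f[4])
            mate = "1" if flag & 0x40 else ("2" if flag & 0x80 else "single")
            if flag & 0x4 or rname == "*":
                out.append(ReadAssignment(qname, mate))
                continue
            strand = "-" if flag & 0x10 else "+"
            unique = mapq == 255
            if rname in te_names:
                out.append(
                    ReadAssignment(qname, mate, TE, rname, pos - 1, strand, unique,
                                   1 if unique else 2)
                )
            elif unique:
                out.append(
                    ReadAssignment(qname, mate, GENOME, rname, pos - 1, strand, True, 1)
                )
            else:
                out.append(ReadAssignment(qname, mate, UNMAPPED, "", -1, ".", False, 2))
    return out
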