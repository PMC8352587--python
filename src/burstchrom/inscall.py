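"""Non-reference TE insertion calling from discordant read pairs.

Pairs with exactly one genome-unique mate and one TE-consensus mate are
junction evidence: a forward genome mate points rightward into the insertion
(left side), a reverse genome mate points leftward (right side). Per
(chromosome, family), anchors are single-linkage clustered and a cluster
becomes a call only when BOTH sides are supported (the "1p1" rule). The
element's strand is voted from the consensus strand of the TE mates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GENOME, TE, Insertion, ReadAssignment


@dataclass(slots=True)
class JunctionEvidence:
    pair_id: str
    side: str  # "left" | "right"
    chrom: str
    genome_anchor: int  # innermost genome coordinate of the genome mate
    genome_mate_strand: str
    family: str
    te_mate_consensus_strand: str
    te_mate_consensus_pos: int


def collect_evidence(
    pairs: list[tuple[ReadAssignment, ReadAssignment]],
    read_length: int,
) -> tuple[list[JunctionEvidence], dict[str, int]]:
    """Extract junction evidence from paired assignments (FR libraries).

    Returns the evidence list plus a summary of skipped pair classes.
    Anchors are innermost coordinates: the 3'-most base of a forward genome
    mate (left side) or the leftmost base of a reverse genome mate (right
    side).
    """
    evidence: list[JunctionEvidence] = []
    summary = {"te_te": 0, "genome_genome": 0, "with_unmapped": 0, "evidence": 0}
    for a1, a2 in pairs:
        cats = {a1.category, a2.category}
        if cats == {TE}:
            summary["te_te"] += 1
            continue
        if cats == {GENOME}:
            summary["genome_genome"] += 1
            continue
        if TE not in cats or GENOME not in cats:
            summary["with_unmapped"] += 1
            continue
        g, t = (a1, a2) if a1.category == GENOME else (a2, a1)
        if g.strand == "+":
            side, anchor = "left", g.pos + read_length - 1
        else:
            side, anchor = "right", g.pos
        evidence.append(
            JunctionEvidence(
                g.read_id, side, g.target, anchor, g.strand,
                t.target, t.strand, t.pos,
            )
        )
        summary["evidence"] += 1
    return evidence, summary


def infer_strand(cluster: list[JunctionEvidence]) -> str:
    """Majority vote over per-record strand votes; exact tie gives '.'.

    A record votes '+' when the TE mate hit the consensus minus strand from
    the left side or the plus strand from the right side (FR geometry);
    otherwise it votes '-'.
    """
    if not cluster:
        raise ValueError("empty evidence cluster")
    plus = sum(
        1
        for ev in cluster
        if (ev.side == "left") == (ev.te_mate_consensus_strand == "-")
    )
    minus = len(cluster) - plus
    if plus > minus:
        return "+"
    if minus > plus:
        return "-"
    return "."


def cluster_and_call(
    evidence: list[JunctionEvidence],
    max_gap: int,
    min_support_per_side: int = 1,
) -> list[Insertion]:
    """Single-linkage clustering of anchors into 1p1-filtered insertion calls.

    Per (chromosome, family), anchors within ``max_gap`` of their neighbour
    join one cluster; a cluster is called only with at least
    ``min_support_per_side`` records on EACH side. The junction interval is
    [innermost left anchor, innermost right anchor], collapsed to its
    midpoint if the sides interleave past each other.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    groups: dict[tuple[str, str], list[JunctionEvidence]] = {}
    for ev in evidence:
        groups.setdefault((ev.chrom, ev.family), []).append(ev)
    calls: list[Insertion] = []
    for (chrom, family), evs in sorted(groups.items()):
        evs.sort(key=lambda e: e.genome_anchor)
        cluster: list[JunctionEvidence] = []
        for ev in evs:
            if cluster and ev.genome_anchor - cluster[-1].genome_anchor > max_gap:
                call = _call_cluster(chrom, family, cluster, min_support_per_side)
                if call:
                    calls.append(call)
                cluster = []
            cluster.append(ev)
        if cluster:
            call = _call_cluster(chrom, family, cluster, min_support_per_side)
            if call:
                calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.start, c.family))
    return calls


def _call_cluster(
    chrom: str, family: str, cluster: list[JunctionEvidence], min_support: int
) -> Insertion | None:
    lefts = [ev.genome_anchor for ev in cluster if ev.side == "left"]
    rights = [ev.genome_anchor for ev in cluster if ev.side == "right"]
    if len(lefts) < min_support or len(rights) < min_support:
        return None
    start, end = max(lefts), min(rights)
    if start > end:
        start = end = (start + end) // 2
    return Insertion(
        chrom, start, end, family, infer_strand(cluster),
        support_left=len(lefts), support_right=len(rights), source="called",
    )


def default_max_gap(fragment_mean: float, fragment_sd: float) -> int:
    """All junction anchors of one insertion fall within one fragment span."""
    return int(fragment_mean + 3 * fragment_sd)


def evaluate_calls(
    calls: list[Insertion],
    truth: list[Insertion],
    position_tolerance: int = 50,
) -> dict:
    """Greedy 1-to-1 matching of calls to truth (same family, within
    tolerance of the junction midpoint) -> precision/recall/position
    error/strand accuracy. Precision is NaN for an empty call set."""
    candidates = []
    for ci, call in enumerate(calls):
        for ti, tr in enumerate(truth):
            if call.family != tr.family or call.chrom != tr.chrom:
                continue
            d = abs(call.midpoint - tr.midpoint)
            if d <= position_tolerance:
                candidates.append((d, ci, ti))
    candidates.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[int, int, int]] = []
    for d, ci, ti in candidates:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        matches.append((d, ci, ti))
    n_match = len(matches)
    strand_ok = sum(
        1
        for _, ci, ti in matches
        if truth[ti].strand == "." or calls[ci].strand == truth[ti].strand
    )
    return {
        "n_calls": len(calls),
        "n_truth": len(truth),
        "n_matched": n_match,
        "precision": n_match / len(calls) if calls else float("nan"),
        "recall": n_match / len(truth) if truth else float("nan"),
        "median_position_error": float(np.median([d for d, _, _ in matches]))
        if matches
        else float("nan"),
        "strand_accuracy": strand_ok / n_match if n_match else float("nan"),
    }
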