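"""Small RNA processing and piRNA profiling.

Raw reads carry a 3' sequencing adapter and four random nucleotides ligated
to each end of the insert. Processing clips the adapter (longest
prefix-of-adapter suffix match, 5 nt exact seed), drops reads shorter than
15 nt after clipping, trims 4 nt from each end, and keeps inserts of
19-31 nt (inclusive). Surviving inserts are assigned to TE consensus
sequences: a plus-strand hit is a sense read, a minus-strand hit (the read
is the reverse complement of consensus sequence) is antisense — the
orientation that matters, because maternally deposited piRNAs guiding Piwi
to TE transcripts are overwhelmingly antisense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assignquant import SeqIndex, find_hits

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"


@dataclass(slots=True)
class SmallRNARead:
    read_id: str
    insert: str
    length: int
    family: str = ""
    orientation: str = "unassigned"  # sense | antisense | unassigned


def _find_adapter(seq: str, adapter: str, seed_len: int = 5) -> int:
    """Leftmost position where a prefix of the adapter matches to read end.

    The first ``seed_len`` bases must match exactly; the rest of the overlap
    tolerates one mismatch per 10 nt. Returns -1 when no adapter is found.
    """
    full = seq.find(adapter)
    if full != -1:
        return full
    seed = adapter[:seed_len]
    L = len(seq)
    start = 0
    while True:
        i = seq.find(seed, start)
        if i == -1 or L - i < seed_len:
            return -1
        overlap = min(len(adapter), L - i)
        mm = sum(1 for a, b in zip(seq[i : i + overlap], adapter[:overlap]) if a != b)
        if mm <= overlap // 10:
            return i
        start = i + 1


def clip_and_trim(
    reads,
    adapter: str = DEFAULT_ADAPTER,
    min_len_postclip: int = 15,
    trim_each_side: int = 4,
    discard_unclipped: bool = False,
):
    """Adapter-clip and end-trim raw small RNA reads.

    Returns ``[(read_id, insert), ...]``. Reads with no detectable adapter
    are retained unclipped unless ``discard_unclipped``; reads shorter than
    ``min_len_postclip`` after clipping are dropped, then ``trim_each_side``
    bases are removed from both ends (the ligated random nucleotides).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    out = []
    for rid, seq in reads:
        pos = _find_adapter(seq, adapter)
        if pos == -1:
            if discard_unclipped:
                continue
            clipped = seq
        else:
            clipped = seq[:pos]
        if len(clipped) < min_len_postclip:
            continue
        insert = clipped[trim_each_side:-trim_each_side] if trim_each_side else clipped
        if insert:
            out.append((rid, insert))
    return out


def size_filter(reads, lo: int = 19, hi: int = 31):
    """Keep reads whose insert length lies in [lo, hi] (inclusive)."""
    return [(rid, seq) for rid, seq in reads if lo <= len(seq) <= hi]


def orient_and_assign(
    reads,
    te_index: SeqIndex,
    seed: int = 0,
    max_mismatches: int = 0,
) -> list[SmallRNARead]:
    """Assign processed inserts to TE families with orientation.

    A '+' strand consensus hit is sense, a '-' strand hit antisense.
    Multimapper ties are broken by a uniform seeded draw, as in genome-scale
    quantification.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rid, seq in reads:
        hits, _ = find_hits(te_index, seq, max_mismatches)
        if hits:
            sid, _, strand = hits[int(rng.integers(0, len(hits)))]
            out.append(
                SmallRNARead(
                    rid, seq, len(seq), te_index.names[sid],
                    "sense" if strand == "+" else "antisense",
                )
            )
        else:
            out.append(SmallRNARead(rid, seq, len(seq)))
    return out


def size_profile(assigned: list[SmallRNARead], lo: int = 19, hi: int = 31) -> pd.DataFrame:
    """Counts per insert length, split by orientation (assigned reads only)."""
    idx = range(lo, hi + 1)
    counts = {o: dict.fromkeys(idx, 0) for o in ("sense", "antisense", "unassigned")}
    for r in assigned:
        if lo <= r.length <= hi:
            counts[r.orientation][r.length] += 1
    df = pd.DataFrame(counts, index=list(idx))
    df.index.name = "length"
    return df


def antisense_fraction_table(
    assigned: list[SmallRNARead], top_n: int = 30
) -> pd.DataFrame:
    """Per-family percentage of all TE-mapping antisense reads.

    Percentages over ALL families sum to 100; the table is restricted to the
    ``top_n`` most antisense-abundant families.
    """
    anti = [r for r in assigned if r.orientation == "antisense"]
    if not anti:
        raise ValueError("no antisense TE-mapping reads")
    counts = pd.Series([r.family for r in anti]).value_counts()
    pct = 100.0 * counts / counts.sum()
    df = pd.DataFrame(
        {"family": counts.index, "antisense_reads": counts.values, "pct": pct.values}
    )
    return df.head(top_n).reset_index(drop=True)
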