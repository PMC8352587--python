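"""Shared domain types used across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(slots=True)
class Insertion:
    """A non-reference TE insertion junction.

    Coordinates are 0-based half-open on the *reference* assembly: ``start``
    and ``end`` bracket the junction interval (zero-length for planted truth
    records, anchor-delimited for calls). ``strand`` is the orientation of
    the inserted element; ``.`` marks an unresolved strand vote.
    """

    chrom: str
    start: int
    end: int
    family: str
    strand: str = "."
    support_left: int = 0
    support_right: int = 0
    source: str = "called"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"insertion interval inverted: {self.start} > {self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


# Read assignment categories (two-tier policy: TE consensus beats genome).
TE = "TE"
GENOME = "GENOME"
UNMAPPED = "UNMAPPED"


@dataclass(slots=True)
class ReadAssignment:
    """Resolved target of one sequencing read.

    ``category`` is ``TE`` (consensus hit, possibly randomly allocated among
    tied families), ``GENOME`` (unique genomic locus) or ``UNMAPPED``
    (no hit, or a genomic multimapper — those are discarded by policy).
    ``pos`` is the 0-based leftmost coordinate on the target.
    ``n_candidates`` counts equal-best hits before tie-breaking.
    """

    read_id: str
    mate: str = "single"  # "1", "2" or "single"
    category: str = UNMAPPED
    target: str = ""
    pos: int = -1
    strand: str = "."
    unique: bool = False
    n_candidates: int = 0

    def __post_init__(self) -> None:
        if self.category == GENOME and not self.unique:
            raise ValueError("GENOME assignments must be unique by policy")
        if self.category == UNMAPPED and self.target:
            raise ValueError("UNMAPPED assignments carry no target")


@dataclass
class RegionSet:
    """Named genomic intervals (0-based half-open), grouped per chromosome."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def total_length(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def overlaps(self, chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.intervals.get(chrom, ()))
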