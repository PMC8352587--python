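"""Synthetic genome and read simulation with full ground truth.

The generator emulates the data types of an embryonic TE-derepression study:

* a toy genome of euchromatic chromosomes (optionally carrying embedded
  constitutive-heterochromatin blocks) plus a small chr4-like chromosome;
* non-reference TE insertions: full-length family consensus copies spliced
  into the *sample* genome at positions that remain points on the
  *reference* genome (no target-site duplication);
* RNA-seq reads whose TE-derived fraction follows a configured per-timepoint
  expression profile (default: one dominant family peaking at 1.7% of the
  transcriptome and >70% of TE reads);
* H3K9me3 ChIP IP/input reads with an exponential enrichment kernel around
  each insertion, skewed downstream of the element's direction of
  transcription and scaled by a per-timepoint lag factor;
* paired-end WGS fragments (FR orientation) feeding the insertion caller;
* small RNA reads carrying 4 random nt on each side of the insert and a
  3' sequencing adapter, antisense-biased, 19-31 nt inserts.

Every emitted read carries exactly one truth tag, and identical config +
seed reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Insertion, RegionSet, revcomp

ADAPTER_3P = "AGATCGGAAGAGCACACGTCT"

EUCHROMATIN = "euchromatin"
HET_BLOCK = "heterochromatin_block"
CHR4_LIKE = "chr4_like"

# fixed stream ids so adding one library never perturbs another
_STREAMS = {"genome": 0, "rnaseq": 1, "chip": 2, "wgs": 3, "smallrna": 4}

_BASES = np.frombuffer(b"ATGC", dtype=np.uint8)


def child_rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Derive an independent generator for one library from a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream], index))
    )


# --------------------------------------------------------------------------
# configuration


@dataclass
class ChromSpec:
    name: str
    length: int
    cls: str = EUCHROMATIN
    # intervals of constitutive heterochromatin embedded in an otherwise
    # euchromatic chromosome (0-based half-open, reference coordinates)
    het_blocks: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class TEFamily:
    name: str
    length: int
    gc: float = 0.42


@dataclass
class ChipKernel:
    """Insertion-centric H3K9me3 enrichment model.

    IP read density relative to input at distance ``d`` from a junction is
    ``1 + (fold_enrichment - 1) * lag[t] * exp(-d / lam_side)`` with
    ``lam_side = decay_bp * downstream_skew`` on the downstream (3') side of
    the element and ``decay_bp`` upstream. ``lag`` maps timepoint labels to
    a kernel scale in [0, 1]; heterochromatin blocks and chr4-like
    chromosomes get constant ``het_fold`` / ``chr4_fold`` enrichment
    independent of timepoint.
    """

    fold_enrichment: float = 5.0
    decay_bp: float = 150.0
    downstream_skew: float = 3.0
    lag: dict[str, float] = field(default_factory=dict)
    het_fold: float = 8.0
    chr4_fold: float = 4.0


@dataclass
class WGSParams:
    fragment_mean: float = 500.0
    fragment_sd: float = 60.0
    read_length: int = 150
    coverage: float = 30.0


@dataclass
class SmallRNAParams:
    # per-family fraction of reads (over TE-mapping reads; remainder, if the
    # fractions sum to < 1, is random unassignable sequence)
    family_fractions: dict[str, float] = field(default_factory=dict)
    antisense_fraction: float = 0.8
    # length distribution over 19..31 nt; mode must sit in the piRNA range
    length_probs: dict[int, float] = field(default_factory=dict)


@dataclass
class SimConfig:
    master_seed: int = 0
    chroms: list[ChromSpec] = field(default_factory=list)
    families: list[TEFamily] = field(default_factory=list)
    n_insertions: dict[str, int] = field(default_factory=dict)
    plus_strand_prob: float = 0.5
    timepoints: list[str] = field(default_factory=list)
    # (family, timepoint) -> fraction of the transcriptome
    expression_profile: dict[tuple[str, str], float] = field(default_factory=dict)
    chip: ChipKernel = field(default_factory=ChipKernel)
    wgs: WGSParams = field(default_factory=WGSParams)
    smallrna: SmallRNAParams = field(default_factory=SmallRNAParams)
    error_rate: float = 0.0
    genome_gc: float = 0.42
    # between-replicate biological variability of ChIP composition: each
    # enrichment component's weight is scaled by an independent lognormal
    # factor per simulated library; repressive-compartment tiles (het
    # blocks, chr4-like) vary more than insertion kernels, reflecting the
    # variable IP efficiency of dense heterochromatin
    replicate_cv: float = 0.15
    het_replicate_cv: float = 0.3
    rna_read_length: int = 50
    chip_read_length: int = 50
    min_insertion_spacing: int = 3000

    def validate(self) -> None:
        if not self.chroms or not self.families:
            raise ValueError("config needs at least one chromosome and TE family")
        for fam in self.families:
            if not (0.0 <= fam.gc <= 1.0):
                raise ValueError(f"GC fraction out of [0,1] for {fam.name}")
        for tp in self.timepoints:
            tot = sum(
                self.expression_profile.get((f.name, tp), 0.0) for f in self.families
            )
            if tot > 1.0 + 1e-12:
                raise ValueError(f"expression fractions exceed 1 at {tp}")
        for (fam, tp), frac in self.expression_profile.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"expression fraction out of [0,1] for {fam}@{tp}")
        if self.wgs.read_length >= self.wgs.fragment_mean:
            raise ValueError("read length must be below the mean fragment length")
        for fam in self.families:
            if fam.length < 2 * self.wgs.read_length:
                raise ValueError(
                    f"consensus for {fam.name} shorter than 2 x WGS read length"
                )
        sr = self.smallrna
        if sr.length_probs:
            if any(not 19 <= ln <= 31 for ln in sr.length_probs):
                raise ValueError("small RNA length support must lie in [19, 31]")
            mode = max(sr.length_probs, key=sr.length_probs.get)
            if not 23 <= mode <= 28:
                raise ValueError("small RNA modal length must lie in [23, 28]")
        if not (0.0 <= sr.antisense_fraction <= 1.0):
            raise ValueError("antisense fraction out of [0,1]")
        if sum(sr.family_fractions.values()) > 1.0 + 1e-12:
            raise ValueError("small RNA family fractions exceed 1")
        if self.error_rate < 0:
            raise ValueError("error rate must be >= 0")
        if self.chip.fold_enrichment < 1 or self.chip.downstream_skew <= 0:
            raise ValueError("chip kernel requires fold >= 1 and skew > 0")


def default_config(master_seed: int = 0) -> SimConfig:
    """Toy-scale study conditions mirroring the embryonic burst design.

    One dominant family ("roo-like") peaks at 1.7% of the transcriptome at
    the 4-6 h timepoint, holding >70% of all TE reads there; the ChIP kernel
    lag peaks one timepoint later (6-8 h). Small RNA fractions put the
    dominant family at ~16% and the second family at ~9% of TE-mapping
    antisense reads.
    """
    timepoints = ["0-2h", "2-4h", "4-6h", "6-8h", "8-10h"]
    expr = {
        ("roo", "0-2h"): 0.0002,
        ("roo", "2-4h"): 0.008,
        ("roo", "4-6h"): 0.017,
        ("roo", "6-8h"): 0.009,
        ("roo", "8-10h"): 0.004,
        ("297", "0-2h"): 0.0002,
        ("297", "2-4h"): 0.001,
        ("297", "4-6h"): 0.002,
        ("297", "6-8h"): 0.0015,
        ("297", "8-10h"): 0.001,
        ("copia", "0-2h"): 0.0001,
        ("copia", "2-4h"): 0.0008,
        ("copia", "4-6h"): 0.0015,
        ("copia", "6-8h"): 0.001,
        ("copia", "8-10h"): 0.0008,
        ("mdg1", "0-2h"): 0.0001,
        ("mdg1", "2-4h"): 0.0003,
        ("mdg1", "4-6h"): 0.0005,
        ("mdg1", "6-8h"): 0.0004,
        ("mdg1", "8-10h"): 0.0003,
    }
    lag = {"0-2h": 0.05, "2-4h": 0.2, "4-6h": 0.6, "6-8h": 1.0, "8-10h": 0.8}
    length_probs = {
        19: 0.01, 20: 0.01, 21: 0.02, 22: 0.05, 23: 0.10, 24: 0.14, 25: 0.17,
        26: 0.18, 27: 0.14, 28: 0.10, 29: 0.04, 30: 0.02, 31: 0.02,
    }
    return SimConfig(
        master_seed=master_seed,
        chroms=[
            ChromSpec("chr2_toy", 500_000, EUCHROMATIN),
            ChromSpec("chr3_toy", 500_000, EUCHROMATIN, het_blocks=[(300_000, 400_000)]),
            ChromSpec("chr4_toy", 50_000, CHR4_LIKE),
        ],
        families=[
            TEFamily("roo", 6000, 0.45),
            TEFamily("297", 4500, 0.40),
            TEFamily("copia", 3500, 0.42),
            TEFamily("mdg1", 2500, 0.44),
        ],
        n_insertions={"roo": 60, "297": 25, "copia": 10, "mdg1": 5},
        timepoints=timepoints,
        expression_profile=expr,
        chip=ChipKernel(5.0, 150.0, 3.0, lag, het_fold=8.0),
        wgs=WGSParams(500.0, 60.0, 150, 30.0),
        smallrna=SmallRNAParams(
            family_fractions={"roo": 0.16, "297": 0.09, "copia": 0.40, "mdg1": 0.35},
            antisense_fraction=0.8,
            length_probs=length_probs,
        ),
    )


def depletion_config(master_seed: int = 0) -> SimConfig:
    """Study conditions for the effector-depletion comparison.

    Mirrors a degron-strain-like insertion landscape: a larger genome with
    sparser insertions than the time-course strain, so that genome-wide
    5 kb bins are predominantly kernel-free background — the regime in which
    bin-level differential analysis and attribution are meaningful.
    """
    cfg = default_config(master_seed)
    cfg.chroms = [
        ChromSpec("chr2_toy", 1_000_000, EUCHROMATIN),
        ChromSpec("chr3_toy", 1_000_000, EUCHROMATIN, het_blocks=[(600_000, 700_000)]),
        ChromSpec("chr4_toy", 50_000, CHR4_LIKE),
    ]
    cfg.n_insertions = {"roo": 41, "297": 13, "copia": 4, "mdg1": 2}
    cfg.min_insertion_spacing = 12_000
    return cfg


# --------------------------------------------------------------------------
# genome construction


@dataclass
class GenomeModel:
    sequences: dict[str, str]
    region_classes: dict[str, RegionSet]
    planted_insertions: list[Insertion] = field(default_factory=list)
    te_consensus: dict[str, str] = field(default_factory=dict)
    # for the sample genome: per planted insertion, its spliced interval in
    # sample coordinates (chrom, start, end)
    sample_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class SimTruth:
    """Ground truth emitted alongside each simulated library."""

    read_tags: pd.DataFrame = field(default_factory=pd.DataFrame)
    insertion_truth: list[Insertion] = field(default_factory=list)
    kernel_truth: dict = field(default_factory=dict)


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random nucleotide string with expected G+C fraction ``gc``."""
    at = (1.0 - gc) / 2.0
    cum = np.array([at, 2 * at, 2 * at + gc / 2.0, 1.0])
    idx = np.searchsorted(cum, rng.random(length), side="right")
    return _BASES[idx].tobytes().decode("ascii")


def _euchrom_intervals(spec: ChromSpec) -> list[tuple[int, int]]:
    if spec.cls != EUCHROMATIN:
        return []
    ivs, cur = [], 0
    for s, e in sorted(spec.het_blocks):
        if s > cur:
            ivs.append((cur, s))
        cur = max(cur, e)
    if cur < spec.length:
        ivs.append((cur, spec.length))
    return ivs


def build_genome(cfg: SimConfig, seed: int | None = None):
    """Build the reference/sample genome pair and the planted-insertion truth.

    The sample genome equals the reference with full-length consensus copies
    spliced at planted positions (no target-site duplication); the reference
    carries none. Returns ``(reference, sample, truth)``.
    """
    cfg.validate()
    rng = child_rng(cfg.master_seed if seed is None else seed, "genome")

    sequences = {c.name: random_sequence(rng, c.length, cfg.genome_gc) for c in cfg.chroms}
    consensus = {f.name: random_sequence(rng, f.length, f.gc) for f in cfg.families}

    region_classes = {
        EUCHROMATIN: RegionSet({}),
        HET_BLOCK: RegionSet({}),
        CHR4_LIKE: RegionSet({}),
    }
    for spec in cfg.chroms:
        if spec.cls == EUCHROMATIN:
            region_classes[EUCHROMATIN].intervals[spec.name] = _euchrom_intervals(spec)
            if spec.het_blocks:
                region_classes[HET_BLOCK].intervals[spec.name] = sorted(spec.het_blocks)
        else:
            region_classes[spec.cls].intervals[spec.name] = [(0, spec.length)]

    # eligible placement space: euchromatin minus an edge margin
    margin = 2000
    slots: list[tuple[str, int, int]] = []
    for chrom, ivs in region_classes[EUCHROMATIN].intervals.items():
        for s, e in ivs:
            if e - s > 2 * margin:
                slots.append((chrom, s + margin, e - margin))

    n_total = sum(cfg.n_insertions.get(f.name, 0) for f in cfg.families)
    insertions: list[Insertion] = []
    if n_total > 0:
        if not slots:
            raise ValueError("no euchromatic space available for insertions")
        lens = np.array([e - s for _, s, e in slots], dtype=float)
        counts = rng.multinomial(n_total, lens / lens.sum())
        d = cfg.min_insertion_spacing
        positions: list[tuple[str, int]] = []
        for (chrom, s, e), n_iv in zip(slots, counts):
            if n_iv == 0:
                continue
            usable = (e - s) - (n_iv - 1) * d
            if usable <= 0:
                raise ValueError(
                    f"insertion count infeasible for euchromatic space on {chrom}"
                )
            u = np.sort(rng.random(n_iv)) * usable
            pos = (s + u + np.arange(n_iv) * d).astype(int)
            positions.extend((chrom, int(p)) for p in pos)
        order = rng.permutation(n_total)
        fam_labels = np.repeat(
            [f.name for f in cfg.families],
            [cfg.n_insertions.get(f.name, 0) for f in cfg.families],
        )[order]
        strands = np.where(rng.random(n_total) < cfg.plus_strand_prob, "+", "-")
        for (chrom, p), fam, strand in zip(positions, fam_labels, strands):
            insertions.append(Insertion(chrom, p, p, str(fam), str(strand), source="planted"))
        insertions.sort(key=lambda i: (i.chrom, i.start))

    # planted insertions are reference-coordinate annotations: the reference
    # model carries them as metadata even though its sequence lacks the copies
    reference = GenomeModel(sequences, region_classes, insertions, consensus)

    sample_seqs: dict[str, str] = {}
    sample_intervals: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[Insertion]] = {}
    for ins in insertions:
        by_chrom.setdefault(ins.chrom, []).append(ins)
    idx_of = {id(ins): i for i, ins in enumerate(insertions)}
    sample_intervals = [("", 0, 0)] * len(insertions)
    for chrom, seq in sequences.items():
        parts, cur, offset = [], 0, 0
        for ins in by_chrom.get(chrom, []):
            parts.append(seq[cur : ins.start])
            te = consensus[ins.family]
            if ins.strand == "-":
                te = revcomp(te)
            s_start = ins.start + offset
            sample_intervals[idx_of[id(ins)]] = (chrom, s_start, s_start + len(te))
            parts.append(te)
            offset += len(te)
            cur = ins.start
        parts.append(seq[cur:])
        sample_seqs[chrom] = "".join(parts)

    sample = GenomeModel(
        sample_seqs, region_classes, insertions, consensus, sample_intervals
    )
    truth = SimTruth(insertion_truth=insertions, kernel_truth={})
    return reference, sample, truth


# --------------------------------------------------------------------------
# read simulation helpers


def _apply_errors(rng: np.random.Generator, seqs: list[str], rate: float) -> list[str]:
    if rate <= 0:
        return seqs
    out = []
    alphabet = "ACGT"
    for s in seqs:
        n_err = rng.binomial(len(s), rate)
        if n_err == 0:
            out.append(s)
            continue
        arr = list(s)
        for p in rng.integers(0, len(s), size=n_err):
            cur = arr[p]
            arr[p] = alphabet[(alphabet.index(cur) + int(rng.integers(1, 4))) % 4]
        out.append("".join(arr))
    return out


def _uniform_genome_positions(
    rng: np.random.Generator,
    intervals: list[tuple[str, int, int]],
    n: int,
    read_length: int,
):
    """Uniform read-start positions over a set of (chrom, start, end) intervals."""
    lens = np.array([max(e - s - read_length, 1) for _, s, e in intervals], dtype=float)
    which = rng.choice(len(intervals), size=n, p=lens / lens.sum())
    offs = rng.random(n)
    chroms, starts = [], np.empty(n, dtype=int)
    for i, (w, o) in enumerate(zip(which, offs)):
        chrom, s, e = intervals[w]
        chroms.append(chrom)
        starts[i] = s + int(o * max(e - s - read_length, 1))
    return chroms, starts


# --------------------------------------------------------------------------
# RNA-seq


def simulate_rnaseq(
    genome: GenomeModel,
    cfg: SimConfig,
    timepoint: str,
    n_reads: int,
    seed: int,
    read_length: int | None = None,
):
    """Simulate one poly(A) RNA-seq library at one timepoint.

    Each read comes from a TE family's consensus (sense strand of the
    transcript, uniform position) with its configured transcriptome fraction,
    or otherwise from background "genic" euchromatic sequence. Returns
    ``(reads, truth)`` where reads is a list of ``(read_id, seq)``.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    fams = [f.name for f in cfg.families]
    fracs = np.array(
        [cfg.expression_profile.get((f, timepoint), 0.0) for f in fams]
    )
    if timepoint not in cfg.timepoints:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    rl = cfg.rna_read_length if read_length is None else read_length
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS["rnaseq"],)))

    probs = np.append(fracs, 1.0 - fracs.sum())
    cats = rng.choice(len(fams) + 1, size=n_reads, p=probs)

    origin = np.empty(n_reads, dtype=object)
    target = np.empty(n_reads, dtype=object)
    posv = np.zeros(n_reads, dtype=int)
    strandv = np.empty(n_reads, dtype=object)
    seqs: list[str | None] = [None] * n_reads

    for j, fam in enumerate(fams):
        idx = np.flatnonzero(cats == j)
        if idx.size == 0:
            continue
        cons = genome.te_consensus[fam]
        pos = rng.integers(0, len(cons) - rl + 1, size=idx.size)
        for i, p in zip(idx, pos):
            seqs[i] = cons[p : p + rl]
        origin[idx], target[idx], posv[idx], strandv[idx] = "TE", fam, pos, "+"

    bg = np.flatnonzero(cats == len(fams))
    if bg.size:
        eu = [
            (c, s, e)
            for c, ivs in genome.region_classes[EUCHROMATIN].intervals.items()
            for s, e in ivs
        ]
        chroms, starts = _uniform_genome_positions(rng, eu, bg.size, rl)
        rev = rng.random(bg.size) < 0.5
        for i, chrom, s, r in zip(bg, chroms, starts, rev):
            frag = genome.sequences[chrom][s : s + rl]
            seqs[i] = revcomp(frag) if r else frag
        origin[bg] = "genome"
        target[bg] = chroms
        posv[bg] = starts
        strandv[bg] = np.where(rev, "-", "+")

    seqs = _apply_errors(rng, seqs, cfg.error_rate)
    ids = [f"rna_{timepoint}_{i}" for i in range(n_reads)]
    reads = list(zip(ids, seqs))
    truth = SimTruth(
        read_tags=pd.DataFrame(
            {
                "read_id": ids,
                "origin": origin,
                "target": target,
                "pos": posv,
                "strand": strandv,
                "timepoint": timepoint,
            }
        )
    )
    return reads, truth


# --------------------------------------------------------------------------
# ChIP-seq


def kernel_density(d: np.ndarray, downstream: bool, kernel: ChipKernel, lag: float):
    """Closed-form IP/input density ratio at distance ``d`` from a junction."""
    lam = kernel.decay_bp * (kernel.downstream_skew if downstream else 1.0)
    return 1.0 + (kernel.fold_enrichment - 1.0) * lag * np.exp(-np.asarray(d) / lam)


def simulate_chip(
    genome: GenomeModel,
    cfg: SimConfig,
    timepoint: str,
    n_reads_ip: int,
    n_reads_input: int,
    seed: int,
    read_length: int | None = None,
    kernel_off_families: frozenset[str] | set[str] = frozenset(),
):
    """Simulate an H3K9me3 IP/input library pair at one timepoint.

    ``genome`` must be the reference-coordinate model carrying the planted
    insertions (junctions are points in reference coordinates; the inserted
    consensus itself is not sampled). Input reads are uniform; IP reads mix
    a uniform background, constant ``het_fold`` enrichment over embedded
    heterochromatin blocks, and the per-insertion exponential kernel scaled
    by ``lag[timepoint]`` and skewed downstream. Families listed in
    ``kernel_off_families`` get no insertion kernel (models loss of
    piRNA-guided deposition upon effector depletion). Returns
    ``(ip_reads, input_reads, truth)``.
    """
    kern = cfg.chip
    if timepoint not in kern.lag:
        raise ValueError(f"timepoint {timepoint!r} missing from chip lag map")
    lag = kern.lag[timepoint]
    rl = cfg.chip_read_length if read_length is None else read_length
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS["chip"],)))

    chrom_names = list(genome.sequences)
    chrom_lens = genome.chrom_lengths
    genome_ivs = [(c, 0, chrom_lens[c]) for c in chrom_names]
    total_len = float(genome.total_length())

    insertions = genome.planted_insertions
    # repressive compartments are tiled so replicate variability is local,
    # not a single coherent block-wide factor
    het_tile = 5000
    het_blocks = []
    for cls, fold in ((HET_BLOCK, kern.het_fold), (CHR4_LIKE, kern.chr4_fold)):
        for c, ivs in genome.region_classes[cls].intervals.items():
            for s, e in ivs:
                for ts in range(s, e, het_tile):
                    het_blocks.append((c, ts, min(ts + het_tile, e), fold))
    excess_ins = max(kern.fold_enrichment - 1.0, 0.0) * lag * kern.decay_bp * (
        1.0 + kern.downstream_skew
    )
    weights = [total_len]
    weights += [(fold - 1.0) * (e - s) for _, s, e, fold in het_blocks]
    weights += [
        0.0 if ins.family in kernel_off_families else excess_ins
        for ins in insertions
    ]
    weights = np.array(weights, dtype=float)
    cvs = np.concatenate(
        [
            [0.0],  # the uniform background is the stable reference
            np.full(len(het_blocks), cfg.het_replicate_cv),
            np.full(len(insertions), cfg.replicate_cv),
        ]
    )
    if (cvs > 0).any():
        sigma = np.sqrt(np.log1p(cvs**2))
        weights = weights * rng.lognormal(-(sigma**2) / 2, sigma)

    def emit(n: int, enriched: bool):
        if n <= 0:
            return [], SimTruth()
        if enriched and weights.sum() > 0:
            counts = rng.multinomial(n, weights / weights.sum())
        else:
            counts = np.zeros(len(weights), dtype=int)
            counts[0] = n
        chroms: list[str] = []
        starts: list[int] = []
        comps: list[str] = []
        # background
        c0, s0 = _uniform_genome_positions(rng, genome_ivs, counts[0], rl)
        chroms += c0
        starts += list(s0)
        comps += ["background"] * counts[0]
        # repressive-compartment tiles
        for (chrom, s, e, _fold), nb in zip(het_blocks, counts[1 : 1 + len(het_blocks)]):
            if nb == 0:
                continue
            p = rng.integers(s, max(e - rl, s + 1), size=nb)
            chroms += [chrom] * nb
            starts += list(p)
            comps += ["het_block"] * nb
        # insertion kernels
        for ins, ni in zip(insertions, counts[1 + len(het_blocks) :]):
            if ni == 0:
                continue
            skew = kern.downstream_skew
            down = rng.random(ni) < skew / (1.0 + skew)
            lam = np.where(down, kern.decay_bp * skew, kern.decay_bp)
            dist = rng.exponential(lam)
            sign = np.where(down, 1, -1) * (1 if ins.strand == "+" else -1)
            center = ins.midpoint + sign * dist
            p = np.clip(center.astype(int) - rl // 2, 0, chrom_lens[ins.chrom] - rl)
            chroms += [ins.chrom] * ni
            starts += list(p)
            comps += [f"insertion:{ins.chrom}:{ins.start}:{ins.family}"] * ni
        order = rng.permutation(n)
        chroms = [chroms[i] for i in order]
        starts = [starts[i] for i in order]
        comps = [comps[i] for i in order]
        seqs = [genome.sequences[c][p : p + rl] for c, p in zip(chroms, starts)]
        rev = rng.random(n) < 0.5
        seqs = [revcomp(s) if r else s for s, r in zip(seqs, rev)]
        seqs = _apply_errors(rng, seqs, cfg.error_rate)
        prefix = "ip" if enriched else "input"
        ids = [f"chip_{prefix}_{timepoint}_{i}" for i in range(n)]
        tags = pd.DataFrame(
            {
                "read_id": ids,
                "origin": comps,
                "target": chroms,
                "pos": starts,
                "strand": np.where(rev, "-", "+"),
                "timepoint": timepoint,
            }
        )
        return list(zip(ids, seqs)), SimTruth(read_tags=tags)

    ip_reads, ip_truth = emit(n_reads_ip, enriched=True)
    input_reads, input_truth = emit(n_reads_input, enriched=False)
    truth = SimTruth(
        read_tags=pd.concat(
            [ip_truth.read_tags, input_truth.read_tags], ignore_index=True
        )
        if n_reads_ip or n_reads_input
        else pd.DataFrame(),
        kernel_truth={
            "fold_enrichment": kern.fold_enrichment,
            "decay_bp": kern.decay_bp,
            "downstream_skew": kern.downstream_skew,
            "lag": lag,
            "het_fold": kern.het_fold,
        },
    )
    return ip_reads, input_reads, truth


# --------------------------------------------------------------------------
# WGS


def simulate_wgs(sample: GenomeModel, cfg: SimConfig, seed: int):
    """Simulate paired-end WGS from the *sample* genome (FR orientation).

    Fragment count is Poisson at ``coverage * genome_length / (2 * read_length)``;
    mate 1 is the forward read-length prefix of the fragment, mate 2 the
    reverse complement of its suffix. Fragments spanning a splice junction of
    a planted insertion are flagged ``junction`` in the truth table
    (coordinates are sample-genome coordinates).
    """
    w = cfg.wgs
    rl = w.read_length
    total = sample.total_length()
    rate = w.coverage * total / (2.0 * rl)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS["wgs"],)))
    n_pairs = int(rng.poisson(rate)) if rate > 0 else 0
    if n_pairs == 0:
        return [], SimTruth(read_tags=pd.DataFrame())

    chrom_names = list(sample.sequences)
    lens = np.array([len(sample.sequences[c]) for c in chrom_names], dtype=float)
    which = rng.choice(len(chrom_names), size=n_pairs, p=lens / lens.sum())
    flen = np.clip(
        np.round(rng.normal(w.fragment_mean, w.fragment_sd, size=n_pairs)), rl, None
    ).astype(int)

    junctions: dict[str, np.ndarray] = {}
    for chrom, s, e in sample.sample_intervals:
        junctions.setdefault(chrom, [])
        junctions[chrom].extend([s, e])
    junctions = {c: np.array(sorted(v)) for c, v in junctions.items()}

    reads = []
    rows = {"read_id": [], "chrom": [], "start": [], "frag_len": [], "junction": []}
    for i in range(n_pairs):
        chrom = chrom_names[which[i]]
        seq = sample.sequences[chrom]
        L = len(seq)
        fl = min(flen[i], L)
        start = int(rng.integers(0, L - fl + 1))
        frag = seq[start : start + fl]
        r1, r2 = frag[:rl], revcomp(frag[-rl:])
        rid = f"wgs_{i}"
        reads.append((rid, r1, r2))
        js = junctions.get(chrom)
        has_j = bool(js is not None and np.any((js > start) & (js < start + fl)))
        rows["read_id"].append(rid)
        rows["chrom"].append(chrom)
        rows["start"].append(start)
        rows["frag_len"].append(fl)
        rows["junction"].append(has_j)
    if cfg.error_rate > 0:
        r1s = _apply_errors(rng, [r[1] for r in reads], cfg.error_rate)
        r2s = _apply_errors(rng, [r[2] for r in reads], cfg.error_rate)
        reads = [(r[0], a, b) for r, a, b in zip(reads, r1s, r2s)]
    truth = SimTruth(
        read_tags=pd.DataFrame(rows), insertion_truth=sample.planted_insertions
    )
    return reads, truth


# --------------------------------------------------------------------------
# small RNA


def simulate_smallrna(genome: GenomeModel, cfg: SimConfig, n_reads: int, seed: int):
    """Simulate a Piwi-bound small RNA library.

    Each raw read is ``4 random nt + insert + 4 random nt + 3' adapter``;
    the insert is a consensus subsequence in sense or antisense orientation
    (antisense with the configured probability), with length drawn from the
    configured 19-31 nt distribution. Reads not allocated to a family are
    random sequence (unassignable background).
    """
    sr = cfg.smallrna
    if not sr.length_probs:
        raise ValueError("small RNA length distribution not configured")
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS["smallrna"],))
    )
    fams = list(sr.family_fractions)
    probs = np.array([sr.family_fractions[f] for f in fams])
    probs = np.append(probs, max(1.0 - probs.sum(), 0.0))
    cats = rng.choice(len(fams) + 1, size=n_reads, p=probs / probs.sum())
    lengths_support = np.array(sorted(sr.length_probs))
    lp = np.array([sr.length_probs[int(ln)] for ln in lengths_support], dtype=float)
    lens = rng.choice(lengths_support, size=n_reads, p=lp / lp.sum())
    anti = rng.random(n_reads) < sr.antisense_fraction

    reads, fam_col, orient_col, ilen_col, insert_col = [], [], [], [], []
    for i in range(n_reads):
        ln = int(lens[i])
        if cats[i] < len(fams):
            fam = fams[cats[i]]
            cons = genome.te_consensus[fam]
            p = int(rng.integers(0, len(cons) - ln + 1))
            insert = cons[p : p + ln]
            orientation = "sense"
            if anti[i]:
                insert = revcomp(insert)
                orientation = "antisense"
        else:
            fam, orientation = "", "none"
            insert = random_sequence(rng, ln, 0.5)
        left = random_sequence(rng, 4, 0.5)
        right = random_sequence(rng, 4, 0.5)
        reads.append((f"srna_{i}", left + insert + right + ADAPTER_3P))
        fam_col.append(fam)
        orient_col.append(orientation)
        ilen_col.append(ln)
        insert_col.append(insert)
    truth = SimTruth(
        read_tags=pd.DataFrame(
            {
                "read_id": [r[0] for r in reads],
                "family": fam_col,
                "orientation": orient_col,
                "insert_length": ilen_col,
                "insert": insert_col,
            }
        )
    )
    return reads, truth
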