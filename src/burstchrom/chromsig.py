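"""Coverage tracks, enrichment windows and insertion-centric signal analysis.

Tracks are rpm-scaled mean per-base coverage in fixed bins (default 10 bp).
Euchromatin is defined operationally: 10 kb windows whose log2 IP/input
enrichment stays below a threshold. Signal matrices around insertion
junctions are oriented so that increasing column index always points
downstream of the element's 5'->3' direction, which makes the downstream
asymmetry of repressive-mark deposition directly measurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import GENOME, Insertion, ReadAssignment, RegionSet


@dataclass
class CoverageTrack:
    bin_size: int
    values: dict[str, np.ndarray]
    library_total: int
    chrom_lengths: dict[str, int]

    def mean_rpm(self) -> float:
        num = sum(v.sum() * self.bin_size for v in self.values.values())
        return num / sum(self.chrom_lengths.values())


def coverage_track(
    assignments: list[ReadAssignment],
    chrom_lengths: dict[str, int],
    library_total: int,
    bin_size: int = 10,
    read_length: int = 50,
) -> CoverageTrack:
    """rpm coverage track from genome-assigned reads.

    Each read contributes its per-base overlap; a bin's value is its mean
    per-base coverage times 1e6/library_total (the final partial bin is
    averaged over its true length). Reads running past the chromosome end
    are clipped and counted in a warning.
    """
    if library_total <= 0:
        raise ValueError("library total must be positive")
    diffs = {c: np.zeros(length + 1) for c, length in chrom_lengths.items()}
    clipped = 0
    for a in assignments:
        if a.category != GENOME or a.target not in diffs:
            continue
        L = chrom_lengths[a.target]
        start = min(max(a.pos, 0), L)
        end = a.pos + read_length
        if end > L:
            clipped += 1
            end = L
        diffs[a.target][start] += 1
        diffs[a.target][end] -= 1
    if clipped:
        warnings.warn(f"{clipped} reads clipped at chromosome ends", stacklevel=2)
    scale = 1e6 / library_total
    values = {}
    for chrom, diff in diffs.items():
        L = chrom_lengths[chrom]
        per_base = np.cumsum(diff[:-1])
        n_bins = -(-L // bin_size)
        padded = np.zeros(n_bins * bin_size)
        padded[:L] = per_base
        sums = padded.reshape(n_bins, bin_size).sum(axis=1)
        widths = np.full(n_bins, bin_size, dtype=float)
        if L % bin_size:
            widths[-1] = L % bin_size
        values[chrom] = sums / widths * scale
    return CoverageTrack(bin_size, values, library_total, dict(chrom_lengths))


def pooled_track(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Pool replicate tracks as if their reads were concatenated."""
    total = sum(t.library_total for t in tracks)
    base = tracks[0]
    values = {
        c: sum(t.values[c] * t.library_total for t in tracks) / total
        for c in base.values
    }
    return CoverageTrack(base.bin_size, values, total, dict(base.chrom_lengths))


# --------------------------------------------------------------------------
# enrichment windows and euchromatin annotation


def window_enrichment(
    ip: CoverageTrack,
    inp: CoverageTrack,
    window: int = 10_000,
    step: int | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """log2((ip_rpm + psi)/(input_rpm + psi)) in sliding windows.

    The step defaults to the window (non-overlapping). Both tracks must
    share the bin size and chromosome set.
    """
    if ip.bin_size != inp.bin_size or set(ip.values) != set(inp.values):
        raise ValueError("tracks must share bin size and chromosomes")
    step = window if step is None else step
    bs = ip.bin_size
    wbins, sbins = max(window // bs, 1), max(step // bs, 1)
    rows = []
    for chrom, vals in ip.values.items():
        other = inp.values[chrom]
        for start_bin in range(0, len(vals), sbins):
            seg_ip = vals[start_bin : start_bin + wbins]
            seg_in = other[start_bin : start_bin + wbins]
            ip_mean, in_mean = seg_ip.mean(), seg_in.mean()
            rows.append(
                {
                    "chrom": chrom,
                    "start": start_bin * bs,
                    "end": min((start_bin + wbins) * bs, ip.chrom_lengths[chrom]),
                    "ip_rpm": ip_mean,
                    "input_rpm": in_mean,
                    "enrichment": np.log2((ip_mean + pseudocount) / (in_mean + pseudocount)),
                }
            )
    return pd.DataFrame(rows)


def call_euchromatin(windows: pd.DataFrame, tau: float = 1.0) -> RegionSet:
    """Maximal runs of windows with enrichment below ``tau``, merged.

    The complement of the result is heterochromatic. Default tau = log2(2),
    i.e. 2-fold IP/input enrichment.
    """
    regions: dict[str, list[tuple[int, int]]] = {}
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        ivs: list[tuple[int, int]] = []
        for _, row in grp.iterrows():
            if row["enrichment"] < tau:
                if ivs and ivs[-1][1] >= row["start"]:
                    ivs[-1] = (ivs[-1][0], int(row["end"]))
                else:
                    ivs.append((int(row["start"]), int(row["end"])))
        regions[chrom] = ivs
    return RegionSet(regions)


# --------------------------------------------------------------------------
# insertion-centric matrices


@dataclass
class SignalMatrix:
    """Oriented per-insertion signal rows around junction midpoints.

    Rows follow ``insertions``; columns span [-flank, +flank) in track bins,
    reversed for '-' strand insertions so that increasing column index is
    downstream of the element. Out-of-chromosome bins are NaN and excluded
    from all statistics.
    """

    values: np.ndarray
    insertions: list[Insertion]
    bin_size: int
    flank: int
    families: list[str] = field(default_factory=list)
    strands: list[str] = field(default_factory=list)

    def sorted_by_position(self) -> "SignalMatrix":
        order = sorted(
            range(len(self.insertions)),
            key=lambda i: (self.insertions[i].chrom, self.insertions[i].start),
        )
        return SignalMatrix(
            self.values[order],
            [self.insertions[i] for i in order],
            self.bin_size,
            self.flank,
            [self.families[i] for i in order],
            [self.strands[i] for i in order],
        )


def insertion_matrix(
    track: CoverageTrack,
    insertions: list[Insertion],
    flank: int = 10_000,
) -> SignalMatrix:
    if flank % track.bin_size:
        raise ValueError("flank must be a multiple of the bin size")
    n_cols = 2 * flank // track.bin_size
    half = flank // track.bin_size
    rows, kept = [], []
    skipped = 0
    for ins in insertions:
        vals = track.values.get(ins.chrom)
        if vals is None:
            skipped += 1
            continue
        center_bin = ins.midpoint // track.bin_size
        lo, hi = center_bin - half, center_bin + half
        row = np.full(n_cols, np.nan)
        src_lo, src_hi = max(lo, 0), min(hi, len(vals))
        if src_hi > src_lo:
            row[src_lo - lo : src_hi - lo] = vals[src_lo:src_hi]
        if ins.strand == "-":
            row = row[::-1]
        rows.append(row)
        kept.append(ins)
    if skipped:
        warnings.warn(f"{skipped} insertions on unknown chromosomes skipped", stacklevel=2)
    values = np.array(rows) if rows else np.empty((0, n_cols))
    return SignalMatrix(
        values, kept, track.bin_size, flank,
        [i.family for i in kept], [i.strand for i in kept],
    )


def metaprofile(matrix: SignalMatrix) -> pd.DataFrame:
    """NaN-masked per-column mean, SD and n of a signal matrix."""
    if matrix.values.shape[0] == 0:
        raise ValueError("empty signal matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(matrix.values, axis=0)
        sd = np.nanstd(matrix.values, axis=0, ddof=0)
    n = np.sum(~np.isnan(matrix.values), axis=0)
    offsets = (np.arange(matrix.values.shape[1]) - matrix.values.shape[1] // 2) * matrix.bin_size
    return pd.DataFrame({"offset": offsets, "mean": mean, "sd": sd, "n": n})


def asymmetry_score(row: np.ndarray, pseudocount: float = 0.5) -> float:
    """(mean downstream + psi) / (mean upstream + psi) for one oriented row.

    Values above 1 mean the repressive signal trails the element's direction
    of transcription.
    """
    half = len(row) // 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        up = np.nanmean(row[:half])
        down = np.nanmean(row[half:])
    up = 0.0 if np.isnan(up) else up
    down = 0.0 if np.isnan(down) else down
    return (down + pseudocount) / (up + pseudocount)


def asymmetry_scores(matrix: SignalMatrix, pseudocount: float = 0.5) -> np.ndarray:
    return np.array([asymmetry_score(r, pseudocount) for r in matrix.values])


# --------------------------------------------------------------------------
# region-level comparisons


def region_mean(track: CoverageTrack, regions: RegionSet) -> float:
    """Length-weighted mean rpm of a track over a region set."""
    num = den = 0.0
    for chrom, ivs in regions.intervals.items():
        vals = track.values.get(chrom)
        if vals is None:
            continue
        bs = track.bin_size
        for s, e in ivs:
            lo, hi = s // bs, -(-e // bs)
            seg = vals[lo:hi]
            num += seg.sum() * bs
            den += len(seg) * bs
    return num / den if den else float("nan")


def region_mean_signal(
    tracks_by_condition: dict[str, list[CoverageTrack]],
    regions: RegionSet,
) -> pd.DataFrame:
    """Per-replicate region means plus a Welch t-test between two conditions.

    Degenerate inputs (zero variance in both groups) give p = 1 for equal
    means and p = 0 (flagged) otherwise.
    """
    if len(tracks_by_condition) != 2:
        raise ValueError("exactly two conditions required")
    (name_a, tracks_a), (name_b, tracks_b) = tracks_by_condition.items()
    if len(tracks_a) < 2 or len(tracks_b) < 2:
        raise ValueError("need >= 2 replicates per condition for the t-test")
    means_a = np.array([region_mean(t, regions) for t in tracks_a])
    means_b = np.array([region_mean(t, regions) for t in tracks_b])
    degenerate = False
    if means_a.std(ddof=1) == 0 and means_b.std(ddof=1) == 0:
        p = 1.0 if means_a.mean() == means_b.mean() else 0.0
        degenerate = True
        t_stat = 0.0 if p == 1.0 else float("inf")
    else:
        t_stat, p = stats.ttest_ind(means_a, means_b, equal_var=False)
    return pd.DataFrame(
        [
            {
                "condition_a": name_a,
                "condition_b": name_b,
                "mean_a": means_a.mean(),
                "sd_a": means_a.std(ddof=1),
                "mean_b": means_b.mean(),
                "sd_b": means_b.std(ddof=1),
                "t": t_stat,
                "p": p,
                "degenerate": degenerate,
            }
        ]
    )
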