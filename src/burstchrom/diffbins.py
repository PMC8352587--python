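"""Negative-binomial differential testing of binned counts with attribution.

Counts (5 kb genome bins or TE families) are compared between two
conditions with a DESeq2-style workflow re-expressed in compact form:
median-of-ratios size factors, per-feature method-of-moments NB dispersion
pooled across both groups and moderated toward the matrix-wide mean
dispersion (empirical-Bayes shrinkage with a prior worth
``dispersion_prior_df`` pseudo-replicates — the same information sharing
DESeq2 performs, in moment form), and a Wald test on the log2 fold-change
with an NB-based standard error referred to the normal distribution.
Without moderation the few-replicate plug-in dispersion makes the normal
Wald reference strongly anticonservative (type-I error ~0.11 at n = 3 per
group) and costs half the power; the moderated test's type-I error is
verified by the null calibration simulation. p-values are
Benjamini-Hochberg adjusted over tested features.

Significantly changed bins are attributed to TE families by proximity:
a bin counts toward family F when it lies within D (default 5 kb,
boundary-inclusive) of an F insertion junction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .assignquant import CountMatrix
from .model import GENOME, Insertion

ALPHA_FLOOR = 1e-8


def bin_counts(
    assignments_by_sample: dict[str, list],
    chrom_lengths: dict[str, int],
    bin_size: int = 5000,
) -> CountMatrix:
    """Count genome-assigned reads per fixed bin (leftmost position rule).

    Feature ids are ``chrom:start-end`` so downstream attribution can
    recover the bin interval.
    """
    features = []
    for chrom, L in chrom_lengths.items():
        for s in range(0, L, bin_size):
            features.append(f"{chrom}:{s}-{min(s + bin_size, L)}")
    index = {f: i for i, f in enumerate(features)}
    cols, totals = {}, {}
    for sample, assignments in assignments_by_sample.items():
        vec = np.zeros(len(features), dtype=int)
        n_assigned = 0
        for a in assignments:
            if a.category != GENOME or a.target not in chrom_lengths:
                continue
            s = (a.pos // bin_size) * bin_size
            key = f"{a.target}:{s}-{min(s + bin_size, chrom_lengths[a.target])}"
            vec[index[key]] += 1
            n_assigned += 1
        cols[sample] = vec
        totals[sample] = n_assigned
    counts = pd.DataFrame(cols, index=features)
    return CountMatrix(counts, pd.Series(totals))


def parse_bin_id(feature_id: str) -> tuple[str, int, int]:
    chrom, span = feature_id.rsplit(":", 1)
    s, e = span.split("-")
    return chrom, int(s), int(e)


# --------------------------------------------------------------------------
# size factors and the NB Wald test


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors.

    Uses features with nonzero counts in every sample as the reference set.
    """
    arr = counts.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; "
            "use a pseudo-reference fallback or filter samples"
        )
    ref = arr[all_nonzero]
    log_geo = np.log(ref).mean(axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geo[:, None], axis=0))
    return pd.Series(factors, index=counts.columns)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ecdf = np.arange(1, m + 1) / m
    ranked = p[order] / ecdf
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def nb_test(
    cm: CountMatrix,
    sf: pd.Series,
    groups: dict[str, str],
    group_order: tuple[str, str] | None = None,
    alpha_floor: float = ALPHA_FLOOR,
    dispersion_prior_df: float = 20.0,
) -> pd.DataFrame:
    """Per-feature NB Wald test of group B vs group A (log2fc = B over A).

    Dispersion is method-of-moments on size-factor-normalised counts,
    pooled across both groups, shrunk toward the matrix-wide mean dispersion
    with ``dispersion_prior_df`` pseudo-degrees of freedom, and floored at
    ``alpha_floor``. Features with all-zero counts are excluded (status
    ``low_count_excluded``); all other features are tested and BH-adjusted
    together.
    """
    labels = sorted(set(groups.values())) if group_order is None else list(group_order)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a_samples = [s for s in cm.counts.columns if groups[s] == labels[0]]
    b_samples = [s for s in cm.counts.columns if groups[s] == labels[1]]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("each group needs >= 2 samples")

    K = cm.counts[a_samples + b_samples].to_numpy(dtype=float)
    s = sf[a_samples + b_samples].to_numpy(dtype=float)
    q = K / s
    nA, nB = len(a_samples), len(b_samples)
    qA, qB = q[:, :nA], q[:, nA:]

    base_mean = q.mean(axis=1)
    tested = K.sum(axis=1) > 0

    muA, muB = qA.mean(axis=1), qB.mean(axis=1)
    varA, varB = qA.var(axis=1, ddof=1), qB.var(axis=1, ddof=1)
    v = ((nA - 1) * varA + (nB - 1) * varB) / (nA + nB - 2)
    xi = (1.0 / s).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (v - base_mean * xi) / base_mean**2
    alpha_raw = np.where(np.isfinite(alpha_raw), alpha_raw, 0.0)
    # moment estimates at few replicates are extremely noisy (df = n - 2);
    # shrink toward the matrix-wide mean before flooring
    df_resid = nA + nB - 2
    alpha_prior = float(np.clip(np.mean(alpha_raw[base_mean > 0]), 0.0, None))
    alpha = (df_resid * alpha_raw + dispersion_prior_df * alpha_prior) / (
        df_resid + dispersion_prior_df
    )
    alpha = np.maximum(alpha, alpha_floor)

    # half-count floor keeps one-sided-zero features testable
    xiA = (1.0 / s[:nA]).mean()
    xiB = (1.0 / s[nA:]).mean()
    muA_ = np.maximum(muA, 0.5 * xiA / nA)
    muB_ = np.maximum(muB, 0.5 * xiB / nB)
    var_lnA = xiA / (nA * muA_) + alpha / nA
    var_lnB = xiB / (nB * muB_) + alpha / nB
    se_ln = np.sqrt(var_lnA + var_lnB)
    lfc = np.log2(muB_ / muA_)
    wald = np.log(muB_ / muA_) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(wald))

    out = pd.DataFrame(
        {
            "feature_id": cm.counts.index,
            "base_mean": base_mean,
            "log2fc": lfc,
            "p": p,
            "padj": np.nan,
            "status": np.where(tested, "tested", "low_count_excluded"),
        }
    )
    out.loc[~tested, ["log2fc", "p"]] = np.nan
    mask = out["status"] == "tested"
    out.loc[mask, "padj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


# --------------------------------------------------------------------------
# attribution of significant bins to nearby insertions


def _interval_distance(s1: int, e1: int, s2: int, e2: int) -> int:
    if e1 <= s2:
        return s2 - e1
    if e2 <= s1:
        return s1 - e2
    return 0


def attribute_bins(
    diff: pd.DataFrame,
    insertions: list[Insertion],
    distance: int = 5000,
    alpha: float = 0.05,
    p_column: str = "padj",
) -> pd.DataFrame:
    """Count significant up/down bins lying within ``distance`` of each
    family's insertion junctions (boundary-inclusive; overlapping = 0).

    Bins near insertions of several families count for each family.
    """
    sig = diff[(diff["status"] == "tested") & (diff[p_column] < alpha)]
    down = sig[sig["log2fc"] < 0]
    up = sig[sig["log2fc"] > 0]
    by_family: dict[str, list[Insertion]] = {}
    for ins in insertions:
        by_family.setdefault(ins.family, []).append(ins)

    def near(bins: pd.DataFrame, fam_ins: list[Insertion]) -> int:
        n = 0
        for fid in bins["feature_id"]:
            chrom, s, e = parse_bin_id(fid)
            for ins in fam_ins:
                if ins.chrom != chrom:
                    continue
                # a point junction is a zero-length interval
                je = max(ins.end, ins.start)
                if _interval_distance(s, e, ins.start, je) <= distance:
                    n += 1
                    break
        return n

    rows = []
    for family, fam_ins in sorted(by_family.items()):
        rows.append(
            {
                "family": family,
                "n_signif_down": len(down),
                "n_signif_up": len(up),
                "n_down_within_D": near(down, fam_ins),
                "n_up_within_D": near(up, fam_ins),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# family-level TE differential expression


def te_differential(
    cm: CountMatrix,
    groups: dict[str, str],
    group_order: tuple[str, str] | None = None,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    use_library_totals: bool = True,
) -> pd.DataFrame:
    """MA-style family differential table (fold-change > 2 class labels).

    By default samples are normalised by their library totals (all TE plus
    genome-mapped reads), the whole-transcriptome denominator: median-of-
    ratios over a handful of TE families alone would absorb a shared
    derepression signal into the size factors.
    """
    if use_library_totals and len(cm.library_totals) == len(cm.counts.columns):
        totals = cm.library_totals[cm.counts.columns].astype(float)
        sf = totals / np.exp(np.log(totals).mean())
    else:
        sf = size_factors(cm.counts)
    diff = nb_test(cm, sf, groups, group_order)
    sig = (diff["status"] == "tested") & (diff["padj"] < alpha)
    big = diff["log2fc"].abs() > lfc_threshold
    cls = np.where(
        sig & big,
        np.where(diff["log2fc"] > 0, "sig_fc2_up", "sig_fc2_down"),
        np.where(sig, "sig", "ns"),
    )
    diff = diff.copy()
    diff["ma_class"] = np.where(diff["status"] == "tested", cls, "excluded")
    return diff


# --------------------------------------------------------------------------
# NB count simulation (calibration studies)


def simulate_nb_matrix(
    n_features: int,
    mu_a: float,
    mu_b: float | np.ndarray,
    dispersion: float,
    n_per_group: int,
    seed: int,
    sample_prefix: str = "s",
) -> CountMatrix:
    """NB(mu, dispersion) count matrix for a two-group design.

    ``mu_b`` may be a scalar or per-feature vector; used for the null and
    power calibration studies of the Wald test.
    """
    rng = np.random.default_rng(seed)
    mu_b = np.broadcast_to(np.asarray(mu_b, dtype=float), (n_features,))
    mus = np.column_stack(
        [np.full(n_features, mu_a)] * n_per_group + [mu_b] * n_per_group
    )
    if dispersion > 0:
        r = 1.0 / dispersion
        K = rng.negative_binomial(r, r / (r + mus))
    else:
        K = rng.poisson(mus)
    samples = [f"{sample_prefix}A{i}" for i in range(n_per_group)] + [
        f"{sample_prefix}B{i}" for i in range(n_per_group)
    ]
    counts = pd.DataFrame(K, columns=samples, index=[f"f{i}" for i in range(n_features)])
    return CountMatrix(counts, pd.Series(counts.sum(axis=0), dtype=int))
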