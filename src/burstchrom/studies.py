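"""Canonical end-to-end studies at the package's default conditions.

Each function runs one complete experiment on freshly simulated data —
generation, assignment, measurement — and returns the summary quantities.
The analysis drivers, the test suite and the reproduction script all call
these, so the numbers they report are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assignquant, chromsig, diffbins, inscall, orchestrate, pirna, simgen
from .model import GENOME, Insertion


def _indexes(reference, k: int = 21):
    return (
        assignquant.SeqIndex(reference.te_consensus, k),
        assignquant.SeqIndex(reference.sequences, k),
    )


def insertion_calling_study(seed: int = 0) -> dict:
    """De novo insertion calling at the default conditions:
    ~1 Mb genome, 100 planted insertions, 30x error-free paired-end WGS."""
    cfg = simgen.default_config(seed)
    reference, sample, truth = simgen.build_genome(cfg, seed)
    pairs, _ = simgen.simulate_wgs(sample, cfg, seed + 1)
    te_index, genome_index = _indexes(reference)
    asn = assignquant.assign_pairs(pairs, te_index, genome_index, 2, seed + 2)
    evidence, summary = inscall.collect_evidence(asn, cfg.wgs.read_length)
    max_gap = inscall.default_max_gap(cfg.wgs.fragment_mean, cfg.wgs.fragment_sd)
    calls = inscall.cluster_and_call(evidence, max_gap)
    res = inscall.evaluate_calls(calls, truth.insertion_truth, position_tolerance=50)
    res["n_pairs"] = len(pairs)
    res["n_evidence"] = summary["evidence"]
    return res


def quantification_study(seed: int = 0, n_reads: int = 200_000) -> dict:
    """Transcriptome-fraction recovery of the dominant family at its peak."""
    cfg = simgen.default_config(seed)
    reference, _, _ = simgen.build_genome(cfg, seed)
    peak_tp = "4-6h"
    reads, truth = simgen.simulate_rnaseq(reference, cfg, peak_tp, n_reads, seed + 3)
    te_index, genome_index = _indexes(reference)
    asn = assignquant.assign_reads(reads, te_index, genome_index, 2, seed + 4)
    fams = [f.name for f in cfg.families]
    cm = assignquant.count_features(asn, "peak", all_features=fams)
    rpm = assignquant.rpm_normalize(cm)["peak"]

    tags = truth.read_tags
    truth_counts = {
        fam: int(((tags["origin"] == "TE") & (tags["target"] == fam)).sum())
        for fam in fams
    }
    counts_match = all(cm.counts.at[f, "peak"] == truth_counts[f] for f in fams)
    te_rpm = rpm.reindex(fams)
    dominant = te_rpm.idxmax()
    return {
        "dominant_family": dominant,
        "dominant_pct": float(te_rpm[dominant] / 1e4),
        "expected_pct": 100 * cfg.expression_profile[(dominant, peak_tp)],
        "total_te_pct": float(te_rpm.sum() / 1e4),
        "dominant_te_share_pct": float(100 * te_rpm[dominant] / te_rpm.sum()),
        "rpm_sum": float(rpm.sum()),
        "counts_match_truth": bool(counts_match),
        "n_reads": n_reads,
    }


def _chip_tracks(reference, cfg, timepoint, n_ip, n_input, seed, k=21):
    te_index, genome_index = _indexes(reference, k)
    ip_reads, input_reads, _ = simgen.simulate_chip(
        reference, cfg, timepoint, n_ip, n_input, seed
    )
    tracks = []
    for reads, s in ((ip_reads, seed + 1), (input_reads, seed + 2)):
        asn = assignquant.assign_reads(reads, te_index, genome_index, 2, s)
        n_mapped = sum(a.category != "UNMAPPED" for a in asn)
        tracks.append(
            chromsig.coverage_track(
                asn, reference.chrom_lengths, n_mapped, 10, cfg.chip_read_length
            )
        )
    return tracks[0], tracks[1]


def euchromatin_study(seed: int = 0, n_reads: int = 80_000) -> dict:
    """Recovery of the planted heterochromatin block from 10 kb windows,
    plus threshold monotonicity of the euchromatin caller."""
    cfg = simgen.default_config(seed)
    reference, _, _ = simgen.build_genome(cfg, seed)
    ip, inp = _chip_tracks(reference, cfg, "6-8h", n_reads, n_reads, seed + 5)
    windows = chromsig.window_enrichment(ip, inp, 10_000, pseudocount=0.5)
    regions = chromsig.call_euchromatin(windows, tau=1.0)
    # planted block: chr3_toy [300k, 400k)
    ivs = regions.intervals["chr3_toy"]
    boundary_error = float("inf")
    if len(ivs) == 2:
        boundary_error = max(abs(ivs[0][1] - 300_000), abs(ivs[1][0] - 400_000))
    prev, monotone = -1, True
    for tau in (-2.0, 0.0, 0.5, 1.0, 2.0, 5.0):
        total = chromsig.call_euchromatin(windows, tau).total_length()
        monotone &= total >= prev
        prev = total
    return {
        "boundary_error_bp": boundary_error,
        "n_euchromatic_intervals_blocked_chrom": len(ivs),
        "threshold_monotone": bool(monotone),
    }


def asymmetry_study(seed: int = 0, n_ip: int = 150_000, n_boot: int = 500) -> dict:
    """Median downstream/upstream signal ratio at insertions for skew 3 vs 1."""
    cfg = simgen.default_config(seed)
    reference, _, truth = simgen.build_genome(cfg, seed)
    te_index, genome_index = _indexes(reference)
    out = {}
    boot_rng = np.random.default_rng(seed + 77)
    for skew in (3.0, 1.0):
        cfg.chip.downstream_skew = skew
        ip_reads, _, _ = simgen.simulate_chip(reference, cfg, "6-8h", n_ip, 0, seed + 6)
        asn = assignquant.assign_reads(ip_reads, te_index, genome_index, 2, seed + 6)
        track = chromsig.coverage_track(
            asn, reference.chrom_lengths, len(asn), 10, cfg.chip_read_length
        )
        matrix = chromsig.insertion_matrix(track, truth.insertion_truth, 10_000)
        scores = chromsig.asymmetry_scores(matrix, 0.5)
        boots = [
            float(np.median(boot_rng.choice(scores, len(scores))))
            for _ in range(n_boot)
        ]
        out[f"median_s{int(skew)}"] = float(np.median(scores))
        out[f"boot_sd_s{int(skew)}"] = float(np.std(boots))
    sep = (out["median_s3"] - out["median_s1"]) / np.hypot(
        out["boot_sd_s3"], out["boot_sd_s1"]
    )
    out["separation_sigma"] = float(sep)
    return out


def nb_calibration_study(seed: int = 0) -> dict:
    """Null type-I error, planted-depletion power and FDR of the NB Wald test."""
    null_cm = diffbins.simulate_nb_matrix(5000, 100.0, 100.0, 0.05, 3, seed + 11)
    groups = {s: ("A" if "A" in s else "B") for s in null_cm.counts.columns}
    sf = pd.Series(1.0, index=null_cm.counts.columns)
    null = diffbins.nb_test(null_cm, sf, groups, ("A", "B"))
    type1 = float((null.loc[null["status"] == "tested", "p"] < 0.05).mean())

    n_affected, n_bins = 200, 500
    mu_b = np.where(np.arange(n_bins) < n_affected, 100.0, 200.0)
    power_cm = diffbins.simulate_nb_matrix(n_bins, 200.0, mu_b, 0.05, 3, seed + 13)
    res = diffbins.nb_test(power_cm, sf, groups, ("A", "B"))
    hit = ((res["padj"] < 0.05) & (res["log2fc"] < 0)).iloc[:n_affected]
    n_rej = int((res["padj"] < 0.05).sum())
    n_null_rej = int((res["padj"] < 0.05).iloc[n_affected:].sum())
    return {
        "null_type1_error": type1,
        "power_2fold_depletion": float(hit.mean()),
        "empirical_fdr": n_null_rej / n_rej if n_rej else 0.0,
        "n_null_features": 5000,
    }


def depletion_attribution_study(seed: int = 0) -> dict:
    """Full depletion comparison: attribution of significant-down bins."""
    pc = orchestrate.PipelineConfig(
        sim=simgen.depletion_config(seed),
        params=orchestrate.StageParams(
            n_rna_reads=30_000, n_ip_reads=60_000, n_input_reads=2000
        ),
        seed=seed,
    )
    summary = orchestrate.run_depletion_comparison(pc)
    att = {a["family"]: a for a in summary["attribution"]}
    depleted = set(pc.depletion.depleted_families)
    n_down = summary["n_signif_down_bins"]
    causal = sum(att[f]["n_down_within_D"] for f in att if f in depleted)
    false = sum(att[f]["n_down_within_D"] for f in att if f not in depleted)
    return {
        "n_signif_down_bins": n_down,
        "n_signif_up_bins": summary["n_signif_up_bins"],
        "causal_attribution_fraction": causal / n_down if n_down else float("nan"),
        "false_attribution_fraction": false / n_down if n_down else float("nan"),
        "ma_classes": summary["ma_classes"],
        "region_stats": summary["region_stats"],
    }


def smallrna_study(seed: int = 0, n_reads: int = 50_000) -> dict:
    """Small RNA processing fidelity and antisense targeting profile."""
    cfg = simgen.default_config(seed)
    reference, _, _ = simgen.build_genome(cfg, seed)
    reads, truth = simgen.simulate_smallrna(reference, cfg, n_reads, seed + 21)
    processed = pirna.clip_and_trim(reads)
    recovered = dict(processed)
    tags = truth.read_tags
    n_exact = sum(
        recovered.get(rid) == ins for rid, ins in zip(tags["read_id"], tags["insert"])
    )
    kept = pirna.size_filter(processed)
    idx = assignquant.SeqIndex(reference.te_consensus, 15)
    assigned = pirna.orient_and_assign(kept, idx, seed=seed + 22)
    n_te = sum(r.orientation in ("sense", "antisense") for r in assigned)
    n_anti = sum(r.orientation == "antisense" for r in assigned)
    table = pirna.antisense_fraction_table(assigned, top_n=30).set_index("family")
    profile = pirna.size_profile(assigned)
    mode = int(profile.sum(axis=1).idxmax())
    return {
        "insert_recovery_fraction": n_exact / n_reads,
        "antisense_fraction": n_anti / n_te,
        "expected_antisense_fraction": cfg.smallrna.antisense_fraction,
        "n_te_reads": n_te,
        "antisense_pct_sum": float(table["pct"].sum()),
        "dominant_antisense_pct": float(table["pct"].get("roo", 0.0)),
        "second_antisense_pct": float(table["pct"].get("297", 0.0)),
        "modal_length": mode,
    }


def oracle_equivalence_study(seed: int = 0, n_instances: int = 20) -> dict:
    """Brute-force cross-checks of bin counting, matrix extraction, size
    factors and region means on random small instances."""
    rng = np.random.default_rng(seed + 31)
    n_ok = {"bin_counts": 0, "matrix": 0, "size_factors": 0, "region_mean": 0}
    for _ in range(n_instances):
        L = int(rng.integers(20_000, 60_000))
        bin_size = int(rng.choice([1000, 2000, 5000]))
        pos = rng.integers(0, L, size=rng.integers(10, 400))
        from .model import ReadAssignment

        asn = [
            ReadAssignment(f"r{i}", "single", GENOME, "c", int(p), "+", True, 1)
            for i, p in enumerate(pos)
        ]
        cm = diffbins.bin_counts({"s": asn}, {"c": L}, bin_size)
        ok = True
        for s in range(0, L, bin_size):
            e = min(s + bin_size, L)
            if cm.counts.at[f"c:{s}-{e}", "s"] != ((pos >= s) & (pos < e)).sum():
                ok = False
        n_ok["bin_counts"] += ok

        n_bins = L // 10
        vals = rng.random(n_bins)
        track = chromsig.CoverageTrack(10, {"c": vals}, 100, {"c": n_bins * 10})
        mids = rng.integers(2000, n_bins * 10 - 2000, size=5)
        strands = rng.choice(["+", "-"], size=5)
        ins = [Insertion("c", int(m), int(m), "f", s) for m, s in zip(mids, strands)]
        matrix = chromsig.insertion_matrix(track, ins, flank=1000)
        rows = []
        for i in ins:
            c = i.midpoint // 10
            row = vals[c - 100 : c + 100]
            rows.append(row[::-1] if i.strand == "-" else row)
        n_ok["matrix"] += bool(np.allclose(matrix.values, np.array(rows)))

        mat = rng.poisson(60, size=(30, 4)) + 1
        df = pd.DataFrame(mat, columns=list("wxyz"))
        sf = diffbins.size_factors(df)
        logs = np.log(mat.astype(float))
        expect = np.exp(np.median(logs - logs.mean(axis=1)[:, None], axis=0))
        n_ok["size_factors"] += bool(np.allclose(sf.to_numpy(), expect))

        s0 = int(rng.integers(0, (n_bins * 10 - 5000) // 10)) * 10
        regions = chromsig.RegionSet({"c": [(s0, s0 + 5000)]})
        got = chromsig.region_mean(track, regions)
        lo, hi = s0 // 10, (s0 + 5000) // 10
        n_ok["region_mean"] += bool(np.isclose(got, vals[lo:hi].mean()))
    return {k: v / n_instances for k, v in n_ok.items()} | {
        "n_instances": n_instances
    }
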