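"""Two-tier assignment policy, counting and rpm normalisation."""

import numpy as np
import pandas as pd
import pytest

from burstchrom import assignquant, simgen
from burstchrom.assignquant import SeqIndex, assign_read, find_hits
from burstchrom.model import GENOME, TE, UNMAPPED, revcomp

from conftest import small_config


class TestSeqIndex:
    def test_seed_position_count_is_l_minus_k_plus_1(self):
        idx = SeqIndex({"s": "A" * 40 + "CGT" * 20}, k=15)
        assert idx.n_seed_positions() == 100 - 15 + 1

    def test_identity_query_hits_once_on_plus(self):
        rng = np.random.default_rng(0)
        seq = simgen.random_sequence(rng, 100, 0.5)
        idx = SeqIndex({"s": seq}, k=15)
        hits, mm = find_hits(idx, seq)
        assert hits == [(0, 0, "+")] and mm == 0

    def test_revcomp_query_hits_same_locus_on_minus(self):
        rng = np.random.default_rng(1)
        seq = simgen.random_sequence(rng, 200, 0.5)
        idx = SeqIndex({"s": seq}, k=15)
        hits, _ = find_hits(idx, revcomp(seq[50:130]))
        assert hits == [(0, 50, "-")]

    def test_invalid_index_inputs_rejected(self):
        with pytest.raises(ValueError):
            SeqIndex({}, k=15)
        with pytest.raises(ValueError):
            SeqIndex({"a": "ACGT" * 10}, k=5)


class TestAssignRead:
    def test_unique_consensus_substring_is_te(self, reference, te_index, genome_index):
        rng = np.random.default_rng(0)
        read = reference.te_consensus["alpha"][100:150]
        a = assign_read(read, te_index, genome_index, 2, rng)
        assert a.category == TE and a.target == "alpha"
        assert a.n_candidates == 1 and a.pos == 100

    def test_genome_multimapper_is_unmapped(self):
        # two identical genome loci, no TE hit -> discarded by policy
        rng = np.random.default_rng(3)
        seg = simgen.random_sequence(rng, 300, 0.5)
        genome = {"c1": seg + simgen.random_sequence(rng, 200, 0.5) + seg}
        te_idx = SeqIndex({"te": simgen.random_sequence(rng, 200, 0.5)}, 21)
        g_idx = SeqIndex(genome, 21)
        a = assign_read(seg[10:80], te_idx, g_idx, 2, np.random.default_rng(0))
        assert a.category == UNMAPPED
        assert a.n_candidates == 2

    def test_unique_genome_read_is_genome(self, reference, te_index, genome_index):
        read = reference.sequences["chrA"][5000:5050]
        a = assign_read(read, te_index, genome_index, 2, np.random.default_rng(0))
        assert a.category == GENOME and a.target == "chrA"
        assert a.unique and a.pos == 5000

    def test_tied_families_allocated_uniformly(self):
        # one shared sequence under two family names: every read is a tie
        rng = np.random.default_rng(5)
        shared = simgen.random_sequence(rng, 400, 0.5)
        te_idx = SeqIndex({"famA": shared, "famB": shared}, 21)
        g_idx = SeqIndex({"g": simgen.random_sequence(rng, 300, 0.5)}, 21)
        alloc_rng = np.random.default_rng(11)
        n = 10_000
        n_a = 0
        for _ in range(n):
            a = assign_read(shared[37:97], te_idx, g_idx, 2, alloc_rng)
            assert a.category == TE and a.n_candidates == 2 and not a.unique
            n_a += a.target == "famA"
        assert abs(n_a - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_tier_hierarchy_te_beats_unique_genome(self, reference):
        # a consensus segment also present once in the genome would be
        # GENOME-unique, but tier 1 wins
        rng = np.random.default_rng(8)
        copy = reference.te_consensus["beta"][200:300]
        genome = {
            "g": simgen.random_sequence(rng, 500, 0.5)
            + copy
            + simgen.random_sequence(rng, 500, 0.5)
        }
        te_idx = SeqIndex(reference.te_consensus, 21)
        g_idx = SeqIndex(genome, 21)
        a = assign_read(copy[10:70], te_idx, g_idx, 2, np.random.default_rng(0))
        assert a.category == TE and a.target == "beta"

    def test_mismatched_read_recovered_within_limit(self, reference, te_index, genome_index):
        read = list(reference.te_consensus["alpha"][300:380])
        read[40] = "A" if read[40] != "A" else "C"
        a = assign_read("".join(read), te_index, genome_index, 2, np.random.default_rng(0))
        assert a.category == TE and a.target == "alpha"

    def test_unalignable_read_is_unmapped_not_error(self, te_index, genome_index):
        a = assign_read("N" * 50, te_index, genome_index, 2, np.random.default_rng(0))
        assert a.category == UNMAPPED and a.target == ""


class TestAssignmentDeterminism:
    def test_same_seed_reproduces_full_vector(self, reference, te_index, genome_index, cfg):
        reads, _ = simgen.simulate_rnaseq(reference, cfg, "t2", 2000, 3)
        a1 = assignquant.assign_reads(reads, te_index, genome_index, 2, seed=9)
        a2 = assignquant.assign_reads(reads, te_index, genome_index, 2, seed=9)
        assert a1 == a2

    def test_seed_changes_only_multimapper_allocations(self, reference, te_index, genome_index, cfg):
        reads, _ = simgen.simulate_rnaseq(reference, cfg, "t2", 2000, 3)
        a1 = assignquant.assign_reads(reads, te_index, genome_index, 2, seed=9)
        a2 = assignquant.assign_reads(reads, te_index, genome_index, 2, seed=10)
        for x, y in zip(a1, a2):
            if x.n_candidates <= 1:
                assert x == y
            else:
                assert x.category == y.category


class TestCounting:
    def test_empty_assignments_give_zero_column(self):
        cm = assignquant.count_features([], "s0", ["roo", "297"])
        assert cm.counts["s0"].sum() == 0
        assert cm.library_totals["s0"] == 0

    def test_te_column_sum_equals_te_assignment_count(self, reference, te_index, genome_index, cfg):
        reads, _ = simgen.simulate_rnaseq(reference, cfg, "t2", 5000, 3)
        asn = assignquant.assign_reads(reads, te_index, genome_index, 2, seed=1)
        cm = assignquant.count_features(asn, "s1")
        n_te = sum(a.category == TE for a in asn)
        fams = [f.name for f in cfg.families]
        assert cm.counts.loc[cm.counts.index.isin(fams), "s1"].sum() == n_te

    def test_counts_match_truth_recount_on_error_free_reads(
        self, reference, te_index, genome_index, cfg
    ):
        reads, truth = simgen.simulate_rnaseq(reference, cfg, "t2", 5000, 3)
        asn = assignquant.assign_reads(reads, te_index, genome_index, 2, seed=1)
        cm = assignquant.count_features(asn, "s1")
        tags = truth.read_tags
        for fam in ("alpha", "beta"):
            expected = ((tags["origin"] == "TE") & (tags["target"] == fam)).sum()
            assert cm.counts.at[fam, "s1"] == expected


class TestRpm:
    def test_rpm_definition_and_percent_scale(self):
        cm = assignquant.CountMatrix(
            pd.DataFrame({"s": [17_000]}, index=["roo"]), pd.Series({"s": 1_000_000})
        )
        rpm = assignquant.rpm_normalize(cm)
        assert rpm.at["roo", "s"] == 17_000  # 1.7% of the transcriptome

    def test_zero_library_total_rejected(self):
        cm = assignquant.CountMatrix(
            pd.DataFrame({"s": [0]}, index=["roo"]), pd.Series({"s": 0})
        )
        with pytest.raises(ValueError):
            assignquant.rpm_normalize(cm)

    def test_scaling_factor_is_file_over_library(self):
        assert assignquant.scaling_factor(500, 1000) == 0.5
        with pytest.raises(ValueError):
            assignquant.scaling_factor(1, 0)

    def test_rpm_sums_to_1e6_over_complete_partition(
        self, reference, te_index, genome_index, cfg
    ):
        reads, _ = simgen.simulate_rnaseq(reference, cfg, "t1", 4000, 3)
        asn = assignquant.assign_reads(reads, te_index, genome_index, 2, seed=1)
        cm = assignquant.count_features(asn, "s1")
        rpm = assignquant.rpm_normalize(cm)
        assert rpm["s1"].sum() == pytest.approx(1e6)


class TestTimecourse:
    def test_zero_te_counts_give_zero_percent(self):
        tables = {"t1": pd.Series({"roo": 0.0}), "t2": pd.Series({"roo": 0.0})}
        tc = assignquant.te_fraction_timecourse(tables, ["roo"])
        assert (tc["pct_mean"] == 0).all()

    def test_family_percentages_sum_to_total(self):
        tables = {"t1": pd.Series({"roo": 12_000.0, "297": 3000.0})}
        tc = assignquant.te_fraction_timecourse(tables, ["roo", "297"])
        per_family = tc[tc["family"] != "total_TE"]["pct_mean"].sum()
        total = tc[tc["family"] == "total_TE"]["pct_mean"].iloc[0]
        assert per_family == pytest.approx(total)
        assert total == pytest.approx(1.5)

    def test_replicates_produce_mean_and_sd(self):
        tables = {"t1": [pd.Series({"roo": 10_000.0}), pd.Series({"roo": 14_000.0})]}
        tc = assignquant.te_fraction_timecourse(tables, ["roo"])
        row = tc[tc["family"] == "roo"].iloc[0]
        assert row["pct_mean"] == pytest.approx(1.2)
        assert row["pct_sd"] > 0


class TestSamIngestion:
    def test_sam_subset_roundtrip(self, tmp_path):
        sam = tmp_path / "mini.sam"
        sam.write_text(
            "@SQ\tSN:chrA\tLN:1000\n"
            "r1\t0\troo\t101\t255\t50M\t*\t0\t0\t*\t*\n"
            "r2\t16\tchrA\t201\t255\t50M\t*\t0\t0\t*\t*\n"
            "r3\t0\tchrA\t301\t3\t50M\t*\t0\t0\t*\t*\n"
            "r4\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
        )
        asn = assignquant.read_sam_assignments(sam, {"roo"})
        assert [a.category for a in asn] == [TE, GENOME, UNMAPPED, UNMAPPED]
        assert asn[0].pos == 100  # 1-based SAM -> 0-based
        assert asn[1].strand == "-"
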