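"""Normalization, aggregation, essentiality calls, log2 ratios and the
doubling-time conversion."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnseqfit.genome import (
    FeatureAnnotation,
    Genome,
    enumerate_ta_sites,
)
from tnseqfit.readproc import SiteCountTable, process_fastq
from tnseqfit.fitness import (
    aggregate,
    apparent_doubling_time,
    classify_defect,
    classify_essential,
    fitness_table,
    library_summary,
    log2_ratio,
    normalize,
    replicate_correlation,
    summarize_library,
    viable_ta_sites,
)


def make_table(sample_id, counts, unique=None, ambiguous=0):
    table = SiteCountTable(sample_id)
    for site, (p, m) in counts.items():
        table.counts[site] = [p, m]
    table.unique_mapped = (
        unique if unique is not None else sum(p + m for p, m in counts.values())
    )
    table.ambiguous = ambiguous
    return table


class TestNormalize:
    def test_forced_arithmetic(self):
        table = make_table("s", {("chr", 0): (60, 40)}, unique=15_000_000,
                           ambiguous=5_000_000)
        norm = normalize(table, reference_total=40_000_000)
        assert norm.factor == 2.0
        assert norm.counts[("chr", 0)] == 200.0

    def test_identity_at_reference_depth(self):
        table = make_table("s", {("chr", 0): (70, 30)}, unique=40_000_000)
        norm = normalize(table)
        assert norm.counts[("chr", 0)] == 100.0

    def test_ambiguous_reads_enter_denominator(self):
        a = make_table("a", {("chr", 0): (100, 0)}, unique=1_000_000, ambiguous=0)
        b = make_table("b", {("chr", 0): (100, 0)}, unique=1_000_000,
                       ambiguous=500_000)
        na, nb = normalize(a), normalize(b)
        assert na.factor != nb.factor
        assert na.counts[("chr", 0)] / nb.counts[("chr", 0)] == pytest.approx(1.5)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            normalize(make_table("s", {}, unique=0))

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        counts = {("chr", i): (int(rng.integers(0, 500)), 0) for i in range(50)}
        table = make_table("s", counts, unique=2_000_000, ambiguous=123_456)
        norm = normalize(table)
        raw = [p for p, _ in counts.values()]
        scaled = [norm.counts[k] for k in counts]
        assert np.array_equal(np.argsort(raw, kind="stable"),
                              np.argsort(scaled, kind="stable"))


def plant_genome(length, ta_positions):
    seq = list("C" * length)
    for p in ta_positions:
        seq[p], seq[p + 1] = "T", "A"
    return Genome.from_string("".join(seq))


class TestAggregate:
    def test_first_window_reads_discounted(self):
        # all insertions within the first 5% of a 1-kb feature count nothing
        genome = plant_genome(1200, [10, 20, 40])
        ta = enumerate_ta_sites(genome)
        feat = FeatureAnnotation("f", "chr", 1, 1000, "+")
        table = make_table("s", {("chr", 10): (50, 0), ("chr", 20): (0, 30),
                                 ("chr", 40): (10, 10)})
        stats = aggregate(normalize(table, 100), [feat], ta)
        assert stats.loc["f", "raw_reads"] == 0
        assert stats.loc["f", "unique_sites_hit"] == 0

    def test_density_per_kb_of_full_length(self):
        positions = [60 + 100 * i for i in range(8)]
        genome = plant_genome(1200, positions)
        ta = enumerate_ta_sites(genome)
        feat = FeatureAnnotation("f", "chr", 1, 1000, "+")
        table = make_table("s", {("chr", p): (5, 5) for p in positions})
        stats = aggregate(normalize(table, table.unique_mapped), [feat], ta)
        assert stats.loc["f", "unique_sites_hit"] == 8
        assert stats.loc["f", "sites_per_kb"] == pytest.approx(8.0)

    def test_ambiguous_site_flags_feature(self):
        genome = plant_genome(1200, [100, 500])
        ta = enumerate_ta_sites(genome)
        feat = FeatureAnnotation("f", "chr", 1, 1000, "+")
        table = make_table("s", {("chr", 100): (5, 0)})
        table.ambiguous = 3
        table.ambiguous_sites = {("chr", 500)}
        stats = aggregate(normalize(table, 100), [feat], ta)
        assert bool(stats.loc["f", "contains_ambiguous_sites"])

    def test_few_available_sites_flagged(self):
        genome = plant_genome(400, [150])
        ta = enumerate_ta_sites(genome)
        feat = FeatureAnnotation("f", "chr", 1, 200, "+")
        table = make_table("s", {("chr", 150): (5, 0)})
        stats = aggregate(normalize(table, 100), [feat], ta)
        assert bool(stats.loc["f", "few_available_sites"])


def stats_frame(rows, reference_total=40_000_000.0):
    df = pd.DataFrame(rows).set_index("feature_id")
    df.attrs["reference_total"] = reference_total
    return df


def stats_row(fid, reads, density, n_sites=20, ambiguous=False):
    return {
        "feature_id": fid,
        "length_bp": 1000,
        "n_available_sites": n_sites,
        "raw_reads": reads,
        "normalized_reads": float(reads),
        "unique_sites_hit": int(density),
        "sites_per_kb": float(density),
        "contains_ambiguous_sites": ambiguous,
        "few_available_sites": n_sites < 3,
    }


class TestClassifyEssential:
    def test_known_calls(self):
        stats = stats_frame([
            stats_row("low_both", 250, 3.5),
            stats_row("typical", 8100, 10.0),
            stats_row("dead", 0, 0.0),
        ])
        for mode in ("both", "either"):
            out = classify_essential(stats, mode=mode)
            assert out.loc["low_both", "call"] == "essential"
            assert out.loc["typical", "call"] == "nonessential"
            assert out.loc["dead", "call"] == "essential"

    def test_single_criterion_never_essential_in_both_mode(self):
        stats = stats_frame([
            stats_row("low_reads_only", 100, 10.0),
            stats_row("low_density_only", 9000, 2.0),
        ])
        both = classify_essential(stats, mode="both")
        assert set(both["call"]) == {"nonessential"}
        either = classify_essential(stats, mode="either")
        assert set(either["call"]) == {"essential"}

    def test_either_mode_is_superset_of_both(self):
        rng = np.random.default_rng(12)
        rows = [
            stats_row(f"g{i}", int(rng.integers(0, 12_000)),
                      float(rng.uniform(0, 12)))
            for i in range(200)
        ]
        stats = stats_frame(rows)
        both = classify_essential(stats, mode="both")
        either = classify_essential(stats, mode="either")
        set_both = set(both.index[both["call"] == "essential"])
        set_either = set(either.index[either["call"] == "essential"])
        assert set_both <= set_either

    def test_guard_demotes_to_low_confidence(self):
        stats = stats_frame([stats_row("tiny", 10_000, 3.0, n_sites=1)])
        out = classify_essential(stats)
        assert out.loc["tiny", "call"] == "low-confidence"

    def test_threshold_scales_with_reference_total(self):
        # 150 normalized reads at a 20M reference is 300 at the 40M scale
        stats = stats_frame([stats_row("g", 200, 3.0)], reference_total=20_000_000.0)
        out = classify_essential(stats)
        assert not bool(out.loc["g", "reads_criterion_met"])
        out = classify_essential(stats_frame([stats_row("g", 100, 3.0)],
                                             reference_total=20_000_000.0))
        assert bool(out.loc["g", "reads_criterion_met"])


class TestLog2Ratio:
    def test_equal_inputs_zero(self):
        assert log2_ratio(123.0, 123.0, pseudocount=0) == 0.0

    def test_forced_arithmetic(self):
        assert log2_ratio(1000.0, 4000.0, pseudocount=0) == -2.0

    def test_pseudocount_keeps_zero_finite(self):
        L = log2_ratio(0.0, 1000.0, pseudocount=1)
        assert L == pytest.approx(math.log2(1 / 1001), abs=1e-12)
        assert L == pytest.approx(-9.97, abs=0.01)


class TestApparentDoublingTime:
    def test_paper_anchor_minus2_gives_15h(self):
        dt = apparent_doubling_time(-2.0, td_p=10.0, G_p=6)
        assert dt.td_m == 15.0
        assert dt.percent_td_change == 50.0

    def test_identity_at_zero(self):
        dt = apparent_doubling_time(0.0)
        assert dt.td_m == 10.0 and dt.percent_td_change == 0.0

    def test_minus3_gives_20h(self):
        assert apparent_doubling_time(-3.0).td_m == 20.0

    def test_deep_depletion_flagged_declining(self):
        dt = apparent_doubling_time(-8.0)  # fumarate hydratase territory
        assert dt.declining and math.isnan(dt.td_m)

    @given(st.floats(min_value=-5.9, max_value=6.0))
    @settings(deadline=None, derandomize=True)
    def test_strictly_decreasing_in_L(self, L):
        eps = 0.01
        a = apparent_doubling_time(L)
        b = apparent_doubling_time(L + eps)
        assert a.td_m > b.td_m

    def test_inverts_growth_model(self):
        # td -> L -> td round trip across the defined domain
        for td in (10.0, 12.5, 15.0, 20.0, 40.0):
            L = 60.0 / td - 6.0
            assert apparent_doubling_time(L).td_m == pytest.approx(td)


class TestClassifyDefect:
    @pytest.mark.parametrize(
        "L,expected",
        [(-3.3, "defective"), (-2.0, "defective"), (-1.0, "below-threshold"),
         (0.0, "below-threshold"), (1.5, "enriched")],
    )
    def test_cutoffs(self, L, expected):
        assert classify_defect(L) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_defect(math.nan)


class TestLibrarySummary:
    def test_summary_arithmetic_on_printed_inputs(self):
        out = summarize_library(
            unique_insertions=33_257, viable_ta_sites=55_000,
            total_reads=40_000_000,
        )
        assert out["ta_recovery_percent"] == 64
        assert out["mean_reads_per_insertion_display"] == 1200

    def test_empty_library(self):
        out = summarize_library(0, 0, 0)
        assert out["ta_recovery_percent"] == 0
        assert out["mean_reads_per_insertion_display"] == 0

    def test_viable_site_conventions(self):
        genome = plant_genome(2000, [100, 500, 1010, 1500])
        ta = enumerate_ta_sites(genome)
        feats = [
            FeatureAnnotation("lethal", "chr", 1001, 1600, "+"),
            FeatureAnnotation("fine", "chr", 1, 600, "+"),
        ]
        # 'whole' nets out both lethal-feature sites; 'beyond5' keeps the
        # 5%-window site (position 1010, offset 10 < window 30)
        assert viable_ta_sites(ta, feats, ["lethal"], "whole") == 2
        assert viable_ta_sites(ta, feats, ["lethal"], "beyond5") == 3

    def test_full_summary_from_table(self):
        genome = plant_genome(2000, [100, 500, 1010, 1500])
        ta = enumerate_ta_sites(genome)
        feats = [FeatureAnnotation("f", "chr", 401, 1600, "+")]
        table = make_table("s", {("chr", 100): (10, 0), ("chr", 500): (5, 5)})
        out = library_summary(table, ta, feats, genome.total_length)
        assert out["unique_insertions"] == 2
        assert out["fraction_in_features"] == 0.5
        assert out["insertions_per_kb"] == pytest.approx(1.0)


class TestReplicateCorrelation:
    def frame(self, values):
        df = pd.DataFrame({
            "feature_id": [f"g{i}" for i in range(len(values))],
            "normalized_reads": values,
        }).set_index("feature_id")
        return df

    def test_identical_replicates(self):
        a = self.frame([10.0, 20.0, 0.0, 40.0])
        assert replicate_correlation(a, a) == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = self.frame([10.0, 20.0, 5.0, 40.0])
        b = self.frame([30.0, 60.0, 15.0, 120.0])
        assert replicate_correlation(a, b) == pytest.approx(1.0)

    def test_too_few_features_rejected(self):
        a = self.frame([1.0, 2.0])
        with pytest.raises(ValueError, match="3 features"):
            replicate_correlation(a, a)

    def test_sequencing_replicates_correlate(self, small_config, small_run, tmp_path):
        """Two independent sequencing draws of the same library correlate
        strongly at the feature level (the Fig-1A style check)."""
        from tnseqfit.simulate import sequence_reads

        result = small_run["result"]
        pop = result.populations["fumarate"]
        rng_a = np.random.default_rng(101)
        rng_b = np.random.default_rng(202)
        stats = []
        for name, rng in (("a", rng_a), ("b", rng_b)):
            fq = tmp_path / f"rep_{name}.fastq"
            sequence_reads(pop, result.genome, small_config, "fumarate", fq, rng=rng)
            pr = process_fastq(fq, result.genome, small_config.barcode_table,
                               small_config.transposon_tag, ta=result.ta)
            norm = normalize(pr.tables["fumarate"])
            stats.append(aggregate(norm, result.annotations, result.ta))
        assert replicate_correlation(stats[0], stats[1]) > 0.95


class TestFitnessTable:
    def test_no_data_and_declining_flags(self):
        cond = stats_frame([stats_row("gone", 0, 0.0), stats_row("ok", 1000, 8.0),
                            stats_row("crash", 0, 0.0)])
        par = stats_frame([stats_row("gone", 0, 0.0), stats_row("ok", 1000, 8.0),
                           stats_row("crash", 200_000, 8.0)])
        out = fitness_table(cond, par)
        assert out.loc["gone", "growth_class"] == "no-data"
        assert out.loc["ok", "growth_class"] == "below-threshold"
        assert out.loc["ok", "log2_ratio"] == 0.0
        assert out.loc["crash", "growth_class"] == "defective"
        assert bool(out.loc["crash", "declining"])
        assert math.isnan(out.loc["crash", "apparent_doubling_time_h"])

    def test_mismatched_features_rejected(self):
        a = stats_frame([stats_row("x", 1, 1.0)])
        b = stats_frame([stats_row("y", 1, 1.0)])
        with pytest.raises(ValueError, match="different features"):
            fitness_table(a, b)
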