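import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import binomial_counts, make_counts
from scvaf.errors import ConfigError, DataError
from scvaf.vaf import (
    ClassificationConfig,
    aggregate_gene,
    chi2_2x2,
    classify_pattern,
    compare_intronic,
    estimate_vaf,
    summarize_snv,
    vaf_histogram,
)

CFG10 = ClassificationConfig(min_cells_pattern=10)


def annot_for(snv_ids, gene="G1", category="utr3"):
    rows = []
    for sid in snv_ids:
        g, c = (gene, category) if isinstance(gene, str) else (gene[sid], category[sid])
        rows.append({"snv_id": sid, "gene": g, "category": c})
    return pd.DataFrame(rows)


class TestEstimateVaf:
    def test_formula_boundary_depth(self):
        est = estimate_vaf(make_counts([("c1", "s1", 7, 3)]), minr=10)
        assert len(est) == 1
        assert est.iloc[0].vaf == pytest.approx(0.3)
        assert est.iloc[0].depth_informative == 10

    def test_below_minr_omitted(self):
        est = estimate_vaf(make_counts([("c1", "s1", 7, 2)]), minr=10)
        assert est.empty

    def test_monoallelic_extreme(self):
        est = estimate_vaf(make_counts([("c1", "s1", 0, 3)]), minr=3)
        assert est.iloc[0].vaf == 1.0

    def test_n_other_excluded_from_depth(self):
        # 5 informative + 5 ambiguous molecules: depth_informative is 5
        est = estimate_vaf(make_counts([("c1", "s1", 2, 3, 5)]), minr=6)
        assert est.empty
        est = estimate_vaf(make_counts([("c1", "s1", 2, 3, 5)]), minr=5)
        assert est.iloc[0].vaf == pytest.approx(0.6)

    def test_bad_minr_rejected(self):
        with pytest.raises(ConfigError):
            estimate_vaf(make_counts([("c1", "s1", 1, 1)]), minr=0)


class TestSummarizeSnv:
    def test_constant_input(self):
        counts = make_counts([(f"c{i}", "s1", 5, 5) for i in range(10)])
        summary = summarize_snv(estimate_vaf(counts, 3), CFG10)
        row = summary.iloc[0]
        assert row.mean_vaf == 0.5 and row.median_vaf == 0.5
        assert row.frac_biallelic == 1.0 and row.frac_strict_mono == 0.0
        assert row.pattern == "biallelic"

    def test_nine_cells_insufficient(self):
        counts = make_counts([(f"c{i}", "s1", 5, 5) for i in range(9)])
        summary = summarize_snv(estimate_vaf(counts, 3))
        row = summary.iloc[0]
        assert row.pattern == "insufficient_cells"
        assert np.isnan(row.frac_biallelic) and np.isnan(row.mean_vaf)

    def test_even_median_midpoint(self):
        counts = make_counts(
            [("c1", "s1", 9, 1), ("c2", "s1", 1, 9)] + [(f"d{i}", "s1", 5, 5) for i in range(8)]
        )
        summary = summarize_snv(estimate_vaf(counts, 3), CFG10)
        assert summary.iloc[0].median_vaf == pytest.approx(0.5)

    def test_strict_mono_rate_matches_binomial(self, rng):
        # exact oracle: P(vaf in {0,1}) = 2 * 0.5^depth at p = 0.5
        depth, n_cells = 10, 200
        counts = binomial_counts(rng, n_cells, depth, 0.5)
        summary = summarize_snv(estimate_vaf(counts, depth), CFG10)
        expected = 2 * 0.5**depth
        se = np.sqrt(expected * (1 - expected) / n_cells)
        assert abs(summary.iloc[0].frac_strict_mono - expected) <= 3 * se

    def test_boundary_cells_are_predominant_not_biallelic(self):
        # vaf exactly 0.2 and 0.8 fall outside the open bi-allelic interval
        counts = make_counts(
            [(f"a{i}", "s1", 8, 2) for i in range(5)]
            + [(f"b{i}", "s1", 2, 8) for i in range(5)]
        )
        row = summarize_snv(estimate_vaf(counts, 10), CFG10).iloc[0]
        assert row.frac_predom_mono == 1.0
        assert row.frac_biallelic == 0.0
        assert row.frac_strict_mono == 0.0

    def test_mixed_minr_rejected(self):
        est = pd.concat(
            [
                estimate_vaf(make_counts([("c1", "s1", 5, 5)]), 3),
                estimate_vaf(make_counts([("c1", "s1", 5, 5)]), 5),
            ],
            ignore_index=True,
        )
        with pytest.raises(DataError):
            summarize_snv(est)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 20), st.integers(0, 20)).filter(
                lambda t: t[0] + t[1] >= 3
            ),
            min_size=10,
            max_size=40,
        )
    )
    def test_partition_identity(self, pairs):
        counts = make_counts(
            [(f"c{i}", "s1", r, v) for i, (r, v) in enumerate(pairs)]
        )
        summary = summarize_snv(estimate_vaf(counts, 3), CFG10)
        row = summary.iloc[0]
        assert row.frac_predom_mono + row.frac_biallelic == pytest.approx(1.0, abs=1e-12)
        assert row.frac_strict_mono <= row.frac_predom_mono + 1e-12


class TestClassifyPattern:
    def test_rme(self):
        assert classify_pattern(100, 0.02, 0.5, 0.48) == "RME"

    def test_skewed(self):
        assert classify_pattern(100, 0.65, 0.05, 0.30) == "skewed"

    def test_biallelic(self):
        assert classify_pattern(100, 0.90, 0.05, 0.05) == "biallelic"

    def test_symmetric_monoallelic_is_not_skewed(self):
        # both alleles well represented: fails the skew one-allele condition
        assert classify_pattern(100, 0.30, 0.35, 0.35) == "biallelic"

    def test_insufficient_cells(self):
        assert classify_pattern(49, 0.9, 0.05, 0.05) == "insufficient_cells"

    def test_rme_takes_precedence_over_skew(self):
        assert classify_pattern(100, 0.03, 0.02, 0.95) == "RME"


class TestAggregateGene:
    def test_singleton_gene(self):
        counts = make_counts([(f"c{i}", "s1", 5, 5) for i in range(10)])
        summary = summarize_snv(estimate_vaf(counts, 3), CFG10)
        table = aggregate_gene(summary, annot_for(["s1"]))
        row = table.iloc[0]
        assert row.concordance_score == 0.0
        assert row.pattern == summary.iloc[0].pattern

    def test_two_snv_concordance_arithmetic(self):
        summary = pd.DataFrame(
            {
                "snv_id": ["s1", "s2"],
                "minR": [3, 3],
                "n_cells": [100, 100],
                "mean_vaf": [0.5, 0.5],
                "median_vaf": [0.5, 0.5],
                "n_strict_mono": [0, 0],
                "n_low": [5, 6],
                "n_high": [5, 6],
                "n_biallelic": [90, 88],
                "frac_strict_mono": [0.0, 0.0],
                "frac_predom_mono": [0.10, 0.12],
                "frac_biallelic": [0.90, 0.88],
                "pattern": ["biallelic", "biallelic"],
            }
        )
        table = aggregate_gene(summary, annot_for(["s1", "s2"]))
        assert table.iloc[0].concordance_score == pytest.approx(0.02)
        assert table.iloc[0].pattern == "biallelic"

    def test_tie_vote_is_discordant(self):
        summary = pd.DataFrame(
            {
                "snv_id": ["s1", "s2"],
                "minR": [3, 3],
                "n_cells": [100, 100],
                "mean_vaf": [0.5, 0.5],
                "median_vaf": [0.5, 0.5],
                "n_strict_mono": [0, 100],
                "n_low": [5, 50],
                "n_high": [5, 50],
                "n_biallelic": [90, 0],
                "frac_strict_mono": [0.0, 1.0],
                "frac_predom_mono": [0.10, 1.0],
                "frac_biallelic": [0.90, 0.0],
                "pattern": ["biallelic", "RME"],
            }
        )
        table = aggregate_gene(summary, annot_for(["s1", "s2"]))
        assert table.iloc[0].pattern == "discordant"

    def test_symmetric_members_classified_identically(self, rng):
        # 4 equal-depth symmetric SNVs in one gene agree in most replicates
        agreements = 0
        for rep in range(20):
            frames = []
            for j in range(4):
                counts = binomial_counts(
                    np.random.default_rng(1000 + 20 * rep + j), 100, 12, 0.5, f"s{j}"
                )
                frames.append(estimate_vaf(counts, 10))
            summary = summarize_snv(pd.concat(frames, ignore_index=True), CFG10)
            if summary["pattern"].nunique() == 1:
                agreements += 1
        assert agreements >= 19

    def test_missing_annotation_raises(self):
        counts = make_counts([(f"c{i}", "s1", 5, 5) for i in range(10)])
        summary = summarize_snv(estimate_vaf(counts, 3), CFG10)
        with pytest.raises(DataError):
            aggregate_gene(summary, annot_for(["s_other"]))


class TestCompareIntronic:
    def test_independence_table(self):
        stat, p = chi2_2x2(np.array([[50, 50], [50, 50]]))
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # sum (O - E)^2 / E with E = 50 everywhere: 4 * 400/50 = 32
        stat, p = chi2_2x2(np.array([[30, 70], [70, 30]]))
        assert stat == pytest.approx(32.0)
        assert p < 1e-7

    def test_group_pooling(self):
        summary = pd.DataFrame(
            {
                "snv_id": ["s1", "s2"],
                "minR": [3, 3],
                "n_cells": [100, 100],
                "n_biallelic": [30, 70],
                "frac_biallelic": [0.3, 0.7],
            }
        )
        annot = annot_for(
            ["s1", "s2"],
            gene={"s1": "G1", "s2": "G2"},
            category={"s1": "intron", "s2": "utr3"},
        )
        res = compare_intronic(summary, annot, 3)
        assert res["applicable"]
        assert res["table"] == [[30, 70], [70, 30]]
        assert res["chi2"] == pytest.approx(32.0)
        assert res["intronic_biallelic_prop"] == pytest.approx(0.3)

    def test_empty_group_not_applicable(self):
        summary = pd.DataFrame(
            {
                "snv_id": ["s1"],
                "minR": [3],
                "n_cells": [100],
                "n_biallelic": [50],
                "frac_biallelic": [0.5],
            }
        )
        res = compare_intronic(summary, annot_for(["s1"], category="utr3"), 3)
        assert res == {"applicable": False, "minR": 3}

    def test_reduced_depth_lowers_biallelic_proportion(self, rng):
        # same true p = 0.5; intronic loci sampled at depth 3 vs 10
        frames = []
        for j in range(5):
            frames.append(estimate_vaf(binomial_counts(rng, 300, 3, 0.5, f"i{j}"), 3))
            frames.append(estimate_vaf(binomial_counts(rng, 300, 10, 0.5, f"e{j}"), 3))
        summary = summarize_snv(pd.concat(frames, ignore_index=True), CFG10)
        ids = [f"i{j}" for j in range(5)] + [f"e{j}" for j in range(5)]
        annot = annot_for(
            ids,
            gene={s: "G" for s in ids},
            category={s: ("intron" if s.startswith("i") else "utr3") for s in ids},
        )
        res = compare_intronic(summary, annot, 3)
        # analytic: P(biallelic | depth 3) = P(Bin(3,.5) in {1,2}) = 0.75
        #           P(biallelic | depth 10) = P(Bin(10,.5) in 3..7) ~ 0.891
        assert res["intronic_biallelic_prop"] < res["nonintronic_biallelic_prop"]
        assert res["intronic_biallelic_prop"] == pytest.approx(0.75, abs=0.05)
        assert res["p_value"] < 0.05


class TestVafHistogram:
    def test_placement(self):
        counts = make_counts(
            [("c1", "s1", 3, 0), ("c2", "s1", 19, 1), ("c3", "s1", 0, 3)]
        )
        hist = vaf_histogram(estimate_vaf(counts, 3))
        by_bin = dict(zip(hist["bin"], hist["count"]))
        assert by_bin["0"] == 1 and by_bin["1"] == 1 and by_bin["(0,0.1]"] == 1
        assert hist["count"].sum() == 3

    def test_uniform_grid_coverage(self):
        # vaf = k/20 for odd k: 0.05, 0.15, ..., 0.95 -> one per interior bin
        counts = make_counts(
            [(f"c{k}", "s1", 20 - k, k) for k in range(1, 20, 2)]
        )
        hist = vaf_histogram(estimate_vaf(counts, 3))
        interior = hist.iloc[1:-1]
        assert (interior["count"] == 1).all()
        assert hist.iloc[0]["count"] == 0 and hist.iloc[-1]["count"] == 0

    def test_twelve_bins_and_total(self, rng):
        counts = binomial_counts(rng, 500, 10, 0.5)
        est = estimate_vaf(counts, 10)
        hist = vaf_histogram(est)
        assert len(hist) == 12
        assert hist["count"].sum() == len(est)

    def test_symmetric_modal_bin_is_central(self, rng):
        counts = binomial_counts(rng, 2000, 12, 0.5)
        est = estimate_vaf(counts, 10)
        hist = vaf_histogram(est)
        modal = hist.loc[hist["count"].idxmax(), "bin"]
        assert modal in ("(0.4,0.5]", "(0.5,0.6]")

    def test_boundary_values_in_left_closed_bins(self):
        # vaf 0.1 -> (0,0.1]; vaf 0.5 -> (0.4,0.5]
        counts = make_counts([("c1", "s1", 9, 1), ("c2", "s1", 5, 5)])
        hist = vaf_histogram(estimate_vaf(counts, 3))
        by_bin = dict(zip(hist["bin"], hist["count"]))
        assert by_bin["(0,0.1]"] == 1 and by_bin["(0.4,0.5]"] == 1

    def test_bad_width_rejected(self):
        counts = make_counts([("c1", "s1", 1, 1)])
        with pytest.raises(ConfigError):
            vaf_histogram(estimate_vaf(counts, 2), bin_width=0.3)


def test_minr_monotonic_strict_mono_fraction(rng):
    # pure binomial p=0.5 with Poisson depths: strict-mono rate falls with minR
    depths = rng.poisson(8, size=3000) + 1
    alts = rng.binomial(depths, 0.5)
    counts = make_counts(
        [
            (f"c{i}", "s1", int(d - a), int(a))
            for i, (d, a) in enumerate(zip(depths, alts))
        ]
    )
    fracs = []
    for minr in (3, 5, 10):
        summary = summarize_snv(estimate_vaf(counts, minr), CFG10)
        fracs.append(summary.iloc[0].frac_strict_mono)
    assert fracs[0] >= fracs[1] >= fracs[2]
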