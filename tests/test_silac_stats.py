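"""Interaction scoring statistics: normalization, tests, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from ppindiff.silac_stats import (
    Thresholds,
    add_significance_a,
    classify_rewiring,
    compare_conditions,
    filter_true_interactors,
    normalize_ratios,
    significance_a,
)
from ppindiff.silac_stats import test_enrichment as enrichment_vs_control
from ppindiff.synthetic_data import (
    SimulationConfig,
    generate_truth_network,
    simulate_silac_experiment,
)


def quant(rows):
    """Build a replicate table from (bait, prey, cond, bio, tech, orient, ratio)."""
    df = pd.DataFrame(
        rows,
        columns=["bait", "prey", "condition", "bio_rep", "tech_rep",
                 "label_orientation", "log2_ratio"],
    )
    df["replicate_id"] = "b" + df["bio_rep"].astype(str) + "t" + df["tech_rep"].astype(str)
    return df


class TestNormalize:
    def test_oriented_median_zero_input_is_unchanged(self):
        # three preys in one MS run, already oriented, median 0
        df = quant([("B", p, "hi", 1, 1, "forward", v)
                    for p, v in zip("abc", [-1.0, 0.0, 1.0])])
        out = normalize_ratios(df)
        assert np.allclose(out["log2_ratio"], df["log2_ratio"])

    def test_reverse_rows_are_sign_flipped(self):
        df = quant([("B", "P", "hi", 1, 1, "reverse", -1.3)])
        out = normalize_ratios(df, center=False)
        assert out["log2_ratio"].iloc[0] == pytest.approx(1.3)

    def test_median_centring(self):
        df = quant([("B", p, "hi", 1, 1, "forward", v)
                    for p, v in zip("abc", [1.0, 2.0, 3.0])])
        assert sorted(normalize_ratios(df)["log2_ratio"]) == [-1.0, 0.0, 1.0]

    def test_missing_orientation_names_rows(self):
        df = quant([("B", "P", "hi", 1, 1, "forward", 0.5)])
        df.loc[0, "label_orientation"] = None
        with pytest.raises(ValueError, match="label_orientation"):
            normalize_ratios(df)

    def test_input_not_modified(self):
        df = quant([("B", "P", "hi", 1, 1, "reverse", -2.0)])
        normalize_ratios(df)
        assert df["log2_ratio"].iloc[0] == -2.0


class TestEnrichment:
    BAIT = [3.1, 2.9, 3.0, 3.2, 2.8, 3.0]
    CTRL = [0.0, 0.1, -0.1, 0.0, 0.05, -0.05]

    def rows(self, bait_vals, ctrl_vals):
        b = quant([("B", "P", "hi", i, 1, "forward", v)
                   for i, v in enumerate(bait_vals, 1)])
        c = quant([("EV", "P", "control_hi", i, 1, "forward", v)
                   for i, v in enumerate(ctrl_vals, 1)])
        return b, c

    def test_strong_enrichment_matches_welch_oracle(self):
        b, c = self.rows(self.BAIT, self.CTRL)
        out = enrichment_vs_control(b, c)
        # independent oracle: scipy Welch t-test, one-sided
        ref = sstats.ttest_ind(self.BAIT, self.CTRL, equal_var=False,
                               alternative="greater")
        assert out["p_value"].iloc[0] == pytest.approx(ref.pvalue, rel=1e-9)
        assert out["p_value"].iloc[0] < 1e-3
        assert out["mean_log2fc"].iloc[0] == pytest.approx(3.0, abs=0.01)

    def test_identical_groups_give_half(self):
        b, c = self.rows(self.CTRL, self.CTRL)
        assert enrichment_vs_control(b, c)["p_value"].iloc[0] == pytest.approx(0.5, abs=0.02)

    def test_depleted_prey_gives_p_above_half(self):
        b, c = self.rows([-v - 1 for v in self.CTRL], self.CTRL)
        assert enrichment_vs_control(b, c)["p_value"].iloc[0] > 0.5

    def test_prey_without_controls_uses_pooled_null(self):
        b = quant([("B", "Q", "hi", i, 1, "forward", v)
                   for i, v in enumerate(self.BAIT, 1)])
        c = quant([("EV", "other", "control_hi", i, 1, "forward", v)
                   for i, v in enumerate(self.CTRL, 1)])
        out = enrichment_vs_control(b, c)
        assert out["p_value"].iloc[0] < 1e-3

    def test_single_replicate_prey_is_skipped(self, caplog):
        b = quant([("B", "P", "hi", 1, 1, "forward", 3.0)])
        c = quant([("EV", "P", "control_hi", i, 1, "forward", v)
                   for i, v in enumerate(self.CTRL, 1)])
        with caplog.at_level("WARNING"):
            out = enrichment_vs_control(b, c)
        assert out.empty and "skipping" in caplog.text

    def test_technical_replicates_are_collapsed(self):
        # 3 bio x 2 tech: test n must be the biological replicate count
        b = quant([("B", "P", "hi", bio, tech, "forward", 3.0 + 0.1 * tech)
                   for bio in (1, 2, 3) for tech in (1, 2)])
        c = quant([("EV", "P", "control_hi", bio, tech, "forward", 0.0)
                   for bio in (1, 2, 3) for tech in (1, 2)])
        assert enrichment_vs_control(b, c)["n_replicates"].iloc[0] == 3


class TestSignificanceA:
    def test_median_value_scores_half(self):
        vals = np.linspace(-2, 2, 21)
        out = significance_a(vals)
        assert out[10] == pytest.approx(0.5)

    def test_z_196_scores_0025(self):
        # quantile grid of a standard normal: robust z == ordinary z
        grid = sstats.norm.ppf(np.linspace(0.0005, 0.9995, 9999))
        vals = np.append(grid, 1.96)
        out = significance_a(vals)
        assert out[-1] == pytest.approx(0.025, abs=0.002)

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=200)
        assert np.allclose(significance_a(vals), significance_a(vals + 5.0))

    def test_degenerate_spread_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            significance_a(np.zeros(20))

    def test_degenerate_spread_saturates_on_request(self):
        vals = np.append(np.zeros(20), [4.0])
        out = significance_a(vals, on_degenerate="saturate")
        assert out[-1] == 0.0 and out[0] == pytest.approx(0.5)

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError, match=">= 10"):
            significance_a(np.arange(5))


class TestFilter:
    def stats_frame(self, rows):
        return pd.DataFrame(rows, columns=["bait", "prey", "mean_log2fc",
                                           "p_value", "sig_a", "n_replicates"])

    def test_step1_excludes_nonsignificant(self):
        df = self.stats_frame([("B1", "P1", 2.0, 0.2, 0.01, 3),
                               ("B1", "P2", 2.0, 0.01, 0.01, 3)])
        out = filter_true_interactors(df, Thresholds(), bait_count=95)
        assert list(out["prey"]) == ["P2"]

    def test_step2_removes_frequent_flyers(self):
        rows = [(f"B{i}", "sticky", 2.0, 0.01, 0.01, 3) for i in range(60)]
        rows += [("B0", "genuine", 2.0, 0.01, 0.01, 3)]
        out = filter_true_interactors(
            self.stats_frame(rows), Thresholds(contaminant_max_frequency=0.5),
            bait_count=95,
        )
        assert set(out["prey"]) == {"genuine"}

    def test_exclusion_list_is_applied(self):
        df = self.stats_frame([("B1", "P1", 2.0, 0.01, 0.01, 3)])
        out = filter_true_interactors(df, Thresholds(), 95, exclusion={"P1"})
        assert out.empty

    def test_default_config_precision(self, default_screen):
        """At study-design defaults the retained interactions are >=90%
        planted truth edges (pooled over both conditions)."""
        truth = default_screen["truth"]
        tp = fp = 0
        for cond in ("hi", "lo"):
            edges = set(zip(default_screen["interactions"][cond]["bait"],
                            default_screen["interactions"][cond]["prey"]))
            tp += len(edges & truth.edges[cond])
            fp += len(edges - truth.edges[cond])
        assert tp / (tp + fp) >= 0.9


class TestCompareConditions:
    def test_null_ratios_give_p_one(self):
        df = quant([("B", f"P{j}", "hi_vs_lo", i, 1, "forward", 0.0)
                    for j in range(12) for i in (1, 2, 3)])
        out = compare_conditions(df)
        assert (out["p_value"] == 1.0).all()

    def test_shifted_prey_among_nulls_is_significant(self):
        rng = np.random.default_rng(2)
        rows = [("B", f"P{j}", "hi_vs_lo", i, 1, "forward", rng.normal(0, 0.05))
                for j in range(30) for i in (1, 2, 3)]
        rows += [("B", "hit", "hi_vs_lo", i, 1, "forward", v)
                 for i, v in enumerate([2.1, 1.9, 2.0], 1)]
        out = compare_conditions(quant(rows)).set_index("prey")
        assert out.loc["hit", "p_value"] < 0.01
        assert out.loc["hit", "sig_a"] < 0.05

    def test_negation_symmetry(self):
        rng = np.random.default_rng(3)
        rows = [("B", f"P{j}", "hi_vs_lo", i, 1, "forward", rng.normal(j / 10, 0.2))
                for j in range(15) for i in (1, 2, 3)]
        df = quant(rows)
        flipped = df.assign(log2_ratio=-df["log2_ratio"])
        a = compare_conditions(df).set_index("prey")
        b = compare_conditions(flipped).set_index("prey")
        assert np.allclose(a["p_value"], b["p_value"])
        assert np.allclose(a["mean_log2fc"], -b["mean_log2fc"])
        assert np.allclose(a["sig_a"], b["sig_a"])


class TestClassifyRewiring:
    def diff(self, rows):
        return pd.DataFrame(rows, columns=["bait", "prey", "mean_log2fc",
                                           "p_value", "sig_a", "n_replicates"])

    def test_significant_single_network_edges(self):
        stats = self.diff([("B", "P", 3.0, 0.001, 0.01, 3)])
        out = classify_rewiring([("B", "P")], [], stats, Thresholds())
        assert out["category"].iloc[0] == "hi_only"

    def test_nonsignificant_single_network_edge_is_unchanged(self):
        stats = self.diff([("B", "P", 3.0, 0.4, 0.01, 3)])
        out = classify_rewiring([("B", "P")], [], stats, Thresholds())
        assert out["category"].iloc[0] == "unchanged"

    def test_shared_edge_direction(self):
        stats = self.diff([("B", "P", 1.5, 0.01, 0.02, 3),
                           ("B", "Q", -1.5, 0.01, 0.02, 3)])
        out = classify_rewiring([("B", "P"), ("B", "Q")],
                                [("B", "P"), ("B", "Q")], stats,
                                Thresholds()).set_index("prey")
        assert out.loc["P", "category"] == "shared_up_hi"
        assert out.loc["Q", "category"] == "shared_up_lo"

    def test_missing_stat_raises_with_edge(self):
        with pytest.raises(ValueError, match="lack"):
            classify_rewiring([("B", "P")], [], self.diff([]), Thresholds())

    def test_categories_partition_union(self, recovery_screen):
        calls = recovery_screen["calls"]
        hi = set(zip(recovery_screen["interactions"]["hi"]["bait"],
                     recovery_screen["interactions"]["hi"]["prey"]))
        lo = set(zip(recovery_screen["interactions"]["lo"]["bait"],
                     recovery_screen["interactions"]["lo"]["prey"]))
        assert len(calls) == len(hi | lo)
        assert calls["category"].isin(
            ["hi_only", "lo_only", "shared_up_hi", "shared_up_lo", "unchanged"]
        ).all()

    def test_hi_lo_swap_mirrors_categories(self, recovery_screen):
        calls = recovery_screen["calls"]
        hi = list(zip(recovery_screen["interactions"]["hi"]["bait"],
                      recovery_screen["interactions"]["hi"]["prey"]))
        lo = list(zip(recovery_screen["interactions"]["lo"]["bait"],
                      recovery_screen["interactions"]["lo"]["prey"]))
        stats = recovery_screen["diff_stats"]
        swapped_stats = stats.assign(mean_log2fc=-stats["mean_log2fc"])
        swapped = classify_rewiring(lo, hi, swapped_stats, Thresholds())
        mirror = {"hi_only": "lo_only", "lo_only": "hi_only",
                  "shared_up_hi": "shared_up_lo", "shared_up_lo": "shared_up_hi",
                  "unchanged": "unchanged"}
        merged = calls.merge(swapped, on=["bait", "prey"], suffixes=("", "_sw"))
        assert (merged["category_sw"] == merged["category"].map(mirror)).all()

    @given(p_tight=st.floats(0.001, 0.05))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_tightening_p_never_grows_rewired_set(self, p_tight):
        rng = np.random.default_rng(11)
        stats = self.diff([
            ("B", f"P{i}", rng.normal(), rng.random(), rng.random(), 3)
            for i in range(40)
        ])
        edges = [("B", f"P{i}") for i in range(40)]
        loose = classify_rewiring(edges, edges, stats, Thresholds())
        tight = classify_rewiring(edges, edges, stats, Thresholds(p_max=p_tight))
        n_loose = (loose["category"] != "unchanged").sum()
        n_tight = (tight["category"] != "unchanged").sum()
        assert n_tight <= n_loose

    def test_noise_free_classification_is_exact(self):
        cfg = SimulationConfig(
            seed=13, n_baits=10, mean_preys_per_bait=15, noise_sd=0.0,
            run_offset_sd=0.0, n_background=150, n_contaminants=0,
        )
        truth = generate_truth_network(cfg)
        from conftest import run_screen

        screen = run_screen(cfg)
        got = {(r.bait, r.prey): r.category
               for r in screen["calls"].itertuples()}
        for edge, want in truth.category.items():
            assert got.get(edge, "missing") == want
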