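"""Binned phenotype frequencies, stratified tests, heatmap, clustering."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from acinoscreen.screen_stats import (
    StratifiedTable,
    bin_phenotypes,
    breslow_day_test,
    build_heatmap,
    cluster_phenotype_groups,
    cmh_test,
    log2_fold_change,
    mantel_haenszel_or,
    zscore_normalize,
    _fitted_cell,
)
from acinoscreen.synthetic_data import (
    ScreenSimConfig,
    TRANSITION_SPREAD_2X,
    simulate_screen_counts,
)


def make_counts(records):
    df = pd.DataFrame.from_records(
        records,
        columns=["condition", "replicate", "time_bin", "class", "count"],
    )
    df["bin_total"] = df.groupby(
        ["condition", "replicate", "time_bin"])["count"].transform("sum")
    return df


class TestBinPhenotypes:
    def test_97_hourly_frames_give_nine_bins(self):
        labeled = pd.DataFrame({
            "condition": "Scr", "replicate": 1,
            "time_h": np.arange(97.0), "label": "Round",
        })
        counts = bin_phenotypes(labeled)
        bins = sorted(counts["time_bin"].unique())
        assert bins == list(range(9))
        totals = counts.drop_duplicates(["time_bin"]).set_index("time_bin")
        assert totals.loc[0, "bin_total"] == 12
        assert totals.loc[8, "bin_total"] == 1  # truncated [96, 97)

    def test_object_contributes_once_per_frame(self):
        labeled = pd.DataFrame({
            "condition": "Scr", "replicate": 1,
            "time_h": np.arange(12.0), "label": "Round",
        })
        counts = bin_phenotypes(labeled)
        row = counts[(counts["class"] == "Round")
                     & (counts["time_bin"] == 0)].iloc[0]
        assert row["count"] == 12 and row["bin_total"] == 12

    def test_unlabeled_record_rejected(self):
        labeled = pd.DataFrame({
            "condition": ["Scr"], "replicate": [1],
            "time_h": [0.0], "label": [None],
        })
        with pytest.raises(ValueError):
            bin_phenotypes(labeled)

    def test_totals_match_simulator_emission(self):
        cfg = ScreenSimConfig(n_conditions=1, n_replicates=1,
                              objects_per_field=10, fields_per_well=2,
                              n_frames=25, seed=3)
        counts = simulate_screen_counts(cfg)
        totals = counts.drop_duplicates(["time_bin"])
        # 10 objects x 2 fields x frames-in-bin
        assert (totals.set_index("time_bin")["bin_total"]
                == [240, 240, 20]).all()


class TestLog2FoldChange:
    def test_equal_proportions_give_zero(self):
        counts = make_counts([
            ("Scr", 1, 0, "Round", 50), ("Scr", 1, 0, "Spread", 50),
            ("kd", 1, 0, "Round", 50), ("kd", 1, 0, "Spread", 50),
        ])
        lfc = log2_fold_change(counts, "Scr")
        assert np.allclose(lfc["log2fc"], 0.0)

    def test_doubled_proportion_near_one(self):
        counts = make_counts([
            ("Scr", 1, 0, "Round", 8000), ("Scr", 1, 0, "Spread", 2000),
            ("kd", 1, 0, "Round", 6000), ("kd", 1, 0, "Spread", 4000),
        ])
        lfc = log2_fold_change(counts, "Scr")
        spread = lfc[lfc["class"] == "Spread"]["log2fc"].iloc[0]
        assert spread == pytest.approx(1.0, abs=0.02)

    def test_doubly_empty_class_gives_exact_zero(self):
        counts = make_counts([
            ("Scr", 1, 0, "Round", 50), ("Scr", 1, 0, "Spread", 0),
            ("kd", 1, 0, "Round", 60), ("kd", 1, 0, "Spread", 0),
        ])
        lfc = log2_fold_change(counts, "Scr")
        spread = lfc[lfc["class"] == "Spread"]["log2fc"].iloc[0]
        assert spread == 0.0


class TestZscore:
    def test_constant_series_all_zero(self):
        assert (zscore_normalize([3.0, 3.0, 3.0]) == 0).all()

    def test_two_point_series(self):
        z = zscore_normalize([0.0, 1.0])
        assert z == pytest.approx([-1.0, 1.0], abs=1e-12) or \
            z == pytest.approx([-0.7071, 0.7071], abs=1e-4)

    def test_output_standardized(self):
        rng = np.random.default_rng(0)
        z = zscore_normalize(rng.normal(5, 3, 40))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)


class TestCMH:
    def test_unit_odds_ratio_strata(self):
        table = StratifiedTable(np.array([[[10, 10], [10, 10]]] * 3))
        statistic, p = cmh_test(table)
        assert statistic == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_single_stratum_closed_form(self):
        table = StratifiedTable(np.array([[[12, 0], [6, 3]]]))
        statistic, p = cmh_test(table)
        # (T-1)/T x Pearson chi2 = 20/21 * 4.667 = 4.444
        assert statistic == pytest.approx(4.444, abs=5e-4)
        assert p == pytest.approx(0.0350, abs=5e-4)

    @given(st.lists(st.integers(1, 40), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_single_stratum_pearson_identity(self, cells):
        a, b, c, d = (float(v) for v in cells)
        statistic, _ = cmh_test(StratifiedTable([[[a, b], [c, d]]]))
        chi2, _, _, _ = stats.chi2_contingency([[a, b], [c, d]],
                                               correction=False)
        t = a + b + c + d
        assert statistic == pytest.approx((t - 1) / t * chi2, rel=1e-10)

    def test_matches_statsmodels_on_random_strata(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            strata = rng.integers(1, 30, size=(3, 2, 2)).astype(float)
            statistic, p = cmh_test(StratifiedTable(strata))
            ref = sm.stats.StratifiedTable(
                [s for s in strata]).test_null_odds(correction=False)
            assert statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_degenerate_strata_flagged(self):
        statistic, p = cmh_test(
            StratifiedTable(np.array([[[0, 0], [5, 5]]])))
        assert np.isnan(statistic) and p == 1.0


class TestBreslowDay:
    def test_identical_strata_perfectly_homogeneous(self):
        table = StratifiedTable(np.array([[[12, 4], [6, 9]]] * 2))
        statistic, p, _ = breslow_day_test(table)
        assert statistic == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_reversed_effect_detected(self):
        table = StratifiedTable(
            np.array([[[20, 5], [5, 20]], [[5, 20], [20, 5]]]))
        statistic, p, common_or = breslow_day_test(table)
        assert statistic > 20
        assert p < 0.01

    def test_matches_statsmodels_on_random_strata(self):
        rng = np.random.default_rng(22)
        checked = 0
        while checked < 100:
            strata = rng.integers(1, 30, size=(3, 2, 2)).astype(float)
            psi = mantel_haenszel_or(strata)
            if abs(psi - 1) < 1e-6:
                continue
            statistic, p, _ = breslow_day_test(StratifiedTable(strata))
            ref = sm.stats.StratifiedTable(
                [s for s in strata]).test_equal_odds(adjust=False)
            assert statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)
            checked += 1

    @given(st.lists(st.integers(1, 50), min_size=8, max_size=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_fitted_counts_respect_margins_and_common_or(self, cells):
        strata = np.array(cells, dtype=float).reshape(2, 2, 2)
        try:
            psi = mantel_haenszel_or(strata)
        except ValueError:
            return
        for a, b, c, d in strata.reshape(-1, 4):
            n1, m1, t = a + b, a + c, a + b + c + d
            a_fit = _fitted_cell(n1, m1, t, psi)
            lo, hi = max(0.0, n1 + m1 - t), min(n1, m1)
            assert lo - 1e-9 <= a_fit <= hi + 1e-9
            b_fit, c_fit = n1 - a_fit, m1 - a_fit
            d_fit = t - n1 - m1 + a_fit
            if min(b_fit, c_fit, d_fit, a_fit) > 1e-9:
                fitted_or = a_fit * d_fit / (b_fit * c_fit)
                assert fitted_or == pytest.approx(psi, rel=1e-6)

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError):
            breslow_day_test(StratifiedTable(np.array([[[5, 5], [5, 5]]])))


def screen_config(seed, effect=None, jitter=0.0, objects=150):
    matrices = [effect] if effect is not None else None
    return ScreenSimConfig(
        n_conditions=2, n_replicates=3, wells_per_condition=1,
        fields_per_well=2, objects_per_field=objects,
        transition_matrix_per_condition=matrices,
        replicate_jitter=jitter, seed=seed,
    )


class TestHeatmap:
    def test_null_produces_no_adjusted_hits(self):
        hits = 0
        cells = 0
        for seed in range(20):
            counts = simulate_screen_counts(screen_config(seed))
            heatmap = build_heatmap(counts, "Scr")
            hits += int((heatmap["cmh_p_adj"] < 0.05).sum())
            cells += len(heatmap)
            assert heatmap["log2fc"].abs().max() < 0.5
        assert hits / cells <= 0.05

    def test_planted_spread_enrichment_recovered_homogeneous(self):
        counts = simulate_screen_counts(
            screen_config(7, effect=TRANSITION_SPREAD_2X))
        heatmap = build_heatmap(counts, "Scr")
        spread = heatmap[heatmap["class"] == "Spread"]
        hit = spread[spread["cmh_p_adj"] < 0.05]
        assert not hit.empty
        assert hit["log2fc"].max() > 0.5
        assert hit["homogeneous"].all()

    def test_heterogeneous_effect_attenuates_cmh_and_flags_bd(self):
        # effect present in 2 of 3 replicates, reversed in the third
        base = simulate_screen_counts(
            screen_config(11, effect=TRANSITION_SPREAD_2X))
        consistent = build_heatmap(base, "Scr")
        flipped = base.copy()
        # swap condition/control counts in replicate 3 (reverses the effect)
        r3 = flipped["replicate"] == 3
        cond = r3 & (flipped["condition"] == "cond1")
        ctrl = r3 & (flipped["condition"] == "Scr")
        flipped.loc[cond, "condition"] = "_tmp"
        flipped.loc[ctrl, "condition"] = "cond1"
        flipped.loc[flipped["condition"] == "_tmp", "condition"] = "Scr"
        mixed = build_heatmap(flipped, "Scr")
        spread_bins = consistent[(consistent["class"] == "Spread")
                                 & (consistent["cmh_p_adj"] < 0.05)
                                 ]["time_bin"]
        late = spread_bins.max()
        cell_cons = consistent[(consistent["class"] == "Spread")
                               & (consistent["time_bin"] == late)].iloc[0]
        cell_mix = mixed[(mixed["class"] == "Spread")
                         & (mixed["time_bin"] == late)].iloc[0]
        assert cell_mix["cmh_p"] > cell_cons["cmh_p"]
        assert cell_mix["bd_p"] < 0.05
        assert not cell_mix["homogeneous"]

    def test_missing_control_rejected(self):
        counts = simulate_screen_counts(screen_config(1))
        with pytest.raises(ValueError):
            build_heatmap(counts, "nonexistent")


def archetype_heatmap(n_groups=7, per_group=5, noise_sd=0.05, seed=0,
                      n_bins=9):
    rng = np.random.default_rng(seed)
    archetypes = rng.normal(0, 1.5, size=(n_groups, 3 * n_bins))
    records = []
    truth = {}
    for g in range(n_groups):
        for i in range(per_group):
            condition = f"g{g}c{i}"
            truth[condition] = g
            profile = archetypes[g] + rng.normal(0, noise_sd, 3 * n_bins)
            idx = 0
            for cls in ("Round", "Spindle", "Spread"):
                for b in range(n_bins):
                    records.append({"condition": condition, "class": cls,
                                    "time_bin": b, "log2fc": profile[idx]})
                    idx += 1
    return pd.DataFrame.from_records(records), truth


def adjusted_rand_index(labels_a, labels_b):
    """ARI from the pair-counting contingency table (closed form)."""
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    ct = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        return x * (x - 1) / 2

    sum_ij = comb2(ct).sum()
    sum_a = comb2(ct.sum(axis=1)).sum()
    sum_b = comb2(ct.sum(axis=0)).sum()
    n = ct.sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2
    return (sum_ij - expected) / (max_index - expected)


class TestClustering:
    def test_planted_archetypes_recovered(self):
        heatmap, truth = archetype_heatmap()
        assignment = cluster_phenotype_groups(heatmap, k=7)
        found = [assignment.groups[c] for c in sorted(truth)]
        planted = [truth[c] for c in sorted(truth)]
        assert adjusted_rand_index(found, planted) == pytest.approx(1.0)

    def test_identical_conditions_merge_first_at_zero(self):
        heatmap, _ = archetype_heatmap(n_groups=3, per_group=1, noise_sd=0.0)
        twin = heatmap[heatmap["condition"] == "g0c0"].copy()
        twin["condition"] = "g0c0twin"
        heatmap = pd.concat([heatmap, twin], ignore_index=True)
        assignment = cluster_phenotype_groups(heatmap, k=2)
        assert assignment.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        merged = {int(assignment.linkage[0, 0]),
                  int(assignment.linkage[0, 1])}
        twins = {assignment.conditions.index("g0c0"),
                 assignment.conditions.index("g0c0twin")}
        assert merged == twins

    def test_single_condition_single_group(self):
        heatmap, _ = archetype_heatmap(n_groups=1, per_group=1)
        assignment = cluster_phenotype_groups(heatmap, k=1)
        assert list(assignment.groups.values()) == [1]

    def test_input_order_invariance(self):
        heatmap, truth = archetype_heatmap(seed=5)
        shuffled = heatmap.sample(frac=1.0, random_state=3)
        a = cluster_phenotype_groups(heatmap, k=7)
        b = cluster_phenotype_groups(shuffled, k=7)
        order_a = [a.groups[c] for c in sorted(truth)]
        order_b = [b.groups[c] for c in sorted(truth)]
        assert adjusted_rand_index(order_a, order_b) == pytest.approx(1.0)

    def test_k_exceeding_conditions_rejected(self):
        heatmap, _ = archetype_heatmap(n_groups=2, per_group=1)
        with pytest.raises(ValueError):
            cluster_phenotype_groups(heatmap, k=5)

    def test_newick_export_contains_all_conditions(self):
        heatmap, truth = archetype_heatmap(n_groups=3, per_group=2)
        assignment = cluster_phenotype_groups(heatmap, k=3)
        newick = assignment.to_newick()
        assert newick.endswith(";")
        for condition in truth:
            assert condition in newick
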