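import itertools

import numpy as np
import pandas as pd
import pytest

from cytocycle.errors import ParameterError
from cytocycle.matrix import ExpressionMatrix
from cytocycle.stats import (bh_adjust, classify_cell_lines,
                             correlation_similarity, differential_test,
                             pseudobulk_aggregate, scale_features,
                             variance_explained, variance_partition)


def as_matrix(x, channels=None, meta=None, scaled=False):
    x = np.asarray(x, float)
    channels = channels or [f"m{i}" for i in range(x.shape[1])]
    meta = meta if meta is not None else pd.DataFrame(index=range(x.shape[0]))
    m = ExpressionMatrix(x, channels, meta, "normalized")
    if scaled:
        m = scale_features(m)
    return m


class TestScaleFeatures:
    def test_channels_become_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        m = scale_features(as_matrix(rng.gamma(2, 1, size=(500, 3))))
        np.testing.assert_allclose(m.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(m.values.std(axis=0), 1.0, atol=1e-9)

    def test_constant_channel_zeroed_with_warning(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="constant"):
            m = scale_features(as_matrix(x))
        np.testing.assert_array_equal(m.values[:, 0], 0.0)

    def test_two_point_channel_maps_to_plus_minus_one(self):
        m = scale_features(as_matrix(np.array([[0.0], [2.0]])))
        np.testing.assert_allclose(np.sort(m.values[:, 0]), [-1.0, 1.0])


class TestBHAdjust:
    def test_reproduces_textbook_step_up_procedure(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205])
        # independent oracle: direct sort-based step-up computation
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = n - rank_from_end
            running = min(running, p[idx] * n / rank)
            adj[idx] = running
        np.testing.assert_allclose(bh_adjust(p), adj, atol=1e-12)


class TestDifferentialTest:
    def _two_group(self, shift, n=2000, n_markers=5, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(2 * n, n_markers))
        x[n:, 0] += shift
        meta = pd.DataFrame({"treatment": ["ctl"] * n + ["tx"] * n})
        return as_matrix(x, meta=meta, scaled=True)

    def test_coefficient_equals_difference_of_scaled_group_means(self):
        m = self._two_group(shift=0.8)
        res = differential_test(m, "treatment", "ctl").set_index("marker")
        tx = m.cell_meta["treatment"] == "tx"
        for j, marker in enumerate(m.channel_names):
            expected = m.values[tx, j].mean() - m.values[~tx, j].mean()
            assert res.loc[marker, "coef"] == pytest.approx(expected, abs=1e-9)

    def test_null_data_produces_no_significant_calls(self):
        m = self._two_group(shift=0.0, seed=1)
        res = differential_test(m, "treatment", "ctl")
        assert not res["significant"].any()
        assert (res["padj"] >= res["wald_p"] - 1e-15).all()

    def test_one_sd_shift_is_detected(self):
        m = self._two_group(shift=1.0, seed=2)
        res = differential_test(m, "treatment", "ctl").set_index("marker")
        assert bool(res.loc["m0", "significant"])
        assert not res.drop("m0")["significant"].any()

    def test_single_level_stratum_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        meta = pd.DataFrame({
            "treatment": ["ctl"] * 50 + ["tx"] * 50,
            "phase": ["A"] * 50 + ["B"] * 50,  # each stratum single-level
        })
        m = as_matrix(rng.normal(size=(100, 2)), meta=meta, scaled=True)
        with pytest.warns(UserWarning, match="single contrast level"):
            res = differential_test(m, "treatment", "ctl", stratify_by="phase")
        assert res.empty

    def test_requires_scaled_features(self):
        m = as_matrix(np.random.default_rng(4).normal(size=(10, 2)),
                      meta=pd.DataFrame({"treatment": ["a"] * 5 + ["b"] * 5}))
        with pytest.raises(ParameterError):
            differential_test(m, "treatment", "a")


class TestVarianceExplained:
    def test_pure_between_group_signal_gives_100_percent(self):
        x = np.array([[1.0], [1.0], [5.0], [5.0]])
        pct = variance_explained(as_matrix(x), np.array(["a", "a", "b", "b"]))
        assert pct.iloc[0] == pytest.approx(100.0)

    def test_equals_100_times_r_squared_of_oneway_model(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(300, 2))
        groups = rng.choice(["a", "b", "c"], size=300)
        x[groups == "b", 0] += 1.0
        pct = variance_explained(as_matrix(x), groups)
        import statsmodels.formula.api as smf
        for j in (0, 1):
            df = pd.DataFrame({"y": x[:, j], "g": groups})
            r2 = smf.ols("y ~ C(g)", df).fit().rsquared
            assert pct.iloc[j] == pytest.approx(100 * r2, abs=1e-9)

    def test_permuted_labels_match_chance_expectation(self):
        rng = np.random.default_rng(6)
        n, k = 5000, 5
        x = rng.normal(size=(n, 20))
        labels = rng.permutation(np.repeat(np.arange(k), n // k))
        pct = variance_explained(as_matrix(x), labels)
        expected = 100 * (k - 1) / (n - 1)
        assert abs(pct.mean() - expected) < 0.05

    def test_single_level_factor_rejected(self):
        with pytest.raises(ParameterError):
            variance_explained(as_matrix(np.ones((4, 1))),
                               np.array(["a"] * 4))


class TestVariancePartition:
    @staticmethod
    def _component(labels, rng):
        levels = pd.unique(labels)
        eff = pd.Series(rng.standard_normal(len(levels)), index=levels)
        v = eff[labels].to_numpy()
        return (v - v.mean()) / v.std(ddof=0)

    def _balanced_design(self, reps=3):
        rows = list(itertools.product(
            [f"L{i}" for i in range(5)], ["G0G1", "S", "G2", "M"],
            ["untx", "drugA", "drugB"], range(reps),
        ))
        return pd.DataFrame(rows, columns=["line", "phase", "treatment", "rep"])

    def test_known_components_recovered_within_5_points(self):
        rng = np.random.default_rng(7)
        fac = self._balanced_design()
        y = (np.sqrt(0.60) * self._component(fac["line"], rng)
             + np.sqrt(0.25) * self._component(fac["phase"], rng)
             + np.sqrt(0.10) * self._component(fac["treatment"], rng))
        noise = rng.standard_normal(len(fac))
        y = y + np.sqrt(0.05) * (noise - noise.mean()) / noise.std(ddof=0)
        res = variance_partition(pd.DataFrame({"mk": y}),
                                 fac[["line", "phase", "treatment"]])
        props = res.set_index("term")["proportion"]
        assert abs(props["line"] - 0.60) < 0.05
        assert abs(props["phase"] - 0.25) < 0.05
        assert abs(props["treatment"] - 0.10) < 0.05
        assert abs(props.sum() - 1.0) < 1e-6

    def test_single_factor_signal_dominates(self):
        rng = np.random.default_rng(8)
        fac = self._balanced_design(reps=2)
        y = self._component(fac["line"], rng) + 1e-3 * rng.standard_normal(len(fac))
        res = variance_partition(pd.DataFrame({"mk": y}),
                                 fac[["line", "phase", "treatment"]])
        props = res.set_index("term")["proportion"]
        assert props["line"] > 0.99

    def test_balanced_design_invariant_to_term_order(self):
        rng = np.random.default_rng(9)
        fac = self._balanced_design(reps=2)
        y = (self._component(fac["line"], rng)
             + 0.5 * self._component(fac["phase"], rng)
             + 0.3 * rng.standard_normal(len(fac)))
        pb = pd.DataFrame({"mk": y})
        a = variance_partition(pb, fac[["line", "phase"]])
        b = variance_partition(pb, fac[["phase", "line"]])
        pa = a.set_index("term")["proportion"]
        pb_ = b.set_index("term")["proportion"]
        for term in ("line", "phase"):
            assert pa[term] == pytest.approx(pb_[term], abs=1e-9)


class TestPseudobulk:
    def test_single_cell_sample_equals_that_cell(self):
        m = as_matrix(np.array([[1.0, 2.0], [7.0, 8.0]]))
        pb = pseudobulk_aggregate(m, np.array(["a", "b"]))
        np.testing.assert_array_equal(pb.loc["a"].to_numpy(), [1.0, 2.0])

    def test_known_median(self):
        m = as_matrix(np.array([[1.0], [2.0], [9.0]]))
        pb = pseudobulk_aggregate(m, np.array(["g", "g", "g"]))
        assert pb.iloc[0, 0] == 2.0

    def test_grand_median_normalization(self):
        m = as_matrix(np.array([[2.0], [4.0]]))
        pb = pseudobulk_aggregate(m, np.array(["a", "b"]), normalize=True)
        np.testing.assert_allclose(sorted(pb["m0"]), [2 / 3, 4 / 3])


class TestClassification:
    def _lines(self, n_per_line=1500, separation=4.0, seed=0):
        rng = np.random.default_rng(seed)
        blocks, labels = [], []
        for i, line in enumerate(("A", "B", "C")):
            x = rng.normal(size=(n_per_line, 6))
            x[:, i] += separation  # disjoint offsets per line
            blocks.append(x)
            labels += [line] * n_per_line
        return np.vstack(blocks), np.array(labels)

    def test_separable_lines_reach_high_accuracy(self):
        x, labels = self._lines()
        from cytocycle.panels import PanelDefinition
        panel = PanelDefinition({f"m{i}": "minimal" for i in range(6)})
        m = as_matrix(x)
        report = classify_cell_lines(m, labels, panel="minimal",
                                     panel_def=panel, train_per_line=800,
                                     test_per_line=400, seed=1)
        assert report.accuracy >= 0.99
        assert (report.per_class["sensitivity"] >= 0.98).all()
        assert (report.pairwise["accuracy"] >= 0.99).all()

    def test_metrics_agree_with_direct_confusion_counting(self):
        x, labels = self._lines(separation=1.0, seed=2)
        from cytocycle.panels import PanelDefinition
        panel = PanelDefinition({f"m{i}": "minimal" for i in range(6)})
        report = classify_cell_lines(as_matrix(x), labels, panel="minimal",
                                     panel_def=panel, train_per_line=800,
                                     test_per_line=400, seed=3)
        row = report.per_class.set_index("class").loc["A"]
        # one-vs-rest identities
        assert 0 <= row["sensitivity"] <= 1 and 0 <= row["specificity"] <= 1

    def test_permuted_labels_fall_to_chance(self):
        x, labels = self._lines(seed=4)
        rng = np.random.default_rng(5)
        permuted = rng.permutation(labels)
        from cytocycle.panels import PanelDefinition
        panel = PanelDefinition({f"m{i}": "minimal" for i in range(6)})
        report = classify_cell_lines(as_matrix(x), permuted, panel="minimal",
                                     panel_def=panel, train_per_line=800,
                                     test_per_line=400, seed=6)
        assert abs(report.accuracy - 1 / 3) < 0.05

    def test_train_and_test_cells_disjoint(self):
        x, labels = self._lines()
        report = classify_cell_lines(
            as_matrix(x), labels, panel="minimal",
            panel_def=__import__("cytocycle").PanelDefinition(
                {f"m{i}": "minimal" for i in range(6)}),
            train_per_line=800, test_per_line=400, seed=7)
        assert report.n_train == 2400 and report.n_test == 1200


class TestCorrelationSimilarity:
    def test_duplicated_group_has_similarity_one(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(200, 5))
        x[:, 1] += x[:, 0]
        xx = np.vstack([x, x])
        groups = np.array(["g"] * 200 + ["h"] * 200)
        sim = correlation_similarity(as_matrix(xx), groups)
        assert sim.loc["g", "h"] == pytest.approx(1.0)

    def test_independent_noise_groups_have_near_zero_similarity(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(20_000, 5))
        groups = np.array(["g"] * 10_000 + ["h"] * 10_000)
        sim = correlation_similarity(as_matrix(x), groups)
        assert abs(sim.loc["g", "h"]) < 0.9  # pure noise: no stable pattern

    def test_feature_permutation_breaks_similarity(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(5000, 4))
        base[:, 1] += 2 * base[:, 0]  # strong correlated pair
        perm = base[:, [2, 3, 0, 1]]
        x = np.vstack([base, perm])
        groups = np.array(["g"] * 5000 + ["h"] * 5000)
        sim = correlation_similarity(as_matrix(x), groups)
        # brute-force expectation from the two correlation matrices
        iu = np.triu_indices(4, k=1)
        cg = np.corrcoef(base, rowvar=False)[iu]
        ch = np.corrcoef(perm, rowvar=False)[iu]
        expected = np.corrcoef(cg, ch)[0, 1]
        assert sim.loc["g", "h"] == pytest.approx(expected, abs=1e-12)
        assert sim.loc["g", "h"] < 1.0

    def test_constant_feature_warns(self):
        x = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0)**2])
        groups = np.array(["g"] * 5 + ["h"] * 5)
        with pytest.warns(UserWarning, match="constant"):
            correlation_similarity(as_matrix(x), groups)
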