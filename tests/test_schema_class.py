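import numpy as np
import pandas as pd
import pytest

import schemacells as sc
from schemacells.schema_class import _batch_pearson, categorize

from conftest import labelled_matrix, task_labels


class TestCrossMazeCorrelation:
    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(5, 2, 72), rng.normal(5, 2, 72)
        r, p = sc.cross_maze_r(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(r_direct, abs=1e-12)

    def test_identity_and_negation(self):
        x = np.arange(72, dtype=float)
        assert sc.cross_maze_r(x, x)[0] == pytest.approx(1.0)
        assert sc.cross_maze_r(x, -x)[0] == pytest.approx(-1.0)

    def test_p_value_uses_t_transform_with_70_df(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 72), rng.normal(0, 1, 72)
        r, p = sc.cross_maze_r(x, y)
        from scipy import stats
        t = r * np.sqrt(70 / (1 - r ** 2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 70), rel=1e-9)

    def test_degenerate_profile_is_nan(self):
        r, p = sc.cross_maze_r(np.ones(72), np.arange(72, dtype=float))
        assert np.isnan(r) and np.isnan(p)


class TestClassification:
    @pytest.mark.parametrize("r,p,expected", [
        (0.85, 1e-10, "schema"),
        (0.81, 0.02, "nonschema"),  # strong r without significance: downgraded
        (0.6, 1e-4, "nonschema"),
        (0.4, 1e-3, "nonschema"),
        (0.39, 0.5, "noncoding"),
        (-0.2, 0.5, "noncoding"),
        (float("nan"), float("nan"), "noncoding"),
    ])
    def test_category_thresholds(self, r, p, expected):
        assert categorize(r, p, sc.AnalysisConfig()) == expected

    def test_classify_unit_end_to_end(self, tuned_unit_matrices):
        m1, m2, _ = tuned_unit_matrices
        p1, p2 = sc.build_profile(m1), sc.build_profile(m2)
        assert sc.classify_unit(p1, p2) == "schema"

    def test_flat_profile_is_noncoding(self):
        assert sc.classify_unit(np.full(72, 2.0), np.arange(72.0)) == "noncoding"

    def test_affine_invariance(self, tuned_unit_matrices):
        m1, m2, _ = tuned_unit_matrices
        p1, p2 = sc.build_profile(m1).values, sc.build_profile(m2).values
        assert sc.classify_unit(p1, p2) == sc.classify_unit(3 * p1 + 2, 3 * p2 + 2)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sc.AnalysisConfig(r_schema=0.3, r_noncoding=0.4)
        with pytest.raises(ValueError):
            sc.AnalysisConfig(n_shuffles=50)


class TestThresholdSweep:
    def test_monotone_nonincreasing_and_endpoints(self):
        rng = np.random.default_rng(4)
        pairs = []
        for corr in np.linspace(0, 0.95, 12):
            x = rng.normal(0, 1, 72)
            y = corr * x + np.sqrt(1 - corr ** 2) * rng.normal(0, 1, 72)
            pairs.append((x + 5, y + 5))
        thresholds = np.linspace(0.0, 1.0, 11)
        frac = sc.threshold_sweep(pairs, thresholds)
        assert np.all(np.diff(frac) <= 0)
        assert frac[-1] == 0.0  # threshold 1: nothing qualifies

    def test_threshold_zero_without_p_counts_positive_r(self):
        pairs = [(np.arange(72.0), np.arange(72.0)),
                 (np.arange(72.0), -np.arange(72.0))]
        frac = sc.threshold_sweep(pairs, [0.0], apply_p=False)
        assert frac[0] == 0.5

    def test_empty_thresholds_rejected(self):
        with pytest.raises(ValueError):
            sc.threshold_sweep([(np.arange(72.0), np.arange(72.0))], [])

    def test_reproducible(self, tuned_unit_matrices, flat_unit_matrices):
        m1, m2, _ = tuned_unit_matrices
        f1, f2 = flat_unit_matrices
        pairs = [(sc.build_profile(m1).values, sc.build_profile(m2).values),
                 (sc.build_profile(f1).values, sc.build_profile(f2).values)]
        a = sc.threshold_sweep(pairs, [0.4, 0.8])
        b = sc.threshold_sweep(pairs, [0.4, 0.8])
        np.testing.assert_array_equal(a, b)


class TestShuffleInvariants:
    """The three structured shuffles preserve per-stratum value multisets
    and hence the grand mean exactly."""

    def test_multisets_and_grand_mean_on_random_matrices(self):
        rng = np.random.default_rng(9)
        labels = task_labels(5)  # 40 rows x 9 epochs
        rank = labels["position"].map({"P1": 0, "P2": 1, "P3": 0, "P4": 1})
        for _ in range(100):
            m = rng.gamma(2.0, 2.0, size=(40, 9))
            out_e = sc.shuffle_epoch(m, rng)
            np.testing.assert_array_equal(np.sort(out_e, axis=1), np.sort(m, axis=1))

            out_r = sc.shuffle_reward(m, labels, rng)
            for sub in "ab":
                for rk in (0, 1):
                    rows = ((labels["subsequence"] == sub) & (rank == rk)).to_numpy()
                    np.testing.assert_array_equal(np.sort(out_r[rows], axis=0),
                                                  np.sort(m[rows], axis=0))

            out_p = sc.shuffle_position(m, labels, rng)
            for rew in (0, 1):
                rows = (labels["rewarded"] == rew).to_numpy()
                np.testing.assert_array_equal(np.sort(out_p[rows], axis=0),
                                              np.sort(m[rows], axis=0))

            for out in (out_e, out_r, out_p):
                assert out.mean() == pytest.approx(m.mean(), abs=1e-12)

    def test_row_constant_matrix_unchanged_by_epoch_shuffle(self):
        rng = np.random.default_rng(0)
        m = np.tile(rng.uniform(1, 5, size=(40, 1)), (1, 9))
        np.testing.assert_array_equal(sc.shuffle_epoch(m, rng), m)

    def test_epoch_shuffle_collapses_epoch_tuning(self):
        # noiseless epoch-tuned unit: shuffled cross-maze r centers near 0
        m = labelled_matrix(lambda row, e: float(e + 1))
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(200):
            p1 = sc.response.profile_from_values(sc.shuffle_epoch(m.values, rng),
                                                 m.labels)
            p2 = sc.response.profile_from_values(sc.shuffle_epoch(m.values, rng),
                                                 m.labels)
            rs.append(_batch_pearson(p1, p2))
        assert abs(np.mean(rs)) < 0.2
        assert np.quantile(rs, 0.99) < 1.0  # far below the unshuffled r of 1

    def test_reward_shuffle_requires_both_categories(self):
        labels = task_labels(2)
        labels["rewarded"] = 0
        with pytest.raises(ValueError, match="reward"):
            sc.shuffle_reward(np.ones((64, 9)), labels, np.random.default_rng(0))


class TestAttribution:
    @pytest.mark.parametrize("tuning,expected", [
        (lambda row, e: 2.0 + e, {"epoch": True, "reward": False, "position": False}),
        (lambda row, e: 10.0 if row["rewarded"] else 2.0,
         {"epoch": False, "reward": True, "position": False}),
        (lambda row, e: 8.0 if row["position"] in ("P1", "P3") else 2.0,
         {"epoch": False, "reward": False, "position": True}),
    ])
    def test_single_factor_units_get_exactly_their_flag(self, tuning, expected):
        m = labelled_matrix(tuning)
        flags, _ = sc.attribute_factors(m, m, sc.AnalysisConfig(n_shuffles=200),
                                        seed=1)
        assert flags == expected

    def test_flat_unit_flags_undefined(self):
        m = labelled_matrix(lambda row, e: 4.0)
        flags, _ = sc.attribute_factors(m, m, sc.AnalysisConfig(n_shuffles=100),
                                        seed=0)
        assert flags == {"epoch": None, "reward": None, "position": None}

    def test_deterministic_given_seed(self, tuned_unit_matrices):
        m1, m2, _ = tuned_unit_matrices
        cfg = sc.AnalysisConfig(n_shuffles=100)
        a = sc.attribute_factors(m1, m2, cfg, seed=5)
        b = sc.attribute_factors(m1, m2, cfg, seed=5)
        assert a == b


class TestSelectivityAnova:
    def test_pure_epoch_unit(self):
        m = labelled_matrix(lambda row, e: float(e), trials_per_type=3)
        res = sc.selectivity_anova(m)
        assert res.partial_eta2["epoch"] == pytest.approx(1.0)
        assert res.partial_eta2["reward"] == pytest.approx(0.0, abs=1e-9)
        assert res.partial_eta2["position"] == pytest.approx(0.0, abs=1e-9)
        assert res.p_values["epoch"] < 1e-6
        assert res.preferred["epoch"] == sc.EPOCH_NAMES[-1]

    def test_balanced_toy_matches_statsmodels(self):
        # independent oracle: Type II ANOVA via statsmodels on a balanced
        # 2x2x2 design where the factors are NOT aliased
        rng = np.random.default_rng(8)
        rows = []
        for pos, rew in [("P1", 0), ("P1", 1), ("P2", 0), ("P2", 1)]:
            for i in range(4):
                rows.append({"type_key": f"x{pos}{rew}", "subsequence": "a",
                             "position": pos, "rewarded": rew,
                             "within_type_index": i + 1})
        labels = pd.DataFrame(rows)
        values = (rng.normal(5, 1, size=(16, 2))
                  + np.where(labels[["rewarded"]].to_numpy() == 1, 2.0, 0.0)
                  + np.where(labels[["position"]].to_numpy() == "P2", 1.0, 0.0)
                  + np.array([[0.0, 1.5]]))
        m = sc.EpochRateMatrix("toy", "maze1", values, labels,
                               epochs=("e1", "e2"))
        res = sc.selectivity_anova(m)

        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        frame = pd.DataFrame({
            "rate": values.ravel(),
            "epoch": np.tile(["e1", "e2"], 16),
            "reward": np.repeat(labels["rewarded"].astype(str), 2),
            "position": np.repeat(labels["position"], 2),
        })
        fit = ols("rate ~ C(epoch) + C(reward) + C(position)", frame).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        ss_err = table.loc["Residual", "sum_sq"]
        for factor, term in [("epoch", "C(epoch)"), ("reward", "C(reward)"),
                             ("position", "C(position)")]:
            ss = table.loc[term, "sum_sq"]
            assert res.partial_eta2[factor] == pytest.approx(ss / (ss + ss_err),
                                                             rel=1e-6)
            assert res.p_values[factor] == pytest.approx(table.loc[term, "PR(>F)"],
                                                         rel=1e-6)

    def test_eta2_bounded_for_random_input(self, flat_unit_matrices):
        m1, _ = flat_unit_matrices
        res = sc.selectivity_anova(m1)
        for factor in ("epoch", "reward", "position"):
            assert 0.0 <= res.partial_eta2[factor] <= 1.0

    def test_reward_tuned_unit_prefers_rewarded(self):
        m = labelled_matrix(lambda row, e: 9.0 if row["rewarded"] else 2.0,
                            trials_per_type=3)
        res = sc.selectivity_anova(m)
        assert res.p_values["reward"] < 0.01
        assert res.preferred["reward"] == "1"
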