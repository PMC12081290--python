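import numpy as np
import pytest

import schemacells as sc
from schemacells.response import EpochAnchorError, epoch_windows

from conftest import labelled_matrix


class TestSmoothBinnedRate:
    def test_empty_spikes_all_zero(self):
        trace = sc.smooth_binned_rate(np.array([]), (0.0, 2.0))
        assert trace.shape == (20,)
        assert np.all(trace == 0)

    def test_uniform_spikes_mean_rate(self):
        spikes = np.linspace(0.05, 4.95, 50)
        trace = sc.smooth_binned_rate(spikes, (0.0, 5.0))
        assert trace.mean() == pytest.approx(10.0, rel=0.01)

    def test_smoothing_preserves_total_count(self):
        rng = np.random.default_rng(3)
        spikes = np.sort(rng.uniform(0.0, 10.0, 200))
        trace = sc.smooth_binned_rate(spikes, (0.0, 10.0))
        assert trace.sum() * 0.1 == pytest.approx(200, rel=0.01)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sc.smooth_binned_rate(np.array([1.0]), (0.0, 1.0), bin_ms=0)
        with pytest.raises(ValueError):
            sc.smooth_binned_rate(np.array([1.0]), (0.0, 1.0), kernel_sd_ms=-5)


class TestEpochWindows:
    def test_nine_half_second_windows(self, session_trials):
        for tr in session_trials[:20]:
            win = epoch_windows(tr)
            assert win.shape == (9, 2)
            np.testing.assert_allclose(win[:, 1] - win[:, 0], 0.5)

    def test_nogo_trial_uses_termination_fallbacks(self, session_trials):
        nogo = next(t for t in session_trials if t.response == "nogo")
        assert "well_entry" not in nogo.event_times
        win = epoch_windows(nogo)
        te = nogo.event_times["trial_end"]
        np.testing.assert_allclose(win[5], [te, te + 0.5])          # choice
        np.testing.assert_allclose(win[6], [te + 0.5, te + 1.0])    # outcome
        np.testing.assert_allclose(win[7], [te + 1.0, te + 1.5])    # postout
        np.testing.assert_allclose(win[8], [te + 1.5, te + 2.0])    # ITIb

    def test_missing_anchor_and_fallback_raises(self, session_trials):
        tr = session_trials[0]
        broken = sc.TrialRecord(**{**tr.__dict__,
                                   "event_times": {"light_on": 1.0, "poke": 2.0,
                                                   "odor_on": 2.5, "unpoke": 3.2}})
        with pytest.raises(EpochAnchorError, match="choice"):
            epoch_windows(broken)


class TestEpochRates:
    def test_regular_train_gives_constant_rate(self, session_trials):
        tr = session_trials[0]
        spikes = np.arange(0.0, tr.event_times["trial_end"] + 5.0, 0.05)
        rates = sc.epoch_rates(spikes, tr)
        np.testing.assert_allclose(rates, 20.0, atol=1.0)
        raw = sc.epoch_rates(spikes, tr, smoothing=False)
        np.testing.assert_allclose(raw, 20.0, atol=2.01)  # count/duration oracle

    def test_spikes_only_in_odor_window(self, session_trials):
        tr = session_trials[0]
        t0 = tr.event_times["odor_on"]
        spikes = np.linspace(t0 + 0.2, t0 + 0.3, 10)  # mid-window, no edge leak
        rates = sc.epoch_rates(spikes, tr)
        odor_idx = sc.EPOCH_NAMES.index("odor")
        assert rates[odor_idx] == pytest.approx(20.0, rel=0.01)
        others = np.delete(rates, odor_idx)
        assert np.all(others < 0.02)

    def test_raw_counts_match_manual_oracle(self, session_trials):
        rng = np.random.default_rng(0)
        tr = session_trials[1]
        spikes = np.sort(rng.uniform(tr.event_times["light_on"] - 1.0,
                                     tr.event_times["trial_end"] + 3.0, 300))
        raw = sc.epoch_rates(spikes, tr, smoothing=False)
        for (t0, t1), r in zip(epoch_windows(tr), raw):
            assert r == np.sum((spikes >= t0) & (spikes < t1)) / 0.5


class TestEpochMatrix:
    def test_default_session_is_160_by_9(self, flat_unit_matrices):
        m1, m2 = flat_unit_matrices
        assert m1.values.shape == (160, 9)
        assert m2.values.shape == (160, 9)
        assert list(m1.labels["type_key"].unique()) == \
            ["aP1", "aP2", "aP3", "aP4", "bP1", "bP2", "bP3", "bP4"]

    def test_15_trials_per_type_is_120_by_9(self, design, session_trials):
        spec = sc.TuningSpec("u", baseline_rate=3.0)
        st = sc.generate_spikes(session_trials, spec, design, seed=2)
        m = sc.build_epoch_matrix(st, session_trials, design, "maze1",
                                  trials_per_type=15)
        assert m.values.shape == (120, 9)

    def test_silent_unit_all_zero(self, design, session_trials):
        st = sc.SpikeTrain("quiet", np.array([]))
        m = sc.build_epoch_matrix(st, session_trials, design, "maze1")
        assert np.all(m.values == 0)

    def test_missing_type_named_in_error(self, design, session_trials):
        st = sc.SpikeTrain("u", np.array([1.0]))
        pruned = [t for t in session_trials
                  if not (t.maze_id == "maze1" and t.type_key == "bP2")]
        with pytest.raises(ValueError, match="bP2"):
            sc.build_epoch_matrix(st, pruned, design, "maze1")

    def test_csv_round_trip(self, flat_unit_matrices, tmp_path):
        m1, _ = flat_unit_matrices
        m1.to_csv(tmp_path / "m.csv")
        back = sc.EpochRateMatrix.from_csv(tmp_path / "m.csv")
        np.testing.assert_allclose(back.values, m1.values, atol=1e-9)
        assert back.maze_id == m1.maze_id


class TestProfiles:
    def test_constant_matrix_constant_profile(self):
        m = labelled_matrix(lambda row, e: 3.5)
        profile = sc.build_profile(m)
        assert profile.values.shape == (72,)
        np.testing.assert_allclose(profile.values, 3.5)

    def test_two_trial_toy_matches_hand_means(self):
        m = labelled_matrix(lambda row, e: row["within_type_index"] * (e + 1),
                            trials_per_type=2)
        profile = sc.build_profile(m)
        # mean over within_type_index {1, 2} -> 1.5 * (e+1) for every type
        expected = np.tile(1.5 * np.arange(1, 10), 8)
        np.testing.assert_allclose(profile.values, expected)

    def test_profile_commutes_with_row_permutation_within_type(self,
                                                               flat_unit_matrices):
        m1, _ = flat_unit_matrices
        rng = np.random.default_rng(5)
        perm = np.concatenate([8 * 20 // 160 * 0 + rng.permutation(20) + 20 * t
                               for t in range(8)])
        shuffled = sc.EpochRateMatrix(m1.unit_id, m1.maze_id, m1.values[perm],
                                      m1.labels.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(sc.build_profile(shuffled).values,
                                   sc.build_profile(m1).values)

    def test_profile_requires_all_types(self, flat_unit_matrices):
        m1, _ = flat_unit_matrices
        sub = sc.EpochRateMatrix(m1.unit_id, m1.maze_id, m1.values[:40],
                                 m1.labels.iloc[:40].reset_index(drop=True))
        with pytest.raises(ValueError, match="8"):
            sc.build_profile(sub)


class TestEpochSubsetAndFilters:
    def test_correct_only_filter_drops_error_trials(self, design, session_trials):
        spec = sc.TuningSpec("u", baseline_rate=3.0)
        st = sc.generate_spikes(session_trials, spec, design, seed=6)
        m = sc.build_epoch_matrix(st, session_trials, design, "maze1",
                                  correct_only=True)
        n_correct = sum(1 for t in session_trials
                        if t.maze_id == "maze1" and t.correct)
        assert m.values.shape == (n_correct, 9)

    def test_epoch_subset_profile_and_classification(self, tuned_unit_matrices):
        from schemacells.pipeline import _slice_epochs
        m1, m2, _ = tuned_unit_matrices
        subset = ("ITIa", "light", "poke", "odor")
        s1, s2 = _slice_epochs(m1, list(subset)), _slice_epochs(m2, list(subset))
        p1, p2 = sc.build_profile(s1), sc.build_profile(s2)
        assert p1.values.shape == (32,)
        assert sc.classify_unit(p1, p2) in ("schema", "nonschema", "noncoding")
        flags, _ = sc.attribute_factors(s1, s2, sc.AnalysisConfig(n_shuffles=100),
                                        seed=0)
        assert set(flags) == {"epoch", "reward", "position"}

    def test_profile_csv_round_trip(self, tuned_unit_matrices, tmp_path):
        m1, _, _ = tuned_unit_matrices
        profile = sc.build_profile(m1)
        profile.to_csv(tmp_path / "p.csv")
        back = sc.TrialTypeProfile.from_csv(tmp_path / "p.csv")
        np.testing.assert_allclose(back.values, profile.values, atol=1e-12)
        assert back.epochs == profile.epochs
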