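"""F-ratio scoring, ranking, profiles and scalp maps."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from tfsldecode.features import (FRatioSelector, f_ratio, f_ratio_scores,
                                 fratio_profile, rank_features, scalp_map,
                                 top_rank_precision)
from tfsldecode.sl import FeatureTensor


def brute_f_ratio(values, labels):
    """Direct two-group computation from the raw definitions."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    groups = [values[labels == c] for c in np.unique(labels)]
    mu = [g.mean() for g in groups]
    grand = np.mean(mu)
    between = sum((m - grand) ** 2 for m in mu) / (len(groups) - 1)
    within = np.mean([g.var(ddof=1) for g in groups])
    return between / within


class TestFRatio:
    def test_hand_computed_example(self):
        values = np.array([0.0, 2.0, 4.0, 6.0])
        labels = np.array([1, 1, 0, 0])
        assert f_ratio(values, labels) == 4.0

    def test_identical_class_distributions_score_zero(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        assert f_ratio(values, labels) == 0.0

    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=24)
        labels = rng.permutation(np.r_[np.ones(12, int), np.zeros(12, int)])
        assert np.isclose(f_ratio(values, labels),
                          brute_f_ratio(values, labels), rtol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(-50, 50), st.floats(0.01, 50))
    def test_shift_and_scale_invariance(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=20)
        labels = rng.permutation(np.r_[np.ones(10, int), np.zeros(10, int)])
        base = f_ratio(values, labels)
        assert np.isclose(f_ratio(values * scale + shift, labels), base,
                          rtol=1e-9, atol=1e-12)

    def test_population_variant_halves_scores(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        assert np.isclose(f_ratio(values, labels, between_denominator=2),
                          f_ratio(values, labels) / 2.0)

    def test_zero_within_variance_with_separated_means_is_inf(self):
        values = np.array([1.0, 1.0, 2.0, 2.0])
        labels = np.array([1, 1, 0, 0])
        with pytest.warns(UserWarning, match="inf"):
            assert f_ratio(values, labels) == np.inf

    def test_class_with_single_trial_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            f_ratio(np.arange(4.0), np.array([1, 0, 0, 0]))


class TestRanking:
    def test_descending_ranks_with_id_order_tie_break(self):
        X = np.array([[0.0, 0.0, 1.0],
                      [0.0, 0.0, 3.0],
                      [1.0, 1.0, 6.0],
                      [1.0, 1.0, 8.0]])
        labels = np.array([1, 1, 0, 0])
        table = rank_features(X, labels)
        # columns 0 and 1 tie (identical data); earlier id wins
        r = table.set_index("feature")["rank"]
        assert r["f0"] < r["f1"]
        assert sorted(table["rank"]) == [1, 2, 3]

    def test_signal_features_dominate_top_ranks(self, desk_dataset):
        _, trials, truth, tensor = desk_dataset
        table = rank_features(tensor, trials.labels)
        precision = top_rank_precision(table, truth.signal_feature_ids(0))
        assert precision >= 0.5

    def test_permuted_labels_match_noise_score_scale(self):
        rng = np.random.default_rng(1)
        n = 200
        X = rng.normal(size=(n, 50))
        X[:, 0] += np.repeat([0.0, 2.0], n // 2)   # one strong feature
        labels = np.repeat([0, 1], n // 2)
        strong = f_ratio_scores(X, labels)[0]
        perm = f_ratio_scores(X, rng.permutation(labels))
        # permutation destroys the effect: scores collapse to O(1/n)
        assert strong > 0.5
        assert perm.max() < 0.2


class TestProfiles:
    def random_tensor(self, n_trials=24, nb=6, ne=64, nw=20, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.05, 0.95, size=(n_trials, nb, ne, nw))
        labels = rng.permutation(np.r_[np.ones(n_trials // 2, int),
                                       np.zeros(n_trials // 2, int)])
        names = tuple(f"b{i}" for i in range(nb))
        return FeatureTensor(values, names, 512.0), labels

    def test_cumulative_feature_counts(self):
        tensor, labels = self.random_tensor()
        prof = fratio_profile(tensor, labels, mode="cumulative")
        np.testing.assert_array_equal(prof.n_features_used,
                                      384 * np.arange(1, 21))
        assert prof.time_ms[0] == 50.0 and prof.time_ms[-1] == 1000.0

    def test_windowed_feature_counts(self):
        tensor, labels = self.random_tensor()
        prof = fratio_profile(tensor, labels, mode="windowed")
        assert np.all(prof.n_features_used == 384)

    def test_oversized_k_averages_all_with_warning(self):
        tensor, labels = self.random_tensor(ne=4)
        with pytest.warns(UserWarning, match="averaging all"):
            prof = fratio_profile(tensor, labels, mode="windowed", k=300)
        scores = f_ratio_scores(
            tensor.restrict_windows([0]).to_matrix(), labels)
        assert np.isclose(prof.mean_top_k[0], scores.mean())

    def test_top_k_mean_non_increasing_in_k(self):
        tensor, labels = self.random_tensor(ne=8)
        ks = [10, 50, 200, 960]
        means = [fratio_profile(tensor, labels, "cumulative", k).mean_top_k[-1]
                 for k in ks]
        assert np.all(np.diff(means) <= 1e-12)

    def test_windowed_profile_peaks_inside_effect_windows(self, desk_dataset):
        cfg, trials, truth, tensor = desk_dataset
        prof = fratio_profile(tensor, trials.labels, mode="windowed", k=50)
        assert int(np.argmax(prof.mean_top_k)) in cfg.effect_windows

    def test_invalid_mode_rejected(self):
        tensor, labels = self.random_tensor(ne=2)
        with pytest.raises(ValueError, match="mode"):
            fratio_profile(tensor, labels, mode="sliding")


class TestScalpMap:
    def test_effect_electrodes_carry_the_maxima(self, desk_dataset):
        cfg, trials, truth, tensor = desk_dataset
        smap = scalp_map(tensor, trials.labels, cfg.effect_windows)
        top = set(np.argsort(smap.values)[-len(cfg.effect_electrodes):])
        assert top == set(cfg.effect_electrodes)

    def test_uniform_data_yields_flat_map(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(size=(200, 2, 8, 4))
        labels = rng.permutation(np.r_[np.ones(100, int), np.zeros(100, int)])
        tensor = FeatureTensor(values, ("a", "b"), 512.0)
        smap = scalp_map(tensor, labels, range(4))
        assert smap.values.max() / smap.values.min() < 4.0

    def test_single_window_consistent_with_direct_average(self, desk_dataset):
        _, trials, _, tensor = desk_dataset
        smap = scalp_map(tensor, trials.labels, [5])
        scores = f_ratio_scores(tensor.restrict_windows([5]).to_matrix(),
                                trials.labels)
        nb, ne = tensor.shape[1], tensor.shape[2]
        expected = scores.reshape(nb, ne).mean(axis=0)
        np.testing.assert_allclose(smap.values, expected)

    def test_empty_window_subset_rejected(self, desk_dataset):
        _, trials, _, tensor = desk_dataset
        with pytest.raises(ValueError, match="empty"):
            scalp_map(tensor, trials.labels, [])


class TestFRatioSelector:
    def test_selects_top_k_columns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 10))
        y = np.repeat([0, 1], 30)
        X[:, 3] += 3.0 * y
        X[:, 7] += 2.0 * y
        sel = FRatioSelector(k=2).fit(X, y)
        assert set(np.flatnonzero(sel.get_support())) == {3, 7}
        assert sel.transform(X).shape == (60, 2)

    def test_sklearn_clone_round_trip(self):
        sel = FRatioSelector(k=5, between_denominator=2)
        assert clone(sel).get_params() == sel.get_params()
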