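"""Synchronization-likelihood core: embedding, recurrence construction,
pairwise/channel TFSL, and exact agreement with a brute-force oracle."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tfsldecode as t
from tfsldecode.bands import BandSpec, SLParams
from tfsldecode.containers import TrialSet
from tfsldecode.protocols import independence_baseline
from tfsldecode.sl import (channel_tfsl, critical_distance,
                           default_anchor_samples, embed, sl_at_anchor,
                           tfsl_pairwise)

TOY_BAND = BandSpec("toy", 4.0, 12.0, lag=2, dim=3)


# ---------------------------------------------------------------------------
# brute-force oracle: explicit distance matrices and recurrence sets
# ---------------------------------------------------------------------------

def oracle_pair_window_sl(trial, band, params, fs):
    """O(N^2) reference TFSL: explicit sets, one pair at a time."""
    vectors = embed(trial, band.lag, band.dim)[:, ::params.candidate_shift]
    theiler = params.theiler_for(band)
    anchors = default_anchor_samples(params) // params.candidate_shift
    pairs = list(combinations(range(trial.shape[0]), 2))
    out = np.empty((len(pairs), len(anchors)))
    for p, (a, b) in enumerate(pairs):
        for k, ai in enumerate(anchors):
            fwd = sl_at_anchor(ai, vectors[a], vectors[b], params, theiler)
            bwd = sl_at_anchor(ai, vectors[b], vectors[a], params, theiler)
            out[p, k] = 0.5 * (fwd + bwd)
    return out


class TestEmbed:
    def test_direct_definition(self):
        vecs = embed(np.array([1.0, 2, 3, 4, 5]), lag=1, dim=3)
        np.testing.assert_array_equal(
            vecs, [[1, 2, 3], [2, 3, 4], [3, 4, 5]])

    def test_count_formula(self):
        assert embed(np.arange(6.0), lag=2, dim=2).shape == (4, 2)

    def test_constant_series_gives_identical_vectors(self):
        vecs = embed(np.full(30, 2.5), lag=3, dim=4)
        assert np.all(vecs == vecs[0])

    def test_too_short_series_reports_required_length(self):
        with pytest.raises(ValueError, match="9"):
            embed(np.arange(8.0), lag=4, dim=3)


class TestCriticalDistance:
    def test_order_statistic_on_known_distances(self):
        anchor = np.zeros(1)
        candidates = np.arange(1.0, 11.0)[:, None]
        assert critical_distance(anchor, candidates, 0.1) == 1.0

    def test_all_candidates_identical_to_anchor(self):
        anchor = np.ones(3)
        candidates = np.tile(anchor, (12, 1))
        assert critical_distance(anchor, candidates, 0.1) == 0.0

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            critical_distance(np.zeros(2), np.zeros((5, 2)), 0.1)

    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.05, 0.5))
    def test_matches_sort_based_oracle(self, seed, p_ref):
        rng = np.random.default_rng(seed)
        candidates = rng.normal(size=(40, 3))
        anchor = rng.normal(size=3)
        eps = critical_distance(anchor, candidates, p_ref)
        dists = sorted(np.sqrt(((c - anchor) ** 2).sum())
                       for c in candidates)
        k = math.ceil(p_ref * len(dists))
        assert eps == dists[k - 1]
        frac = np.mean(np.asarray(dists) <= eps)
        assert frac >= p_ref


class TestSLAtAnchor:
    params = SLParams(anchor_shift=25, n_anchors=4)

    def test_identical_channels_give_unity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=150)
        vx = embed(x, 2, 3)
        assert sl_at_anchor(50, vx, vx.copy(), self.params, theiler=4) == 1.0

    def test_directed_value_matches_explicit_set_construction(self):
        rng = np.random.default_rng(1)
        vx = embed(rng.normal(size=180), 2, 3)
        vy = embed(rng.normal(size=180), 2, 3)
        theiler = 4
        got = sl_at_anchor(60, vx, vy, self.params, theiler)
        pos = np.arange(len(vx))
        excl = np.abs(pos - 60) <= theiler
        r_sets = []
        for v in (vx, vy):
            d = np.sqrt(((v - v[60]) ** 2).sum(axis=1))
            eps = critical_distance(v[60], v, self.params.p_ref, excl)
            r_sets.append({i for i in pos[~excl] if d[i] <= eps})
        assert got == len(r_sets[0] & r_sets[1]) / len(r_sets[0])

    def test_roughly_symmetric_on_random_inputs(self):
        rng = np.random.default_rng(2)
        diffs = []
        for _ in range(30):
            vx = embed(rng.normal(size=200), 2, 3)
            vy = embed(rng.normal(size=200), 2, 3)
            fwd = sl_at_anchor(80, vx, vy, self.params, theiler=4)
            bwd = sl_at_anchor(80, vy, vx, self.params, theiler=4)
            diffs.append(fwd - bwd)
        assert abs(np.mean(diffs)) < 0.02


class TestIndependenceBaseline:
    def test_white_noise_baseline_near_p_ref(self):
        means = independence_baseline(seed=42, n_realizations=10)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 0.1) < max(3 * se, 0.01)


class TestTfslPairwise:
    fs = 512.0

    def test_default_anchors_tile_the_second(self):
        anchors = default_anchor_samples(SLParams())
        np.testing.assert_array_equal(anchors, np.arange(0, 500, 25))

    def test_three_channels_three_pairs(self):
        rng = np.random.default_rng(3)
        trial = rng.normal(size=(3, 550))
        params = SLParams(n_anchors=20)
        pw = tfsl_pairwise(trial, TOY_BAND, params, self.fs)
        assert pw.shape == (3, 20)
        assert np.all((pw >= 0) & (pw <= 1))

    def test_coupled_pair_high_others_near_p_ref(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=550)
        trial = np.stack([base, base, rng.normal(size=550)])
        pw = tfsl_pairwise(trial, TOY_BAND, SLParams(), self.fs)
        assert np.all(pw[0] == 1.0)          # pair (0,1): identical signals
        assert abs(pw[1:].mean() - 0.1) < 0.05

    def test_matches_brute_force_oracle_bit_for_bit(self):
        rng = np.random.default_rng(5)
        trial = rng.normal(size=(4, 180))    # <= 200-sample toy epoch
        params = SLParams(anchor_shift=25, n_anchors=5, theiler=4)
        fast = tfsl_pairwise(trial, TOY_BAND, params, self.fs, n_windows=5)
        slow = oracle_pair_window_sl(trial, TOY_BAND, params, self.fs)
        np.testing.assert_array_equal(fast, slow)

    def test_candidate_subsampling_matches_oracle(self):
        rng = np.random.default_rng(6)
        trial = rng.normal(size=(3, 200))
        params = SLParams(candidate_shift=5, anchor_shift=25, n_anchors=3,
                          theiler=10)
        fast = tfsl_pairwise(trial, TOY_BAND, params, self.fs, n_windows=3)
        slow = oracle_pair_window_sl(trial, TOY_BAND, params, self.fs)
        np.testing.assert_array_equal(fast, slow)


class TestChannelAggregation:
    def test_uniform_pairwise_values_pass_through(self):
        pw = np.full((6, 5), 0.3)
        np.testing.assert_allclose(channel_tfsl(pw, 4), np.full((4, 5), 0.3))

    def test_three_channel_hand_mean(self):
        pw = np.array([[0.9], [0.1], [0.1]])  # pairs (ab, ac, bc)
        np.testing.assert_allclose(channel_tfsl(pw, 3),
                                   [[0.5], [0.5], [0.1]])

    def test_pair_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            channel_tfsl(np.zeros((5, 2)), 4)


class TestFeatureTensor:
    def make_trials(self, n_trials=3, n_channels=4, seed=0):
        rng = np.random.default_rng(seed)
        return TrialSet(rng.normal(size=(n_trials, n_channels, 687)),
                        rng.integers(0, 2, n_trials), 512.0)

    def test_two_band_feature_count(self):
        trials = self.make_trials()
        bands = (t.get_band("alpha"), t.get_band("beta"))
        tensor = t.compute_feature_tensor(trials, bands)
        assert tensor.shape == (3, 2, 4, 20)
        assert tensor.n_features == 160

    def test_values_in_unit_interval_and_deterministic(self):
        trials = self.make_trials(seed=9)
        bands = (t.get_band("gamma2"),)
        t1 = t.compute_feature_tensor(trials, bands)
        t2 = t.compute_feature_tensor(trials, bands)
        assert np.all((t1.values >= 0) & (t1.values <= 1))
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_feature_id_order_is_band_major(self):
        trials = self.make_trials(n_trials=2, n_channels=3)
        tensor = t.compute_feature_tensor(trials, (t.get_band("gamma1"),
                                                   t.get_band("gamma2")))
        ids = tensor.feature_ids()
        assert ids[0] == "B1E1T1"
        assert ids[20] == "B1E2T1"
        assert ids[60] == "B2E1T1"
        # flattened matrix follows the same order
        np.testing.assert_array_equal(tensor.to_matrix()[:, 20],
                                      tensor.values[:, 0, 1, 0])

    def test_channel_aggregate_consistent_with_pairwise_path(self):
        trials = self.make_trials(n_trials=2, n_channels=4, seed=11)
        band = t.get_band("alpha")
        tensor = t.compute_feature_tensor(trials, (band,))
        from tfsldecode.preprocess import bandpass
        filtered = bandpass(trials.data, band, 512.0)
        pw = tfsl_pairwise(filtered[0], band, SLParams(), 512.0)
        np.testing.assert_allclose(tensor.values[0, 0], channel_tfsl(pw, 4),
                                   rtol=0, atol=1e-12)
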