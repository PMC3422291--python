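"""F-ratio feature ranking and discriminability profiles.

The F-ratio of a feature is the ratio of the variance of the two class means
(sample variance over the two means, denominator 1) to the average of the
unbiased within-class variances:

    FR = [(mu_C - mu_bar)^2 + (mu_NC - mu_bar)^2] / [(s2_C + s2_NC) / 2]
       = (mu_C - mu_NC)^2 / (s2_C + s2_NC)

It is invariant to adding a constant to all values and to common rescaling,
and to swapping the class labels.  Ranking is descending with deterministic
ties broken by feature-id (band, electrode, window) order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .sl import FeatureTensor

__all__ = ["f_ratio", "f_ratio_scores", "rank_features", "fratio_profile",
           "scalp_map", "FRatioSelector", "ProfileResult", "ScalpMap",
           "biosemi64_positions"]


def _class_split(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    return labels == classes[0], labels == classes[1]


def f_ratio_scores(X: np.ndarray, labels: np.ndarray,
                   between_denominator: int = 1) -> np.ndarray:
    """Vectorized F-ratio of every column of the trial x feature matrix.

    ``between_denominator`` selects the variance convention over the two
    class means: 1 (sample, default) or 2 (population; halves every score
    and leaves ranks unchanged).
    """
    X = np.asarray(X, dtype=np.float64)
    in_a, in_b = _class_split(labels)
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each class needs at least 2 trials")
    mu_a = X[in_a].mean(axis=0)
    mu_b = X[in_b].mean(axis=0)
    var_a = X[in_a].var(axis=0, ddof=1)
    var_b = X[in_b].var(axis=0, ddof=1)
    mu_bar = 0.5 * (mu_a + mu_b)
    between = ((mu_a - mu_bar) ** 2 + (mu_b - mu_bar) ** 2) / between_denominator
    within = 0.5 * (var_a + var_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fr = between / within
    zero_within = within == 0
    if np.any(zero_within):
        fr = np.where(zero_within & (between > 0), np.inf, fr)
        fr = np.where(zero_within & (between == 0), 0.0, fr)
        if np.any(zero_within & (between > 0)):
            warnings.warn("zero within-class variance with differing means; "
                          "F-ratio set to +inf")
    return fr


def f_ratio(values: np.ndarray, labels: np.ndarray,
            between_denominator: int = 1) -> float:
    """F-ratio of a single feature's per-trial values."""
    return float(f_ratio_scores(np.asarray(values, float)[:, None], labels,
                                between_denominator)[0])


def rank_order(scores: np.ndarray) -> np.ndarray:
    """Indices of features in descending score order, ties by feature id."""
    return np.argsort(-scores, kind="stable")


def rank_features(tensor: FeatureTensor | np.ndarray, labels: np.ndarray,
                  between_denominator: int = 1) -> pd.DataFrame:
    """F-ratio table over all features, ranked descending (rank 1 largest).

    Accepts a FeatureTensor (feature ids become ``B_i E_j T_k`` names) or a
    plain trial x feature matrix.
    """
    if isinstance(tensor, FeatureTensor):
        X = tensor.to_matrix()
        ids = tensor.feature_ids()
        triples = tensor.index_triples()
    else:
        X = np.asarray(tensor, dtype=np.float64)
        ids = [f"f{i}" for i in range(X.shape[1])]
        triples = None
    scores = f_ratio_scores(X, labels, between_denominator)
    order = rank_order(scores)
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(order) + 1)
    table = pd.DataFrame({"feature": ids, "f_ratio": scores, "rank": ranks})
    if triples is not None:
        table["band"] = triples[:, 0]
        table["electrode"] = triples[:, 1]
        table["window"] = triples[:, 2]
    return table


@dataclass
class ProfileResult:
    """Temporal discriminability profile: mean top-k F-ratio per time step."""

    mode: str                    # "cumulative" or "windowed"
    time_ms: np.ndarray          # window endpoints, strictly increasing
    mean_top_k: np.ndarray
    n_features_used: np.ndarray  # features entering the ranking per step


def fratio_profile(tensor: FeatureTensor, labels: np.ndarray,
                   mode: str = "cumulative", k: int = 300,
                   window_ms: float = 50.0) -> ProfileResult:
    """Mean F-ratio of the top-k features as a function of time.

    Cumulative mode ranks the features of windows ``0..k'`` at step ``k'``
    (384 features at the first step under the default configuration);
    windowed mode uses only window ``k'``'s features.  When fewer than ``k``
    features exist, all of them are averaged.
    """
    if mode not in ("cumulative", "windowed"):
        raise ValueError("mode must be 'cumulative' or 'windowed'")
    n_windows = tensor.shape[3]
    means = np.empty(n_windows)
    used = np.empty(n_windows, dtype=int)
    warned = False
    for step in range(n_windows):
        windows = (np.arange(step + 1) if mode == "cumulative"
                   else np.array([step]))
        X = tensor.restrict_windows(windows).to_matrix()
        scores = f_ratio_scores(X, labels)
        top = min(k, scores.shape[0])
        if top < k and not warned:
            warnings.warn(f"only {scores.shape[0]} features available; "
                          f"averaging all of them instead of top {k}")
            warned = True
        means[step] = np.sort(scores)[::-1][:top].mean()
        used[step] = scores.shape[0]
    time_ms = (np.arange(n_windows) + 1) * window_ms
    return ProfileResult(mode, time_ms, means, used)


@dataclass
class ScalpMap:
    """Per-electrode F-ratio averaged over bands and a window range."""

    values: np.ndarray                  # one value per electrode
    windows: tuple[int, ...]
    positions: np.ndarray | None = None  # (n_electrodes, 2) for rendering


def scalp_map(tensor: FeatureTensor, labels: np.ndarray,
              time_range, positions: np.ndarray | None = None) -> ScalpMap:
    """Mean F-ratio per electrode over all bands and the selected windows."""
    windows = tuple(int(w) for w in np.atleast_1d(time_range))
    if not windows:
        raise ValueError("empty window subset")
    sub = tensor.restrict_windows(list(windows))
    scores = f_ratio_scores(sub.to_matrix(), labels)
    n_bands, n_elec, n_win = sub.shape[1:]
    per_electrode = scores.reshape(n_bands, n_elec, n_win).mean(axis=(0, 2))
    return ScalpMap(per_electrode, windows, positions)


def biosemi64_positions() -> np.ndarray:
    """2-D scalp coordinates of the standard BioSemi 64-electrode montage
    (azimuthal projection of the template positions)."""
    import mne
    montage = mne.channels.make_standard_montage("biosemi64")
    pos3 = np.stack([montage.get_positions()["ch_pos"][ch]
                     for ch in montage.ch_names])
    return pos3[:, :2]


def plot_scalp_map(smap: ScalpMap, ax=None, resolution: int = 64):
    """Render a ScalpMap by interpolating over 2-D electrode positions."""
    import matplotlib.pyplot as plt
    from scipy.interpolate import griddata

    if smap.positions is None:
        raise ValueError("scalp map has no electrode positions")
    if ax is None:
        _, ax = plt.subplots()
    x, y = smap.positions[:, 0], smap.positions[:, 1]
    xi = np.linspace(x.min(), x.max(), resolution)
    yi = np.linspace(y.min(), y.max(), resolution)
    zi = griddata((x, y), smap.values, tuple(np.meshgrid(xi, yi)),
                  method="cubic")
    im = ax.contourf(xi, yi, zi, levels=16)
    ax.scatter(x, y, s=6, c="k")
    ax.set_aspect("equal")
    return im


class FRatioSelector(SelectorMixin, BaseEstimator):
    """Select the ``k`` features with the largest F-ratio.

    scikit-learn selector: ``fit`` computes F-ratios on the training data,
    ``transform`` keeps the top-``k`` columns (ties broken by column order).

    Attributes
    ----------
    scores_ : ndarray
        F-ratio of every feature on the training data.
    ranking_ : ndarray
        Feature indices in descending score order.
    """

    def __init__(self, k: int = 300, between_denominator: int = 1):
        self.k = k
        self.between_denominator = between_denominator

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.scores_ = f_ratio_scores(X, y, self.between_denominator)
        self.ranking_ = rank_order(self.scores_)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.scores_.shape[0], dtype=bool)
        mask[self.ranking_[:min(self.k, len(self.ranking_))]] = True
        return mask


def top_rank_precision(table: pd.DataFrame,
                       truth_triples: set[tuple[int, int, int]]) -> float:
    """Fraction of the top-|truth| ranked features that are ground truth."""
    top = table.nsmallest(len(truth_triples), "rank")
    hits = sum((int(r.band), int(r.electrode), int(r.window)) in truth_triples
               for r in top.itertuples())
    return hits / len(truth_triples)
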