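"""Synchronization likelihood (SL) and its time-frequency resolved features.

SL quantifies generalized synchronization between two signals through
recurrences of time-delay embedded states.  For an *anchor* state in signal
X, the critical distance ``eps_x`` is the smallest radius within which a
fraction ``p_ref`` of the candidate states of X lie (Theiler-excluded around
the anchor); the recurrence set ``R_x`` collects those candidates.  The
directed SL at the anchor is ``|R_x & R_y| / |R_x|``: the probability that a
recurrence of X's state is accompanied by a recurrence of Y's state at the
same time.  Independent signals give SL ~ p_ref; identical signals give 1.

Time-frequency resolution comes from band-pass filtering before embedding
(with band-specific lag/dimension) and from evaluating SL at anchors tiling
the 1 s epoch, one 50 ms window each at the default parameters.  Per-channel
features average the pair SL over each channel's partners, giving the
band x electrode x window feature tensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .bands import DEFAULT_BANDS, BandSpec, SLParams
from .containers import TrialSet, window_grid
from .preprocess import bandpass

__all__ = [
    "embed", "critical_distance", "sl_at_anchor", "tfsl_pairwise",
    "channel_tfsl", "compute_feature_tensor", "FeatureTensor",
    "default_anchor_samples",
]


# ---------------------------------------------------------------------------
# Embedding and recurrence primitives
# ---------------------------------------------------------------------------

def embed(x: np.ndarray, lag: int, dim: int) -> np.ndarray:
    """Time-delay embedding: row t is ``(x_t, x_{t+L}, ..., x_{t+(m-1)L})``.

    Returns ``len(x) - (dim - 1) * lag`` vectors of length ``dim``.
    """
    x = np.asarray(x, dtype=np.float64)
    span = (dim - 1) * lag
    n = x.shape[-1] - span
    if n < 1:
        raise ValueError(f"series of length {x.shape[-1]} too short for "
                         f"embedding (needs >= {span + 1} samples)")
    idx = np.arange(n)[:, None] + np.arange(dim)[None, :] * lag
    return x[..., idx]


def critical_distance(anchor: np.ndarray, candidates: np.ndarray,
                      p_ref: float, excluded: np.ndarray | None = None,
                      ) -> float:
    """Smallest radius capturing a fraction ``p_ref`` of the candidates.

    Equivalently the ``ceil(p_ref * N)``-th order statistic of the Euclidean
    distances from the anchor to the ``N`` non-excluded candidates.
    """
    d = np.sqrt(np.sum((candidates - anchor) ** 2, axis=-1))
    if excluded is not None:
        d = d[~excluded]
    n_valid = d.shape[0]
    if n_valid < math.ceil(1.0 / p_ref):
        raise ValueError(f"only {n_valid} candidates available; need at "
                         f"least {math.ceil(1.0 / p_ref)} for p_ref={p_ref}")
    k = math.ceil(p_ref * n_valid)
    return float(np.partition(d, k - 1)[k - 1])


def _recurrence_mask(vectors: np.ndarray, anchor_index: int, p_ref: float,
                     excluded: np.ndarray) -> np.ndarray:
    """Boolean recurrence set of one channel at one anchor."""
    eps = critical_distance(vectors[anchor_index], vectors, p_ref, excluded)
    d = np.sqrt(np.sum((vectors - vectors[anchor_index]) ** 2, axis=-1))
    return (d <= eps) & ~excluded


def sl_at_anchor(anchor_index: int, x_vectors: np.ndarray,
                 y_vectors: np.ndarray, params: SLParams,
                 theiler: int, positions: np.ndarray | None = None,
                 ) -> float:
    """Directed SL ``|R_x & R_y| / |R_x|`` at one anchor.

    ``positions`` gives the sample position of each candidate vector
    (defaults to ``index * candidate_shift``); the Theiler zone excludes
    candidates within ``theiler`` samples of the anchor, the anchor itself
    included.
    """
    if x_vectors.shape != y_vectors.shape:
        raise ValueError("channel vector sequences must be aligned")
    n = x_vectors.shape[0]
    if positions is None:
        positions = np.arange(n) * params.candidate_shift
    excluded = np.abs(positions - positions[anchor_index]) <= theiler
    r_x = _recurrence_mask(x_vectors, anchor_index, params.p_ref, excluded)
    r_y = _recurrence_mask(y_vectors, anchor_index, params.p_ref, excluded)
    n_x = int(r_x.sum())
    if n_x == 0:
        raise ValueError("empty recurrence set R_x")
    value = float((r_x & r_y).sum() / n_x)
    return min(max(value, 0.0), 1.0)


def default_anchor_samples(params: SLParams) -> np.ndarray:
    """Anchor sample indices ``k * anchor_shift`` for k = 0..n_anchors-1."""
    return np.arange(params.n_anchors) * params.anchor_shift


# ---------------------------------------------------------------------------
# Per-trial TFSL
# ---------------------------------------------------------------------------

def _pair_sl_matrices(trial: np.ndarray, band: BandSpec, params: SLParams,
                      ) -> np.ndarray:
    """Symmetrized channel x channel SL matrix at every anchor.

    Returns an ``(n_anchors, n_channels, n_channels)`` array; entry
    ``(k, a, b)`` is the mean of the two directed SL values of channels
    ``a`` and ``b`` at anchor ``k``.  Vectorized over channels: for each
    anchor the per-channel recurrence sets are built once and intersected
    with a boolean matrix product.
    """
    n_channels = trial.shape[0]
    vectors = embed(trial, band.lag, band.dim)  # (n_ch, n_cand_full, m)
    if params.candidate_shift > 1:
        vectors = vectors[:, ::params.candidate_shift]
    n_cand = vectors.shape[1]
    positions = np.arange(n_cand) * params.candidate_shift
    theiler = params.theiler_for(band)

    anchors = default_anchor_samples(params)
    if np.any(anchors % params.candidate_shift):
        raise ValueError("anchor samples must coincide with candidate "
                         "vectors (anchor_shift must be a multiple of "
                         "candidate_shift)")
    anchor_idx = anchors // params.candidate_shift
    if anchor_idx.max() >= n_cand:
        raise ValueError("epoch too short: last anchor has no embedding "
                         "vector (increase the epoch tail)")

    out = np.empty((len(anchor_idx), n_channels, n_channels))
    for k, ai in enumerate(anchor_idx):
        excluded = np.abs(positions - positions[ai]) <= theiler
        valid = ~excluded
        n_valid = int(valid.sum())
        if n_valid < params.min_candidates():
            raise ValueError(f"only {n_valid} candidates at anchor sample "
                             f"{anchors[k]}; need >= {params.min_candidates()}")
        kth = math.ceil(params.p_ref * n_valid)
        # distances from each channel's anchor vector to all its candidates
        diff = vectors - vectors[:, ai, None, :]
        d = np.sqrt(np.sum(diff ** 2, axis=-1))        # (n_ch, n_cand)
        d_valid = d[:, valid]
        eps = np.partition(d_valid, kth - 1, axis=1)[:, kth - 1]
        masks = (d <= eps[:, None]) & valid[None, :]
        m = masks.astype(np.float64)
        counts = m @ m.T                                # |R_a & R_b|
        sizes = np.diag(counts)
        directed = counts / sizes[:, None]              # row a: |Ra&Rb|/|Ra|
        out[k] = 0.5 * (directed + directed.T)
    return np.clip(out, 0.0, 1.0)


def _anchor_to_window(params: SLParams, fs: float, n_windows: int,
                      ) -> np.ndarray:
    """Window index of each anchor.

    With the default one-anchor-per-window layout the mapping is by index;
    otherwise anchors are assigned to the window whose sample range contains
    them and windows holding several anchors average them.
    """
    anchors = default_anchor_samples(params)
    if params.n_anchors == n_windows:
        return np.arange(n_windows)
    grid = window_grid(fs, n_windows)
    starts = np.array([g[0] for g in grid])
    return np.clip(np.searchsorted(starts, anchors, side="right") - 1,
                   0, n_windows - 1)


def tfsl_pairwise(trial: np.ndarray, band: BandSpec, params: SLParams,
                  fs: float = 512.0, n_windows: int = 20) -> np.ndarray:
    """Pair x window SL matrix of one band-filtered trial.

    Pairs are enumerated as ``itertools.combinations(range(n_channels), 2)``;
    each entry is the symmetrized SL of that pair at the window's anchor(s).
    """
    per_anchor = _pair_sl_matrices(np.asarray(trial, float), band, params)
    n_channels = trial.shape[0]
    pairs = np.array(list(combinations(range(n_channels), 2)))
    win_of = _anchor_to_window(params, fs, n_windows)
    out = np.zeros((len(pairs), n_windows))
    counts = np.zeros(n_windows)
    for k, w in enumerate(win_of):
        out[:, w] += per_anchor[k, pairs[:, 0], pairs[:, 1]]
        counts[w] += 1
    with np.errstate(invalid="ignore"):
        out = out / counts[None, :]
    return out


def channel_tfsl(pairwise: np.ndarray, n_channels: int) -> np.ndarray:
    """Electrode x window matrix: mean SL over the pairs containing each
    electrode."""
    pairs = list(combinations(range(n_channels), 2))
    if pairwise.shape[0] != len(pairs):
        raise ValueError(f"expected {len(pairs)} pairs for {n_channels} "
                         f"channels, got {pairwise.shape[0]}")
    out = np.zeros((n_channels, pairwise.shape[1]))
    for p, (a, b) in enumerate(pairs):
        out[a] += pairwise[p]
        out[b] += pairwise[p]
    return out / (n_channels - 1)


# ---------------------------------------------------------------------------
# Feature tensor
# ---------------------------------------------------------------------------

@dataclass
class FeatureTensor:
    """TFSL features: trial x band x electrode x window.

    Flattening follows the ``B_i E_j T_k`` naming order (band-major, then
    electrode, then window); ``feature_ids()`` yields names with 1-based
    indices like ``B1E1T1``.
    """

    values: np.ndarray
    band_names: tuple[str, ...]
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError("values must be trial x band x electrode x window")
        if self.values.shape[1] != len(self.band_names):
            raise ValueError("one name per band required")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return int(np.prod(self.values.shape[1:]))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def to_matrix(self) -> np.ndarray:
        """Trial x feature matrix in B_i E_j T_k order."""
        return self.values.reshape(self.n_trials, -1)

    def index_triples(self) -> np.ndarray:
        """(n_features, 3) array of 0-based (band, electrode, window)."""
        _, nb, ne, nw = self.values.shape
        grid = np.indices((nb, ne, nw)).reshape(3, -1).T
        return grid

    def feature_ids(self) -> list[str]:
        return [f"B{b + 1}E{e + 1}T{w + 1}"
                for b, e, w in self.index_triples()]

    def restrict_windows(self, windows) -> "FeatureTensor":
        """Sub-tensor keeping only the given window indices."""
        windows = np.atleast_1d(np.asarray(windows, dtype=int))
        return FeatureTensor(self.values[:, :, :, windows],
                             self.band_names, self.sampling_rate)


def compute_feature_tensor(trials: TrialSet,
                           bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
                           params: SLParams = SLParams()) -> FeatureTensor:
    """Band-pass, embed and evaluate TFSL for every trial and band.

    At the defaults (6 bands, 64 electrodes, 20 windows) this yields
    6 * 64 * 20 = 7680 features per trial.
    """
    n_trials, n_channels = trials.n_trials, trials.n_channels
    n_windows = trials.n_windows
    win_of = _anchor_to_window(params, trials.sampling_rate, n_windows)
    out = np.empty((n_trials, len(bands), n_channels, n_windows))
    for bi, band in enumerate(bands):
        filtered = bandpass(trials.data, band, trials.sampling_rate)
        for t in range(n_trials):
            per_anchor = _pair_sl_matrices(filtered[t], band, params)
            # channel value = mean pair SL over partners; the symmetric SL
            # matrix has unit diagonal, so drop it from the row sums
            chan = (per_anchor.sum(axis=2) - 1.0) / (n_channels - 1)
            acc = np.zeros((n_channels, n_windows))
            counts = np.zeros(n_windows)
            for k, w in enumerate(win_of):
                acc[:, w] += chan[k]
                counts[w] += 1
            out[t, bi] = acc / counts[None, :]
    return FeatureTensor(out, tuple(b.name for b in bands),
                         trials.sampling_rate)
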