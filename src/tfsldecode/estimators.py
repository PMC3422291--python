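"""scikit-learn front-end: the TFSL feature extraction as a transformer.

``TFSLTransformer`` turns epoched multichannel trials — a
``(n_trials, n_channels, n_samples)`` array or a :class:`TrialSet` — into
the flattened band x electrode x window feature matrix, so it composes with
:class:`~tfsldecode.features.FRatioSelector` and
:class:`~tfsldecode.nnet.LMNetClassifier` in an sklearn ``Pipeline``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .bands import DEFAULT_BANDS, SLParams
from .containers import TrialSet
from .sl import compute_feature_tensor

__all__ = ["TFSLTransformer"]


class TFSLTransformer(TransformerMixin, BaseEstimator):
    """Stateless TFSL feature extraction with estimator ergonomics.

    Parameters
    ----------
    bands : tuple of BandSpec
        Frequency bands with embedding parameters.
    sl_params : SLParams
        Recurrence construction parameters.
    sampling_rate : float
        Used when ``X`` is a bare array; ignored for TrialSet input.
    n_windows : int
        Number of 50 ms windows tiling the analysis epoch.

    Attributes
    ----------
    feature_names_ : list of str
        ``B_i E_j T_k`` identifiers of the output columns (set by ``fit``).
    """

    def __init__(self, bands=DEFAULT_BANDS, sl_params: SLParams = SLParams(),
                 sampling_rate: float = 512.0, n_windows: int = 20):
        self.bands = bands
        self.sl_params = sl_params
        self.sampling_rate = sampling_rate
        self.n_windows = n_windows

    def _as_trialset(self, X) -> TrialSet:
        if isinstance(X, TrialSet):
            return X
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("expected trials x channels x samples")
        return TrialSet(X, np.zeros(X.shape[0], dtype=np.int64),
                        self.sampling_rate, None, "F1", None, self.n_windows)

    def fit(self, X, y=None):
        trials = self._as_trialset(X)
        nb, ne, nw = len(self.bands), trials.n_channels, self.n_windows
        self.feature_names_ = [f"B{b + 1}E{e + 1}T{w + 1}"
                               for b in range(nb) for e in range(ne)
                               for w in range(nw)]
        self.n_features_out_ = nb * ne * nw
        return self

    def transform(self, X) -> np.ndarray:
        trials = self._as_trialset(X)
        tensor = compute_feature_tensor(trials, self.bands, self.sl_params)
        return tensor.to_matrix()

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
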