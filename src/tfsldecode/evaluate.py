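"""Evaluation protocols: repeated stratified splits and k-fold CV."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .nnet import ANNConfig

__all__ = ["EvalResult", "stratified_split_indices", "repeated_split_eval",
           "kfold_eval"]


@dataclass
class EvalResult:
    """Accuracy mean +/- SD (in percent) over repetitions or folds."""

    accuracies: np.ndarray
    protocol: str

    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=np.float64)
        self.mean = float(self.accuracies.mean())
        self.sd = (float(self.accuracies.std(ddof=1))
                   if len(self.accuracies) > 1 else 0.0)

    @property
    def se(self) -> float:
        """Standard error of the mean across runs."""
        return self.sd / np.sqrt(len(self.accuracies))


def _check_counts(y: np.ndarray, fracs: tuple[float, float, float]) -> None:
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if min(fracs) * cnt < 1:
            raise ValueError(
                f"class {cls!r} has {cnt} trials; too few for a "
                f"{'/'.join(str(int(100 * f)) for f in fracs)} split")


def stratified_split_indices(y: np.ndarray,
                             fracs: tuple[float, float, float] = (.6, .2, .2),
                             seed: int | None = None):
    """Stratified train/validation/test indices at the given fractions."""
    y = np.asarray(y)
    _check_counts(y, fracs)
    idx = np.arange(len(y))
    train_idx, rest_idx = train_test_split(
        idx, train_size=fracs[0], stratify=y, random_state=seed)
    val_share = fracs[1] / (fracs[1] + fracs[2])
    val_idx, test_idx = train_test_split(
        rest_idx, train_size=val_share, stratify=y[rest_idx],
        random_state=None if seed is None else seed + 1)
    return train_idx, val_idx, test_idx


def _fit_and_score(X, y, train_idx, val_idx, test_idx, config: ANNConfig,
                   seed) -> float:
    clf = config.make_classifier(random_state=seed)
    validation = ((X[val_idx], y[val_idx]) if len(val_idx) else None)
    clf.fit(X[train_idx], y[train_idx], validation_data=validation)
    pred = clf.predict(X[test_idx])
    return 100.0 * float(np.mean(pred == y[test_idx]))


def repeated_split_eval(X: np.ndarray, y: np.ndarray,
                        config: ANNConfig = ANNConfig(), n_reps: int = 10,
                        split: tuple[float, float, float] = (.6, .2, .2),
                        seed: int | None = None) -> EvalResult:
    """Repeated stratified 60/20/20 evaluation.

    Each repetition draws a fresh stratified split, trains on the 60%
    partition with early stopping on the validation 20%, and scores the
    held-out 20%.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2 ** 31 - 1))
        tr, va, te = stratified_split_indices(y, split, rep_seed)
        accs.append(_fit_and_score(X, y, tr, va, te, config, rep_seed))
    return EvalResult(np.asarray(accs), "split60_20_20x%d" % n_reps)


def kfold_eval(X: np.ndarray, y: np.ndarray, config: ANNConfig = ANNConfig(),
               k: int = 5, seed: int | None = None) -> EvalResult:
    """Stratified k-fold cross-validation accuracy."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    if k == len(y):
        # leave-one-out boundary: one trial per fold, stratification moot
        splits = [(np.delete(np.arange(k), i), np.array([i]))
                  for i in range(k)]
    else:
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < k:
            raise ValueError(f"class {classes[counts.argmin()]!r} has "
                             f"{counts.min()} trials; needs >= {k} for "
                             f"{k}-fold CV")
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2 ** 31 - 1)))
        splits = list(skf.split(X, y))
    accs = []
    for train_idx, test_idx in splits:
        rep_seed = int(rng.integers(2 ** 31 - 1))
        accs.append(_fit_and_score(X, y, train_idx, np.array([], dtype=int),
                                   test_idx, config, rep_seed))
    return EvalResult(np.asarray(accs), f"kfold{k}")
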