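"""Sequential forward selection, CGM/PAM scopes and chance estimation.

Feature selection is wrapper-style: features enter in descending F-ratio
order (ranked on the training partition only) and the decoder is retrained
after each addition; selection stops once the score fails to improve for
``patience`` consecutive additions and the best-scoring prefix is kept.
By default the selection score is the *validation* partition accuracy, so
the held-out test partition never influences which features are chosen; the
``scoring='test'`` option reproduces the historical protocol that scores
selection on the test partition directly.

Two model scopes are supported: CGM (combined global model — trials of all
participants pooled into one classifier, SD across repetitions) and PAM
(personalized average model — one classifier per participant, mean and SD
across participants).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .containers import TrialSet
from .evaluate import EvalResult, stratified_split_indices
from .features import f_ratio_scores, rank_order
from .nnet import ANNConfig
from .sl import FeatureTensor, compute_feature_tensor
from .bands import DEFAULT_BANDS, SLParams

__all__ = ["SFSResult", "RunReport", "sfs_select", "decode_with_sfs",
           "run_scope", "temporal_decoding_profile", "quasi_random_chance"]


@dataclass
class SFSResult:
    """Outcome of one sequential-forward-selection pass."""

    trajectory: np.ndarray          # accuracy (%) after each addition
    selected_features: np.ndarray   # column indices, rank order
    best_accuracy: float

    @property
    def selected_n(self) -> int:
        return len(self.selected_features)


def _flip_two_class(y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("label flipping requires exactly two classes")
    out = y.copy()
    swap = {classes[0]: classes[1], classes[1]: classes[0]}
    out[idx] = [swap[v] for v in y[idx]]
    return out


def _sfs_on_split(X, y, train_idx, val_idx, test_idx, config: ANNConfig,
                  patience, max_features, scoring, seed):
    """Run SFS on a fixed split; returns (SFSResult, test accuracy %)."""
    ranking = rank_order(f_ratio_scores(X[train_idx], y[train_idx]))
    limit = min(max_features or X.shape[1], X.shape[1])
    score_idx = val_idx if scoring == "validation" else test_idx
    rng = np.random.default_rng(seed)

    traj, best, best_k, fails = [], -np.inf, 0, 0
    best_test = 0.0
    for k in range(1, limit + 1):
        cols = ranking[:k]
        clf = config.make_classifier(int(rng.integers(2 ** 31 - 1)))
        clf.fit(X[np.ix_(train_idx, cols)], y[train_idx],
                validation_data=(X[np.ix_(val_idx, cols)], y[val_idx]))
        acc = 100.0 * float(np.mean(
            clf.predict(X[np.ix_(score_idx, cols)]) == y[score_idx]))
        traj.append(acc)
        if acc > best:
            best, best_k, fails = acc, k, 0
            best_test = 100.0 * float(np.mean(
                clf.predict(X[np.ix_(test_idx, cols)]) == y[test_idx]))
        else:
            fails += 1
            if patience is not None and fails >= patience:
                break
    result = SFSResult(np.asarray(traj), ranking[:best_k], best)
    return result, best_test


def sfs_select(X: np.ndarray, y: np.ndarray, config: ANNConfig = ANNConfig(),
               patience: int | None = 1, max_features: int | None = None,
               scoring: str = "validation",
               split: tuple[float, float, float] = (.6, .2, .2),
               seed: int | None = None) -> SFSResult:
    """Sequential forward selection on one stratified split."""
    if scoring not in ("validation", "test"):
        raise ValueError("scoring must be 'validation' or 'test'")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    tr, va, te = stratified_split_indices(y, split, seed)
    result, _ = _sfs_on_split(X, y, tr, va, te, config, patience,
                              max_features, scoring, seed)
    return result


def decode_with_sfs(X: np.ndarray, y: np.ndarray,
                    config: ANNConfig = ANNConfig(), n_reps: int = 10,
                    patience: int | None = 1,
                    max_features: int | None = None,
                    scoring: str = "validation",
                    split: tuple[float, float, float] = (.6, .2, .2),
                    seed: int | None = None,
                    ) -> tuple[EvalResult, list[SFSResult]]:
    """Full decoding protocol: per repetition, a fresh stratified split,
    F-ratio ranking on the training partition, SFS, and the selected model's
    accuracy on the held-out test partition."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    accs, results = [], []
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2 ** 31 - 1))
        tr, va, te = stratified_split_indices(y, split, rep_seed)
        res, test_acc = _sfs_on_split(X, y, tr, va, te, config, patience,
                                      max_features, scoring, rep_seed)
        accs.append(test_acc if scoring == "validation" else res.best_accuracy)
        results.append(res)
    return EvalResult(np.asarray(accs), f"sfs+split x{n_reps}"), results


@dataclass
class RunReport:
    """Per-scope evaluation summary with full provenance."""

    scope: str
    evaluation: EvalResult
    sfs_results: list[SFSResult]
    per_participant: dict[int, EvalResult] | None
    seed: int | None
    config_hash: str

    def summary(self) -> dict:
        return {"scope": self.scope, "accuracy_mean": self.evaluation.mean,
                "accuracy_sd": self.evaluation.sd, "seed": self.seed,
                "config_hash": self.config_hash}


def _config_hash(config: ANNConfig, extra: dict) -> str:
    payload = {"ann": asdict(config), **extra}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_scope(trials: TrialSet, scope: str, config: ANNConfig = ANNConfig(),
              seed: int | None = None, tensor: FeatureTensor | None = None,
              bands=DEFAULT_BANDS, sl_params: SLParams = SLParams(),
              n_reps: int = 10, patience: int | None = 1,
              max_features: int | None = None, scoring: str = "validation",
              min_trials: int = 10) -> RunReport:
    """Evaluate one model scope.

    CGM pools every participant's trials into a single decoder (SD across
    repetitions); PAM fits one decoder per participant and reports the mean
    and SD of the per-participant accuracies.  ``tensor`` may carry
    precomputed TFSL features to avoid recomputation.
    """
    scope = scope.lower()
    if scope not in ("cgm", "pam"):
        raise ValueError("scope must be 'cgm' or 'pam'")
    if tensor is None:
        tensor = compute_feature_tensor(trials, bands, sl_params)
    X = tensor.to_matrix()
    y = trials.labels
    chash = _config_hash(config, {"scope": scope, "n_reps": n_reps,
                                  "patience": patience,
                                  "max_features": max_features,
                                  "scoring": scoring})

    if scope == "cgm":
        ev, sfs = decode_with_sfs(X, y, config, n_reps, patience,
                                  max_features, scoring, seed=seed)
        return RunReport("cgm", ev, sfs, None, seed, chash)

    per: dict[int, EvalResult] = {}
    all_sfs: list[SFSResult] = []
    for i, p in enumerate(np.unique(trials.participant_ids)):
        mask = trials.participant_ids == p
        if mask.sum() < min_trials:
            warnings.warn(f"participant {p} has {int(mask.sum())} trials "
                          f"(< {min_trials}); skipped")
            continue
        # offset per participant; a lone participant reduces to the CGM call
        ev, sfs = decode_with_sfs(X[mask], y[mask], config, n_reps, patience,
                                  max_features, scoring,
                                  seed=None if seed is None else seed + i)
        per[int(p)] = ev
        all_sfs.extend(sfs)
    if not per:
        raise ValueError("no participant met the minimum trial count")
    # PAM summary: mean across participants, SD across participants
    participant_means = np.array([ev.mean for ev in per.values()])
    summary = EvalResult(participant_means, f"pam x{len(per)} participants")
    return RunReport("pam", summary, all_sfs, per, seed, chash)


def temporal_decoding_profile(tensor: FeatureTensor, labels: np.ndarray,
                              config: ANNConfig = ANNConfig(),
                              n_reps: int = 5, patience: int | None = 1,
                              max_features: int | None = None,
                              seed: int | None = None) -> np.ndarray:
    """Accuracy (%) as a function of cumulative window count.

    Point ``k'`` repeats the full SFS + evaluation protocol restricted to
    windows ``0..k'``; the curve rises while informative windows keep
    arriving and plateaus afterwards.
    """
    n_windows = tensor.shape[3]
    rng = np.random.default_rng(seed)
    curve = np.empty(n_windows)
    for k in range(1, n_windows + 1):
        sub = tensor.restrict_windows(np.arange(k)).to_matrix()
        ev, _ = decode_with_sfs(sub, labels, config, n_reps, patience,
                                max_features,
                                seed=int(rng.integers(2 ** 31 - 1)))
        curve[k - 1] = ev.mean
    return curve


def quasi_random_chance(X: np.ndarray, y: np.ndarray,
                        config: ANNConfig = ANNConfig(), n_runs: int = 10,
                        seed: int | None = None, n_features: int = 20,
                        flip_fraction: float = 0.5,
                        split: tuple[float, float, float] = (.6, .2, .2),
                        ) -> EvalResult:
    """Empirical chance level by quasi-randomization.

    Per run: a fresh stratified split; the labels of a uniformly random
    ``flip_fraction`` of the trials seen during training (the train and
    validation partitions together; ``floor(n/2)`` of them at the default)
    are flipped; the top ``n_features`` features are ranked on the flipped
    training labels; the decoder is trained and then scored on the untouched
    test partition with the true labels.  With half the training labels
    flipped the training signal is destroyed, so the mean accuracy estimates
    the classifier's true chance level.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if not 0.0 <= flip_fraction <= 1.0:
        raise ValueError("flip_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_runs):
        rep_seed = int(rng.integers(2 ** 31 - 1))
        tr, va, te = stratified_split_indices(y, split, rep_seed)
        pool = np.concatenate([tr, va])
        n_flip = int(np.floor(flip_fraction * len(pool)))
        flip_idx = pool[rng.choice(len(pool), size=n_flip, replace=False)]
        y_run = _flip_two_class(y, flip_idx)
        cols = rank_order(f_ratio_scores(X[tr], y_run[tr]))[:n_features]
        clf = config.make_classifier(rep_seed)
        clf.fit(X[np.ix_(tr, cols)], y_run[tr],
                validation_data=(X[np.ix_(va, cols)], y_run[va]))
        pred = clf.predict(X[np.ix_(te, cols)])
        accs.append(100.0 * float(np.mean(pred == y[te])))
    return EvalResult(np.asarray(accs), f"quasi-random chance x{n_runs}")
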