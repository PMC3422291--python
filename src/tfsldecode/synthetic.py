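"""Synthetic multichannel epochs with known class-dependent coupling.

The generator emulates the study conditions of a two-alternative face
preference experiment: 64-channel, 512 Hz, 1 s epochs (plus embedding tail)
in two classes, *chosen* and *not chosen*.  Every channel is independent
1/f-shaped Gaussian noise.  Trials of the chosen class additionally receive
a shared narrowband driver — band-limited noise, one realization per trial —
additively mixed with coefficient ``kappa`` into a configurable electrode
set, only inside configurable 50 ms windows (cosine-ramped edges).  A common
driver creates generalized synchronization among the effect electrodes that
synchronization likelihood detects, so the ground-truth
(band, electrode, window) triples are known exactly.

Two regimes mirror the pooled / per-participant analyses: a *shared* effect
topography (same electrodes for everyone) and an *idiosyncratic* one (an
independent random electrode set per participant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bands import BAND_NAMES, DEFAULT_BANDS, embedding_tail, get_band
from .containers import CHOSEN, NOT_CHOSEN, TrialSet, window_grid
from .preprocess import bandpass


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic generator.

    ``effect_electrodes`` is either an explicit tuple of channel indices
    (shared topography) or an integer count, in which case each participant
    receives an independent random electrode set of that size (idiosyncratic
    topography).  ``coupling_strength`` is the driver-to-background mixing
    coefficient kappa: the driver has unit RMS like the background noise, so
    kappa = 1 means driver amplitude approximately equal to background RMS.
    ``coupling_strength_nc`` optionally injects a weaker driver into the
    not-chosen class (default none).
    """

    n_participants: int = 1
    trials_per_participant: int = 200
    n_channels: int = 64
    sampling_rate: float = 512.0
    epoch_length: float = 1.0
    effect_band: str = "alpha"
    effect_windows: tuple[int, ...] = (4, 5, 6, 7, 8, 9, 10, 11)
    effect_electrodes: tuple[int, ...] | int = (8, 18, 28, 38)
    coupling_strength: float = 1.0
    coupling_strength_nc: float = 0.0
    class_balance: float = 0.5
    noise_exponent: float = 1.0
    n_windows: int = 20
    tail_samples: int | None = None   # None -> max (m-1)*L over default bands
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_band not in BAND_NAMES:
            raise ValueError(f"unknown effect_band {self.effect_band!r}")
        if any(not 0 <= w < self.n_windows for w in self.effect_windows):
            raise ValueError(f"effect windows must lie in "
                             f"0..{self.n_windows - 1}")
        if isinstance(self.effect_electrodes, int):
            if not 0 < self.effect_electrodes <= self.n_channels:
                raise ValueError("per-participant electrode count out of range")
        elif any(not 0 <= e < self.n_channels for e in self.effect_electrodes):
            raise ValueError("effect electrodes must lie in "
                             f"0..{self.n_channels - 1}")
        if self.coupling_strength < 0 or self.coupling_strength_nc < 0:
            raise ValueError("coupling strength kappa must be >= 0")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if self.n_participants < 1 or self.trials_per_participant < 1:
            raise ValueError("need at least one participant and one trial")

    @property
    def idiosyncratic(self) -> bool:
        return isinstance(self.effect_electrodes, int)

    def resolved_tail(self) -> int:
        return (embedding_tail(DEFAULT_BANDS) if self.tail_samples is None
                else self.tail_samples)


@dataclass
class GroundTruth:
    """Which (band, electrode, window) triples carry class information."""

    band_index: int
    effect_windows: tuple[int, ...]
    per_participant_map: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def electrodes_for(self, participant: int) -> tuple[int, ...]:
        return self.per_participant_map[participant]

    def signal_feature_ids(self, participant: int | None = None,
                           ) -> set[tuple[int, int, int]]:
        """0-based (band, electrode, window) triples; union over
        participants when none is given."""
        participants = ([participant] if participant is not None
                        else list(self.per_participant_map))
        return {(self.band_index, e, w)
                for p in participants
                for e in self.per_participant_map[p]
                for w in self.effect_windows}

    def save(self, path: str | Path) -> None:
        payload = {"band_index": self.band_index,
                   "effect_windows": list(self.effect_windows),
                   "per_participant_map": {str(k): list(v) for k, v in
                                           self.per_participant_map.items()}}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["band_index"], tuple(d["effect_windows"]),
                   {int(k): tuple(v) for k, v in
                    d["per_participant_map"].items()})


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                     n_samples: int, exponent: float, fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f**exponent power spectrum.

    White Gaussian noise is shaped in the frequency domain by
    ``f**(-exponent / 2)`` (DC removed) and rescaled channel-wise to unit
    standard deviation.
    """
    white = rng.standard_normal(shape + (n_samples,))
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spectrum * gain, n=n_samples, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def effect_window_mask(config: SimConfig, n_samples: int,
                       ramp_s: float = 0.010) -> np.ndarray:
    """Per-sample gain of the driver: 1 inside the effect windows, 0
    elsewhere, with cosine ramps at each edge to avoid spectral splatter."""
    grid = window_grid(config.sampling_rate, config.n_windows)
    mask = np.zeros(n_samples)
    for w in config.effect_windows:
        lo, hi = grid[w]
        mask[lo:hi] = 1.0
    ramp = max(int(round(ramp_s * config.sampling_rate)), 1)
    # smooth each 0->1 / 1->0 transition of every contiguous run
    padded = np.concatenate([[0.0], mask, [0.0]])
    starts = np.flatnonzero(np.diff(padded) > 0)
    stops = np.flatnonzero(np.diff(padded) < 0)
    smooth = np.zeros_like(mask)
    for a, b in zip(starts, stops):
        r = min(ramp, (b - a) // 2) or 1
        up = 0.5 * (1 - np.cos(np.pi * (np.arange(r) + 0.5) / r))
        smooth[a:b] = 1.0
        smooth[a:a + r] = up
        smooth[b - r:b] = up[::-1]
    return smooth


def _band_limited_driver(rng: np.random.Generator, n_samples: int,
                         config: SimConfig) -> np.ndarray:
    band = get_band(config.effect_band)
    white = rng.standard_normal(n_samples)
    driver = bandpass(white, band, config.sampling_rate)
    sd = driver.std()
    return driver / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_trialset(config: SimConfig, seed: int | None = None,
                      ) -> tuple[TrialSet, GroundTruth]:
    """Generate one epoched dataset and its ground truth.

    Trials are blocked by participant.  Labels realize exactly
    ``round(trials_per_participant * class_balance)`` chosen trials per
    participant, in shuffled order.  Reproducible: identical
    ``(config, seed)`` gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_analysis = int(round(config.sampling_rate * config.epoch_length))
    n_samples = n_analysis + config.resolved_tail()
    n_trials = config.n_participants * config.trials_per_participant

    data = one_over_f_noise(rng, (n_trials, config.n_channels), n_samples,
                            config.noise_exponent, config.sampling_rate)

    # per-participant effect electrodes
    per_participant: dict[int, tuple[int, ...]] = {}
    for p in range(config.n_participants):
        if config.idiosyncratic:
            chosen = rng.choice(config.n_channels,
                                size=config.effect_electrodes, replace=False)
            per_participant[p] = tuple(sorted(int(c) for c in chosen))
        else:
            per_participant[p] = tuple(sorted(config.effect_electrodes))

    # labels: exact class counts per participant, shuffled
    labels = np.empty(n_trials, dtype=np.int64)
    participant_ids = np.repeat(np.arange(config.n_participants),
                                config.trials_per_participant)
    n_chosen = int(round(config.trials_per_participant * config.class_balance))
    n_chosen = min(max(n_chosen, 1), config.trials_per_participant - 1)
    for p in range(config.n_participants):
        block = np.full(config.trials_per_participant, NOT_CHOSEN)
        block[:n_chosen] = CHOSEN
        rng.shuffle(block)
        labels[p * config.trials_per_participant:
               (p + 1) * config.trials_per_participant] = block

    mask = effect_window_mask(config, n_samples)
    for t in range(n_trials):
        kappa = (config.coupling_strength if labels[t] == CHOSEN
                 else config.coupling_strength_nc)
        if kappa <= 0:
            # burn the draw so label assignment does not shift the noise
            _ = _band_limited_driver(rng, n_samples, config)
            continue
        driver = _band_limited_driver(rng, n_samples, config) * mask * kappa
        electrodes = list(per_participant[int(participant_ids[t])])
        data[t, electrodes] += driver[None, :]

    trials = TrialSet(data, labels, config.sampling_rate, participant_ids,
                      "F2", n_analysis, config.n_windows)
    truth = GroundTruth(BAND_NAMES.index(config.effect_band),
                        tuple(sorted(config.effect_windows)), per_participant)
    return trials, truth


def save_dataset(trials: TrialSet, truth: GroundTruth, config: SimConfig,
                 directory: str | Path) -> None:
    """Persist trials, ground truth and configuration side by side."""
    directory = Path(directory)
    trials.save(directory)
    truth.save(directory / "ground_truth.json")
    cfg = asdict(config)
    if isinstance(cfg["effect_electrodes"], tuple):
        cfg["effect_electrodes"] = list(cfg["effect_electrodes"])
    cfg["effect_windows"] = list(cfg["effect_windows"])
    (directory / "sim_config.json").write_text(json.dumps(cfg, indent=1))
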