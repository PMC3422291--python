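"""In-memory containers: continuous recordings and epoched trial sets.

Sample indexing is 0-based and all intervals are half-open.  The 1 s
analysis window of every epoch is tiled by 20 half-open 50 ms windows whose
boundaries are ``round(k * 0.05 * fs)``; at 512 Hz this gives alternating
26/25-sample windows that tile samples ``[0, 512)`` exactly.  Epochs carry an
extra *tail* past the analysis window so that time-delay embedding vectors
anchored anywhere inside it are complete.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Event codes used by the epoching step.
EV_F1_ONSET = 1
EV_F1_KEYPRESS = 2
EV_F2_ONSET = 3
EV_RESP_LEFT = 4
EV_RESP_RIGHT = 5

CHOSEN = 1
NOT_CHOSEN = 0


def window_grid(fs: float, n_windows: int = 20,
                window_s: float = 0.05) -> list[tuple[int, int]]:
    """Half-open sample ranges ``[round(k*w*fs), round((k+1)*w*fs))``.

    The ranges are disjoint, ordered, and concatenate to exactly
    ``[0, round(n_windows * window_s * fs))``.
    """
    edges = [int(round(k * window_s * fs)) for k in range(n_windows + 1)]
    return [(edges[k], edges[k + 1]) for k in range(n_windows)]


@dataclass
class Recording:
    """A continuous multichannel recording with event markers.

    ``data`` is channels x samples; ``events`` is a list of
    ``(sample_index, event_code)`` pairs sorted by sample index.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    events: list[tuple[int, int]]
    participant_id: str = "p0"
    channel_positions: np.ndarray | None = None  # (n_channels, 2), optional

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[0]} channels")
        self.events = sorted((int(s), int(c)) for s, c in self.events)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialSet:
    """Epoched trials ready for TFSL extraction.

    ``data`` is trials x channels x samples where samples =
    ``analysis_samples + tail_samples``; ``labels`` holds ``CHOSEN`` /
    ``NOT_CHOSEN`` per trial.
    """

    data: np.ndarray
    labels: np.ndarray
    sampling_rate: float
    participant_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    face: str = "F1"
    analysis_samples: int | None = None
    n_windows: int = 20

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("one label per trial required")
        if self.analysis_samples is None:
            self.analysis_samples = int(round(self.sampling_rate * 1.0))
        if self.data.shape[2] < self.analysis_samples:
            raise ValueError("trials shorter than the analysis window")
        if self.participant_ids is None:
            self.participant_ids = np.zeros(self.data.shape[0], dtype=np.int64)
        else:
            self.participant_ids = np.asarray(self.participant_ids)
            if self.participant_ids.shape != (self.data.shape[0],):
                raise ValueError("one participant id per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def tail_samples(self) -> int:
        return self.data.shape[2] - self.analysis_samples

    @property
    def windows(self) -> list[tuple[int, int]]:
        grid = window_grid(self.sampling_rate, self.n_windows)
        if grid[-1][1] != self.analysis_samples:
            raise ValueError("window grid does not tile the analysis window")
        return grid

    def select(self, mask: np.ndarray) -> "TrialSet":
        """Subset of trials by boolean mask or index array."""
        return TrialSet(self.data[mask], self.labels[mask],
                        self.sampling_rate, self.participant_ids[mask],
                        self.face, self.analysis_samples, self.n_windows)

    # -- persistence (npy matrix + JSON metadata) -------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "trials.npy", self.data)
        meta = {
            "sampling_rate": self.sampling_rate,
            "labels": self.labels.tolist(),
            "participant_ids": np.asarray(self.participant_ids).tolist(),
            "face": self.face,
            "analysis_samples": self.analysis_samples,
            "n_windows": self.n_windows,
            "window_grid": self.windows,
        }
        (directory / "trials.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "TrialSet":
        directory = Path(directory)
        meta = json.loads((directory / "trials.json").read_text())
        data = np.load(directory / "trials.npy")
        return cls(data, np.asarray(meta["labels"]), meta["sampling_rate"],
                   np.asarray(meta["participant_ids"]), meta["face"],
                   meta["analysis_samples"], meta["n_windows"])
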