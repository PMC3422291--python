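"""Loading, re-referencing, band-pass filtering and epoching.

Filtering follows the convention of ``butter(10, [low, high])``: a 10th-order
band-pass prototype (20 poles), applied zero-phase (forward-backward) by
default so that the 50 ms feature windows keep their post-onset latency
interpretation.  A causal single-pass option is available for completeness.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy import signal

from .bands import BandSpec
from .containers import (EV_F1_ONSET, EV_F2_ONSET, EV_RESP_LEFT,
                         EV_RESP_RIGHT, CHOSEN, NOT_CHOSEN, Recording,
                         TrialSet)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, stem: str | Path) -> None:
    """Write a Recording in the plain 'matrix' dialect.

    ``<stem>.npy`` holds the channels x samples float64 array; ``<stem>.json``
    holds sampling rate, channel labels, events and participant id.
    """
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), rec.data)
    header = {
        "sampling_rate": rec.sampling_rate,
        "channel_labels": rec.channel_labels,
        "events": [[int(s), int(c)] for s, c in rec.events],
        "participant_id": rec.participant_id,
        "data_file": stem.with_suffix(".npy").name,
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=1))


def load_recording(path: str | Path, format: str = "auto") -> Recording:
    """Load a recording from BDF/EDF (via MNE) or the matrix dialect.

    For BDF/EDF, events are decoded from the ``Status`` trigger channel if
    present, otherwise from a ``<path>.events.json`` sidecar.  Raises a
    descriptive error when no events can be found.
    """
    path = Path(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = {".bdf": "BDF", ".edf": "EDF", ".json": "matrix",
                  ".npy": "matrix"}.get(suffix, "")
        if not format:
            raise ValueError(f"cannot infer format from {path.name!r}; "
                             "pass format='BDF'|'EDF'|'matrix'")
    format = format.upper() if format.lower() != "matrix" else "matrix"

    if format == "matrix":
        stem = path.with_suffix("")
        header = json.loads(stem.with_suffix(".json").read_text())
        data = np.load(stem.parent / header["data_file"])
        if data.shape[0] != len(header["channel_labels"]):
            raise ValueError(
                f"matrix file has {data.shape[0]} channels but header lists "
                f"{len(header['channel_labels'])} labels")
        events = [(int(s), int(c)) for s, c in header["events"]]
        if not events:
            raise ValueError(f"no events in {path}")
        return Recording(data, header["sampling_rate"],
                         list(header["channel_labels"]), events,
                         header.get("participant_id", "p0"))

    if format in ("BDF", "EDF"):
        import mne
        reader = mne.io.read_raw_bdf if format == "BDF" else mne.io.read_raw_edf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = reader(path, preload=True, verbose="error")
        events: list[tuple[int, int]] = []
        if "Status" in raw.ch_names:
            ev = mne.find_events(raw, stim_channel="Status", verbose="error",
                                 consecutive=True)
            events = [(int(s), int(c)) for s, _, c in ev]
            raw = raw.drop_channels(["Status"])
        else:
            sidecar = path.with_suffix(path.suffix + ".events.json")
            if sidecar.exists():
                events = [(int(s), int(c))
                          for s, c in json.loads(sidecar.read_text())]
        if not events:
            raise ValueError(f"no events found in {path} "
                             "(no Status channel, no events sidecar)")
        return Recording(raw.get_data(), raw.info["sfreq"],
                         list(raw.ch_names), events, path.stem)

    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Re-referencing
# ---------------------------------------------------------------------------

def rereference_to_mastoids(rec: Recording,
                            mastoid_labels: tuple[str, str] = ("M1", "M2"),
                            ) -> Recording:
    """Subtract the average of the two mastoid channels; drop the mastoids."""
    for lab in mastoid_labels:
        if lab not in rec.channel_labels:
            raise ValueError(f"mastoid channel {lab!r} not present")
    idx = [rec.channel_labels.index(lab) for lab in mastoid_labels]
    reference = rec.data[idx].mean(axis=0)
    keep = [i for i in range(rec.n_channels) if i not in idx]
    data = rec.data[keep] - reference
    labels = [rec.channel_labels[i] for i in keep]
    positions = (rec.channel_positions[keep]
                 if rec.channel_positions is not None else None)
    return Recording(data, rec.sampling_rate, labels, list(rec.events),
                     rec.participant_id, positions)


# ---------------------------------------------------------------------------
# Band-pass filtering
# ---------------------------------------------------------------------------

def bandpass(data: np.ndarray, band: BandSpec, fs: float,
             order: int = 10, zero_phase: bool = True) -> np.ndarray:
    """Butterworth band-pass along the last axis (second-order sections).

    ``order`` is the prototype order per edge; the realized band-pass has
    ``2 * order`` poles.  ``zero_phase`` applies the filter forward and
    backward (no group delay, squared magnitude response).
    """
    nyquist = fs / 2.0
    if band.high >= nyquist:
        raise ValueError(f"band {band.name!r} upper edge {band.high} Hz is at "
                         f"or above Nyquist ({nyquist} Hz)")
    sos = signal.butter(order, [band.low, band.high], btype="bandpass",
                        fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, data, axis=-1)
    return signal.sosfilt(sos, data, axis=-1)


# ---------------------------------------------------------------------------
# Epoching and labelling
# ---------------------------------------------------------------------------

def _iter_trials(events: list[tuple[int, int]]):
    """Group an event stream into (f1_onset, f2_onset, response_code) trials."""
    f1 = f2 = None
    for sample, code in events:
        if code == EV_F1_ONSET:
            f1, f2 = sample, None
        elif code == EV_F2_ONSET and f1 is not None:
            f2 = sample
        elif code in (EV_RESP_LEFT, EV_RESP_RIGHT) and f2 is not None:
            yield f1, f2, code
            f1 = f2 = None


def epoch_and_label(rec: Recording, tail_samples: int,
                    response_map: dict[int, int] | None = None,
                    n_windows: int = 20) -> tuple[TrialSet, TrialSet]:
    """Cut 1 s (+tail) epochs from both face onsets and label them.

    ``response_map`` maps the final response event code to the chosen face
    (1 or 2); the default maps a left response to face 1 and a right response
    to face 2.  A final choice of face 1 labels the trial's F1 epoch CHOSEN
    and its F2 epoch NOT_CHOSEN, and vice versa.  Epochs running past the end
    of the recording drop the whole trial with a warning.
    """
    if response_map is None:
        response_map = {EV_RESP_LEFT: 1, EV_RESP_RIGHT: 2}
    n_analysis = int(round(rec.sampling_rate * 1.0))
    n_epoch = n_analysis + tail_samples

    f1_epochs, f2_epochs, f1_labels, f2_labels = [], [], [], []
    for f1_onset, f2_onset, resp in _iter_trials(rec.events):
        if max(f1_onset, f2_onset) + n_epoch > rec.n_samples:
            warnings.warn(f"trial at sample {f1_onset} extends past the end "
                          "of the recording; dropped")
            continue
        chosen_face = response_map[resp]
        f1_epochs.append(rec.data[:, f1_onset:f1_onset + n_epoch])
        f2_epochs.append(rec.data[:, f2_onset:f2_onset + n_epoch])
        f1_labels.append(CHOSEN if chosen_face == 1 else NOT_CHOSEN)
        f2_labels.append(CHOSEN if chosen_face == 2 else NOT_CHOSEN)

    def build(epochs, labels, face):
        if epochs:
            data = np.stack(epochs)
        else:
            data = np.empty((0, rec.n_channels, n_epoch))
        return TrialSet(data, np.asarray(labels, dtype=np.int64),
                        rec.sampling_rate, None, face, n_analysis, n_windows)

    return build(f1_epochs, f1_labels, "F1"), build(f2_epochs, f2_labels, "F2")
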