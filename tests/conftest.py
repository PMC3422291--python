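"""Shared fixtures: synthetic datasets (generated at test time) and a
minimal BDF writer used to build loader fixtures on the fly."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import tfsldecode as t
from tfsldecode.protocols import desk_sim_config

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def desk_dataset():
    """200-trial, 16-channel dataset with a strong localized alpha-band
    effect, plus its full 6-band TFSL feature tensor.

    Session-scoped: the tensor is the most expensive object in the suite
    and several behavioural checks share it.
    """
    cfg = desk_sim_config(seed=11)
    trials, truth = t.generate_trialset(cfg)
    tensor = t.compute_feature_tensor(trials)
    return cfg, trials, truth, tensor


@pytest.fixture(scope="session")
def small_signal_trials():
    """120 trials, 8 channels, alpha effect confined to the first four
    50 ms windows; single-band tensor for profile/recovery checks."""
    cfg = t.SimConfig(n_participants=1, trials_per_participant=120,
                      n_channels=8, effect_band="alpha",
                      effect_windows=(0, 1, 2, 3), effect_electrodes=(1, 3, 5),
                      coupling_strength=1.2, seed=9)
    trials, truth = t.generate_trialset(cfg)
    tensor = t.compute_feature_tensor(trials, (t.get_band("alpha"),))
    return cfg, trials, truth, tensor


def write_bdf(path, data_digital: np.ndarray, labels: list[str],
              fs: int, status: np.ndarray | None = None) -> None:
    """Write a minimal single-record 24-bit BDF file (synthetic fixture).

    ``data_digital`` is channels x samples of integers in the signed 24-bit
    range; ``status`` is an optional trigger channel of event codes appended
    as the conventional ``Status`` channel.
    """
    chans = [np.asarray(row, dtype=np.int64) for row in data_digital]
    names = list(labels)
    if status is not None:
        chans.append(np.asarray(status, dtype=np.int64))
        names.append("Status")
    n_ch = len(chans)
    n_samp = len(chans[0])

    def pad(text, width):
        return text[:width].ljust(width).encode("ascii")

    hdr = b"\xffBIOSEMI"
    hdr += pad("synthetic fixture", 80)
    hdr += pad("synthetic recording", 80)
    hdr += pad("01.01.20", 8) + pad("00.00.00", 8)
    hdr += pad(str((n_ch + 1) * 256), 8)
    hdr += pad("24BIT", 44)
    hdr += pad("1", 8)                       # one data record
    hdr += pad(str(n_samp / fs), 8)          # record duration (s)
    hdr += pad(str(n_ch), 4)
    hdr += b"".join(pad(n, 16) for n in names)
    hdr += b"".join(pad("synthetic", 80) for _ in names)
    for name in names:
        hdr += pad("" if name == "Status" else "uV", 8)
    hdr += b"".join(pad("-8388608", 8) for _ in names)
    hdr += b"".join(pad("8388607", 8) for _ in names)
    hdr += b"".join(pad("-8388608", 8) for _ in names)
    hdr += b"".join(pad("8388607", 8) for _ in names)
    hdr += b"".join(pad("", 80) for _ in names)
    hdr += b"".join(pad(str(n_samp), 8) for _ in names)
    hdr += b"".join(pad("", 32) for _ in names)

    body = bytearray()
    for chan in chans:
        vals = np.clip(chan, -(2 ** 23), 2 ** 23 - 1).astype(np.int64)
        u = np.where(vals < 0, vals + 2 ** 24, vals).astype(np.uint32)
        raw = np.empty((n_samp, 3), dtype=np.uint8)
        raw[:, 0] = u & 0xFF
        raw[:, 1] = (u >> 8) & 0xFF
        raw[:, 2] = (u >> 16) & 0xFF
        body += raw.tobytes()
    path.write_bytes(hdr + bytes(body))
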