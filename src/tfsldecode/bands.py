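"""Frequency-band definitions and synchronization-likelihood parameters.

Each band carries, besides its pass-band edges, the time-delay embedding
parameters used for state-space reconstruction in that band: the lag ``L``
(in samples) and the dimension ``m``.  An embedded vector therefore spans
``(m - 1) * L`` samples, which sets the minimum epoch tail needed so that
vectors anchored inside the 1 s analysis window are complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with its embedding parameters.

    Parameters
    ----------
    name : str
        Canonical band name (``delta`` ... ``gamma2``).
    low, high : float
        Pass-band edges in Hz; ``0 < low < high``.
    lag : int
        Embedding lag ``L`` in samples (``>= 1``).
    dim : int
        Embedding dimension ``m`` (``>= 2``).
    """

    name: str
    low: float
    high: float
    lag: int
    dim: int

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"band {self.name!r}: need 0 < low < high, got "
                             f"({self.low}, {self.high})")
        if self.lag < 1:
            raise ValueError(f"band {self.name!r}: lag must be >= 1")
        if self.dim < 2:
            raise ValueError(f"band {self.name!r}: dim must be >= 2")

    @property
    def span(self) -> int:
        """Samples spanned by one embedded vector beyond its anchor."""
        return (self.dim - 1) * self.lag


#: Default six-band decomposition with per-band embedding parameters
#: (lag decreases with frequency so each vector covers a few cycles).
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0, lag=25, dim=8),
    BandSpec("theta", 4.0, 8.0, lag=21, dim=7),
    BandSpec("alpha", 8.0, 12.0, lag=14, dim=6),
    BandSpec("beta", 12.0, 30.0, lag=6, dim=8),
    BandSpec("gamma1", 30.0, 40.0, lag=5, dim=5),
    BandSpec("gamma2", 40.0, 60.0, lag=3, dim=6),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def get_band(name: str, bands: tuple[BandSpec, ...] = DEFAULT_BANDS) -> BandSpec:
    for band in bands:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in bands]}")


def embedding_tail(bands: tuple[BandSpec, ...] = DEFAULT_BANDS) -> int:
    """Extra samples needed past the analysis window: max (m-1)*L over bands."""
    return max(b.span for b in bands)


@dataclass(frozen=True)
class SLParams:
    """Parameters of the synchronization-likelihood recurrence construction.

    ``p_ref`` is the reference recurrence probability: each anchor's critical
    distance is the smallest radius capturing a fraction ``p_ref`` of the
    candidate vectors, which makes ``p_ref`` the expected SL between
    statistically independent signals.  ``theiler`` is the half-width (in
    samples) of the temporal exclusion zone around each anchor; ``None``
    defaults to the embedded-vector span ``(m - 1) * L`` of the band in use.
    """

    p_ref: float = 0.1
    candidate_shift: int = 1
    anchor_shift: int = 25
    n_anchors: int = 20
    theiler: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_ref < 1.0:
            raise ValueError("p_ref must be in (0, 1)")
        if self.candidate_shift < 1:
            raise ValueError("candidate_shift must be >= 1")
        if self.anchor_shift < 1:
            raise ValueError("anchor_shift must be >= 1")
        if self.n_anchors < 1:
            raise ValueError("n_anchors must be >= 1")
        if self.theiler is not None and self.theiler < 0:
            raise ValueError("theiler must be >= 0")

    def theiler_for(self, band: BandSpec) -> int:
        return band.span if self.theiler is None else self.theiler

    def min_candidates(self) -> int:
        return math.ceil(1.0 / self.p_ref)

    def with_(self, **kw) -> "SLParams":
        return replace(self, **kw)
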