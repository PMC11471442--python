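"""Shared frequency-band conventions for the fluctuation-spectroscopy analysis.

Band edges are half-open ``[low, high)`` in Hz. The defaults partition the
analysis band of a 25 Hz acquisition (0.05–12.5 Hz) into the three regimes
used throughout: slow collective/membrane motion (low), mid-range organelle
transport (mid), and fast vesicle/undulation dynamics (high). Concurrent
enhancement of the low and high bands is the apoptosis signature.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FrequencyBand", "LOW_BAND", "MID_BAND", "HIGH_BAND", "DEFAULT_BANDS"]


@dataclass(frozen=True)
class FrequencyBand:
    """A half-open frequency interval ``[low_hz, high_hz)``."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: low_hz must be < high_hz "
                f"(got [{self.low_hz}, {self.high_hz}))"
            )

    def mask(self, freqs):
        """Boolean mask of ``freqs`` falling inside the band."""
        import numpy as np

        f = np.asarray(freqs, dtype=float)
        return (f >= self.low_hz) & (f < self.high_hz)


LOW_BAND = FrequencyBand("low", 0.05, 0.5)
MID_BAND = FrequencyBand("mid", 0.5, 3.0)
HIGH_BAND = FrequencyBand("high", 3.0, 12.5)

DEFAULT_BANDS = (LOW_BAND, MID_BAND, HIGH_BAND)
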