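"""EEG frequency-band scheme and band <-> DFT-bin bookkeeping.

The default partition is Kubicki's eight clinical bands (delta 1.5-6 Hz up to
gamma 35-44 Hz).  Band edges fall on half-integer frequencies, so with 1-s
epochs (1 Hz spectral resolution) every DFT bin center belongs to at most one
band; bins in gaps (e.g. 30-35 Hz) belong to none.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["Band", "BandScheme", "KUBICKI_BANDS"]


@dataclass(frozen=True)
class Band:
    name: str
    low: float   # Hz, inclusive
    high: float  # Hz, inclusive


KUBICKI_BANDS = (
    Band("delta", 1.5, 6.0),
    Band("theta", 6.5, 8.0),
    Band("alpha1", 8.5, 10.0),
    Band("alpha2", 10.5, 12.0),
    Band("beta1", 12.5, 18.0),
    Band("beta2", 18.5, 21.0),
    Band("beta3", 21.5, 30.0),
    Band("gamma", 35.0, 44.0),
)


class BandScheme:
    """Ordered, non-overlapping collection of named frequency bands."""

    def __init__(self, bands: tuple[Band, ...] = KUBICKI_BANDS):
        names = [b.name for b in bands]
        if len(set(names)) != len(names):
            raise ConfigurationError("bands: names must be unique")
        for b in bands:
            if not b.low < b.high:
                raise ConfigurationError(f"bands: band {b.name!r} has low >= high")
        ordered = sorted(bands, key=lambda b: b.low)
        for a, b in zip(ordered, ordered[1:]):
            if b.low <= a.high:
                raise ConfigurationError(
                    f"bands: bands {a.name!r} and {b.name!r} overlap"
                )
        self.bands = tuple(bands)

    def __iter__(self):
        return iter(self.bands)

    def __len__(self):
        return len(self.bands)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    @property
    def max_edge(self) -> float:
        return max(b.high for b in self.bands)

    def bin_indices(self, band: Band, n_samples: int, sfreq: float) -> np.ndarray:
        """One-sided DFT bin indices whose center frequency lies in *band*.

        Bin k has center frequency k * sfreq / n_samples; a bin belongs to the
        band when low <= f_k <= high.
        """
        k = np.arange(n_samples // 2 + 1)
        f = k * sfreq / n_samples
        return k[(f >= band.low) & (f <= band.high)]
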