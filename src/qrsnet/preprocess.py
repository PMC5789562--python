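"""Difference and averaged-difference preprocessing.

Two derived signals feed the detector:

* the *difference* signal ``s_d[n] = s_r[n] - s_r[n-1]``, which accentuates
  the steep slopes of the QRS complex on the raw timebase, and
* the *averaged-difference* signal: the raw trace block-averaged by a factor
  ``n_i`` (decimating the timebase by the same factor) and then differenced,
  giving a coarse whole-beat view.

No band-pass filtering, wavelet denoising or amplitude normalisation is
applied anywhere; the differencing itself removes the DC level and baseline
drift well enough for the downstream network.

Boundary convention: the first element of every differenced sequence is 0,
so derived signals stay index-aligned with their source timebase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import RawSignal

__all__ = [
    "DifferenceSignal",
    "AverageDifferenceSignal",
    "difference",
    "block_average",
    "average_difference",
    "DEFAULT_AVERAGING_FACTOR",
]

#: Default block-averaging factor. At 360 Hz a 56-sample window then spans
#: 56*5/360 = 0.78 s on the averaged timebase and 56/360 = 0.16 s raw.
DEFAULT_AVERAGING_FACTOR = 5


@dataclass(frozen=True)
class DifferenceSignal:
    """First-order difference of a raw signal, same length and timebase."""

    samples: np.ndarray
    sampling_rate: float

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class AverageDifferenceSignal:
    """Block-averaged-then-differenced signal on the decimated timebase."""

    samples: np.ndarray
    effective_rate: float
    n_i: int

    def __len__(self) -> int:
        return int(self.samples.size)


def _diff_with_leading_zero(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    out[0] = 0.0
    out[1:] = x[1:] - x[:-1]
    return out


def difference(signal: RawSignal) -> DifferenceSignal:
    """Adjacent-sample difference; ``out[0] = 0`` by convention.

    Raises
    ------
    ValueError
        If the signal holds fewer than two samples (enforced by
        :class:`~qrsnet.records.RawSignal` itself).
    """
    x = np.asarray(signal.samples, dtype=float)
    if x.size < 2:
        raise ValueError("difference requires at least 2 samples")
    return DifferenceSignal(_diff_with_leading_zero(x), signal.sampling_rate)


def block_average(signal: RawSignal | np.ndarray, n_i: int) -> np.ndarray:
    """Mean of non-overlapping blocks of ``n_i`` consecutive samples.

    The trailing partial block is discarded, so the output length is
    ``floor(len / n_i)``.
    """
    x = signal.samples if isinstance(signal, RawSignal) else np.asarray(signal, dtype=float)
    n_i = int(n_i)
    if n_i < 1:
        raise ValueError("averaging factor n_i must be >= 1")
    if x.size < n_i:
        raise ValueError("signal shorter than one averaging block")
    n_blocks = x.size // n_i
    return x[: n_blocks * n_i].reshape(n_blocks, n_i).mean(axis=1)


def average_difference(signal: RawSignal, n_i: int) -> AverageDifferenceSignal:
    """Block-average by ``n_i`` then difference, ``out[0] = 0``."""
    averaged = block_average(signal, n_i)
    if averaged.size < 2:
        raise ValueError("averaged signal too short to difference")
    return AverageDifferenceSignal(
        _diff_with_leading_zero(averaged),
        effective_rate=signal.sampling_rate / n_i,
        n_i=int(n_i),
    )
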