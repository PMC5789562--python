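"""Core record containers: raw ECG signals and beat annotations.

Conventions used throughout the package:

* sample indices are 0-based and refer to the raw (undecimated) timebase
  unless a name says otherwise;
* amplitudes are in millivolts;
* sampling rates are in hertz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RawSignal", "BeatAnnotationSet", "RecordBundle"]


@dataclass(frozen=True)
class RawSignal:
    """A uniformly sampled single-lead ECG trace.

    Parameters
    ----------
    samples : ndarray of float
        Sample values in mV.
    sampling_rate : float
        Sampling frequency in Hz.
    record_id : str
        Free-form record identifier.
    """

    samples: np.ndarray
    sampling_rate: float
    record_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("signal must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains NaN or infinite samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return len(self) / self.sampling_rate


# Minimum physiologically admissible RR interval used to validate annotations.
_MIN_RR_S = 0.2


@dataclass(frozen=True)
class BeatAnnotationSet:
    """Ordered R-peak sample indices, with optional Q/S landmarks per beat.

    ``r_indices`` must be strictly increasing.  ``q_indices``/``s_indices``,
    when present, are parallel to ``r_indices`` (one landmark per beat).
    """

    r_indices: np.ndarray
    q_indices: np.ndarray | None = None
    s_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r_indices, dtype=np.int64)
        object.__setattr__(self, "r_indices", r)
        if r.ndim != 1:
            raise ValueError("r_indices must be 1-D")
        if r.size and np.any(r < 0):
            raise ValueError("annotation indices must be non-negative")
        if r.size > 1 and np.any(np.diff(r) <= 0):
            raise ValueError("r_indices must be strictly increasing")
        for name in ("q_indices", "s_indices"):
            val = getattr(self, name)
            if val is not None:
                arr = np.asarray(val, dtype=np.int64)
                if arr.shape != r.shape:
                    raise ValueError(f"{name} must be parallel to r_indices")
                object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return int(self.r_indices.size)

    def validate_rr(self, sampling_rate: float) -> None:
        """Check that consecutive beats are at least 0.2 s apart."""
        if len(self) > 1:
            rr = np.diff(self.r_indices) / sampling_rate
            if np.any(rr < _MIN_RR_S):
                raise ValueError(f"consecutive R indices closer than {_MIN_RR_S} s")


@dataclass
class RecordBundle:
    """A signal together with (optional) reference annotations."""

    signal: RawSignal
    annotations: BeatAnnotationSet | None = None
    source_format: str = "csv"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.annotations is not None and len(self.annotations):
            if int(self.annotations.r_indices.max()) >= len(self.signal):
                raise ValueError("annotation index beyond signal length")
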