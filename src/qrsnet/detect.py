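"""Sliding detection: turn the per-point class posteriors into R-peak marks.

The classifier is evaluated at every valid centre of the averaged timebase
(stride = ``n_i`` raw samples).  Contiguous runs where the R posterior
exceeds a threshold become candidate events; each event is placed at the
centre with the maximal R posterior, mapped back to the raw timebase,
deduplicated under a physiological refractory period and finally refined to
the nearest raw-amplitude apex.

The decision policy (threshold 0.5, refractory 0.2 s, 0.05 s refinement
window) is this package's own construction: the network itself only scores
points, and Q/S posteriors are exposed in the stream but do not form
events — beat-level scoring counts R events only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnn import NetworkParams, NetworkSpec, forward_batch
from .preprocess import DEFAULT_AVERAGING_FACTOR, average_difference, difference
from .records import BeatAnnotationSet, RawSignal
from .segment import (
    WINDOW_AFTER,
    WINDOW_BEFORE,
    WINDOW_LENGTH,
    center_raw_index,
    valid_center_range,
)

__all__ = [
    "PosteriorStream",
    "DetectionResult",
    "scan",
    "decide",
    "refine_to_peak",
    "QRSDetector",
    "DEFAULT_THRESHOLD",
    "DEFAULT_REFRACTORY_S",
    "DEFAULT_REFINE_WINDOW_S",
]

DEFAULT_THRESHOLD = 0.5
DEFAULT_REFRACTORY_S = 0.2
DEFAULT_REFINE_WINDOW_S = 0.05


@dataclass(frozen=True)
class PosteriorStream:
    """Per-centre posteriors over {Q, R, S, non-QRS}.

    ``centers_avg`` are averaged-timebase indices; ``posteriors`` is the
    parallel (n, 4) matrix; ``effective_rate`` the averaged timebase rate.
    """

    centers_avg: np.ndarray
    posteriors: np.ndarray
    effective_rate: float
    n_i: int
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.posteriors.shape != (self.centers_avg.size, 4):
            raise ValueError("posteriors must be (n_centers, 4)")

    @property
    def r_posterior(self) -> np.ndarray:
        from .segment import ClassLabel

        return self.posteriors[:, int(ClassLabel.R)]


@dataclass(frozen=True)
class DetectionResult:
    """Predicted beats with per-beat confidence (peak R posterior)."""

    annotations: BeatAnnotationSet
    confidences: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.confidences.shape != self.annotations.r_indices.shape:
            raise ValueError("confidences must be parallel to detections")

    def __len__(self) -> int:
        return len(self.annotations)


def scan(
    record: RawSignal,
    spec: NetworkSpec,
    params: NetworkParams,
    n_i: int = DEFAULT_AVERAGING_FACTOR,
) -> PosteriorStream:
    """Classify every valid averaged-timebase centre of a record."""
    sd = difference(record)
    sad = average_difference(record, n_i)
    lo, hi = valid_center_range(len(sd), len(sad), n_i)
    if hi <= lo:
        raise ValueError("record too short for a single detection window")
    centers = np.arange(lo, hi)
    raw_centers = centers * n_i + n_i // 2

    obj = np.lib.stride_tricks.sliding_window_view(sad.samples, WINDOW_LENGTH)[
        centers - WINDOW_BEFORE
    ]
    part = np.lib.stride_tricks.sliding_window_view(sd.samples, WINDOW_LENGTH)[
        raw_centers - WINDOW_BEFORE
    ]
    # chunked evaluation keeps the convolution workspace bounded on long records
    chunk = 8192
    posteriors = np.concatenate(
        [
            forward_batch(spec, params, part[i : i + chunk], obj[i : i + chunk])
            for i in range(0, centers.size, chunk)
        ]
    )
    return PosteriorStream(
        centers_avg=centers,
        posteriors=posteriors,
        effective_rate=sad.effective_rate,
        n_i=n_i,
        sampling_rate=record.sampling_rate,
    )


def decide(
    stream: PosteriorStream,
    threshold: float = DEFAULT_THRESHOLD,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> DetectionResult:
    """Form R events from supra-threshold runs of the R posterior.

    Each contiguous run contributes one event at its maximal-posterior
    centre; events closer than the refractory period keep only the
    higher-confidence one (earlier wins ties).
    """
    p_r = stream.r_posterior
    above = p_r > threshold
    events: list[tuple[int, float]] = []  # (raw index, confidence)
    if above.any():
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        starts = np.concatenate(([0] if above[0] else [], edges[~above[edges]] + 1)).astype(int)
        ends = np.concatenate((edges[above[edges]] + 1, [above.size] if above[-1] else [])).astype(int)
        for s, e in zip(starts, ends):
            k = s + int(np.argmax(p_r[s:e]))
            raw = center_raw_index(int(stream.centers_avg[k]), stream.n_i)
            events.append((raw, float(p_r[k])))

    refractory = int(round(refractory_s * stream.sampling_rate))
    kept: list[tuple[int, float]] = []
    for raw, conf in events:  # events arrive ordered in time
        if kept and raw - kept[-1][0] < refractory:
            if conf > kept[-1][1]:
                kept[-1] = (raw, conf)
        else:
            kept.append((raw, conf))

    idx = np.asarray([r for r, _ in kept], dtype=np.int64)
    conf = np.asarray([c for _, c in kept], dtype=float)
    return DetectionResult(
        annotations=BeatAnnotationSet(r_indices=idx),
        confidences=conf,
        sampling_rate=stream.sampling_rate,
    )


def refine_to_peak(
    detections: DetectionResult,
    raw_signal: RawSignal,
    window_s: float = DEFAULT_REFINE_WINDOW_S,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> DetectionResult:
    """Snap each detection to the maximal-|amplitude| raw sample nearby.

    Amplitude ties break towards the original index (then leftmost), so a
    flat signal leaves indices unchanged and the operation is idempotent.
    Ordering and the refractory constraint are re-asserted afterwards.
    """
    x = raw_signal.samples
    w = int(round(window_s * raw_signal.sampling_rate))
    refined = []
    for r, conf in zip(detections.annotations.r_indices, detections.confidences):
        lo = max(0, int(r) - w)
        hi = min(x.size, int(r) + w + 1)
        mag = np.abs(x[lo:hi])
        ties = np.flatnonzero(mag == mag.max()) + lo
        best = int(ties[np.argmin(np.abs(ties - int(r)))])
        refined.append((best, float(conf)))
    refined.sort()
    refractory = int(round(refractory_s * raw_signal.sampling_rate))
    kept: list[tuple[int, float]] = []
    for raw, conf in refined:
        if kept and raw - kept[-1][0] < refractory:
            if conf > kept[-1][1]:
                kept[-1] = (raw, conf)
        else:
            kept.append((raw, conf))
    return DetectionResult(
        annotations=BeatAnnotationSet(r_indices=np.asarray([r for r, _ in kept], dtype=np.int64)),
        confidences=np.asarray([c for _, c in kept], dtype=float),
        sampling_rate=raw_signal.sampling_rate,
    )


@dataclass
class QRSDetector:
    """A trained network bundled with its detection policy."""

    spec: NetworkSpec
    params: NetworkParams
    n_i: int = DEFAULT_AVERAGING_FACTOR
    threshold: float = DEFAULT_THRESHOLD
    refractory_s: float = DEFAULT_REFRACTORY_S
    refine_window_s: float = DEFAULT_REFINE_WINDOW_S

    def detect(self, record: RawSignal) -> DetectionResult:
        stream = scan(record, self.spec, self.params, self.n_i)
        result = decide(stream, self.threshold, self.refractory_s)
        return refine_to_peak(result, record, self.refine_window_s, self.refractory_s)
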