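"""Dual-timebase windowing around candidate detection points, and labelling.

A detection point lives on the *averaged* timebase (one point per ``n_i``
raw samples).  Around each point two aligned 56-sample windows are cut:

* the **object-level** window from the averaged-difference signal
  (coarse, spans a whole beat: 0.78 s at 360 Hz with ``n_i = 5``), and
* the **part-level** window from the difference signal on the raw timebase
  (fine, spans the QRS itself: 0.16 s),

each covering 22 samples before the point and 33 after it (22 + 1 + 33 = 56).
The raw-timebase centre of averaged index ``c`` is ``c*n_i + n_i//2``, the
middle of the averaged block.

Labelling assigns one of four classes (Q, R, S, non-QRS) to a centre, or
excludes it: centres in the ambiguous band between the QRS neighbourhood and
the far field never enter a training set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .preprocess import AverageDifferenceSignal, DifferenceSignal
from .records import BeatAnnotationSet, RawSignal, RecordBundle

__all__ = [
    "SegmentPair",
    "ClassLabel",
    "SegmentDataset",
    "WINDOW_BEFORE",
    "WINDOW_AFTER",
    "WINDOW_LENGTH",
    "extract_pair",
    "valid_center_range",
    "center_raw_index",
    "label_center",
    "locate_qs_landmarks",
    "build_dataset",
    "merge_datasets",
]

WINDOW_BEFORE = 22
WINDOW_AFTER = 33
WINDOW_LENGTH = WINDOW_BEFORE + 1 + WINDOW_AFTER  # 56

#: R-label tolerance: 1 averaged sample either side of the annotated apex.
TOL_R_AVG = 1
#: Q/S-label tolerance in raw samples.
TOL_QS_RAW = 2
#: Centres farther than this (seconds) from every R apex are non-QRS.
NONQRS_EXCLUSION_S = 0.2
#: Half-width (seconds) of the search window for Q/S troughs beside R.
QS_SEARCH_S = 0.06


class ClassLabel(enum.IntEnum):
    """Four-way segment class; the integer value indexes the network output."""

    Q = 0
    R = 1
    S = 2
    NONQRS = 3

    @property
    def one_hot(self) -> np.ndarray:
        t = np.zeros(4)
        t[int(self)] = 1.0
        return t


@dataclass(frozen=True)
class SegmentPair:
    """Aligned part-level / object-level windows at one detection point."""

    part_window: np.ndarray    # 56 values from the difference signal
    object_window: np.ndarray  # 56 values from the averaged-difference signal
    center_avg_index: int
    center_raw_index: int

    def __post_init__(self) -> None:
        for name in ("part_window", "object_window"):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.shape != (WINDOW_LENGTH,):
                raise ValueError(f"{name} must have exactly {WINDOW_LENGTH} samples")
            object.__setattr__(self, name, w)


def center_raw_index(center_avg_index: int, n_i: int) -> int:
    """Raw-timebase sample aligned with an averaged-timebase centre."""
    return int(center_avg_index) * int(n_i) + int(n_i) // 2


def valid_center_range(sd_len: int, sad_len: int, n_i: int) -> tuple[int, int]:
    """Half-open range of averaged-timebase centres with in-bounds windows.

    Both the object window (on the averaged signal) and the part window (on
    the raw-timebase difference signal) must fit.
    """
    lo_avg = WINDOW_BEFORE
    hi_avg = sad_len - WINDOW_AFTER  # exclusive
    # part-window constraints on the raw timebase
    half = int(n_i) // 2
    lo_raw = -(-(WINDOW_BEFORE - half) // int(n_i))  # ceil division
    hi_raw = (sd_len - WINDOW_AFTER - half - 1) // int(n_i) + 1
    return max(lo_avg, lo_raw, 0), min(hi_avg, hi_raw)


def extract_pair(
    sd: DifferenceSignal,
    sad: AverageDifferenceSignal,
    center_avg_index: int,
) -> SegmentPair:
    """Cut the aligned 56-sample window pair at one averaged-timebase centre.

    Raises
    ------
    IndexError
        If either window would run past its signal's bounds.
    """
    n_i = sad.n_i
    c_avg = int(center_avg_index)
    c_raw = center_raw_index(c_avg, n_i)
    lo, hi = valid_center_range(len(sd), len(sad), n_i)
    if not lo <= c_avg < hi:
        raise IndexError(
            f"centre {c_avg} out of the valid range [{lo}, {hi}) for this record"
        )
    obj = sad.samples[c_avg - WINDOW_BEFORE : c_avg + WINDOW_AFTER + 1]
    part = sd.samples[c_raw - WINDOW_BEFORE : c_raw + WINDOW_AFTER + 1]
    return SegmentPair(part, obj, c_avg, c_raw)


def locate_qs_landmarks(signal: RawSignal, annotations: BeatAnnotationSet) -> BeatAnnotationSet:
    """Fill missing Q/S landmarks as raw-signal minima beside each R apex.

    Beat-level reference annotations usually mark only the R fiducial; the Q
    and S troughs are located as the signal minimum within ``QS_SEARCH_S``
    seconds before / after each R.  Existing landmarks are kept.
    """
    if annotations.q_indices is not None and annotations.s_indices is not None:
        return annotations
    x = signal.samples
    w = max(1, int(round(QS_SEARCH_S * signal.sampling_rate)))
    q_idx, s_idx = [], []
    for r in annotations.r_indices:
        lo = max(0, r - w)
        hi = min(len(x), r + w + 1)
        q_idx.append(lo + int(np.argmin(x[lo:r])) if r > lo else int(r))
        s_idx.append(r + 1 + int(np.argmin(x[r + 1 : hi])) if hi > r + 1 else int(r))
    return BeatAnnotationSet(
        r_indices=annotations.r_indices,
        q_indices=annotations.q_indices if annotations.q_indices is not None else np.asarray(q_idx),
        s_indices=annotations.s_indices if annotations.s_indices is not None else np.asarray(s_idx),
    )


def label_center(
    center_raw: int,
    annotations: BeatAnnotationSet,
    fs: float,
    n_i: int,
) -> ClassLabel | None:
    """Classify one raw-timebase centre, or return None when it falls in the
    ambiguous band between the QRS neighbourhood and the far field.

    Precedence: R (within ±1 averaged sample of an apex), then Q, then S
    (within ±2 raw samples of the landmark), then non-QRS (farther than
    0.2 s from every apex).
    """
    r = annotations.r_indices
    if r.size == 0:
        return ClassLabel.NONQRS
    pos = int(np.searchsorted(r, center_raw))
    nearest = min(
        (abs(center_raw - int(r[i])) for i in (pos - 1, pos) if 0 <= i < r.size),
    )
    if nearest <= TOL_R_AVG * n_i:
        return ClassLabel.R
    for landmarks, label in ((annotations.q_indices, ClassLabel.Q), (annotations.s_indices, ClassLabel.S)):
        if landmarks is not None and landmarks.size:
            j = int(np.searchsorted(landmarks, center_raw))
            d = min(
                (abs(center_raw - int(landmarks[i])) for i in (j - 1, j) if 0 <= i < landmarks.size),
            )
            if d <= TOL_QS_RAW:
                return label
    if nearest > NONQRS_EXCLUSION_S * fs:
        return ClassLabel.NONQRS
    return None


@dataclass
class SegmentDataset:
    """Labelled segment pairs as dense matrices, ready for training.

    ``part`` and ``objects`` are (n, 56) arrays; ``labels`` holds
    :class:`ClassLabel` integer values; ``centers_raw`` the raw-timebase
    centre of each pair.
    """

    part: np.ndarray
    objects: np.ndarray
    labels: np.ndarray
    centers_raw: np.ndarray

    def __post_init__(self) -> None:
        n = self.part.shape[0]
        if self.part.shape != (n, WINDOW_LENGTH) or self.objects.shape != (n, WINDOW_LENGTH):
            raise ValueError("window matrices must be (n, 56)")
        if self.labels.shape != (n,) or self.centers_raw.shape != (n,):
            raise ValueError("labels and centers must be parallel to the windows")

    def __len__(self) -> int:
        return int(self.part.shape[0])

    @property
    def one_hot(self) -> np.ndarray:
        t = np.zeros((len(self), 4))
        t[np.arange(len(self)), self.labels] = 1.0
        return t

    def class_counts(self) -> dict[str, int]:
        return {lab.name: int(np.sum(self.labels == int(lab))) for lab in ClassLabel}

    def save(self, path) -> None:
        np.savez(
            path,
            part=self.part,
            objects=self.objects,
            labels=self.labels,
            centers_raw=self.centers_raw,
        )

    @classmethod
    def load(cls, path) -> "SegmentDataset":
        with np.load(path) as z:
            return cls(z["part"], z["objects"], z["labels"], z["centers_raw"])


def merge_datasets(datasets: list[SegmentDataset]) -> SegmentDataset:
    return SegmentDataset(
        part=np.concatenate([d.part for d in datasets]),
        objects=np.concatenate([d.objects for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        centers_raw=np.concatenate([d.centers_raw for d in datasets]),
    )


def build_dataset(
    record: RecordBundle,
    n_i: int,
    balance: dict[str, int],
    seed: int = 0,
) -> SegmentDataset:
    """Draw a per-class-balanced labelled dataset from one annotated record.

    Every valid centre is labelled; the requested number per class is then
    sampled uniformly (seeded).  Raises a ``ValueError`` naming the class if
    a record cannot supply enough eligible centres.
    """
    from .preprocess import average_difference, difference

    if record.annotations is None:
        raise ValueError("record must carry reference annotations")
    ann = locate_qs_landmarks(record.signal, record.annotations)
    sd = difference(record.signal)
    sad = average_difference(record.signal, n_i)
    lo, hi = valid_center_range(len(sd), len(sad), n_i)

    centers = np.arange(lo, hi)
    raw_centers = centers * n_i + n_i // 2
    by_class: dict[int, list[int]] = {int(lab): [] for lab in ClassLabel}
    for c_avg, c_raw in zip(centers, raw_centers):
        lab = label_center(int(c_raw), ann, record.signal.sampling_rate, n_i)
        if lab is not None:
            by_class[int(lab)].append(int(c_avg))

    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    labels: list[int] = []
    for name, want in balance.items():
        lab = ClassLabel[name]
        pool = by_class[int(lab)]
        if len(pool) < want:
            raise ValueError(
                f"record supplies only {len(pool)} eligible {name} centres; {want} requested"
            )
        pick = rng.choice(len(pool), size=want, replace=False)
        chosen.extend(pool[i] for i in sorted(pick))
        labels.extend([int(lab)] * want)

    pairs = [extract_pair(sd, sad, c) for c in chosen]
    return SegmentDataset(
        part=np.stack([p.part_window for p in pairs]),
        objects=np.stack([p.object_window for p in pairs]),
        labels=np.asarray(labels, dtype=np.int64),
        centers_raw=np.asarray([p.center_raw_index for p in pairs], dtype=np.int64),
    )
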