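"""Beat-level scoring: annotation matching, Sen/PPR/DER/Acc, noise sweeps.

Predictions are matched one-to-one to reference beats by greedy
nearest-neighbour assignment within a tolerance window (default 0.15 s,
the standard beat-matching practice).  From the resulting TP/FP/FN counts:

    Sen = TP / (TP + FN) * 100
    PPR = TP / (TP + FP) * 100
    DER = (FN + FP) / (TP + FN) * 100
    Acc = TP / (TP + FP + FN) * 100

All percentages are kept at full precision internally and rounded half-up
to two decimals only for reporting.  Pooled ("overall") metrics over many
records are computed from summed counts, never by averaging percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .records import BeatAnnotationSet, RecordBundle
from .synth import add_gaussian_noise

__all__ = [
    "EvalCounts",
    "Metrics",
    "match",
    "metrics",
    "evaluate_record",
    "pool_counts",
    "snr_sweep",
    "DEFAULT_MATCH_TOL_S",
]

DEFAULT_MATCH_TOL_S = 0.15


@dataclass(frozen=True)
class EvalCounts:
    """True-positive / false-positive / false-negative beat counts."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_reference(self) -> int:
        return self.tp + self.fn

    @property
    def n_predicted(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, positive predictivity, detection error rate, accuracy
    (percent, full precision)."""

    sen: float
    ppr: float
    der: float
    acc: float

    def rounded(self, ndigits: int = 2) -> "Metrics":
        """Half-up rounding for report formatting."""

        def r(v: float) -> float:
            q = Decimal(1).scaleb(-ndigits)
            return float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))

        return Metrics(r(self.sen), r(self.ppr), r(self.der), r(self.acc))

    def as_dict(self) -> dict[str, float]:
        return {"sen": self.sen, "ppr": self.ppr, "der": self.der, "acc": self.acc}


def match(
    pred: BeatAnnotationSet,
    ref: BeatAnnotationSet,
    tol_s: float = DEFAULT_MATCH_TOL_S,
    fs: float = 360.0,
) -> EvalCounts:
    """Greedy one-to-one nearest-neighbour matching within ``tol_s``.

    Candidate (reference, prediction) pairs within the tolerance are
    accepted in order of increasing distance (leftmost reference breaks
    ties); each beat participates in at most one match.  This equals the
    optimal assignment whenever beats are separated by more than twice the
    tolerance.
    """
    r = ref.r_indices.astype(np.int64)
    p = pred.r_indices.astype(np.int64)
    tol = tol_s * fs
    candidates: list[tuple[float, int, int]] = []
    j0 = 0
    for i, rv in enumerate(r):
        j0 = int(np.searchsorted(p, rv - tol, side="left"))
        j = j0
        while j < p.size and p[j] <= rv + tol:
            candidates.append((abs(float(p[j] - rv)), i, j))
            j += 1
    candidates.sort()
    used_r = np.zeros(r.size, dtype=bool)
    used_p = np.zeros(p.size, dtype=bool)
    tp = 0
    for _, i, j in candidates:
        if not used_r[i] and not used_p[j]:
            used_r[i] = used_p[j] = True
            tp += 1
    return EvalCounts(tp=tp, fp=int(p.size - tp), fn=int(r.size - tp))


def metrics(counts: EvalCounts) -> Metrics:
    """Sen/PPR/DER/Acc from TP/FP/FN.

    Raises
    ------
    ZeroDivisionError
        When no reference beats or no predictions exist, with one
        exception: Sen and DER stay defined when only predictions are
        missing, and vice versa; truly empty denominators raise.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fn == 0:
        raise ZeroDivisionError("no reference beats: Sen/DER undefined")
    if tp + fp == 0:
        raise ZeroDivisionError("no predictions: PPR undefined")
    return Metrics(
        sen=tp / (tp + fn) * 100.0,
        ppr=tp / (tp + fp) * 100.0,
        der=(fn + fp) / (tp + fn) * 100.0,
        acc=tp / (tp + fp + fn) * 100.0,
    )


def metrics_or_worst(counts: EvalCounts) -> Metrics:
    """Like :func:`metrics`, but an eventless detector (tp + fp = 0) scores
    the worst defined values instead of raising."""
    if counts.tp + counts.fp == 0 and counts.tp + counts.fn > 0:
        return Metrics(sen=0.0, ppr=0.0, der=100.0, acc=0.0)
    return metrics(counts)


def pool_counts(counts: list[EvalCounts]) -> EvalCounts:
    """Summed counts for pooled ("overall") metrics."""
    return EvalCounts(
        tp=sum(c.tp for c in counts),
        fp=sum(c.fp for c in counts),
        fn=sum(c.fn for c in counts),
    )


def evaluate_record(
    record: RecordBundle,
    detector,
    tol_s: float = DEFAULT_MATCH_TOL_S,
) -> dict:
    """Run detection on one annotated record and score it.

    Returns a report row: record id, total beats, TP/FP/FN and the four
    metrics (2-decimal rounded values alongside full precision).
    """
    if record.annotations is None:
        raise ValueError("record must carry reference annotations")
    result = detector.detect(record.signal)
    counts = match(result.annotations, record.annotations, tol_s, record.signal.sampling_rate)
    m = metrics_or_worst(counts)
    rounded = m.rounded()
    return {
        "record": record.signal.record_id,
        "total": counts.n_reference,
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "sen": rounded.sen,
        "ppr": rounded.ppr,
        "der": rounded.der,
        "acc": rounded.acc,
        "_counts": counts,
        "_metrics": m,
    }


def snr_sweep(
    record: RecordBundle,
    detector,
    snr_list_db: list[float],
    n_seeds: int = 5,
    tol_s: float = DEFAULT_MATCH_TOL_S,
    base_seed: int = 0,
) -> list[dict]:
    """Detection metrics under additive Gaussian noise at each SNR.

    The first row is the noise-free baseline; each following row reports
    the mean metrics over ``n_seeds`` independent noise realisations at
    one SNR.  Rows carry ``snr_db = inf`` for the baseline.
    """
    rows = []
    baseline = evaluate_record(record, detector, tol_s)
    rows.append({"snr_db": float("inf"), **{k: baseline[k] for k in ("sen", "ppr", "der", "acc")}})
    for snr in snr_list_db:
        per_seed = []
        for s in range(n_seeds):
            noisy = add_gaussian_noise(record.signal, snr, seed=(base_seed * 101 + s) % (2**31))
            noisy_record = RecordBundle(
                signal=noisy, annotations=record.annotations, source_format=record.source_format
            )
            per_seed.append(evaluate_record(noisy_record, detector, tol_s)["_metrics"])
        rows.append(
            {
                "snr_db": float(snr),
                "sen": float(np.mean([m.sen for m in per_seed])),
                "ppr": float(np.mean([m.ppr for m in per_seed])),
                "der": float(np.mean([m.der for m in per_seed])),
                "acc": float(np.mean([m.acc for m in per_seed])),
            }
        )
    return rows
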