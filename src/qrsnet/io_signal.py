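"""File formats: CSV signals with a JSON sidecar, plain-text annotations,
self-describing model containers, TSV/JSON evaluation reports, and optional
WFDB import.

* **Signal CSV**: two columns ``index,mV`` (comma separator, ``.`` decimal,
  optional auto-detected header) plus a ``<stem>.json`` sidecar holding
  ``{"record_id": ..., "fs": ...}``.
* **Annotations**: two whitespace/comma-separated columns
  ``sample_index label`` with label in {Q, R, S}; indices are 0-based.
* **Models**: a NumPy ``.npz`` archive holding every parameter array plus an
  embedded JSON block describing the architecture and training metadata;
  loading verifies the architecture and every array shape.
* **WFDB**: MIT-BIH-style records can be imported when the optional
  ``wfdb`` package is installed; a named channel (default MLII) is
  selected and beat annotations are converted to 0-based indices.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cnn import NetworkParams, NetworkSpec
from .records import BeatAnnotationSet, RawSignal

__all__ = [
    "read_signal",
    "write_signal",
    "read_annotations",
    "write_annotations",
    "save_model",
    "load_model",
    "write_report_tsv",
    "ChannelNotFoundError",
    "ArchitectureMismatchError",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["record", "total", "tp", "fp", "fn", "sen", "ppr", "der", "acc"]


class ChannelNotFoundError(KeyError):
    """Requested lead is absent from a multi-channel record."""


class ArchitectureMismatchError(ValueError):
    """Stored parameter arrays do not fit the stored architecture."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_signal(signal: RawSignal, path) -> None:
    """Write ``index,mV`` CSV plus the ``{record_id, fs}`` JSON sidecar."""
    path = Path(path)
    frame = pd.DataFrame({"index": np.arange(len(signal)), "mV": signal.samples})
    frame.to_csv(path, index=False, float_format="%.9f")
    _sidecar_path(path).write_text(
        json.dumps({"record_id": signal.record_id, "fs": signal.sampling_rate}) + "\n"
    )


def _read_signal_csv(path: Path) -> RawSignal:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"sampling-rate sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    try:
        frame = pd.read_csv(path)
        if not {"index", "mV"} <= set(frame.columns):
            # headerless variant
            frame = pd.read_csv(path, header=None, names=["index", "mV"])
    except Exception as exc:  # malformed file
        raise ValueError(f"malformed signal CSV {path}: {exc}") from exc
    idx = frame["index"].to_numpy()
    if np.any(np.diff(idx) <= 0):
        raise ValueError("sample index column must be strictly increasing")
    samples = frame["mV"].to_numpy(dtype=float)
    if not np.all(np.isfinite(samples)):
        raise ValueError("signal contains NaN or infinite samples")
    return RawSignal(samples, float(meta["fs"]), record_id=str(meta.get("record_id", path.stem)))


def _read_signal_wfdb(path: Path, channel: str) -> RawSignal:
    try:
        import wfdb  # optional dependency
    except ImportError as exc:
        raise ImportError(
            "WFDB support requires the optional 'wfdb' package (pip install qrsnet[wfdb])"
        ) from exc
    record = wfdb.rdrecord(str(path))
    names = list(record.sig_name)
    if channel not in names:
        raise ChannelNotFoundError(f"channel {channel!r} not in record (has {names})")
    samples = np.asarray(record.p_signal[:, names.index(channel)], dtype=float)
    if not np.all(np.isfinite(samples)):
        raise ValueError("signal contains NaN or infinite samples")
    return RawSignal(samples, float(record.fs), record_id=str(record.record_name))


def read_signal(path, format: str = "csv", channel: str = "MLII") -> RawSignal:
    """Read a single-lead signal from CSV (+sidecar) or a WFDB record."""
    path = Path(path)
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_signal_csv(path)
    if format == "wfdb":
        return _read_signal_wfdb(path, channel)
    raise ValueError(f"unknown signal format {format!r}")


_BEAT_LABELS = {"Q", "R", "S"}


def write_annotations(annotations: BeatAnnotationSet, path) -> None:
    """Two-column text: ``sample_index label``, one row per landmark."""
    rows = [(int(i), "R") for i in annotations.r_indices]
    for arr, lab in ((annotations.q_indices, "Q"), (annotations.s_indices, "S")):
        if arr is not None:
            rows.extend((int(i), lab) for i in arr)
    rows.sort()
    Path(path).write_text("".join(f"{i}\t{lab}\n" for i, lab in rows))


def read_annotations(path) -> BeatAnnotationSet:
    """Parse a two-column annotation file; R indices are sorted and
    deduplicated, non-beat labels are ignored (with a logged count)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    by_label: dict[str, list[int]] = {lab: [] for lab in _BEAT_LABELS}
    ignored = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'index label'")
        try:
            idx = int(parts[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer index {parts[0]!r}") from exc
        if idx < 0:
            raise ValueError(f"{path}:{lineno}: negative sample index")
        label = parts[1].upper()
        if label in by_label:
            by_label[label].append(idx)
        else:
            ignored += 1
    if ignored:
        logger.info("ignored %d non-beat annotation rows in %s", ignored, path)
    r = np.unique(np.asarray(sorted(set(by_label["R"])), dtype=np.int64))
    q = np.asarray(sorted(set(by_label["Q"])), dtype=np.int64)
    s = np.asarray(sorted(set(by_label["S"])), dtype=np.int64)
    return BeatAnnotationSet(
        r_indices=r,
        q_indices=q if q.size == r.size and r.size else None,
        s_indices=s if s.size == r.size and r.size else None,
    )


MODEL_FORMAT_VERSION = 1


def save_model(
    params: NetworkParams,
    spec: NetworkSpec,
    path,
    metadata: dict | None = None,
) -> None:
    """Serialise every weight/bias bit-exactly with an architecture block."""
    header = {
        "format_version": MODEL_FORMAT_VERSION,
        "architecture": spec.to_dict(),
        "metadata": metadata or {},
    }
    arrays = {f"param::{k}": v for k, v in params.items()}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> tuple[NetworkParams, NetworkSpec, dict]:
    """Load and validate a saved model; raises on architecture mismatch."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path) as archive:
        header = json.loads(bytes(archive["__header__"]).decode())
        if header.get("format_version") != MODEL_FORMAT_VERSION:
            raise ArchitectureMismatchError("unsupported model format version")
        spec = NetworkSpec.from_dict(header["architecture"])
        params = NetworkParams(
            {k[len("param::"):]: archive[k] for k in archive.files if k.startswith("param::")}
        )
    from .cnn import init_params

    expected = init_params(spec, seed=0)
    if set(expected) != set(params):
        raise ArchitectureMismatchError(
            f"parameter names {sorted(params)} do not match the stored architecture"
        )
    for k in expected:
        if expected[k].shape != params[k].shape:
            raise ArchitectureMismatchError(
                f"{k}: stored shape {params[k].shape}, architecture requires {expected[k].shape}"
            )
    return params, spec, header["metadata"]


def write_report_tsv(rows: list[dict], path) -> None:
    """Per-record metric table (Record, Total beats, TP, FP, FN, Sen, PPR,
    DER, Acc) as TSV, with a pooled 'Overall' row appended."""
    from .evaluation import metrics_or_worst, pool_counts

    frame = pd.DataFrame([{k: row[k] for k in REPORT_COLUMNS} for row in rows])
    pooled = pool_counts([row["_counts"] for row in rows])
    m = metrics_or_worst(pooled).rounded()
    overall = {
        "record": "Overall",
        "total": pooled.n_reference,
        "tp": pooled.tp,
        "fp": pooled.fp,
        "fn": pooled.fn,
        "sen": m.sen,
        "ppr": m.ppr,
        "der": m.der,
        "acc": m.acc,
    }
    frame = pd.concat([frame, pd.DataFrame([overall])], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False)
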