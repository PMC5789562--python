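"""Synthetic single-lead ECG with ground-truth beat annotations.

Each heartbeat is modelled as a superposition of five Gaussian deflections
(P, Q, R, S, T) placed at fixed offsets around a scheduled R time.  RR
intervals follow a lognormal multiplicative jitter around ``60 / mean_hr``,
clipped to the physiological range [0.3 s, 2.0 s].  Optional sinusoidal
baseline wander and additive white Gaussian noise at a requested SNR
complete the model.

This generator emulates the morphology of a clean MLII lead well enough to
exercise every downstream stage (preprocessing, segmentation, network
training, sliding detection, evaluation); it makes no attempt at pathology,
multi-lead synthesis, or structured noise such as electrode motion.

All outputs are pure functions of ``(config, seed)``.  A single seed is
split into independent substreams (RR schedule / noise) so that noise can
be varied while the underlying beat sequence stays fixed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .records import BeatAnnotationSet, RawSignal, RecordBundle

__all__ = [
    "WaveParams",
    "SynthConfig",
    "generate_record",
    "add_gaussian_noise",
    "make_training_corpus",
    "DEFAULT_WAVES",
]


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian deflection: amplitude (mV), width sigma (s), offset from R (s)."""

    amplitude: float
    width: float
    offset: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("wave width must be positive")


#: Default beat morphology: a dominant positive R deflection flanked by the
#: small negative Q and S troughs, a low P hump ~0.2 s before and a broad T
#: hump ~0.3 s after the R apex.
DEFAULT_WAVES: dict[str, WaveParams] = {
    "P": WaveParams(0.15, 0.030, -0.20),
    "Q": WaveParams(-0.15, 0.012, -0.04),
    "R": WaveParams(1.00, 0.020, 0.00),
    "S": WaveParams(-0.20, 0.012, 0.04),
    "T": WaveParams(0.30, 0.070, 0.30),
}

_RR_CLIP_S = (0.3, 2.0)
# Margin kept free of beats at both record edges so every wave fits.
_EDGE_MARGIN_S = 0.45


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic ECG generator.

    Parameters
    ----------
    sampling_rate : float
        Hz; 360 matches the MIT-BIH MLII convention.
    duration : float
        Record length in seconds.
    mean_hr : float
        Mean heart rate, beats/min; must lie in [20, 300].
    hr_jitter : float
        Fractional standard deviation of the lognormal RR jitter
        (0 gives a perfectly regular rhythm).
    wave_params : dict
        Per-wave morphology; keys P, Q, R, S, T.
    baseline_wander_amplitude, baseline_wander_freq : float
        Sinusoidal baseline drift (mV, Hz); amplitude 0 disables it.
    """

    sampling_rate: float = 360.0
    duration: float = 60.0
    mean_hr: float = 60.0
    hr_jitter: float = 0.05
    wave_params: dict[str, WaveParams] = field(default_factory=lambda: dict(DEFAULT_WAVES))
    baseline_wander_amplitude: float = 0.0
    baseline_wander_freq: float = 0.33
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not 20.0 <= self.mean_hr <= 300.0:
            raise ValueError("mean_hr must lie in [20, 300] beats/min")
        if self.hr_jitter < 0:
            raise ValueError("hr_jitter must be non-negative")
        r_amp = abs(self.wave_params["R"].amplitude)
        for name in ("P", "T"):
            if name in self.wave_params and abs(self.wave_params[name].amplitude) >= r_amp:
                raise ValueError(f"R amplitude must dominate the {name} wave")


def _substream(seed: int, purpose: str) -> np.random.Generator:
    """Independent generator for one purpose, derived from the global seed."""
    tag = zlib.crc32(purpose.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _schedule_r_times(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """RR-scheduled R-apex times, lognormal jitter, clipped to [0.3, 2.0] s."""
    mean_rr = 60.0 / config.mean_hr
    # sigma of the underlying normal chosen so the multiplicative factor has
    # roughly the requested fractional sd
    sigma = math.sqrt(math.log(1.0 + config.hr_jitter**2))
    times = []
    t = mean_rr * 0.5
    limit = config.duration - _EDGE_MARGIN_S
    while t <= limit:
        times.append(t)
        if config.hr_jitter > 0:
            factor = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
        else:
            factor = 1.0
        t += float(np.clip(mean_rr * factor, *_RR_CLIP_S))
    return np.asarray(times)


def generate_record(config: SynthConfig, seed: int | None = None) -> tuple[RawSignal, BeatAnnotationSet]:
    """Generate one annotated synthetic record.

    Returns the signal and an annotation set whose ``r_indices`` mark the
    scheduled R-apex samples; ``q_indices``/``s_indices`` carry the true Q/S
    trough locations.

    Raises
    ------
    ValueError
        If the duration is too short to fit a single beat.
    """
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = _substream(seed, "schedule")

    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs

    r_times = _schedule_r_times(config, rng)
    if r_times.size == 0:
        raise ValueError("duration too short to schedule a single beat")

    x = np.zeros(n)
    for rt in r_times:
        for wave in config.wave_params.values():
            c = rt + wave.offset
            # Gaussian support truncated at 5 sigma for speed
            lo = max(0, int((c - 5 * wave.width) * fs))
            hi = min(n, int((c + 5 * wave.width) * fs) + 1)
            if lo >= hi:
                continue
            x[lo:hi] += wave.amplitude * np.exp(-0.5 * ((t[lo:hi] - c) / wave.width) ** 2)

    if config.baseline_wander_amplitude:
        x += config.baseline_wander_amplitude * np.sin(2 * np.pi * config.baseline_wander_freq * t)

    def _idx(times: np.ndarray, offset: float) -> np.ndarray:
        return np.round((times + offset) * fs).astype(np.int64)

    ann = BeatAnnotationSet(
        r_indices=_idx(r_times, config.wave_params["R"].offset),
        q_indices=_idx(r_times, config.wave_params["Q"].offset) if "Q" in config.wave_params else None,
        s_indices=_idx(r_times, config.wave_params["S"].offset) if "S" in config.wave_params else None,
    )
    sig = RawSignal(x, fs, record_id=f"synth-{seed}")
    return sig, ann


def add_gaussian_noise(signal: RawSignal, snr_db: float, seed: int = 0) -> RawSignal:
    """Add white Gaussian noise at the requested SNR.

    The signal power reference is the mean square of the mean-removed
    record; the noise variance is ``P_signal / 10**(snr_db/10)``.
    ``snr_db = inf`` is the noise-free sentinel and returns the input
    unchanged.
    """
    if math.isinf(snr_db) and snr_db > 0:
        return signal
    if not math.isfinite(snr_db):
        raise ValueError("snr_db must be finite (or +inf to disable noise)")
    x = signal.samples
    p_signal = float(np.mean((x - x.mean()) ** 2))
    if p_signal == 0.0:
        raise ValueError("constant signal has zero power; SNR undefined")
    noise_sd = math.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
    rng = _substream(seed, "noise")
    noisy = x + rng.normal(0.0, noise_sd, size=x.size)
    return RawSignal(noisy, signal.sampling_rate, record_id=signal.record_id)


def make_training_corpus(
    config: SynthConfig,
    n_qrs: int,
    seed: int = 0,
    n_i: int | None = None,
):
    """Build a balanced labelled training corpus of segment pairs.

    Generates as many records as needed to supply ``n_qrs`` beats and draws
    ``n_qrs`` examples of each class (Q, R, S, non-QRS) from them using the
    segmentation labelling rules.

    Returns a :class:`~qrsnet.segment.SegmentDataset`.
    """
    from .preprocess import DEFAULT_AVERAGING_FACTOR
    from .segment import build_dataset, merge_datasets

    if n_qrs < 4:
        raise ValueError("n_qrs must be at least 4")
    if n_i is None:
        n_i = DEFAULT_AVERAGING_FACTOR

    beats_per_record = max(1, int(config.duration * config.mean_hr / 60.0) - 2)
    n_records = math.ceil(n_qrs / beats_per_record)

    datasets = []
    remaining = n_qrs
    for k in range(n_records):
        rec_seed = (seed * 1009 + k) % (2**31)
        sig, ann = generate_record(config, seed=rec_seed)
        if len(ann) < 4 and n_records == 1:
            raise ValueError("record too short to supply the requested beats")
        take = min(remaining, max(1, len(ann) - 2))
        bundle = RecordBundle(signal=sig, annotations=ann, source_format="synthetic")
        datasets.append(
            build_dataset(
                bundle,
                n_i=n_i,
                balance={"Q": take, "R": take, "S": take, "NONQRS": take},
                seed=rec_seed,
            )
        )
        remaining -= take
        if remaining <= 0:
            break
    if remaining > 0:
        raise ValueError("could not supply the requested number of beats")
    return merge_datasets(datasets)


def heldout_records(
    config: SynthConfig, n_records: int, seed: int = 0
) -> list[RecordBundle]:
    """Generate a list of annotated evaluation records disjoint (by seed
    stream) from :func:`make_training_corpus` output."""
    out = []
    for k in range(n_records):
        rec_seed = (seed * 2003 + 500_000 + k) % (2**31)
        sig, ann = generate_record(config, seed=rec_seed)
        out.append(RecordBundle(signal=sig, annotations=ann, source_format="synthetic"))
    return out
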