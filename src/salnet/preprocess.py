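"""Continuous recordings → clean, condition-labelled 700 ms epoch sets.

The stage order is fixed and enforced by :func:`preprocess_recording`:
band-pass filter → segment → detrend/baseline → amplitude rejection →
random subsampling. The 6th-order Butterworth band-pass (0.1–50 Hz) is
applied zero-phase (forward–backward), which preserves component latencies
needed by the mismatch-negativity window at the cost of doubling the
effective magnitude order. The 75 µV absolute-maximum rejection criterion is
evaluated after baseline correction, per epoch over all channels. Manual
independent-component artifact rejection performed on real recordings has no
automated counterpart here; the amplitude criterion stands alone, a fidelity
gap documented in the methods note.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import RunConfig
from .simulate import SensorRecording

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Fixed-length multi-channel segments of one condition.

    ``data`` is epochs × channels × samples in µV. ``tmin`` is the time of
    the first sample relative to stimulus onset (oddball: -0.1 s) or segment
    start (resting: 0), with a half-open time axis [tmin, tmin + T).
    """

    data: np.ndarray
    condition: str               # 'RS' | 'Std' | 'Dev'
    sampling_rate: float
    tmin: float
    channel_names: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be epochs × channels × samples")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.tmin + np.arange(n) / self.sampling_rate


def butter_bandpass_sos(low_hz: float, high_hz: float, fs: float,
                        order: int = 6) -> np.ndarray:
    """Design the band-pass used throughout: Butterworth, given design order."""
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) Hz incompatible with "
            f"sampling rate {fs} Hz")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=fs, output="sos")


def bandpass_filter(recording: SensorRecording,
                    cfg: RunConfig | None = None) -> SensorRecording:
    """Zero-phase 6th-order Butterworth band-pass, 0.1–50 Hz by default."""
    cfg = cfg or RunConfig()
    if recording.sampling_rate <= 100:
        raise ValueError("sampling rate must exceed 100 Hz")
    sos = butter_bandpass_sos(cfg.filter_low_hz, cfg.filter_high_hz,
                              recording.sampling_rate, cfg.filter_order)
    data = signal.sosfiltfilt(sos, recording.data, axis=1)
    return SensorRecording(data, recording.sampling_rate,
                           recording.channel_names, recording.condition,
                           events=recording.events,
                           subject_id=recording.subject_id,
                           group=recording.group)


def segment(recording: SensorRecording,
            cfg: RunConfig | None = None) -> dict[str, EpochSet]:
    """Cut a recording into 700 ms epochs.

    Resting: consecutive non-overlapping windows from the start. Oddball:
    one epoch per event spanning [-100, 600) ms around onset, split into Std
    and Dev sets by event code; events too close to a recording edge are
    dropped with a log entry.
    """
    cfg = cfg or RunConfig()
    fs = recording.sampling_rate
    n_len = int(round(cfg.epoch_length_s * fs))
    out: dict[str, EpochSet] = {}
    if recording.condition == "resting":
        n = recording.data.shape[1] // n_len
        ep = recording.data[:, :n * n_len].reshape(
            recording.data.shape[0], n, n_len).transpose(1, 0, 2)
        out["RS"] = EpochSet(ep.copy(), "RS", fs, 0.0,
                             recording.channel_names,
                             {"subject": recording.subject_id,
                              "group": recording.group})
        return out
    if recording.events is None:
        raise ValueError("oddball recording requires an event table")
    pre = int(round(cfg.prestim_s * fs))
    total = recording.data.shape[1]
    by_code = {"standard": [], "deviant": []}
    dropped = 0
    for _, ev in recording.events.iterrows():
        onset = int(ev["onset_sample"])
        start = onset - pre
        if start < 0 or start + n_len > total:
            dropped += 1
            continue
        by_code[str(ev["code"])].append(
            recording.data[:, start:start + n_len])
    if dropped:
        logger.info("dropped %d events too close to the recording edge",
                    dropped)
    for code, cond in (("standard", "Std"), ("deviant", "Dev")):
        if by_code[code]:
            arr = np.stack(by_code[code])
        else:
            arr = np.empty((0, recording.data.shape[0], n_len))
        out[cond] = EpochSet(arr, cond, fs, -cfg.prestim_s,
                             recording.channel_names,
                             {"subject": recording.subject_id,
                              "group": recording.group,
                              "dropped_events": dropped})
    return out


def detrend_and_baseline(epochs: EpochSet) -> EpochSet:
    """Per epoch and channel: remove the linear trend, then (oddball only)
    subtract the mean of the pre-stimulus interval [-100, 0) ms."""
    data = signal.detrend(epochs.data, axis=2, type="linear")
    if epochs.tmin < 0:
        n_pre = int(round(-epochs.tmin * epochs.sampling_rate))
        base = data[:, :, :n_pre].mean(axis=2, keepdims=True)
        data = data - base
    return EpochSet(data, epochs.condition, epochs.sampling_rate, epochs.tmin,
                    epochs.channel_names, dict(epochs.provenance))


def reject_amplitude(epochs: EpochSet, threshold_uv: float = 75.0) -> EpochSet:
    """Drop every epoch whose absolute maximum over all channels exceeds
    the threshold (µV). Rejection is per epoch, never per channel."""
    keep = np.max(np.abs(epochs.data), axis=(1, 2)) <= threshold_uv
    if not keep.any():
        logger.warning("amplitude rejection removed every epoch (%s)",
                       epochs.condition)
    prov = dict(epochs.provenance)
    prov["rejected"] = int((~keep).sum())
    return EpochSet(epochs.data[keep], epochs.condition, epochs.sampling_rate,
                    epochs.tmin, epochs.channel_names, prov)


def subsample_epochs(epochs: EpochSet, quota: int,
                     rng: np.random.Generator) -> EpochSet:
    """Uniform random selection of `quota` epochs without replacement.

    If fewer epochs are available than the quota, all are retained with a
    warning. Selected indices are recorded in provenance, in sorted order so
    the temporal ordering of epochs is preserved.
    """
    n = epochs.n_epochs
    if n <= quota:
        if n < quota:
            warnings.warn(
                f"only {n} epochs available for quota {quota} "
                f"({epochs.condition}); retaining all", UserWarning,
                stacklevel=2)
        idx = np.arange(n)
    else:
        idx = np.sort(rng.choice(n, size=quota, replace=False))
    prov = dict(epochs.provenance)
    prov["selected_indices"] = idx.tolist()
    return EpochSet(epochs.data[idx], epochs.condition, epochs.sampling_rate,
                    epochs.tmin, epochs.channel_names, prov)


def preprocess_recording(recording: SensorRecording,
                         cfg: RunConfig,
                         rng: np.random.Generator) -> dict[str, EpochSet]:
    """The full fixed-order chain for one recording.

    Returns the condition → EpochSet map ('RS' for resting; 'Std' and 'Dev'
    for oddball), each filtered, detrended/baselined, amplitude-screened and
    subsampled to its quota.
    """
    filtered = bandpass_filter(recording, cfg)
    out = {}
    for cond, eps in segment(filtered, cfg).items():
        eps = detrend_and_baseline(eps)
        eps = reject_amplitude(eps, cfg.reject_uv)
        eps = subsample_epochs(eps, cfg.epoch_quota[cond], rng)
        out[cond] = eps
    return out
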