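"""Weighted phase-lag index between salience-network nodes.

For each 0.7 s epoch, band and ROI pair: band-pass filter (zero-phase
6th-order Butterworth at the band edges), Hilbert-transform instantaneous
phase, then

    wPLI = |E[sin Δϕ(t)]| / E[|sin Δϕ(t)|]

where Δϕ(t) is the instantaneous phase difference and E(.) the arithmetic
mean over the trimmed interior of the epoch: the first and last 0.1 s are
excluded to suppress filter/Hilbert edge transients, which for oddball
epochs simultaneously discards the pre-stimulus baseline interval. Values
range from 0 (no consistent lag) to 1 (constant-sign phase lag). A zero
denominator — every sin Δϕ exactly 0, e.g. perfectly in-phase signals —
returns 0 with a quality flag so epoch averaging stays total. The debiased
wPLI variant is deliberately not implemented. Epoch-level values are
averaged per (band, condition, edge); the salience-network global strength
is the sum of the three averaged edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import BANDS, EDGES, ROI_NAMES
from .preprocess import butter_bandpass_sos
from .source import ROISignal


def band_filter_epoch(data: np.ndarray, band: tuple[float, float],
                      fs: float, order: int = 6) -> np.ndarray:
    """Zero-phase Butterworth band-pass of per-epoch signals (last axis)."""
    sos = butter_bandpass_sos(band[0], band[1], fs, order)
    return signal.sosfiltfilt(sos, data, axis=-1)


def instantaneous_phase(data: np.ndarray) -> np.ndarray:
    """Angle of the analytic signal along the last axis, radians."""
    return np.angle(signal.hilbert(data, axis=-1))


@dataclass
class WpliResult:
    value: float
    degenerate: bool = False   # zero-denominator epoch


def wpli(phase_x: np.ndarray, phase_y: np.ndarray, fs: float,
         trim_s: float = 0.1) -> WpliResult:
    """wPLI of one epoch from two per-sample phase series.

    ``trim_s`` seconds are discarded at each end before the expectation.
    Symmetric in its arguments, invariant to a common phase offset, and
    always in [0, 1].
    """
    phase_x = np.asarray(phase_x, dtype=float)
    phase_y = np.asarray(phase_y, dtype=float)
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase series must have equal length")
    n_trim = int(round(trim_s * fs))
    n = phase_x.shape[-1]
    if 2 * n_trim >= n:
        raise ValueError("trim leaves no interior samples")
    sl = slice(n_trim, n - n_trim) if n_trim else slice(None)
    d = np.sin(phase_x[..., sl] - phase_y[..., sl])
    den = float(np.mean(np.abs(d)))
    if den == 0.0:
        return WpliResult(0.0, degenerate=True)
    return WpliResult(float(abs(np.mean(d)) / den))


def epoch_wpli(sig_x: np.ndarray, sig_y: np.ndarray, band: tuple[float, float],
               fs: float, trim_s: float = 0.1, order: int = 6) -> np.ndarray:
    """Per-epoch band wPLI of two (epochs × samples) ROI signal arrays."""
    fx = band_filter_epoch(sig_x, band, fs, order)
    fy = band_filter_epoch(sig_y, band, fs, order)
    px = instantaneous_phase(fx)
    py = instantaneous_phase(fy)
    return np.array([wpli(px[e], py[e], fs, trim_s).value
                     for e in range(px.shape[0])])


@dataclass
class SalienceNetwork:
    """Epoch-averaged wPLI of the three salience-network edges.

    ``edges`` maps (roi_a, roi_b) → mean wPLI in [0, 1]; ``strength`` is
    exactly their sum.
    """

    subject: str
    group: str
    band: str
    condition: str
    edges: dict[tuple[str, str], float]
    n_epochs: int
    strength: float = field(init=False)

    def __post_init__(self) -> None:
        for e, v in self.edges.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"edge {e} wPLI {v} outside [0, 1]")
        if set(self.edges) != set(EDGES):
            raise ValueError("exactly the three salience-network edges "
                             "are required")
        self.strength = float(sum(self.edges.values()))


def assemble_network(epoch_values: dict[tuple[str, str], np.ndarray],
                     subject: str, group: str, band: str,
                     condition: str) -> SalienceNetwork:
    """Average per-epoch wPLI values over epochs, one edge at a time."""
    edges = {}
    n_ep = None
    for edge in EDGES:
        if edge not in epoch_values:
            raise KeyError(f"missing edge {edge}")
        vals = np.asarray(epoch_values[edge], dtype=float)
        if vals.size == 0:
            raise ValueError(f"no epochs for edge {edge}")
        if n_ep is None:
            n_ep = vals.size
        edges[edge] = float(np.mean(vals))
    return SalienceNetwork(subject, group, band, condition, edges, int(n_ep))


def subject_networks(roi_signals: dict[str, ROISignal], subject: str,
                     group: str, condition: str,
                     bands: dict[str, tuple[float, float]] | None = None,
                     trim_s: float = 0.1,
                     order: int = 6) -> list[SalienceNetwork]:
    """All band networks of one subject-condition from its ROI signals."""
    bands = dict(BANDS) if bands is None else bands
    fs = roi_signals[ROI_NAMES[0]].sampling_rate
    out = []
    for band_name, edges_hz in bands.items():
        epoch_values = {}
        for a, b in EDGES:
            epoch_values[(a, b)] = epoch_wpli(
                roi_signals[a].data, roi_signals[b].data, edges_hz, fs,
                trim_s, order)
        out.append(assemble_network(epoch_values, subject, group, band_name,
                                    condition))
    return out


def networks_to_frame(networks: list[SalienceNetwork]):
    """Tidy per-subject table: one row per (subject, band, condition)."""
    import pandas as pd

    rows = []
    for n in networks:
        row = {"subject": n.subject, "group": n.group, "band": n.band,
               "condition": n.condition, "strength": n.strength,
               "n_epochs": n.n_epochs}
        for (a, b), v in n.edges.items():
            row[f"wpli_{a}_{b}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
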