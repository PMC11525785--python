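"""Classification feature table: condition-dependent connectivity plus
conventional band-power and mismatch-negativity measures.

Per subject the table holds, in fixed column order:

* ``FCdev_<a>_<b>`` — deviant-condition wPLI of each salience-network edge;
* ``FCdiff_<a>_<b>`` — deviant minus standard wPLI (the connectivity
  analogue of a mismatch difference wave), in [-1, 1];
* ``BP<band>_<region>`` — resting-state absolute band power (µV²) for each
  analysis band over six sensor regions (bilateral frontal, central,
  parieto-occipital). All four bands are computed as candidates; feature
  selection downstream prunes;
* ``MMN`` — mean of the frontocentral deviant-minus-standard difference wave
  over 130–280 ms after 0.1–30 Hz filtering, µV.

Band power is a sensor-level measure (Welch periodogram of each whole 700 ms
epoch under a Hann window, integrated over the band, averaged over region
electrodes and epochs) and is stored raw in µV²; z-normalization during
classification absorbs scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .config import BANDS, EDGES, RunConfig
from .connectivity import SalienceNetwork
from .preprocess import EpochSet, butter_bandpass_sos

BAND_SHORT = {"alpha": "a", "low_beta": "b1", "high_beta": "b2", "gamma": "g"}


def feature_columns(cfg: RunConfig | None = None) -> list[str]:
    """The fixed feature column order of the assembled table."""
    cfg = cfg or RunConfig()
    cols = [f"FCdev_{a}_{b}" for a, b in EDGES]
    cols += [f"FCdiff_{a}_{b}" for a, b in EDGES]
    for band in cfg.bands:
        for region in cfg.regions:
            cols.append(f"BP{BAND_SHORT.get(band, band)}_{region}")
    cols.append("MMN")
    return cols


def fc_features(net_std: SalienceNetwork,
                net_dev: SalienceNetwork) -> dict[str, float]:
    """FCdev copied from the deviant condition; FCdiff = Dev − Std per edge."""
    if net_std.condition != "Std" or net_dev.condition != "Dev":
        raise ValueError("expected one Std and one Dev network")
    out: dict[str, float] = {}
    for a, b in EDGES:
        out[f"FCdev_{a}_{b}"] = net_dev.edges[(a, b)]
        out[f"FCdiff_{a}_{b}"] = net_dev.edges[(a, b)] - net_std.edges[(a, b)]
    return out


def band_power(epochs: EpochSet, band: tuple[float, float],
               electrodes: tuple[str, ...]) -> float:
    """Absolute band power, µV²: Welch PSD per epoch and channel (whole-epoch
    Hann segment), integrated over [low, high] Hz, averaged over the region's
    electrodes and over epochs."""
    idx = [epochs.channel_names.index(c) for c in electrodes
           if c in epochs.channel_names]
    if not idx:
        raise ValueError("region has no electrodes present in the data")
    x = epochs.data[:, idx, :]
    n = x.shape[2]
    freqs, psd = signal.welch(x, fs=epochs.sampling_rate, window="hann",
                              nperseg=n, noverlap=0, axis=2)
    df = freqs[1] - freqs[0]
    sel = (freqs >= band[0]) & (freqs <= band[1])
    power = psd[:, :, sel].sum(axis=2) * df
    return float(power.mean())


def erp_curve(epochs: EpochSet, electrodes: tuple[str, ...],
              band_hz: tuple[float, float] = (0.1, 30.0),
              order: int = 6) -> np.ndarray:
    """Channel-averaged evoked curve: average epochs, average the
    frontocentral electrodes, band-pass 0.1–30 Hz zero-phase, re-baseline."""
    if epochs.n_epochs == 0:
        raise ValueError("cannot average an empty epoch set")
    idx = [epochs.channel_names.index(c) for c in electrodes
           if c in epochs.channel_names]
    if not idx:
        raise ValueError("no frontocentral electrodes present")
    curve = epochs.data[:, idx, :].mean(axis=(0, 1))
    sos = butter_bandpass_sos(band_hz[0], band_hz[1], epochs.sampling_rate,
                              order)
    curve = signal.sosfiltfilt(sos, curve)
    if epochs.tmin < 0:
        n_pre = int(round(-epochs.tmin * epochs.sampling_rate))
        curve = curve - curve[:n_pre].mean()
    return curve


def mmn_amplitude(std_epochs: EpochSet, dev_epochs: EpochSet,
                  electrodes: tuple[str, ...],
                  window_ms: tuple[float, float] = (130.0, 280.0),
                  band_hz: tuple[float, float] = (0.1, 30.0)) -> float:
    """Mean of the deviant-minus-standard difference wave over the MMN
    window (inclusive endpoints), µV."""
    diff = (erp_curve(dev_epochs, electrodes, band_hz)
            - erp_curve(std_epochs, electrodes, band_hz))
    times_ms = std_epochs.times * 1000.0
    sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("MMN window outside the epoch time axis")
    return float(diff[sel].mean())


@dataclass
class SubjectInputs:
    """Everything feature assembly needs for one subject."""

    subject: str
    group: str
    networks: dict[str, SalienceNetwork]   # keyed f"{band}:{condition}"
    rs_epochs: EpochSet
    std_epochs: EpochSet
    dev_epochs: EpochSet


def assemble_features(subjects: list[SubjectInputs],
                      cfg: RunConfig | None = None,
                      fc_band: str = "high_beta") -> pd.DataFrame:
    """Build the subjects × features table with group labels.

    Connectivity features are taken from ``fc_band`` (the band the
    group-by-condition analysis targets). Raises if any value is missing:
    the table must be complete before classification.
    """
    cfg = cfg or RunConfig()
    cols = feature_columns(cfg)
    rows = []
    for s in subjects:
        net_std = s.networks[f"{fc_band}:Std"]
        net_dev = s.networks[f"{fc_band}:Dev"]
        row: dict[str, float] = dict(fc_features(net_std, net_dev))
        for band_name, edges_hz in cfg.bands.items():
            for region, elecs in cfg.regions.items():
                key = f"BP{BAND_SHORT.get(band_name, band_name)}_{region}"
                row[key] = band_power(s.rs_epochs, edges_hz, elecs)
        row["MMN"] = mmn_amplitude(s.std_epochs, s.dev_epochs,
                                   cfg.frontocentral, cfg.mmn_window_ms,
                                   cfg.mmn_band_hz)
        row["group"] = s.group
        rows.append(pd.Series(row, name=s.subject))
    table = pd.DataFrame(rows)[cols + ["group"]]
    if table[cols].isna().any().any():
        raise ValueError("feature table contains missing values")
    return table
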