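"""Synthetic cohort EEG with known ground-truth phase coupling.

The generator emulates the study design that the analysis pipeline targets:
1000 Hz sampling on 62 extended 10-20 channels, eyes-closed resting blocks,
and a passive duration-deviant oddball stream (750 trials, 10% deviants,
600 ms inter-stimulus interval) with a deviant-evoked frontocentral
deflection. Three salience-network sources (dACC, left and right insula)
oscillate in each analysis band; the phase difference between the dACC hub
and each insula is a planted mean lag plus von Mises jitter whose
concentration κ depends on (group, condition, band). κ is the ground-truth
coupling dial: the expected weighted phase-lag index is strictly increasing
in κ at a fixed nonzero mean lag, and the von Mises law gives a Monte-Carlo
oracle for its value.

Coupling model
--------------
The dACC is the hub. For each band, the hub phase advances at the band's
center frequency; insula phases equal the hub phase plus ``dphi0 + j(t)``
where ``j(t)`` is piecewise-constant von Mises(0, κ) jitter over 25 ms
blocks (the coherence time of the jitter process). The lIns-rIns phase
difference is therefore implied by the two hub edges rather than
independently specifiable: with default lags +π/4 (dACC-lIns) and -π/4
(dACC-rIns) it has mean π/2 and a concentration that grows with both κs.
A mean lag of 0 with finite κ > 0 is a degenerate case for the wPLI
(sin Δϕ is then symmetric about 0, so the index is near 0 despite strong
locking); the generator warns rather than forbids it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BANDS, CHANNELS_62, EDGES, ROI_NAMES, ROI_SEEDS_MM

GROUPS = ("nrMDD", "rMDD", "HC")

#: Coherence time of the phase-jitter process, seconds.
JITTER_BLOCK_S = 0.025

#: Default mean phase lags (radians) of the two hub edges.
DEFAULT_LAGS = {("dACC", "lIns"): np.pi / 4, ("dACC", "rIns"): -np.pi / 4}

#: Band center frequencies used for the carrier oscillations, Hz.
BAND_CENTERS = {"alpha": 10.0, "low_beta": 15.0, "high_beta": 24.0,
                "gamma": 40.0}


@dataclass
class ERPSpec:
    """Deviant-evoked deflection added at sensor level.

    ``amplitude_uv`` is the peak of a Hann-shaped deflection spanning
    ``window_ms`` after deviant onset on the ``channels`` electrodes.
    Negative by default: a mismatch-negativity-like component.
    """

    amplitude_uv: float = -3.0
    window_ms: tuple[float, float] = (130.0, 280.0)
    channels: tuple[str, ...] = ("F3", "Fz", "F4", "FC3", "FCz", "FC4",
                                 "C3", "Cz", "C4")
    amplitude_jitter_sd: float = 0.0  # off by default: deterministic ERP


@dataclass
class SimulationConfig:
    n_subjects_per_group: dict[str, int] = field(
        default_factory=lambda: {"nrMDD": 14, "rMDD": 17, "HC": 21})
    sampling_rate: float = 1000.0
    n_channels: int = 62
    resting_duration: float = 300.0      # seconds
    n_oddball_trials: int = 750
    deviant_probability: float = 0.10
    isi_ms: float = 600.0                # onset-to-onset
    std_duration_ms: float = 50.0
    dev_duration_ms: float = 100.0
    coupling_spec: dict = field(default_factory=lambda: default_coupling_spec())
    erp_spec: ERPSpec = field(default_factory=ERPSpec)
    source_amplitude: float = 5.0        # per band, arbitrary source units
    noise_sd: float = 2.0                # µV additive sensor noise
    subject_kappa_log_sd: float = 0.2    # between-subject random effect on κ
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.deviant_probability < 1:
            raise ValueError("deviant probability must lie in (0, 1)")
        for name in ("sampling_rate", "resting_duration", "isi_ms",
                     "std_duration_ms", "dev_duration_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_oddball_trials < 1:
            raise ValueError("need at least one oddball trial")
        if self.noise_sd < 0 or self.subject_kappa_log_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        for key, (kappa, dphi0) in self.coupling_spec.items():
            if kappa < 0:
                raise ValueError(f"coupling κ must be >= 0 at {key}")
            if kappa > 0 and np.isclose(_wrap(dphi0), 0.0):
                warnings.warn(
                    f"mean lag 0 with κ > 0 at {key}: wPLI is near 0 for "
                    "zero-lag locking (sin Δϕ symmetric about 0)",
                    UserWarning, stacklevel=2)


def default_coupling_spec(
    high_beta_kappa: dict[str, dict[str, float]] | None = None,
    other_kappa: float = 1.0,
) -> dict:
    """Study-condition coupling: a group-by-condition reversal in high beta.

    Healthy controls ramp coupling up from rest through standard to deviant
    stimulation; non-remitted patients show the opposite, inefficient
    reconfiguration (hyperconnected at rest, hypoconnected under deviants);
    remitted patients track the controls. Other bands are condition- and
    group-invariant. Keys: (group, condition, band, edge) → (κ, mean lag).
    """
    if high_beta_kappa is None:
        high_beta_kappa = {
            "HC":    {"RS": 0.5, "Std": 1.0, "Dev": 2.0},
            "rMDD":  {"RS": 0.6, "Std": 1.0, "Dev": 1.8},
            "nrMDD": {"RS": 2.0, "Std": 1.0, "Dev": 0.5},
        }
    spec: dict = {}
    for group in GROUPS:
        for cond in ("RS", "Std", "Dev"):
            for band in BANDS:
                for edge, lag in DEFAULT_LAGS.items():
                    if band == "high_beta":
                        kappa = high_beta_kappa[group][cond]
                    else:
                        kappa = other_kappa
                    spec[(group, cond, band, edge)] = (kappa, lag)
    return spec


def null_coupling_spec(kappa: float = 1.0) -> dict:
    """Coupling with no group or condition dependence (null hypothesis)."""
    spec: dict = {}
    for group in GROUPS:
        for cond in ("RS", "Std", "Dev"):
            for band in BANDS:
                for edge, lag in DEFAULT_LAGS.items():
                    spec[(group, cond, band, edge)] = (kappa, lag)
    return spec


@dataclass
class LeadField:
    """Forward operator: sensor gain per unit source amplitude.

    ``gain`` is channels × voxels with arbitrary overall scale (µV per unit
    source); ``voxel_coords`` is mm in the same head frame as the ROI seeds.
    """

    gain: np.ndarray
    voxel_coords: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field has non-finite entries")
        if self.voxel_coords.shape != (self.gain.shape[1], 3):
            raise ValueError("one coordinate row per gain column required")
        if len(self.channel_names) != self.gain.shape[0]:
            raise ValueError("channel names do not match gain rows")

    def nearest_voxel(self, coord_mm) -> int:
        d = np.linalg.norm(self.voxel_coords - np.asarray(coord_mm), axis=1)
        return int(np.argmin(d))


@dataclass
class SensorRecording:
    data: np.ndarray                 # channels × samples, µV
    sampling_rate: float
    channel_names: tuple[str, ...]
    condition: str                   # 'resting' | 'oddball'
    events: pd.DataFrame | None = None
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.condition == "oddball" and self.events is not None:
            on = self.events["onset_sample"].to_numpy()
            if np.any(on < 0) or np.any(on >= self.data.shape[1]):
                raise ValueError("events reference samples outside recording")


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    coupling: dict                   # (condition, band, edge) → (κ, lag)
    events: pd.DataFrame | None = None
    source_phases: dict | None = None  # (band, roi) → phase series, radians


def _wrap(phi):
    return np.angle(np.exp(1j * np.asarray(phi, dtype=float)))


# ---------------------------------------------------------------------------
# events


def generate_events(cfg: SimulationConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fixed-ISI oddball event table with Bernoulli deviants.

    Onsets are strictly increasing at the configured ISI; the first onset is
    placed one pre-stimulus interval (100 ms at 1 kHz) plus one ISI into the
    recording so every epoch fits.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    fs = cfg.sampling_rate
    isi = int(round(cfg.isi_ms / 1000.0 * fs))
    start = int(round(0.1 * fs)) + isi
    onsets = start + isi * np.arange(cfg.n_oddball_trials)
    deviant = rng.random(cfg.n_oddball_trials) < cfg.deviant_probability
    codes = np.where(deviant, "deviant", "standard")
    return pd.DataFrame({"onset_sample": onsets, "code": codes})


# ---------------------------------------------------------------------------
# coupled sources


def _sample_jitter(n_samples: int, kappa: float, fs: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant von Mises(0, κ) phase jitter, one value per block."""
    block = max(1, int(round(JITTER_BLOCK_S * fs)))
    n_blocks = int(np.ceil(n_samples / block))
    if np.isinf(kappa):
        vals = np.zeros(n_blocks)
    elif kappa == 0:
        vals = rng.uniform(-np.pi, np.pi, n_blocks)
    else:
        vals = rng.vonmises(0.0, kappa, n_blocks)
    return np.repeat(vals, block)[:n_samples]


def simulate_coupled_sources(
    cfg: SimulationConfig,
    group: str,
    condition: str,
    duration_s: float,
    rng: np.random.Generator,
    subject_kappa_factor: dict | None = None,
    bands: tuple[str, ...] | None = None,
) -> tuple[dict, GroundTruth]:
    """True ROI time courses with planted band-limited phase coupling.

    Returns ``(sources, truth)`` where ``sources`` maps each band to a
    (3 ROIs × samples) array (rows ordered as :data:`ROI_NAMES`) and
    ``truth`` records the realized κ and lag per (condition, band, edge)
    and the per-band ROI phase series.
    """
    bands = tuple(BANDS) if bands is None else bands
    fs = cfg.sampling_rate
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    sources: dict[str, np.ndarray] = {}
    phases: dict = {}
    realized: dict = {}
    for band in bands:
        fc = BAND_CENTERS[band]
        hub_phase = 2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi)
        band_phases = {"dACC": hub_phase}
        for edge in DEFAULT_LAGS:
            key = (group, condition, band, edge)
            if key not in cfg.coupling_spec:
                raise KeyError(f"coupling_spec missing entry for {key}")
            kappa, lag = cfg.coupling_spec[key]
            if subject_kappa_factor is not None:
                kappa = kappa * subject_kappa_factor.get((band, edge), 1.0)
            jit = _sample_jitter(n, kappa, fs, rng)
            band_phases[edge[1]] = hub_phase + lag + jit
            realized[(condition, band, edge)] = (kappa, lag)
        arr = np.vstack([cfg.source_amplitude * np.cos(band_phases[r])
                         for r in ROI_NAMES])
        sources[band] = arr
        for r in ROI_NAMES:
            phases[(band, r)] = band_phases[r]
    truth = GroundTruth(coupling=realized, source_phases=phases)
    return sources, truth


def expected_wpli_vonmises(kappa: float, dphi0: float,
                           n_mc: int = 1_000_000, seed: int = 12345) -> float:
    """Monte-Carlo oracle: E-value of |E sin Δϕ| / E|sin Δϕ| under the
    von Mises(dphi0, κ) law the generator plants."""
    rng = np.random.default_rng(seed)
    if np.isinf(kappa):
        d = np.full(n_mc, dphi0)
    elif kappa == 0:
        d = rng.uniform(-np.pi, np.pi, n_mc) + dphi0
    else:
        d = rng.vonmises(dphi0, kappa, n_mc)
    s = np.sin(d)
    den = np.mean(np.abs(s))
    return 0.0 if den == 0 else abs(np.mean(s)) / den


# ---------------------------------------------------------------------------
# lead field


def _electrode_positions_mm(channel_names) -> np.ndarray:
    """Electrode positions from the standard 10-05 montage, mm."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            montage = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # renamed in newer mne
            montage = mne.channels.make_standard_montage("colin27_1005")
    pos = montage.get_positions()["ch_pos"]
    return np.array([pos[c] for c in channel_names]) * 1000.0


def spherical_gain(elec_mm: np.ndarray, voxels_mm: np.ndarray,
                   radius_mm: float) -> np.ndarray:
    """Analytic single-shell gain: radial dipole in a homogeneous sphere.

    The surface potential of a radially oriented unit dipole at fractional
    eccentricity f = b/R, with x = cos of the source-electrode angle, is
    proportional to the closed form of the Legendre series
    Σ (2n+1) f^(n-1) P_n(x):

        g(f, x) = 2 (x - f) / d³ + (1/d - 1) / f,   d = sqrt(1 - 2 f x + f²)

    with the f → 0 limit 3x. Overall scale is arbitrary (absorbed in the
    source units); electrodes are projected onto the sphere.
    """
    e = elec_mm / np.linalg.norm(elec_mm, axis=1, keepdims=True)  # on sphere
    b = np.linalg.norm(voxels_mm, axis=1)
    if np.any(b >= radius_mm):
        raise ValueError("source voxels must lie strictly inside the sphere")
    f = b / radius_mm
    with np.errstate(divide="ignore", invalid="ignore"):
        v_hat = np.where(b[:, None] > 0, voxels_mm / b[:, None], 0.0)
    x = e @ v_hat.T                                  # channels × voxels
    fg = f[None, :]
    d = np.sqrt(1.0 - 2.0 * fg * x + fg ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 2.0 * (x - fg) / d ** 3 + (1.0 / d - 1.0) / fg
    g = np.where(fg > 1e-9, g, 3.0 * x)              # central-source limit
    return g


def make_leadfield(
    channel_names: tuple[str, ...] = CHANNELS_62,
    grid_spacing_mm: float = 15.0,
    head_radius_mm: float = 85.0,
    source_max_radius_mm: float = 75.0,
    roi_seeds: dict | None = None,
    mode: str = "spherical",
    n_voxels_random: int = 200,
    seed: int = 0,
) -> LeadField:
    """Single-shell spherical-head lead field on a coarse grid.

    The grid always contains the three ROI seed coordinates as exact voxels
    so planted sources sit on grid points. ``mode='random'`` returns a seeded
    Gaussian matrix instead; it exists only for unit tests of downstream
    linear algebra and has no head geometry.
    """
    roi_seeds = dict(ROI_SEEDS_MM) if roi_seeds is None else roi_seeds
    if mode == "random":
        rng = np.random.default_rng(seed)
        gain = rng.standard_normal((len(channel_names), n_voxels_random))
        coords = rng.uniform(-60, 60, (n_voxels_random, 3))
        return LeadField(gain, coords, tuple(channel_names))
    if mode != "spherical":
        raise ValueError("mode must be 'spherical' or 'random'")
    ax = np.arange(-source_max_radius_mm, source_max_radius_mm + 1e-9,
                   grid_spacing_mm)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    r = np.linalg.norm(grid, axis=1)
    # radial orientation is undefined at the sphere center; keep a small
    # central exclusion zone
    grid = grid[(r <= source_max_radius_mm) & (r >= 10.0)]
    seeds = np.array([roi_seeds[r] for r in ROI_NAMES], dtype=float)
    coords = np.vstack([grid, seeds])
    elec = _electrode_positions_mm(channel_names)
    # scale electrode shell to the model sphere
    elec = elec / np.linalg.norm(elec, axis=1, keepdims=True) * head_radius_mm
    gain = spherical_gain(elec, coords, head_radius_mm)
    # arbitrary overall scale: strongest source projects with unit total
    # gain, so source amplitudes are roughly sensor µV
    gain = gain / np.linalg.norm(gain, axis=0).max()
    return LeadField(gain, coords, tuple(channel_names))


def roi_voxel_indices(leadfield: LeadField,
                      roi_seeds: dict | None = None) -> dict[str, int]:
    """Index of the exact seed voxel of each ROI in the lead-field grid."""
    roi_seeds = dict(ROI_SEEDS_MM) if roi_seeds is None else roi_seeds
    return {r: leadfield.nearest_voxel(roi_seeds[r]) for r in ROI_NAMES}


# ---------------------------------------------------------------------------
# sensor projection


def _erp_waveform(n_samples: int, fs: float, erp: ERPSpec) -> np.ndarray:
    """Hann-shaped deflection, peak ``amplitude_uv``, over the ERP window."""
    w = np.zeros(n_samples)
    i0 = int(round(erp.window_ms[0] / 1000.0 * fs))
    i1 = int(round(erp.window_ms[1] / 1000.0 * fs))
    i0, i1 = max(i0, 0), min(i1, n_samples)
    if i1 > i0:
        w[i0:i1] = erp.amplitude_uv * np.hanning(i1 - i0)
    return w


def project_to_sensors(
    sources: dict,
    leadfield: LeadField,
    roi_index: dict[str, int],
    noise_sd: float,
    rng: np.random.Generator,
    erp_spec: ERPSpec | None = None,
    events: pd.DataFrame | None = None,
    fs: float = 1000.0,
) -> np.ndarray:
    """Linear forward projection: gain × sources (+ ERP on deviants) + noise.

    ``sources`` maps band → (3 ROIs × samples); all bands are summed at each
    ROI before projection. Returns channels × samples, µV.
    """
    bands = list(sources)
    n = sources[bands[0]].shape[1]
    roi_sum = np.zeros((len(ROI_NAMES), n))
    for band in bands:
        if sources[band].shape != (len(ROI_NAMES), n):
            raise ValueError("inconsistent source dimensions across bands")
        roi_sum += sources[band]
    cols = np.array([roi_index[r] for r in ROI_NAMES])
    data = leadfield.gain[:, cols] @ roi_sum
    if erp_spec is not None and events is not None:
        dev = events.loc[events["code"] == "deviant", "onset_sample"]
        wave = _erp_waveform(n, fs, erp_spec)
        nz = np.nonzero(wave)[0]
        chan_idx = [leadfield.channel_names.index(c)
                    for c in erp_spec.channels if c in leadfield.channel_names]
        for onset in dev.to_numpy():
            amp = 1.0
            if erp_spec.amplitude_jitter_sd > 0:
                amp = 1.0 + erp_spec.amplitude_jitter_sd * rng.standard_normal()
            sel = nz[onset + nz < n]
            for ci in chan_idx:
                data[ci, onset + sel] += amp * wave[sel]
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return data


# ---------------------------------------------------------------------------
# cohort generation


def _subject_kappa_factors(cfg: SimulationConfig,
                           rng: np.random.Generator) -> dict:
    """Multiplicative lognormal between-subject random effect on κ."""
    sd = cfg.subject_kappa_log_sd
    return {(band, edge): float(np.exp(sd * rng.standard_normal()))
            for band in BANDS for edge in DEFAULT_LAGS}


def simulate_subject(
    cfg: SimulationConfig,
    subject_id: str,
    group: str,
    leadfield: LeadField,
    rng: np.random.Generator,
    bands: tuple[str, ...] | None = None,
) -> tuple[dict[str, SensorRecording], GroundTruth]:
    """One subject's resting and oddball recordings plus ground truth."""
    fs = cfg.sampling_rate
    roi_idx = roi_voxel_indices(leadfield)
    factors = _subject_kappa_factors(cfg, rng)
    coupling: dict = {}

    # resting
    src_rs, truth_rs = simulate_coupled_sources(
        cfg, group, "RS", cfg.resting_duration, rng,
        subject_kappa_factor=factors, bands=bands)
    rs_data = project_to_sensors(src_rs, leadfield, roi_idx, cfg.noise_sd,
                                 rng, fs=fs)
    coupling.update(truth_rs.coupling)
    rest = SensorRecording(rs_data, fs, leadfield.channel_names, "resting",
                           subject_id=subject_id, group=group)

    # oddball: one continuous stream; Std/Dev share carrier sources whose
    # coupling switches with the trial type at each onset
    events = generate_events(cfg, rng)
    isi = int(round(cfg.isi_ms / 1000.0 * fs))
    total = int(events["onset_sample"].iloc[-1]) + isi + int(0.2 * fs)
    dur = total / fs
    src_std, t_std = simulate_coupled_sources(
        cfg, group, "Std", dur, rng, subject_kappa_factor=factors, bands=bands)
    src_dev, t_dev = simulate_coupled_sources(
        cfg, group, "Dev", dur, rng, subject_kappa_factor=factors, bands=bands)
    dev_mask = np.zeros(total, dtype=bool)
    for _, ev in events.iterrows():
        if ev["code"] == "deviant":
            o = int(ev["onset_sample"])
            dev_mask[max(o - int(0.1 * fs), 0):o + isi] = True
    src_odd = {b: np.where(dev_mask[None, :], src_dev[b][:, :total],
                           src_std[b][:, :total]) for b in src_std}
    odd_data = project_to_sensors(src_odd, leadfield, roi_idx, cfg.noise_sd,
                                  rng, erp_spec=cfg.erp_spec, events=events,
                                  fs=fs)
    coupling.update(t_std.coupling)
    coupling.update(t_dev.coupling)
    oddball = SensorRecording(odd_data, fs, leadfield.channel_names,
                              "oddball", events=events,
                              subject_id=subject_id, group=group)
    truth = GroundTruth(coupling=coupling, events=events)
    return {"resting": rest, "oddball": oddball}, truth


def simulate_cohort(
    cfg: SimulationConfig,
    leadfield: LeadField | None = None,
    bands: tuple[str, ...] | None = None,
):
    """Generate every subject of the configured cohort (iterator).

    Yields ``(subject_id, group, recordings, truth)``. All randomness stems
    from ``cfg.seed``; two runs with the same config are identical.
    """
    if leadfield is None:
        leadfield = make_leadfield()
    rng = np.random.default_rng(cfg.seed)
    for group in GROUPS:
        n = cfg.n_subjects_per_group.get(group, 0)
        for i in range(n):
            sid = f"{group}_{i:02d}"
            recs, truth = simulate_subject(cfg, sid, group, leadfield, rng,
                                           bands=bands)
            yield sid, group, recs, truth


# ---------------------------------------------------------------------------
# coupling-level cohort shortcut (for statistical calibration at scale)


def simulate_network_cohort(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    bands: tuple[str, ...] = ("high_beta",),
    n_epochs: dict[str, int] | None = None,
    blocks_per_epoch: int = 20,
) -> pd.DataFrame:
    """Per-subject epoch-averaged wPLI drawn directly from the coupling model.

    Skips sensor projection and source localization: for each subject,
    condition, band and epoch it draws the planted block-wise von Mises
    phase differences and evaluates |mean sin Δϕ| / mean |sin Δϕ| exactly as
    the connectivity stage would on noiseless sources. 20 blocks per epoch
    correspond to the 0.5 s trimmed interior of a 0.7 s epoch at the 25 ms
    jitter coherence time. Used by the statistical power/calibration
    simulations where hundreds of full sensor-level cohorts would be
    pointlessly expensive; the sensor path is exercised by the end-to-end
    pipeline tests.
    """
    if n_epochs is None:
        n_epochs = {"RS": 250, "Std": 300, "Dev": 45}
    rows = []
    for group in GROUPS:
        for i in range(cfg.n_subjects_per_group.get(group, 0)):
            sid = f"{group}_{i:02d}"
            factors = _subject_kappa_factors(cfg, rng)
            for band in bands:
                for cond in ("RS", "Std", "Dev"):
                    ne = n_epochs[cond]
                    jit = {}
                    for edge in DEFAULT_LAGS:
                        kappa, lag = cfg.coupling_spec[(group, cond, band,
                                                        edge)]
                        kappa *= factors[(band, edge)]
                        if np.isinf(kappa):
                            j = np.zeros((ne, blocks_per_epoch))
                        elif kappa == 0:
                            j = rng.uniform(-np.pi, np.pi,
                                            (ne, blocks_per_epoch))
                        else:
                            j = rng.vonmises(0.0, kappa,
                                             (ne, blocks_per_epoch))
                        jit[edge] = (j, lag)
                    dphi = {
                        ("dACC", "lIns"): jit[("dACC", "lIns")][0]
                        + jit[("dACC", "lIns")][1],
                        ("dACC", "rIns"): jit[("dACC", "rIns")][0]
                        + jit[("dACC", "rIns")][1],
                        ("lIns", "rIns"):
                            (jit[("dACC", "lIns")][0]
                             + jit[("dACC", "lIns")][1])
                            - (jit[("dACC", "rIns")][0]
                               + jit[("dACC", "rIns")][1]),
                    }
                    edge_wpli = {}
                    for edge, d in dphi.items():
                        s = np.sin(d)
                        den = np.mean(np.abs(s), axis=1)
                        num = np.abs(np.mean(s, axis=1))
                        w = np.where(den > 0, num / np.where(den > 0, den, 1),
                                     0.0)
                        edge_wpli[edge] = float(np.mean(w))
                    strength = float(sum(edge_wpli.values()))
                    row = {"subject": sid, "group": group, "band": band,
                           "condition": cond, "strength": strength,
                           "n_epochs": ne}
                    for edge, w in edge_wpli.items():
                        row[f"wpli_{edge[0]}_{edge[1]}"] = w
                    rows.append(row)
    return pd.DataFrame(rows)
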