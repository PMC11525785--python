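"""Run configuration, analysis-band and region defaults, and the reproducibility manifest.

All sensor-level amplitudes are in microvolts (µV); the readers in
:mod:`salnet.io` convert on ingest. One config object governs a whole run and
serializes losslessly to YAML, so a manifest (config hash + seeds) pins down
every random draw of the pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Analysis bands, Hz. Theta is deliberately absent: the 600 ms
#: inter-stimulus interval leaves too few cycles of a 4 Hz oscillation
#: inside a 0.7 s epoch for a meaningful phase estimate.
BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 12.0),
    "low_beta": (12.0, 18.0),
    "high_beta": (18.0, 30.0),
    "gamma": (30.0, 50.0),
}

#: The three salience-network nodes and their pairwise edges.
ROI_NAMES = ("dACC", "lIns", "rIns")
EDGES = (("dACC", "lIns"), ("dACC", "rIns"), ("lIns", "rIns"))

#: Default ROI seed coordinates, mm, in the MNI-like frame of the lead field.
#: These are literature-standard salience-network seeds, editable in the run
#: config; they are a package default, not a measured quantity.
ROI_SEEDS_MM: dict[str, tuple[float, float, float]] = {
    "dACC": (0.0, 22.0, 35.0),
    "lIns": (-38.0, 14.0, -6.0),
    "rIns": (38.0, 14.0, -6.0),
}

#: 62 analysis channels of the extended 10-20 system (mastoids excluded).
CHANNELS_62 = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

#: Six cortical sensor regions for resting-state band power: bilateral
#: frontal, central and parieto-occipital. Midline (z) electrodes are not
#: assigned to a hemispheric region. Package defaults, editable in config.
REGIONS: dict[str, tuple[str, ...]] = {
    "LF": ("Fp1", "AF7", "AF3", "F7", "F5", "F3", "F1"),
    "RF": ("Fp2", "AF8", "AF4", "F8", "F6", "F4", "F2"),
    "LC": ("FT7", "FC5", "FC3", "FC1", "T7", "C5", "C3", "C1",
           "TP7", "CP5", "CP3", "CP1"),
    "RC": ("FT8", "FC6", "FC4", "FC2", "T8", "C6", "C4", "C2",
           "TP8", "CP6", "CP4", "CP2"),
    "LPO": ("P7", "P5", "P3", "P1", "PO7", "PO5", "PO3", "O1"),
    "RPO": ("P8", "P6", "P4", "P2", "PO8", "PO6", "PO4", "O2"),
}

#: Frontocentral electrodes used for the mismatch-negativity difference wave.
FRONTOCENTRAL = ("F3", "Fz", "F4", "FC3", "FCz", "FC4", "C3", "Cz", "C4")

CONDITIONS = ("RS", "Std", "Dev")


@dataclass
class RunConfig:
    """All tunable parameters of one analysis run.

    Numeric fields are validated against documented ranges on construction;
    ``to_yaml``/``from_yaml`` round-trip losslessly.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: v for k, v in BANDS.items()})
    # preprocessing
    filter_low_hz: float = 0.1
    filter_high_hz: float = 50.0
    filter_order: int = 6          # design order; applied zero-phase
    epoch_length_s: float = 0.7
    prestim_s: float = 0.1         # oddball pre-stimulus interval
    reject_uv: float = 75.0        # absolute max-amplitude criterion
    epoch_quota: dict[str, int] = field(
        default_factory=lambda: {"RS": 250, "Std": 300, "Dev": 45})
    # source localization
    roi_seeds_mm: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(ROI_SEEDS_MM))
    roi_radius_mm: float = 5.0
    depth_gamma: float = 0.5
    inverse_snr: float = 3.0       # sets lambda = trace(GWG')/(n_ch * SNR^2)
    # connectivity
    wpli_trim_s: float = 0.1       # edge trim at each end of the epoch
    # features
    mmn_window_ms: tuple[float, float] = (130.0, 280.0)
    mmn_band_hz: tuple[float, float] = (0.1, 30.0)
    regions: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(REGIONS))
    frontocentral: tuple[str, ...] = FRONTOCENTRAL
    # statistics
    n_bootstrap: int = 5000
    edge_gate_p: float = 0.10      # strength interaction p gating edge tests
    # classification
    k_range: tuple[int, int] = (1, 15)
    fisher_variant: str = "two_class"  # or "generalized"
    svm_c: float = 1.0
    knn_k: int = 5
    # seeds
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.filter_low_hz < self.filter_high_hz:
            raise ValueError("filter band edges must satisfy 0 < low < high")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.epoch_length_s <= 0 or self.prestim_s < 0:
            raise ValueError("epoch lengths must be positive")
        if self.reject_uv <= 0:
            raise ValueError("rejection threshold must be positive (µV)")
        if self.roi_radius_mm < 0:
            raise ValueError("ROI radius must be >= 0 mm")
        if not 0 <= self.depth_gamma <= 1:
            raise ValueError("depth-weight exponent must lie in [0, 1]")
        if self.inverse_snr <= 0:
            raise ValueError("inverse SNR must be positive")
        if 2 * self.wpli_trim_s >= self.epoch_length_s:
            raise ValueError("trim leaves no samples in the epoch")
        if self.n_bootstrap < 1:
            raise ValueError("bootstrap count must be >= 1")
        if not 0 <= self.edge_gate_p <= 1:
            raise ValueError("edge gate must be a p-value threshold in [0,1]")
        lo, hi = self.k_range
        if not 1 <= lo <= hi:
            raise ValueError("feature-count range must satisfy 1 <= lo <= hi")
        if self.fisher_variant not in ("two_class", "generalized"):
            raise ValueError("unknown Fisher-score variant")
        for name, (lo_hz, hi_hz) in self.bands.items():
            if not 0 < lo_hz < hi_hz:
                raise ValueError(f"band {name!r} has invalid edges")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return _jsonable(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs = dict(d)
        for key in ("bands", "mmn_window_ms", "mmn_band_hz", "k_range"):
            if key in kwargs and key != "bands":
                kwargs[key] = tuple(kwargs[key])
        if "bands" in kwargs:
            kwargs["bands"] = {k: tuple(v) for k, v in kwargs["bands"].items()}
        if "roi_seeds_mm" in kwargs:
            kwargs["roi_seeds_mm"] = {
                k: tuple(v) for k, v in kwargs["roi_seeds_mm"].items()}
        if "regions" in kwargs:
            kwargs["regions"] = {
                k: tuple(v) for k, v in kwargs["regions"].items()}
        if "frontocentral" in kwargs:
            kwargs["frontocentral"] = tuple(kwargs["frontocentral"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        """Stable sha256 of the canonical JSON form."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def manifest(cfg: RunConfig, seeds: dict[str, int] | None = None) -> dict:
    """Reproducibility manifest: config hash plus every seed in use."""
    return {
        "config_hash": cfg.hash(),
        "config": cfg.to_dict(),
        "seeds": dict(seeds or {"seed": cfg.seed}),
    }
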