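"""Reading and writing the pipeline's external formats.

Recordings are stored in a documented array-on-disk layout: one directory
per (subject, condition) holding ``data.npy`` (channels × samples, float64,
µV), ``meta.json`` (sampling rate, channel names, condition, subject, group,
units) and, for oddball recordings, ``events.tsv`` (columns onset_sample,
code). EDF files are also readable (via mne) and converted to µV on ingest.
Epoch sets are ``.npy`` arrays with a JSON sidecar carrying condition, time
axis and provenance. Tabular results are CSV; every run emits a JSON
manifest with the config hash and seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, manifest
from .preprocess import EpochSet
from .simulate import LeadField, SensorRecording

UNITS = "uV"


# ---------------------------------------------------------------------------
# recordings


def write_recording(rec: SensorRecording, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / "data.npy", rec.data)
    meta = {"sampling_rate": rec.sampling_rate,
            "channel_names": list(rec.channel_names),
            "condition": rec.condition, "subject_id": rec.subject_id,
            "group": rec.group, "units": UNITS}
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    if rec.events is not None:
        rec.events.to_csv(d / "events.tsv", sep="\t", index=False)
    return d


def read_recording(path) -> SensorRecording:
    """Read a recording from the array-on-disk layout or an EDF file.

    An oddball recording without an event table is an error, never a silent
    fall-back to resting state.
    """
    p = Path(path)
    if p.is_file() and p.suffix.lower() == ".edf":
        return _read_edf(p)
    if not (p / "meta.json").exists():
        raise ValueError(f"unknown recording format at {p}")
    meta = json.loads((p / "meta.json").read_text())
    data = np.load(p / "data.npy")
    if meta.get("units", UNITS) == "V":
        data = data * 1e6
    elif meta.get("units", UNITS) not in (UNITS, "uV", "µV"):
        raise ValueError(f"unsupported units {meta['units']!r}")
    events = None
    if (p / "events.tsv").exists():
        events = pd.read_csv(p / "events.tsv", sep="\t")
    if meta["condition"] == "oddball" and events is None:
        raise ValueError(f"oddball recording at {p} has no events.tsv")
    return SensorRecording(data, float(meta["sampling_rate"]),
                           tuple(meta["channel_names"]), meta["condition"],
                           events=events, subject_id=meta.get("subject_id", ""),
                           group=meta.get("group", ""))


def _read_edf(path: Path) -> SensorRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne works in volts
    events_path = path.with_suffix(".tsv")
    events = pd.read_csv(events_path, sep="\t") if events_path.exists() \
        else None
    condition = "oddball" if events is not None else "resting"
    return SensorRecording(data, float(raw.info["sfreq"]),
                           tuple(raw.ch_names), condition, events=events)


# ---------------------------------------------------------------------------
# epoch sets


def write_epochs(epochs: EpochSet, stem) -> Path:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".npy"), epochs.data)
    side = {"condition": epochs.condition,
            "sampling_rate": epochs.sampling_rate, "tmin": epochs.tmin,
            "channel_names": list(epochs.channel_names),
            "provenance": epochs.provenance, "units": UNITS}
    stem.with_suffix(".json").write_text(json.dumps(side, indent=1))
    return stem.with_suffix(".npy")


def read_epochs(stem) -> EpochSet:
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    side = json.loads(stem.with_suffix(".json").read_text())
    return EpochSet(data, side["condition"], float(side["sampling_rate"]),
                    float(side["tmin"]), tuple(side["channel_names"]),
                    side.get("provenance", {}))


# ---------------------------------------------------------------------------
# lead field


def write_leadfield(lf: LeadField, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "gain.txt", lf.gain)
    np.savetxt(d / "voxel_coords.txt", lf.voxel_coords)
    (d / "channels.json").write_text(json.dumps(list(lf.channel_names)))
    return d


def read_leadfield(directory) -> LeadField:
    d = Path(directory)
    gain = np.loadtxt(d / "gain.txt")
    coords = np.loadtxt(d / "voxel_coords.txt")
    names = tuple(json.loads((d / "channels.json").read_text()))
    return LeadField(gain, coords, names)


# ---------------------------------------------------------------------------
# reports


def write_report(outdir, cfg: RunConfig, networks: pd.DataFrame | None = None,
                 features: pd.DataFrame | None = None,
                 stats_table: pd.DataFrame | None = None,
                 cv_result=None, seeds: dict | None = None) -> dict:
    """Emit every tabular interface of a run plus the manifest.

    Returns the manifest dict. All CSVs round-trip with pandas defaults;
    the CV summary JSON repeats the best configuration's metrics, which are
    recomputable from the per-fold CSV.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if networks is not None:
        networks.to_csv(out / "networks.csv", index=False)
        written.append("networks.csv")
    if features is not None:
        features.to_csv(out / "features.csv", index_label="subject")
        written.append("features.csv")
    if stats_table is not None:
        stats_table.to_csv(out / "stats.csv", index=False)
        written.append("stats.csv")
    if cv_result is not None:
        cv_result.metrics.to_csv(out / "cv_metrics.csv", index=False)
        cv_result.fold_frame().to_csv(out / "cv_folds.csv", index=False)
        roc = cv_result.roc
        pd.DataFrame({"fpr": roc["fpr"], "tpr": roc["tpr"],
                      "threshold": roc["thresholds"]}).to_csv(
            out / "roc.csv", index=False)
        m = cv_result.metrics
        best = m[(m["k"] == cv_result.best_k)
                 & (m["classifier"] == cv_result.best_classifier)].iloc[0]
        summary = {"best_k": cv_result.best_k,
                   "best_classifier": cv_result.best_classifier,
                   "positive_class": cv_result.positive,
                   "accuracy": float(best["accuracy"]),
                   "sensitivity": float(best["sensitivity"]),
                   "specificity": float(best["specificity"]),
                   "auc": roc["auc"]}
        (out / "cv_summary.json").write_text(json.dumps(summary, indent=1))
        written.extend(["cv_metrics.csv", "cv_folds.csv", "roc.csv",
                        "cv_summary.json"])
    man = manifest(cfg, seeds)
    man["files"] = written
    (out / "manifest.json").write_text(json.dumps(man, indent=1))
    return man
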