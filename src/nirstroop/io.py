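"""File I/O: SNIRF recordings, BIDS-style event tables, QC sidecars.

The SNIRF support covers the subset this pipeline produces and consumes:
one data block of continuous-wave intensities (or processed series) with a
measurement list, 3-D probe geometry and landmark positions.  Everything
tabular travels as TSV; ground truth and QC reports as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import ProbeLayout
from .simulate import EventSchedule

__all__ = [
    "write_snirf",
    "read_snirf",
    "write_events_tsv",
    "read_events_tsv",
    "write_json",
]


def write_snirf(
    path,
    intensity: np.ndarray,
    sample_period: float,
    wavelengths,
    layout: ProbeLayout,
    data_type_label: str | None = None,
) -> None:
    """Write a single-block SNIRF file.

    ``intensity`` is (n_channels, n_wavelengths, n_times).  Raw
    continuous-wave amplitude is the default; pass ``data_type_label``
    (e.g. 'dOD') for processed series.
    """
    intensity = np.asarray(intensity, float)
    n_chan, n_wl, n_t = intensity.shape
    wavelengths = np.asarray(wavelengths, float)
    time = np.arange(n_t) * sample_period

    # measurement columns: channel-major, wavelength-minor
    flat = intensity.transpose(2, 0, 1).reshape(n_t, n_chan * n_wl)

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=wavelengths)
        probe.create_dataset("sourcePos3D", data=layout.emitters)
        probe.create_dataset("detectorPos3D", data=layout.detectors)
        if layout.fiducials:
            labels = sorted(layout.fiducials)
            probe.create_dataset(
                "landmarkPos3D",
                data=np.array([layout.fiducials[k] for k in labels]))
            probe.create_dataset(
                "landmarkLabels",
                data=np.array(labels, dtype=h5py.string_dtype()))

        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=time)
        idx = 1
        for ch in range(n_chan):
            e, d = layout.channel_pairs[ch]
            for w in range(n_wl):
                ml = data.create_group(f"measurementList{idx}")
                ml.create_dataset("sourceIndex", data=int(e) + 1)
                ml.create_dataset("detectorIndex", data=int(d) + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=99999 if data_type_label else 1)
                if data_type_label:
                    ml.create_dataset("dataTypeLabel", data=data_type_label)
                idx += 1


def read_snirf(path) -> dict:
    """Read a SNIRF file written by :func:`write_snirf` (or compatible).

    Returns a dict with intensity (channels x wavelengths x times),
    sample_period, wavelengths, and the reconstructed :class:`ProbeLayout`.
    """
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        probe = nirs["probe"]
        wavelengths = probe["wavelengths"][()]
        emitters = probe["sourcePos3D"][()]
        detectors = probe["detectorPos3D"][()]
        fiducials = {}
        if "landmarkPos3D" in probe:
            labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in probe["landmarkLabels"][()]]
            fiducials = dict(zip(labels, probe["landmarkPos3D"][()]))

        data = nirs["data1"]
        flat = data["dataTimeSeries"][()]
        time = data["time"][()]
        n_meas = flat.shape[1]
        pairs, seen = [], {}
        col_map = np.empty(n_meas, int)
        n_wl = len(wavelengths)
        for idx in range(1, n_meas + 1):
            ml = data[f"measurementList{idx}"]
            key = (int(ml["sourceIndex"][()]) - 1,
                   int(ml["detectorIndex"][()]) - 1)
            if key not in seen:
                seen[key] = len(pairs)
                pairs.append(key)
            col_map[idx - 1] = seen[key] * n_wl + int(ml["wavelengthIndex"][()]) - 1

    n_chan = len(pairs)
    ordered = np.empty_like(flat)
    ordered[:, col_map] = flat
    intensity = ordered.reshape(-1, n_chan, n_wl).transpose(1, 2, 0)
    layout = ProbeLayout(emitters=emitters, detectors=detectors,
                         channel_pairs=np.array(pairs), fiducials=fiducials)
    return {
        "intensity": intensity,
        "sample_period": float(np.diff(time).mean()) if len(time) > 1 else 0.0,
        "wavelengths": wavelengths,
        "layout": layout,
    }


def write_events_tsv(path, schedule: EventSchedule,
                     duration: float = 1.5) -> None:
    """BIDS-style events table: onset, duration, trial_type, is_oddball, block."""
    t = schedule.trials
    out = pd.DataFrame({
        "onset": t["onset"],
        "duration": duration,
        "trial_type": t["task"] + "_" + t["congruency"],
        "is_oddball": t["is_oddball"].astype(int),
        "block": t["block_index"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    """Read an events TSV back into the trial-table layout used internally."""
    raw = pd.read_csv(path, sep="\t")
    task_congr = raw["trial_type"].str.split("_", n=1, expand=True)
    return pd.DataFrame({
        "onset": raw["onset"],
        "task": task_congr[0],
        "congruency": task_congr[1],
        "is_oddball": raw["is_oddball"].astype(bool),
        "block_index": raw["block"],
    })


def write_json(path, payload: dict) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
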