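"""On-disk session layout: trials CSV, spikes HDF5, iEEG HDF5, manifest JSON."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ..ieeg import IeegSegments
from .spikes_sim import UnitRecording

MANIFEST_NAME = "manifest.json"


def write_trials(path: Path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, index=False)


def read_trials(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "correct" in df:
        df["correct"] = df["correct"].astype("boolean")
    return df


def write_units(path: Path, units: list[UnitRecording]) -> None:
    with h5py.File(path, "w") as f:
        for u in units:
            g = f.create_group(u.unit_id)
            g.create_dataset("spike_times", data=u.spike_times)
            g.create_dataset("trial_offsets", data=u.trial_offsets)
            g.create_dataset("stimuli", data=u.stimuli.astype(np.int64))
            g.create_dataset(
                "conditions", data=np.asarray(u.conditions, dtype="S")
            )
            g.attrs["region"] = u.region
            g.attrs["unit_class"] = u.unit_class
            g.attrs["session"] = u.session
            g.attrs["window"] = u.window
            g.attrs["ground_truth"] = json.dumps(u.ground_truth, sort_keys=True)


def read_units(path: Path) -> list[UnitRecording]:
    units = []
    with h5py.File(path, "r") as f:
        for uid in sorted(f.keys()):
            g = f[uid]
            units.append(
                UnitRecording(
                    unit_id=uid,
                    region=str(g.attrs["region"]),
                    unit_class=str(g.attrs["unit_class"]),
                    spike_times=g["spike_times"][:],
                    trial_offsets=g["trial_offsets"][:],
                    stimuli=g["stimuli"][:],
                    conditions=g["conditions"][:].astype(str),
                    window=tuple(g.attrs["window"]),
                    session=str(g.attrs["session"]),
                    ground_truth=json.loads(g.attrs["ground_truth"]),
                )
            )
    return units


def write_segments(path: Path, segments: IeegSegments) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=segments.data)
        f.create_dataset("conditions", data=np.asarray(segments.conditions, dtype="S"))
        if segments.artifact_truth is not None:
            f.create_dataset("artifact_truth", data=segments.artifact_truth)
        f.create_dataset("artifact_mask", data=segments.artifact_mask)
        f.attrs["rate"] = segments.rate
        f.attrs["window_ms"] = segments.window_ms
        f.attrs["region"] = segments.region
        f.attrs["session"] = segments.session


def read_segments(path: Path) -> IeegSegments:
    with h5py.File(path, "r") as f:
        return IeegSegments(
            data=f["data"][:],
            rate=float(f.attrs["rate"]),
            window_ms=tuple(f.attrs["window_ms"]),
            conditions=f["conditions"][:].astype(str),
            region=str(f.attrs["region"]),
            session=str(f.attrs["session"]),
            artifact_mask=f["artifact_mask"][:].astype(bool),
            artifact_truth=f["artifact_truth"][:].astype(bool)
            if "artifact_truth" in f
            else None,
        )


def write_session(
    out_dir,
    trials: pd.DataFrame,
    units: list[UnitRecording] | None = None,
    segments: IeegSegments | None = None,
    extra: dict | None = None,
) -> Path:
    """Write one session directory and its manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"session": str(trials["session"].iloc[0]), "files": {}}
    write_trials(out / "trials.csv", trials)
    manifest["files"]["trials"] = "trials.csv"
    if units is not None:
        write_units(out / "spikes.h5", units)
        manifest["files"]["spikes"] = "spikes.h5"
        manifest["n_units"] = len(units)
    if segments is not None:
        write_segments(out / "ieeg.h5", segments)
        manifest["files"]["ieeg"] = "ieeg.h5"
    if extra:
        manifest.update(extra)
    path = out / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_session(session_dir):
    """Load a session directory written by :func:`write_session`."""
    d = Path(session_dir)
    manifest = json.loads((d / MANIFEST_NAME).read_text())
    files = manifest["files"]
    trials = read_trials(d / files["trials"])
    units = read_units(d / files["spikes"]) if "spikes" in files else None
    segments = read_segments(d / files["ieeg"]) if "ieeg" in files else None
    return trials, units, segments, manifest
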