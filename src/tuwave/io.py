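"""Plain-text readers and writers for waveforms, beats and results.

Two waveform formats are supported, both self-describing and text-only:

* CSV: a ``# key=value`` comment header carrying ``fs_hz`` and ``unit``,
  then one time column (seconds) and one column per lead (mV).
* A minimal WFDB-style pair: a ``.hea`` text header (record name, lead
  count, sampling rate, lead labels) next to a whitespace-separated sample
  matrix in ``.dat.txt``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .containers import AveragedBeat, EcgRecording, FiducialSet

__all__ = [
    "write_recording",
    "read_recording",
    "write_beat",
    "read_beat",
    "write_fiducials",
    "read_fiducials",
]

PathLike = Union[str, Path]


def write_recording(recording: EcgRecording, path: PathLike,
                    format: str = "csv") -> None:
    """Write a multi-lead recording as CSV or a WFDB-style text pair."""
    path = Path(path)
    if format == "csv":
        with open(path, "w") as fh:
            fh.write(f"# fs_hz={recording.fs}\n# unit=mV\n")
            cols = ["time_s"] + list(recording.lead_labels)
            fh.write(",".join(cols) + "\n")
            t = np.arange(recording.n_samples) / recording.fs
            np.savetxt(fh, np.column_stack([t, recording.samples.T]),
                       delimiter=",", fmt="%.6f")
    elif format == "wfdb":
        name = path.stem
        hea = path.with_suffix(".hea")
        dat = path.with_suffix(".dat.txt")
        with open(hea, "w") as fh:
            fh.write(f"{name} {recording.n_leads} {recording.fs:g} "
                     f"{recording.n_samples}\n")
            for lab in recording.lead_labels:
                fh.write(f"{dat.name} mV {lab}\n")
        np.savetxt(dat, recording.samples.T, fmt="%.6f")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_recording(path: PathLike, format: str = "csv") -> EcgRecording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    ValueError
        On a malformed or incomplete header, a non-uniform time column, or
        a unit other than mV.
    """
    path = Path(path)
    if format == "csv":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
        if "fs_hz" not in meta:
            raise ValueError("malformed header: missing required field fs_hz")
        if meta.get("unit", "mV") != "mV":
            raise ValueError(f"unit mismatch: expected mV, got {meta.get('unit')}")
        fs = float(meta["fs_hz"])
        df = pd.read_csv(path, comment="#")
        if "time_s" not in df.columns:
            raise ValueError("malformed file: missing time_s column")
        t = df["time_s"].to_numpy()
        dt = np.diff(t)
        if len(dt) and (np.max(dt) - np.min(dt)) > 0.25 / fs:
            raise ValueError("non-uniform time column")
        labels = [c for c in df.columns if c != "time_s"]
        return EcgRecording(samples=df[labels].to_numpy().T, fs=fs,
                            lead_labels=labels)
    if format == "wfdb":
        hea = path.with_suffix(".hea")
        lines = hea.read_text().strip().splitlines()
        head = lines[0].split()
        if len(head) < 4:
            raise ValueError("malformed header: expected 'name n_leads fs n_samples'")
        n_leads, fs = int(head[1]), float(head[2])
        labels = [ln.split()[2] for ln in lines[1:1 + n_leads]]
        dat = path.with_suffix(".dat.txt")
        samples = np.loadtxt(dat).T
        return EcgRecording(samples=samples, fs=fs, lead_labels=labels)
    raise ValueError(f"unknown format {format!r}")


def write_beat(beat: AveragedBeat, path: PathLike) -> None:
    """Averaged beat as CSV; the header carries fs, mean RR and beat count."""
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={beat.fs}\n# unit=mV\n# mean_rr_s={beat.mean_rr}\n"
                 f"# n_beats_used={beat.n_beats_used}\n# r_offset={beat.r_offset}\n")
        cols = ["time_s"] + list(beat.lead_labels)
        fh.write(",".join(cols) + "\n")
        t = np.arange(beat.n_samples) / beat.fs
        np.savetxt(fh, np.column_stack([t, beat.samples.T]),
                   delimiter=",", fmt="%.6f")


def read_beat(path: PathLike) -> AveragedBeat:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    for field in ("fs_hz", "mean_rr_s", "n_beats_used"):
        if field not in meta:
            raise ValueError(f"malformed header: missing required field {field}")
    df = pd.read_csv(path, comment="#")
    labels = [c for c in df.columns if c != "time_s"]
    return AveragedBeat(
        samples=df[labels].to_numpy().T,
        fs=float(meta["fs_hz"]),
        lead_labels=labels,
        mean_rr=float(meta["mean_rr_s"]),
        n_beats_used=int(meta["n_beats_used"]),
        r_offset=int(meta.get("r_offset", 0)),
    )


def write_fiducials(fiducials: FiducialSet, path: PathLike) -> None:
    Path(path).write_text(json.dumps(fiducials.to_dict(), indent=2))


def read_fiducials(path: PathLike) -> FiducialSet:
    d = json.loads(Path(path).read_text())
    return FiducialSet(
        q_onset=d["q_onset"], j_point=d["j_point"], t_peak=d["t_peak"],
        bottom_b=d["bottom_b"], u_peak=d["u_peak"],
        t_end=d["t_end_s"], u_end=d["u_end_s"],
        analysis_lead=d["analysis_lead"], fs=d["fs_hz"],
        baseline=d.get("baseline_mv", 0.0),
    )
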