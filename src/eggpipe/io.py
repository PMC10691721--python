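"""Plain-text signal files with JSON metadata sidecars.

A recording is stored as delimited text -- either a single amplitude
column (uV) or two columns ``time_s,amplitude_uv`` -- next to a JSON
sidecar ``<file>.json`` holding ``fs_hz``, subject/session identifiers,
condition, stimulation frequency and channel label.  Round trips are
lossless at full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocessing import Recording

__all__ = ["read_recording", "write_recording", "sidecar_path"]

_REQUIRED = ("fs_hz", "subject_id", "session_id", "condition", "stim_freq_hz")


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_recording(recording: Recording, path, time_column: bool = False) -> None:
    """Write samples (optionally with a time column) plus the sidecar."""
    path = Path(path)
    if time_column:
        t = np.arange(len(recording.samples)) / recording.fs_hz
        data = np.column_stack([t, recording.samples])
        np.savetxt(path, data, fmt="%.17g", delimiter=",")
    else:
        np.savetxt(path, recording.samples, fmt="%.17g")
    meta = {
        "fs_hz": recording.fs_hz,
        "subject_id": recording.subject_id,
        "session_id": recording.session_id,
        "condition": recording.condition,
        "stim_freq_hz": recording.stim_freq_hz,
        "channel_label": recording.channel_label,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_recording(path) -> Recording:
    """Read a signal file and its sidecar back into a Recording.

    Fails with a named-field error when the sidecar is incomplete, on
    non-finite samples (listing the offending indices), and when a time
    column disagrees with the sidecar sampling rate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing sidecar {sc}")
    meta = json.loads(sc.read_text())
    missing = [k for k in _REQUIRED if k not in meta]
    if missing:
        raise KeyError(f"sidecar {sc} missing fields: {', '.join(missing)}")
    data = np.loadtxt(path, delimiter="," if _has_comma(path) else None, ndmin=2)
    if data.shape[1] == 2:
        t, samples = data[:, 0], data[:, 1]
        if len(t) > 1:
            fs_from_t = 1.0 / np.median(np.diff(t))
            if abs(fs_from_t - meta["fs_hz"]) > 1e-6 * meta["fs_hz"]:
                raise ValueError(
                    f"time column implies fs = {fs_from_t:.6g} Hz, "
                    f"sidecar says {meta['fs_hz']:.6g} Hz"
                )
    else:
        samples = data[:, 0]
    bad = np.flatnonzero(~np.isfinite(samples))
    if len(bad):
        raise ValueError(f"non-finite samples at indices {bad[:10].tolist()}")
    return Recording(
        samples=samples,
        fs_hz=float(meta["fs_hz"]),
        subject_id=str(meta["subject_id"]),
        session_id=str(meta["session_id"]),
        condition=str(meta["condition"]),
        stim_freq_hz=float(meta["stim_freq_hz"]),
        channel_label=str(meta.get("channel_label", "gastric2")),
    )


def _has_comma(path: Path) -> bool:
    with open(path) as fh:
        return "," in fh.readline()
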