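"""On-disk formats: flat-binary recordings, CSV event tables, JSON configs.

A recording is stored as ``<stem>.bin`` (raw little-endian float32,
channel-major) plus ``<stem>.json`` with the metadata
``{fs_hz, n_channels, depths_um, units, t0}``.  Event tables are CSV with
a header; spectra and profiles are CSV; ground truth and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Recording
from .synthlfp import GroundTruth

__all__ = [
    "save_recording",
    "load_recording",
    "save_events",
    "load_events",
    "save_ground_truth",
    "load_ground_truth",
]

EVENT_COLUMNS = ["onset_s", "offset_s", "peak_s", "channel", "kind"]


def save_recording(rec: Recording, stem: str | Path) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    rec.samples.astype("<f4").tofile(stem.with_suffix(".bin"))
    sidecar = {
        "fs_hz": rec.fs,
        "n_channels": rec.n_channels,
        "depths_um": None if rec.depths_um is None else rec.depths_um.tolist(),
        "units": "mV",
        "t0": rec.t0,
        "channel_labels": rec.channel_labels,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_recording(stem: str | Path) -> Recording:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".bin"), dtype="<f4")
    n_ch = int(meta["n_channels"])
    if data.size % n_ch:
        raise ValueError(
            f"{stem}.bin length {data.size} is not divisible by "
            f"n_channels={n_ch}"
        )
    samples = data.reshape(n_ch, -1).astype(float)
    return Recording(
        samples=samples,
        fs=float(meta["fs_hz"]),
        depths_um=None if meta.get("depths_um") is None else np.asarray(
            meta["depths_um"], dtype=float
        ),
        channel_labels=list(meta.get("channel_labels", [])),
        t0=float(meta.get("t0", 0.0)),
    )


def save_events(events, path: str | Path) -> None:
    """Write burst events (DataFrame or BurstEvent list) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(events, pd.DataFrame):
        df = events
    else:
        df = pd.DataFrame(
            [
                {
                    "onset_s": b.onset_s,
                    "offset_s": b.offset_s,
                    "peak_s": b.peak_s,
                    "peak_env_mv": b.peak_envelope,
                    "channel": b.channel,
                    "kind": getattr(b.band, "name", "hfo") if b.band else "hfo",
                }
                for b in events
            ]
        )
    df.to_csv(path, index=False)


def load_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("onset_s", "offset_s", "peak_s") if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path} lacks columns {missing}")
    return df


def save_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(gt.to_dict(), indent=1))


def load_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))
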