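"""File formats for pipeline artifacts.

Signals are stored as channel-interleaved float32 (``.f32``) with a JSON
sidecar holding the sampling rate and sample count, plus per-second truth
channels in a companion CSV. Everything else is plain CSV or JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import SignalRecording

__all__ = ["save_recording", "load_recording", "sha256_file", "write_manifest"]


def save_recording(recording: SignalRecording, prefix: Path) -> list:
    """Write ``<prefix>.f32`` + ``<prefix>.json`` + ``<prefix>.truth.csv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    raw = recording.acceleration.astype(np.float32)
    bin_path = prefix.with_suffix(".f32")
    raw.tofile(bin_path)
    meta_path = prefix.with_suffix(".json")
    meta_path.write_text(
        json.dumps(
            {
                "sampling_rate": recording.sampling_rate,
                "n_samples": int(raw.shape[0]),
                "n_channels": 3,
                "dtype": "float32",
                "layout": "channel-interleaved",
            }
        )
    )
    truth_path = prefix.parent / (prefix.name + ".truth.csv")
    pd.DataFrame(
        {"label": recording.truth_label, "speed_mps": recording.truth_speed}
    ).to_csv(truth_path, index_label="second")
    return [bin_path, meta_path, truth_path]


def load_recording(prefix: Path) -> SignalRecording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    raw = np.fromfile(prefix.with_suffix(".f32"), dtype=np.float32)
    acc = raw.reshape(meta["n_samples"], meta["n_channels"]).astype(float)
    truth = pd.read_csv(prefix.parent / (prefix.name + ".truth.csv"))
    return SignalRecording(
        sampling_rate=int(meta["sampling_rate"]),
        acceleration=acc,
        truth_label=truth["label"].to_numpy(np.uint8),
        truth_speed=truth["speed_mps"].to_numpy(float),
    )


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, paths) -> Path:
    """Checksum manifest over the run's artifacts, for provenance checks."""
    out_dir = Path(out_dir)
    manifest = {
        str(Path(p).relative_to(out_dir)): sha256_file(p) for p in sorted(map(Path, paths))
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath
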