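"""Readers and writers: delimited-text recordings, event tables, NIfTI maps.

Recordings are stored as one row per sample (time_s, y, r, theta) with a
JSON sidecar carrying the sampling rate, trial markers and contraction
blocks; events as a tab-separated table; volumes as NIfTI-1.  Every
artifact can carry a provenance manifest (seed plus a hash of the
generating configuration) so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .emg import EmgRecording
from .protocol import ContractionBlock, TrialEvent


def write_recording(rec: EmgRecording, tsv_path, json_path=None) -> None:
    tsv_path = Path(tsv_path)
    n = len(rec.y)
    t = np.arange(n) / rec.fs
    pd.DataFrame({"time_s": t, "y": rec.y, "r": rec.r, "theta": rec.theta}).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.9g"
    )
    sidecar = {
        "fs": rec.fs,
        "muscle": rec.muscle,
        "channels": ["y", "r", "theta"],
        "trial_markers": [
            {
                "sample": int(i),
                "index": ev.index,
                "velocity": ev.velocity,
                "onset_s": ev.onset,
                "t_hold_s": ev.t_hold,
            }
            for i, ev in rec.trial_markers
        ],
        "contraction_blocks": [
            {"start_s": b.start, "stop_s": b.stop, "direction": b.direction}
            for b in rec.contraction_blocks
        ],
    }
    json_path = Path(json_path) if json_path else tsv_path.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=1))


def read_recording(tsv_path, json_path=None) -> EmgRecording:
    tsv_path = Path(tsv_path)
    json_path = Path(json_path) if json_path else tsv_path.with_suffix(".json")
    df = pd.read_csv(tsv_path, sep="\t")
    meta = json.loads(json_path.read_text())
    markers = [
        (
            m["sample"],
            TrialEvent(
                index=m["index"],
                velocity=m["velocity"],
                onset=m["onset_s"],
                t_hold=m["t_hold_s"],
            ),
        )
        for m in meta["trial_markers"]
    ]
    blocks = [
        ContractionBlock(b["start_s"], b["stop_s"], b["direction"])
        for b in meta["contraction_blocks"]
    ]
    return EmgRecording(
        fs=meta["fs"],
        y=df["y"].to_numpy(),
        r=df["r"].to_numpy(),
        theta=df["theta"].to_numpy(),
        trial_markers=markers,
        contraction_blocks=blocks,
        muscle=meta.get("muscle", "FCR"),
    )


def write_events(events, path) -> None:
    rows = [
        {
            "index": ev.index,
            "muscle": ev.muscle_stretched,
            "direction": "stretch",
            "velocity_deg_s": ev.velocity,
            "onset_s": ev.onset,
            "t_hold_s": ev.t_hold,
        }
        for ev in events
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_events(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        TrialEvent(
            index=int(r["index"]),
            velocity=float(r["velocity_deg_s"]),
            onset=float(r["onset_s"]),
            t_hold=float(r["t_hold_s"]),
        )
        for _, r in df.iterrows()
    ]


def save_nifti(data, path, voxel_mm=(2.0, 2.0, 2.0)) -> None:
    data = np.asarray(data)
    affine = np.diag(list(voxel_mm) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, config: dict, seed: int, stage: str) -> None:
    Path(path).write_text(
        json.dumps(
            {"stage": stage, "seed": seed, "config_hash": config_hash(config)},
            indent=1,
            sort_keys=True,
        )
    )


def write_json(path, payload) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=default))
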