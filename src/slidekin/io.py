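"""Plain-text I/O for trajectories, segmentations, and CSM tables.

Trajectories travel as TSV (time_s, donor, acceptor[, fret]) with a JSON
ground-truth sidecar for simulated data; tabular outputs are CSV with the
documented headers; CSM candidate lists are serialized as
``P1:r1--P2:r2;P1:r1--P2:r3``.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .qc import Trajectory
from .segmentation import Segmentation
from .simulate import GroundTruth

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_ground_truth",
    "segmentation_to_frame",
    "serialize_candidates",
    "parse_candidates",
    "write_csm_table",
    "read_csm_table",
]


def write_trajectory(traj: Trajectory, path) -> None:
    cols = {"time_s": traj.time_s, "donor": traj.donor, "acceptor": traj.acceptor}
    if traj.fret is not None:
        cols["fret"] = traj.fret
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_trajectory(path, meta: dict | None = None) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "donor", "acceptor"):
        if col not in df.columns:
            raise ValueError(f"trajectory TSV lacks column {col!r}")
    return Trajectory(
        time_s=df["time_s"].to_numpy(),
        donor=df["donor"].to_numpy(),
        acceptor=df["acceptor"].to_numpy(),
        fret=df["fret"].to_numpy() if "fret" in df.columns else None,
        meta=dict(meta or {}),
    )


def write_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "label_class": gt.label_class,
        "segments": [asdict(s) for s in gt.segments],
        "donor_bleach_times": list(gt.donor_bleach_times),
        "acceptor_bleach_time": gt.acceptor_bleach_time,
        "blink_intervals": [list(b) for b in gt.blink_intervals],
        "bp_at_frames": np.asarray(gt.bp_at_frames).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def segmentation_to_frame(seg: Segmentation) -> pd.DataFrame:
    """One CSV-ready row per segment."""
    return pd.DataFrame(
        [
            {
                "trace_id": seg.trace_id,
                "kind": s.kind,
                "label": s.label,
                "start_s": s.start_s,
                "end_s": s.end_s,
                "duration_s": s.duration_s,
                "fret_level": s.fret_level,
                "censored": s.censored,
            }
            for s in seg.segments
        ]
    )


def serialize_candidates(cands) -> str:
    return ";".join(f"{p1}:{r1}--{p2}:{r2}" for p1, r1, p2, r2 in cands)


def parse_candidates(text: str):
    out = []
    for part in str(text).split(";"):
        left, right = part.split("--")
        p1, r1 = left.rsplit(":", 1)
        p2, r2 = right.rsplit(":", 1)
        out.append((p1, int(r1), p2, int(r2)))
    return out


def write_csm_table(table: pd.DataFrame, path) -> None:
    df = table.copy()
    df["candidates"] = df["candidates"].map(serialize_candidates)
    df.to_csv(path, index=False)


def read_csm_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["candidates"] = df["candidates"].map(parse_candidates)
    df["decoy"] = df["decoy"].astype(bool)
    return df
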