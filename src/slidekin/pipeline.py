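"""End-to-end single-trace and dataset analysis: QC -> HMM -> statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .pause_stats import pause_durations, step_sizes
from .qc import (
    BleachEvent,
    QCDecision,
    Trajectory,
    apply_qc,
    compute_fret,
    detect_photobleach,
    truncate_backtracking,
)
from .segmentation import HMMSegmenter, Segmentation, states_to_segments

__all__ = ["TraceAnalysis", "analyze_trace", "analyze_set"]


@dataclass
class TraceAnalysis:
    trace_id: str | None
    decision: QCDecision
    segmentation: Segmentation | None
    bleach_events: list[BleachEvent]
    initial_fret: float | None


def analyze_trace(
    traj: Trajectory,
    calib: CalibrationCurve,
    segmenter: HMMSegmenter | None = None,
    initial_fret_threshold: float = 0.775,
    backtrack_tolerance: float = 0.05,
    translocation_min_dbp: float = 1.0,
    blink_mask_frac: float = 0.3,
) -> TraceAnalysis:
    """Run one trajectory through FRET computation, QC, and segmentation.

    The analysis window ends at the earliest photobleach; frames whose total
    intensity falls below ``blink_mask_frac`` of the running median (dye
    blinks) are masked out of the HMM fit; backtracking truncation is applied
    to the resulting segments.  Excluded traces return ``segmentation=None``.
    """
    trace_id = traj.meta.get("trace_id")
    if traj.fret is None:
        traj = compute_fret(traj)
    bleach = detect_photobleach(traj)
    if traj.meta.get("no_signal"):
        return TraceAnalysis(
            trace_id, QCDecision(False, "no_signal"), None, bleach, None
        )
    end = traj.n_frames
    first_bleach = min((e.frame for e in bleach), default=None)
    if first_bleach is not None:
        end = max(first_bleach, 1)
    fret = traj.fret[:end]
    total = traj.total[:end]
    med = np.median(total)
    mask = total < blink_mask_frac * med if med > 0 else None

    segmenter = segmenter if segmenter is not None else HMMSegmenter()
    try:
        segmenter = segmenter.fit(fret, mask=mask)
    except ValueError:
        # window too short to segment: treat as no usable signal
        return TraceAnalysis(
            trace_id, QCDecision(False, "no_signal"), None, bleach, None
        )
    initial = segmenter.initial_level_
    decision = apply_qc(
        traj, initial, bleach_events=bleach,
        initial_fret_threshold=initial_fret_threshold,
    )
    if not decision.include:
        return TraceAnalysis(trace_id, decision, None, bleach, initial)
    seg = states_to_segments(
        segmenter.to_state_path(frame_period_s=traj.frame_period_s),
        calib=calib,
        translocation_min_dbp=translocation_min_dbp,
        trace_id=trace_id,
    )
    if first_bleach is not None:
        seg.truncated = True
        seg.truncation_reason = "photobleach"
    seg = truncate_backtracking(seg, tolerance=backtrack_tolerance)
    return TraceAnalysis(trace_id, decision, seg, bleach, initial)


def analyze_set(
    trajectories,
    calib: CalibrationCurve,
    **kwargs,
) -> dict:
    """Analyze a collection of trajectories and tabulate the results.

    Returns a dict with the QC report (one row per trace), the retained
    segmentations, and the pooled pause and step tables.
    """
    analyses = [analyze_trace(traj, calib, **kwargs) for traj in trajectories]
    qc_rows = [
        {
            "trace_id": a.trace_id,
            "include": a.decision.include,
            "reason": a.decision.reason,
            "truncate_at_s": a.decision.truncate_at_s,
            "initial_fret": a.initial_fret,
        }
        for a in analyses
    ]
    segs = [a.segmentation for a in analyses if a.segmentation is not None]
    return {
        "qc": pd.DataFrame(qc_rows),
        "segmentations": segs,
        "pauses": pause_durations(segs),
        "steps": step_sizes(segs, calib),
        "analyses": analyses,
    }
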