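"""FRET computation and trajectory quality control.

Implements the inclusion/exclusion and truncation rules used for
single-nucleosome remodeling trajectories:

* traces with two-step donor photobleaching carry two labeled H3 copies and
  are excluded;
* traces whose fitted initial FRET is lower than 0.775 start from the
  distally-labeled population (mid-FRET cluster at 0.57) and are excluded —
  the threshold is strict, exactly 0.775 is kept;
* the analysis window of a retained trace ends at the earliest photobleach;
* any part of a trajectory including and subsequent to a backtracking event
  (FRET increasing instead of decreasing) is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .segmentation import Segment, Segmentation, dp_changepoints

__all__ = [
    "Trajectory",
    "QCDecision",
    "BleachEvent",
    "compute_fret",
    "detect_photobleach",
    "apply_qc",
    "truncate_backtracking",
]

QC_REASONS = ("ok", "two_step_donor_bleach", "low_initial_fret", "no_signal")


@dataclass
class Trajectory:
    """Two-channel intensity time series for one immobilized nucleosome."""

    time_s: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    fret: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (self.time_s.size == self.donor.size == self.acceptor.size):
            raise ValueError("time, donor, and acceptor must have equal length")
        if self.time_s.size >= 2 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.fret is not None:
            self.fret = np.asarray(self.fret, dtype=float)
            if self.fret.size != self.time_s.size:
                raise ValueError("fret series length mismatch")

    @property
    def n_frames(self) -> int:
        return self.time_s.size

    @property
    def frame_period_s(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need >= 2 frames for a frame period")
        return float(np.median(np.diff(self.time_s)))

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


@dataclass(frozen=True)
class BleachEvent:
    channel: str  # "donor" | "acceptor"
    time_s: float
    frame: int


@dataclass(frozen=True)
class QCDecision:
    include: bool
    reason: str  # one of QC_REASONS
    truncate_at_s: float | None = None

    def __post_init__(self):
        if self.reason not in QC_REASONS:
            raise ValueError(f"unknown QC reason {self.reason!r}")


# ---------------------------------------------------------------------------
# FRET computation
# ---------------------------------------------------------------------------

def compute_fret(
    traj: Trajectory,
    leakage: float = 0.0,
    direct_excitation: float = 0.0,
    gamma: float = 1.0,
    min_total: float | None = None,
) -> Trajectory:
    """Compute per-frame FRET and attach it to a copy of the trajectory.

    The default (no corrections) is the uncorrected proximity ratio
    ``E = I_A / (I_A + I_D)``.  Donor leakage, direct acceptor excitation and
    the detection-efficiency factor gamma can be supplied:
    ``E = A' / (A' + gamma * I_D)`` with
    ``A' = I_A - leakage * I_D - direct_excitation``.

    Values are clipped to ``[-0.1, 1.1]``; frames outside ``[0, 1]`` before
    clipping set ``meta['fret_out_of_range']``.  Frames with non-positive
    corrected total have undefined FRET (NaN); if the whole trace lacks
    signal (median total below ``min_total``), ``meta['no_signal']`` is set.
    """
    acc = traj.acceptor - leakage * traj.donor - direct_excitation
    total = acc + gamma * traj.donor
    with np.errstate(divide="ignore", invalid="ignore"):
        fret = np.where(total > 0, acc / total, np.nan)
    out_of_range = bool(np.any((fret < 0) | (fret > 1)))
    fret = np.clip(fret, -0.1, 1.1)
    meta = dict(traj.meta)
    meta["fret_out_of_range"] = out_of_range
    if min_total is None:
        # default: a tenth of the peak observed total; scale-free enough for
        # synthetic and camera-count data alike
        peak = float(np.nanmax(total)) if total.size else 0.0
        min_total = 0.1 * max(peak, 0.0)
    # judge signal on the early window: a dye that bleaches mid-trace was
    # still a signal at the start, while an unlabeled nucleosome never is
    head = total[: max(10, total.size // 20)]
    no_signal = bool(np.nanmedian(head) <= min_total) if total.size else True
    if np.all(~np.isfinite(fret)):
        no_signal = True
    meta["no_signal"] = no_signal
    return Trajectory(
        time_s=traj.time_s,
        donor=traj.donor,
        acceptor=traj.acceptor,
        fret=fret,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# photobleach detection
# ---------------------------------------------------------------------------

def _step_levels(y: np.ndarray, max_steps: int):
    """Piecewise-constant fit with BIC-selected number of steps.

    Returns (changepoints, levels).
    """
    n = y.size
    best = None
    for k in range(0, max_steps + 1):
        if k >= n:
            break
        cps, sse = dp_changepoints(y, k)
        score = n * np.log(sse / n + 1e-12) + 3.0 * k * np.log(n)
        if best is None or score < best[0]:
            best = (score, cps)
    cps = best[1]
    bounds = np.concatenate([[0], cps, [n]]).astype(int)
    levels = np.array(
        [float(np.mean(y[a:b])) for a, b in zip(bounds[:-1], bounds[1:])]
    )
    return cps, levels


def detect_photobleach(
    traj: Trajectory,
    drop_frac: float = 0.4,
    background_frac: float = 0.08,
    max_steps: int = 4,
) -> list[BleachEvent]:
    """Detect irreversible single-step dye photobleaching events.

    Donor-dye bleaches remove both the donor's direct emission and its
    sensitized acceptor emission, so they appear as step drops in the *total*
    intensity of at least ``drop_frac`` of the pre-step level.  Acceptor
    bleaching leaves the total unchanged (the donor recovers its full
    emission) while the acceptor channel falls to background
    (``background_frac`` of the initial total).  FRET changes caused by
    remodeling redistribute intensity between channels without moving the
    total and without reaching background, so they are not reported.
    """
    events: list[BleachEvent] = []
    n = traj.n_frames
    if n < 4:
        return events
    total = traj.total
    init_total = float(np.median(total[: max(4, n // 20)]))
    if init_total <= 0:
        return events

    cps_t, lev_t = _step_levels(total, max_steps)
    donor_cps = []
    for i, cp in enumerate(cps_t):
        pre, post = lev_t[i], lev_t[i + 1]
        # bleaching is irreversible: the total must never recover above the
        # dropped level afterwards (transient dips are blinks, not bleaches)
        recovers = np.max(lev_t[i + 1 :]) > (1.0 - drop_frac) * pre
        if pre > 0 and (pre - post) >= drop_frac * pre and not recovers:
            donor_cps.append(int(cp))
            events.append(
                BleachEvent("donor", float(traj.time_s[cp]), int(cp))
            )

    cps_a, lev_a = _step_levels(traj.acceptor, max_steps)
    for i, cp in enumerate(cps_a):
        pre, post = lev_a[i], lev_a[i + 1]
        # compare against the total still detected after the step: a
        # remodeling plateau keeps a finite FRET fraction of the total,
        # whereas a bleached acceptor contributes nothing to it
        nxt = cps_a[i + 1] if i + 1 < len(cps_a) else n
        local_total = float(np.mean(total[cp:nxt]))
        thresh = background_frac * max(local_total, 1e-12)
        recovers = np.max(lev_a[i + 1 :]) > max(thresh, pre * (1 - 0.99))
        if post <= thresh and pre > post and not recovers:
            # skip drops explained by a coincident donor bleach
            if any(abs(cp - d) <= 3 for d in donor_cps):
                continue
            events.append(
                BleachEvent("acceptor", float(traj.time_s[cp]), int(cp))
            )
            break  # a single acceptor dye bleaches at most once
    events.sort(key=lambda e: e.frame)
    return events


# ---------------------------------------------------------------------------
# inclusion / exclusion
# ---------------------------------------------------------------------------

def apply_qc(
    traj: Trajectory,
    segmentation_initial_fret: float | None,
    bleach_events: list[BleachEvent] | None = None,
    initial_fret_threshold: float = 0.775,
) -> QCDecision:
    """Apply the trajectory inclusion rules.

    Excludes traces with two-step donor bleaching (two labeled H3 copies),
    traces without signal, and traces whose fitted initial FRET is strictly
    lower than the threshold (distally labeled population).  Retained traces
    are truncated at the earliest photobleach.  Idempotent by construction:
    the decision is a pure function of its inputs.
    """
    if traj.meta.get("no_signal"):
        return QCDecision(include=False, reason="no_signal")
    if segmentation_initial_fret is None:
        raise ValueError("an initial-level estimate is required for QC")
    if bleach_events is None:
        bleach_events = detect_photobleach(traj)
    n_donor = sum(1 for e in bleach_events if e.channel == "donor")
    if n_donor >= 2:
        return QCDecision(include=False, reason="two_step_donor_bleach")
    if segmentation_initial_fret < initial_fret_threshold:
        return QCDecision(include=False, reason="low_initial_fret")
    truncate_at = min((e.time_s for e in bleach_events), default=None)
    if truncate_at is not None and truncate_at >= float(traj.time_s[-1]):
        truncate_at = None
    return QCDecision(include=True, reason="ok", truncate_at_s=truncate_at)


# ---------------------------------------------------------------------------
# backtracking truncation
# ---------------------------------------------------------------------------

def truncate_backtracking(
    segmentation: Segmentation, tolerance: float = 0.05
) -> Segmentation:
    """Remove backtracking events and everything after them.

    A pause whose FRET level exceeds the preceding pause level by more than
    ``tolerance`` marks a backtrack (the nucleosome moved toward the labeled
    end).  The translocation leading into that pause and all later segments
    are removed; the retained segments are a prefix of the input.
    """
    pauses_seen: list[Segment] = []
    cut_index: int | None = None
    prev_level: float | None = None
    for i, seg in enumerate(segmentation.segments):
        if seg.kind != "pause":
            continue
        if prev_level is not None and seg.fret_level > prev_level + tolerance:
            # remove from the translocation that produced this pause
            cut_index = i - 1 if i > 0 and segmentation.segments[i - 1].kind == "translocation" else i
            break
        prev_level = seg.fret_level
        pauses_seen.append(seg)
    if cut_index is None:
        return segmentation
    retained = list(segmentation.segments[:cut_index])
    if retained and retained[-1].kind == "pause":
        retained[-1] = replace(retained[-1], censored=True)
    return Segmentation(
        segments=retained,
        trace_id=segmentation.trace_id,
        frame_period_s=segmentation.frame_period_s,
        truncated=True,
        truncation_reason="backtrack",
    )
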