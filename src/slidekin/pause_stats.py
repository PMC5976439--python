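"""Pause-duration and step-size statistics with trajectory-level bootstrap.

Aggregates per-trace segmentations into the quantities a remodeling study
reports: mean durations of the wait/p1/p2 pauses, step-size distributions in
base pairs (inter-pause FRET change converted through the calibration
curve), empirical CDFs of steps, and bootstrap standard deviations.  The
resampling unit of every bootstrap is the trajectory, not the individual
pause or step, so correlations within a trace are respected.

Pauses cut short by photobleaching, backtrack truncation, or the end of the
recording are flagged as censored and excluded from duration means by
default (their observed duration underestimates the true dwell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .segmentation import Segmentation

__all__ = [
    "PAUSE_LABELS",
    "BootstrapEstimate",
    "pause_durations",
    "mean_pause_durations",
    "bootstrap",
    "step_sizes",
    "step_ecdf",
    "summarize_pauses",
]

PAUSE_LABELS = ("wait", "p1", "p2", "p3", "p4", "p5")
MIN_TRACES_WARNING = 100  # datasets below this are reported, with a warning


@dataclass(frozen=True)
class BootstrapEstimate:
    """A statistic with its trajectory-bootstrap standard deviation."""

    value: float
    sd: float
    n_boot: int
    seed: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("bootstrap SD cannot be negative")


def pause_durations(segmentations) -> pd.DataFrame:
    """One row per pause across a set of segmentations.

    Columns: trace_id, label, duration_s, fret_level, censored.  Censored
    pauses (cut by bleach, truncation, or trace end) are flagged; downstream
    means exclude them by default.  Empty input gives an empty table.
    """
    rows = []
    for seg in segmentations:
        if not isinstance(seg, Segmentation):
            raise TypeError("expected Segmentation objects")
        for s in seg.pauses():
            rows.append(
                {
                    "trace_id": seg.trace_id,
                    "label": s.label,
                    "duration_s": s.duration_s,
                    "fret_level": s.fret_level,
                    "censored": bool(s.censored),
                }
            )
    return pd.DataFrame(
        rows, columns=["trace_id", "label", "duration_s", "fret_level", "censored"]
    )


def mean_pause_durations(
    pause_table: pd.DataFrame, include_censored: bool = False
) -> pd.Series:
    """Mean duration per pause label, excluding censored pauses by default."""
    df = pause_table
    if not include_censored and len(df):
        df = df[~df["censored"]]
    if not len(df):
        return pd.Series(dtype=float)
    return df.groupby("label")["duration_s"].mean()


def bootstrap(
    values_by_trace, statistic, n_boot: int = 1000, seed: int = 0
) -> BootstrapEstimate:
    """Trajectory-level bootstrap of an arbitrary statistic.

    Parameters
    ----------
    values_by_trace : mapping or DataFrame
        Either ``{trace_id: array of values}`` or a DataFrame with a
        ``trace_id`` column; traces (not values) are resampled with
        replacement.
    statistic : callable
        Applied to the pooled values of a resampled set (1-D array) or, for
        a DataFrame input, to the resampled DataFrame.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    if isinstance(values_by_trace, pd.DataFrame):
        groups = {
            tid: g.drop(columns=["trace_id"])
            for tid, g in values_by_trace.groupby("trace_id", sort=True)
        }
        def pooled(ids):
            return pd.concat([groups[i] for i in ids], ignore_index=True)
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in values_by_trace.items()}
        def pooled(ids):
            return np.concatenate([np.atleast_1d(groups[i]) for i in ids])
    ids = sorted(groups)
    if not ids:
        raise ValueError("need at least one trace")
    point = float(statistic(pooled(ids)))
    reps = np.empty(n_boot)
    for b in range(n_boot):
        sample = [ids[j] for j in rng.integers(0, len(ids), len(ids))]
        reps[b] = statistic(pooled(sample))
    return BootstrapEstimate(
        value=point, sd=float(np.std(reps, ddof=0)), n_boot=n_boot, seed=seed
    )


def step_sizes(segmentations, calib: CalibrationCurve) -> pd.DataFrame:
    """Translocation distances from consecutive pause FRET levels.

    For pause levels ``(f_i, f_{i+1})`` the step is
    ``dbp = fret_to_bp(f_{i+1}) - fret_to_bp(f_i)`` — positive when the
    nucleosome moves away from the labeled end (FRET decreasing).  Rows
    whose pause level falls outside the calibration range are flagged
    ``in_range=False`` and should be excluded from distributions.
    """
    rows = []
    for seg in segmentations:
        levels = seg.pause_levels()
        for i in range(len(levels) - 1):
            f0, f1 = levels[i], levels[i + 1]
            in_range = calib.contains_fret(f0) and calib.contains_fret(f1)
            dbp = (
                calib.fret_to_bp(f1, clamp=True) - calib.fret_to_bp(f0, clamp=True)
            )
            rows.append(
                {
                    "trace_id": seg.trace_id,
                    "step_index": i + 1,
                    "dfret": f1 - f0,
                    "dbp": dbp,
                    "in_range": in_range,
                }
            )
    return pd.DataFrame(
        rows, columns=["trace_id", "step_index", "dfret", "dbp", "in_range"]
    )


def step_ecdf(
    step_table: pd.DataFrame,
    step_index: int,
    n_boot: int = 1000,
    seed: int = 0,
    min_steps: int = 5,
) -> pd.DataFrame:
    """ECDF of step sizes at one step index with a pointwise bootstrap band.

    Returns a DataFrame (x, F, band_sd): F is the fraction of steps <= x
    over the observed support; band_sd is the per-point standard deviation
    of ECDFs recomputed over trajectory-level bootstrap resamples.
    """
    df = step_table[
        (step_table["step_index"] == step_index) & step_table["in_range"]
    ]
    n = len(df)
    if n < min_steps:
        raise ValueError(
            f"only {n} steps at index {step_index} (need >= {min_steps})"
        )
    x = np.sort(df["dbp"].unique())
    vals = df["dbp"].to_numpy()
    F = np.searchsorted(np.sort(vals), x, side="right") / vals.size

    groups = {tid: g["dbp"].to_numpy() for tid, g in df.groupby("trace_id")}
    ids = sorted(groups)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, x.size))
    for b in range(n_boot):
        sample = np.concatenate(
            [groups[ids[j]] for j in rng.integers(0, len(ids), len(ids))]
        )
        reps[b] = np.searchsorted(np.sort(sample), x, side="right") / sample.size
    return pd.DataFrame({"x": x, "F": F, "band_sd": reps.std(axis=0, ddof=0)})


def summarize_pauses(
    pause_table: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> dict:
    """Per-label mean pause duration with trajectory-bootstrap SD.

    Returns ``{label: {mean_s, bootstrap_sd, n_pauses, n_traces}}``; emits a
    warning entry when the dataset is smaller than the customary minimum of
    100 trajectories.
    """
    out: dict = {}
    df = pause_table[~pause_table["censored"]]
    n_traces = pause_table["trace_id"].nunique()
    for label, g in df.groupby("label"):
        est = bootstrap(
            {tid: gg["duration_s"].to_numpy() for tid, gg in g.groupby("trace_id")},
            statistic=np.mean,
            n_boot=n_boot,
            seed=seed,
        )
        out[label] = {
            "mean_s": est.value,
            "bootstrap_sd": est.sd,
            "n_pauses": int(len(g)),
            "n_traces": int(g["trace_id"].nunique()),
        }
    if n_traces < MIN_TRACES_WARNING:
        out["warning"] = (
            f"only {n_traces} trajectories; datasets customarily pool >= "
            f"{MIN_TRACES_WARNING} trajectories from >= 3 experiments"
        )
    return out
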