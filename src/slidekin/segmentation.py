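"""Pause/translocation segmentation of single-nucleosome FRET trajectories.

Remodeling trajectories alternate between constant-FRET *pauses* and brief
*translocation* phases during which the nucleosome moves along the DNA and
FRET drops.  Following ISWI nomenclature the first pause is the "wait" pause,
subsequent pauses are p1, p2, ...; translocation phases are t1, t2, ....

Segmentation is done with a discrete-state Gaussian HMM with a *sticky*
(self-transition-biased) transition matrix, which suppresses spurious
transitions from dye blinking and noise excursions.  The number of occupied
states is selected by BIC.  An exact dynamic-programming least-squares
changepoint fit (`oracle_segment`) provides an independent global-optimum
reference for testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from hmmlearn.hmm import GaussianHMM
from sklearn.base import BaseEstimator

from .calibration import CalibrationCurve

# hmmlearn reports EM convergence via logging; model selection handles
# non-converged candidates itself, so the per-fit chatter is noise here
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

__all__ = [
    "Segment",
    "Segmentation",
    "StatePath",
    "HMMSegmenter",
    "fit_hmm",
    "states_to_segments",
    "oracle_segment",
    "dp_changepoints",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One pause or translocation phase of a trajectory."""

    kind: str  # "pause" | "translocation"
    label: str  # wait | p1 | p2 | ... | t1 | t2 | ...
    start_s: float
    end_s: float
    fret_level: float | None = None  # pauses only
    start_frame: int | None = None
    end_frame: int | None = None  # exclusive
    censored: bool = False  # cut by trace end / bleach / truncation

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Segmentation:
    """Ordered, contiguous alternation of pause and translocation segments."""

    segments: list[Segment]
    trace_id: str | None = None
    frame_period_s: float | None = None
    truncated: bool = False
    truncation_reason: str | None = None

    def pauses(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "pause"]

    def translocations(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "translocation"]

    def pause_levels(self) -> list[float]:
        return [s.fret_level for s in self.pauses()]

    @property
    def initial_fret(self) -> float | None:
        p = self.pauses()
        return p[0].fret_level if p else None

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


@dataclass
class StatePath:
    """Per-frame MAP state sequence of a fitted discrete-state HMM."""

    states: np.ndarray  # int per frame
    means: np.ndarray  # emission mean per state index
    variances: np.ndarray
    log_likelihood: float
    bic: float
    n_states: int
    frame_period_s: float = field(default=1.0)

    @property
    def n_frames(self) -> int:
        return self.states.size


# ---------------------------------------------------------------------------
# exact least-squares changepoint fit (test oracle, also used for bleach steps)
# ---------------------------------------------------------------------------

def dp_changepoints(y: np.ndarray, n_changepoints: int):
    """Globally optimal least-squares piecewise-constant fit.

    Dynamic programming over all changepoint placements; returns
    ``(changepoints, sse)`` where changepoints are the first indices of each
    new segment (length ``n_changepoints``), and ``sse`` the residual sum of
    squares of the optimal fit.  Equivalent to exhaustive enumeration.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n_changepoints < 0:
        raise ValueError("n_changepoints must be >= 0")
    if n_changepoints >= n:
        raise ValueError("more changepoints than data points")
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost(a, b):
        # SSE of y[a:b] around its mean; a, b arrays or ints (b exclusive)
        num = s1[b] - s1[a]
        return s2[b] - s2[a] - num * num / (b - a)

    if n_changepoints == 0:
        return np.array([], dtype=int), float(seg_cost(0, n))

    # D[j] = optimal cost of fitting y[:j] with the current number of segments
    idx = np.arange(n + 1)
    D = np.full(n + 1, np.inf)
    D[1:] = seg_cost(0, idx[1:])
    back = np.zeros((n_changepoints, n + 1), dtype=int)
    for k in range(1, n_changepoints + 1):
        D_new = np.full(n + 1, np.inf)
        for b in range(k + 1, n + 1):
            a = np.arange(k, b)
            cand = D[a] + seg_cost(a, b)
            j = int(np.argmin(cand))
            D_new[b] = cand[j]
            back[k - 1, b] = a[j]
        D = D_new
    cps = []
    b = n
    for k in range(n_changepoints, 0, -1):
        b = int(back[k - 1, b])
        cps.append(b)
    return np.array(cps[::-1], dtype=int), float(D[n])


def oracle_segment(
    fret_series,
    max_changepoints: int,
    frame_period_s: float = 1.0,
    calib: CalibrationCurve | None = None,
    n_changepoints: int | None = None,
) -> Segmentation:
    """Exhaustive least-squares piecewise-constant segmentation (global optimum).

    Intended as an independent reference for testing the HMM path.  The
    number of changepoints is either fixed (``n_changepoints``) or selected
    up to ``max_changepoints`` by a BIC-type penalty on the Gaussian
    residual variance.
    """
    y = np.asarray(fret_series, dtype=float)
    n = y.size
    if n > 2000:
        raise ValueError("oracle_segment is limited to series of <= 2000 frames")
    if max_changepoints > 4:
        raise ValueError("oracle_segment is limited to <= 4 changepoints")
    if n_changepoints is not None:
        ks = [n_changepoints]
    else:
        ks = list(range(0, max_changepoints + 1))
    best = None
    for k in ks:
        cps, sse = dp_changepoints(y, k)
        score = n * np.log(sse / n + 1e-12) + 3.0 * k * np.log(n)
        if best is None or score < best[0]:
            best = (score, cps)
    cps = best[1]
    bounds = np.concatenate([[0], cps, [n]]).astype(int)
    states = np.zeros(n, dtype=int)
    means = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        states[a:b] = i
        means.append(float(np.mean(y[a:b])))
    path = StatePath(
        states=states,
        means=np.asarray(means),
        variances=np.full(len(means), float(np.var(y))),
        log_likelihood=np.nan,
        bic=np.nan,
        n_states=len(means),
        frame_period_s=frame_period_s,
    )
    return states_to_segments(path, calib=calib, frame_period_s=frame_period_s)


# ---------------------------------------------------------------------------
# sticky Gaussian HMM
# ---------------------------------------------------------------------------

class HMMSegmenter(BaseEstimator):
    """Discrete-state Gaussian HMM with a sticky transition prior.

    The transition matrix is held fixed at a large self-transition mass
    (``self_transition_bias`` on the diagonal, remainder spread uniformly),
    which penalizes short-lived excursions so that blinking and noise are not
    read as remodeling transitions.  Emission means/variances and the initial
    state distribution are learned by EM; the number of occupied states is
    chosen by BIC over ``1..max_states`` with early stopping.  Initialization
    is deterministic (emission means at data quantiles), so fits are
    reproducible without any hidden randomness.

    Parameters
    ----------
    max_states : int
        Largest candidate state count.
    self_transition_bias : float
        Diagonal mass of the fixed transition matrix (0 < bias < 1).
    min_dwell_frames : int
        State runs shorter than this are merged into the preceding run after
        Viterbi decoding.
    min_covar : float
        Variance floor for emissions (guards zero-noise input).
    bic_patience : int
        Stop growing the state count after this many consecutive BIC
        increases.

    Attributes
    ----------
    n_states_ : int
        Number of occupied states of the selected model.
    means_, variances_ : ndarray
        Emission parameters per state index of the selected model.
    state_path_ : ndarray of int
        MAP (Viterbi) state per frame, after minimum-dwell cleanup.
    log_likelihood_, bic_ : float
    initial_level_ : float
        Emission mean of the first dwell — the fitted initial FRET used by QC.
    """

    def __init__(
        self,
        max_states: int = 12,
        self_transition_bias: float = 0.995,
        min_dwell_frames: int = 3,
        min_covar: float = 1e-5,
        n_iter: int = 100,
        tol: float = 1e-4,
        bic_patience: int = 2,
        random_state: int = 0,
    ):
        self.max_states = max_states
        self.self_transition_bias = self_transition_bias
        self.min_dwell_frames = min_dwell_frames
        self.min_covar = min_covar
        self.n_iter = n_iter
        self.tol = tol
        self.bic_patience = bic_patience
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _make_model(self, k: int, y: np.ndarray) -> GaussianHMM:
        model = GaussianHMM(
            n_components=k,
            covariance_type="diag",
            min_covar=self.min_covar,
            n_iter=self.n_iter,
            tol=self.tol,
            params="smc",  # transmat stays fixed (sticky prior)
            init_params="",
            random_state=self.random_state,
        )
        model.startprob_ = np.full(k, 1.0 / k)
        if k == 1:
            model.transmat_ = np.ones((1, 1))
        else:
            off = (1.0 - self.self_transition_bias) / (k - 1)
            model.transmat_ = np.full((k, k), off)
            np.fill_diagonal(model.transmat_, self.self_transition_bias)
        # deterministic init: means spread over the full data range so that
        # sparsely occupied levels (e.g. a short wait pause) are still
        # captured; state 0 = high FRET
        means = np.linspace(np.max(y), np.min(y), k)
        # break exact ties so EM can separate states on constant input
        means = means + 1e-6 * np.arange(k)
        model.means_ = means.reshape(-1, 1)
        noise_var = max(self._noise_estimate(y) ** 2, self.min_covar)
        model.covars_ = np.full((k, 1), noise_var)
        return model

    @staticmethod
    def _noise_estimate(y: np.ndarray) -> float:
        # robust sd from first differences; insensitive to level changes
        d = np.diff(y)
        if d.size == 0:
            return 0.0
        return float(np.median(np.abs(d)) / (0.6745 * np.sqrt(2)))

    def fit(self, fret_series, mask=None):
        """Fit the segmenter to one FRET trajectory.

        Parameters
        ----------
        fret_series : array-like
            FRET efficiency per frame.
        mask : boolean array-like, optional
            Frames to exclude from fitting (e.g. blinks, where total
            intensity drops below background).  Excluded frames are assigned
            the state of the preceding retained frame in ``state_path_``.
        """
        y_full = np.asarray(fret_series, dtype=float).ravel()
        keep = np.isfinite(y_full)
        if mask is not None:
            keep &= ~np.asarray(mask, dtype=bool)
        y = y_full[keep]
        if y.size < 2 * self.min_dwell_frames:
            raise ValueError(
                f"series too short: {y.size} usable frames "
                f"(need >= {2 * self.min_dwell_frames})"
            )
        X = y.reshape(-1, 1)
        n = y.size
        best = None
        n_worse = 0
        for k in range(1, self.max_states + 1):
            if k > n:
                break
            model = self._make_model(k, y)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(X)
                    ll = float(model.score(X))
            except (ValueError, FloatingPointError):
                continue
            if not np.isfinite(ll):
                continue
            n_params = 2 * k + (k - 1)
            bic = -2.0 * ll + n_params * np.log(n)
            if best is None or bic < best[0]:
                best = (bic, k, model, ll)
                n_worse = 0
            else:
                n_worse += 1
                if n_worse >= self.bic_patience:
                    break
        if best is None:
            raise RuntimeError("HMM fit failed for every candidate state count")
        bic, k, model, ll = best
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            states = model.predict(X)
        states = self._enforce_min_dwell(states)
        # map back onto the full frame grid (masked frames inherit neighbor)
        full_states = np.empty(y_full.size, dtype=int)
        idx = np.flatnonzero(keep)
        full_states[idx] = states
        if idx.size and idx[0] > 0:
            full_states[: idx[0]] = states[0]
        pos = np.searchsorted(idx, np.arange(y_full.size), side="right") - 1
        pos = np.clip(pos, 0, idx.size - 1)
        full_states = full_states[idx[pos]]

        self.means_ = model.means_.ravel().copy()
        self.variances_ = model.covars_.ravel().copy()
        self.log_likelihood_ = ll
        self.bic_ = bic
        self.state_path_ = full_states
        self.n_states_ = int(np.unique(full_states).size)
        self.initial_level_ = float(self.means_[full_states[0]])
        return self

    def _enforce_min_dwell(self, states: np.ndarray) -> np.ndarray:
        if self.min_dwell_frames <= 1:
            return states
        states = states.copy()
        changed = True
        while changed:
            changed = False
            runs = _runs(states)
            if len(runs) <= 1:
                break
            for i, (s, a, b) in enumerate(runs):
                if b - a < self.min_dwell_frames:
                    tgt = runs[i - 1][0] if i > 0 else runs[i + 1][0]
                    states[a:b] = tgt
                    changed = True
                    break
        return states

    def to_state_path(self, frame_period_s: float = 1.0) -> StatePath:
        return StatePath(
            states=self.state_path_,
            means=self.means_,
            variances=self.variances_,
            log_likelihood=self.log_likelihood_,
            bic=self.bic_,
            n_states=self.n_states_,
            frame_period_s=frame_period_s,
        )


def fit_hmm(
    fret_series,
    max_states: int = 12,
    self_transition_bias: float = 0.995,
    min_dwell_frames: int = 3,
    seed: int = 0,
    frame_period_s: float = 1.0,
    mask=None,
) -> StatePath:
    """Functional wrapper around :class:`HMMSegmenter`."""
    seg = HMMSegmenter(
        max_states=max_states,
        self_transition_bias=self_transition_bias,
        min_dwell_frames=min_dwell_frames,
        random_state=seed,
    ).fit(fret_series, mask=mask)
    return seg.to_state_path(frame_period_s=frame_period_s)


def _runs(states: np.ndarray):
    """Contiguous constant runs as (state, start, end_exclusive)."""
    change = np.flatnonzero(np.diff(states) != 0) + 1
    bounds = np.concatenate([[0], change, [states.size]])
    return [
        (int(states[a]), int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])
    ]


# ---------------------------------------------------------------------------
# state path -> labeled segments
# ---------------------------------------------------------------------------

def states_to_segments(
    path: StatePath,
    calib: CalibrationCurve | None = None,
    translocation_min_dbp: float = 1.0,
    frame_period_s: float | None = None,
    t0: float = 0.0,
    trace_id: str | None = None,
) -> Segmentation:
    """Convert a per-frame state path into labeled pause/translocation segments.

    Runs of a constant state become pauses at the state's emission mean.
    Adjacent runs whose level difference is below ``translocation_min_dbp``
    base pairs (via the calibration curve; ties merge) are merged into a
    single pause.  Each inter-pause transition becomes a translocation
    segment spanning one frame period (transitions faster than the sampling
    interval are censored at one frame).  Labels follow the wait/t1/p1/t2/p2
    convention; the wait-pause clock starts at ``t0`` (enzyme injection).
    """
    if path.n_frames == 0:
        raise ValueError("empty state path")
    dt = frame_period_s if frame_period_s is not None else path.frame_period_s
    runs = _runs(path.states)
    levels = [float(np.clip(path.means[s], -0.1, 1.1)) for s, _, _ in runs]
    spans = [(a, b) for _, a, b in runs]

    def dbp(f1: float, f2: float) -> float:
        if calib is None:
            # fall back to a FRET-difference criterion when no curve is given
            return abs(f2 - f1) * 20.0
        b1 = calib.fret_to_bp(f1, clamp=True)
        b2 = calib.fret_to_bp(f2, clamp=True)
        return abs(b2 - b1)

    # merge runs whose separation is below the minimum translocation distance
    merged = True
    while merged and len(levels) > 1:
        merged = False
        for i in range(len(levels) - 1):
            if dbp(levels[i], levels[i + 1]) <= translocation_min_dbp:
                a0, b0 = spans[i]
                a1, b1 = spans[i + 1]
                w0, w1 = b0 - a0, b1 - a1
                levels[i] = (levels[i] * w0 + levels[i + 1] * w1) / (w0 + w1)
                spans[i] = (a0, b1)
                del levels[i + 1], spans[i + 1]
                merged = True
                break

    segments: list[Segment] = []
    n_frames = path.n_frames
    for i, ((a, b), lvl) in enumerate(zip(spans, levels)):
        p_label = "wait" if i == 0 else f"p{i}"
        # pauses span their frames; the transition spans the final frame gap
        start_s = t0 + a * dt
        end_s = t0 + (b - 1) * dt if i < len(spans) - 1 else t0 + b * dt
        if i > 0:
            segments.append(
                Segment(
                    kind="translocation",
                    label=f"t{i}",
                    start_s=t0 + (a - 1) * dt,
                    end_s=start_s,
                    start_frame=a - 1,
                    end_frame=a,
                    censored=True,  # duration below one frame is unresolved
                )
            )
        segments.append(
            Segment(
                kind="pause",
                label=p_label,
                start_s=start_s,
                end_s=end_s,
                fret_level=lvl,
                start_frame=a,
                end_frame=b,
                censored=(b == n_frames),  # last pause is cut by the trace end
            )
        )
    return Segmentation(
        segments=segments, trace_id=trace_id, frame_period_s=dt
    )


def relabel(segmentation: Segmentation) -> Segmentation:
    """Reassign wait/t1/p1/... labels after segments have been removed."""
    out = []
    i_pause = 0
    i_trans = 0
    for seg in segmentation.segments:
        if seg.kind == "pause":
            label = "wait" if i_pause == 0 else f"p{i_pause}"
            i_pause += 1
        else:
            i_trans += 1
            label = f"t{i_trans}"
        out.append(replace(seg, label=label))
    return Segmentation(
        segments=out,
        trace_id=segmentation.trace_id,
        frame_period_s=segmentation.frame_period_s,
        truncated=segmentation.truncated,
        truncation_reason=segmentation.truncation_reason,
    )
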