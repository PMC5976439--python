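"""Synthetic data generators for every pipeline stage.

The trajectory simulator emulates single-molecule FRET remodeling traces:
an immobilized, end-positioned nucleosome (bp-from-end = 0) is moved in
alternating pause/translocation phases.  Pause durations are exponential
with index-dependent means (wait, p1, p2+); each translocation covers a
distance drawn around the configured step mean (defaults ~8 bp first, ~5 bp
after) realized as successive 1-2 bp elementary sub-steps at a constant
speed.  The donor-label stoichiometry follows the 2:1 unlabeled:labeled H3
mixing used experimentally, giving proximal-only, distal-only, both- and
unlabeled populations; photobleaching, blinking and Gaussian camera noise
are applied on top of the two-channel intensity model (donor + acceptor
conserved per active dye before bleaching).

Ensemble generators produce titration, inhibition and ATPase time courses
directly from the kinetic models that the fitting stage estimates, and the
crosslinking-MS generator produces CSM tables with target/decoy labels,
class-separated classifier features, ambiguous site localizations and
configurable between-condition domain-pair enrichment.

Every generator takes an explicit seed; identical configs and seeds give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .ensemble import EnsembleTimeCourse
from .qc import Trajectory
from .xlms import FEATURE_COLUMNS, DomainMap, default_domain_map

__all__ = [
    "TrajectorySimConfig",
    "GroundTruth",
    "GTSegment",
    "simulate_trajectory",
    "simulate_trajectory_set",
    "simulate_titration",
    "simulate_inhibition_series",
    "simulate_atpase_timecourse",
    "XlmsSimConfig",
    "simulate_xlms_csms",
]

LABEL_CLASSES = ("proximal", "distal", "both", "none")


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySimConfig:
    """Study conditions for the smFRET trajectory generator.

    Defaults follow the experimental acquisition (7.4 Hz, 100 ms exposure,
    2:1 unlabeled:labeled H3 so each H3 carries a dye with probability 1/3)
    and the observed kinetic structure (~8 bp first step, ~5 bp subsequent
    steps, 1-2 bp elementary sub-steps).  Quantities the experiments do not
    constrain (translocation speed, bleach/blink rates, step dispersions)
    carry field-realistic defaults documented in the methods note.
    """

    n_frames: int = 1110
    frame_rate_hz: float = 7.4
    exposure_s: float = 0.1
    wait_mean_s: float = 20.0
    p1_mean_s: float = 10.0
    p2plus_mean_s: float = 10.0
    step1_bp_mean: float = 8.0
    step2plus_bp_mean: float = 5.0
    step1_bp_sd: float = 2.0
    step2plus_bp_sd: float = 1.5
    substep_bp: float = 1.0
    translocation_rate_bp_per_s: float = 40.0
    labeled_fraction: float = 1.0 / 3.0
    bleach_mean_s: float | None = 600.0  # per dye; None disables bleaching
    blink_rate_per_s: float = 0.005
    blink_mean_s: float = 0.3
    noise_sd: float = 0.05
    backtrack_prob: float = 0.05
    total_intensity: float = 1.0
    distal_fret_scale: float = 0.6  # mid-FRET cluster 0.57 / high 0.95

    def validate(self):
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.frame_rate_hz <= 0 or self.exposure_s <= 0:
            raise ValueError("sampling parameters must be positive")
        for name in (
            "wait_mean_s", "p1_mean_s", "p2plus_mean_s",
            "step1_bp_mean", "step2plus_bp_mean", "substep_bp",
            "translocation_rate_bp_per_s", "total_intensity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "step1_bp_sd", "step2plus_bp_sd", "blink_rate_per_s",
            "blink_mean_s", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must lie in [0, 1]")
        if not 0.0 <= self.backtrack_prob <= 1.0:
            raise ValueError("backtrack_prob must lie in [0, 1]")
        if self.bleach_mean_s is not None and self.bleach_mean_s <= 0:
            raise ValueError("bleach_mean_s must be > 0 or None")
        if not 0.5 <= self.substep_bp <= 2.0:
            raise ValueError("elementary sub-steps are 1-2 bp (0.5-2 allowed)")

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass(frozen=True)
class GTSegment:
    kind: str  # "pause" | "translocation"
    start_s: float
    end_s: float
    start_bp: float
    end_bp: float
    backtrack: bool = False


@dataclass
class GroundTruth:
    """True kinetic path and photophysics of one simulated trajectory."""

    segments: list[GTSegment]
    label_class: str
    donor_bleach_times: list[float]
    acceptor_bleach_time: float | None
    blink_intervals: list[tuple[float, float]]
    bp_at_frames: np.ndarray
    config: TrajectorySimConfig

    def __post_init__(self):
        for a, b in zip(self.segments[:-1], self.segments[1:]):
            if not np.isclose(a.end_s, b.start_s):
                raise ValueError("ground-truth segments must be contiguous")

    def pause_durations(self) -> list[float]:
        return [
            s.end_s - s.start_s for s in self.segments if s.kind == "pause"
        ]

    def step_sizes(self) -> list[float]:
        return [
            s.end_bp - s.start_bp
            for s in self.segments
            if s.kind == "translocation"
        ]


def _simulate_kinetic_path(config: TrajectorySimConfig, bp_max: float, rng):
    """Continuous-time alternating pause/translocation path, clamped to
    [0, bp_max]; returns ground-truth segments covering [0, duration]."""
    T = config.duration_s
    t, bp = 0.0, 0.0
    segments: list[GTSegment] = []
    pause_idx = 0
    while t < T:
        mean = (
            config.wait_mean_s if pause_idx == 0
            else config.p1_mean_s if pause_idx == 1
            else config.p2plus_mean_s
        )
        dwell = rng.exponential(mean)
        seg_end = min(t + dwell, T)
        segments.append(GTSegment("pause", t, seg_end, bp, bp))
        t = seg_end
        if t >= T:
            break
        # translocation event
        step_mean = config.step1_bp_mean if pause_idx == 0 else config.step2plus_bp_mean
        step_sd = config.step1_bp_sd if pause_idx == 0 else config.step2plus_bp_sd
        if step_sd == 0:
            size = step_mean
        else:
            size = rng.normal(step_mean, step_sd)
        n_sub = max(1, int(round(size / config.substep_bp)))
        size = n_sub * config.substep_bp
        direction = -1.0 if (bp > 0 and rng.random() < config.backtrack_prob) else 1.0
        target = np.clip(bp + direction * size, 0.0, bp_max)
        realized = target - bp
        if realized == 0.0:
            # already at the boundary: absorbing final pause
            segments[-1] = replace(segments[-1], end_s=T)
            t = T
            break
        dur = abs(realized) / config.translocation_rate_bp_per_s
        seg_end = min(t + dur, T)
        segments.append(
            GTSegment(
                "translocation", t, seg_end, bp,
                bp + realized * (seg_end - t) / dur if dur > 0 else target,
                backtrack=direction < 0,
            )
        )
        bp = segments[-1].end_bp
        t = seg_end
        pause_idx += 1
    return segments


def _bp_at(segments: list[GTSegment], times: np.ndarray) -> np.ndarray:
    bp = np.empty_like(times)
    starts = np.array([s.start_s for s in segments])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(segments) - 1)
    for i, (ti, j) in enumerate(zip(times, idx)):
        s = segments[j]
        if s.kind == "pause" or s.end_s == s.start_s:
            bp[i] = s.start_bp
        else:
            frac = (ti - s.start_s) / (s.end_s - s.start_s)
            bp[i] = s.start_bp + frac * (s.end_bp - s.start_bp)
    return bp


def _blink_intervals(rate: float, mean_dark: float, T: float, rng):
    out = []
    if rate <= 0 or mean_dark <= 0:
        return out
    t = rng.exponential(1.0 / rate)
    while t < T:
        dark = rng.exponential(mean_dark)
        out.append((t, min(t + dark, T)))
        t = t + dark + rng.exponential(1.0 / rate)
    return out


def simulate_trajectory(
    config: TrajectorySimConfig,
    calib: CalibrationCurve,
    seed,
    label_class: str | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one two-channel smFRET remodeling trajectory.

    ``label_class`` forces the H3 labeling class; by default it is drawn from
    the Bernoulli(labeled_fraction) per-H3 mixture.  Returns the trajectory
    (time, donor, acceptor) and the ground truth used to generate it.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if label_class is None:
        prox = rng.random() < config.labeled_fraction
        dist = rng.random() < config.labeled_fraction
        label_class = (
            "both" if (prox and dist)
            else "proximal" if prox
            else "distal" if dist
            else "none"
        )
    elif label_class not in LABEL_CLASSES:
        raise ValueError(f"unknown label class {label_class!r}")

    segments = _simulate_kinetic_path(config, calib.bp_max, rng)
    dt = config.frame_period_s
    times = np.arange(config.n_frames) * dt
    bp = _bp_at(segments, times)
    e_prox = calib.bp_to_fret(np.clip(bp, calib.bp_min, calib.bp_max))
    e_dist = config.distal_fret_scale * e_prox

    T = config.duration_s
    donor_dyes = []  # (efficiency series, bleach time, blink intervals)
    if label_class in ("proximal", "both"):
        donor_dyes.append(e_prox)
    if label_class in ("distal", "both"):
        donor_dyes.append(e_dist)
    if config.bleach_mean_s is None:
        donor_bleach = [np.inf] * len(donor_dyes)
        acceptor_bleach = np.inf
    else:
        donor_bleach = [float(rng.exponential(config.bleach_mean_s)) for _ in donor_dyes]
        acceptor_bleach = float(rng.exponential(config.bleach_mean_s))
    blink_all: list[tuple[float, float]] = []
    blinks_per_dye = []
    for _ in donor_dyes:
        b = _blink_intervals(config.blink_rate_per_s, config.blink_mean_s, T, rng)
        blinks_per_dye.append(b)
        blink_all.extend(b)

    I0 = config.total_intensity
    donor = np.zeros(config.n_frames)
    acceptor = np.zeros(config.n_frames)
    acc_alive = times < acceptor_bleach
    for e, tb, blinks in zip(donor_dyes, donor_bleach, blinks_per_dye):
        active = times < tb
        for a, b in blinks:
            active &= ~((times >= a) & (times < b))
        donor += np.where(active, np.where(acc_alive, I0 * (1 - e), I0), 0.0)
        acceptor += np.where(active & acc_alive, I0 * e, 0.0)
    if config.noise_sd > 0:
        donor = donor + rng.normal(0.0, config.noise_sd * I0, config.n_frames)
        acceptor = acceptor + rng.normal(0.0, config.noise_sd * I0, config.n_frames)

    traj = Trajectory(
        time_s=times,
        donor=donor,
        acceptor=acceptor,
        meta={"label_class": label_class, "seed": seed},
    )
    gt = GroundTruth(
        segments=segments,
        label_class=label_class,
        donor_bleach_times=[t for t in donor_bleach if np.isfinite(t)],
        acceptor_bleach_time=(
            acceptor_bleach if np.isfinite(acceptor_bleach) else None
        ),
        blink_intervals=blink_all,
        bp_at_frames=bp,
        config=config,
    )
    return traj, gt


def simulate_trajectory_set(
    config: TrajectorySimConfig,
    calib: CalibrationCurve,
    n_traj: int,
    seed,
    label_class: str | None = None,
) -> list[tuple[Trajectory, GroundTruth]]:
    """Simulate ``n_traj`` independent trajectories.

    Label classes are drawn per trajectory from two independent
    Bernoulli(labeled_fraction) draws (one per H3 copy) unless forced with
    ``label_class``.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    config.validate()
    children = np.random.SeedSequence(seed).spawn(n_traj)
    out = []
    for i in range(n_traj):
        traj, gt = simulate_trajectory(
            config, calib, children[i], label_class=label_class
        )
        traj.meta["trace_id"] = f"sim{i:05d}"
        out.append((traj, gt))
    return out


# ---------------------------------------------------------------------------
# ensemble generators
# ---------------------------------------------------------------------------

def _hill_kobs(X, k_max, K_m_app, h):
    return k_max * X**h / (K_m_app**h + X**h)


def simulate_titration(
    model: dict,
    concentrations,
    timepoints,
    noise_sd: float = 0.0,
    seed=None,
    y0: float = 0.95,
    p: float = 0.05,
) -> list[EnsembleTimeCourse]:
    """Fraction-end-positioned time courses across an enzyme titration.

    For each concentration X the observed rate follows the cooperative
    binding model ``k_obs = k_max X^h / (K_m_app^h + X^h)``; the time course
    is the single-exponential decay with shared y0 and plateau p, plus
    optional additive Gaussian noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    k_max, K_m, h = model["k_max"], model["K_m_app"], model["h"]
    if min(k_max, K_m, h) <= 0:
        raise ValueError("model parameters must be > 0")
    X = np.asarray(concentrations, dtype=float)
    if np.any(X <= 0):
        raise ValueError("concentrations must be > 0")
    t = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for x in X:
        k = _hill_kobs(x, k_max, K_m, h)
        y = (y0 - p) * np.exp(-k * t) + p
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, t.size)
        out.append(
            EnsembleTimeCourse(
                t=t, y=y,
                meta={"concentration": float(x), "k_obs_true": float(k)},
            )
        )
    return out


def simulate_inhibition_series(
    k0: float, K_I: float, peptide_concs, noise_sd: float = 0.0, seed=None
) -> pd.DataFrame:
    """Observed rate vs competitor-peptide concentration, Eq.-3 style."""
    if k0 <= 0 or K_I <= 0:
        raise ValueError("k0 and K_I must be > 0")
    X = np.asarray(peptide_concs, dtype=float)
    if np.any(X < 0):
        raise ValueError("concentrations must be nonnegative")
    k = k0 / (1.0 + X / K_I)
    if noise_sd > 0:
        k = k + np.random.default_rng(seed).normal(0.0, noise_sd, X.size)
    return pd.DataFrame({"X": X, "k_obs": k})


def simulate_atpase_timecourse(
    rate: float, timepoints, total_atp: float, noise_sd: float = 0.0, seed=None
) -> pd.DataFrame:
    """Inorganic phosphate vs time: linear at ``rate`` until curvature onset
    (10% of total ATP consumed), then a single-exponential approach to
    ``total_atp``; the two phases join with matching slope."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if total_atp <= 0:
        raise ValueError("total_atp must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(timepoints, dtype=float)
    if rate == 0:
        pi = np.zeros_like(t)
    else:
        onset = 0.1 * total_atp / rate
        remaining = 0.9 * total_atp
        pi = np.where(
            t <= onset,
            rate * t,
            total_atp - remaining * np.exp(-rate * (t - onset) / remaining),
        )
    if noise_sd > 0:
        pi = pi + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return pd.DataFrame({"t": t, "Pi": pi})


# ---------------------------------------------------------------------------
# crosslinking-MS generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class XlmsSimConfig:
    """Study conditions for the CSM-table generator.

    Classifier features are Gaussian per class with class-separated means
    (the search engine reports the feature names only); ambiguity draws a
    candidate count k > 1 with the given distribution; the enrichment map
    multiplies the sampling weight of specific domain pairs in condition B
    relative to condition A.
    """

    n_target_csms: int = 1000  # per condition
    n_decoy_csms: int = 100
    decoy_multiplicity: int = 10
    conditions: tuple[str, str] = ("ADP", "ADP-BeFx")
    condition_enrichment: dict = field(default_factory=dict)
    ambiguity_prob: float = 0.2
    ambiguity_k_probs: dict = field(
        default_factory=lambda: {2: 0.8, 3: 0.15, 4: 0.05}
    )
    target_feature_means: dict = field(
        default_factory=lambda: {
            "score_difference": 15.0,
            "pct_product_ions_matched": 60.0,
            "precursor_charge": 4.0,
            "rank_peptide1": 1.0,
            "rank_peptide2": 1.0,
        }
    )
    decoy_feature_means: dict = field(
        default_factory=lambda: {
            "score_difference": 1.0,
            "pct_product_ions_matched": 25.0,
            "precursor_charge": 4.0,
            "rank_peptide1": 3.0,
            "rank_peptide2": 3.0,
        }
    )
    feature_sds: dict = field(
        default_factory=lambda: {
            "score_difference": 3.0,
            "pct_product_ions_matched": 8.0,
            "precursor_charge": 1.0,
            "rank_peptide1": 0.4,
            "rank_peptide2": 0.4,
        }
    )

    def validate(self):
        if self.n_target_csms < 0 or self.n_decoy_csms < 0:
            raise ValueError("CSM counts must be >= 0")
        if self.decoy_multiplicity < 1:
            raise ValueError("decoy_multiplicity must be >= 1")
        if not 0.0 <= self.ambiguity_prob <= 1.0:
            raise ValueError("ambiguity_prob must lie in [0, 1]")
        if any(k < 2 for k in self.ambiguity_k_probs):
            raise ValueError("ambiguous CSMs have k >= 2 candidates")
        if any(m <= 0 for m in self.condition_enrichment.values()):
            raise ValueError("enrichment multipliers must be > 0")


def _draw_features(means: dict, sds: dict, rng) -> dict:
    out = {}
    for f in FEATURE_COLUMNS:
        v = rng.normal(means[f], sds[f])
        if f == "precursor_charge":
            v = int(np.clip(round(v), 2, 8))
        elif f.startswith("rank"):
            v = int(np.clip(round(v), 1, 10))
        out[f] = v
    return out


def _domain_pair_key(d1: str, d2: str):
    return tuple(sorted((d1, d2)))


def simulate_xlms_csms(
    config: XlmsSimConfig,
    domain_map: DomainMap | None = None,
    seed=None,
) -> pd.DataFrame:
    """Generate a CSM table over the given domain map.

    Target CSMs pick a domain pair (condition-B weights scaled by the
    enrichment map), then residues uniformly within each domain; ambiguous
    CSMs add nearby same-domain candidate residues.  Decoy CSMs draw random
    residue pairs from randomized-copy decoy proteins and decoy-class
    features.
    """
    config.validate()
    if domain_map is None:
        domain_map = default_domain_map()
    if not domain_map.domains:
        raise ValueError("empty domain map")
    rng = np.random.default_rng(seed)

    dom_entries = [
        (prot, name, start, end)
        for prot, doms in domain_map.domains.items()
        for name, start, end in doms
    ]
    n_dom = len(dom_entries)
    pair_idx = [(i, j) for i in range(n_dom) for j in range(i, n_dom)]
    base_w = np.ones(len(pair_idx))

    def pair_weights(condition_index: int) -> np.ndarray:
        w = base_w.copy()
        if condition_index == 1 and config.condition_enrichment:
            for k, (i, j) in enumerate(pair_idx):
                di = f"{dom_entries[i][0]}:{dom_entries[i][1]}"
                dj = f"{dom_entries[j][0]}:{dom_entries[j][1]}"
                mult = config.condition_enrichment.get(
                    _domain_pair_key(di, dj)
                )
                if mult is not None:
                    w[k] *= mult
        return w / w.sum()

    def draw_candidates(prot2, res2, start2, end2, prot1, res1):
        cands = [(prot1, res1, prot2, res2)]
        if rng.random() < config.ambiguity_prob:
            ks = sorted(config.ambiguity_k_probs)
            probs = np.array([config.ambiguity_k_probs[k] for k in ks], dtype=float)
            k = int(rng.choice(ks, p=probs / probs.sum()))
            offsets = rng.permutation([-3, -2, -1, 1, 2, 3])
            for off in offsets:
                if len(cands) >= k:
                    break
                r = res2 + int(off)
                if start2 <= r <= end2 and (prot1, res1, prot2, r) not in cands:
                    cands.append((prot1, res1, prot2, r))
        return cands

    rows = []
    sid = 0
    for ci, cond in enumerate(config.conditions):
        w = pair_weights(ci)
        for _ in range(config.n_target_csms):
            i, j = pair_idx[int(rng.choice(len(pair_idx), p=w))]
            p1, _, s1, e1 = dom_entries[i]
            p2, _, s2, e2 = dom_entries[j]
            r1 = int(rng.integers(s1, e1 + 1))
            r2 = int(rng.integers(s2, e2 + 1))
            rows.append(
                {
                    "spectrum_id": f"csm{sid:06d}",
                    "condition": cond,
                    "decoy": False,
                    "candidates": draw_candidates(p2, r2, s2, e2, p1, r1),
                    **_draw_features(
                        config.target_feature_means, config.feature_sds, rng
                    ),
                }
            )
            sid += 1
        for _ in range(config.n_decoy_csms):
            i, j = pair_idx[int(rng.choice(len(pair_idx)))]
            p1, _, s1, e1 = dom_entries[i]
            p2, _, s2, e2 = dom_entries[j]
            c1 = int(rng.integers(1, config.decoy_multiplicity + 1))
            c2 = int(rng.integers(1, config.decoy_multiplicity + 1))
            rows.append(
                {
                    "spectrum_id": f"csm{sid:06d}",
                    "condition": cond,
                    "decoy": True,
                    "candidates": [
                        (
                            f"decoy{c1}_{p1}", int(rng.integers(s1, e1 + 1)),
                            f"decoy{c2}_{p2}", int(rng.integers(s2, e2 + 1)),
                        )
                    ],
                    **_draw_features(
                        config.decoy_feature_means, config.feature_sds, rng
                    ),
                }
            )
            sid += 1
    return pd.DataFrame(rows)
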