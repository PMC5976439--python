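"""Ensemble remodeling and ATPase kinetics fits.

Models
------
single exponential    y(t) = (y0 - p) e^(-k_obs t) + p
cooperative binding   k_obs(X) = k_max X^h / (K_m_app^h + X^h)
competition binding   k_obs(X) = k0 / (1 + X / K_I)
two-phase decay       y(t) = p + (y0 - p)[f_fast e^(-k_fast t)
                                          + (1 - f_fast) e^(-k_slow t)]
ATPase initial rate   OLS slope of Pi(t) over the first `fraction` of total ATP

Remodeling titrations are analyzed in two stages, matching the experimental
workflow: time courses at each enzyme concentration are fit to the single
exponential with y0 and the plateau p shared across the series, and the
per-concentration k_obs values are then fit to the cooperative binding model.

All fits are trust-region nonlinear least squares (scipy) with physically
motivated bounds (rates nonnegative, fractions in [0, 1]); standard errors
come from the Jacobian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "EnsembleTimeCourse",
    "KineticFitResult",
    "SingleExponentialDecay",
    "HillCurve",
    "CompetitionCurve",
    "TwoPhaseExponentialDecay",
    "InitialRate",
    "fit_single_exponential",
    "fit_hill",
    "fit_competition",
    "fit_two_phase",
    "fit_initial_rate",
]


@dataclass
class EnsembleTimeCourse:
    """One ensemble observable vs time (fraction end-positioned, FRET, Pi)."""

    t: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have the same shape")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("t must be nondecreasing")


@dataclass
class KineticFitResult:
    model: str
    params: dict
    se: dict
    residual_norm: float
    converged: bool
    n_points: int
    flags: list[str] = field(default_factory=list)
    message: str | None = None
    extras: dict = field(default_factory=dict)


def _se_from_jacobian(jac: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    n, p = jac.shape
    dof = max(n - p, 1)
    sigma2 = float(residuals @ residuals) / dof
    cov = sigma2 * np.linalg.pinv(jac.T @ jac)
    var = np.clip(np.diag(cov), 0.0, np.inf)
    return np.sqrt(var)


def _ls(resid_fn, x0, bounds, n_points):
    sol = least_squares(
        resid_fn, x0, bounds=bounds, method="trf", xtol=1e-14, ftol=1e-14,
        gtol=1e-14, max_nfev=20000,
    )
    se = _se_from_jacobian(sol.jac, sol.fun)
    return sol, se


# ---------------------------------------------------------------------------
# single exponential (optionally with shared y0, p across a series set)
# ---------------------------------------------------------------------------

def _exp1(t, y0, k, p):
    return (y0 - p) * np.exp(-k * t) + p


class SingleExponentialDecay(BaseEstimator):
    """Fit ``y = (y0 - p) e^(-k_obs t) + p`` to one time course."""

    def __init__(self, y0_init=None, k_init=None, p_init=None):
        self.y0_init = y0_init
        self.k_init = k_init
        self.p_init = p_init

    def fit(self, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.size < 4:
            raise ValueError("need >= 4 points for a single-exponential fit")
        y0_0 = self.y0_init if self.y0_init is not None else float(y[0])
        p_0 = self.p_init if self.p_init is not None else float(y[-1])
        k_0 = self.k_init if self.k_init is not None else _guess_rate(t, y, y0_0, p_0)
        x0 = [y0_0, max(k_0, 1e-9), p_0]
        lo = [-np.inf, 0.0, -np.inf]
        hi = [np.inf, np.inf, np.inf]
        sol, se = _ls(lambda th: _exp1(t, th[0], th[1], th[2]) - y, x0, (lo, hi), t.size)
        self.y0_, self.k_obs_, self.p_ = map(float, sol.x)
        self.flags_ = []
        if abs(self.y0_ - self.p_) < 1e-8 * max(1.0, abs(self.y0_)):
            # zero amplitude: the rate is unidentifiable on a flat series
            self.k_obs_ = 0.0
            self.flags_.append("zero_amplitude")
        self.se_ = dict(zip(("y0", "k_obs", "p"), map(float, se)))
        self.residual_norm_ = float(np.linalg.norm(sol.fun))
        self.converged_ = bool(sol.success)
        self.n_points_ = t.size
        return self

    def predict(self, t):
        return _exp1(np.asarray(t, dtype=float), self.y0_, self.k_obs_, self.p_)

    def result(self) -> KineticFitResult:
        return KineticFitResult(
            model="single_exponential",
            params={"y0": self.y0_, "k_obs": self.k_obs_, "p": self.p_},
            se=self.se_,
            residual_norm=self.residual_norm_,
            converged=self.converged_,
            n_points=self.n_points_,
            flags=list(self.flags_),
        )


def _guess_rate(t, y, y0, p) -> float:
    span = y0 - p
    if abs(span) < 1e-12:
        return 1e-3
    z = (y - p) / span
    good = (z > 1e-3) & (t > 0)
    if good.sum() < 2:
        return 1.0 / max(float(t[-1]), 1e-9)
    slope, _ = np.polyfit(t[good], np.log(z[good]), 1)
    return max(-float(slope), 1e-9)


def fit_single_exponential(series, share=None):
    """Fit Eq.-1-type decays; optionally share y0 and p across a series set.

    Parameters
    ----------
    series : EnsembleTimeCourse or (t, y) or sequence thereof
    share : set or None
        If it contains both ``"y0"`` and ``"p"``, all series are fit jointly
        with a common initial value and plateau and a per-series k_obs.

    Returns a :class:`KineticFitResult` (single series) or a list of them.
    """
    many, courses = _as_courses(series)
    if share and {"y0", "p"} <= set(share) and many:
        return _fit_exp1_shared(courses)
    results = []
    for c in courses:
        est = SingleExponentialDecay().fit(c.t, c.y)
        res = est.result()
        res.extras["meta"] = c.meta
        results.append(res)
    return results if many else results[0]


def _as_courses(series):
    if isinstance(series, EnsembleTimeCourse):
        return False, [series]
    if isinstance(series, tuple) and len(series) == 2 and np.ndim(series[0]) == 1:
        return False, [EnsembleTimeCourse(series[0], series[1])]
    out = []
    for s in series:
        if isinstance(s, EnsembleTimeCourse):
            out.append(s)
        else:
            out.append(EnsembleTimeCourse(s[0], s[1]))
    return True, out


def _fit_exp1_shared(courses):
    m = len(courses)
    for c in courses:
        if c.t.size < 4:
            raise ValueError("each series needs >= 4 points")
    singles = [SingleExponentialDecay().fit(c.t, c.y) for c in courses]
    y0_0 = float(np.mean([s.y0_ for s in singles]))
    p_0 = float(np.mean([s.p_ for s in singles]))
    k_0 = [max(s.k_obs_, 1e-9) for s in singles]
    x0 = np.array([y0_0, p_0] + k_0)
    lo = np.array([-np.inf, -np.inf] + [0.0] * m)
    hi = np.full(2 + m, np.inf)

    def resid(th):
        y0, p = th[0], th[1]
        return np.concatenate(
            [_exp1(c.t, y0, th[2 + i], p) - c.y for i, c in enumerate(courses)]
        )

    sol, se = _ls(resid, x0, (lo, hi), sum(c.t.size for c in courses))
    y0, p = float(sol.x[0]), float(sol.x[1])
    results = []
    off = 0
    for i, c in enumerate(courses):
        r = sol.fun[off : off + c.t.size]
        off += c.t.size
        results.append(
            KineticFitResult(
                model="single_exponential_shared",
                params={"y0": y0, "k_obs": float(sol.x[2 + i]), "p": p},
                se={
                    "y0": float(se[0]),
                    "p": float(se[1]),
                    "k_obs": float(se[2 + i]),
                },
                residual_norm=float(np.linalg.norm(r)),
                converged=bool(sol.success),
                n_points=c.t.size,
                extras={"meta": c.meta},
            )
        )
    return results


# ---------------------------------------------------------------------------
# cooperative (Hill) binding of the titration
# ---------------------------------------------------------------------------

def _hill(X, k_max, K_m, h):
    Xh = np.power(X, h)
    return k_max * Xh / (np.power(K_m, h) + Xh)


class HillCurve(BaseEstimator):
    """Fit ``k_obs = k_max X^h / (K_m_app^h + X^h)``."""

    def __init__(self, fix_h=None):
        self.fix_h = fix_h

    def fit(self, X, k_obs):
        X = np.asarray(X, dtype=float)
        k = np.asarray(k_obs, dtype=float)
        ok = X > 0
        if (~ok).any():
            X, k = X[ok], k[ok]
        if np.unique(X).size < 4:
            raise ValueError("need >= 4 distinct positive concentrations")
        k_max0 = float(np.max(k))
        K_m0 = float(np.median(X))
        if self.fix_h is None:
            x0 = [max(k_max0, 1e-9), K_m0, 1.0]
            lo, hi = [0.0, 0.0, 1e-3], [np.inf, np.inf, 20.0]
            fn = lambda th: _hill(X, th[0], th[1], th[2]) - k
        else:
            h = float(self.fix_h)
            x0 = [max(k_max0, 1e-9), K_m0]
            lo, hi = [0.0, 0.0], [np.inf, np.inf]
            fn = lambda th: _hill(X, th[0], th[1], h) - k
        sol, se = _ls(fn, x0, (lo, hi), X.size)
        self.k_max_ = float(sol.x[0])
        self.K_m_app_ = float(sol.x[1])
        self.h_ = float(sol.x[2]) if self.fix_h is None else float(self.fix_h)
        names = ("k_max", "K_m_app") + (("h",) if self.fix_h is None else ())
        self.se_ = dict(zip(names, map(float, se)))
        self.residual_norm_ = float(np.linalg.norm(sol.fun))
        self.converged_ = bool(sol.success)
        self.n_points_ = X.size
        return self

    def predict(self, X):
        return _hill(np.asarray(X, dtype=float), self.k_max_, self.K_m_app_, self.h_)

    def result(self) -> KineticFitResult:
        return KineticFitResult(
            model="hill",
            params={"k_max": self.k_max_, "K_m_app": self.K_m_app_, "h": self.h_},
            se=self.se_,
            residual_norm=self.residual_norm_,
            converged=self.converged_,
            n_points=self.n_points_,
        )


def fit_hill(X, k_obs=None, fix_h=None) -> KineticFitResult:
    """Fit the cooperative binding model to a (X, k_obs) table."""
    if k_obs is None:  # accept a DataFrame-like with X / k_obs columns
        X, k_obs = np.asarray(X["X"]), np.asarray(X["k_obs"])
    return HillCurve(fix_h=fix_h).fit(X, k_obs).result()


# ---------------------------------------------------------------------------
# competition binding (LANA-peptide inhibition)
# ---------------------------------------------------------------------------

def _competition(X, k0, K_I):
    return k0 / (1.0 + X / K_I)


class CompetitionCurve(BaseEstimator):
    """Fit ``k_obs = k0 / (1 + X / K_I)``."""

    def fit(self, X, k_obs):
        X = np.asarray(X, dtype=float)
        k = np.asarray(k_obs, dtype=float)
        if np.any(X < 0):
            raise ValueError("peptide concentrations must be nonnegative")
        if X.size < 3:
            raise ValueError("need >= 3 points")
        self.flags_ = []
        spread = np.ptp(k) / max(np.max(np.abs(k)), 1e-30)
        k0_0 = float(k[np.argmin(X)])
        K_I0 = float(np.median(X[X > 0])) if np.any(X > 0) else 1.0
        sol, se = _ls(
            lambda th: _competition(X, th[0], th[1]) - k,
            [max(k0_0, 1e-9), max(K_I0, 1e-9)],
            ([0.0, 0.0], [np.inf, np.inf]),
            X.size,
        )
        self.k0_ = float(sol.x[0])
        self.K_I_ = float(sol.x[1])
        self.se_ = dict(zip(("k0", "K_I"), map(float, se)))
        self.residual_norm_ = float(np.linalg.norm(sol.fun))
        self.converged_ = bool(sol.success)
        self.n_points_ = X.size
        if spread < 1e-6 or self.K_I_ > 1e3 * max(float(np.max(X)), 1e-30):
            self.flags_.append("non_identifiable")
        return self

    def predict(self, X):
        return _competition(np.asarray(X, dtype=float), self.k0_, self.K_I_)

    def result(self) -> KineticFitResult:
        return KineticFitResult(
            model="competition",
            params={"k0": self.k0_, "K_I": self.K_I_},
            se=self.se_,
            residual_norm=self.residual_norm_,
            converged=self.converged_,
            n_points=self.n_points_,
            flags=list(self.flags_),
        )


def fit_competition(X, k_obs=None) -> KineticFitResult:
    if k_obs is None:
        X, k_obs = np.asarray(X["X"]), np.asarray(X["k_obs"])
    return CompetitionCurve().fit(X, k_obs).result()


# ---------------------------------------------------------------------------
# two-phase exponential decay (ensemble FRET)
# ---------------------------------------------------------------------------

def _exp2(t, y0, p, f, kf, ks):
    return p + (y0 - p) * (f * np.exp(-kf * t) + (1 - f) * np.exp(-ks * t))


class TwoPhaseExponentialDecay(BaseEstimator):
    """Fit the two-phase decay; output normalized so k_fast >= k_slow.

    If the two rates are within a factor of ``identifiability_ratio`` at the
    optimum, the constrained single-exponential fit and an AIC comparison are
    attached (``alt_single_``, ``aic_two_``, ``aic_single_``) and the result
    carries a ``weak_identifiability`` flag.
    """

    def __init__(self, identifiability_ratio: float = 3.0):
        self.identifiability_ratio = identifiability_ratio

    def fit(self, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.size < 6:
            raise ValueError("need >= 6 points for a two-phase fit")
        single = SingleExponentialDecay().fit(t, y)
        k1 = max(single.k_obs_, 1e-9)
        x0 = [single.y0_, single.p_, 0.5, 3.0 * k1, k1 / 3.0]
        lo = [-np.inf, -np.inf, 0.0, 0.0, 0.0]
        hi = [np.inf, np.inf, 1.0, np.inf, np.inf]
        sol, se = _ls(
            lambda th: _exp2(t, *th) - y, x0, (lo, hi), t.size
        )
        y0, p, f, kf, ks = map(float, sol.x)
        se_map = dict(zip(("y0", "p", "f_fast", "k_fast", "k_slow"), map(float, se)))
        if kf < ks:  # enforce the k_fast >= k_slow convention
            kf, ks = ks, kf
            f = 1.0 - f
            se_map["k_fast"], se_map["k_slow"] = se_map["k_slow"], se_map["k_fast"]
        self.y0_, self.p_, self.f_fast_, self.k_fast_, self.k_slow_ = y0, p, f, kf, ks
        self.se_ = se_map
        self.residual_norm_ = float(np.linalg.norm(sol.fun))
        self.converged_ = bool(sol.success)
        self.n_points_ = t.size
        self.flags_ = []
        self.alt_single_ = None
        ratio = kf / ks if ks > 0 else np.inf
        degenerate = (
            ratio < self.identifiability_ratio
            or f >= 1.0 - 1e-6
            or f <= 1e-6
        )
        if degenerate:
            reason = (
                "weak_identifiability" if ratio < self.identifiability_ratio
                else "single_phase_limit"
            )
            self.flags_.append(reason)
            self.alt_single_ = single.result()
            n = t.size
            sse2 = self.residual_norm_ ** 2
            sse1 = single.residual_norm_ ** 2
            self.aic_two_ = n * np.log(sse2 / n + 1e-300) + 2 * 5
            self.aic_single_ = n * np.log(sse1 / n + 1e-300) + 2 * 3
        return self

    def predict(self, t):
        return _exp2(
            np.asarray(t, dtype=float),
            self.y0_, self.p_, self.f_fast_, self.k_fast_, self.k_slow_,
        )

    def result(self) -> KineticFitResult:
        extras = {}
        if self.alt_single_ is not None:
            extras = {
                "single_exponential": self.alt_single_,
                "aic_two_phase": float(self.aic_two_),
                "aic_single": float(self.aic_single_),
            }
        return KineticFitResult(
            model="two_phase_exponential",
            params={
                "y0": self.y0_, "p": self.p_, "f_fast": self.f_fast_,
                "k_fast": self.k_fast_, "k_slow": self.k_slow_,
            },
            se=self.se_,
            residual_norm=self.residual_norm_,
            converged=self.converged_,
            n_points=self.n_points_,
            flags=list(self.flags_),
            extras=extras,
        )


def fit_two_phase(t, y=None) -> KineticFitResult:
    if y is None and isinstance(t, EnsembleTimeCourse):
        t, y = t.t, t.y
    return TwoPhaseExponentialDecay().fit(t, y).result()


# ---------------------------------------------------------------------------
# ATPase initial rate
# ---------------------------------------------------------------------------

class InitialRate(BaseEstimator):
    """Initial-rate estimate: OLS line through the first ``fraction`` of Pi.

    Points with ``Pi <= fraction * total_atp`` enter the regression; if fewer
    than two qualify, the window expands to the first three points and the
    result is flagged ``expanded_window``.
    """

    def __init__(self, fraction: float = 0.10):
        self.fraction = fraction

    def fit(self, t, pi, total_atp: float | None = None):
        t = np.asarray(t, dtype=float)
        pi = np.asarray(pi, dtype=float)
        if total_atp is None:
            total_atp = float(np.max(pi))
        self.flags_ = []
        sel = pi <= self.fraction * total_atp
        if sel.sum() < 2:
            if t.size < 2:
                raise ValueError("need >= 2 points for an initial rate")
            sel = np.zeros_like(sel)
            sel[: min(3, t.size)] = True
            self.flags_.append("expanded_window")
        tt, yy = t[sel], pi[sel]
        A = np.vstack([tt, np.ones_like(tt)]).T
        coef, res, *_ = np.linalg.lstsq(A, yy, rcond=None)
        self.rate_ = float(coef[0])
        self.intercept_ = float(coef[1])
        resid = yy - A @ coef
        dof = max(tt.size - 2, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.pinv(A.T @ A)
        self.se_ = {"rate": float(np.sqrt(max(cov[0, 0], 0.0)))}
        self.residual_norm_ = float(np.linalg.norm(resid))
        self.n_points_ = int(tt.size)
        self.converged_ = True
        return self

    def result(self) -> KineticFitResult:
        return KineticFitResult(
            model="atpase_initial_rate",
            params={"rate": self.rate_, "intercept": self.intercept_},
            se=self.se_,
            residual_norm=self.residual_norm_,
            converged=self.converged_,
            n_points=self.n_points_,
            flags=list(self.flags_),
        )


def fit_initial_rate(t, pi=None, fraction: float = 0.10, total_atp=None) -> KineticFitResult:
    if pi is None and isinstance(t, EnsembleTimeCourse):
        total_atp = total_atp if total_atp is not None else t.meta.get("total_atp")
        t, pi = t.t, t.y
    return InitialRate(fraction=fraction).fit(t, pi, total_atp=total_atp).result()
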