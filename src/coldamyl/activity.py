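"""Reducing-end activity assays and the two-site Ca2+ activation model.

The colorimetric MBTH assay quantifies reducing carbohydrate ends released
by amylase action on hydrolyzed starch. Absorbance at 620 nm is converted to
nmol of reducing ends via a maltose standard curve; the initial velocity is
the slope of a linear regression over the early, linear part of the
timecourse (330 s by default). Activity versus CaCl2 concentration follows a
bell shape and is modelled by a two-site scheme in which binding of the
first Ca2+ (dissociation constant kl1) activates the enzyme and binding of
a second, weaker ion (kl2) inhibits it:

    v([Ca]) = (vmax_apo*kl1 + vmax_l1*[Ca] + vmax_l2*[Ca]^2/kl2)
              / (kl1 + [Ca] + [Ca]^2/kl2)

which is the singularity-free form of the classic apo/one-bound/two-bound
velocity average; at [Ca]=0 it returns vmax_apo and at saturation vmax_l2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "MaltoseStandardCurve",
    "ActivityTimecourse",
    "VelocityResult",
    "ActivityProfile",
    "CaResponseParams",
    "fit_standard_curve",
    "absorbance_to_reducing_ends",
    "initial_velocity",
    "normalize_profile",
    "ca_model_velocity",
    "fit_ca_model",
]


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Ordinary least-squares line fit.

    Returns (slope, intercept, slope_se, intercept_se, r_squared).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    if sxx == 0:
        raise ValueError("all x values identical; cannot fit a line")
    slope = np.sum((x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    if n > 2:
        sigma2 = ss_res / (n - 2)
    else:
        sigma2 = 0.0
    slope_se = float(np.sqrt(sigma2 / sxx))
    intercept_se = float(np.sqrt(sigma2 * (1.0 / n + xbar**2 / sxx)))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), slope_se, intercept_se, float(r2)


@dataclass
class MaltoseStandardCurve:
    """Linear A620 response to maltose amount (nmol)."""

    amounts: np.ndarray
    absorbances: np.ndarray
    slope: float = 0.0        # A620 per nmol
    intercept: float = 0.0    # A620
    slope_se: float = 0.0
    r_squared: float = 1.0
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class ActivityTimecourse:
    """Reducing ends (nmol) accumulating over time (s) in one reaction."""

    times: np.ndarray
    reducing_ends: np.ndarray
    enzyme_conc: float = np.nan     # nM
    reaction_volume: float = np.nan  # uL

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.reducing_ends = np.asarray(self.reducing_ends, dtype=float)
        if self.times.size != self.reducing_ends.size:
            raise ValueError("times and reducing_ends must have equal length")
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.reducing_ends))):
            raise ValueError("timecourse contains non-finite values")


@dataclass
class VelocityResult:
    velocity: float              # nmol reducing ends / min
    stderr: float                # same units
    r_squared: float
    specific_activity: float = np.nan  # mol product / min / mol enzyme
    intercept: float = 0.0
    n_points: int = 0
    degenerate: bool = False


@dataclass
class ActivityProfile:
    """Velocity as a function of one assay condition (T, pH, NaCl or CaCl2)."""

    condition_name: str
    condition_values: np.ndarray
    velocities: np.ndarray
    stderrs: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.condition_values = np.asarray(self.condition_values, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.stderrs is not None:
            self.stderrs = np.asarray(self.stderrs, dtype=float)
            if self.stderrs.size != self.velocities.size:
                raise ValueError("stderrs length mismatch")
        if self.condition_values.size != self.velocities.size:
            raise ValueError("condition/velocity length mismatch")


@dataclass
class CaResponseParams:
    """Two-site Ca2+ activation/inhibition parameters."""

    vmax_apo: float
    vmax_l1: float
    vmax_l2: float
    kl1: float   # mM, activating site
    kl2: float   # mM, inhibitory site
    stderrs: dict = field(default_factory=dict)
    chi2: float = np.nan
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.vmax_apo, self.vmax_l1, self.vmax_l2, self.kl1, self.kl2])


def fit_standard_curve(amounts, absorbances) -> MaltoseStandardCurve:
    """Fit the maltose standard line (A620 vs nmol) by OLS."""
    amounts = np.asarray(amounts, dtype=float)
    absorbances = np.asarray(absorbances, dtype=float)
    if amounts.size < 2:
        raise ValueError("standard curve needs at least 2 points")
    if amounts.size != absorbances.size:
        raise ValueError("amounts and absorbances must have equal length")
    if not (np.all(np.isfinite(amounts)) and np.all(np.isfinite(absorbances))):
        raise ValueError("non-finite standard-curve input")
    if np.any(amounts <= 0):
        raise ValueError("maltose amounts must be strictly positive")
    if np.unique(amounts).size < 2:
        raise ValueError("amounts must contain at least 2 distinct values")
    slope, intercept, slope_se, _, r2 = _ols_line(amounts, absorbances)
    if slope <= 0:
        raise ValueError("fitted standard-curve slope is not positive")
    resid = absorbances - (slope * amounts + intercept)
    return MaltoseStandardCurve(amounts, absorbances, slope, intercept, slope_se, r2, resid)


def absorbance_to_reducing_ends(a620: float, curve: MaltoseStandardCurve,
                                dilution: float = 1.0) -> float:
    """Convert an A620 reading into nmol reducing ends.

    Sub-baseline readings yield (flagged) negative amounts rather than an
    error, so blank-subtracted noise can pass through regressions.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("standard curve slope is zero")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    nmol = dilution * (a620 - curve.intercept) / curve.slope
    if nmol < 0:
        warnings.warn("sub-baseline absorbance produced negative reducing ends",
                      stacklevel=2)
    return float(nmol)


def initial_velocity(tc: ActivityTimecourse, window: float = 330.0) -> VelocityResult:
    """Initial velocity from linear regression of reducing ends over time.

    Only points with t <= ``window`` (seconds) enter the regression; the
    slope is converted to nmol/min. Specific activity (mol product per min
    per mol enzyme) is filled in when enzyme concentration and reaction
    volume are known.
    """
    mask = tc.times <= window
    t = tc.times[mask]
    y = tc.reducing_ends[mask]
    if t.size < 3:
        raise ValueError(f"regression window contains {t.size} points; need >= 3")
    if np.allclose(y, y[0]):
        warnings.warn("constant signal: velocity 0, r^2 undefined (reported as 0)",
                      stacklevel=2)
        return VelocityResult(0.0, 0.0, 0.0, specific_activity=0.0,
                              intercept=float(y[0]), n_points=t.size, degenerate=True)
    slope, intercept, slope_se, _, r2 = _ols_line(t, y)
    v = slope * 60.0
    v_se = slope_se * 60.0
    spec = np.nan
    if np.isfinite(tc.enzyme_conc) and np.isfinite(tc.reaction_volume):
        # nmol enzyme in reaction = conc(nM) * volume(uL) * 1e-6
        enzyme_nmol = tc.enzyme_conc * tc.reaction_volume * 1e-6
        if enzyme_nmol > 0:
            spec = v / enzyme_nmol
    return VelocityResult(float(v), float(v_se), r2, specific_activity=float(spec),
                          intercept=float(intercept), n_points=t.size)


def normalize_profile(p: ActivityProfile) -> ActivityProfile:
    """Scale a profile so its maximum velocity is 1; stderrs scale identically."""
    vmax = np.max(p.velocities)
    if vmax <= 0:
        raise ValueError("profile has no strictly positive velocity")
    stderrs = None if p.stderrs is None else p.stderrs / vmax
    return ActivityProfile(p.condition_name, p.condition_values.copy(),
                           p.velocities / vmax, stderrs, normalized=True)


def ca_model_velocity(params: CaResponseParams, ca) -> np.ndarray | float:
    """Two-site model velocity at Ca2+ concentration(s) ``ca`` (mM).

    Evaluated in the singularity-free polynomial form so ca = 0 returns the
    analytic apo limit exactly.
    """
    ca_arr = np.asarray(ca, dtype=float)
    if np.any(ca_arr < 0):
        raise ValueError("Ca2+ concentration must be non-negative")
    if params.kl1 <= 0 or params.kl2 <= 0:
        raise ValueError("dissociation constants must be positive")
    num = (params.vmax_apo * params.kl1
           + params.vmax_l1 * ca_arr
           + params.vmax_l2 * ca_arr**2 / params.kl2)
    den = params.kl1 + ca_arr + ca_arr**2 / params.kl2
    out = num / den
    return float(out) if np.isscalar(ca) else out


def _ca_model_vec(ca: np.ndarray, theta: np.ndarray) -> np.ndarray:
    va, v1, v2, k1, k2 = theta
    num = va * k1 + v1 * ca + v2 * ca**2 / k2
    den = k1 + ca + ca**2 / k2
    return num / den


def fit_ca_model(ca, v, stderrs=None, n_starts: int = 12,
                 seed: int | None = None) -> CaResponseParams:
    """Fit the two-site Ca2+ model by multi-start damped least squares.

    Weighted by 1/stderr when uncertainties are supplied (default
    unweighted). vmax starting guesses come from the data extremes; the two
    dissociation constants are seeded log-spaced over the concentration
    range, which copes with the multimodality of bell-shaped fits.
    """
    ca = np.asarray(ca, dtype=float)
    v = np.asarray(v, dtype=float)
    if ca.size != v.size:
        raise ValueError("ca and v length mismatch")
    if ca.size < 5:
        raise ValueError("need at least 5 concentrations (5 parameters)")
    w = np.ones_like(v)
    if stderrs is not None:
        s = np.asarray(stderrs, dtype=float)
        if np.any(s <= 0):
            raise ValueError("stderrs must be positive")
        w = 1.0 / s

    degenerate = bool(np.allclose(v, v[0]))

    v0 = v[np.argmin(ca)]
    vpk = float(np.max(v))
    vend = v[np.argmax(ca)]
    pos = ca[ca > 0]
    lo, hi = float(pos.min()), float(pos.max())
    k_seeds = np.geomspace(lo, hi, max(3, n_starts // 3))

    def resid(theta):
        return w * (_ca_model_vec(ca, theta) - v)

    best = None
    rng = np.random.default_rng(seed)
    starts = []
    for k1 in k_seeds:
        for k2 in k_seeds:
            starts.append([v0, vpk, vend, k1, k2])
    # a few randomized restarts guard against grid-aligned local minima
    for _ in range(4):
        starts.append([v0 * rng.uniform(0.5, 1.5), vpk * rng.uniform(0.8, 1.2),
                       vend * rng.uniform(0.5, 1.5),
                       np.exp(rng.uniform(np.log(lo), np.log(hi))),
                       np.exp(rng.uniform(np.log(lo), np.log(hi)))])
    lb = [0.0, 0.0, 0.0, 1e-8, 1e-8]
    ub = [np.inf] * 5
    for x0 in starts:
        x0 = np.clip(x0, 1e-8, None)
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lb, ub),
                                         method="trf", xtol=1e-14, ftol=1e-14,
                                         gtol=1e-14)
        except Exception:
            continue
        cost = sol.cost
        if best is None or cost < best.cost - 1e-30 * max(1.0, best.cost):
            best = sol
    if best is None:
        raise RuntimeError("two-site Ca model fit failed to converge from all starts")

    theta = best.x
    dof = max(ca.size - 5, 1)
    chi2 = 2 * best.cost / dof
    # parameter SEs from the Jacobian (Gauss-Newton covariance)
    stderr_map: dict = {}
    try:
        J = best.jac
        cov = np.linalg.pinv(J.T @ J) * (2 * best.cost / dof)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr_map = dict(zip(["vmax_apo", "vmax_l1", "vmax_l2", "kl1", "kl2"], ses))
        if degenerate or not np.all(np.isfinite(ses)):
            degenerate = True
    except np.linalg.LinAlgError:
        degenerate = True
    if degenerate:
        warnings.warn("degenerate Ca-response fit: kl values unidentifiable",
                      stacklevel=2)
    return CaResponseParams(*theta, stderrs=stderr_map, chi2=float(chi2),
                            degenerate=degenerate)
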