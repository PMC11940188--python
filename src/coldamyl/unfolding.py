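"""Thermal unfolding models for CD melts and DSF fluorescence-ratio curves.

Two equilibrium models are provided:

* A three-state N <-> I <-> D model for far-UV CD melts. The apparent
  signal is the Boltzmann-weighted average of three linear state baselines,
  with weights

      w_N = exp(+dH1 (1 - T/Tm1) / (R T)),  w_I = 1,
      w_D = exp(-dH2 (1 - T/Tm2) / (R T)),

  where T, Tm1, Tm2 are absolute temperatures (inputs in Celsius are
  converted internally with +273.15). The four structural parameters
  (tm1, tm2, dh1, dh2) are shared globally across wavelengths while each
  wavelength carries its own linear baselines per state.

* A two-state F <-> U model for the DSF 350/330 nm intrinsic-fluorescence
  ratio, with equilibrium constant K = exp(-dH (1 - t/tm) / (R t)). By
  default the temperature variable enters the exponent on the scale the
  data are recorded on (Celsius); ``kelvin=True`` switches to the
  thermodynamically conventional absolute-temperature form. Both variants
  put the midpoint exactly at tm.

Global fits use variable projection: for any trial of the structural
parameters the baselines enter the model linearly and are profiled out by
weighted linear least squares, leaving a low-dimensional damped
least-squares problem that is multi-started from a coarse (tm1, tm2) grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, softmax

from .constants import R_GAS

__all__ = [
    "BaselineConfig",
    "CDMeltDataset",
    "ThreeStateParams",
    "DSFCurve",
    "TwoStateParams",
    "three_state_signal",
    "population_fractions",
    "fit_cd_global",
    "two_state_ratio",
    "fit_dsf",
    "reversibility_metric",
]

_KELVIN = 273.15


@dataclass(frozen=True)
class BaselineConfig:
    """Which states carry a sloped (vs constant) baseline."""

    sloped_n: bool = True
    sloped_i: bool = True
    sloped_d: bool = True


@dataclass
class CDMeltDataset:
    """Ellipticity matrix (temperature x wavelength) from a thermal ramp."""

    temperatures: np.ndarray    # deg C
    wavelengths: np.ndarray     # nm
    ellipticity: np.ndarray     # (n_temp, n_wl)
    scan_rate: float = 1.0      # deg C / min

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.ellipticity.shape != (self.temperatures.size, self.wavelengths.size):
            raise ValueError("ellipticity matrix shape does not match axes")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")

    def select_wavelengths(self, indices) -> "CDMeltDataset":
        idx = np.asarray(indices, dtype=int)
        return CDMeltDataset(self.temperatures, self.wavelengths[idx],
                             self.ellipticity[:, idx], self.scan_rate)


@dataclass
class ThreeStateParams:
    """Shared melting parameters plus per-wavelength state baselines.

    ``baselines`` has one row per wavelength with columns
    (bs_n, as_n, bs_i, as_i, bs_d, as_d) in signal and signal/degC units.
    """

    tm1: float                  # deg C
    tm2: float                  # deg C
    dh1: float                  # J/mol
    dh2: float                  # J/mol
    baselines: np.ndarray
    baseline_config: BaselineConfig = field(default_factory=BaselineConfig)
    stderrs: dict = field(default_factory=dict)
    chi2: float = np.nan
    degenerate: bool = False
    transitions_in_range: bool = True

    def __post_init__(self) -> None:
        self.baselines = np.atleast_2d(np.asarray(self.baselines, dtype=float))
        if self.tm1 > self.tm2:
            raise ValueError("identifiability convention requires tm1 <= tm2")
        if self.dh1 <= 0 or self.dh2 <= 0:
            raise ValueError("melting enthalpies must be positive")


@dataclass
class DSFCurve:
    """350/330 nm fluorescence ratio against temperature."""

    temperatures: np.ndarray
    ratio: np.ndarray
    direction: str = "heating"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.temperatures.size != self.ratio.size:
            raise ValueError("temperature and ratio length mismatch")
        if np.any(self.ratio <= 0):
            raise ValueError("fluorescence ratio must be positive")
        if self.direction not in ("heating", "cooling"):
            raise ValueError("direction must be 'heating' or 'cooling'")


@dataclass
class TwoStateParams:
    """Two-state unfolding parameters with linear folded/unfolded baselines."""

    tm: float            # deg C
    dh_unf: float        # J/mol
    i_f: float
    i_fb: float
    i_u: float
    i_ub: float
    kelvin: bool = False
    stderrs: dict = field(default_factory=dict)
    chi2: float = np.nan
    no_transition: bool = False

    def __post_init__(self) -> None:
        if self.dh_unf <= 0:
            raise ValueError("unfolding enthalpy must be positive")


# ---------------------------------------------------------------------------
# three-state CD model


def _three_state_logw(t, tm1, tm2, dh1, dh2) -> np.ndarray:
    """Log Boltzmann weights of (N, I, D), shape (..., 3)."""
    t = np.asarray(t, dtype=float)
    T = t + _KELVIN
    a = dh1 * (1.0 - T / (tm1 + _KELVIN)) / (R_GAS * T)
    c = -dh2 * (1.0 - T / (tm2 + _KELVIN)) / (R_GAS * T)
    return np.stack([a, np.zeros_like(a), c], axis=-1)


def population_fractions(t, params: ThreeStateParams) -> np.ndarray:
    """Equilibrium fractions (fN, fI, fD); always sums to 1.

    fN = fI at t = tm1 and fI = fD at t = tm2 by construction.
    """
    logw = _three_state_logw(t, params.tm1, params.tm2, params.dh1, params.dh2)
    return softmax(logw, axis=-1)


def three_state_signal(t, params: ThreeStateParams, wavelength_index: int = 0):
    """Apparent CD signal at temperature(s) t for one wavelength."""
    b = params.baselines[wavelength_index]
    t_arr = np.asarray(t, dtype=float)
    frac = population_fractions(t_arr, params)
    states = np.stack([b[0] + b[1] * t_arr,
                       b[2] + b[3] * t_arr,
                       b[4] + b[5] * t_arr], axis=-1)
    out = np.sum(frac * states, axis=-1)
    return float(out) if np.isscalar(t) else out


def _cd_design(frac: np.ndarray, t: np.ndarray, config: BaselineConfig):
    """Design columns for the per-wavelength linear baseline fit.

    Returns (matrix, column index -> baseline slot map of length 6).
    """
    cols, slots = [], []
    for state, sloped, slot in ((0, config.sloped_n, 0),
                                (1, config.sloped_i, 2),
                                (2, config.sloped_d, 4)):
        cols.append(frac[:, state])
        slots.append(slot)
        if sloped:
            cols.append(frac[:, state] * t)
            slots.append(slot + 1)
    return np.column_stack(cols), slots


def _cd_profiled(theta, t, Y, config):
    """Residuals and profiled baselines for structural parameters theta.

    theta = (tm1, dtm, dh1, dh2) with tm2 = tm1 + dtm >= tm1.
    """
    tm1, dtm, dh1, dh2 = theta
    tm2 = tm1 + dtm
    frac = softmax(_three_state_logw(t, tm1, tm2, dh1, dh2), axis=-1)
    A, slots = _cd_design(frac, t, config)
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    resid = (A @ coef - Y).ravel(order="F")
    baselines = np.zeros((Y.shape[1], 6))
    for j, slot in enumerate(slots):
        baselines[:, slot] = coef[j]
    return resid, baselines


def fit_cd_global(data: CDMeltDataset, config: BaselineConfig | None = None,
                  wavelength_indices=None, wavelength_step: int = 1,
                  n_grid: int = 6, dh_seeds=(200e3, 500e3)) -> ThreeStateParams:
    """Global three-state fit with tm1/tm2/dh1/dh2 shared across wavelengths.

    ``wavelength_indices`` or ``wavelength_step`` restrict the fitted
    wavelength set (e.g. every second wavelength). Baselines are profiled
    out by linear least squares at every step of a multi-started damped
    least-squares optimization of the four structural parameters.
    """
    config = config or BaselineConfig()
    ds = data
    if wavelength_indices is not None:
        ds = ds.select_wavelengths(wavelength_indices)
    elif wavelength_step != 1:
        ds = ds.select_wavelengths(np.arange(0, ds.wavelengths.size, wavelength_step))
    if ds.wavelengths.size < 2:
        raise ValueError("global fit needs at least 2 wavelengths")
    t = ds.temperatures
    if t.size < 20:
        raise ValueError("need at least 20 temperatures spanning both transitions")
    Y = ds.ellipticity

    lo, hi = t.min(), t.max()
    span = hi - lo
    tm_grid = np.linspace(lo + 0.15 * span, hi - 0.15 * span, n_grid)

    best, best_cost = None, np.inf
    lb = [lo - 20.0, 1e-3, 1e3, 1e3]
    ub = [hi + 20.0, span + 40.0, 5e6, 5e6]
    for tm1_0 in tm_grid:
        for dtm_0 in (1.0, 0.1 * span, 0.3 * span):
            for dh0 in dh_seeds:
                x0 = np.clip([tm1_0, dtm_0, dh0, dh0], lb, ub)
                try:
                    sol = optimize.least_squares(
                        lambda th: _cd_profiled(th, t, Y, config)[0],
                        x0, bounds=(lb, ub), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
                except Exception:
                    continue
                if sol.cost < best_cost:
                    best, best_cost = sol, sol.cost
    if best is None:
        raise RuntimeError("global three-state fit failed to converge")

    tm1, dtm, dh1, dh2 = best.x
    tm2 = tm1 + dtm
    _, baselines = _cd_profiled(best.x, t, Y, config)

    n_resid = Y.size
    n_par = 4 + len(_cd_design(np.ones((1, 3)) / 3.0, t[:1], config)[1]) * Y.shape[1]
    dof = max(n_resid - n_par, 1)
    s2 = 2 * best_cost / dof
    stderrs: dict = {}
    degenerate = False
    try:
        J = best.jac
        # relative (column-scaled) conditioning of the structural Jacobian;
        # a collapsed direction means the two transitions are not separately
        # identifiable (e.g. effectively two-state data)
        sv = np.linalg.svd(J * np.abs(best.x)[None, :], compute_uv=False)
        if sv.min() <= 5e-4 * sv.max():
            degenerate = True
        cov = np.linalg.pinv(J.T @ J) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderrs = {"tm1": se[0], "tm2": float(np.sqrt(se[0] ** 2 + se[1] ** 2)),
                   "dh1": se[2], "dh2": se[3]}
        if not np.all(np.isfinite(se)) or se[0] > span or se[1] > span:
            degenerate = True
    except np.linalg.LinAlgError:
        degenerate = True
    if degenerate:
        warnings.warn("three-state fit degenerate: transitions unresolved "
                      "(SE blow-up)", stacklevel=2)
    in_range = bool(lo <= tm1 <= hi and lo <= tm2 <= hi)
    if not in_range:
        warnings.warn("fitted transition lies outside the temperature range",
                      stacklevel=2)
    return ThreeStateParams(float(tm1), float(tm2), float(dh1), float(dh2),
                            baselines, config, stderrs, float(s2),
                            degenerate, in_range)


# ---------------------------------------------------------------------------
# two-state DSF model


def _two_state_fu(t, tm, dh, kelvin: bool) -> np.ndarray:
    """Unfolded fraction K/(1+K) evaluated stably as a logistic."""
    t = np.asarray(t, dtype=float)
    if kelvin:
        tt, tmm = t + _KELVIN, tm + _KELVIN
    else:
        tt, tmm = t, tm
    if np.any(tt == 0):
        raise ZeroDivisionError("temperature equal to zero on the model scale")
    logK = -dh * (1.0 - tt / tmm) / (R_GAS * tt)
    return expit(logK)


def two_state_ratio(t, params: TwoStateParams):
    """Model fluorescence ratio at temperature(s) t.

    At t = tm the equilibrium constant is 1 and the ratio is exactly the
    mean of the folded and unfolded baselines.
    """
    t_arr = np.asarray(t, dtype=float)
    fu = _two_state_fu(t_arr, params.tm, params.dh_unf, params.kelvin)
    folded = params.i_f + params.i_fb * t_arr
    unfolded = params.i_u + params.i_ub * t_arr
    out = folded * (1.0 - fu) + unfolded * fu
    return float(out) if np.isscalar(t) else out


def _dsf_profiled(theta, t, y, kelvin):
    tm, dh = theta
    fu = _two_state_fu(t, tm, dh, kelvin)
    ff = 1.0 - fu
    A = np.column_stack([ff, ff * t, fu, fu * t])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return A @ coef - y, coef


def fit_dsf(curves: DSFCurve | list[DSFCurve], kelvin: bool = False,
            dh_seeds=(50e3, 150e3, 300e3, 600e3)) -> TwoStateParams:
    """Fit the two-state ratio model; a list of curves is fitted globally.

    Replicates share all six parameters (global fit of technical repeats).
    The midpoint is seeded at the temperature of steepest ratio change and
    on a coarse grid; enthalpy seeds span soft to very sharp transitions.
    """
    if isinstance(curves, DSFCurve):
        curves = [curves]
    t = np.concatenate([c.temperatures for c in curves])
    y = np.concatenate([c.ratio for c in curves])
    if t.size < 15:
        raise ValueError("need at least 15 points spanning the transition")

    c0 = curves[0]
    grad = np.gradient(c0.ratio, c0.temperatures)
    tm_steepest = float(c0.temperatures[np.argmax(np.abs(grad))])
    lo, hi = t.min(), t.max()
    tm_seeds = np.unique(np.concatenate([[tm_steepest],
                                         np.linspace(lo + 5, hi - 5, 5)]))

    best, best_cost = None, np.inf
    lb, ub = [lo - 20.0, 1e3], [hi + 20.0, 5e6]
    for tm0 in tm_seeds:
        for dh0 in dh_seeds:
            x0 = np.clip([tm0, dh0], lb, ub)
            try:
                sol = optimize.least_squares(
                    lambda th: _dsf_profiled(th, t, y, kelvin)[0],
                    x0, bounds=(lb, ub), method="trf",
                    xtol=1e-13, ftol=1e-13, gtol=1e-13)
            except Exception:
                continue
            if sol.cost < best_cost:
                best, best_cost = sol, sol.cost
    if best is None:
        raise RuntimeError("two-state DSF fit failed to converge")

    tm, dh = best.x
    _, coef = _dsf_profiled(best.x, t, y, kelvin)
    i_f, i_fb, i_u, i_ub = coef

    dof = max(t.size - 6, 1)
    s2 = 2 * best_cost / dof
    stderrs: dict = {}
    try:
        J = best.jac
        cov = np.linalg.pinv(J.T @ J) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderrs = {"tm": float(se[0]), "dh_unf": float(se[1])}
    except np.linalg.LinAlgError:
        pass

    amp = abs((i_u + i_ub * tm) - (i_f + i_fb * tm))
    rms = float(np.sqrt(s2))
    span = float(y.max() - y.min())
    # monotone-baseline-only data: the baseline separation at tm is tiny
    # against either the residual level or the overall signal span
    no_transition = bool(amp < max(3 * rms, 0.05 * span)
                         or not (lo <= tm <= hi))
    if no_transition:
        warnings.warn("no clear transition in DSF data; fit flagged",
                      stacklevel=2)
    return TwoStateParams(float(tm), float(dh), float(i_f), float(i_fb),
                          float(i_u), float(i_ub), kelvin, stderrs,
                          float(s2), no_transition)


def reversibility_metric(heat: DSFCurve, cool: DSFCurve) -> dict:
    """Hysteresis between a heating scan and its in-run cooling scan.

    Returns the mean absolute ratio difference over the overlapping
    temperature range and the fraction of the unfolding signal recovered at
    the cold end (1 = fully reversible, 0 = curve stays at the unfolded
    value).
    """
    lo = max(heat.temperatures.min(), cool.temperatures.min())
    hi = min(heat.temperatures.max(), cool.temperatures.max())
    if lo >= hi:
        raise ValueError("heating and cooling scans do not overlap in temperature")
    grid = np.linspace(lo, hi, 200)
    h = np.interp(grid, heat.temperatures, heat.ratio)
    order = np.argsort(cool.temperatures)
    c = np.interp(grid, cool.temperatures[order], cool.ratio[order])
    hysteresis = float(np.mean(np.abs(h - c)))
    folded_val = h[0]
    unfolded_val = h[-1]
    denom = unfolded_val - folded_val
    if denom == 0:
        recovered = 1.0 if hysteresis == 0 else 0.0
    else:
        recovered = float(np.clip(1.0 - (c[0] - folded_val) / denom, 0.0, 1.0))
    return {"hysteresis": hysteresis, "recovered_fraction": recovered}
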