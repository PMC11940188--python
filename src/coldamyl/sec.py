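"""Size-exclusion chromatography: column calibration and peak deconvolution.

Globular-protein standards define a linear relation between elution volume
and log10(MW); unknowns are sized by interpolation on that line. A280
chromatograms are deconvolved into sums of Gaussian peaks (optionally
exponentially modified Gaussians for skewed peaks, such as a
monomer-dimer exchange peak) above a constant baseline, and area fractions
are computed from the fitted analytic areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "SECStandardSet",
    "SECCalibration",
    "Chromatogram",
    "PeakSet",
    "calibrate",
    "estimate_mw",
    "fit_peaks",
]


@dataclass
class SECStandardSet:
    names: list
    mw: np.ndarray               # kDa
    elution_volume: np.ndarray   # mL

    def __post_init__(self) -> None:
        self.mw = np.asarray(self.mw, dtype=float)
        self.elution_volume = np.asarray(self.elution_volume, dtype=float)
        if np.any(self.mw <= 0):
            raise ValueError("standard MWs must be positive")
        if self.mw.size != self.elution_volume.size or self.mw.size < 3:
            raise ValueError("need >= 3 matched standards")


@dataclass
class SECCalibration:
    slope: float       # log10(kDa) per mL, negative: larger elutes earlier
    intercept: float   # log10(kDa)
    r_squared: float
    ve_range: tuple = (np.nan, np.nan)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("calibration slope must be negative")


@dataclass
class Chromatogram:
    volume: np.ndarray   # mL
    a280: np.ndarray     # AU

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.a280 = np.asarray(self.a280, dtype=float)
        if self.volume.size != self.a280.size:
            raise ValueError("volume and a280 length mismatch")


@dataclass
class PeakSet:
    centers: np.ndarray    # mL
    widths: np.ndarray     # mL (Gaussian sigma)
    areas: np.ndarray      # AU * mL
    fractions: np.ndarray
    baseline: float = 0.0
    taus: np.ndarray | None = None   # EMG decay constants when used
    stderrs: dict = field(default_factory=dict)
    unresolved: bool = False


def calibrate(standards: SECStandardSet) -> SECCalibration:
    """OLS of log10(MW) against elution volume for the standard set."""
    ve = standards.elution_volume
    if np.unique(ve).size != ve.size:
        raise ValueError("duplicate elution volumes in standards")
    y = np.log10(standards.mw)
    slope, intercept = np.polyfit(ve, y, 1)
    pred = slope * ve + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SECCalibration(float(slope), float(intercept), r2,
                          (float(ve.min()), float(ve.max())))


def estimate_mw(ve: float, cal: SECCalibration) -> float:
    """MW (kDa) of a species eluting at ``ve`` mL; warns outside the
    calibrated volume range."""
    lo, hi = cal.ve_range
    if np.isfinite(lo) and not (lo <= ve <= hi):
        warnings.warn("elution volume outside the standard range; "
                      "extrapolating the calibration line", stacklevel=2)
    return float(10.0 ** (cal.slope * ve + cal.intercept))


def _gauss(v, center, sigma, area):
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((v - center) / sigma) ** 2)


def _emg(v, center, sigma, area, tau):
    # exponentially modified Gaussian, area-normalized
    arg = (sigma**2 / tau - (v - center)) / (np.sqrt(2) * sigma)
    return (area / (2 * tau) * np.exp(sigma**2 / (2 * tau**2) - (v - center) / tau)
            * special.erfc(arg))


def fit_peaks(chrom: Chromatogram, n_peaks: int = 1, model: str = "gaussian",
              baseline: bool = True) -> PeakSet:
    """Deconvolve a chromatogram into ``n_peaks`` analytic peaks.

    Peaks are Gaussian by default (``model='emg'`` adds an exponential tail
    for skewed peaks). Initialization splits the signal mass into quantile
    segments; fractions are the fitted analytic areas normalized to their
    sum. Strongly correlated parameters (overlapping unresolvable peaks)
    set the ``unresolved`` flag.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if model not in ("gaussian", "emg"):
        raise ValueError("model must be 'gaussian' or 'emg'")
    v, y = chrom.volume, chrom.a280
    base0 = float(np.percentile(y, 5)) if baseline else 0.0
    work = np.clip(y - base0, 0, None)
    total = np.trapezoid(work, v)
    if total <= 0:
        raise ValueError("chromatogram has no signal above baseline")
    # seed centers at signal-mass quantiles, widths from local spread
    cdf = np.cumsum(work)
    cdf = cdf / cdf[-1]
    qs = (np.arange(n_peaks) + 0.5) / n_peaks
    centers0 = np.interp(qs, cdf, v)
    span = (v.max() - v.min())
    sigma0 = max(span / (8 * n_peaks), 1e-3)
    npar = 3 if model == "gaussian" else 4

    def unpack(theta):
        base = theta[-1] if baseline else 0.0
        return theta[:n_peaks * npar].reshape(n_peaks, npar), base

    def predict(theta):
        P, base = unpack(theta)
        out = np.full_like(v, base)
        for row in P:
            if model == "gaussian":
                out = out + _gauss(v, *row)
            else:
                out = out + _emg(v, *row)
        return out

    x0 = []
    for c in centers0:
        row = [c, sigma0, total / n_peaks]
        if model == "emg":
            row.append(sigma0)
        x0.extend(row)
    if baseline:
        x0.append(base0)
    x0 = np.array(x0)
    lb, ub = [], []
    for _ in range(n_peaks):
        lb += [v.min(), 1e-4, 0.0] + ([1e-4] if model == "emg" else [])
        ub += [v.max(), span, np.inf] + ([span] if model == "emg" else [])
    if baseline:
        lb.append(-np.inf)
        ub.append(np.inf)

    sol = optimize.least_squares(lambda th: predict(th) - y, x0,
                                 bounds=(lb, ub), method="trf",
                                 xtol=1e-13, ftol=1e-13, gtol=1e-13)
    if not sol.success and sol.status <= 0:
        raise RuntimeError("peak fit did not converge")
    P, base = unpack(sol.x)
    order = np.argsort(P[:, 0])
    P = P[order]
    areas = P[:, 2]
    fractions = areas / areas.sum()

    unresolved = False
    stderrs: dict = {}
    dof = max(v.size - sol.x.size, 1)
    s2 = 2 * sol.cost / dof
    try:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * s2
        dcv = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderrs = {"params": dcv}
        if n_peaks > 1 and np.all(dcv > 0):
            corr = cov / np.outer(dcv, dcv)
            off = np.abs(corr - np.eye(corr.shape[0]))
            if np.nanmax(off) > 0.999:
                unresolved = True
                warnings.warn("overlapping peaks: parameters strongly "
                              "correlated", stacklevel=2)
    except np.linalg.LinAlgError:
        unresolved = True
    return PeakSet(P[:, 0], P[:, 1], areas, fractions, float(base),
                   P[:, 3] if model == "emg" else None,
                   stderrs, unresolved)
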