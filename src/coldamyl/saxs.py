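"""Small-angle X-ray scattering analysis for oligomeric-state determination.

Model-independent analysis: Guinier regression for Rg and forward
scattering, an indirect Fourier transform (IFT) giving the pair distance
distribution p(r) with Dmax/Rg/I(0), and absolute-scale molecular weight
M = I(0) * N_A / (c * drho_m^2) with drho_m = 2.0e10 cm/g for proteins.

Model-dependent analysis: orientationally averaged scattering of rigid
atomic or bead models via the Debye double sum with Gaussian form factors
for all non-H scatterers, construction/optimization of two-fold (P2)
symmetric dimers, and non-negative linear-combination fits of oligomer
component curves to measured data on absolute scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import (
    DISPLACED_VOLUMES,
    ELECTRON_COUNTS,
    N_AVOGADRO,
    PROTEIN_DRHO_M,
    R_ELECTRON_CM,
    atomic_mass,
    vdw_radius,
)

__all__ = [
    "ScatteringCurve",
    "PDDFResult",
    "AtomicModel",
    "MixtureFit",
    "ClashError",
    "guinier_fit",
    "ift",
    "ift_back_transform",
    "dmax_scan",
    "mw_from_i0",
    "debye_curve",
    "build_p2_dimer",
    "optimize_p2",
    "fit_mixture",
    "reduced_chi2",
]


class ClashError(ValueError):
    """Raised when a symmetry-built oligomer has interpenetrating chains."""


@dataclass
class ScatteringCurve:
    """Scattering intensity on absolute scale (cm^-1) vs q (A^-1)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.q <= 0) or not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing and positive")
        if self.sigma is None:
            self.sigma = np.full_like(self.intensity, np.nan)
        else:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")
        if not (self.q.size == self.intensity.size == self.sigma.size):
            raise ValueError("q/intensity/sigma length mismatch")


@dataclass
class PDDFResult:
    """Pair distance distribution and the size parameters derived from it."""

    r: np.ndarray
    p_r: np.ndarray
    dmax: float
    rg: float
    i0: float
    alpha: float
    chi2: float = np.nan


@dataclass
class AtomicModel:
    """Rigid scatterer: coordinates plus per-atom excess scattering lengths.

    ``b`` are excess scattering lengths in cm ((Z - rho_w * V) * r_e for
    atoms); ``sigma_ff`` are Gaussian form-factor widths in A (0 for point
    scatterers). Hydrogens are dropped on construction from elements.
    """

    coords: np.ndarray
    elements: list
    b: np.ndarray
    sigma_ff: np.ndarray
    residue_ids: np.ndarray | None = None
    chains: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.b = np.asarray(self.b, dtype=float)
        self.sigma_ff = np.asarray(self.sigma_ff, dtype=float)
        if not (len(self.elements) == self.coords.shape[0] == self.b.size == self.sigma_ff.size):
            raise ValueError("inconsistent atom counts")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_elements(cls, coords, elements, residue_ids=None, chains=None,
                      solvent_density: float = 0.334) -> "AtomicModel":
        """Build a model from coordinates and element symbols.

        Excess lengths use vacuum electron counts minus displaced-solvent
        volume times the water electron density. H atoms are excluded from
        the scattering sums. Gaussian widths are matched to the vdW-sphere
        radius of gyration (sigma = r_vdw / sqrt(5)).
        """
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        elements = [str(e).upper() for e in elements]
        keep = [i for i, e in enumerate(elements) if e != "H"]
        coords = coords[keep]
        elements = [elements[i] for i in keep]
        if residue_ids is not None:
            residue_ids = np.asarray(residue_ids)[keep]
        if chains is not None:
            chains = np.asarray(chains)[keep]
        b = np.array([
            (ELECTRON_COUNTS.get(e, 6) - solvent_density * DISPLACED_VOLUMES.get(e, 16.44))
            * R_ELECTRON_CM for e in elements])
        sig = np.array([vdw_radius(e) / np.sqrt(5.0) for e in elements])
        return cls(coords, elements, b, sig, residue_ids, chains)

    @classmethod
    def from_beads(cls, coords, b_per_bead: float = 1.0,
                   sigma_ff: float = 0.0) -> "AtomicModel":
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = coords.shape[0]
        return cls(coords, ["BEAD"] * n,
                   np.full(n, b_per_bead), np.full(n, sigma_ff))

    def mass(self) -> float:
        """Sum of atomic masses in Da (bead models have no defined mass)."""
        return float(sum(atomic_mass(e) for e in self.elements if e != "BEAD"))


@dataclass
class MixtureFit:
    labels: list
    weights: np.ndarray        # mg/mL per component
    chi2: float
    collinear: bool = False

    @property
    def total_conc(self) -> float:
        return float(np.sum(self.weights))


# ---------------------------------------------------------------------------
# model-independent analysis


def guinier_fit(curve: ScatteringCurve, qrg_max: float = 1.3,
                min_points: int = 5) -> dict:
    """Guinier regression ln I = ln I0 - q^2 Rg^2 / 3 on the low-q region.

    The q-range is iterated so that q*Rg <= qrg_max for every point used. A
    positive low-q slope (upturn) is the classic aggregation signature and
    is flagged rather than silently fitted.
    """
    q, I = curve.q, curve.intensity
    ok = I > 0
    q, I = q[ok], I[ok]
    if q.size < min_points:
        raise ValueError("not enough positive-intensity points for Guinier fit")
    n = max(min_points, q.size // 4)
    rg = None
    for _ in range(60):
        x, y = q[:n] ** 2, np.log(I[:n])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            warnings.warn("positive Guinier slope: low-q upturn suggests "
                          "aggregation", stacklevel=2)
            return {"rg": np.nan, "i0": float(np.exp(intercept)),
                    "n_points": n, "aggregated": True}
        rg = float(np.sqrt(-3.0 * slope))
        n_new = int(np.searchsorted(q, qrg_max / rg, side="right"))
        n_new = max(min_points, min(n_new, q.size))
        if n_new == n:
            break
        n = n_new
    if q[0] * rg > qrg_max:
        # no usable Guinier region: the apparent size exceeds what the
        # lowest measured q can support -- low-q upturn / aggregation
        warnings.warn("q_min*Rg exceeds the Guinier limit: low-q upturn "
                      "suggests aggregation", stacklevel=2)
        return {"rg": rg, "i0": float(np.exp(intercept)), "n_points": n,
                "aggregated": True}
    return {"rg": rg, "i0": float(np.exp(intercept)), "n_points": n,
            "aggregated": False}


def _ift_solve(curve: ScatteringCurve, dmax: float, nbins: int, alpha: float,
               nonneg: bool):
    q, I = curve.q, curve.intensity
    sig = curve.sigma
    if np.any(~np.isfinite(sig)):
        sig = np.full_like(I, max(1e-3 * np.max(np.abs(I)), 1e-30))
    r = np.linspace(0.0, dmax, nbins)
    dr = r[1] - r[0]
    # interior bins only: p(0) = p(dmax) = 0 by construction
    rin = r[1:-1]
    qr = np.outer(q, rin)
    A = 4.0 * np.pi * dr * np.sinc(qr / np.pi)
    W = 1.0 / sig
    Aw = A * W[:, None]
    yw = I * W
    m = rin.size
    D = np.zeros((m, m))
    # second differences including the implicit zero endpoints
    for i in range(m):
        D[i, i] = -2.0
        if i > 0:
            D[i, i - 1] = 1.0
        if i < m - 1:
            D[i, i + 1] = 1.0
    scale = np.mean(np.abs(Aw)) / max(np.mean(np.abs(D)), 1e-30)
    stacked_A = np.vstack([Aw, np.sqrt(alpha) * scale * D])
    stacked_y = np.concatenate([yw, np.zeros(m)])
    if nonneg:
        x, _ = optimize.nnls(stacked_A, stacked_y)
    else:
        x, *_ = np.linalg.lstsq(stacked_A, stacked_y, rcond=None)
    p = np.zeros(nbins)
    p[1:-1] = x
    resid = (Aw @ x - yw)
    return r, p, resid


def ift(curve: ScatteringCurve, dmax: float, nbins: int = 100,
        alpha: float | None = None, nonneg: bool = True) -> PDDFResult:
    """Regularized indirect Fourier transform of a scattering curve.

    Solves a smoothness-penalized (second-difference), optionally
    non-negative linear least-squares problem for p(r) on [0, dmax] with
    p(0) = p(dmax) = 0. When ``alpha`` is None it is chosen by an L-curve
    corner search. Rg and I(0) come from the moments of p(r):
    Rg^2 = int r^2 p dr / (2 int p dr), I(0) = 4 pi int p dr.
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    if alpha is not None and alpha <= 0:
        raise ValueError("regularization alpha must be positive")
    if dmax < np.pi / curve.q.max():
        warnings.warn("dmax below the resolution limit of the data",
                      stacklevel=2)
    if alpha is None:
        alphas = np.geomspace(1e-8, 1e4, 25)
        rnorm, snorm = [], []
        for a in alphas:
            r, p, resid = _ift_solve(curve, dmax, nbins, a, nonneg)
            rnorm.append(np.log(np.sum(resid**2) + 1e-300))
            snorm.append(np.log(np.sum(np.diff(p, 2) ** 2) + 1e-300))
        rnorm, snorm = np.array(rnorm), np.array(snorm)
        # discrete curvature of the L-curve; corner = max curvature
        d1r, d1s = np.gradient(rnorm), np.gradient(snorm)
        d2r, d2s = np.gradient(d1r), np.gradient(d1s)
        curv = (d1r * d2s - d1s * d2r) / np.power(d1r**2 + d1s**2, 1.5)
        alpha = float(alphas[np.nanargmax(curv)])
    r, p, resid = _ift_solve(curve, dmax, nbins, alpha, nonneg)
    dr = r[1] - r[0]
    total = np.trapezoid(p, dx=dr)
    if total <= 0:
        raise RuntimeError("IFT produced a non-positive p(r) integral")
    rg = float(np.sqrt(np.trapezoid(r**2 * p, dx=dr) / (2.0 * total)))
    i0 = float(4.0 * np.pi * total)
    dof = max(curve.q.size - max(int(np.sum(p > 0)), 1), 1)
    chi2 = float(np.sum(resid**2) / dof)
    return PDDFResult(r, p, float(dmax), rg, i0, float(alpha), chi2)


def ift_back_transform(pddf: PDDFResult, q) -> np.ndarray:
    """Reconstruct I(q) = 4 pi int p(r) sinc(qr) dr from a p(r)."""
    q = np.asarray(q, dtype=float)
    dr = pddf.r[1] - pddf.r[0]
    qr = np.outer(q, pddf.r)
    return 4.0 * np.pi * dr * (np.sinc(qr / np.pi) @ pddf.p_r)


def dmax_scan(curve: ScatteringCurve, dmax_values, nbins: int = 100,
              alpha: float | None = None, tol: float = 0.05) -> dict:
    """Scan candidate Dmax values and pick the most parsimonious one.

    The fit quality (chi^2) plateaus once dmax covers the particle's true
    support; the scan returns the smallest dmax whose chi^2 is within
    ``tol`` of the plateau minimum (an Occam criterion).
    """
    dmax_values = np.asarray(dmax_values, dtype=float)
    chi2s = np.array([ift(curve, d, nbins=nbins, alpha=alpha).chi2
                      for d in dmax_values])
    best = np.min(chi2s)
    ok = chi2s <= best * (1.0 + tol)
    chosen = float(dmax_values[np.argmax(ok)])
    return {"dmax": chosen, "dmax_values": dmax_values, "chi2": chi2s}


def mw_from_i0(i0: float, conc: float, monomer_mw: float | None = None) -> dict:
    """Molecular weight from absolute forward scattering.

    M(Da) = I(0) * N_A / (c * drho_m^2) with I(0) in cm^-1, c the mass
    concentration converted from mg/mL to g/cm^3 and drho_m = 2.0e10 cm/g.
    The oligomerization state n_mer = M / monomer_mw (kDa).
    """
    if i0 <= 0 or conc <= 0:
        raise ValueError("i0 and concentration must be positive")
    c_g_cm3 = conc * 1e-3
    mw_da = i0 * N_AVOGADRO / (c_g_cm3 * PROTEIN_DRHO_M**2)
    out = {"mw_kda": mw_da / 1e3}
    if monomer_mw is not None:
        if monomer_mw <= 0:
            raise ValueError("monomer MW must be positive")
        out["n_mer"] = out["mw_kda"] / monomer_mw
    return out


def i0_from_mw(mw_kda: float, conc: float) -> float:
    """Forward scattering (cm^-1) expected for a given MW and concentration."""
    return mw_kda * 1e3 * (conc * 1e-3) * PROTEIN_DRHO_M**2 / N_AVOGADRO


# ---------------------------------------------------------------------------
# model-dependent analysis


def _form_factors(model: AtomicModel, q: np.ndarray) -> np.ndarray:
    """Per-atom Gaussian form factors, shape (nq, natoms)."""
    return model.b[None, :] * np.exp(-0.5 * (q[:, None] ** 2) * (model.sigma_ff[None, :] ** 2))


def debye_curve(model: AtomicModel, qgrid, scale: float = 1.0,
                chunk: int = 8) -> ScatteringCurve:
    """Orientationally averaged scattering of a rigid model (Debye sum).

    I(q) = sum_ij f_i(q) f_j(q) sinc(q d_ij) with f_i(q) =
    b_i exp(-q^2 sigma_i^2 / 2); the q -> 0 limit of sinc is handled by
    numpy's sinc. ``scale`` multiplies the final intensity (e.g. to place a
    per-particle curve on a concentration scale).
    """
    if model.n_atoms == 0:
        raise ValueError("empty model")
    q = np.asarray(qgrid, dtype=float)
    F = _form_factors(model, q)
    iu, ju = np.triu_indices(model.n_atoms, k=1)
    d = np.linalg.norm(model.coords[iu] - model.coords[ju], axis=1)
    I = np.empty_like(q)
    for s in range(0, q.size, chunk):
        qs = q[s:s + chunk]
        sinc = np.sinc(np.outer(qs, d) / np.pi)
        Fi = F[s:s + chunk][:, iu]
        Fj = F[s:s + chunk][:, ju]
        cross = np.sum(Fi * Fj * sinc, axis=1)
        I[s:s + chunk] = np.sum(F[s:s + chunk] ** 2, axis=1) + 2.0 * cross
    return ScatteringCurve(q, scale * I,
                           sigma=np.full(q.size, 1e-6 * np.max(scale * I)))


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _euler_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.from_euler("zyz", [alpha, beta, gamma]).as_matrix()


def build_p2_dimer(monomer: AtomicModel, axis_theta: float = 0.0,
                   axis_phi: float = 0.0, euler=(0.0, 0.0, 0.0),
                   offset=(0.0, 0.0, 0.0), clash_tol: float = 2.0) -> AtomicModel:
    """Build a two-fold (P2) symmetric dimer from one monomer copy.

    The monomer is rotated by ``euler`` (zyz, radians) about its centroid
    and shifted by ``offset``; the second chain is the 180-degree rotation
    of the first about the symmetry axis with polar angles (theta, phi)
    through the origin. Configurations with interchain atoms closer than
    ``clash_tol`` (A) are rejected.
    """
    axis = np.array([np.sin(axis_theta) * np.cos(axis_phi),
                     np.sin(axis_theta) * np.sin(axis_phi),
                     np.cos(axis_theta)])
    cen = monomer.coords.mean(axis=0)
    Rm = _euler_matrix(*euler)
    a = (monomer.coords - cen) @ Rm.T + cen + np.asarray(offset, dtype=float)
    C2 = _rotation_about_axis(axis, np.pi)
    b_coords = a @ C2.T
    # clash check on minimum interchain distance
    from scipy.spatial import cKDTree
    dmin = cKDTree(a).query(b_coords, k=1)[0].min()
    if dmin < clash_tol:
        raise ClashError(f"interchain clash: min distance {dmin:.2f} A < {clash_tol} A")
    coords = np.vstack([a, b_coords])
    elements = list(monomer.elements) * 2
    b = np.concatenate([monomer.b, monomer.b])
    sig = np.concatenate([monomer.sigma_ff, monomer.sigma_ff])
    res = None
    if monomer.residue_ids is not None:
        res = np.concatenate([monomer.residue_ids, monomer.residue_ids])
    chains = np.array(["A"] * monomer.n_atoms + ["B"] * monomer.n_atoms)
    return AtomicModel(coords, elements, b, sig, res, chains)


def optimize_p2(monomer: AtomicModel, target: ScatteringCurve,
                n_seeds: int = 6, scale: float = 1.0,
                clash_tol: float = 2.0, seed: int = 0) -> dict:
    """Optimize the P2 dimer arrangement against a measured curve.

    Five parameters (two symmetry-axis angles, three monomer-orientation
    Euler angles) are grid/random seeded and refined by Nelder-Mead on the
    reduced chi^2; clashing configurations are penalized.
    """
    rng = np.random.default_rng(seed)
    q = target.q

    def objective(x):
        try:
            dim = build_p2_dimer(monomer, x[0], x[1], euler=tuple(x[2:5]),
                                 clash_tol=clash_tol)
        except ClashError:
            return 1e6
        model = debye_curve(dim, q, scale=scale)
        return reduced_chi2(model, target, nparams=5)

    best_x, best_f = None, np.inf
    seeds = [np.zeros(5)]
    for _ in range(n_seeds - 1):
        seeds.append(rng.uniform(0, np.pi, size=5))
    for x0 in seeds:
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-8,
                                         "maxiter": 400})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    dimer = build_p2_dimer(monomer, best_x[0], best_x[1],
                           euler=tuple(best_x[2:5]), clash_tol=clash_tol)
    return {"params": best_x, "chi2": float(best_f), "dimer": dimer}


def _resample_log(component: ScatteringCurve, q: np.ndarray) -> np.ndarray:
    """Interpolate a component curve onto q, linearly in log I."""
    if q.min() < component.q.min() - 1e-12 or q.max() > component.q.max() + 1e-12:
        raise ValueError("extrapolation of component curves is forbidden")
    pos = component.intensity > 0
    return np.exp(np.interp(q, component.q[pos], np.log(component.intensity[pos])))


def fit_mixture(components: dict | list, data: ScatteringCurve) -> MixtureFit:
    """Non-negative linear-combination fit of oligomer curves to data.

    ``components`` maps labels to per-1-mg/mL curves (or is a list of
    curves); the fitted non-negative weights are therefore concentrations
    in mg/mL on absolute scale. Near-collinear component pairs are flagged.
    """
    if isinstance(components, dict):
        labels = list(components)
        curves = [components[k] for k in labels]
    else:
        curves = list(components)
        labels = [f"component_{i}" for i in range(len(curves))]
    q = data.q
    A = np.column_stack([_resample_log(c, q) for c in curves])
    sig = data.sigma
    if np.any(~np.isfinite(sig)):
        sig = np.full_like(data.intensity, 1e-3 * np.max(data.intensity))
    Aw = A / sig[:, None]
    yw = data.intensity / sig
    collinear = False
    if A.shape[1] > 1:
        Cn = Aw / np.linalg.norm(Aw, axis=0)
        gram = Cn.T @ Cn
        if np.any(np.abs(gram[np.triu_indices_from(gram, k=1)]) > 0.9999):
            collinear = True
            warnings.warn("near-collinear mixture components", stacklevel=2)
    w, _ = optimize.nnls(Aw, yw)
    resid = Aw @ w - yw
    dof = max(q.size - A.shape[1], 1)
    chi2 = float(np.sum(resid**2) / dof)
    return MixtureFit(labels, w, chi2, collinear)


def reduced_chi2(model: ScatteringCurve, data: ScatteringCurve,
                 nparams: int = 0) -> float:
    """Reduced chi^2 between a model curve and data on matching grids."""
    if model.q.size != data.q.size or not np.allclose(model.q, data.q):
        raise ValueError("model and data q grids do not match")
    if data.q.size <= nparams:
        raise ValueError("fewer points than parameters")
    resid = (data.intensity - model.intensity) / data.sigma
    return float(np.sum(resid**2) / (data.q.size - nparams))
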