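"""Seeded generators for every input class the analysis stages consume.

Each generator reproduces the statistical structure its analysis assumes
(linear reducing-end timecourses, bell-shaped Ca2+ responses, two- and
three-state melt curves with linear state baselines, Gaussian SEC peaks,
sphere/bead scattering with q-dependent noise, harmonic per-residue
fluctuation ensembles) and returns its ground truth alongside the data, so
recovery tests are self-contained. Every generator is reproducible given
(parameters, seed). Defaults mirror the assay conditions of the study
system: 30 s sampling, Ca2+ grid 0-20 mM, CD melts 210-230 nm over
8-90 degC, DSF 15-95 degC at 1 degC steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import ActivityProfile, ActivityTimecourse, CaResponseParams, ca_model_velocity
from .mdflex import Topology, TrajectoryEnsemble
from .saxs import AtomicModel, ScatteringCurve, build_p2_dimer
from .sec import Chromatogram, PeakSet, _gauss
from .unfolding import (
    BaselineConfig,
    CDMeltDataset,
    DSFCurve,
    ThreeStateParams,
    TwoStateParams,
    three_state_signal,
    two_state_ratio,
)

__all__ = [
    "NoiseSpec",
    "gen_timecourse",
    "gen_ca_response",
    "default_cd_params",
    "gen_cd_melt",
    "gen_dsf",
    "gen_chromatogram",
    "gen_sphere_curve",
    "sphere_form_factor",
    "gen_bead_model",
    "make_chain_topology",
    "gen_harmonic_ensemble",
]

CA_GRID_MM = (0.0, 0.01, 0.05, 0.2, 0.5, 2.0, 5.0, 20.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model attached to a generator run."""

    model: str = "gaussian-constant"   # | gaussian-proportional | saxs
    scale: float = 0.0
    floor: float = 0.0                 # additive floor for the saxs model
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale < 0 or self.floor < 0:
            raise ValueError("noise scale must be non-negative")
        if self.model not in ("gaussian-constant", "gaussian-proportional", "saxs"):
            raise ValueError(f"unknown noise model {self.model!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def sigma_for(self, signal: np.ndarray) -> np.ndarray:
        signal = np.abs(np.asarray(signal, dtype=float))
        if self.model == "gaussian-constant":
            return np.full_like(signal, self.scale)
        if self.model == "gaussian-proportional":
            return self.scale * signal
        return self.scale * np.sqrt(signal) + self.floor


def _apply_noise(signal: np.ndarray, noise: NoiseSpec | None):
    if noise is None or noise.scale == 0 and (noise is None or noise.floor == 0):
        return np.asarray(signal, dtype=float).copy(), None
    sigma = noise.sigma_for(signal)
    rng = noise.rng()
    return signal + rng.normal(0.0, np.where(sigma > 0, sigma, 0.0)), sigma


def gen_timecourse(true_velocity: float, n_points: int = 12,
                   interval: float = 30.0, noise: NoiseSpec | None = None,
                   enzyme_conc: float = 135.0,
                   reaction_volume: float = 25.0):
    """Linear reducing-end accumulation sampled every ``interval`` seconds.

    ``true_velocity`` is in nmol/min; the default 12 x 30 s grid covers the
    330 s regression window. Returns (ActivityTimecourse, truth dict).
    """
    if n_points < 3:
        raise ValueError("need at least 3 time points")
    t = np.arange(n_points) * interval
    ends = true_velocity / 60.0 * t
    ends, sigma = _apply_noise(ends, noise)
    tc = ActivityTimecourse(t, ends, enzyme_conc, reaction_volume)
    return tc, {"velocity": true_velocity, "sigma": sigma}


def gen_ca_response(params: CaResponseParams, grid=CA_GRID_MM,
                    noise: NoiseSpec | None = None):
    """Two-site model velocities on the assay's CaCl2 grid (mM)."""
    ca = np.asarray(grid, dtype=float)
    v = np.array([ca_model_velocity(params, c) for c in ca])
    vn, sigma = _apply_noise(v, noise)
    prof = ActivityProfile("CaCl2 mM", ca, vn,
                           stderrs=sigma if sigma is not None else None)
    return prof, {"params": params, "clean": v}


def default_cd_params(tm1: float, tm2: float, dh1: float, dh2: float,
                      n_wavelengths: int = 21,
                      config: BaselineConfig | None = None,
                      seed: int = 0) -> ThreeStateParams:
    """Three-state parameters with distinct, reproducible per-wavelength
    baselines spanning typical far-UV ellipticity magnitudes."""
    rng = np.random.default_rng(seed)
    config = config or BaselineConfig()
    base = np.zeros((n_wavelengths, 6))
    base[:, 0] = rng.uniform(-30, -10, n_wavelengths)       # native level
    base[:, 2] = base[:, 0] * rng.uniform(0.45, 0.65, n_wavelengths)
    base[:, 4] = rng.uniform(-6, -1, n_wavelengths)         # denatured level
    if config.sloped_n:
        base[:, 1] = rng.uniform(0.01, 0.05, n_wavelengths)
    if config.sloped_i:
        base[:, 3] = rng.uniform(-0.02, 0.02, n_wavelengths)
    if config.sloped_d:
        base[:, 5] = rng.uniform(0.005, 0.03, n_wavelengths)
    return ThreeStateParams(tm1, tm2, dh1, dh2, base, config)


def gen_cd_melt(params: ThreeStateParams,
                wavelengths=None, temperatures=None,
                noise: NoiseSpec | None = None):
    """CD melt matrix from the three-state model (default 210-230 nm,
    8-90 degC at 1 degC steps, matching a 1 degC/min ramp)."""
    n_wl = params.baselines.shape[0]
    if wavelengths is None:
        wavelengths = np.arange(210, 210 + n_wl, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size != n_wl:
        raise ValueError("wavelength count must match baseline rows")
    if temperatures is None:
        temperatures = np.arange(8.0, 90.0 + 0.5, 1.0)
    temperatures = np.asarray(temperatures, dtype=float)
    Y = np.column_stack([three_state_signal(temperatures, params, k)
                         for k in range(n_wl)])
    Yn, sigma = _apply_noise(Y, noise)
    ds = CDMeltDataset(temperatures, wavelengths, Yn, scan_rate=1.0)
    return ds, {"params": params, "clean": Y, "sigma": sigma}


def gen_dsf(params: TwoStateParams, temperatures=None,
            noise: NoiseSpec | None = None, direction: str = "heating"):
    """DSF 350/330 ratio curve (default 15-95 degC at 1 degC steps)."""
    if temperatures is None:
        temperatures = np.arange(15.0, 95.0 + 0.5, 1.0)
    temperatures = np.asarray(temperatures, dtype=float)
    y = two_state_ratio(temperatures, params)
    yn, sigma = _apply_noise(y, noise)
    curve = DSFCurve(temperatures, yn, direction)
    return curve, {"params": params, "clean": y, "sigma": sigma}


def gen_chromatogram(peaks: PeakSet, volumes=None,
                     noise: NoiseSpec | None = None):
    """Sum-of-Gaussians A280 trace from an analytic peak set."""
    if volumes is None:
        volumes = np.linspace(8.0, 20.0, 600)
    volumes = np.asarray(volumes, dtype=float)
    y = np.full_like(volumes, peaks.baseline)
    for c, w, a in zip(peaks.centers, peaks.widths, peaks.areas):
        y = y + _gauss(volumes, c, w, a)
    yn, sigma = _apply_noise(y, noise)
    return Chromatogram(volumes, yn), {"peaks": peaks, "clean": y, "sigma": sigma}


def sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Normalized scattering amplitude squared of a homogeneous sphere."""
    x = np.asarray(q, dtype=float) * radius
    amp = np.ones_like(x)
    nz = x != 0
    amp[nz] = 3.0 * (np.sin(x[nz]) - x[nz] * np.cos(x[nz])) / x[nz] ** 3
    return amp**2


def gen_sphere_curve(radius: float = 30.0, i0: float = 1.0, q=None,
                     noise: NoiseSpec | None = None) -> tuple[ScatteringCurve, dict]:
    """Analytic homogeneous-sphere scattering with q-dependent noise
    (sigma(q) = scale*sqrt(I) + floor, emulating counting statistics)."""
    if q is None:
        q = np.linspace(0.004, 0.35, 180)
    q = np.asarray(q, dtype=float)
    I = i0 * sphere_form_factor(q, radius)
    if noise is None or (noise.scale == 0 and noise.floor == 0):
        sigma = 1e-4 * i0 * np.ones_like(q)
        In = I.copy()
    else:
        sigma = noise.sigma_for(I)
        sigma = np.clip(sigma, 1e-12 * i0, None)
        In = I + noise.rng().normal(0.0, sigma)
    curve = ScatteringCurve(q, In, sigma, metadata={"wavelength": 1.34})
    return curve, {"radius": radius, "i0": i0,
                   "rg": np.sqrt(3.0 / 5.0) * radius, "clean": I}


def _lattice_sphere(radius: float, n_beads: int) -> np.ndarray:
    """Deterministic quasi-uniform filling of a sphere with a cubic lattice."""
    spacing = (4.0 / 3.0 * np.pi * radius**3 / n_beads) ** (1.0 / 3.0)
    g = np.arange(-radius, radius + spacing, spacing)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return pts[np.linalg.norm(pts, axis=1) <= radius]


def gen_bead_model(shape: str = "sphere", n_beads: int = 2000,
                   radius: float = 25.0, separation: float = 10.0,
                   seed: int = 0, placement: str = "lattice") -> AtomicModel:
    """Bead models for scattering fixtures.

    shapes: 'sphere' (radius), 'dumbbell' (two spheres, surface gap
    ``separation``), 'dimer-of-monomer' (random compact blob plus its
    two-fold copy). Lattice placement is deterministic; 'random' draws
    uniform positions with the given seed.
    """
    rng = np.random.default_rng(seed)
    if shape == "sphere":
        if placement == "lattice":
            pts = _lattice_sphere(radius, n_beads)
        else:
            u = rng.random(n_beads)
            r = radius * u ** (1.0 / 3.0)
            v = rng.normal(size=(n_beads, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            pts = r[:, None] * v
        return AtomicModel.from_beads(pts)
    if shape == "dumbbell":
        # two spheres with center-to-center distance `separation`;
        # the p(r) support is then separation + 2*radius
        half = gen_bead_model("sphere", n_beads // 2, radius, seed=seed,
                              placement=placement).coords
        shift = np.array([separation / 2.0, 0.0, 0.0])
        return AtomicModel.from_beads(np.vstack([half - shift, half + shift]))
    if shape == "dimer-of-monomer":
        blob = rng.normal(scale=radius / 2.0, size=(n_beads // 2, 3))
        blob[:, 0] += 2.5 * radius  # keep the monomer off the symmetry axis
        monomer = AtomicModel.from_beads(blob)
        return build_p2_dimer(monomer, axis_theta=0.0, axis_phi=0.0)
    raise ValueError(f"unknown shape {shape!r}")


def make_chain_topology(n_residues: int, chain: str = "A",
                        domains: dict | None = None,
                        residue_names=None) -> tuple[Topology, np.ndarray]:
    """Minimal poly-alanine-like backbone (N, CA, C, O per residue) laid
    out on a gentle helix; returns (topology, reference coordinates)."""
    names, elements, res_index = [], [], []
    coords = []
    rise, turn, rad = 1.5, 100.0 * np.pi / 180.0, 2.3
    offsets = {"N": np.array([-0.7, -0.6, 0.0]),
               "CA": np.array([0.0, 0.0, 0.0]),
               "C": np.array([0.8, 0.6, 0.2]),
               "O": np.array([0.9, 1.2, 1.0])}
    for ri in range(n_residues):
        ang = ri * turn
        ca = np.array([rad * np.cos(ang), rad * np.sin(ang), rise * ri])
        for name in ("N", "CA", "C", "O"):
            names.append(name)
            elements.append(name[0])
            res_index.append(ri)
            coords.append(ca + offsets[name])
    if residue_names is None:
        residue_names = ["ALA"] * n_residues
    top = Topology(np.array(names, dtype=object),
                   np.array(elements, dtype=object),
                   np.array(res_index),
                   residue_ids=np.arange(1, n_residues + 1),
                   residue_names=np.asarray(residue_names, dtype=object),
                   residue_chains=np.array([chain] * n_residues, dtype=object),
                   domains=domains or {})
    return top, np.asarray(coords, dtype=float)


def gen_harmonic_ensemble(topology: Topology, reference: np.ndarray,
                          sigma_per_residue, n_frames: int = 200,
                          n_replicates: int = 3, seed: int = 0,
                          collective_sd: float = 0.0):
    """Harmonic fluctuation ensemble: isotropic per-coordinate Gaussians.

    Each atom of residue i jitters independently with per-coordinate sd
    sigma_i (A), so the expected residue RMSF is sqrt(3)*sigma_i. An
    optional collective mode (x-displacements following a second harmonic
    along the chain, amplitude ~ N(0, collective_sd^2)) provides a dominant
    principal component; the second harmonic is orthogonal to rigid
    translations and nearly orthogonal to rigid rotations, so superposition
    does not absorb it. The expected leading eigenvalue is
    collective_sd^2 * mode_norm_sq. Returns (TrajectoryEnsemble, truth).
    """
    sigma = np.asarray(sigma_per_residue, dtype=float)
    if sigma.size != topology.n_residues:
        raise ValueError("one sigma per residue required")
    atom_sigma = sigma[topology.residue_index]
    rng = np.random.default_rng(seed)
    n_atoms = topology.n_atoms
    mode = np.zeros((n_atoms, 3))
    mode[:, 0] = np.cos(4.0 * np.pi * np.arange(n_atoms) / n_atoms)
    reps = []
    for _ in range(n_replicates):
        jitter = rng.normal(size=(n_frames, n_atoms, 3)) * atom_sigma[None, :, None]
        frames = reference[None, :, :] + jitter
        if collective_sd > 0:
            amp = rng.normal(0.0, collective_sd, size=n_frames)
            frames = frames + amp[:, None, None] * mode[None, :, :]
        reps.append(frames)
    ens = TrajectoryEnsemble(topology, reps, frame_spacing=100.0,
                             reference=reference.copy())
    truth = {"sigma_per_residue": sigma,
             "expected_rmsf": np.sqrt(3.0) * sigma,
             "collective_sd": collective_sd,
             "mode_norm_sq": float(np.sum(mode**2)),
             "expected_ev1": collective_sd**2 * float(np.sum(mode**2))}
    return ens, truth
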