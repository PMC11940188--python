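# Methods

This note documents the models implemented in `coldamyl`, the choices made
where the underlying procedures are conventionally underspecified, and
what the synthetic-data generators do and do not emulate.

## Activity and the two-site Ca²⁺ model

Initial velocities are ordinary least-squares slopes of reducing-end
amounts over time, restricted to a configurable window (default 330 s —
equivalently the 5.5 min used in some assay variants) and multiplied by 60
to give nmol/min. Specific activity divides by the molar amount of enzyme
in the reaction (concentration × volume), giving mol product · min⁻¹ ·
mol⁻¹ enzyme; the enzyme amount must be supplied by the user since it is
assay-specific. Constant-signal timecourses return velocity 0 with r²
reported as 0 and a degeneracy flag rather than an error.

The Ca²⁺ response is the equilibrium-weighted average of the velocities of
the apo, one-bound and two-bound enzyme. The textbook form has K_L1/[Ca]
terms and is singular at [Ca] = 0; we multiply numerator and denominator
by [Ca] so the expression is a ratio of quadratics that evaluates to
v(0) = V_apo exactly — the assay includes a 0 mM point, so this matters in
practice. Limits: v(0) = V_apo, v(∞) = V_L2, and for V_L1 >
max(V_apo, V_L2) the curve has a single interior maximum between K_L1 and
K_L2. Fitting is damped least squares (trust-region reflective, all
parameters bounded non-negative) multi-started from velocity extremes and
log-spaced K seeds, optionally 1/σ-weighted (default unweighted, since
assay replicates rarely justify strong weighting); parameter SEs come from
the Gauss–Newton covariance at the optimum. Constant data are fitted but
flagged: the K values are then unidentifiable.

## Thermal unfolding

**Three-state CD model.** The apparent ellipticity is the population
average of three linear state baselines with Boltzmann weights
w_N = exp(+ΔH₁(1 − T/T_m1)/(R·T)), w_I = 1, w_D = exp(−ΔH₂(1 − T/T_m2)/(R·T)),
where T is the absolute temperature (inputs in °C, converted with
+273.15) and R = 8.314 J·mol⁻¹·K⁻¹ (ΔH in J/mol; SI chosen since the unit
is conventionally left unstated). The intermediate's weight is fixed at 1,
the standard three-state normalization. Population fractions are computed
with a softmax over the log-weights, so no exponent ever overflows.

The global fit shares (t_m1, t_m2, ΔH₁, ΔH₂) across wavelengths while
each wavelength carries its own baselines. Because the baselines enter
linearly, they are profiled out by linear least squares at every step
(variable projection), reducing a ~130-parameter problem (21 wavelengths ×
6 baselines + 4) to a 4-parameter damped least-squares problem. The
ordering t_m1 ≤ t_m2 is enforced structurally by parameterizing
(t_m1, Δt_m ≥ 0), which removes label switching. Multi-start seeds come
from a coarse grid of t_m1 over the observed range crossed with several
transition separations and two enthalpy scales. Which states carry sloped
baselines is a per-dataset configuration ({sloped N, I, D}, default all
sloped), and wavelength subsetting (an explicit index list or an
every-second-wavelength stride) is supported, since real melts often need
both adjustments to converge. Degeneracy (effectively two-state data fed
to the three-state model) is detected from the column-scaled conditioning
of the structural Jacobian (relative singular-value ratio below 5×10⁻⁴)
or from SEs exceeding the temperature span, and reported as a flag plus a
warning, never silently.

**Two-state DSF model.** The 350/330 nm ratio is (F + U·K)/(1 + K) with
K = exp(−ΔH(1 − t/t_m)/(R·t)) and linear folded/unfolded baselines. By
default the temperature variable enters the exponent on the Celsius scale
on which the data are recorded and fitted in common practice; a
`kelvin=True` switch gives the thermodynamically conventional
absolute-temperature variant. Both place the midpoint exactly at t_m —
round-trip recovery of t_m is insensitive to the convention, but ΔH is
convention-dependent and should only be compared within one convention.
The Celsius form makes transitions extremely sharp for typical ΔH; the
fitter therefore seeds t_m at the steepest point of the measured curve in
addition to a coarse grid, with enthalpy seeds spanning 50–600 kJ/mol.
Replicates are fitted globally by stacking (all six parameters shared),
which shrinks the t_m SE roughly as 1/√n. Transitionless data are flagged
when the fitted baseline separation at t_m is small against both the
residual level and the overall signal span.

**Reversibility.** The hysteresis score is the mean absolute ratio
difference between heating and cooling scans over their overlapping
temperature range; the recovered fraction compares the cooled signal at
the cold end of the overlap with the folded and unfolded levels of the
heating scan (1 = full refolding, 0 = trapped unfolded). This scoring is a
pragmatic summary, not a thermodynamic quantity.

## SAXS

**Guinier.** ln I vs q² regression iterated so q·R_g ≤ 1.3 for all points
used. Two aggregation signatures abort with a flag: a positive slope, and
q_min·R_g exceeding the Guinier limit (the apparent particle is too large
for the measured q range — the classic low-q upturn).

**IFT.** p(r) is solved on a uniform grid over [0, D_max] with p(0) =
p(D_max) = 0 by stacking the 1/σ-weighted transform matrix
(I(q) = 4π∫p(r)·sinc(qr)dr) with a √α-scaled second-difference penalty;
non-negativity (default on) makes it an NNLS problem. The smoothness
functional is a standard second-difference penalty — the exact functional
of classical IFT implementations is not published in closed form, and any
smoothness-type regularizer serves. α is chosen by an L-curve corner
search (maximum discrete curvature over a log-spaced scan) unless fixed.
R_g² = ∫r²p dr / (2∫p dr) and I(0) = 4π∫p dr. The D_max scan uses an
Occam criterion: χ² plateaus once D_max covers the true support, and the
smallest D_max within 5% of the plateau minimum is selected.

**Molecular weight.** M = I(0)·N_A/(c·Δρ_m²) with Δρ_m = 2.0×10¹⁰ cm/g
and c converted from mg/mL to g/cm³. The Avogadro factor is required for
the result to come out in g/mol — formulations that omit it implicitly
fold N_A into Δρ_m² — and the implementation states it explicitly so the
round trip is exact by construction.

**Debye modelling.** I(q) = Σᵢⱼ fᵢ(q)fⱼ(q)·sinc(q·dᵢⱼ) over all non-H
atoms with Gaussian form factors fᵢ(q) = bᵢ·exp(−q²σᵢ²/2). Excess
scattering lengths are (Zᵢ − ρ_w·Vᵢ)·r_e with Fraser-style displaced
volumes and ρ_w = 0.334 e/Å³; widths match each element's vdW-sphere
radius of gyration (σ = r_vdW/√5). Bead models use user-set b and σ
(points by default). The sum is evaluated exactly (condensed distance
vector, chunked over q) — no distance binning — so it agrees with a naive
double loop to machine precision. A note on validation against the
analytic sphere form factor: an N-bead Debye sum carries an irreducible
self-term of relative size 1/N and the analytic curve has exact zeros, so
agreement is assessed as deviation relative to the forward intensity
(max |I/I(0) − F²| ≤ 2% for 2000 beads, qR ≤ 6), not pointwise.

**P2 dimers.** The second chain is the 180° rotation of the (optionally
re-oriented, offset) monomer about a symmetry axis through the origin;
configurations with interchain contacts closer than 2 Å are rejected.
Optimization against a measured curve refines the five angles
(two axis, three monomer-orientation) by Nelder–Mead on reduced χ² from
grid/random seeds, with clashes penalized.

**Mixtures.** Components are supplied per 1 mg/mL on absolute scale and
resampled onto the data grid by interpolation linear in log I
(extrapolation is refused); non-negative least squares then returns
weights that are concentrations in mg/mL directly. Near-collinear
components (weighted cosine > 0.9999) are flagged.

## SEC

Calibration is OLS of log₁₀(MW/kDa) on elution volume (slope necessarily
negative); MW estimates outside the standard range warn. Chromatograms
are deconvolved as sums of Gaussians above a constant baseline
(area-parameterized, seeded at signal-mass quantiles), with an
exponentially modified Gaussian option for skewed peaks. Area fractions
use the fitted analytic areas, not raw integrals, matching how combined
peak areas are normally quoted; strong parameter correlations (overlapping
unresolvable peaks) set an `unresolved` flag.

## MD flexibility

Superposition uses the optimal proper rotation (SVD-based) on a masked
atom set (default backbone N/CA/C/O). RMSF uses the per-replicate average
structure as reference — frames are iteratively superposed to their
running mean — because RMSF values depend strongly on the reference
choice; per-residue values are RMS over the residue's backbone atoms and
replicates combine as mean ± sd. RMSD and R_g are reported as mean ± SEM
over the concatenated replicates, matching the way trajectory tables are
conventionally summarized.

SASA is Shrake–Rupley with a golden-spiral point lattice (960 points,
probe 1.4 Å) over Bondi vdW radii; an independent implementation
(mdtraj's) agrees to well within 1% on shared inputs. Hydrogen bonds
count donor(N/O with bonded H)–acceptor(N/O) pairs at heavy-atom distance
≤ 3.5 Å and H–donor–acceptor angle ≤ 30°, excluding same-residue pairs;
these cutoffs are the common trajectory-analysis defaults and are
configurable since no single convention is universal. Topologies without
hydrogens fall back to a distance-only criterion on unordered polar
pairs, with a warning. Salt bridges count each
(Asp/Glu carboxylate-O, Lys/Arg/His cationic-N) residue pair once when the
closest O–N distance is ≤ 4.0 Å.

Homolog comparison aligns sequences globally (BLOSUM62, gap open −11,
extend −1) and classifies each mapped residue by ΔRMSF = RMSF_psychro −
RMSF_homolog at a ±0.5 Å threshold with *strict* inequalities — a residue
exactly at the threshold counts as unchanged; "at least 0.5 Å" phrasing
is ambiguous and strictness is the documented choice. Counts are
attributed to the annotated domains (A, B, C, N of the GH13 architecture)
of the first enzyme. PCA diagonalizes the covariance of masked coordinates
over the concatenated, globally superposed trajectory; eigenvalues are in
Å², projections are reported on the first two eigenvectors, and cumulative
variance fractions support "first k eigenvectors cover x%" summaries.
Coordinates are unweighted (mass weighting optional by supplying a mask
and weights upstream), as the common tooling's default.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`), bit-reproducible, and
return their ground truth beside the data. Defaults encode the study
conditions: 30 s sampling over a 330 s window; the CaCl₂ grid
{0, 0.01, 0.05, 0.2, 0.5, 2, 5, 20} mM; CD melts at 210–230 nm over
8–90 °C in 1 °C steps (1 °C/min ramp); DSF over 15–95 °C in 1 °C steps;
SAXS with λ = 1.34 Å metadata and noise σ(q) = a·√I(q) + b emulating
counting statistics (no error model is standard, so a photon-like model
was chosen once). Harmonic ensembles jitter every atom of a residue
independently and isotropically with per-coordinate sd σᵢ, the simplest
model for which the expected RMSF has the closed form √3·σᵢ; an optional
collective mode follows a second harmonic along the chain so that rigid-
body superposition cannot absorb it, giving a leading PCA eigenvalue of
σ_mode²·Σmode² by construction. What these generators deliberately do
*not* emulate: correlated atomic motions and anharmonicity of real
trajectories, realistic CD band shapes below 210 nm, scan-rate hysteresis,
interparticle structure factors, and chromatographic tailing beyond the
EMG shape. Passing recovery tests therefore demonstrates correctness of
the estimators under their stated statistical assumptions, not robustness
to every pathology of real data.

## Problem sizes and numerical choices

The test suite and the reproduction script run at desk scale by design:
melts use the full experimental grids (83 temperatures × 21 wavelengths),
bead models ≤ 2000 beads, harmonic ensembles 3 × ~670 frames of a
150-residue chain, SASA on strided frames. Optimizer tolerances are
1e-12–1e-14 on damped least squares; IFT grids default to 100 r-bins;
the Debye sum chunks q to bound memory. Known limitations: the CD fit's
SEs are Gauss–Newton approximations (no profile likelihood); the
P2 optimizer is a local refiner over seeds, not a global search; hydration
shells for atomic models are not generated automatically (bead b/σ can be
set to mimic them); and the Celsius-scale DSF exponent, while faithful to
common practice, makes ΔH values convention-bound.
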