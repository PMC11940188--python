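"""Trajectory-derived flexibility metrics for psychrophile/mesophile pairs.

Implements the comparative-dynamics toolbox used to contrast cold-active
enzymes with their thermostable homologs: Kabsch superposition and RMSD,
replicate-combined per-residue RMSF, radius of gyration, Shrake-Rupley
solvent-accessible surface area, hydrogen-bond and salt-bridge counting,
sequence-mapped per-residue flexibility classification at a +/-0.5 A
threshold with domain attribution, and backbone principal component
analysis (essential dynamics) with projections onto the first two
eigenvectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .constants import atomic_mass, vdw_radius

__all__ = [
    "Topology",
    "TrajectoryEnsemble",
    "ResidueProfile",
    "FlexComparison",
    "PCAResult",
    "StructureMetrics",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_profile",
    "gyration",
    "sasa",
    "hbond_count",
    "salt_bridge_count",
    "align_residues",
    "compare_flexibility",
    "pca_backbone",
    "metrics_table",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: side-chain atoms carrying formal charge, by residue name
ANIONIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
CATIONIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
                  "HIS": ("ND1", "NE2")}


@dataclass
class Topology:
    """Static description of the simulated system.

    Per-atom arrays (atom_names, elements, residue_index, radii) plus
    per-residue arrays (residue_ids, residue_names, residue_chains).
    ``domains`` maps a domain label to a list of inclusive residue-id
    intervals; intervals must not overlap across domains.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    residue_index: np.ndarray      # per atom, 0-based residue position
    residue_ids: np.ndarray        # per residue
    residue_names: np.ndarray
    residue_chains: np.ndarray
    radii: np.ndarray | None = None
    domains: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray([str(e).upper() for e in self.elements],
                                   dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.residue_index.size != self.atom_names.size:
            raise ValueError("every atom must map to a residue")
        if self.residue_index.size and self.residue_index.max() >= len(self.residue_ids):
            raise ValueError("residue_index out of range")
        if self.radii is None:
            self.radii = np.array([vdw_radius(e) for e in self.elements])
        else:
            self.radii = np.asarray(self.radii, dtype=float)
        self._check_domains()

    def _check_domains(self) -> None:
        seen: list[tuple[int, int]] = []
        for label, intervals in self.domains.items():
            for lo, hi in intervals:
                for plo, phi in seen:
                    if lo <= phi and plo <= hi:
                        raise ValueError(f"domain interval overlap at {label}")
                seen.append((lo, hi))

    @property
    def n_atoms(self) -> int:
        return self.atom_names.size

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def backbone_mask(self) -> np.ndarray:
        return np.isin(self.atom_names.astype(str), BACKBONE_ATOMS)

    @property
    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(e) for e in self.elements])

    def domain_of(self, residue_id: int) -> str | None:
        for label, intervals in self.domains.items():
            for lo, hi in intervals:
                if lo <= residue_id <= hi:
                    return label
        return None


@dataclass
class TrajectoryEnsemble:
    """Replicated coordinate frames over a shared topology."""

    topology: Topology
    replicates: list            # each (n_frames, n_atoms, 3), A
    frame_spacing: float = 1.0  # ps
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]
        for r in self.replicates:
            if r.ndim != 3 or r.shape[1] != self.topology.n_atoms or r.shape[0] < 1:
                raise ValueError("replicate shape must be (frames, atoms, 3)")
        if self.reference is None and self.replicates:
            self.reference = self.replicates[0][0].copy()

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.replicates, axis=0)


@dataclass
class ResidueProfile:
    residue_ids: np.ndarray
    rmsf_mean: np.ndarray     # A
    rmsf_sd: np.ndarray | None = None   # across replicates; None if single


@dataclass
class FlexComparison:
    pairs: list                   # (residue_id_a, residue_id_b)
    delta_rmsf: np.ndarray        # rmsf_a - rmsf_b, A
    labels: np.ndarray            # 'increased' | 'decreased' | 'unchanged'
    threshold: float
    n_increased: int
    n_decreased: int
    per_domain: dict              # domain -> {'increased': n, 'decreased': n}
    unmapped_a: list = field(default_factory=list)
    unmapped_b: list = field(default_factory=list)

    @property
    def fraction_increased(self) -> float:
        return self.n_increased / max(len(self.pairs), 1)


@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # A^2, descending
    eigenvectors: np.ndarray       # (3N, 3N) columns orthonormal
    projections: np.ndarray        # (n_frames, 2), A
    cumulative_variance: np.ndarray


@dataclass
class StructureMetrics:
    rmsd: tuple          # (mean, sem) A
    rmsf: tuple          # (mean over residues, sd) A
    rg: tuple            # (mean, sem) A
    sasa_nm2: tuple      # (mean, sem) nm^2
    n_hbonds: tuple      # (mean, sem)
    n_salt_bridges: tuple


# ---------------------------------------------------------------------------
# superposition and deviation metrics


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return float(x.mean()), sem


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     mask: np.ndarray | None = None):
    """Least-squares superposition of ``mobile`` onto ``reference``.

    The optimal proper rotation is found on the masked atoms and applied to
    all atoms. Returns (aligned coordinates, masked RMSD in A).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mask is None:
        mask = np.ones(mobile.shape[0], dtype=bool)
    a = mobile[mask]
    b = reference[mask]
    if a.shape[0] < 3:
        raise ValueError("need at least 3 masked atoms")
    ac, bc = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ac, b - bc
    if np.linalg.matrix_rank(a0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) atom selection")
    rot, _ = Rotation.align_vectors(b0, a0)
    R = rot.as_matrix()
    aligned = (mobile - ac) @ R.T + bc
    rmsd = float(np.sqrt(np.mean(np.sum((aligned[mask] - reference[mask]) ** 2,
                                        axis=1))))
    return aligned, rmsd


def rmsd_series(ens: TrajectoryEnsemble, reference: np.ndarray | None = None,
                mask: np.ndarray | None = None) -> dict:
    """Per-frame superposed RMSD plus the concatenated-replicate mean +/- SEM."""
    if not ens.replicates:
        raise ValueError("empty trajectory ensemble")
    if reference is None:
        reference = ens.reference
    if mask is None:
        mask = ens.topology.backbone_mask
    per_rep = []
    for rep in ens.replicates:
        vals = np.array([kabsch_superpose(f, reference, mask)[1] for f in rep])
        per_rep.append(vals)
    allv = np.concatenate(per_rep)
    mean, sem = _mean_sem(allv)
    return {"per_frame": per_rep, "mean": mean, "sem": sem}


def _superpose_to_mean(frames: np.ndarray, mask: np.ndarray,
                       n_iter: int = 2) -> np.ndarray:
    """Iteratively superpose frames to their running average structure."""
    ref = frames[0]
    out = frames
    for _ in range(n_iter):
        out = np.stack([kabsch_superpose(f, ref, mask)[0] for f in out])
        ref = out.mean(axis=0)
    return np.stack([kabsch_superpose(f, ref, mask)[0] for f in out])


def rmsf_profile(ens: TrajectoryEnsemble, mask: np.ndarray | None = None) -> ResidueProfile:
    """Per-residue backbone RMSF, combined across replicates as mean +/- sd.

    Each replicate is superposed to its own average structure (the RMSF
    reference) before fluctuations are measured; the per-residue value is
    the RMS over that residue's masked atoms.
    """
    top = ens.topology
    if mask is None:
        mask = top.backbone_mask
    per_rep = []
    for rep in ens.replicates:
        if rep.shape[0] < 2:
            raise ValueError("RMSF needs >= 2 frames per replicate")
        aligned = _superpose_to_mean(rep, mask)
        mean_struct = aligned.mean(axis=0)
        msf_atom = np.mean(np.sum((aligned - mean_struct) ** 2, axis=2), axis=0)
        res_vals = np.empty(top.n_residues)
        for ri in range(top.n_residues):
            sel = (top.residue_index == ri) & mask
            res_vals[ri] = np.sqrt(msf_atom[sel].mean()) if sel.any() else np.nan
        per_rep.append(res_vals)
    arr = np.stack(per_rep)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else None
    return ResidueProfile(np.asarray(top.residue_ids), arr.mean(axis=0), sd)


def gyration(ens: TrajectoryEnsemble, mask: np.ndarray | None = None) -> dict:
    """Mass-weighted radius of gyration per frame, mean +/- SEM."""
    top = ens.topology
    if mask is None:
        mask = np.ones(top.n_atoms, dtype=bool)
    if not mask.any():
        raise ValueError("empty atom mask")
    m = top.masses[mask]
    M = m.sum()
    if M <= 0:
        raise ValueError("zero total mass")
    per_rep = []
    for rep in ens.replicates:
        x = rep[:, mask, :]
        com = np.einsum("fax,a->fx", x, m) / M
        d2 = np.sum((x - com[:, None, :]) ** 2, axis=2)
        per_rep.append(np.sqrt(np.einsum("fa,a->f", d2, m) / M))
    allv = np.concatenate(per_rep)
    mean, sem = _mean_sem(allv)
    return {"per_frame": per_rep, "mean": mean, "sem": sem}


# ---------------------------------------------------------------------------
# surfaces and interactions


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(frame: np.ndarray, topology: Topology, probe: float = 1.4,
         n_points: int = 960, mask: np.ndarray | None = None) -> dict:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's vdW sphere is inflated by the probe radius and sampled with
    a fixed spherical point lattice; points inside any neighbouring
    inflated sphere are inaccessible. Returns per-atom areas (A^2) plus the
    total in A^2 and nm^2.
    """
    frame = np.asarray(frame, dtype=float)
    if mask is None:
        mask = np.ones(topology.n_atoms, dtype=bool)
    radii = topology.radii + probe
    pts = _sphere_points(n_points)
    coords = frame[mask]
    rads = radii[mask]
    tree = cKDTree(coords)
    rmax = rads.max()
    per_atom = np.zeros(topology.n_atoms)
    idx_map = np.where(mask)[0]
    for ii, (c, r) in enumerate(zip(coords, rads)):
        neigh = tree.query_ball_point(c, r + rmax)
        neigh = [j for j in neigh if j != ii]
        test = c + r * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((test - coords[j]) ** 2, axis=1)
            accessible &= d2 > rads[j] ** 2
            if not accessible.any():
                break
        per_atom[idx_map[ii]] = 4.0 * np.pi * r**2 * accessible.mean()
    total = float(per_atom.sum())
    return {"per_atom": per_atom, "total_A2": total, "total_nm2": total / 100.0}


def _bonded_hydrogens(frame, topology, heavy_idx, max_bond: float = 1.3):
    """Indices of H atoms within bonding distance of each heavy atom."""
    h_idx = np.where(topology.elements == "H")[0]
    out: dict[int, list[int]] = {i: [] for i in heavy_idx}
    if h_idx.size == 0:
        return out
    tree = cKDTree(frame[h_idx])
    for i in heavy_idx:
        for jj in tree.query_ball_point(frame[i], max_bond):
            out[i].append(int(h_idx[jj]))
    return out


def hbond_count(frame: np.ndarray, topology: Topology, d_max: float = 3.5,
                angle_max: float = 30.0) -> int:
    """Count intra-protein hydrogen bonds.

    Criterion: donor(N/O with attached H)-acceptor(N/O) heavy-atom distance
    <= d_max and H-donor-acceptor angle <= angle_max degrees. Same-residue
    pairs are excluded. Without hydrogens in the topology a distance-only
    heavy-atom criterion is used (flagged via a warning).
    """
    frame = np.asarray(frame, dtype=float)
    polar = np.where(np.isin(topology.elements.astype(str), ("N", "O")))[0]
    if polar.size == 0:
        return 0
    has_h = bool(np.any(topology.elements == "H"))
    hydrogens = _bonded_hydrogens(frame, topology, polar) if has_h else {}
    if has_h:
        donors = np.array([i for i in polar if hydrogens[i]], dtype=int)
    else:
        warnings.warn("topology lacks hydrogens: distance-only H-bond "
                      "criterion", stacklevel=2)
        donors = polar
    acceptors = polar
    if donors.size == 0:
        return 0
    tree = cKDTree(frame[acceptors])
    cos_min = np.cos(np.deg2rad(angle_max))
    count = 0
    for d in donors:
        for jj in tree.query_ball_point(frame[d], d_max):
            a = int(acceptors[jj])
            if a == d:
                continue
            if topology.residue_index[a] == topology.residue_index[d]:
                continue
            if not has_h:
                # donor/acceptor roles are indistinct without H: count
                # each unordered polar pair once
                if a > d:
                    count += 1
                continue
            ok = False
            for h in hydrogens[d]:
                v1 = frame[h] - frame[d]
                v2 = frame[a] - frame[d]
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if cosang >= cos_min:
                    ok = True
                    break
            count += ok
    return int(count)


def salt_bridge_count(frame: np.ndarray, topology: Topology,
                      cutoff: float = 4.0) -> int:
    """Count salt bridges: one per (anionic, cationic) residue pair whose
    closest carboxylate-O to cationic-N distance is <= cutoff (A)."""
    frame = np.asarray(frame, dtype=float)
    top = topology
    res_names = np.asarray(top.residue_names).astype(str)
    an_atoms, an_res = [], []
    cat_atoms, cat_res = [], []
    for i in range(top.n_atoms):
        ri = top.residue_index[i]
        rn = res_names[ri]
        name = str(top.atom_names[i])
        if rn in ANIONIC_ATOMS and name in ANIONIC_ATOMS[rn]:
            an_atoms.append(i)
            an_res.append(ri)
        if rn in CATIONIC_ATOMS and name in CATIONIC_ATOMS[rn]:
            cat_atoms.append(i)
            cat_res.append(ri)
    if not an_atoms or not cat_atoms:
        return 0
    an_xyz = frame[an_atoms]
    cat_xyz = frame[cat_atoms]
    d = np.linalg.norm(an_xyz[:, None, :] - cat_xyz[None, :, :], axis=2)
    pairs = set()
    ii, jj = np.where(d <= cutoff)
    for a, c in zip(ii, jj):
        pairs.add((an_res[a], cat_res[c]))
    return len(pairs)


# ---------------------------------------------------------------------------
# homolog comparison


def align_residues(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Globally align two sequences, returning matched index pairs only.

    Uses BLOSUM62 with affine gap penalties (open -11, extend -1); gapped
    positions are dropped so the mapping pairs equivalent residues.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def compare_flexibility(profile_a: ResidueProfile, profile_b: ResidueProfile,
                        mapping: list[tuple[int, int]] | None = None,
                        threshold: float = 0.5,
                        topology_a: Topology | None = None) -> FlexComparison:
    """Classify per-residue RMSF differences of enzyme A vs homolog B.

    Delta = rmsf_a - rmsf_b per mapped residue pair; a residue is labelled
    'increased' when delta > threshold, 'decreased' when delta < -threshold
    and 'unchanged' otherwise (strict inequalities: a tie at the threshold
    is unchanged). Counts are attributed to the domains of enzyme A when a
    topology with domain annotations is supplied.
    """
    ids_a = np.asarray(profile_a.residue_ids)
    ids_b = np.asarray(profile_b.residue_ids)
    if mapping is None:
        if ids_a.size != ids_b.size:
            raise ValueError("profiles differ in length; supply a mapping")
        mapping = list(zip(range(ids_a.size), range(ids_b.size)))
    mapped_a = {i for i, _ in mapping}
    mapped_b = {j for _, j in mapping}
    unmapped_a = [int(ids_a[i]) for i in range(ids_a.size) if i not in mapped_a]
    unmapped_b = [int(ids_b[j]) for j in range(ids_b.size) if j not in mapped_b]

    pairs, deltas, labels = [], [], []
    per_domain: dict = {}
    n_inc = n_dec = 0
    for i, j in mapping:
        d = profile_a.rmsf_mean[i] - profile_b.rmsf_mean[j]
        if d > threshold:
            lab = "increased"
            n_inc += 1
        elif d < -threshold:
            lab = "decreased"
            n_dec += 1
        else:
            lab = "unchanged"
        rid_a = int(ids_a[i])
        pairs.append((rid_a, int(ids_b[j])))
        deltas.append(d)
        labels.append(lab)
        if topology_a is not None and lab != "unchanged":
            dom = topology_a.domain_of(rid_a) or "unassigned"
            per_domain.setdefault(dom, {"increased": 0, "decreased": 0})
            per_domain[dom][lab] += 1
    return FlexComparison(pairs, np.asarray(deltas), np.asarray(labels),
                          threshold, n_inc, n_dec, per_domain,
                          unmapped_a, unmapped_b)


# ---------------------------------------------------------------------------
# essential dynamics


def pca_backbone(ens: TrajectoryEnsemble, mask: np.ndarray | None = None) -> PCAResult:
    """PCA of the masked-coordinate covariance over the concatenated
    trajectory (frames superposed to the global mean structure first)."""
    top = ens.topology
    if mask is None:
        mask = top.backbone_mask
    frames = ens.concatenated()
    if frames.shape[0] < 2:
        raise ValueError("PCA needs at least 2 frames")
    frames = _superpose_to_mean(frames, mask)
    X = frames[:, mask, :].reshape(frames.shape[0], -1)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    proj = Xc @ evecs[:, :2]
    cum = np.cumsum(evals) / max(evals.sum(), 1e-300)
    return PCAResult(evals, evecs, proj, cum)


# ---------------------------------------------------------------------------
# summary report


def metrics_table(ens: TrajectoryEnsemble, sasa_stride: int = 10,
                  hbond_stride: int = 10, probe: float = 1.4,
                  n_points: int = 960) -> StructureMetrics:
    """Trajectory-average structural metrics (mean +/- SEM convention).

    RMSD/Rg use every frame of the concatenated replicates; SASA, H-bond
    and salt-bridge counts are evaluated on a strided frame subset (they
    are by far the costliest metrics).
    """
    top = ens.topology
    rmsd = rmsd_series(ens)
    prof = rmsf_profile(ens)
    rg = gyration(ens)
    frames = ens.concatenated()[::max(sasa_stride, 1)]
    sasa_vals = np.array([sasa(f, top, probe=probe, n_points=n_points)["total_nm2"]
                          for f in frames])
    frames_hb = ens.concatenated()[::max(hbond_stride, 1)]
    hb = np.array([hbond_count(f, top) for f in frames_hb], dtype=float)
    sb = np.array([salt_bridge_count(f, top) for f in frames_hb], dtype=float)
    rmsf_mean = float(np.nanmean(prof.rmsf_mean))
    rmsf_sd = float(np.nanmean(prof.rmsf_sd)) if prof.rmsf_sd is not None else 0.0
    return StructureMetrics(
        rmsd=(rmsd["mean"], rmsd["sem"]),
        rmsf=(rmsf_mean, rmsf_sd),
        rg=(rg["mean"], rg["sem"]),
        sasa_nm2=_mean_sem(sasa_vals),
        n_hbonds=_mean_sem(hb),
        n_salt_bridges=_mean_sem(sb),
    )
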