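"""Trajectory metrics, flexibility comparison and essential dynamics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from coldamyl.mdflex import (
    Topology,
    TrajectoryEnsemble,
    ResidueProfile,
    align_residues,
    compare_flexibility,
    gyration,
    hbond_count,
    kabsch_superpose,
    metrics_table,
    pca_backbone,
    rmsd_series,
    rmsf_profile,
    salt_bridge_count,
    sasa,
)
from coldamyl.synth import gen_harmonic_ensemble, make_chain_topology


def single_atom_topology(element="C", name="CA", res_name="ALA"):
    return Topology(np.array([name], dtype=object), np.array([element], dtype=object),
                    np.array([0]), np.array([1]), np.array([res_name], dtype=object),
                    np.array(["A"], dtype=object))


def point_topology(n, element="C"):
    return Topology(np.array(["X"] * n, dtype=object),
                    np.array([element] * n, dtype=object),
                    np.zeros(n, dtype=int), np.array([1]),
                    np.array(["ALA"], dtype=object), np.array(["A"], dtype=object))


class TestKabsch:
    def test_identical_structures(self, rng):
        x = rng.normal(size=(50, 3))
        _, r = kabsch_superpose(x, x)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rotation_translation_invariance(self, rng):
        x = rng.normal(size=(80, 3)) * 10
        R = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).as_matrix()
        y = x @ R.T + np.array([3.0, -7.0, 1.5])
        _, r = kabsch_superpose(y, x)
        assert r < 1e-9

    def test_single_displacement_matches_optimizer_oracle(self, rng):
        from scipy.optimize import minimize

        x = rng.normal(size=(100, 3)) * 12
        y = x.copy()
        y[0] += np.array([1.0, 0.0, 0.0])
        _, r_kabsch = kabsch_superpose(y, x)

        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)

        def cost(rv):
            R = Rotation.from_rotvec(rv).as_matrix()
            return np.mean(np.sum((yc @ R.T - xc) ** 2, axis=1))

        best = min((minimize(cost, rv0, method="Nelder-Mead",
                             options={"xatol": 1e-12, "fatol": 1e-16})
                    for rv0 in [np.zeros(3), np.array([0.01, 0, 0])]),
                   key=lambda r: r.fun)
        assert r_kabsch == pytest.approx(np.sqrt(best.fun), abs=1e-6)
        assert r_kabsch == pytest.approx(np.sqrt(1.0 / 100), rel=0.05)

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + 1.0)


class TestRMSD:
    def test_static_trajectory_zero(self):
        top, ref = make_chain_topology(10)
        ens = TrajectoryEnsemble(top, [np.stack([ref] * 5)])
        out = rmsd_series(ens)
        assert out["mean"] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_jitter_expectation(self):
        top, ref = make_chain_topology(200)
        sigma = 0.3
        ens, _ = gen_harmonic_ensemble(top, ref, np.full(200, sigma),
                                       n_frames=60, n_replicates=1, seed=2)
        out = rmsd_series(ens, reference=ref,
                          mask=np.ones(top.n_atoms, dtype=bool))
        assert out["mean"] == pytest.approx(np.sqrt(3) * sigma, rel=0.02)

    def test_concatenated_mean_is_frame_weighted(self):
        top, ref = make_chain_topology(12)
        ens, _ = gen_harmonic_ensemble(top, ref, np.full(12, 0.2),
                                       n_frames=20, n_replicates=3, seed=3)
        out = rmsd_series(ens)
        per_rep_means = [v.mean() for v in out["per_frame"]]
        ns = [len(v) for v in out["per_frame"]]
        weighted = np.average(per_rep_means, weights=ns)
        assert out["mean"] == pytest.approx(weighted, rel=1e-12)


class TestRMSF:
    def test_static_zero_and_identical_replicates(self):
        top, ref = make_chain_topology(8)
        frames = np.stack([ref] * 4)
        ens = TrajectoryEnsemble(top, [frames, frames.copy(), frames.copy()])
        prof = rmsf_profile(ens)
        assert np.allclose(prof.rmsf_mean, 0.0, atol=1e-12)
        assert np.allclose(prof.rmsf_sd, 0.0, atol=1e-12)

    def test_harmonic_amplitude_recovery(self):
        top, ref = make_chain_topology(150)
        sig = np.linspace(0.2, 1.2, 150)
        ens, truth = gen_harmonic_ensemble(top, ref, sig, n_frames=667,
                                           n_replicates=3, seed=0)
        prof = rmsf_profile(ens)
        rel = np.abs(prof.rmsf_mean - truth["expected_rmsf"]) / truth["expected_rmsf"]
        assert rel.max() < 0.05
        assert np.corrcoef(prof.rmsf_mean, truth["expected_rmsf"])[0, 1] > 0.99

    def test_single_replicate_has_no_sd(self):
        top, ref = make_chain_topology(6)
        ens, _ = gen_harmonic_ensemble(top, ref, np.full(6, 0.1),
                                       n_frames=10, n_replicates=1, seed=1)
        assert rmsf_profile(ens).rmsf_sd is None


class TestGyration:
    def test_cube_closed_form(self):
        corners = np.array([[x, y, z] for x in (-1, 1) for y in (-1, 1)
                            for z in (-1, 1)], dtype=float)
        top = point_topology(8)
        ens = TrajectoryEnsemble(top, [corners[None]])
        out = gyration(ens)
        assert out["mean"] == pytest.approx(np.sqrt(3.0), rel=1e-12)

    def test_uniform_sphere(self, rng):
        n = 4000
        u = rng.random(n) ** (1 / 3)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = 20.0 * u[:, None] * v
        top = point_topology(n)
        ens = TrajectoryEnsemble(top, [pts[None]])
        assert gyration(ens)["mean"] == pytest.approx(np.sqrt(3 / 5) * 20.0, rel=0.02)

    def test_translation_invariance(self, rng):
        pts = rng.normal(size=(30, 3)) * 5
        top = point_topology(30)
        g1 = gyration(TrajectoryEnsemble(top, [pts[None]]))["mean"]
        g2 = gyration(TrajectoryEnsemble(top, [(pts + 100.0)[None]]))["mean"]
        assert g1 == pytest.approx(g2, rel=1e-12)


class TestSASA:
    def test_isolated_carbon_closed_form(self):
        top = single_atom_topology("C")
        out = sasa(np.zeros((1, 3)), top)
        assert out["total_A2"] == pytest.approx(4 * np.pi * 3.1**2, rel=0.005)

    def test_distant_atoms_additive(self):
        top = point_topology(2)
        joined = sasa(np.array([[0.0, 0, 0], [100.0, 0, 0]]), top)["total_A2"]
        single = sasa(np.zeros((1, 3)), single_atom_topology("C"))["total_A2"]
        assert joined == pytest.approx(2 * single, rel=1e-9)

    def test_caged_atom_buried(self):
        # central atom surrounded by a tight icosahedral-ish cage
        from coldamyl.mdflex import _sphere_points
        cage = 2.8 * _sphere_points(60)
        coords = np.vstack([[0.0, 0, 0], cage])
        top = point_topology(61)
        out = sasa(coords, top)
        assert out["per_atom"][0] == pytest.approx(0.0, abs=1e-9)

    def test_rotation_invariance(self, rng):
        pts = rng.normal(size=(20, 3)) * 4
        top = point_topology(20)
        R = Rotation.from_euler("zyx", [1.0, 0.3, -0.7]).as_matrix()
        a = sasa(pts, top)["total_A2"]
        b = sasa(pts @ R.T, top)["total_A2"]
        assert abs(a - b) / a < 2e-3  # grid effects only

    def test_cross_check_against_mdtraj(self, tmp_path):
        """Independent implementation comparison on a written-out PDB."""
        import mdtraj
        from coldamyl.io import write_trajectory_pdb
        from coldamyl.mdflex import TrajectoryEnsemble
        from coldamyl.synth import make_chain_topology

        top, ref = make_chain_topology(20)
        ens = TrajectoryEnsemble(top, [np.stack([ref] * 2)])
        path = tmp_path / "chain.pdb"
        write_trajectory_pdb(ens, path)
        traj = mdtraj.load(str(path))
        mine = sasa(ref, top)["total_nm2"]
        theirs = mdtraj.shrake_rupley(traj, probe_radius=0.14,
                                      n_sphere_points=960).sum(axis=1)[0]
        assert mine == pytest.approx(theirs, rel=0.01)


def brute_force_hbonds(frame, top, d_max=3.5, angle_max=30.0):
    """Exhaustive donor/acceptor loops (oracle)."""
    polar = [i for i, e in enumerate(top.elements) if e in ("N", "O")]
    hyd = {i: [] for i in polar}
    for h in range(top.n_atoms):
        if top.elements[h] != "H":
            continue
        for i in polar:
            if np.linalg.norm(frame[h] - frame[i]) < 1.3:
                hyd[i].append(h)
    count = 0
    for d in polar:
        if not hyd[d]:
            continue
        for a in polar:
            if a == d or top.residue_index[a] == top.residue_index[d]:
                continue
            if np.linalg.norm(frame[a] - frame[d]) > d_max:
                continue
            for h in hyd[d]:
                v1 = frame[h] - frame[d]
                v2 = frame[a] - frame[d]
                ang = np.degrees(np.arccos(np.clip(
                    v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1)))
                if ang <= angle_max:
                    count += 1
                    break
    return count


class TestHBonds:
    def helix_fragment(self, n_bonds=10, spacing=3.0):
        """n_bonds ideal linear N-H...O bonds, each in its own residue pair."""
        names, elements, res_index = [], [], []
        coords = []
        for k in range(n_bonds):
            y = 10.0 * k
            # donor residue: N and its H; acceptor residue: O
            names += ["N", "H", "O"]
            elements += ["N", "H", "O"]
            res_index += [2 * k, 2 * k, 2 * k + 1]
            coords += [[0.0, y, 0.0], [1.0, y, 0.0], [2.9, y, 0.0]]
        n_res = 2 * n_bonds
        top = Topology(np.array(names, dtype=object), np.array(elements, dtype=object),
                       np.array(res_index), np.arange(1, n_res + 1),
                       np.array(["ALA"] * n_res, dtype=object),
                       np.array(["A"] * n_res, dtype=object))
        return np.asarray(coords), top

    def test_ideal_bond_and_distance_cutoff(self):
        coords, top = self.helix_fragment(1)
        assert hbond_count(coords, top) == 1
        far = coords.copy()
        far[2, 0] = 4.0
        assert hbond_count(far, top) == 0

    def test_angle_cutoff(self):
        coords, top = self.helix_fragment(1)
        bent = coords.copy()
        # acceptor at 60 degrees from the N-H direction
        bent[2] = [2.9 * np.cos(np.pi / 3), 2.9 * np.sin(np.pi / 3), 0.0]
        assert hbond_count(bent, top) == 0

    def test_fragment_matches_brute_force(self):
        coords, top = self.helix_fragment(10)
        assert hbond_count(coords, top) == 10
        assert hbond_count(coords, top) == brute_force_hbonds(coords, top)

    def test_heavy_atom_fallback_flagged(self):
        coords, top = self.helix_fragment(1)
        keep = [0, 2]
        top2 = Topology(top.atom_names[keep], top.elements[keep],
                        top.residue_index[keep], top.residue_ids,
                        top.residue_names, top.residue_chains)
        with pytest.warns(UserWarning):
            n = hbond_count(coords[keep], top2)
        assert n == 1


class TestSaltBridges:
    def asp_lys(self, dist):
        top = Topology(np.array(["OD1", "OD2", "NZ"], dtype=object),
                       np.array(["O", "O", "N"], dtype=object),
                       np.array([0, 0, 1]), np.array([1, 2]),
                       np.array(["ASP", "LYS"], dtype=object),
                       np.array(["A", "A"], dtype=object))
        frame = np.array([[0.0, 0, 0], [0.0, 2.2, 0], [dist, 0, 0]])
        return frame, top

    def test_pair_within_and_beyond_cutoff(self):
        f, top = self.asp_lys(3.0)
        assert salt_bridge_count(f, top) == 1
        f2, _ = self.asp_lys(5.0)
        assert salt_bridge_count(f2, top) == 0

    def test_shared_lysine_counts_residue_pairs(self):
        # three Asp residues bridging one Lys: 3 residue-pair counts
        names = ["OD1"] * 3 + ["NZ"]
        elements = ["O"] * 3 + ["N"]
        res_index = [0, 1, 2, 3]
        top = Topology(np.array(names, dtype=object), np.array(elements, dtype=object),
                       np.array(res_index), np.array([1, 2, 3, 4]),
                       np.array(["ASP", "ASP", "ASP", "LYS"], dtype=object),
                       np.array(["A"] * 4, dtype=object))
        frame = np.array([[3.0, 0, 0], [-3.0, 0, 0], [0, 3.0, 0], [0.0, 0, 0]])
        assert salt_bridge_count(frame, top) == 3
        # brute-force enumeration oracle
        brute = sum(1 for i in range(3)
                    if np.linalg.norm(frame[i] - frame[3]) <= 4.0)
        assert salt_bridge_count(frame, top) == brute


class TestAlignResidues:
    def test_identity(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        pairs = align_residues(seq, seq)
        assert pairs == [(i, i) for i in range(len(seq))]

    def test_insertion_skips_positions(self):
        a = "MKTAYIAKQRQISFVK"
        b = a[:8] + "GGG" + a[8:]
        pairs = align_residues(a, b)
        assert len(pairs) == len(a)
        skipped = set(range(len(b))) - {j for _, j in pairs}
        assert len(skipped) == 3

    def test_score_matches_dp_oracle(self, rng):
        from Bio.Align import substitution_matrices
        mat = substitution_matrices.load("BLOSUM62")
        letters = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(list(letters), 100))
        b = "".join(rng.choice(list(letters), 100))

        # quadratic Gotoh DP with affine gaps (open -11, extend -1)
        go, ge = -11.0, -1.0
        n, m = len(a), len(b)
        NEG = -1e9
        M = np.full((n + 1, m + 1), NEG)
        X = np.full((n + 1, m + 1), NEG)
        Y = np.full((n + 1, m + 1), NEG)
        M[0, 0] = 0.0
        for i in range(1, n + 1):
            X[i, 0] = go + (i - 1) * ge
        for j in range(1, m + 1):
            Y[0, j] = go + (j - 1) * ge
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                s = mat[a[i - 1], b[j - 1]]
                M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
                X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge)
                Y[i, j] = max(M[i, j - 1] + go, Y[i, j - 1] + ge)
        oracle = max(M[n, m], X[n, m], Y[n, m])

        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = mat
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        assert aligner.score(a, b) == pytest.approx(oracle)
        # the mapping must be consistent with a valid global alignment
        pairs = align_residues(a, b)
        assert all(i2 > i1 and j2 > j1
                   for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_residues("", "ACD")


class TestCompareFlexibility:
    def make_profiles(self, deltas):
        n = len(deltas)
        base = np.full(n, 1.0)
        a = ResidueProfile(np.arange(1, n + 1), base + np.asarray(deltas))
        b = ResidueProfile(np.arange(1, n + 1), base)
        return a, b

    def test_identical_profiles(self):
        a, b = self.make_profiles(np.zeros(20))
        cmp = compare_flexibility(a, b)
        assert cmp.n_increased == 0 and cmp.n_decreased == 0

    def test_constructed_counts(self):
        deltas = [0.6] * 12 + [-0.7] * 4 + [0.0] * 10
        a, b = self.make_profiles(deltas)
        cmp = compare_flexibility(a, b)
        assert cmp.n_increased == 12
        assert cmp.n_decreased == 4

    def test_boundary_is_unchanged(self):
        a, b = self.make_profiles([0.5, -0.5, 0.5001, -0.5001])
        cmp = compare_flexibility(a, b)
        assert cmp.n_increased == 1 and cmp.n_decreased == 1
        assert cmp.labels[0] == "unchanged" and cmp.labels[1] == "unchanged"

    def test_exchange_antisymmetry(self):
        rng = np.random.default_rng(7)
        deltas = rng.normal(0, 0.8, 50)
        a, b = self.make_profiles(deltas)
        fwd = compare_flexibility(a, b)
        rev = compare_flexibility(b, a)
        assert fwd.n_increased == rev.n_decreased
        assert fwd.n_decreased == rev.n_increased

    def test_domain_attribution(self):
        deltas = [0.8] * 5 + [0.0] * 5 + [-0.9] * 5
        a, b = self.make_profiles(deltas)
        top, _ = make_chain_topology(15, domains={"N": [(1, 5)], "A": [(6, 10)],
                                                  "B": [(11, 15)]})
        cmp = compare_flexibility(a, b, topology_a=top)
        assert cmp.per_domain["N"]["increased"] == 5
        assert cmp.per_domain["B"]["decreased"] == 5
        assert "A" not in cmp.per_domain


class TestPCA:
    def test_single_line_motion(self):
        top, ref = make_chain_topology(10)
        amp = np.linspace(-1, 1, 30)
        mode = np.zeros((top.n_atoms, 3))
        mode[:, 0] = np.cos(4 * np.pi * np.arange(top.n_atoms) / top.n_atoms)
        frames = ref[None] + amp[:, None, None] * mode[None]
        ens = TrajectoryEnsemble(top, [frames])
        pca = pca_backbone(ens, mask=np.ones(top.n_atoms, dtype=bool))
        # superposition couples marginally into rotational directions, so
        # a sliver of variance leaks out of the driven mode
        assert pca.eigenvalues[0] / pca.eigenvalues.sum() > 0.995

    def test_two_mode_eigenvalue_ratio(self):
        top, ref = make_chain_topology(40)
        n = top.n_atoms
        rng = np.random.default_rng(11)
        idx = np.arange(n)
        m1 = np.zeros((n, 3))
        m1[:, 0] = np.cos(4 * np.pi * idx / n)
        m2 = np.zeros((n, 3))
        m2[:, 1] = np.cos(6 * np.pi * idx / n)
        a1 = rng.normal(0, 2.0, 4000)
        a2 = rng.normal(0, 1.0, 4000)
        frames = ref[None] + a1[:, None, None] * m1[None] + a2[:, None, None] * m2[None]
        ens = TrajectoryEnsemble(top, [frames])
        pca = pca_backbone(ens, mask=np.ones(n, dtype=bool))
        ratio = pca.eigenvalues[0] / pca.eigenvalues[1]
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_orthonormality_and_trace(self):
        top, ref = make_chain_topology(15)
        ens, _ = gen_harmonic_ensemble(top, ref, np.linspace(0.1, 0.5, 15),
                                       n_frames=50, n_replicates=2, seed=5)
        pca = pca_backbone(ens)
        V = pca.eigenvectors
        assert np.abs(V.T @ V - np.eye(V.shape[1])).max() < 1e-8
        assert np.all(pca.eigenvalues >= 0)
        assert np.all(np.diff(pca.cumulative_variance) >= -1e-12)


class TestMetricsTable:
    def test_static_ensemble_zeroes(self):
        top, ref = make_chain_topology(10)
        frames = np.stack([ref] * 4)
        ens = TrajectoryEnsemble(top, [frames, frames.copy()])
        m = metrics_table(ens, sasa_stride=4, hbond_stride=4, n_points=240)
        assert m.rmsd[0] == pytest.approx(0.0, abs=1e-12)
        assert m.rmsf[0] == pytest.approx(0.0, abs=1e-12)

    def test_doubled_jitter_orders_metrics(self):
        top, ref = make_chain_topology(20)
        e1, _ = gen_harmonic_ensemble(top, ref, np.full(20, 0.2),
                                      n_frames=40, n_replicates=2, seed=6)
        e2, _ = gen_harmonic_ensemble(top, ref, np.full(20, 0.4),
                                      n_frames=40, n_replicates=2, seed=6)
        m1 = metrics_table(e1, sasa_stride=40, hbond_stride=40, n_points=120)
        m2 = metrics_table(e2, sasa_stride=40, hbond_stride=40, n_points=120)
        assert m2.rmsd[0] > m1.rmsd[0]
        assert m2.rmsf[0] > m1.rmsf[0]

    def test_sem_scales_with_frames(self):
        top, ref = make_chain_topology(15)
        e_small, _ = gen_harmonic_ensemble(top, ref, np.full(15, 0.3),
                                           n_frames=50, n_replicates=1, seed=8)
        e_big, _ = gen_harmonic_ensemble(top, ref, np.full(15, 0.3),
                                         n_frames=200, n_replicates=1, seed=8)
        s_small = rmsd_series(e_small)["sem"]
        s_big = rmsd_series(e_big)["sem"]
        assert s_big == pytest.approx(s_small / 2, rel=0.35)
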