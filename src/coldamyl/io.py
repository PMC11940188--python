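"""Plain-text readers and writers for the formats the analyses consume.

CSV handling goes through pandas; PDB files (single- and multi-model)
through biotite. Scattering data use the conventional 3-column whitespace
layout (q, I, sigma) with '#' comment lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .activity import ActivityProfile, ActivityTimecourse, MaltoseStandardCurve, absorbance_to_reducing_ends
from .mdflex import Topology, TrajectoryEnsemble
from .saxs import AtomicModel, ScatteringCurve
from .sec import Chromatogram
from .unfolding import CDMeltDataset, DSFCurve

__all__ = [
    "read_timecourse_csv",
    "read_profile_csv",
    "write_profile_csv",
    "read_cd_melt_csv",
    "write_cd_melt_csv",
    "read_dsf_csv",
    "write_dsf_csv",
    "read_chromatogram_csv",
    "write_chromatogram_csv",
    "read_scattering_dat",
    "write_scattering_dat",
    "read_atomic_model_pdb",
    "read_topology_pdb",
    "read_trajectory_pdb",
    "write_trajectory_pdb",
]


def read_timecourse_csv(path, curve: MaltoseStandardCurve | None = None,
                        enzyme_conc: float = np.nan,
                        reaction_volume: float = np.nan) -> ActivityTimecourse:
    """Columns: time_s plus either nmol, or a620 (+ optional dilution)."""
    df = pd.read_csv(path)
    if "nmol" in df.columns:
        ends = df["nmol"].to_numpy(dtype=float)
    elif "a620" in df.columns:
        if curve is None:
            raise ValueError("a620 input requires a maltose standard curve")
        dil = df["dilution"].to_numpy(dtype=float) if "dilution" in df.columns else np.ones(len(df))
        ends = np.array([absorbance_to_reducing_ends(a, curve, d)
                         for a, d in zip(df["a620"], dil)])
    else:
        raise ValueError("timecourse CSV needs an 'nmol' or 'a620' column")
    return ActivityTimecourse(df["time_s"].to_numpy(dtype=float), ends,
                              enzyme_conc, reaction_volume)


def read_profile_csv(path, condition_name: str | None = None) -> ActivityProfile:
    df = pd.read_csv(path)
    cond_col = df.columns[0] if condition_name is None else condition_name
    stderrs = df["stderr"].to_numpy(dtype=float) if "stderr" in df.columns else None
    return ActivityProfile(cond_col, df[cond_col].to_numpy(dtype=float),
                           df["velocity"].to_numpy(dtype=float), stderrs)


def write_profile_csv(profile: ActivityProfile, path) -> None:
    data = {profile.condition_name: profile.condition_values,
            "velocity": profile.velocities}
    if profile.stderrs is not None:
        data["stderr"] = profile.stderrs
    pd.DataFrame(data).to_csv(path, index=False)


def read_cd_melt_csv(path) -> CDMeltDataset:
    """Wide matrix: first column temperature (degC), remaining columns one
    wavelength each, header giving the wavelength in nm."""
    df = pd.read_csv(path)
    temps = df.iloc[:, 0].to_numpy(dtype=float)
    wl = np.array([float(c) for c in df.columns[1:]])
    return CDMeltDataset(temps, wl, df.iloc[:, 1:].to_numpy(dtype=float))


def write_cd_melt_csv(ds: CDMeltDataset, path) -> None:
    df = pd.DataFrame(ds.ellipticity, columns=[f"{w:g}" for w in ds.wavelengths])
    df.insert(0, "temperature_C", ds.temperatures)
    df.to_csv(path, index=False)


def read_dsf_csv(path) -> DSFCurve:
    df = pd.read_csv(path)
    direction = str(df["direction"].iloc[0]) if "direction" in df.columns else "heating"
    return DSFCurve(df["temperature_C"].to_numpy(dtype=float),
                    df["ratio"].to_numpy(dtype=float), direction)


def write_dsf_csv(curve: DSFCurve, path) -> None:
    pd.DataFrame({"temperature_C": curve.temperatures, "ratio": curve.ratio,
                  "direction": curve.direction}).to_csv(path, index=False)


def read_chromatogram_csv(path) -> Chromatogram:
    df = pd.read_csv(path)
    return Chromatogram(df["volume_mL"].to_numpy(dtype=float),
                        df["a280"].to_numpy(dtype=float))


def write_chromatogram_csv(chrom: Chromatogram, path) -> None:
    pd.DataFrame({"volume_mL": chrom.volume,
                  "a280": chrom.a280}).to_csv(path, index=False)


def read_scattering_dat(path) -> ScatteringCurve:
    arr = np.loadtxt(path, comments="#")
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("scattering file needs >= 2 whitespace columns")
    sigma = arr[:, 2] if arr.shape[1] >= 3 else None
    return ScatteringCurve(arr[:, 0], arr[:, 1], sigma)


def write_scattering_dat(curve: ScatteringCurve, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# q[1/A]  I[1/cm]  sigma[1/cm]\n")
        for q, I, s in zip(curve.q, curve.intensity, curve.sigma):
            fh.write(f"{q:.8e} {I:.8e} {s:.8e}\n")


# ---------------------------------------------------------------------------
# PDB structures and trajectories (biotite)


def _load_pdb(path):
    import biotite.structure.io.pdb as pdb
    return pdb.PDBFile.read(str(path))


def read_atomic_model_pdb(path) -> AtomicModel:
    """Non-H atoms of the first model as a scattering-ready AtomicModel."""
    pdbf = _load_pdb(path)
    arr = pdbf.get_structure(model=1)
    return AtomicModel.from_elements(arr.coord, arr.element,
                                     residue_ids=arr.res_id,
                                     chains=arr.chain_id)


def read_topology_pdb(path, domains: dict | None = None):
    """First model as (Topology, coordinates) for trajectory analysis."""
    pdbf = _load_pdb(path)
    arr = pdbf.get_structure(model=1)
    res_keys = list(dict.fromkeys(zip(arr.chain_id, arr.res_id)))
    key_to_idx = {k: i for i, k in enumerate(res_keys)}
    res_index = np.array([key_to_idx[(c, r)]
                          for c, r in zip(arr.chain_id, arr.res_id)])
    res_ids = np.array([r for _, r in res_keys])
    first_atom = [int(np.argmax(res_index == i)) for i in range(len(res_keys))]
    res_names = np.array([arr.res_name[i] for i in first_atom], dtype=object)
    res_chains = np.array([k[0] for k in res_keys], dtype=object)
    top = Topology(arr.atom_name.astype(object), arr.element.astype(object),
                   res_index, res_ids, res_names, res_chains,
                   domains=domains or {})
    return top, np.asarray(arr.coord, dtype=float)


def read_trajectory_pdb(paths, domains: dict | None = None,
                        frame_spacing: float = 1.0) -> TrajectoryEnsemble:
    """Multi-model PDB file(s), one file per replicate."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    top = None
    reps = []
    for p in paths:
        pdbf = _load_pdb(p)
        stack = pdbf.get_structure()
        if top is None:
            top, _ = read_topology_pdb(p, domains)
        reps.append(np.asarray(stack.coord, dtype=float))
    return TrajectoryEnsemble(top, reps, frame_spacing)


def write_trajectory_pdb(ens: TrajectoryEnsemble, path,
                         replicate: int = 0) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    top = ens.topology
    frames = ens.replicates[replicate]
    n = top.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = frames[0]
    arr.atom_name = np.asarray(top.atom_names, dtype="U6")
    arr.element = np.asarray(top.elements, dtype="U2")
    arr.res_id = np.asarray(top.residue_ids)[top.residue_index]
    arr.res_name = np.asarray(top.residue_names, dtype="U5")[top.residue_index]
    arr.chain_id = np.asarray(top.residue_chains, dtype="U4")[top.residue_index]
    stack = struc.stack([arr] * frames.shape[0])
    stack.coord = frames
    pdbf = pdb.PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(path))
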