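"""End-to-end orchestration: synthesize inputs, fit models, write reports.

A run is configured by a plain dictionary (loadable from YAML), is
deterministic given (config, seed), and writes JSON/CSV reports plus a log
recording parameter provenance. Any stage failure aborts the run with a
stage-tagged error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import io as cio
from .activity import CaResponseParams, fit_ca_model
from .sec import fit_peaks, PeakSet
from .synth import (
    NoiseSpec,
    default_cd_params,
    gen_ca_response,
    gen_cd_melt,
    gen_chromatogram,
    gen_dsf,
    gen_sphere_curve,
)
from .unfolding import TwoStateParams, fit_cd_global, fit_dsf
from .saxs import guinier_fit, ift, mw_from_i0

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "PipelineError"]

logger = logging.getLogger("coldamyl.pipeline")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


DEFAULT_CONFIG: dict = {
    "stages": ["activity", "cd", "dsf", "sec", "saxs"],
    "seed": 0,
    "activity": {"vmax_apo": 10.0, "vmax_l1": 100.0, "vmax_l2": 20.0,
                 "kl1": 0.5, "kl2": 8.0, "noise": 0.0},
    "cd": {"tm1": 55.98, "tm2": 58.32, "dh1": 400e3, "dh2": 500e3,
           "n_wavelengths": 21, "noise": 0.0},
    "dsf": {"tm": 61.97, "dh": 300e3, "noise": 0.0},
    "sec": {"centers": [11.0, 13.0], "widths": [0.3, 0.35],
            "fractions": [0.26, 0.74], "total_area": 10.0, "noise": 0.0},
    "saxs": {"radius": 30.0, "mw_kda": 56.0, "conc": 1.0, "noise": 0.0},
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _merge(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def _stage_activity(cfg, seed, outdir):
    truth = CaResponseParams(cfg["vmax_apo"], cfg["vmax_l1"], cfg["vmax_l2"],
                             cfg["kl1"], cfg["kl2"])
    noise = NoiseSpec("gaussian-constant", cfg["noise"], seed=seed) if cfg["noise"] else None
    prof, _ = gen_ca_response(truth, noise=noise)
    fit = fit_ca_model(prof.condition_values, prof.velocities, seed=seed)
    cio.write_profile_csv(prof, outdir / "ca_profile.csv")
    return {"true": truth.as_array().tolist(),
            "fitted": fit.as_array().tolist(), "chi2": fit.chi2}


def _stage_cd(cfg, seed, outdir):
    params = default_cd_params(cfg["tm1"], cfg["tm2"], cfg["dh1"], cfg["dh2"],
                               n_wavelengths=cfg["n_wavelengths"], seed=seed)
    noise = NoiseSpec("gaussian-constant", cfg["noise"], seed=seed) if cfg["noise"] else None
    ds, _ = gen_cd_melt(params, noise=noise)
    fit = fit_cd_global(ds)
    cio.write_cd_melt_csv(ds, outdir / "cd_melt.csv")
    return {"true_tm": [cfg["tm1"], cfg["tm2"]],
            "fitted_tm": [fit.tm1, fit.tm2],
            "fitted_dh": [fit.dh1, fit.dh2]}


def _stage_dsf(cfg, seed, outdir):
    params = TwoStateParams(cfg["tm"], cfg["dh"], 0.85, 5e-4, 1.05, 2e-4)
    noise = NoiseSpec("gaussian-constant", cfg["noise"], seed=seed) if cfg["noise"] else None
    curve, _ = gen_dsf(params, noise=noise)
    fit = fit_dsf(curve)
    cio.write_dsf_csv(curve, outdir / "dsf_curve.csv")
    return {"true_tm": cfg["tm"], "fitted_tm": fit.tm,
            "fitted_dh": fit.dh_unf, "tm_se": fit.stderrs.get("tm")}


def _stage_sec(cfg, seed, outdir):
    fr = np.asarray(cfg["fractions"], dtype=float)
    areas = cfg["total_area"] * fr / fr.sum()
    peaks = PeakSet(np.asarray(cfg["centers"], dtype=float),
                    np.asarray(cfg["widths"], dtype=float),
                    areas, fr / fr.sum())
    noise = NoiseSpec("gaussian-constant", cfg["noise"], seed=seed) if cfg["noise"] else None
    chrom, _ = gen_chromatogram(peaks, noise=noise)
    fit = fit_peaks(chrom, n_peaks=len(peaks.centers))
    cio.write_chromatogram_csv(chrom, outdir / "chromatogram.csv")
    return {"true_fractions": (fr / fr.sum()).tolist(),
            "fitted_fractions": fit.fractions.tolist(),
            "fitted_centers": fit.centers.tolist()}


def _stage_saxs(cfg, seed, outdir):
    from .saxs import i0_from_mw
    i0 = i0_from_mw(cfg["mw_kda"], cfg["conc"])
    noise = (NoiseSpec("saxs", cfg["noise"], floor=cfg["noise"] * 1e-3, seed=seed)
             if cfg["noise"] else None)
    curve, truth = gen_sphere_curve(cfg["radius"], i0, noise=noise)
    gu = guinier_fit(curve)
    pr = ift(curve, dmax=2.2 * cfg["radius"])
    mw = mw_from_i0(pr.i0, cfg["conc"], monomer_mw=cfg["mw_kda"])
    cio.write_scattering_dat(curve, outdir / "saxs_curve.dat")
    return {"true_rg": truth["rg"], "guinier_rg": gu["rg"], "ift_rg": pr.rg,
            "ift_dmax": pr.dmax, "mw_kda": mw["mw_kda"], "n_mer": mw["n_mer"]}


_STAGES = {"activity": _stage_activity, "cd": _stage_cd, "dsf": _stage_dsf,
           "sec": _stage_sec, "saxs": _stage_saxs}


def run_pipeline(config: dict | None = None, outdir="coldamyl_run") -> dict:
    """Run the configured stages; returns (and writes) the report bundle."""
    cfg = _merge(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {"config_hash": _config_hash(cfg), "seed": seed, "stages": {}}
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    for stage in cfg["stages"]:
        if stage not in _STAGES:
            raise PipelineError(stage, ValueError("unknown stage"))
        logger.info("running stage %s (seed=%d)", stage, seed)
        try:
            report["stages"][stage] = _STAGES[stage](cfg[stage], seed, outdir)
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise PipelineError(stage, exc) from exc
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
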