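"""End-to-end orchestration: simulate -> supercell ensembles -> structure
factors -> difference maps -> peaks / IADDAT / map CC -> ADP analytics ->
titration fits, with seeded reproducibility and a JSON-serializable report.

Every stochastic stage consumes an explicit seed derived from the config, so
re-running with the same config reproduces the report bit-identically.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, asdict

import numpy as np

from . import __version__
from .adp import peak_axis_alignment, residue_bdiff, rosenfield
from .diffmap import find_peaks, fo_minus_fo_map, iaddat, mainchain, map_cc_masked
from .sf import sf_ensemble
from .supercell import ion_counts, modification_fraction
from .synth import (TitrationSpec, ToyCrystalSpec, make_ensemble,
                    make_observations, make_titration, make_toy_pair,
                    water_site)
from .titration import delta_g, fit_ph_rate, fit_pka, TitrationSeries, bell_curve

log = logging.getLogger("xtalens.pipeline")


@dataclass
class PipelineConfig:
    """Everything a full run needs; unknown config keys are rejected."""

    # toy crystal
    occ_closed: float = 0.64
    occ_closed_bound: float = 0.39
    occ_reactive: float = 0.85
    occ_adduct: float = 0.53
    occ_water: float = 0.64
    adp_scale: float = 10.0
    bdiff: float = 4.0
    loop_shift: float = 1.6
    # observations
    dmin: float = 1.5
    noise_frac: float = 0.03
    # supercell ensemble
    dims: tuple = (2, 2, 2)
    n_frames: int = 8
    # analysis thresholds
    peak_sigma: float = 3.2
    peak_max_dist: float = 5.0
    iaddat_sigma: float = 3.0
    iaddat_radius: float = 2.5
    cc_radius: float = 2.0
    rosenfield_bins: int = 10
    # titration
    pka: float = 5.7
    titration_noise_sd: float = 0.02
    rate_pka_rise: float = 4.4
    rate_pka_fall: float = 6.1
    rate_vmax: float = 1.0
    temperature: float = 298.0
    # buffer bookkeeping (mol/L) and solvent volume (L)
    buffer_mg: float = 0.125
    buffer_cl: float = 0.367
    buffer_k: float = 0.050
    solvent_volume: float = 1.0379e-21
    # seeds
    seed: int = 7

    def toy_spec(self) -> ToyCrystalSpec:
        return ToyCrystalSpec(
            occ_closed=self.occ_closed, occ_closed_bound=self.occ_closed_bound,
            occ_reactive=self.occ_reactive, occ_adduct=self.occ_adduct,
            occ_water=self.occ_water, adp_scale=self.adp_scale,
            bdiff=self.bdiff, loop_shift=self.loop_shift, seed=self.seed)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Plain-text sectioned key = value config; unknown keys are errors."""
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    kwargs = {}
    for section in cp.sections():
        for key, raw in cp.items(section):
            if key not in fields:
                raise ValueError(f"unknown config key {key!r} in [{section}]")
            ftype = fields[key].type
            if key == "dims":
                kwargs[key] = tuple(int(x) for x in raw.split())
            elif ftype in ("int",):
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
    for key in ("n_frames", "seed", "rosenfield_bins"):
        if key in kwargs:
            kwargs[key] = int(kwargs[key])
    return PipelineConfig(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _timed(report, stage):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s ...", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            log.info("stage %s done in %.2f s", stage, dt)
            if exc is not None:
                report["error"] = {"stage": stage, "message": str(exc)}
                raise StageError(stage, exc) from exc
    return _Ctx()


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Execute the full analysis; returns the JSON-serializable report.

    Stages run in dependency order; a failing stage raises
    :class:`StageError` after recording the completed stages in the report.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    seeds = {name: int(s) for name, s in zip(
        ("obs_on", "obs_off", "ens_on", "ens_off", "titration", "rate"),
        rng.integers(2 ** 31, size=6))}
    report: dict = {
        "provenance": {"config": asdict(cfg), "config_hash": cfg.digest(),
                       "seeds": seeds, "version": __version__},
        "stages": {},
    }
    stages = report["stages"]

    with _timed(report, "simulate"):
        spec = cfg.toy_spec()
        s0, s30 = make_toy_pair(spec)
        stages["simulate"] = {
            "n_atoms_0s": len(s0), "n_atoms_30s": len(s30),
            "occupancies": {"closed_0s": cfg.occ_closed,
                            "closed_30s": cfg.occ_closed_bound,
                            "reactive": cfg.occ_reactive,
                            "adduct": cfg.occ_adduct,
                            "water": cfg.occ_water}}

    with _timed(report, "observations"):
        obs0 = make_observations(s0, cfg.dmin, cfg.noise_frac, seeds["obs_off"])
        obs30 = make_observations(s30, cfg.dmin, cfg.noise_frac, seeds["obs_on"])
        stages["observations"] = {"n_reflections": len(obs0),
                                  "dmin": cfg.dmin,
                                  "noise_frac": cfg.noise_frac}

    with _timed(report, "diffmap"):
        dmap = fo_minus_fo_map(obs30, obs0, phase_model=s0, dmin=cfg.dmin)
        peaks = find_peaks(dmap, cfg.peak_sigma, model=s30,
                           max_dist=cfg.peak_max_dist)
        wsite = water_site(spec) if cfg.occ_water > 0 else None
        water_peak = None
        if wsite is not None:
            for p in peaks.positive():
                d = p.frac - wsite
                d -= np.round(d)
                dist = float(np.linalg.norm(dmap.cell.frac_to_cart(d)))
                if dist <= 3.0:
                    water_peak = {"height_sigma": p.height_sigma,
                                  "distance_A": dist}
                    break
        stages["diffmap"] = {
            "map_sigma_e_A3": dmap.sigma,
            "n_peaks": len(peaks),
            "n_positive": len(peaks.positive()),
            "n_negative": len(peaks.negative()),
            "strongest_peak_sigma": peaks[0].height_sigma if len(peaks) else 0.0,
            "water_peak": water_peak}

    with _timed(report, "iaddat"):
        prof = iaddat(dmap, s0, cfg.iaddat_sigma, cfg.iaddat_radius)
        loop = set(range(*spec.loop_range)) | {spec.loop_range[1]}
        by_res = {f"{r[0]}:{r[1]}": v for r, v in prof.items()}
        argmax = prof.argmax()
        stages["iaddat"] = {
            "profile": by_res,
            "max_residue": f"{argmax[0]}:{argmax[1]}",
            "max_in_loop_or_active_site":
                argmax[1] in (loop | {spec.nucleophile_resid, 100, 200})}

    with _timed(report, "ensemble"):
        ens0 = make_ensemble(s0, cfg.dims, cfg.n_frames, seeds["ens_off"])
        ens30 = make_ensemble(s30, cfg.dims, cfg.n_frames, seeds["ens_on"])
        f0 = sf_ensemble(ens0, cfg.dmin)
        f30 = sf_ensemble(ens30, cfg.dmin)
        ens_map = fo_minus_fo_map(f30, f0, phase_model=s0, dmin=cfg.dmin,
                                  shape=dmap.shape)
        loop_sel = mainchain(resnums=set(range(spec.loop_range[0],
                                               spec.loop_range[1] + 1)))
        cc_loop = map_cc_masked(ens_map, dmap, s0, loop_sel, cfg.cc_radius)
        cc_all = map_cc_masked(ens_map, dmap, s0, mainchain(), cfg.cc_radius)
        stages["ensemble"] = {
            "dims": list(cfg.dims), "n_frames": cfg.n_frames,
            "n_copies": len(ens0.manifest["copies"]),
            "loop_mainchain_cc": cc_loop,
            "all_mainchain_cc": cc_all}

    with _timed(report, "adp"):
        bdiff = residue_bdiff(s30, s0, mainchain())
        ros = rosenfield(s0, mainchain(), bins=cfg.rosenfield_bins)
        align = None
        pos, neg = peaks.positive(), peaks.negative()
        if pos and neg:
            # strongest +/- pair near the nucleophile sulfur
            sg = next(a for a in s30.atoms
                      if a.name == "SG" and a.altloc == "A")
            cos_major, cos_best = peak_axis_alignment(
                pos[0].frac, neg[0].frac, sg, cell=s30.cell)
            align = {"cos_major": cos_major, "cos_best": cos_best}
        stages["adp"] = {
            "bdiff": {f"{r[0]}:{r[1]}": v for r, v in bdiff.items()},
            "rosenfield_mean_abs": float(np.mean(np.abs(ros.matrix))),
            "rosenfield_antisymmetry_max":
                float(np.abs(ros.matrix + ros.matrix.T).max()),
            "peak_axis_alignment": align}

    with _timed(report, "titration"):
        tser = make_titration(TitrationSpec(
            pka=cfg.pka, noise_sd=cfg.titration_noise_sd,
            seed=seeds["titration"]))
        pfit = fit_pka(tser, n_boot=200, seed=seeds["titration"])
        rate_rng = np.random.default_rng(seeds["rate"])
        ph = np.linspace(3.5, 8.5, 11)
        v = bell_curve(ph, cfg.rate_pka_rise, cfg.rate_pka_fall, cfg.rate_vmax)
        v = v + rate_rng.standard_normal(len(ph)) * 0.01 * cfg.rate_vmax
        rfit = fit_ph_rate(TitrationSeries(ph, np.clip(v, 0, None),
                                           kind="rate"))
        stages["titration"] = {
            "pka_fit": {"pka": pfit.pka, "direction": pfit.direction,
                        "ci": pfit.ci, "ok": pfit.ok},
            "rate_fit": {"pka_rise": rfit.pka_rise, "pka_fall": rfit.pka_fall,
                         "optimum": rfit.optimum, "vmax": rfit.vmax,
                         "ok": rfit.ok}}

    with _timed(report, "bookkeeping"):
        stages["bookkeeping"] = {
            "modification_pct": modification_fraction(cfg.occ_adduct,
                                                      cfg.occ_reactive),
            "delta_g_kj_mol": delta_g(cfg.occ_closed, 1.0 - cfg.occ_closed,
                                      cfg.temperature),
            "ion_counts": ion_counts(
                {"MG": cfg.buffer_mg, "CL": cfg.buffer_cl, "K": cfg.buffer_k},
                cfg.solvent_volume).counts}

    return report


def report_to_json(report: dict, path=None) -> str:
    text = json.dumps(report, indent=1, sort_keys=True, default=_jsonify)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO if verbose
                        else logging.WARNING,
                        format="%(asctime)s %(name)s: %(message)s")
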