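"""Reproducible experiment presets.

Each preset bundles a base configuration, a sweep axis, replicate counts
and an analysis chain into a single runnable unit.  The full-scale
replicate counts follow the study protocols (at least 100 trajectories
for positioning ensembles, 100 runs for phase-scan points, >= 40000
one-particle encounters); ``scale`` < 1 reduces replicates and horizons
proportionally and is recorded in every manifest.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import analysis, engine, rd, theory
from .io import read_config, write_manifest, write_table
from .params import ModelParams, RDParams

__all__ = ["ExperimentPreset", "PRESETS", "run_preset",
           "load_packaged_config"]


def load_packaged_config(name: str = "baseline") -> ModelParams:
    """Load a packaged parameter set ("baseline" or "desk")."""
    ref = resources.files("pomsim.configs") / f"{name}.toml"
    with resources.as_file(ref) as path:
        params, _, _ = read_config(path)
    return params


@dataclass(frozen=True)
class ExperimentPreset:
    """A named, fully determined experiment."""

    name: str
    description: str
    config: str                      # packaged config name
    runner: Callable = field(repr=False, default=None)
    full_scale: dict = field(default_factory=dict)


def _seeds(base_seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(base_seed).generate_state(n)]


def _scaled(n: int, scale: float, minimum: int = 1) -> int:
    return max(minimum, int(round(n * scale)))


# -- preset runners ---------------------------------------------------------

def _positioning_ensemble(params, base_seed, scale, out):
    n_runs = _scaled(100, scale)
    t_end = max(1200.0, 7200.0 * scale)
    seeds = _seeds(base_seed, n_runs)
    trajs = []
    incomplete = []
    for i, s in enumerate(seeds):
        try:
            tr, _ = engine.run_dynamic(params, s, t_end=t_end, record_dt=10.0)
            trajs.append(tr)
            write_table(tr.frame, out / f"trajectory_{i:03d}.tsv",
                        {"seed": s, **params.to_dict()})
        except Exception as exc:  # pragma: no cover
            incomplete.append({"replicate": i, "error": str(exc)})
    stats = analysis.binned_trajectory_stats(trajs)
    write_table(stats, out / "binned_stats.tsv", {"n_runs": len(trajs)})
    return {"n_runs": n_runs, "t_end_s": t_end,
            "outputs": ["trajectory_*.tsv", "binned_stats.tsv"],
            "incomplete": incomplete}


def _stationary_profiles(params, base_seed, scale, out):
    fracs = (0.1, 0.3, 0.5)
    n_runs = _scaled(10, scale)
    t_end = params.t_min + max(400.0, 4000.0 * scale)
    rp = RDParams.from_model_params(params)
    seeds = _seeds(base_seed, n_runs * len(fracs))
    k = 0
    for frac in fracs:
        x_c = frac * params.L
        runs = []
        for _ in range(n_runs):
            runs.append(engine.run_stationary(params, x_c, seeds[k],
                                              t_end=t_end))
            k += 1
        c = np.mean([r.c for r in runs], axis=0)
        cb = np.mean([r.c_b for r in runs], axis=0)
        flux = np.mean([r.flux for r in runs], axis=0)
        prof = rd.solve_stationary(rp, x_c)
        frame = pd.DataFrame({
            "x_um": runs[0].x, "c_sim": c, "c_b_sim": cb,
            "c_rd": prof.c, "c_b_rd": prof.c_b})
        write_table(frame, out / f"profiles_{int(frac*100)}pct.tsv",
                    {"x_c_um": x_c, "n_runs": n_runs,
                     "j_diff_rd": prof.j_diff})
    return {"n_runs": n_runs, "t_end_s": t_end, "positions": list(fracs),
            "outputs": ["profiles_*pct.tsv"]}


def _one_particle_force(params, base_seed, scale, out):
    n_int = _scaled(40000, scale, minimum=500)
    rec = engine.run_one_particle(params, n_int, base_seed)
    est = theory.estimate_C(rec, params.k_h, seed=base_seed)
    write_table(rec, out / "interaction_records.tsv",
                {"n_interactions": n_int, **params.to_dict()})
    write_manifest({"C_pNs": est.C, "C_int_pNs": est.C_int,
                    "C_se": est.C_se, "f_pN": est.f, "dx0_um": est.dx0,
                    "n_records": est.n_records},
                   out / "C_estimate.json")
    return {"n_interactions": n_int,
            "outputs": ["interaction_records.tsv", "C_estimate.json"]}


def _friction_assay(params, base_seed, scale, out):
    n_runs = _scaled(100, scale)
    fv = engine.run_friction_assay(
        params.replace(k_h=0.0, infinite_lattice=True), N_bound=20,
        F_ext_list=[0.005, 0.01, 0.02], n_runs=n_runs, seed=base_seed)
    gamma, ci, _ = analysis.force_velocity_fit(fv)
    gamma_th = theory.effective_friction(20, params)
    write_table(fv, out / "force_velocity.tsv",
                {"gamma_fit": gamma, "gamma_theory": gamma_th,
                 "ci_lo": ci[0], "ci_hi": ci[1]})
    return {"n_runs": n_runs, "gamma_fit": gamma, "gamma_theory": gamma_th,
            "outputs": ["force_velocity.tsv"]}


def _kh_sweep(params, base_seed, scale, out):
    kh_grid = [0.1, 0.3, 1.0, 3.0, 10.0]
    n_int = _scaled(20000, scale, minimum=500)
    x_probe = 0.2 * params.L
    rows = []
    seeds = _seeds(base_seed, len(kh_grid))
    for s, kh in zip(seeds, kh_grid):
        p = params.replace(k_h=kh)
        rec = engine.run_one_particle(p, n_int, s)
        est = theory.estimate_C(rec, kh, seed=s)
        prof = rd.solve_stationary(RDParams.from_model_params(p), x_probe)
        gamma = theory.effective_friction(prof.N_bound, p)
        rows.append({"k_h": kh, "C_pNs": est.C, "j_diff": prof.j_diff,
                     "N_bound": prof.N_bound, "gamma": gamma,
                     "v_um_s": est.C * prof.j_diff / gamma})
    frame = pd.DataFrame(rows)
    write_table(frame, out / "kh_sweep.tsv", {"x_probe_um": x_probe})
    return {"k_h_grid": kh_grid, "n_interactions": n_int,
            "outputs": ["kh_sweep.tsv"]}


def _phase_scan(params, base_seed, scale, out):
    d_pomz = [0.001, 0.01, 0.1]
    d_cluster = [1e-4, 1e-3]
    n_runs = _scaled(100, scale, minimum=4)
    t_end = params.t_min + max(3000.0, 600000.0 * scale)
    rows = []
    k = 0
    seeds = _seeds(base_seed, len(d_pomz) * len(d_cluster) * n_runs)
    for dp in d_pomz:
        for dc in d_cluster:
            p = params.replace(D_nuc=dp, D_clu=dp, gamma_c=params.kBT / dc)
            trajs = []
            for _ in range(n_runs):
                tr, _ = engine.run_dynamic(p, seeds[k], t_end=t_end,
                                           record_dt=6.0, x_c0=p.L / 2)
                trajs.append(tr)
                k += 1
            rep = analysis.fft_oscillation_detector(
                trajs, L=p.L, t_start=p.t_min)
            rows.append({"D_PomZ": dp, "D_cluster": dc,
                         "classification": rep.classification,
                         "frequency_per_min": rep.frequency_per_min,
                         "histogram_shape": rep.histogram_shape})
    frame = pd.DataFrame(rows)
    write_table(frame, out / "phase_scan.tsv",
                {"n_runs": n_runs, "t_end_s": t_end})
    return {"n_runs": n_runs, "t_end_s": t_end,
            "outputs": ["phase_scan.tsv"]}


PRESETS: dict[str, ExperimentPreset] = {
    "positioning-ensemble": ExperimentPreset(
        "positioning-ensemble",
        "dynamic-cluster ensemble from the left nucleoid pole; binned "
        "mean trajectory (full scale: 100 replicates)",
        "baseline", _positioning_ensemble),
    "stationary-profiles": ExperimentPreset(
        "stationary-profiles",
        "frozen-cluster density/flux profiles at 10/30/50% nucleoid "
        "length vs. the stationary RD solution",
        "baseline", _stationary_profiles),
    "one-particle-force": ExperimentPreset(
        "one-particle-force",
        "single-dimer encounters with a midnucleoid cluster; estimates "
        "the force constant C (full scale: 40000 encounters)",
        "baseline", _one_particle_force),
    "friction-assay": ExperimentPreset(
        "friction-assay",
        "force-velocity curve of a cluster tethered by 20 dimers on "
        "unbounded lattices; compares the fitted friction to theory",
        "baseline", _friction_assay),
    "kh-sweep": ExperimentPreset(
        "kh-sweep",
        "velocity decomposition v = C*j_diff/gamma over a hydrolysis-rate "
        "grid (non-monotone velocity)",
        "desk", _kh_sweep),
    "phase-scan": ExperimentPreset(
        "phase-scan",
        "oscillation classification over a (D_PomZ, D_cluster) grid with "
        "clusters started at midnucleoid",
        "desk", _phase_scan),
}


def run_preset(name: str, base_seed: int, scale: float = 1.0,
               out_dir=".") -> dict:
    """Execute a preset; writes its outputs plus a provenance manifest."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must be in (0, 1]")
    preset = PRESETS[name]
    params = load_packaged_config(preset.config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    result = preset.runner(params, int(base_seed), float(scale), out)
    manifest = {
        "preset": name, "description": preset.description,
        "config": preset.config, "params": params.to_dict(),
        "base_seed": int(base_seed), "scale": scale,
        "wall_clock_s": round(time.time() - t0, 3),
        **result,
    }
    write_manifest(manifest, out / "manifest.json")
    return manifest
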