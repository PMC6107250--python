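"""Event-driven stochastic engine for PomZ-driven cluster positioning.

The model couples a lattice gas of elastically tethered PomZ dimers to the
overdamped motion of the PomXY cluster on a 1D nucleoid:

* cytosolic dimers attach uniformly to nucleoid sites outside the cluster
  footprint and diffuse by nearest-neighbour hopping;
* a nucleoid-bound dimer binds a cluster site at the attachment rate
  weighted by the Boltzmann factor of the tether-spring energy, so binding
  in a stretched configuration is possible;
* a doubly-bound dimer hops on both lattices with detailed-balance rates
  and is released into the cytosol at the hydrolysis rate ``k_h``;
* the cluster obeys the force balance
  ``gamma_c dx_c/dt = -k sum_i (x_i_clu - x_i_nuc) + F_ext`` with no
  thermal noise; between Gillespie events it is advanced in closed form.

``run_dynamic``, ``run_stationary``, ``run_one_particle`` and
``run_friction_assay`` execute the four simulation protocols through
numba-compiled kernels.  ``gillespie_step`` / ``build_propensities``
provide a transparent pure-Python reference of the same event catalogue
for small systems.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .params import ModelParams

__all__ = [
    "DimerState", "SystemState", "Trajectory", "StationaryRunResult",
    "ConditionedAccumulator", "cluster_binding_rate", "hop_rate",
    "attachment_propensity", "sample_attachment_site", "advance_cluster",
    "build_propensities", "gillespie_step", "run_dynamic", "run_stationary",
    "run_one_particle", "run_friction_assay",
]

logger = logging.getLogger("pomsim")


# ---------------------------------------------------------------------------
# elementary rates
# ---------------------------------------------------------------------------

def cluster_binding_rate(x_nuc: float, x_clu_site: float,
                         params: ModelParams) -> float:
    """Rate for a nucleoid-bound dimer to bind one cluster site.

    ``ka0`` multiplied by the Boltzmann factor of the spring energy of the
    resulting stretch; symmetric in the sign of the offset.
    """
    d = x_clu_site - x_nuc
    return params.ka0 * math.exp(-params.k * d * d / (2.0 * params.kBT))


def total_cluster_binding_rate(x_nuc: float, x_c: float,
                               params: ModelParams) -> float:
    """Sum of :func:`cluster_binding_rate` over all candidate cluster sites."""
    sites = params.cluster_sites(x_c)
    smax = _kernels.pruning_distance(params.k, params.kBT)
    sel = np.abs(sites - x_nuc) <= smax
    return float(sum(cluster_binding_rate(x_nuc, s, params)
                     for s in sites[sel]))


def hop_rate(stretch_from: float, stretch_to: float, channel: str,
             params: ModelParams) -> float:
    """Detailed-balance hop rate of one binding site of a bound dimer.

    ``channel`` selects the bare rate ``D_nuc/a^2`` ("nucleoid") or
    ``D_clu/a^2`` ("cluster"); the Boltzmann factor carries half the
    spring-energy change so that forward and backward rates multiply to
    the squared bare rate.
    """
    if channel == "nucleoid":
        eps0 = params.eps_nuc
    elif channel == "cluster":
        eps0 = params.eps_clu
    else:
        raise ValueError(f"unknown hop channel {channel!r}")
    de = (stretch_to**2 - stretch_from**2) * params.k / (4.0 * params.kBT)
    return eps0 * math.exp(-de)


# ---------------------------------------------------------------------------
# explicit system state (reference path)
# ---------------------------------------------------------------------------

@dataclass
class DimerState:
    """One PomZ dimer: nucleoid anchor, optional cluster anchor, origin side."""

    x_nuc: float
    x_clu: Optional[float] = None
    origin_side: int = 0

    @property
    def bound(self) -> bool:
        return self.x_clu is not None

    def stretch(self) -> float:
        if self.x_clu is None:
            raise ValueError("dimer is not cluster-bound")
        return self.x_clu - self.x_nuc


@dataclass
class SystemState:
    """Instantaneous state: time, cluster position, dimers, cytosolic pool."""

    t: float
    x_c: float
    dimers: list[DimerState] = field(default_factory=list)
    N_cyto: int = 0

    @property
    def n_bound(self) -> int:
        return sum(1 for d in self.dimers if d.bound)

    @property
    def total_stretch(self) -> float:
        return sum(d.stretch() for d in self.dimers if d.bound)

    def check_conservation(self, params: ModelParams) -> None:
        n = self.N_cyto + len(self.dimers)
        if n != params.N_total:
            raise AssertionError(
                f"particle conservation violated: {n} != {params.N_total}")


def attachment_propensity(state: SystemState, params: ModelParams) -> float:
    """Aggregate cytosol-to-nucleoid attachment propensity.

    ``k_on * N_cyto * (L - L_c)/L``: the accessible fraction matches the
    sink term of the RD model.
    """
    if params.L_c >= params.L:
        raise ValueError("no attachment site exists: L_c >= L")
    return params.k_on * state.N_cyto * (params.L - params.L_c) / params.L


def sample_attachment_site(state: SystemState, rng: np.random.Generator,
                           params: ModelParams) -> float:
    """Uniform landing position outside the cluster footprint (um)."""
    sites = params.nucleoid_sites()
    lo = state.x_c - params.L_c / 2
    hi = state.x_c + params.L_c / 2
    eligible = sites[(sites < lo) | (sites > hi)]
    if eligible.size == 0:
        raise ValueError("no eligible attachment site (cluster covers nucleoid)")
    return float(rng.choice(eligible))


def advance_cluster(state: SystemState, dt: float,
                    params: ModelParams) -> float:
    """Closed-form overdamped cluster displacement over ``dt``.

    With the binding-site assignment frozen, every bound stretch shifts
    rigidly with the cluster, so the total stretch relaxes exponentially
    and ``x_c(dt) = x_c + x* (1 - exp(-k N dt / gamma_c))`` with the
    fixed point ``x* = (F_ext - k S0)/(k N)``.  Returns the new ``x_c``
    without mutating ``state``.
    """
    n = state.n_bound
    if n == 0:
        return state.x_c + params.F_ext * dt / params.gamma_c
    s0 = state.total_stretch
    r = params.k * n / params.gamma_c
    xstar = (params.F_ext - params.k * s0) / (params.k * n)
    return state.x_c + xstar * (1.0 - math.exp(-r * dt))


def build_propensities(state: SystemState, params: ModelParams):
    """Enumerate the full event catalogue with rates (reference path).

    Returns ``(rates, events)`` where each event is a tuple
    ``(tag, dimer_index, payload)`` with tags ``attach``, ``hop_nuc``,
    ``hop_clu``, ``bind``, ``hydrolysis``, ``detach`` and ``null``.
    """
    p = params
    rates: list[float] = []
    events: list[tuple] = []
    if state.N_cyto > 0 and p.L_c < p.L:
        rates.append(attachment_propensity(state, p))
        events.append(("attach", None, None))
    smax = _kernels.pruning_distance(p.k, p.kBT)
    csites = p.cluster_sites(state.x_c)
    for i, d in enumerate(state.dimers):
        if not d.bound:
            if d.x_nuc - p.a > 0 or p.infinite_lattice:
                rates.append(p.eps_nuc)
                events.append(("hop_nuc", i, -1))
            if d.x_nuc + p.a < p.L or p.infinite_lattice:
                rates.append(p.eps_nuc)
                events.append(("hop_nuc", i, +1))
            if p.k_off > 0:
                rates.append(p.k_off)
                events.append(("detach", i, None))
            for j, xs in enumerate(csites):
                if abs(xs - d.x_nuc) <= smax:
                    rates.append(cluster_binding_rate(d.x_nuc, xs, p))
                    events.append(("bind", i, j))
        else:
            s = d.stretch()
            if d.x_nuc - p.a > 0 or p.infinite_lattice:
                rates.append(hop_rate(s, s + p.a, "nucleoid", p))
                events.append(("hop_nuc", i, -1))
            if d.x_nuc + p.a < p.L or p.infinite_lattice:
                rates.append(hop_rate(s, s - p.a, "nucleoid", p))
                events.append(("hop_nuc", i, +1))
            j = int(round((d.x_clu - (state.x_c - p.L_c / 2 + 0.5 * p.a))
                          / p.a))
            if j > 0 or p.infinite_lattice:
                rates.append(hop_rate(s, s - p.a, "cluster", p))
                events.append(("hop_clu", i, -1))
            if j < p.n_cluster_sites - 1 or p.infinite_lattice:
                rates.append(hop_rate(s, s + p.a, "cluster", p))
                events.append(("hop_clu", i, +1))
            if p.k_h > 0:
                rates.append(p.k_h)
                events.append(("hydrolysis", i, None))
    if p.lambda_null > 0:
        rates.append(p.lambda_null)
        events.append(("null", None, None))
    return np.asarray(rates), events


def gillespie_step(state: SystemState, rng: np.random.Generator,
                   params: ModelParams):
    """Draw the waiting time and the next event (does not mutate ``state``).

    ``dt = -ln(xi)/alpha`` with ``xi`` uniform on (0, 1] and ``alpha`` the
    propensity sum; the event is drawn proportionally to the rates, which
    are frozen at the current time.
    """
    rates, events = build_propensities(state, params)
    alpha = float(rates.sum())
    if alpha <= 0.0:
        raise RuntimeError(
            "absorbing state: total propensity is zero "
            "(no dimers and no channels)")
    xi = 1.0 - rng.random()
    dt = -math.log(xi) / alpha
    u = rng.random() * alpha
    acc = np.cumsum(rates)
    idx = int(np.searchsorted(acc, u, side="right"))
    idx = min(idx, len(events) - 1)
    return dt, events[idx]


# ---------------------------------------------------------------------------
# run outputs
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled cluster trajectory of one stochastic run."""

    frame: pd.DataFrame          # t_s, x_c_um, n_cluster_bound, ...
    seed: int
    params: ModelParams
    x_c_final: float = 0.0
    x_c_min: float = 0.0
    x_c_max: float = 0.0

    def __post_init__(self):
        t = self.frame["t_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise AssertionError("trajectory times must strictly increase")


@dataclass
class ConditionedAccumulator:
    """Raw position-conditioned accumulation sums from a dynamic run."""

    occ_n: np.ndarray            # time-weighted occupancy, absolute sites
    occ_c: np.ndarray
    flux_net: np.ndarray         # net hop counts per bond (nucleoid-only)
    occ_n_rel: np.ndarray        # cluster-relative offsets, index M = 0
    occ_c_rel: np.ndarray
    flux_rel: np.ndarray
    force_dt: float              # time integral of the spring force (pN s)
    nb_dt: float                 # time integral of the bound count (s)
    dwell: float                 # total accumulation time (s)
    n_epochs: int


@dataclass
class StationaryRunResult:
    """Time-averaged profiles from a frozen-cluster run."""

    x: np.ndarray                # site centres (um)
    c: np.ndarray                # nucleoid-only density (1/um)
    c_b: np.ndarray              # cluster-bound density mapped to sites
    x_bonds: np.ndarray          # bond positions (um)
    flux: np.ndarray             # net nucleoid-only flux per bond (1/s)
    stretch_grid: np.ndarray     # lattice of bound-dimer stretches (um)
    stretch_occupancy: np.ndarray  # time fraction per stretch value
    force_mean: float            # time-averaged spring force on cluster (pN)
    n_bound_mean: float
    T_acc: float
    x_c: float
    seed: int
    params: ModelParams


def _kernel_seed(seed) -> int:
    """Fold an arbitrary seed spec into the kernel's 32-bit seed space."""
    return int(np.random.SeedSequence(seed).generate_state(1)[0])


def _binding_table(params: ModelParams):
    return _kernels.build_binding_table(
        params.k, params.kBT, params.ka0, params.a, params.n_cluster_sites)


# ---------------------------------------------------------------------------
# simulation protocols
# ---------------------------------------------------------------------------

def run_dynamic(params: ModelParams, seed, t_end: float,
                record_dt: float = 10.0,
                x_c0: Optional[float] = None,
                condition: Optional[tuple[float, float, float]] = None,
                ) -> tuple[Trajectory, Optional[ConditionedAccumulator]]:
    """Coupled PomZ/cluster dynamics.

    All dimers start cytosolic; the cluster is frozen for ``t_min`` so the
    PomZ distribution can equilibrate, then moves under the tether forces.
    By default the cluster starts with its left edge at the left nucleoid
    edge (``x_c(0) = L_c/2``).

    ``condition = (target_frac, enter_frac, exit_frac)`` switches on
    position-conditioned accumulation of density/flux profiles: recording
    begins when ``|x_c - target| <= enter`` and stops when
    ``|x_c - target| > exit`` (fractions of ``L``).
    """
    if params.infinite_lattice:
        raise ValueError("run_dynamic requires a finite lattice")
    x_c0 = params.L_c / 2 if x_c0 is None else x_c0
    v0, dv, tab = _binding_table(params)
    smax = _kernels.pruning_distance(params.k, params.kBT)
    if condition is None:
        cond = (False, 0.0, 0.0, 0.0, 0.0)
    else:
        target, enter, exit_ = condition
        if exit_ < enter:
            raise ValueError("exit tolerance must be >= enter tolerance")
        cond = (True,
                (target - enter) * params.L, (target + enter) * params.L,
                (target - exit_) * params.L, (target + exit_) * params.L)
    out = _kernels._run_lattice(
        _kernel_seed(seed), params.N_total, params.n_sites,
        params.n_cluster_sites, params.a, params.L, params.L_c,
        params.eps_nuc, params.eps_clu, params.k_h, params.k_off,
        params.k_on, params.k, params.kBT, params.gamma_c, params.F_ext,
        params.lambda_null, x_c0, True, params.t_min, t_end, record_dt,
        v0, dv, tab, smax, *cond)
    (t_rec, xc_rec, nb_rec, nn_rec, occ_n, occ_c, flux_net,
     occ_n_rel, occ_c_rel, flux_rel, _occ_s, force_dt, nb_dt, T_acc,
     n_epochs, xc_min, xc_max, xc_fin) = out
    frame = pd.DataFrame({
        "t_s": t_rec, "x_c_um": xc_rec,
        "n_cluster_bound": nb_rec, "n_nucleoid_only": nn_rec,
        "n_cyto": params.N_total - nb_rec - nn_rec})
    if (xc_min < params.L_c / 2 - params.a
            or xc_max > params.L - params.L_c / 2 + params.a):
        logger.warning(
            "cluster left the nucleoid during the run: x_c range "
            "[%.4f, %.4f] um outside [%.4f, %.4f]",
            xc_min, xc_max, params.L_c / 2, params.L - params.L_c / 2)
    traj = Trajectory(frame=frame, seed=_kernel_seed(seed), params=params,
                      x_c_final=xc_fin, x_c_min=xc_min, x_c_max=xc_max)
    acc = None
    if condition is not None:
        acc = ConditionedAccumulator(
            occ_n=occ_n, occ_c=occ_c, flux_net=flux_net,
            occ_n_rel=occ_n_rel, occ_c_rel=occ_c_rel, flux_rel=flux_rel,
            force_dt=float(force_dt), nb_dt=float(nb_dt),
            dwell=float(T_acc), n_epochs=int(n_epochs))
    return traj, acc


def run_stationary(params: ModelParams, x_c_fixed: float, seed,
                   t_end: float, t_eq: Optional[float] = None,
                   ) -> StationaryRunResult:
    """PomZ dynamics around an immobile cluster at ``x_c_fixed``.

    Accumulates (after an equilibration period, default ``t_min``) the
    time-averaged occupancy per lattice site -- nucleoid binding site for
    nucleoid-only dimers, cluster binding site for bound dimers -- the net
    hop flux of nucleoid-only dimers per bond, and the time-averaged
    spring force on the cluster.
    """
    if params.infinite_lattice:
        raise ValueError("run_stationary requires a finite lattice")
    t_eq = params.t_min if t_eq is None else t_eq
    v0, dv, tab = _binding_table(params)
    smax = _kernels.pruning_distance(params.k, params.kBT)
    out = _kernels._run_lattice(
        _kernel_seed(seed), params.N_total, params.n_sites,
        params.n_cluster_sites, params.a, params.L, params.L_c,
        params.eps_nuc, params.eps_clu, params.k_h, params.k_off,
        params.k_on, params.k, params.kBT, params.gamma_c, 0.0,
        params.lambda_null, x_c_fixed, False, t_eq, t_end, max(t_end, 1.0),
        v0, dv, tab, smax, False, 0.0, 0.0, 0.0, 0.0)
    (_, _, _, _, occ_n, occ_c, flux_net, _, _, _, occ_s,
     force_dt, nb_dt, T_acc, _, _, _, _) = out
    if T_acc <= 0:
        raise RuntimeError("no accumulation time: t_end must exceed t_eq")
    x = params.nucleoid_sites()
    M = params.n_sites
    return StationaryRunResult(
        x=x, c=occ_n / (T_acc * params.a), c_b=occ_c / (T_acc * params.a),
        x_bonds=x[:-1] + params.a / 2, flux=flux_net / T_acc,
        stretch_grid=(np.arange(2 * M + 1) - M) * params.a,
        stretch_occupancy=occ_s / T_acc,
        force_mean=float(force_dt / T_acc),
        n_bound_mean=float(nb_dt / T_acc), T_acc=float(T_acc),
        x_c=x_c_fixed, seed=_kernel_seed(seed), params=params)


def run_one_particle(params: ModelParams, n_interactions: int, seed,
                     start_distance: Optional[float] = None) -> pd.DataFrame:
    """Repeated single-dimer encounters with a cluster frozen at midnucleoid.

    The dimer is (re)placed on the nucleoid to the right of the cluster,
    outside the range where cluster binding is possible, and diffuses until
    it binds and is eventually released by hydrolysis.  Per encounter the
    returned frame carries the attachment stretch ``stretch_attach =
    x_nuc - x_clu`` (positive when stretched toward the arrival side), the
    interaction time ``t_i``, the time-integrated force ``f_int`` exerted
    on the cluster (positive pushes the cluster rightward, i.e. toward the
    dimer's origin side) and the time-averaged force ``f_i = f_int/t_i``.
    """
    if params.k_h <= 0:
        raise ValueError("one-particle protocol requires k_h > 0")
    x_c = params.L / 2
    smax = _kernels.pruning_distance(params.k, params.kBT)
    if start_distance is None:
        start_distance = max(2 * smax, 0.05)
    if start_distance <= smax:
        raise ValueError("start_distance must exceed the binding range")
    x_start = x_c + params.L_c / 2 + start_distance
    i_start = int(x_start / params.a)
    if i_start >= params.n_sites:
        raise ValueError("start site beyond the nucleoid end")
    v0, dv, tab = _binding_table(params)
    s_att, t_att, t_det, f_int = _kernels._run_one_particle(
        _kernel_seed(seed), params.n_sites, params.n_cluster_sites,
        params.a, params.L, params.L_c, params.eps_nuc, params.eps_clu,
        params.k_h, params.k, params.kBT, x_c, i_start,
        int(n_interactions), v0, dv, tab, smax)
    t_i = t_det - t_att
    return pd.DataFrame({
        "t_attach_s": t_att, "t_detach_s": t_det, "t_i_s": t_i,
        "f_int_pNs": f_int, "f_i_pN": f_int / t_i,
        "stretch_attach_um": s_att})


def run_friction_assay(params: ModelParams, N_bound: int,
                       F_ext_list: Sequence[float], n_runs: int, seed,
                       t_end: float = 100.0, t_skip: float = 5.0,
                       return_velocities: bool = False):
    """Force-velocity measurement on unbounded lattices.

    ``N_bound`` dimers are permanently bound to the cluster (``k_h = 0``)
    with initially relaxed tethers; for each external force the mean
    steady-state velocity over ``n_runs`` trajectories is estimated from
    the displacement between ``t_skip`` and ``t_end``.  With
    ``return_velocities`` the per-run velocities are returned as well.
    """
    if params.k_h != 0:
        raise ValueError("friction assay requires k_h = 0 "
                         "(permanently bound dimers)")
    rows = []
    per_run: dict[float, np.ndarray] = {}
    ss = np.random.SeedSequence(_kernel_seed(seed))
    children = ss.generate_state(len(F_ext_list) * n_runs)
    idx = 0
    for F in F_ext_list:
        vels = []
        for _ in range(n_runs):
            run_seed = int(children[idx]); idx += 1
            if N_bound == 0:
                # free overdamped particle: deterministic drift
                vels.append(F / params.gamma_c)
                continue
            t_rec, xc_rec = _kernels._run_friction(
                run_seed, int(N_bound), params.a, params.eps_nuc,
                params.eps_clu, params.k, params.kBT, params.gamma_c,
                float(F), float(t_end), 1.0)
            use = t_rec >= t_skip
            tt, xx = t_rec[use], xc_rec[use]
            vels.append((xx[-1] - xx[0]) / (tt[-1] - tt[0]))
        vels = np.asarray(vels)
        per_run[float(F)] = vels
        rows.append({"F_ext_pN": F, "v_mean_um_s": vels.mean(),
                     "v_se_um_s": (vels.std(ddof=1) / math.sqrt(len(vels))
                                   if len(vels) > 1 else 0.0),
                     "n_runs": len(vels)})
    table = pd.DataFrame(rows)
    if return_velocities:
        return table, per_run
    return table
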