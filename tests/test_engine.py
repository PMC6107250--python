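"""Event machinery: waiting-time law, event selection, closed-form cluster
advance, particle conservation, detachment statistics, null-event
insensitivity."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

import pomsim
from pomsim.engine import (DimerState, SystemState, advance_cluster,
                           build_propensities, gillespie_step)
from pomsim.params import ModelParams


def _one_dimer_state(p: ModelParams) -> SystemState:
    return SystemState(t=0.0, x_c=p.L / 2,
                       dimers=[DimerState(x_nuc=0.105)], N_cyto=0)


class _XiRng:
    """Deterministic stand-in for a Generator: random() returns a constant."""

    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


def test_waiting_time_zero_at_xi_one():
    p = ModelParams(N_total=1, k_on=0.0)
    dt, _ = gillespie_step(_one_dimer_state(p), _XiRng(0.0), p)
    assert dt == 0.0


def test_waiting_time_exponential_law():
    """dt draws at frozen total propensity follow Exp(alpha) (KS test)."""
    p = ModelParams(N_total=1, k_on=0.0)
    state = _one_dimer_state(p)
    rates, _ = build_propensities(state, p)
    alpha = rates.sum()
    rng = np.random.default_rng(2024)
    draws = np.array([gillespie_step(state, rng, p)[0]
                      for _ in range(100000)])
    assert draws.mean() == pytest.approx(1 / alpha, rel=0.01)
    res = kstest(draws, "expon", args=(0, 1 / alpha))
    assert res.pvalue > 0.01


def test_event_selection_matches_rates():
    """Empirical event frequencies reproduce the propensity weights."""
    from scipy.stats import chisquare

    p = ModelParams(N_total=1, k_on=0.0, k_off=0.3)
    state = _one_dimer_state(p)
    rates, events = build_propensities(state, p)
    rng = np.random.default_rng(99)
    counts = {tag: 0 for tag, _, _ in events}
    n = 20000
    for _ in range(n):
        _, ev = gillespie_step(state, rng, p)
        counts[ev[0]] += 1
    probs = {}
    for r, (tag, _, _) in zip(rates, events):
        probs[tag] = probs.get(tag, 0.0) + r / rates.sum()
    tags = sorted(probs)
    res = chisquare([counts[t] for t in tags],
                    [probs[t] * n for t in tags])
    assert res.pvalue > 0.01


def test_gillespie_absorbing_state_signals():
    p = ModelParams(N_total=0, k_on=0.5)
    state = SystemState(t=0.0, x_c=p.L / 2, dimers=[], N_cyto=0)
    with pytest.raises(RuntimeError, match="absorbing"):
        gillespie_step(state, np.random.default_rng(0), p)


# -- closed-form cluster advance -------------------------------------------

def test_advance_cluster_no_dimers_no_force():
    p = ModelParams()
    state = SystemState(t=0.0, x_c=1.7, dimers=[], N_cyto=p.N_total)
    assert advance_cluster(state, 5.0, p) == 1.7


def test_advance_cluster_single_tether_relaxation():
    """One bound dimer: the stretch decays as exp(-k dt / gamma_c)."""
    p = ModelParams()
    s0 = 0.03
    d = DimerState(x_nuc=p.L / 2, x_clu=p.L / 2 + s0)
    state = SystemState(t=0.0, x_c=p.L / 2, dimers=[d], N_cyto=0)
    dt = 0.25
    x_new = advance_cluster(state, dt, p)
    s_new = s0 + (x_new - p.L / 2)
    assert s_new == pytest.approx(s0 * math.exp(-p.k * dt / p.gamma_c),
                                  rel=1e-12)


def test_advance_cluster_external_force_fixed_point():
    p = ModelParams(F_ext=0.05)
    d = DimerState(x_nuc=2.0, x_clu=2.0)
    state = SystemState(t=0.0, x_c=p.L / 2, dimers=[d], N_cyto=0)
    x_new = advance_cluster(state, 1e6, p)
    # stationary stretch balances the external force: k*s = F_ext
    assert (x_new - p.L / 2) == pytest.approx(p.F_ext / p.k, rel=1e-9)


def test_advance_cluster_matches_fine_euler():
    """Closed form vs explicit Euler with 1e4 substeps: relative 1e-6."""
    p = ModelParams(F_ext=0.01)
    stretches = [0.03, -0.01, 0.02]
    dimers = [DimerState(x_nuc=2.0, x_clu=2.0 + s) for s in stretches]
    state = SystemState(t=0.0, x_c=p.L / 2, dimers=dimers, N_cyto=0)
    dt = 0.5
    x_exact = advance_cluster(state, dt, p)

    n_sub = 10000
    h = dt / n_sub
    x = state.x_c
    S = sum(stretches)
    N = len(stretches)
    for _ in range(n_sub):
        v = (-p.k * S + p.F_ext) / p.gamma_c
        x += v * h
        S += N * v * h
    assert x_exact == pytest.approx(x, rel=1e-6)


# -- full-run invariants ----------------------------------------------------

def test_no_dimers_cluster_immobile(desk):
    p = desk.replace(N_total=0, t_min=0.0)
    traj, _ = pomsim.run_dynamic(p, seed=1, t_end=50.0, record_dt=5.0)
    assert np.all(traj.frame["x_c_um"] == p.L_c / 2)


def test_particle_conservation_full_run(dynamic_ensemble, desk):
    for tr in dynamic_ensemble:
        f = tr.frame
        total = f.n_cluster_bound + f.n_nucleoid_only + f.n_cyto
        assert (total == desk.N_total).all()
        assert (np.diff(f.t_s) > 0).all()


def test_bound_count_never_decreases_without_release(desk):
    p = desk.replace(k_h=0.0, k_off=0.0, t_min=0.0, N_total=10)
    traj, _ = pomsim.run_dynamic(p, seed=3, t_end=100.0, record_dt=1.0)
    on_lattice = (traj.frame.n_cluster_bound + traj.frame.n_nucleoid_only)
    assert (np.diff(on_lattice) >= 0).all()


def test_interaction_durations_exponential_in_kh(desk):
    """Encounter durations are Exp(k_h) (hydrolysis-limited detachment)."""
    p = desk.replace(k_h=0.1)
    rec = pomsim.run_one_particle(p, 1500, seed=42)
    lam = 1.0 / rec["t_i_s"].mean()
    assert lam == pytest.approx(0.1, rel=0.05)
    res = kstest(rec["t_i_s"], "expon", args=(0, rec["t_i_s"].mean()))
    assert res.pvalue > 0.01


def test_koff_gives_exponential_nucleoid_residence(desk):
    """Never-cluster-bound dimers leave the nucleoid at rate k_off."""
    # place the cluster irrelevantly far by disabling binding
    p = desk.replace(ka0=0.0, k_off=0.5, N_total=20, t_min=0.0)
    traj, _ = pomsim.run_dynamic(p, seed=11, t_end=400.0, record_dt=1.0)
    n_nuc = traj.frame.n_nucleoid_only.to_numpy()
    # stationary occupancy of the two-state cycle matches the rate ratio
    att = p.k_on * (p.L - p.L_c) / p.L
    expected = p.N_total * att / (att + p.k_off)
    assert n_nuc[100:].mean() == pytest.approx(expected, rel=0.15)


def test_null_event_rate_does_not_change_statistics(desk):
    """A high no-op rate only shortens steps; observables are unchanged."""
    def mean_bound(lam, seeds):
        p = desk.replace(lambda_null=lam, t_min=50.0)
        vals = []
        for s in seeds:
            tr, _ = pomsim.run_dynamic(p, s, t_end=250.0, record_dt=2.0)
            f = tr.frame
            vals.append(f.n_cluster_bound[f.t_s > 100.0].mean())
        return np.array(vals)

    # lambda ~ 10x the intrinsic propensity sum of the desk system
    a = mean_bound(0.0, [(61, i) for i in range(6)])
    b = mean_bound(2e5, [(62, i) for i in range(6)])
    se = math.hypot(a.std(ddof=1) / math.sqrt(len(a)),
                    b.std(ddof=1) / math.sqrt(len(b)))
    assert abs(a.mean() - b.mean()) < 4 * se + 0.05 * a.mean()


def test_mirror_symmetry_of_stationary_profiles(desk):
    """Profiles for clusters at x_c and L - x_c are mirror images."""
    x_c = 0.3 * desk.L
    runs_l = [pomsim.run_stationary(desk, x_c, (71, i), t_end=500.0)
              for i in range(4)]
    runs_r = [pomsim.run_stationary(desk, desk.L - x_c, (72, i),
                                    t_end=500.0)
              for i in range(4)]
    dens_l = np.mean([r.c + r.c_b for r in runs_l], axis=0)
    dens_r = np.mean([r.c + r.c_b for r in runs_r], axis=0)[::-1]
    # compare coarse 10-bin averages within Monte-Carlo error
    bl = np.array([b.mean() for b in np.array_split(dens_l, 10)])
    br = np.array([b.mean() for b in np.array_split(dens_r, 10)])
    scale = dens_l.mean()
    assert np.max(np.abs(bl - br)) < 0.25 * scale
    f_l = np.mean([r.force_mean for r in runs_l])
    f_r = np.mean([r.force_mean for r in runs_r])
    assert f_l == pytest.approx(-f_r, abs=0.3 * abs(f_l) + 1e-3)
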