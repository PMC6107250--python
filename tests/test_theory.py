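"""Semi-analytic machinery: force constant estimators, the friction
formula's algebra, the velocity field and trajectory integration, and the
timescale criterion."""

import numpy as np
import pandas as pd
import pytest

from pomsim import theory
from pomsim.params import ModelParams


def test_estimate_C_empty_rejected():
    with pytest.raises(ValueError):
        theory.estimate_C(pd.DataFrame(columns=["f_int_pNs", "t_i_s",
                                                "stretch_attach_um"]), 1.0)


def test_estimate_C_zero_forces():
    rec = pd.DataFrame({"f_int_pNs": np.zeros(50),
                        "t_i_s": np.ones(50),
                        "stretch_attach_um": np.zeros(50)})
    est = theory.estimate_C(rec, 2.0, n_boot=10)
    assert est.C == 0.0 and est.C_int == 0.0


def test_estimate_C_two_estimators_agree(one_particle_records, desk):
    """C = f/k_h and C = <f_int> are computed from the same records and
    must agree within their combined bootstrap uncertainty."""
    est = theory.estimate_C(one_particle_records, desk.k_h, seed=5)
    diff = abs(est.C - est.C_int)
    assert diff < 3 * np.hypot(est.C_se, est.C_int_se)
    assert est.C > 0  # right-side arrivals push the cluster rightward
    assert est.dx0 > 0  # attachment biased towards the arrival side


def test_effective_friction_algebra():
    p = ModelParams()
    assert theory.effective_friction(0, p) == p.gamma_c
    g1 = theory.effective_friction(10, p) - p.gamma_c
    p2 = p.replace(D_nuc=2 * p.D_nuc, D_clu=2 * p.D_clu)
    g2 = theory.effective_friction(10, p2) - p2.gamma_c
    assert g2 == pytest.approx(g1 / 2)
    with pytest.raises(ValueError):
        theory.effective_friction(-1, p)


def test_velocity_field_signs_and_antisymmetry(desk):
    vf = theory.VelocityField(desk, C=0.005, n_grid=31)
    mid = desk.L / 2
    assert vf(mid) == pytest.approx(0.0, abs=1e-12)
    assert vf(0.3 * desk.L) > 0          # drives towards midnucleoid
    assert vf(0.7 * desk.L) < 0
    for d in (0.1, 0.25, 0.4):
        assert vf(mid - d) == pytest.approx(-vf(mid + d), rel=1e-6,
                                            abs=1e-15)


def test_velocity_linear_in_C(desk):
    x = 0.25 * desk.L
    v1 = theory.velocity_field(x, 0.004, desk)
    v2 = theory.velocity_field(x, 0.002, desk)
    assert v1 == pytest.approx(2 * v2, rel=1e-12)


def test_trajectory_constant_at_midnucleoid(desk):
    vf = theory.VelocityField(desk, C=0.005, n_grid=21)
    traj = theory.integrate_trajectory(desk.L / 2, 500.0, vf)
    assert np.allclose(traj.x_c_um, desk.L / 2, atol=1e-9)


def test_trajectory_monotone_without_overshoot(desk):
    vf = theory.VelocityField(desk, C=0.005, n_grid=31)
    traj = theory.integrate_trajectory(desk.L_c / 2, 4000.0, vf)
    x = traj.x_c_um.to_numpy()
    assert (np.diff(x) >= -1e-9).all()
    assert x.max() <= desk.L / 2 + 1e-6
    assert x[-1] == pytest.approx(desk.L / 2, abs=0.02)


def test_trajectory_time_rescales_with_C(desk):
    vf1 = theory.VelocityField(desk, C=0.004, n_grid=31)
    vf2 = theory.VelocityField(desk, C=0.002, n_grid=31)
    t1 = theory.integrate_trajectory(0.2, 1000.0, vf1)
    t2 = theory.integrate_trajectory(0.2, 2000.0, vf2)
    # halving C doubles the time to reach any position
    x1 = np.interp(600.0, t1.t_s, t1.x_c_um)
    x2 = np.interp(1200.0, t2.t_s, t2.x_c_um)
    assert x1 == pytest.approx(x2, rel=1e-5)


def test_timescale_arithmetic():
    p = ModelParams(L=5.0, D_nuc=1e-4)
    rep = theory.timescale_criterion(p, C=0.006)
    assert rep.t_PomZ == pytest.approx(2.5e5)


def test_fast_diffusion_is_stable(desk):
    fast = desk.replace(D_nuc=1e3)
    rep = theory.timescale_criterion(fast, C=0.005)
    assert rep.stable
    assert rep.margin < 1e-3


def test_margin_reported_with_verdict(desk):
    rep = theory.timescale_criterion(desk, C=0.005, rho=0.1)
    assert rep.stable == (rep.margin < rep.rho)
    assert rep.t_cluster == pytest.approx(
        desk.L * rep.gamma_mid / (0.005 * rep.j_right))
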