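"""Elementary rate laws: binding Boltzmann factor, detailed-balance hops,
attachment sampling, and the tabulated total binding rate."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pomsim import _kernels
from pomsim.engine import (SystemState, attachment_propensity,
                           cluster_binding_rate, hop_rate,
                           sample_attachment_site,
                           total_cluster_binding_rate)
from pomsim.params import ModelParams

P = ModelParams()


def test_binding_rate_zero_offset_is_ka0():
    assert cluster_binding_rate(1.0, 1.0, P) == pytest.approx(P.ka0)


def test_binding_rate_unit_exponent():
    d = math.sqrt(2 * P.kBT / P.k)
    assert cluster_binding_rate(1.0, 1.0 + d, P) == pytest.approx(
        P.ka0 / math.e)


def test_binding_rate_symmetric_in_offset_sign():
    assert cluster_binding_rate(1.0, 1.3, P) == cluster_binding_rate(1.3, 1.0, P)


def test_total_binding_rate_gaussian_tail():
    # a dimer far outside the cluster effectively cannot bind
    x_far = P.L / 2 + P.L_c / 2 + 20 * math.sqrt(P.kBT / P.k)
    assert total_cluster_binding_rate(x_far, P.L / 2, P) < 1e-6 * P.ka0


def test_binding_table_matches_exact_sum():
    v0, dv, tab = _kernels.build_binding_table(
        P.k, P.kBT, P.ka0, P.a, P.n_cluster_sites)
    rng = np.random.default_rng(7)
    x_c = P.L / 2
    t0 = x_c - P.L_c / 2 + 0.5 * P.a
    for x in rng.uniform(x_c - P.L_c, x_c + P.L_c, size=40):
        interp = _kernels._table_lookup(x - t0, v0, dv, tab)
        exact = total_cluster_binding_rate(x, x_c, P)
        assert interp == pytest.approx(exact, rel=1e-4, abs=1e-9 * P.ka0)


def test_hop_rate_equal_stretch_is_bare_rate():
    assert hop_rate(0.02, 0.02, "nucleoid", P) == pytest.approx(P.eps_nuc)
    assert hop_rate(-0.01, -0.01, "cluster", P) == pytest.approx(P.eps_clu)


@given(st.floats(-0.05, 0.05), st.floats(-0.05, 0.05))
def test_hop_detailed_balance_product(s_from, s_to):
    """forward * backward = (eps0)^2 for every admissible stretch pair."""
    fwd = hop_rate(s_from, s_to, "nucleoid", P)
    bwd = hop_rate(s_to, s_from, "nucleoid", P)
    assert fwd * bwd == pytest.approx(P.eps_nuc**2, rel=1e-12)


@given(st.floats(-0.05, 0.05), st.floats(-0.05, 0.05))
def test_hop_ratio_is_boltzmann(s_from, s_to):
    """forward/backward = exp(-dE/kBT) with dE the spring-energy change."""
    fwd = hop_rate(s_from, s_to, "cluster", P)
    bwd = hop_rate(s_to, s_from, "cluster", P)
    dE = P.k * (s_to**2 - s_from**2) / 2
    assert fwd / bwd == pytest.approx(math.exp(-dE / P.kBT), rel=1e-9)


def test_hop_rate_unknown_channel():
    with pytest.raises(ValueError):
        hop_rate(0.0, 0.0, "membrane", P)


def test_attachment_propensity_zero_cytosol():
    st_ = SystemState(t=0.0, x_c=P.L / 2, N_cyto=0)
    assert attachment_propensity(st_, P) == 0.0


def test_attachment_propensity_accessible_fraction():
    st_ = SystemState(t=0.0, x_c=P.L / 2, N_cyto=10)
    assert attachment_propensity(st_, P) == pytest.approx(
        P.k_on * 10 * (P.L - P.L_c) / P.L)
    # vanishing cluster footprint: per-dimer rate -> k_on
    tiny = P.replace(L_c=P.a)
    st2 = SystemState(t=0.0, x_c=tiny.L / 2, N_cyto=1)
    assert attachment_propensity(st2, tiny) == pytest.approx(
        tiny.k_on * (1 - tiny.a / tiny.L))


def test_attachment_requires_accessible_sites():
    p = ModelParams(L=1.0, L_c=1.0)
    st_ = SystemState(t=0.0, x_c=0.5, N_cyto=1)
    with pytest.raises(ValueError):
        attachment_propensity(st_, p)


def test_attachment_landing_uniform_outside_footprint():
    """Long-run landing histogram is uniform outside the cluster region."""
    from scipy.stats import chisquare

    p = ModelParams(L=1.0, L_c=0.3, N_total=1)
    st_ = SystemState(t=0.0, x_c=0.4, N_cyto=1)
    rng = np.random.default_rng(12345)
    draws = np.array([sample_attachment_site(st_, rng, p)
                      for _ in range(40000)])
    lo, hi = st_.x_c - p.L_c / 2, st_.x_c + p.L_c / 2
    assert not np.any((draws > lo) & (draws < hi))
    # chi^2 against uniform over the eligible sites (10 coarse groups)
    sites = p.nucleoid_sites()
    eligible = sites[(sites < lo) | (sites > hi)]
    groups = np.array_split(np.sort(eligible), 10)
    counts = [np.isin(draws, g).sum() for g in groups]
    expected = [len(g) / len(eligible) * len(draws) for g in groups]
    res = chisquare(counts, expected)
    assert res.pvalue > 0.01
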