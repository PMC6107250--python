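"""Shared fixtures.

The heavy stochastic ensembles are session-scoped and shared across the
unit and acceptance tests; all seeds are fixed so the suite is
deterministic up to library versioning.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import pomsim
from pomsim import theory

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk():
    """Reduced validation geometry (2 um nucleoid, 30 dimers)."""
    return pomsim.load_packaged_config("desk")


@pytest.fixture(scope="session")
def baseline():
    """Wild-type-like geometry (5 um nucleoid, 100 dimers)."""
    return pomsim.load_packaged_config("baseline")


@pytest.fixture(scope="session")
def one_particle_records(desk):
    """6000 single-dimer encounters with a midnucleoid cluster."""
    return pomsim.run_one_particle(desk, 6000, seed=101)


@pytest.fixture(scope="session")
def C_desk(one_particle_records, desk):
    return theory.estimate_C(one_particle_records, desk.k_h, seed=101)


STATIONARY_FRACS = (0.1, 0.2, 0.3, 0.4, 0.5)


@pytest.fixture(scope="session")
def stationary_ensembles(desk):
    """8 frozen-cluster runs per position at 10..50% nucleoid length."""
    out = {}
    for kf, frac in enumerate(STATIONARY_FRACS):
        runs = [pomsim.run_stationary(desk, frac * desk.L, (201, kf, i),
                                      t_end=desk.t_min + 600.0)
                for i in range(8)]
        out[frac] = runs
    return out


@pytest.fixture(scope="session")
def dynamic_ensemble(desk):
    """20 coupled runs from the left nucleoid pole (adiabatic regime)."""
    return [pomsim.run_dynamic(desk, (301, i), t_end=1600.0,
                               record_dt=10.0)[0]
            for i in range(20)]


@pytest.fixture(scope="session")
def slow_pomz_params(desk):
    """Slow PomZ dynamics: oscillatory regime of the phase diagram.

    PomZ diffusion 20x below baseline with a moderately mobile cluster
    and a larger dimer pool; the extra dimers average out shot noise in
    the arrival flux, giving a coherent oscillation whose spectral peak
    clearly clears the low-frequency background."""
    return desk.replace(D_nuc=0.005, D_clu=0.005, N_total=60,
                        gamma_c=1.0)


@pytest.fixture(scope="session")
def oscillatory_ensemble(slow_pomz_params):
    """24 midnucleoid-started runs deep in the oscillatory regime."""
    p = slow_pomz_params
    return [pomsim.run_dynamic(p, (401, i), t_end=3200.0, record_dt=3.0,
                               x_c0=p.L / 2)[0]
            for i in range(24)]


@pytest.fixture(scope="session")
def stable_mid_ensemble(desk):
    """6 midnucleoid-started runs in the stable (fast-PomZ) regime."""
    return [pomsim.run_dynamic(desk, (501, i), t_end=2000.0, record_dt=6.0,
                               x_c0=desk.L / 2)[0]
            for i in range(6)]
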