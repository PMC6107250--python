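"""Stationary reaction-diffusion model of PomZ density and flux.

For a fixed cluster position the PomZ dynamics reduce to a linear
stationary problem: nucleoid-only dimers diffuse with ``D_nuc`` and are
produced uniformly outside the cluster footprint by cytosolic attachment;
inside the footprint ``I_c = [x_c - L_c/2, x_c + L_c/2]`` they convert to
doubly-bound dimers at the aggregate rate ``k_a_total``; doubly-bound
dimers diffuse with ``D_b`` and are released into the cytosol at the
hydrolysis rate ``k_h``.  Outer boundaries and the cluster edges are
no-flux.  The cytosolic pool closes the system through total particle
number conservation.

The solution is assembled in closed form from edge-anchored exponential
basis functions (numerically robust for steep boundary layers) by solving
a 7x7 linear matching system.  The one-sided inflows at the cluster edges,
``j_R`` and ``j_L``, and their difference ``j_diff = j_R - j_L`` are the
position-sensing signal of the flux-balance mechanism: a cluster left of
midnucleoid receives more PomZ from the right than from the left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ModelParams, RDParams

__all__ = ["StationaryProfile", "solve_stationary", "flux_difference",
           "bound_count", "scan_flux_difference"]


@dataclass
class StationaryProfile:
    """Stationary RD solution for one cluster position.

    Densities are per um; ``j = -D_nuc dc/dx`` is the nucleoid flux of
    singly-bound dimers (1/s); ``j_R``/``j_L`` are the inflow magnitudes at
    the right/left cluster edge.
    """

    x: np.ndarray
    c: np.ndarray
    c_b: np.ndarray
    j: np.ndarray
    x_c: float
    N_cyto: float
    N_bound: float
    j_R: float
    j_L: float
    j_diff: float
    params: RDParams
    #: relative residuals of the conservation identities (diagnostics)
    balance_residual: float = 0.0
    number_residual: float = 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"x_um": self.x, "c": self.c, "c_b": self.c_b,
                             "j": self.j})


class _ClosedForm:
    """Piecewise closed-form solution with coefficients from the matching system."""

    def __init__(self, p: RDParams, x_c: float):
        self.p = p
        self.x_c = x_c
        self.xl = x_c - p.L_c / 2
        self.xr = x_c + p.L_c / 2
        if self.xl < -1e-12 or self.xr > p.L + 1e-12:
            raise ValueError(
                f"cluster at x_c={x_c} extends beyond the nucleoid [0, {p.L}]")
        if p.k_a_total > 0 and p.k_h <= 0:
            raise ValueError(
                "no stationary state with finite bound number: k_h = 0 "
                "while the cluster-binding rate is positive")
        self._solve()

    def _solve(self) -> None:
        p, xl, xr = self.p, self.xl, self.xr
        D, Db, kon, koff, kh, N_tot = (p.D_nuc, p.D_b, p.k_on, p.k_off,
                                       p.k_h, p.N_total)
        ka = p.k_a_total
        L, Lc = p.L, p.L_c
        wl, wr = xl, L - xr  # outer segment lengths

        if ka == 0.0 and not (koff > 0 and kon > 0):
            # without a cluster sink the cyclic flux vanishes; the steady
            # state is a flat profile set by which pool absorbs everything
            self.kind = "uniform"
            if kon > 0:            # koff = 0: all dimers end nucleoid-bound
                self.c_unif = N_tot / L
                self.N_cyto = 0.0
            else:                  # nothing attaches: all dimers cytosolic
                self.c_unif = 0.0
                self.N_cyto = float(N_tot)
            return

        lam = math.sqrt((ka + koff) / D)
        if ka > 0:
            mu = math.sqrt(kh / Db)
            beta_den = kh - Db * lam * lam
            if abs(beta_den) < 1e-9 * max(kh, Db * lam * lam):
                # resonant degeneracy of the particular solution; nudge
                lam *= 1.0 + 1e-7
                beta_den = kh - Db * lam * lam
            beta = ka / beta_den
        else:
            mu = 1.0  # unused
            beta = 0.0

        q = math.exp(-lam * Lc)
        r = math.exp(-mu * Lc) if ka > 0 else 0.0

        # unknowns: a0, b0, A, B, C1, C2, N_cyto
        M = np.zeros((7, 7))
        rhs = np.zeros(7)

        if koff == 0.0:
            # outer quadratics: left c = a0 - s x^2/(2D), s = kon*Ncyto/L
            cl_val = -kon * xl * xl / (2 * D * L)        # Ncyto coeff at xl
            cr_val = -kon * wr * wr / (2 * D * L)
            cl_der = -kon * xl / (D * L)                  # c'(xl) Ncyto coeff
            cr_der = kon * wr / (D * L)                   # c'(xr) Ncyto coeff
            il_a0, il_n = wl, -kon * wl**3 / (6 * D * L)  # integral coeffs
            ir_b0, ir_n = wr, -kon * wr**3 / (6 * D * L)
        else:
            nv = math.sqrt(koff / D)
            tl = math.tanh(nv * wl)
            tr = math.tanh(nv * wr)
            cl_val = kon / (L * koff)
            cr_val = kon / (L * koff)
            cl_der = 0.0  # via a0 instead
            cr_der = 0.0
            il_a0, il_n = tl / nv, kon * wl / (L * koff)
            ir_b0, ir_n = tr / nv, kon * wr / (L * koff)

        # R1/R2: continuity of c at xl, xr
        M[0, 0] = 1.0; M[0, 6] = cl_val; M[0, 2] = -1.0; M[0, 3] = -q
        M[1, 1] = 1.0; M[1, 6] = cr_val; M[1, 2] = -q;   M[1, 3] = -1.0
        # R3/R4: continuity of c' at xl, xr
        if koff == 0.0:
            M[2, 6] = cl_der
            M[3, 6] = cr_der
        else:
            M[2, 0] = nv * tl
            M[3, 1] = -nv * tr
        M[2, 2] = lam;      M[2, 3] = -lam * q
        M[3, 2] = lam * q;  M[3, 3] = -lam
        # R5/R6: no-flux of c_b at the cluster edges
        if ka > 0:
            M[4, 4] = -mu; M[4, 5] = mu * r
            M[4, 2] = -beta * lam; M[4, 3] = beta * lam * q
            M[5, 4] = -mu * r; M[5, 5] = mu
            M[5, 2] = -beta * lam * q; M[5, 3] = beta * lam
        else:
            M[4, 4] = 1.0
            M[5, 5] = 1.0
        # R7: total particle number
        M[6, 0] = il_a0
        M[6, 1] = ir_b0
        M[6, 2] = (1 + beta) * (1 - q) / lam
        M[6, 3] = (1 + beta) * (1 - q) / lam
        if ka > 0:
            M[6, 4] = (1 - r) / mu
            M[6, 5] = (1 - r) / mu
        M[6, 6] = 1.0 + il_n + ir_n
        rhs[6] = N_tot

        try:
            sol = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ValueError(
                "singular matching system for the stationary RD model "
                f"(x_c={self.x_c}, params={self.p})") from exc
        self.kind = "general"
        (self.a0, self.b0, self.A, self.B,
         self.C1, self.C2, self.N_cyto) = sol
        self.lam, self.mu, self.beta, self.q, self.r = lam, mu, beta, q, r
        self.koff = koff
        self.nv = math.sqrt(koff / D) if koff > 0 else 0.0

    # -- evaluation ------------------------------------------------------

    def c(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "uniform":
            return np.full_like(x, self.c_unif)
        p, xl, xr = self.p, self.xl, self.xr
        s = p.k_on * self.N_cyto / p.L
        out = np.empty_like(x)
        left = x < xl
        right = x > xr
        mid = ~(left | right)
        if self.koff == 0.0:
            out[left] = self.a0 - s * x[left] ** 2 / (2 * p.D_nuc)
            out[right] = self.b0 - s * (p.L - x[right]) ** 2 / (2 * p.D_nuc)
        else:
            nv = self.nv
            out[left] = (s / self.koff + self.a0 *
                         np.cosh(nv * x[left]) / math.cosh(nv * xl))
            out[right] = (s / self.koff + self.b0 *
                          np.cosh(nv * (p.L - x[right])) /
                          math.cosh(nv * (p.L - xr)))
        lam = self.lam
        out[mid] = (self.A * np.exp(-lam * (x[mid] - xl)) +
                    self.B * np.exp(-lam * (xr - x[mid])))
        return out

    def dc(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "uniform":
            return np.zeros_like(x)
        p, xl, xr = self.p, self.xl, self.xr
        s = p.k_on * self.N_cyto / p.L
        out = np.empty_like(x)
        left = x < xl
        right = x > xr
        mid = ~(left | right)
        if self.koff == 0.0:
            out[left] = -s * x[left] / p.D_nuc
            out[right] = s * (p.L - x[right]) / p.D_nuc
        else:
            nv = self.nv
            out[left] = (self.a0 * nv * np.sinh(nv * x[left]) /
                         math.cosh(nv * xl))
            out[right] = (-self.b0 * nv * np.sinh(nv * (p.L - x[right])) /
                          math.cosh(nv * (p.L - xr)))
        lam = self.lam
        out[mid] = lam * (-self.A * np.exp(-lam * (x[mid] - xl)) +
                          self.B * np.exp(-lam * (xr - x[mid])))
        return out

    def c_b(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if self.kind == "uniform" or self.p.k_a_total == 0:
            return out
        xl, xr = self.xl, self.xr
        mid = (x >= xl - 1e-15) & (x <= xr + 1e-15)
        xm = x[mid]
        lam, mu = self.lam, self.mu
        out[mid] = (self.C1 * np.exp(-mu * (xm - xl)) +
                    self.C2 * np.exp(-mu * (xr - xm)) +
                    self.beta * (self.A * np.exp(-lam * (xm - xl)) +
                                 self.B * np.exp(-lam * (xr - xm))))
        return out

    def integrals(self) -> tuple[float, float, float]:
        """(int c over [0,L], int c over I_c, int c_b)."""
        if self.kind == "uniform":
            return self.c_unif * self.p.L, self.c_unif * self.p.L_c, 0.0
        p, xl, xr = self.p, self.xl, self.xr
        s = p.k_on * self.N_cyto / p.L
        wl, wr = xl, p.L - xr
        if self.koff == 0.0:
            int_l = self.a0 * wl - s * wl**3 / (6 * p.D_nuc)
            int_r = self.b0 * wr - s * wr**3 / (6 * p.D_nuc)
        else:
            nv = self.nv
            int_l = s * wl / self.koff + self.a0 * math.tanh(nv * wl) / nv
            int_r = s * wr / self.koff + self.b0 * math.tanh(nv * wr) / nv
        lam = self.lam
        int_c_mid = (self.A + self.B) * (1 - self.q) / lam
        if p.k_a_total > 0:
            int_cb = ((self.C1 + self.C2) * (1 - self.r) / self.mu +
                      self.beta * int_c_mid)
        else:
            int_cb = 0.0
        return int_l + int_r + int_c_mid, int_c_mid, int_cb


def solve_stationary(params: RDParams | ModelParams,
                     x_c: float,
                     grid: np.ndarray | None = None) -> StationaryProfile:
    """Solve the stationary RD model for a cluster fixed at ``x_c``.

    ``grid`` defaults to the cell-centred lattice of spacing ``a`` so that
    the profile is directly comparable to stochastic site occupancies.
    """
    if isinstance(params, ModelParams):
        params = RDParams.from_model_params(params)
    cf = _ClosedForm(params, x_c)
    if grid is None:
        n = round(params.L / params.a)
        grid = (np.arange(n) + 0.5) * params.a
    c = cf.c(grid)
    c_b = cf.c_b(grid)
    j = -params.D_nuc * cf.dc(grid)
    if cf.kind == "uniform":
        N_cyto, N_bound = float(cf.N_cyto), 0.0
        j_R = j_L = 0.0
        bal_res = num_res = 0.0
    else:
        N_cyto = float(cf.N_cyto)
        int_c, int_c_mid, N_bound = cf.integrals()
        j_R = float(params.D_nuc * cf.dc(np.array([cf.xr]))[0])
        j_L = float(-params.D_nuc * cf.dc(np.array([cf.xl]))[0])
        # conservation diagnostics
        influx = params.k_on * N_cyto * (params.L - params.L_c) / params.L
        outflux = params.k_h * N_bound + params.k_off * int_c
        scale = max(abs(influx), abs(outflux), 1e-300)
        bal_res = abs(influx - outflux) / scale
        total = N_cyto + int_c + N_bound
        num_res = abs(total - params.N_total) / max(params.N_total, 1)
    return StationaryProfile(
        x=grid, c=c, c_b=c_b, j=j, x_c=x_c, N_cyto=N_cyto,
        N_bound=float(N_bound), j_R=j_R, j_L=j_L, j_diff=j_R - j_L,
        params=params, balance_residual=float(bal_res),
        number_residual=float(num_res))


def flux_difference(params: RDParams | ModelParams, x_c: float) -> float:
    """Net one-sided inflow difference ``j_R - j_L`` at cluster position ``x_c``."""
    return solve_stationary(params, x_c, grid=np.array([0.0])).j_diff


def bound_count(params: RDParams | ModelParams, x_c: float) -> float:
    """Stationary number of cluster-bound dimers ``N(x_c)``."""
    return solve_stationary(params, x_c, grid=np.array([0.0])).N_bound


def scan_flux_difference(params: RDParams | ModelParams,
                         x_c_grid: np.ndarray) -> np.ndarray:
    """``j_diff`` evaluated on a grid of cluster positions."""
    return np.array([flux_difference(params, float(x)) for x in x_c_grid])
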