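"""Model parameters shared by the stochastic engine, the RD solver and the theory.

All public quantities are in micrometres, seconds and piconewtons:
lengths in um, rates in 1/s, diffusivities in um^2/s, forces in pN,
energies in pN*um and friction coefficients in pN*s/um.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

__all__ = ["ModelParams", "RDParams", "KBT_298K"]

#: Thermal energy at 298 K in pN*um.
KBT_298K = 4.1e-3


@dataclass(frozen=True)
class ModelParams:
    """Physical rates, geometry and constants of the positioning model.

    The defaults are the packaged baseline describing a wild-type-like
    *M. xanthus* cell: a 5 um nucleoid carrying a 0.7 um PomXY cluster and
    about 100 PomZ dimers.  See ``docs/methods.md`` for the provenance of
    each value.

    Attributes
    ----------
    L:
        Nucleoid length (um).
    L_c:
        PomXY cluster length (um).
    a:
        Lattice spacing of both the nucleoid and cluster lattices (um).
    k:
        Spring stiffness of a PomZ dimer tether (pN/um).  The spring models
        the combined elasticity of the chromosome and the dimer.
    kBT:
        Thermal energy (pN*um).
    k_on:
        Attachment rate scale of a cytosolic PomZ dimer to the nucleoid
        (1/s); includes the nucleotide-exchange delay, so the per-dimer
        propensity is ``k_on * (L - L_c) / L``.
    ka0:
        Per-cluster-site binding rate scale of a nucleoid-bound dimer (1/s).
    k_h:
        Hydrolysis/detachment rate of cluster-bound dimers (1/s).
    k_off:
        Optional detachment rate of nucleoid-only dimers (1/s); 0 in the
        baseline model.
    D_nuc, D_clu:
        Diffusion coefficient of a PomZ binding site on the nucleoid and on
        the cluster (um^2/s).
    gamma_c:
        Cytosolic friction coefficient of the cluster (pN*s/um);
        equivalently the bare cluster diffusivity is ``kBT / gamma_c``.
    N_total:
        Total number of PomZ dimers (conserved).
    t_min:
        Equilibration time with a frozen cluster before the coupled
        dynamics start (s).
    infinite_lattice:
        If true, both lattices are unbounded (friction-assay geometry).
    F_ext:
        Constant external force on the cluster (pN).
    lambda_null:
        Optional null-event rate added to the propensity sum; shortens
        Gillespie steps without any physical effect (bounds the error made
        by freezing time-dependent rates between events).
    """

    L: float = 5.0
    L_c: float = 0.7
    a: float = 0.01
    k: float = 100.0
    kBT: float = KBT_298K
    k_on: float = 0.1
    ka0: float = 50.0
    k_h: float = 1.0
    k_off: float = 0.0
    D_nuc: float = 0.1
    D_clu: float = 0.1
    gamma_c: float = 20.0
    N_total: int = 100
    t_min: float = 600.0
    infinite_lattice: bool = False
    F_ext: float = 0.0
    lambda_null: float = 0.0

    def __post_init__(self) -> None:
        errors = self.validation_errors()
        if errors:
            raise ValueError("invalid ModelParams:\n- " + "\n- ".join(errors))

    # -- validation ------------------------------------------------------

    def validation_errors(self) -> list[str]:
        """Return all invariant violations (empty list if valid)."""
        err: list[str] = []
        for name in ("L", "L_c", "a", "k", "kBT", "k_on", "ka0", "k_h",
                     "k_off", "D_nuc", "D_clu", "gamma_c", "t_min",
                     "lambda_null"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                err.append(f"{name} must be finite and >= 0, got {v!r}")
        if self.a <= 0:
            err.append(f"a must be > 0, got {self.a!r}")
        if self.gamma_c <= 0:
            err.append(f"gamma_c must be > 0, got {self.gamma_c!r}")
        if self.kBT <= 0:
            err.append(f"kBT must be > 0, got {self.kBT!r}")
        if self.N_total < 0:
            err.append(f"N_total must be >= 0, got {self.N_total!r}")
        if not self.infinite_lattice:
            if self.L_c > self.L:
                err.append(f"L_c={self.L_c!r} exceeds L={self.L!r}")
            for name in ("L", "L_c"):
                v = getattr(self, name)
                if self.a > 0 and v > 0:
                    n = v / self.a
                    if abs(n - round(n)) > 1e-6 * max(n, 1.0):
                        err.append(
                            f"a={self.a!r} does not divide {name}={v!r} "
                            "to within one part in 1e6")
        if not math.isfinite(self.F_ext):
            err.append(f"F_ext must be finite, got {self.F_ext!r}")
        return err

    # -- derived quantities ----------------------------------------------

    @property
    def n_sites(self) -> int:
        """Number of nucleoid lattice sites."""
        return round(self.L / self.a)

    @property
    def n_cluster_sites(self) -> int:
        """Number of cluster lattice sites."""
        return round(self.L_c / self.a)

    @property
    def eps_nuc(self) -> float:
        """Bare nucleoid hop rate D_nuc / a^2 (1/s)."""
        return self.D_nuc / self.a**2

    @property
    def eps_clu(self) -> float:
        """Bare cluster hop rate D_clu / a^2 (1/s)."""
        return self.D_clu / self.a**2

    @property
    def sigma(self) -> float:
        """Thermal stretch scale sqrt(kBT / k) of the tether spring (um)."""
        return math.sqrt(self.kBT / self.k)

    @property
    def D_cluster(self) -> float:
        """Bare cytosolic diffusivity of the cluster kBT / gamma_c (um^2/s)."""
        return self.kBT / self.gamma_c

    def nucleoid_sites(self):
        """Cell-centred nucleoid site positions a*(i + 1/2) (um)."""
        import numpy as np

        return (np.arange(self.n_sites) + 0.5) * self.a

    def cluster_sites(self, x_c: float):
        """Cluster site positions for a cluster centred at ``x_c`` (um)."""
        import numpy as np

        return x_c - self.L_c / 2 + (np.arange(self.n_cluster_sites) + 0.5) * self.a

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown ModelParams keys: {', '.join(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class RDParams:
    """Parameters of the stationary reaction-diffusion model.

    Mirrors :class:`ModelParams` plus the two coarse-grained couplings:
    ``D_b``, the diffusivity of doubly-bound dimers, and ``k_a_total``, the
    aggregate cluster-binding rate inside the cluster footprint.  The
    latter is the lattice sum of the per-site Boltzmann-weighted binding
    rates, ``ka0 * sqrt(2*pi*kBT/k) / a`` in the continuum limit, so that
    the RD model and the lattice model describe the same attachment flux.
    """

    L: float
    L_c: float
    k_on: float
    k_h: float
    k_off: float
    D_nuc: float
    kBT: float
    k: float
    ka0: float
    N_total: int
    a: float
    D_b: float = field(default=0.0)
    k_a_total: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.D_b == 0.0:
            object.__setattr__(self, "D_b", 0.5 * self.D_nuc)
        if self.k_a_total == 0.0 and self.ka0 > 0:
            object.__setattr__(
                self, "k_a_total",
                self.ka0 * math.sqrt(2 * math.pi * self.kBT / self.k) / self.a)
        if self.k_a_total < 0:
            raise ValueError("k_a_total must be >= 0")

    @classmethod
    def from_model_params(cls, p: ModelParams) -> "RDParams":
        return cls(L=p.L, L_c=p.L_c, k_on=p.k_on, k_h=p.k_h, k_off=p.k_off,
                   D_nuc=p.D_nuc, kBT=p.kBT, k=p.k, ka0=p.ka0,
                   N_total=p.N_total, a=p.a)
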