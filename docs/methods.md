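# Methods

## The model

`pomsim` simulates midnucleoid positioning of the PomXY cluster in
*Myxococcus xanthus* by the ParA/MinD-family ATPase PomZ. Nucleoid and
cluster are one-dimensional lattices of lengths `L` and `L_c` with common
spacing `a`; positions are continuous multiples of `a` (nucleoid sites at
`a(i + 1/2)`, cluster sites at `x_c - L_c/2 + a(j + 1/2)`). A PomZ dimer
is an elastic tether (spring stiffness `k`) with one nucleoid and one
cluster binding site.

The stochastic dynamics comprise five processes:

1. **Nucleoid attachment.** A cytosolic dimer attaches to a uniformly
   chosen nucleoid site outside the cluster footprint with aggregate
   propensity `k_on * N_cyto * (L - L_c)/L`. The rate `k_on` folds in the
   nucleotide-exchange delay of the ADP-bound monomers, so no explicit
   exchange kinetics appear.
2. **Diffusion.** Binding sites hop to nearest-neighbour sites with bare
   rates `D_nuc/a^2` (nucleoid) and `D_clu/a^2` (cluster), weighted by
   `exp(-k (s_to^2 - s_from^2) / (4 kBT))` where `s = x_clu - x_nuc` is
   the tether stretch. The half-weight in the exponent makes forward and
   backward rates multiply to the squared bare rate, so detailed balance
   holds and the equilibrium stretch distribution is the lattice
   Boltzmann distribution. Lattice ends and cluster edges reflect.
3. **Cluster binding.** A nucleoid-bound dimer binds cluster site `j`
   with rate `ka0 * exp(-k (x_clu_j - x_nuc)^2 / (2 kBT))`; binding in a
   stretched configuration from outside the footprint is possible. Sites
   whose Boltzmann factor is below 1e-12 are pruned (Gaussian-tail error
   bound). The per-dimer total over candidate sites is tabulated once per
   run on a grid of `a/64` and linearly interpolated (relative error
   about 1e-5); the bound site itself is drawn with exact weights.
4. **Hydrolysis.** A doubly-bound dimer is released into the cytosol with
   rate `k_h` (hydrolysis and detachment folded into one step). In the
   baseline model nucleoid-only dimers never detach; the optional
   extension rate `k_off` releases them too.
5. **Cluster motion.** The cluster is overdamped with no thermal noise:
   `gamma_c dx_c/dt = -k sum_i s_i + F_ext`. Because bound cluster sites
   ride rigidly with the cluster, the total stretch `S` relaxes
   exponentially between events, and the update
   `x_c += x* (1 - exp(-k N dt / gamma_c))`, `x* = (F_ext - kS)/(kN)`, is
   exact — there is no integration error. The cluster is not clamped to
   the nucleoid; excursions are logged (the restoring fluxes pull it
   back).

Events are generated with a Gillespie algorithm. Propensities are frozen
between events; the error of ignoring the cluster-position dependence of
the rates within one step is bounded by an optional null-event rate
`lambda_null` that shortens steps without physical effect (default 0; the
test suite verifies that observables are insensitive to it). Waiting
times use `dt = -ln(xi)/alpha` with `xi` uniform on (0, 1].

No excluded volume anywhere: dimers interact only through the cluster.

## Parameters

All lengths in um, times in s, forces in pN, energies in pN um.

| name | default | meaning / provenance |
|------|---------|----------------------|
| `L` | 5.0 | nucleoid length of a wild-type cell |
| `L_c` | 0.7 | PomXY cluster length (imaging estimate) |
| `a` | 0.01 | lattice spacing |
| `k` | 100 | tether stiffness; gives a thermal stretch `sqrt(kBT/k)` = 6.4 nm, below one lattice spacing, and reproduces the ~1 nm mean attachment stretch of the stiff-spring regime |
| `kBT` | 4.1e-3 | thermal energy at 298 K |
| `k_on` | 0.1 | cytosolic re-attachment rate; ~10 s nucleotide-exchange delay |
| `ka0` | 50 | per-cluster-site binding rate scale; deep in the regime where positioning speed has saturated in `ka0` |
| `k_h` | 1.0 | hydrolysis rate; fixed by the ratio of the measured one-particle force to the force constant (`k_h = f/C`) |
| `k_off` | 0 | optional nucleoid detachment (extension) |
| `D_nuc`, `D_clu` | 0.1 | PomZ diffusivity on nucleoid/cluster; fast-diffusion (adiabatic) regime |
| `gamma_c` | 20 | cytosolic cluster friction; bare cluster diffusivity `kBT/gamma_c` ~ 2e-4 um^2/s, far below PomZ mobility |
| `N_total` | 100 | wild-type PomZ dimer count |
| `t_min` | 600 | equilibration with frozen cluster before coupling |

The packaged `desk` configuration scales the geometry down for fast
validation: `L` = 2, `L_c` = 0.28 (same ratio), `N_total` = 30,
`k_on` = 0.2, `gamma_c` = 5, `t_min` = 200. It preserves the physics —
adiabatic positioning, the same binding/hopping microdynamics, a
stability margin `t_PomZ/t_cluster` ~ 0.03 — at roughly two orders of
magnitude less event throughput. All stochastic-vs-theory validation in
the test suite runs on this geometry; the one-particle force assay also
runs at the full baseline (it involves a single dimer and is cheap).

## Stationary reaction–diffusion model

For a fixed cluster the PomZ density obeys linear RD equations: outside
the footprint `D_nuc c'' + k_on N_cyto / L = 0`; inside,
`D_nuc c'' = k_a_total c` and `D_b c_b'' + k_a_total c - k_h c_b = 0`
with `D_b = D_nuc/2`; no-flux at the nucleoid ends and (for `c_b`) the
cluster edges; the cytosolic pool closes the system through particle
conservation. The aggregate binding rate is the lattice sum of the
per-site rates, `k_a_total = ka0 sqrt(2 pi kBT / k) / a` in the
continuum limit, so the RD and lattice models describe the same
attachment flux; this package uses the lattice-sum (per-time) convention
throughout.

The solution is closed-form piecewise (quadratic/cosh outside, mixed
exponentials inside) with coefficients from a 7x7 linear matching
system, assembled in an edge-anchored exponential basis for numerical
robustness at steep boundary layers. Degeneracies are handled
explicitly: `ka0 = 0` yields the flat profile; `k_h = 0` with binding
has no stationary state and raises a diagnostic; the measure-zero
resonance `k_h = D_b (k_a_total + k_off)/D_nuc` is lifted by an 1e-7
relative nudge of the decay constant. Conservation residuals are
reported on every solve and are at machine precision. A
finite-difference implicit-Euler relaxation oracle in the test suite
confirms the closed form to better than 1e-4.

One-sided inflows are evaluated exactly at the cluster edges:
`j_R = D_nuc c'(x_r)`, `j_L = -D_nuc c'(x_l)`,
`j_diff = j_R - j_L` (positive = net inflow from the right, pushing the
cluster rightward). The stochastic flux-profile estimator instead takes
the two extreme values of the nucleoid-only flux profile, which sit a
short distance outside the edges because of stretched-configuration
binding; both conventions are exposed and agree to a few percent.

## Semi-analytic theory

In the adiabatic regime the mean velocity factorizes as
`v(x_c) = C j_diff(x_c) / gamma(x_c)`:

* `C = f/k_h` is estimated from one-particle simulations as the
  duration-weighted mean force `f = sum f_int_i / sum t_i` divided by
  `k_h`, or equivalently as the plain mean of the time-integrated force
  (the mean interaction time converges to `1/k_h`). Bootstrap standard
  errors (1000 resamples) accompany both estimators; they agree within
  error, and `C` is position-independent (verified by the constancy of
  `F/j_diff` across cluster positions).
* `gamma(N) = gamma_c + kBT N / (D_clu + D_nuc)`: each tether adds drag
  inversely proportional to the combined mobility of its binding sites.
  Verified against force-velocity simulations on unbounded lattices.
  This continuum formula assumes the thermal stretch `sqrt(kBT/k)`
  exceeds the lattice spacing. At the packaged stiffness
  (`k a^2 / kBT` ~ 2.4) the exact lattice linear-response value — from
  the Poisson equation of the stretch birth-death chain, reproduced by
  the simulations — exceeds it by ~35% per tether (0.028 vs
  0.021 pN s/um at the packaged diffusivities). The package keeps the
  continuum expression as the public `effective_friction` because the
  tether term is a small correction to `gamma_c` everywhere the velocity
  decomposition is used; the discrepancy only becomes visible in assays
  engineered to amplify it.
* `N(x_c)` and `j_diff(x_c)` come from the stationary RD model.

The trajectory follows from integrating `dx_c/dt = v(x_c)` (adaptive
Runge-Kutta, rtol 1e-8, over a 41-point interpolated velocity field).
Stability of midnucleoid positioning is operationalized by the
dimensionless margin `t_PomZ / t_cluster` with `t_PomZ = L^2/D_nuc` and
`t_cluster = L gamma(L/2) / (C j_R(L/2))`; the packaged verdict uses the
configurable threshold `rho = 0.1`, and the margin itself is always
reported because "much less than" has no canonical cutoff.

In the one-particle protocol the dimer starts on the right of the
cluster just outside the binding range (`max(2 s_max, 0.05)` um beyond
the edge, `s_max` the binding-prune distance), so every encounter begins
unbiased. The recorded attachment stretch is `x_nuc - x_clu`, positive
when the tether points back toward the arrival side; with this sign the
mean attachment stretch is positive and the mean force on the cluster
points toward the dimer's origin side.

## Analysis conventions

* Trajectory ensembles are summarized per 3.33-min time bin (pooled
  positions; mean and SD).
* Position-conditioned profiles: recording starts when the cluster is
  within ±0.2% of `L` of the target and stops beyond ±1%; every profile
  is weighted by dwell time. Zero dwell yields a flagged empty result.
* Histogram bimodality: 100 bins over `[0, L]`, Gaussian smoothing with
  sigma = 2 bins; bimodal iff a local minimum exists, the max-peak minus
  min-peak difference strictly exceeds 2% of the maximum count, and the
  maximum lies farther from midnucleoid than the minimum. Plateaus in
  the smoothed profile count as single extrema, and plateaus touching
  the array ends are not extrema (this keeps empty histogram tails from
  producing spurious minima). The verdict is stable under ±50% bin-count
  changes on the calibration mixtures.
* FFT oscillation detection: each run is resampled by previous-value
  interpolation onto a uniform 0.2-min grid, mean-subtracted and
  transformed; moduli are summed across runs, smoothed (sigma = 2
  frequency bins), and the ensemble is oscillatory iff an interior local
  maximum exceeds 1.2x the smoothed value at `f_min = 1/T_max`. The
  zero-frequency bin (identically ~0 after mean subtraction) is excluded
  before smoothing. Calibration: a noisy sinusoid is recovered to one
  frequency bin; with the 100-runs-per-ensemble protocol the
  false-positive rate on white noise is below 5%; mean-reverting
  (OU-like) noise is not flagged. The smoothing widths are package
  choices, recorded in every report.

## What the validation does and does not show

The generator *is* the model; there is no external data. Green tests
show internal consistency of four independent routes (event-driven
stochastic dynamics, closed-form RD steady states, the semi-analytic
velocity decomposition, and brute-force/numerical oracles) plus the
qualitative phase structure: positioning from a pole start, an interior
velocity maximum in `k_h`, slower positioning as `D_clu` drops,
oscillations when PomZ diffusion is slow relative to cluster motion,
with monomodal or bimodal position histograms. They do not show that the
reconstructed baseline rate values equal those of any particular cell:
the published parameter table behind the baseline is not reproduced in
the available text, so `k_on`, `ka0` and `gamma_c` are physically
motivated choices (see the table above) rather than transcriptions, and
quantities that depend on them (e.g. the one-particle force constant,
computed here as ~0.008 pN s at the baseline) carry that uncertainty.

## Known limitations

* Strictly 1D; no cluster assembly/splitting, no FtsZ biology, no
  excluded volume, no thermal noise on the cluster, no explicit
  nucleotide exchange.
* The adiabatic theory deliberately excludes the oscillatory regime; the
  package documents its failure there (overshoot) rather than extending
  it.
* Event rates are frozen between events. The error is negligible for
  the packaged parameters (validated via the null-event rate), but for
  extremely fast clusters a nonzero `lambda_null` should be set.
* The binding-rate table introduces a ~1e-5 relative propensity error;
  site selection within a binding event is exact.
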