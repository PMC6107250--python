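# pomsim

Stochastic and semi-analytic models of **flux-based midnucleoid
positioning** of the PomXY cluster by the ParA-family ATPase PomZ in
*Myxococcus xanthus*.

In these cells the PomX/PomY proteins form a single cluster on the
nucleoid that must find midcell, where it licenses division-ring
assembly. PomZ dimers tether the cluster to the chromosome: they attach
to the nucleoid, diffuse, bind the cluster through an elastic tether,
and are released into the cytosol after ATP hydrolysis. When the cluster
sits off-center, more PomZ arrives per unit time from the far side than
from the near side; because each dimer, on average, pushes the cluster
toward the side it came from, the flux imbalance biases the cluster
toward the point where the fluxes balance — midnucleoid.

`pomsim` provides four coupled components:

* **`pomsim.engine`** — an event-driven (Gillespie) lattice-gas
  simulation of PomZ dimers as springs with nucleoid and cluster binding
  sites, coupled to overdamped, noise-free cluster motion
  `γ_c dx_c/dt = −k Σ_i (x_i^clu − x_i^nuc) + F_ext`, with closed-form
  (error-free) cluster updates between events. Four protocols:
  coupled dynamics, frozen-cluster profiling, one-particle force assays
  and force–velocity (friction) assays on unbounded lattices.
* **`pomsim.rd`** — the exact stationary solution of the
  reaction–diffusion description of PomZ density `c(x)`, bound density
  `c_b(x)`, flux `j(x) = −D_nuc ∂x c` and the flux difference
  `j_diff(x_c) = j_R − j_L` at the cluster edges.
* **`pomsim.theory`** — the adiabatic velocity decomposition
  `v(x_c) = C · j_diff(x_c) / γ(x_c)` with the one-particle force
  constant `C = f/k_h`, the effective friction
  `γ = γ_c + k_B T · N/(D_clu + D_nuc)`, predicted mean trajectories,
  and the timescale criterion `t_PomZ ≪ t_cluster` for stable
  positioning versus oscillations.
* **`pomsim.analysis`** — trajectory binning, position-conditioned
  profiles, flux-difference and friction estimators, and the two
  oscillation classifiers (FFT peak rule, histogram bimodality rule).

See `docs/methods.md` for the model, parameter provenance and numerical
choices.

## Worked example

```python
import numpy as np
import pomsim
from pomsim import theory, analysis

params = pomsim.load_packaged_config("desk")   # reduced 2-um geometry

# one-particle force constant
rec = pomsim.run_one_particle(params, 6000, seed=11)
est = theory.estimate_C(rec, params.k_h, seed=11)
print(f"C = {est.C:.5f} +- {est.C_se:.5f} pN s")

# stability of midnucleoid positioning
ts = theory.timescale_criterion(params, est.C)
print(f"t_PomZ = {ts.t_PomZ:.0f} s, t_cluster = {ts.t_cluster:.0f} s, "
      f"margin = {ts.margin:.3f}, stable = {ts.stable}")

# stochastic ensemble vs. semi-analytic prediction
vf = theory.VelocityField(params, est.C)
pred = theory.integrate_trajectory(params.L_c / 2, 1400, vf)
trajs = [pomsim.run_dynamic(params, (21, i), t_end=1600)[0]
         for i in range(10)]
stats = analysis.binned_trajectory_stats(trajs, bin_s=100.0)
row = stats.iloc[8]
x_pred = np.interp(row.t_mid_s - params.t_min, pred.t_s, pred.x_c_um)
print(f"t = {row.t_mid_s:.0f} s: ensemble mean = {row.mean_um:.3f} um "
      f"(sd {row.sd_um:.3f}), predicted = {x_pred:.3f} um")
```

prints

```
C = 0.00411 +- 0.00026 pN s
t_PomZ = 40 s, t_cluster = 1576 s, margin = 0.025, stable = True
t = 850 s: ensemble mean = 0.854 um (sd 0.076), predicted = 0.816 um
```

The force constant says a single PomZ encounter transfers about
4 mpN·s of directed impulse to the cluster; the timescale margin of
0.03 puts the system deep in the adiabatic (stable-positioning) regime;
and the integrated velocity field tracks the stochastic ensemble mean to
well within one ensemble standard deviation as the cluster moves from
the pole (0.14 μm) to midnucleoid (1.0 μm).

From the shell, the same machinery is available as a CLI:

```sh
pomsim rd-scan --xc-grid 0.1:0.9:17 --out jdiff.tsv
pomsim run-dynamic --seed 7 --t-end 1600 --out traj.tsv
pomsim preset run kh-sweep --seed 1 --scale 0.1 --out out/
```

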