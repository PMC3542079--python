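# lifediff

**Lifetime-diffusion analysis of single-molecule membrane-binding
trajectories.**

Peripheral signaling proteins such as the phosphatase PTEN work by
shuttling between the cytosol and the plasma membrane.  Single-molecule
imaging (TIRFM) yields trajectories of individual membrane-binding
events: a sequence of positions at a fixed frame interval from the onset
of binding until the molecule dissociates (or its fluorophore bleaches).
Classical analyses treat either the *temporal* side (binding-lifetime
distributions) or the *spatial* side (displacement distributions) in
isolation and disagree about the underlying states.  Lifetime-diffusion
analysis couples the two: each membrane-binding state *j* is
characterized jointly by a diffusion coefficient `D_j` and an apparent
dissociation rate `λ'_j = λ_j + λ_b` (with `λ_b` the photobleaching
rate), and states interconvert with first-order rates `k_ij`.

`lifediff` provides, for an arbitrary number of states:

* **Exact kinetics** (`lifediff.models`) — the rate matrix `K` with
  `dQ/dt = K Q`, membrane residence probability
  `R(t) = Σ_j [e^{Kt} q]_j`, subpopulation probabilities `Q_j(t)`, the
  position density `P_j(x, y, t)` obtained by numerical inversion of the
  transform-space solution, the one-lag displacement density (a mixture
  of Rayleigh-form components with scales `σ_j² = D_j Δt + ε²`, where
  `ε` is the localization error), and mean binding lifetimes.
* **A trajectory simulator** (`lifediff.simulate`) — exact
  continuous-time Markov state switching plus Brownian steps on a 1/300 s
  fine grid, recorded at 1/30 s frames with Gaussian localization noise
  (`ε = 0.04 µm`) over a 60 s horizon, the standard protocol.
* **The four-step inference pipeline** (`lifediff.analysis`) —
  (1) dissociation test against `λ_b`; (2) state counting by AIC over
  maximum-likelihood Rayleigh-mixture fits of the displacements;
  (3) transition detection from time-resolved decay profiles
  `Q_obs,j(t) = R_obs(t) p_j(t)`; (4) weighted least-squares estimation
  of `λ'_j`, `k_ij` and initial probabilities `q_j` from the profiles,
  with a position-density consistency check.
* **A membrane-density compartment model** (`lifediff.distribution`) —
  per-state association frequencies `μ_j = q_j · ratio / τ` from a bulk
  membrane/cytosol ratio, steady states of the bound occupancy
  (`K n = −μ c`), and mass-conserving ODE (or exact stochastic) time
  courses for uniform and polarized (anterior/posterior) cells.

## Worked example

Simulate 1000 binding events of a two-state switching model
(`D = 0.01/0.10 µm²/s`, `λ = 0.10/1.00 1/s`, `k12 = 0.10`,
`k21 = 0.50 1/s`, `q1 = 0.20`, `ε = 0.04 µm`) and run the full pipeline:

```python
import lifediff as ld

model = ld.make_fixture("demo_2state_switching")
ens = ld.simulate_ensemble(model, 1000, seed=1)
report = ld.run_full_analysis(ens, lam_b=0.0, eps=0.04,
                              force_topology="chain")

best = next(f for f in report.mixture_fits
            if f.n_states == report.chosen_n)
print(report.chosen_n, best.D)
print(report.kinetic_fit.lam_apparent,
      report.kinetic_fit.k[0, 1], report.kinetic_fit.k[1, 0],
      report.kinetic_fit.q[0])
```

Output (seed 1):

```
2 [0.0109 0.1075]
[0.116 1.094] 0.058 0.403 0.257
```

The AIC scan (`-348666.9, -351911.6, -351909.2, -351905.3` for 1 to 4
states) picks two states; the fitted diffusion coefficients land within
a few percent of the truth, and the kinetic parameters are recovered
with the ±20–25% single-run scatter that is characteristic of this
protocol (the overall dissociation rate, 0.159 1/s, sits well above a
typical photobleaching rate of 0.1 1/s, so membrane dissociation is
flagged).  Run-to-run seeds change the third digit of `D` and the second
digit of the rates.

The same tools drive the PTEN application: the bundled
`pten3_nonpolar` three-state parameter set plus the measured
membrane/cytosol ratio 0.76 give association frequencies
`μ = (0.541, 1.377, 0.357) 1/s`; in a spherical cell of radius 5 µm with
20000 cytosolic molecules the steady state holds 15200 bound molecules
(48.4 molecules/µm²), and the polarized tail/pseudopod parameter sets
yield a posterior-to-anterior density ratio of 2.47 — the quantitative
account of PTEN depletion from the pseudopod.

A CLI mirrors the library: `lifediff simulate`, `lifediff analyze`,
`lifediff theory`, `lifediff density` (see `--help`).

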