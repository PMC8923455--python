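# autocrine-allee

Modeling toolkit for Allee effects that emerge in cell populations when
division is up-regulated by a self-secreted (autocrine) growth factor.

The package provides, end to end:

- **`gf_field`** — explicit finite-difference solver for the growth-factor
  reaction–diffusion equation `dg/dt = D lap(g) + rho*c - delta*g` on a
  square lattice with no-flux boundaries, plus a direct sparse steady-state
  solver used as a cross-check.
- **`ib_sim`** — stochastic individual-based lattice model: cells divide at
  rate `alpha*(1 + g)` at their own site, die at rate `mu`, migrate at rate
  `nu` to von Neumann neighbors, with long-range (uniform over the lattice)
  or short-range (von Neumann) daughter dispersal and site exclusion.
  Inner loops are numba-compiled; runs are reproducible from a seed.
- **`meanfield`** — the mean-field ODE `dn/dt = (A + B*n)*n*(1-n) - mu*n`
  with the mechanistic reduction `A = alpha + alpha*rho*K/N`,
  `B = alpha*rho/delta - alpha*rho*K/N`, `K = 1/(2*delta) + L/(4*sqrt(delta*D))`;
  weak/strong Allee classification, critical death rate `mu_c = A`,
  extinction threshold `n_c`, fixed-point/stability analysis, and a
  forward-Euler solver (0.25 h default step).
- **`fitting`** — multistart Nelder–Mead least squares of the Allee model
  and its nested logistic special case (`B = 0`) against multi-density
  growth curves, with AIC model selection.
- **`trackstats`** — mean-squared-displacement analysis of cell tracks and
  diffusion-coefficient estimation via `MSD(t) = 4*D*t` (zero-intercept
  regression, 10 h cutoff).
- **`synthdata`** — synthetic growth curves (noisy Euler trajectories at
  six seeding densities, eight replicates, 120 h, first 3.5 h discarded),
  Brownian track sets, and occupancy-grid fixtures, all with ground truth.
- **`workflows` / CLI** — death-rate sweeps comparing lattice ensembles to
  the ODE, and growth-curve fit reports.

## Command line

Everything is exposed under a single entry point:

```bash
autocrine-allee simulate --dispersal long --mu 3.75e-5 --n0 0.01 \
    --t-days 11 --replicates 10 --out trajectories.csv
autocrine-allee ode --A 1.787 --B 2.202 --mu 1.792 --n0 0.05 --report ode.json
autocrine-allee sweep --mu-min 2e-5 --mu-max 4e-5 --n-mu 9 --fast --out sweep.csv
autocrine-allee synth curves --A 0.08 --B 0.25 --mu 0.07 --out curves.csv
autocrine-allee fit curves.csv --out report.json
autocrine-allee synth tracks --cell-diffusion 1.6e-10 --out tracks.csv
autocrine-allee msd tracks.csv --out msd.csv --report msd.json
```

`simulate` and `sweep` also accept a YAML `--config`; explicit flags win
over config values. All workflow outputs carry a provenance block
(package version, seed, config) sufficient to re-run them.

### File formats

- growth curves: CSV with `curve_id,time_h,density` (optional `replicate`
  column is averaged on load); densities are normalized confluency in [0,1]
- tracks: CSV with `track_id,t_s,x_cm,y_cm` (optional `label`)
- trajectories/sweeps: CSV; analysis reports: JSON

## Notes and conventions

- **AIC convention:** `AIC = 2k + n*ln(E)` where `E` is the summed
  per-curve mean squared error exactly as minimized — *no square root is
  taken*. `n` counts all retained data points across curves.
- **Initial conditions in fits:** each curve's trajectory starts from its
  *observed* density at the first retained time point. With very low
  seeding densities, measurement noise on that single value propagates
  through the whole model trajectory and dominates the parameter
  uncertainty — fits of low-density data should be read with that in mind.
- **Time units:** mechanistic rates are per second; fitted growth-law
  parameters are per hour. `PhenomParams.to_unit` converts explicitly.
- **Scaled-down lattices:** shrink the domain, not the cells — use
  `L = N * 20e-4` cm so the site (cell) diameter stays 20 µm.
- The scheduler advances cells with a capped per-step event probability
  (`IBParams.prob_cap`, default 0.02); tighten it when comparing against
  exact stochastic limits.
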