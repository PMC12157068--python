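# lemnopt

Canopy growth modelling and harvest-process optimization for free-floating
macrophyte (duckweed) cultures grown under artificial light.

The core model treats the areal dry-biomass density `D` (gDW·m⁻²) of a
floating plant mat as a one-dimensional ODE: photoperiod-scaled
photosynthesis minus constant respiration, where mutual shading inside the
mat follows Beer–Lambert attenuation of the surface light intensity `I_S`
and the local light response is of Monod type. Averaging over the layer
yields a closed-form mean limitation factor, giving

```
dD/dt = D · ( E · r_phot_i · [ln(k + I_S) − ln(k + I_S·e^(−ε̂·D))]/(ε̂·D) − r_resp )
```

On top of this the package provides:

- **model_core** — limitation factors, growth rates (including a published
  logistic-capacity comparator model), Dormand–Prince trajectory
  simulation, limit (carrying-capacity) density, dry-weight/LAI helpers.
- **fitting** — least-squares estimation of the four kinetic parameters
  from end-of-trial densities, Gauss–Newton standard errors and p-values,
  R², and fixed-parameter validation against long-term series.
- **harvest** — semi-continuous harvest optimization: optimal residual
  density `D_opt`, maximum average daily yield `ṁ_max`, light-use
  efficiency (LUE) and the LUE-optimal intensity, plus grid sweeps.
- **light_field** — empirical (directional) variograms, anisotropic
  spherical variogram fitting, ordinary kriging on a 100×100 grid, and
  averaging over circular ring subareas.
- **synthetic** — deterministic, seeded generators for growth-trial,
  long-term and light-survey datasets with known ground truth.
- **cli** — a `lemnopt` command-line tool tying the stages together.

## CLI

```bash
lemnopt synth --kind all --seed 0 --out data/          # synthetic datasets
lemnopt fit --trials data/trials.csv --out fit.json    # parameter estimation
lemnopt simulate --d0 10 --i-s 123.9 --t-end 7 --out traj.csv
lemnopt optimize --i-grid 10:500:50 --intervals 0,5,10,20 --out sweep.csv
lemnopt lue --intervals 0,5,10,20 --out lue.csv        # I_LUEmax per interval
lemnopt lightfield --survey data/survey.csv --rings rings.csv --out rings_out.csv
lemnopt validate --longterm data/longterm.csv --out scores.json
```

Model parameters travel as flat YAML key-value files
(`r_phot_i, r_resp, eps_hat, k, E`; comparator: `r_phot_i, r_resp, h_D,
K_I, E`). Built-in reference values fitted for *Lemna minor* in a
recirculating indoor vertical farm are used when no file is given.

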