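# rangedyn

Dynamic-occupancy range-change modelling for sika deer (*Cervus nippon*) on
gridded presence–absence surveys, with habitat-suitability surfaces,
WAIC-based model selection, climate-vs-land-use change decomposition, and
stochastic projection of future range under environmental scenarios.

## The problem

Sika deer expanded their range across Japan dramatically between the 1978
and 2003 national 5-km-mesh surveys, with serious consequences for forestry
and native vegetation. Two drivers compete as explanations: shorter snow
cover (climate change, which opens winter forage) and rural land
abandonment (land-use change, which creates wasteland habitat). Managing
the expansion requires a model that separates these drivers and projects
the range decades ahead. `rangedyn` implements that analysis as a reusable
pipeline for anyone working with two-survey occupancy grids and per-epoch
environmental tables — and, because the national survey data are not
publicly distributable, it ships a synthetic-landscape generator that
reproduces the statistical structure of the real data so every stage is
testable end-to-end.

## The model

Occupancy `X_{i,t2} ~ Bernoulli(q_i)` is conditional on the first-survey
state: a persistence–colonization (dynamic occupancy) model

```
q_i = φ_i X_{i,t1} + γ_i (1 − X_{i,t1})
logit(φ_i) = φ0 + φd·D_i + φh·H_i        (persistence)
logit(γ_i) = γ0 + γd·D_i + γh·H_i        (colonization)
```

where `D_i ∈ [0,1]` is the **neighborhood occupancy** — the
distance-weighted proportion of occupied cells within a radius (10–100 km,
equal / inverse / inverse-squared weights), a proxy for immigration
pressure — and `H_i` is the **habitat suitability**, the log-odds linear
predictor of a logistic regression of first-survey presence on snow cover
period (with a Hokkaido-vs-other-islands interaction), land-use proportions
(forest, wasteland, agriculture + its square, built-up), and slope.
Candidate habitat formulas (12; 84 with autologistic covariates), two
surface epochs, and 15 dispersal neighborhoods give 2,520 candidates,
fitted by MCMC under flat priors and ranked by per-observation WAIC.
Suitability change between epochs decomposes exactly into climate and
land-use blocks (`ΔH = ΔH_CL + ΔH_LU`); future range is projected by
simulating the transition model forward in 25-year steps under scenario
bundles (baseline / land-use only / climate only / combined), with the
potential distribution defined by a 95%-sensitivity threshold on the
per-cell occupancy frequency.

## Worked example

Generate a ~2,000-cell synthetic landscape from the published coefficient
values, fit the transition model, and decompose the suitability change:

```python
import rangedyn as rd

model = rd.load_reference_habitat_model()          # published habitat coefficients
params = rd.reference_dynamics_params()            # published posterior medians
spec = rd.NeighborhoodSpec(radius_km=25, weight_exponent=2)

bundle = rd.generate_bundle(
    rd.LandscapeConfig(n_rows=45, n_cols=45, seed=0), model, params, spec, seed=0
)
d = rd.neighborhood_occupancy(bundle.occ1978, bundle.grid, spec)
h = rd.suitability(model, bundle.env2003, bundle.grid).h
data = rd.TransitionData(bundle.occ1978.x, bundle.occ2003.x, d, h)

fit = rd.fit_dynamics_mcmc(data, seed=1)
print(fit.summary.round(2))
q = rd.transition_probability(fit.medians, data.x1978, data.d, data.h)
print(f"WAIC/n = {fit.waic_per_obs:.4f}   AUC = {rd.auc(q, data.x2003):.3f}")

dec = rd.decompose_change(model, bundle.env1978, bundle.env2003, bundle.grid)
print(f"suitability increased in {dec.pct_increased:.1f}% of cells, chi2 = {dec.chi2:.0f}")
```

This prints:

```
       mean    sd  q2.5   q25   q50   q75  q97.5  rhat
phi0  -0.29  0.63 -1.56 -0.70 -0.29  0.13   0.99  1.00
phi_d  7.68  1.50  4.62  6.69  7.61  8.61  10.76  1.00
phi_h  0.52  0.23  0.05  0.36  0.51  0.68   0.97  1.00
gam0  -1.40  0.33 -2.08 -1.62 -1.40 -1.18  -0.74  1.01
gam_d  7.60  0.84  5.91  7.05  7.57  8.18   9.21  1.01
gam_h  0.50  0.12  0.26  0.43  0.51  0.59   0.74  1.00
WAIC/n = 0.2126   AUC = 0.949
suitability increased in 66.7% of cells, chi2 = 1534
```

The posterior table mirrors the structure of a published fit: all Rhat
round to 1.00–1.01 (converged chains), the dispersal slopes are large and
positive (colonization especially depends on occupied neighbors), the
habitat slopes are moderate and positive, and the 95% intervals cover the
generating values (φd = 5.94, γd = 8.28, ...). The decomposition line says
that on this synthetic landscape suitability rose in two-thirds of cells
between the epochs, and the contingency test confirms the association
between the direction of change and its dominant driver.

The same analysis is available from a shell:

```sh
rangedyn simulate-data --outdir data --rows 30 --cols 30 --seed 1
rangedyn validate --cells data/cells.csv --env data/env.csv --occupancy data/occupancy.csv
rangedyn fit-habitat --cells data/cells.csv --env data/env.csv \
    --occupancy data/occupancy.csv --epoch 1978 --out model.json
rangedyn fit-dynamics --cells data/cells.csv --env data/env.csv \
    --occupancy data/occupancy.csv --model model.json --radius 25 --out-prefix dyn
rangedyn project --cells data/cells.csv --env data/env.csv \
    --occupancy data/occupancy.csv --model model.json --params dyn_summary.json \
    --radius 25 --outdir proj
```

or as one orchestrated run with a manifest: `rangedyn run --config cfg.yaml`.

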