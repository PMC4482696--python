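# vegmosaic

Probabilistic vegetation modelling and climate-impact decomposition on
raster landscapes.

## The problem

Land managers and conservation planners need to know not just *whether*
vegetation will change under 21st-century climate change, but *where* the
landscape is most at risk. `vegmosaic` addresses this with a probabilistic
vegetation model (PVM): a multinomial logistic regression that maps
environmental predictor rasters to a **vector of relative probabilities
over K vegetation types at every pixel**, rather than a single hard class.
Projecting that surface over a large ensemble of future climate scenarios
and measuring community turnover per pixel decomposes projected change into

- **exposure** — how much the local climate changes relative to the region,
- **sensitivity** — how much the vegetation probability vector changes per
  degree of local warming, and
- **vulnerability** — their product.

The package is aimed at landscape ecologists and SDM practitioners who want
this pipeline as a library (with a thin CLI for end-to-end runs), and ships
a synthetic-landscape generator so every stage is testable without
proprietary raster data.

## The model

For pixel *i* with expanded feature vector **x**ᵢ (intercept, linear,
quadratic, and pairwise-interaction terms of z-scored predictors; 36
columns for seven predictors), the probability of vegetation type *j* is
the softmax

&nbsp;&nbsp;&nbsp;&nbsp;p
<sub>ij</sub> = exp(**x**ᵢᵀ **β**ⱼ) / Σₖ exp(**x**ᵢᵀ **β**ₖ),&nbsp;&nbsp;
**β**₁ ≡ **0** (reference type),

fitted by maximum conditional likelihood (optionally ridge-penalized).
With no penalty, the score equations force Σᵢ p<sub>ij</sub> = n<sub>j</sub>:
modelled regional frequencies reproduce observed frequencies exactly — the
projection is *zero-sum*, so gains in some types are exactly offset by
losses in others. Predictors are ranked by the BIC cost of refitting
without each one.

Across a scenario ensemble *s* = 1..S, per-pixel change is the Bray-Curtis
dissimilarity D<sub>is</sub> = ½·Σⱼ|p<sub>ij</sub><sup>(s)</sup> −
p<sub>ij</sub><sup>(0)</sup>|, and

&nbsp;&nbsp;&nbsp;&nbsp;sensitivityᵢ = Σₛ D<sub>is</sub>·ΔTᵢₛ / Σₛ ΔTᵢₛ²
(through-origin slope on local warming),<br>
&nbsp;&nbsp;&nbsp;&nbsp;exposureᵢ = through-origin slope of local on
regional warming,<br>
&nbsp;&nbsp;&nbsp;&nbsp;vulnerabilityᵢ = sensitivityᵢ × exposureᵢ.

Per-type regional frequency trajectories are fitted with linear, quadratic,
or exponential responses to warming (plus an additive precipitation term),
selected by BIC; distribution shifts are tracked as probability-weighted
mean positions along elevation and coast-distance axes.

## Worked example

```python
import vegmosaic as vm
from vegmosaic.landscape import PREDICTOR_NAMES

cfg = vm.LandscapeConfig(grid_rows=80, grid_cols=80, n_types=6, seed=7)
env = vm.generate_environment(cfg)
spec = vm.build_spec(PREDICTOR_NAMES, env.samples())
truth = vm.generate_true_model(6, spec, seed=7)
vegmap = vm.sample_vegetation(env, truth, seed=7)
model = vm.fit(vm.expand(spec, env.samples()), vegmap.labels.ravel())

suite = vm.generate_scenarios(env, n_scenarios=54, seed=7)
baseline = vm.project(model, env)
futures = [vm.project(model, s) for s in suite.scenarios]
summary = vm.decompose_impacts(baseline, futures, suite)
```

Running `python examples/04_impact_decomposition.py` (exactly this
pipeline) prints:

```
sensitivity:   0.0016 .. 0.2544 per degC (163-fold range)
exposure:      0.819 .. 1.200 (mean 1.000)
vulnerability: 0.0015 .. 0.2190

sensitivity ~ baseline predictors: R^2 = 0.196
after dropping ['soil_depth', 'cwd', 'jja']: R^2 = 0.158
```

Sensitivity spans two orders of magnitude while exposure varies only a few
tens of percent: vulnerability is driven by where vegetation sits in
climate space (pixels near steep class boundaries), not by how much the
local climate changes. The regression lines show how much of that spatial
pattern the baseline predictors explain.

The other scripts in `examples/` cover landscape simulation, model fitting
and drop-one predictor ranking, and scenario projection; the whole pipeline
also runs from a shell:

```bash
vegmosaic run -c config.yaml -o runs/demo -v
```

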