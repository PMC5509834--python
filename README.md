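# cardiomap

Active-learning planning of cardiac voltage-mapping sequences.

During radiofrequency catheter ablation, an operator samples position and
electrogram amplitude at points on the endocardium to build a voltage map;
low-voltage regions indicate scar tissue. Mapping time is scarce, so the
order in which points are taken matters. `cardiomap` plans that order: a
Gaussian-process (GP) surrogate of the voltage field proposes, after every
observation, the next point that maximizes the posterior differential
entropy

    H[f′ | x′, A] = ½ log σ²(x′ | A) + ½ log 2πe ,

optionally divided by the catheter travel distance s (with an exclusion
radius s_min so consecutive points do not collapse). Two strategies are
provided:

- **PE (pure exploitation)** — entropy under a fixed prior kernel
  hyperparameter θ₀ learned from expert demonstration sequences;
- **IE (implicit exploration)** — expected entropy under a posterior
  p(θ_A) over the Matérn kernel hyperparameters (length scale, signal
  variance), tracked online by a regularized particle filter
  (systematic resampling + Epanechnikov kernel move), so the model adapts
  to the individual heart as points accumulate.

The package also contains the kernel-prior learning step (four candidate
kernel families fitted by marginal likelihood, ranked by cross-validated
RMSE), a geometry-coverage baseline planner (farthest-point /
distance-plus-curvature, labelled `baseline-approx`), grid and
triangulated-mesh sampling domains with the standard preprocessing
(duplicate removal, nearest-vertex projection), and a synthetic 2D
Gaussian-mixture benchmark scored by SSIM. Audience: researchers in
computational cardiology / interventional planning who want a reproducible
reference implementation to experiment against — not a clinical device.

## Worked example

Plan a 30-point IE mapping run on the 60×60 benchmark grid against a
20-component Gaussian-mixture field, then compare with the geometry
baseline:

```python
import numpy as np
from cardiomap import (make_grid_domain, sample_mixtures, mixture_field,
                       run_mapping, plan_geometry, PlanConfig,
                       ObservationSet, ssim_index)
from cardiomap.sim_eval import BENCHMARK_THETA0, centre_index
from cardiomap.planner import _mean_and_var

dom = make_grid_domain(10.0, 60)                      # 3600 candidates
truth = mixture_field(sample_mixtures(20, 10.0, seed=7), dom)
dom = dom.with_values(truth)
start = centre_index(dom)                             # index 1830

run = run_mapping(dom, truth, BENCHMARK_THETA0,
                  PlanConfig(strategy="IE", n_points=30,
                             start_index=start, seed=7))
est, _ = _mean_and_var(run.final_spec,
                       ObservationSet(run.positions, run.values), dom.points)
print(run.indices[:6])          # [1830, 0, 59, 3540, 3599, 29]
print(run.final_spec.length_scale)   # 2.696  (adapted from the prior l=1)
print(run.mean_l1[-1])               # 0.2196
print(run.median_sd[0], run.median_sd[-1])   # 1.007 -> 0.217
print(ssim_index(est.reshape(60, 60), truth.reshape(60, 60)))   # 0.750

geo = plan_geometry(dom, 30, ratio=1.0, start_index=start)
est_g, _ = _mean_and_var(BENCHMARK_THETA0,
                         ObservationSet(geo.positions, truth[geo.indices]),
                         dom.points)
print(ssim_index(est_g.reshape(60, 60), truth.reshape(60, 60)))  # 0.741
```

The entropy criterion first spreads points to the corners (maximum prior
uncertainty), the particle filter stretches the length scale towards the
field's true smoothness, the median posterior SD over unmapped points — the
live "mapping sufficiency" indicator — falls from 1.007 to 0.217, and the
adaptive IE estimate edges out the coverage baseline on SSIM.

The same runs are available from the shell:

```bash
cardiomap fit-prior demos.csv prior.json            # theta_0 from expert data
cardiomap plan --strategy ie --mixture-k 20 --points 30 --seed 7 --out run/
cardiomap benchmark --groups 5,20,40,60 --trials 20 --points 30 --seed 1
cardiomap evaluate est.csv truth.csv --grid-n 60
```

Every command writes a manifest (config, master seed, version, input
digests) and is byte-for-byte reproducible from its seed.

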