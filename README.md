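# cjsdisp

Spatial Cormack–Jolly–Seber (CJS) models for estimating **climate-directed
natal and adult dispersal** from multi-year banding/recapture data on a grid.

Long-term mark–recapture studies of territorial birds — the motivating system
is a trailing-edge population of black-throated blue warblers monitored over
two decades along a steep Appalachian climate gradient — record where
individuals were banded and where (if ever) they were seen again. Whether
young birds disperse *toward* cooler, wetter sites is a key question for
populations at the warm edge of a shifting range, but it cannot be answered
by tabulating observed movements: birds can only be re-found where someone
looked, so raw dispersal records are biased toward the surveyed plots.
`cjsdisp` is built for ecologists and biometricians who want to fit the full
hidden-state model that corrects for this.

## The model

The study area is discretized into `N` square grid cells (800 m in the
motivating design). Conditional on first capture, each individual each year

* survives and stays in the study area with age-specific *apparent survival*
  `phi_a` (death and permanent emigration are confounded, absorbing),
* if alive, selects a destination cell by the anisotropic kernel

  `h[j,k] = exp(-beta1_a * X[j,k] + beta2_a * c[k])`,
  `theta[j,k] = h[j,k] / sum_k' h[j,k']`

  with `X` the inter-cell distance (km) and `c` the standardized climate
  score (PC1 of May temperature/precipitation normals; higher = hotter and
  drier). `beta1_a > 0` is distance decay; `beta2_a < 0` means dispersal is
  skewed away from hot, dry cells,
* is detected with probability `p1` (intensive plots) or `p2` (auxiliary
  plots) where and when survey effort `s[k,t] = 1`, and never elsewhere.

The likelihood marginalizes the latent alive/location process exactly
(forward algorithm over `N+1` states, verified against brute-force path
enumeration), and the posterior over
`(beta1_a, beta2_a, phi_a, p1, p2)` is sampled by ensemble MCMC with the
field-standard priors, including `beta1_a ~ Exponential(0.1)` — which keeps
the prior probability of mean dispersal distances beyond 30 km under 0.05.
See `docs/methods.md` for the full specification, priors, and numerical
choices.

## Worked example

Everything is testable without field data: the built-in generator simulates
the full study design (320 cells, 21 years, 2 intensive + 17 staggered
auxiliary plots, ~2,000 nestlings and ~1,000 adults).

```python
import numpy as np
import cjsdisp as cd
from cjsdisp import AgeClass

scenario = cd.scenario_paper_like(seed=1)
truth = cd.simulate_histories(scenario)

rates = cd.return_rates(truth.histories)
for age, r in rates.items():
    print(f"{age.value:9s} banded={r.n_banded:5d} returned={r.n_returned:4d} rate={100*r.rate:.1f}%")

origin = int(np.argmax(truth.climate.score))
theta = cd.transition_probs(origin, AgeClass.NESTLING, scenario.true_params,
                            truth.grid, truth.climate)
print(f"natal kernel from hottest cell {origin}: stay-put prob {theta[origin]:.3f}, "
      f"mass on cooler cells {theta[truth.climate.score < truth.climate.score[origin]].sum():.3f}")

ll = cd.marginal_loglik(truth.histories, scenario.true_params, truth.grid, truth.climate)
print(f"marginal log-likelihood at the generating parameters: {ll:.1f}")
```

prints

```
nestling  banded= 1993 returned=  52 rate=2.6%
adult     banded=  978 returned= 234 rate=23.9%
natal kernel from hottest cell 40: stay-put prob 0.135, mass on cooler cells 0.865
marginal log-likelihood at the generating parameters: -1203.6
```

The nestling return rate (2.6%) is the raw fraction of banded nestlings ever
seen again under sparse, staggered survey effort — an order of magnitude
below adult returns, and far below the true 10% first-year apparent survival,
which is exactly why the hidden-state model rather than the raw rates must
carry the inference. The kernel line shows anisotropy: a nestling hatched in
the hottest cell is predicted to leave it with probability 0.865 toward
cooler cells, because its generating climate effect is negative
(`beta2_natal = -0.41`).

Fitting and summarizing (short chains for illustration):

```python
config = cd.FitConfig(n_chains=3, n_iterations=4800, warmup=0.5, n_walkers=16, seed=42)
post = cd.fit(truth.histories, truth.grid, truth.climate, config)
cd.summarize(post)["beta2_nestling"]  # {'median': ..., 'q2.5': ..., 'q97.5': ..., 'rhat': ...}
```

The same pipeline is scriptable from a shell:

```bash
cjsdisp simulate --out-dir data --seed 1
cjsdisp summarize --data-dir data --out-dir results
cjsdisp fit --data-dir data --out-dir results --iterations 4800 --warmup 0.5 --seed 42
cjsdisp predict-kernel --data-dir data --out-dir results --origin 40 \
    --age nestling --params data/true_params.yaml
cjsdisp loglik --data-dir data --params data/true_params.yaml
```

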