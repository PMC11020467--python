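# Methods

## Model

`cjsdisp` implements a discrete-time, discrete-space extension of the
Cormack–Jolly–Seber (CJS) open-population model for estimating
climate-directed dispersal from multi-year banding/recapture data. The
landscape is a rectangular grid of `N` square cells (the motivating system
uses 320 cells of 800 × 800 m); all capture locations are snapped to cell
centers. Conditional on first capture, each individual each year:

1. **survives and remains in the study area** with age-specific apparent
   survival `phi_a` (nestling in the hatch year, adult thereafter). Death
   and permanent emigration are confounded and absorbing — "dead" means
   *dead or permanently gone*, and there is no temporary-emigration state;
2. **selects a destination cell** from the multinomial probabilities
   `theta[j, ·]` obtained by normalizing the anisotropic kernel

   `h[j, k] = exp(-beta1_a * X[j, k] + beta2_a * c[k])`

   over all grid cells, where `X` is the center-to-center distance in km and
   `c[k]` the standardized climate score of the destination. `beta1 > 0`
   sets the distance-decay scale (mean dispersal distance `1/beta1` km);
   `beta2 < 0` skews dispersal away from hot/dry cells. With `beta2 = 0`
   the kernel is isotropic. Staying put (`X = 0`) enters like any other
   destination, and the choice set is exactly the study-area grid — longer
   moves are absorbed by apparent survival, so inference concerns
   within-study-area dispersal only;
3. **is detected** at its cell with probability `p1` (intensive plots) or
   `p2` (auxiliary plots) when the cell was surveyed that year
   (`s[k, t] = 1`), and never otherwise.

Modelling *all* banded individuals — not just the redetected ones — is what
prevents selection bias: conditioning on redetection would make dispersal
appear directed toward the surveyed plots.

The climate score is PC1 of the per-cell (standardized) mean May temperature
and precipitation normals, sign-fixed so that the temperature loading is
positive: larger score = hotter and drier. Scores keep the raw PC1 scale of
standardized inputs (no re-standardization), so `beta2` is interpreted per
unit of that score. The PCA is invariant to affine rescaling of the raw
covariates.

## Likelihood: exact marginalization

Instead of sampling the latent alive/location states (the data-augmented
form the model family is usually fit in), the likelihood marginalizes them
exactly with the forward algorithm over the `(N+1)`-state chain (N cells
plus the absorbing dead state). Three structural facts make this fast:

* a detection collapses the forward distribution to a point mass, so each
  consecutive-year redetection contributes the closed-form factor
  `phi * theta[j, k] * p_k(t)`;
* redetections separated by gap years (a bird alive but missed) need only a
  short chain of `N × N` matrix products, batched across individuals that
  share the same gap;
* the trailing "never seen after year t" factor is shared by every
  individual last seen in the same cell/year/age and comes from one backward
  recursion `B[t, j] = (1 - phi) + phi * sum_k theta[j,k] (1 - p_k(t+1)) B[t+1, k]`.

The result is algebraically identical to brute-force enumeration over all
latent paths; the test suite and acceptance checks verify agreement to
1e-10 on small problems (≤ 5 cells, ≤ 4 years, 100 random parameter draws).
One full-study evaluation (320 cells, 21 years, ~3,000 individuals) costs a
few N × N matrix products, about 10 ms.

## Priors

| parameter | prior | rationale |
|---|---|---|
| `p1` | Uniform(0.8, 1.0) | detection near 1 on intensive plots |
| `p2` | LogitNormal(0, sd 1.78) | ≈ uniform on the probability scale |
| `beta1_a` | Exponential(rate 0.1) | < 0.05 prior mass on mean dispersal > 30 km |
| `beta2_a` | Normal(0, 1) | weakly informative, sign-free |
| `phi_nestling` | Uniform(0, 0.3) | literature range for first-year apparent survival |
| `phi_adult` | Beta(5, 2) | literature range for adult apparent survival |

Users should note one deliberate choice: the source model description
states both a Normal(0, 1) prior on `beta1` and an Exponential(0.1) prior
on `beta1_a` alongside the requirement that `beta1` be strictly positive.
This package uses Exponential(0.1) for `beta1_a` (consistent with
positivity and the quoted 30-km tail statement) and Normal(0, 1) for
`beta2_a` only. The LogitNormal scale 1.78 is interpreted as the *standard
deviation* on the logit scale — close to the logistic sd of 1.81 whose
push-forward is exactly uniform. Both conventions are configurable at the
code level (`cjsdisp.statespace.PRIOR_LOGIT_SD_P2`).

## Inference

The posterior `exp(loglik + logprior)` is sampled with affine-invariant
ensemble MCMC (emcee) on an unconstrained reparameterization — log for
`beta1`, scaled logit for the probabilities — with the log-Jacobian included
so the mapped-back draws target the stated density exactly. Each "chain" is
an independent ensemble (≥ 16 walkers; at least twice the parameter count)
seeded separately, with initial walkers drawn from the prior (re-drawn a
bounded number of times if the density is non-finite). The default
configuration retains 15,000 draws per chain across 3 chains (45,000 total)
after discarding a 25% warm-up fraction; `warmup=0` reproduces a
retain-everything run. Identical seeds give bit-identical posteriors.

Convergence is monitored with a between/within-chain variance-ratio
(Gelman–Rubin) statistic, `R = sqrt((W + B_n) / W)` with `W` the mean
within-chain variance and `B_n` the variance of chain means. This variant is
exactly 1 for identical chains and never below 1; the conventional
`(n-1)/n`-weighted estimator differs by O(1/n) and can dip below 1.
Parameters at or above 1.1 are flagged. Posterior summaries are medians and
central 95% intervals via pooled empirical quantiles with numpy's linear
interpolation rule (fixed so interval endpoints are reproducible
bit-for-bit).

## Synthetic data

The generator draws an elevation surface (smooth ridge-to-valley gradient
spanning 600–1500 m plus Gaussian cell noise, sd 30 m), maps it to May
temperature and precipitation through the linear anchors 17.5 °C / 1868 mm
at 600 m and 13.9 °C / 2514 mm at 1400 m, adds independent Gaussian noise
(sd 0.25 °C and 40 mm — small relative to the elevation-driven range, so
climate stays "highly correlated with elevation"), and standardizes through
the same PCA as real data. Capture histories are then simulated forward
from banding through the state/detection equations above.

`scenario_paper_like(seed)` bundles the study-design facts: 320 cells,
years 2002–2022, one low- and one high-elevation two-cell intensive plot
active from 2002/2003, 17 single-cell auxiliary plots activated 2014–2018,
~2,000 nestlings banded on the intensive plots (about two-thirds at the
high-elevation plot, mirroring the reported banding imbalance) and ~1,000
adults across active plots. Default generating parameters:
`beta1 = 1.0 (natal) / 4.0 (adult) per km`, `beta2 = -0.41 / 0.18`,
`phi = 0.10 / 0.55`, `p1 = 0.9`, `p2 = 0.3`. The nestling return rate this
produces is of order 1–3%, bracketing the observed 1.2%.

`scenario_dense(seed)` is the estimator-validation benchmark: the same
landscape but every cell in an always-active plot (alternating intensive /
auxiliary columns), 2,000 nestlings + 1,000 adults banded at uniform random
cells over 20 years, and generating values
`beta2_natal = -0.4, beta2_adult = 0, phi = 0.10 / 0.55, p2 = 0.5`. The
short-chain configuration used in validation (3 chains × 16 walkers × 600
steps, half discarded, 4,800 retained draws per chain) keeps a full
recovery run under ten minutes on one CPU while leaving credible intervals
accurate enough for coverage checks.

What the generator does *not* emulate: within-season movement and nest
fate, territory geometry inside cells, sex differences, density dependence,
and raw (sub-cell) capture coordinates. Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the model's own
assumptions, not robustness to the ways real field data violate them.

## Descriptive summaries

Natal dispersal records pair the banding cell with the first redetection
(optionally restricted to next-year returns); adult records pair successive
observed years, including the post-return moves of nestling-banded birds.
Distances are between snapped cell centers, so observed moves within a cell
are 0 m and the grid cannot resolve the tens-of-meters site fidelity that
raw territory coordinates would show; `DispersalRecord.distance` is an
explicit field so raw-coordinate distances can be substituted when
available. Return rate is the raw fraction of banded individuals ever
redetected — a datum, not apparent survival. Climate-use summaries compare
destination-cell scores against all-cell ("available") and banding-cell
scores; nestlings first redetected more than one year after hatching are
excluded from the natal destination distribution by default because their
intermediate moves are unobserved.

## Numerical and design notes

* Kernel rows are computed as log-weights and normalized by row-max shift
  (log-sum-exp), so steep kernels (`beta1 * X` in the hundreds) never
  underflow to all-zero rows.
* Cell indexing is row-major from the lower-left corner; snapping uses
  half-open cell squares, ties going to the increasing-coordinate side —
  deterministic and partition-complete.
* Distances are Euclidean between cell centers in *projected planar*
  coordinates (km); the package requires pre-projected input and does not
  compute geodesics.
* Per-individual likelihood terms are products of probabilities bounded
  well away from the float64 underflow threshold for realistic study spans
  (tens of years); logs are taken per factor group, and any exactly-zero
  factor yields -inf (rejected during MCMC) rather than an exception.
* An observation at a cell-year with no effort contradicts the data model
  and is rejected at likelihood construction with the individual's id.
* Elevation noise is clipped to the [elev_min, elev_max] band; climate
  noise is unclipped Gaussian.
* Individuals banded in the final study year contribute no transitions but
  are retained (they enter return-rate denominators).

## Known limitations

* Detection and survival are constant over calendar time (only the effort
  indicator varies); no transience or trap-dependence terms.
* A nestling first redetected years later contributes one nestling-kernel
  transition followed by adult transitions — the hatch-year move is the
  only natal move the model recognizes.
* The ensemble sampler mixes slowly for weakly identified detection
  parameters (notably `p1` against `phi`) at short run lengths; the
  Gelman–Rubin flag should be consulted before interpreting intervals.
* No model comparison (WAIC/LOO) and no sex-specific or continuous-space
  extensions.
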