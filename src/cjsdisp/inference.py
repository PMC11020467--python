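"""Bayesian inference for the dispersal model.

The posterior targets ``exp(marginal_loglik + log_prior)``. Sampling uses
affine-invariant ensemble MCMC (emcee) on an unconstrained reparameterization
(log for the positive distance-decay parameters, scaled logit for the
probabilities), with the log-Jacobian folded into the density so the draws,
mapped back, follow the stated priors and likelihood exactly. Each "chain" is
an independent ensemble with its own seed and prior-drawn initial walkers;
convergence is assessed with a between/within-chain variance-ratio
(Gelman-Rubin) statistic, flagging parameters at or above 1.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .kernel import ModelParams
from .statespace import PRIOR_LOGIT_SD_P2, MarginalLikelihood, log_prior

__all__ = [
    "PARAM_NAMES",
    "FitConfig",
    "Posterior",
    "fit",
    "gelman_rubin",
    "summarize",
    "sample_prior",
]

PARAM_NAMES = (
    "beta1_nestling",
    "beta1_adult",
    "beta2_nestling",
    "beta2_adult",
    "phi_nestling",
    "phi_adult",
    "p1",
    "p2",
)

# (lower, upper) bounds for logit-transformed parameters; None = untransformed
# or log-transformed (see _to_unconstrained).
_BOUNDS = {
    "phi_nestling": (0.0, 0.3),
    "phi_adult": (0.0, 1.0),
    "p1": (0.8, 1.0),
    "p2": (0.0, 1.0),
}
_LOG_PARAMS = ("beta1_nestling", "beta1_adult")


def _to_unconstrained(params: ModelParams) -> np.ndarray:
    u = []
    for name in PARAM_NAMES:
        v = getattr(params, name)
        if name in _LOG_PARAMS:
            u.append(math.log(v))
        elif name in _BOUNDS:
            lo, hi = _BOUNDS[name]
            u.append(float(logit((v - lo) / (hi - lo))))
        else:
            u.append(v)
    return np.asarray(u)


def _from_unconstrained(u: np.ndarray) -> tuple[ModelParams, float]:
    """Map an unconstrained vector to parameters, returning log |dx/du|."""
    vals, log_jac = {}, 0.0
    for name, ui in zip(PARAM_NAMES, u):
        if name in _LOG_PARAMS:
            vals[name] = math.exp(ui)
            log_jac += ui
        elif name in _BOUNDS:
            lo, hi = _BOUNDS[name]
            s = expit(ui)
            vals[name] = lo + (hi - lo) * s
            # guard the open-interval ends against floating-point saturation
            if not (lo < vals[name] < hi):
                vals[name] = min(max(vals[name], np.nextafter(lo, hi)), np.nextafter(hi, lo))
            log_jac += math.log(hi - lo) + math.log(s) + math.log1p(-s)
        else:
            vals[name] = ui
    return ModelParams(**vals), log_jac


def sample_prior(rng: np.random.Generator) -> ModelParams:
    """One draw from the joint prior."""
    return ModelParams(
        beta1_nestling=rng.exponential(10.0),
        beta1_adult=rng.exponential(10.0),
        beta2_nestling=rng.normal(),
        beta2_adult=rng.normal(),
        phi_nestling=rng.uniform(0.0, 0.3),
        phi_adult=rng.beta(5.0, 2.0),
        p1=rng.uniform(0.8, 1.0),
        p2=float(expit(rng.normal(scale=PRIOR_LOGIT_SD_P2))),
    )


@dataclass(frozen=True)
class FitConfig:
    """MCMC run configuration.

    ``n_iterations`` is the number of retained posterior draws per chain
    (the run default, 3 chains of 15,000, retains 45,000 draws in total);
    ``warmup`` is the fraction of additional ensemble steps discarded before
    retention (0 reproduces a retain-everything run). Each chain is an
    ensemble of ``n_walkers`` walkers.
    """

    n_chains: int = 3
    n_iterations: int = 15_000
    warmup: float = 0.25
    n_walkers: int = 16
    seed: int = 0
    max_init_attempts: int = 200

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iterations < 1:
            raise ValueError("n_chains and n_iterations must be >= 1")
        if self.n_walkers < 2 * len(PARAM_NAMES):
            raise ValueError(
                f"ensemble sampling needs at least {2 * len(PARAM_NAMES)} walkers"
            )
        if not (0.0 <= self.warmup < 1.0):
            raise ValueError("warmup must be a fraction in [0, 1)")


@dataclass
class Posterior:
    """Posterior draws across chains with convergence diagnostics.

    ``draws`` has shape (n_chains, n_iterations, n_params) on the natural
    parameter scale, ordered as :data:`PARAM_NAMES`.
    """

    draws: np.ndarray
    param_names: tuple[str, ...] = PARAM_NAMES
    rhat: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[1]

    def param_draws(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_iterations)."""
        return self.draws[:, :, self.param_names.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.param_draws(name).ravel()

    def iter_params(self, max_draws: int | None = None):
        """Yield draws as :class:`ModelParams` (evenly strided subsample)."""
        flat = self.draws.reshape(-1, len(self.param_names))
        if max_draws is not None and len(flat) > max_draws:
            idx = np.linspace(0, len(flat) - 1, max_draws).astype(int)
            flat = flat[idx]
        for row in flat:
            yield ModelParams(**dict(zip(self.param_names, row)))

    def summary(self) -> dict[str, dict[str, float]]:
        return summarize(self)

    def to_dataframe(self) -> pd.DataFrame:
        n_chains, n_iter, _ = self.draws.shape
        df = pd.DataFrame(
            self.draws.reshape(-1, len(self.param_names)), columns=list(self.param_names)
        )
        df.insert(0, "iteration", np.tile(np.arange(n_iter), n_chains))
        df.insert(0, "chain", np.repeat(np.arange(n_chains), n_iter))
        return df


def gelman_rubin(chains: np.ndarray) -> float:
    """Between/within variance-ratio convergence statistic for one parameter.

    ``chains`` has shape (n_chains, n_draws). The statistic is
    ``sqrt((W + B_n) / W)`` where ``W`` is the mean within-chain variance and
    ``B_n`` the variance of the chain means: exactly 1 for identical chains,
    always >= 1, and approaching 1 as stationary chains grow. Values at or
    above 1.1 indicate non-convergence.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    if n < 10:
        raise ValueError("Gelman-Rubin requires at least 10 draws per chain")
    w = chains.var(axis=1, ddof=1).mean()
    b_n = chains.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b_n == 0.0 else np.inf
    return float(np.sqrt((w + b_n) / w))


def summarize(posterior: Posterior) -> dict[str, dict[str, float]]:
    """Per-parameter median and central 95% credible interval.

    Empirical quantiles are computed over all retained draws pooled across
    chains, with numpy's linear interpolation rule (so the endpoints are
    reproducible bit-for-bit given the same draws).
    """
    if posterior.draws.size == 0:
        raise ValueError("empty posterior")
    out = {}
    for name in posterior.param_names:
        x = posterior.pooled(name)
        q = np.quantile(x, [0.025, 0.5, 0.975])
        out[name] = {
            "median": float(q[1]),
            "q2.5": float(q[0]),
            "q97.5": float(q[2]),
            "rhat": float(posterior.rhat.get(name, np.nan)),
        }
    return out


def _log_posterior_factory(engine: MarginalLikelihood):
    def log_post(u: np.ndarray) -> float:
        try:
            params, log_jac = _from_unconstrained(u)
        except (ValueError, OverflowError):
            return -np.inf
        lp = log_prior(params)
        if not np.isfinite(lp):
            return -np.inf
        ll = engine(params)
        if not np.isfinite(ll):
            return -np.inf
        return lp + ll + log_jac

    return log_post


def fit(histories, grid, climate, config: FitConfig | None = None) -> Posterior:
    """Sample the posterior of :class:`ModelParams` given capture histories.

    Runs ``config.n_chains`` independent ensembles; initial walkers are drawn
    from the prior (re-drawn, up to ``max_init_attempts``, if the posterior
    density is non-finite at an initial point). Draws are returned on the
    natural parameter scale; identical seeds and configs give identical
    posteriors.
    """
    config = config or FitConfig()
    engine = MarginalLikelihood(histories, grid, climate)
    log_post = _log_posterior_factory(engine)
    ndim = len(PARAM_NAMES)

    retain_steps = math.ceil(config.n_iterations / config.n_walkers)
    warm_steps = (
        math.ceil(retain_steps * config.warmup / (1.0 - config.warmup))
        if config.warmup > 0
        else 0
    )

    seed_seq = np.random.SeedSequence(config.seed)
    chain_seeds = seed_seq.generate_state(2 * config.n_chains, dtype=np.uint32)
    all_draws = np.empty((config.n_chains, config.n_iterations, ndim))
    for c in range(config.n_chains):
        rng = np.random.Generator(np.random.PCG64(chain_seeds[2 * c]))
        p0 = np.empty((config.n_walkers, ndim))
        for w in range(config.n_walkers):
            for attempt in range(config.max_init_attempts + 1):
                u = _to_unconstrained(sample_prior(rng))
                if np.isfinite(log_post(u)):
                    p0[w] = u
                    break
            else:
                raise RuntimeError(
                    "could not find initial values with finite posterior density "
                    f"after {config.max_init_attempts} prior draws (chain {c}, walker {w})"
                )
        sampler = emcee.EnsembleSampler(config.n_walkers, ndim, log_post)
        sampler.random_state = np.random.RandomState(int(chain_seeds[2 * c + 1])).get_state()
        sampler.run_mcmc(p0, warm_steps + retain_steps, progress=False)
        chain_u = sampler.get_chain(discard=warm_steps)  # (steps, walkers, dim)
        flat_u = chain_u.reshape(-1, ndim)[-config.n_iterations :]
        for i, u in enumerate(flat_u):
            params, _ = _from_unconstrained(u)
            all_draws[c, i] = [getattr(params, n) for n in PARAM_NAMES]

    rhat = (
        {
            name: gelman_rubin(all_draws[:, :, i])
            for i, name in enumerate(PARAM_NAMES)
        }
        if config.n_chains >= 2
        else {}
    )
    meta = {
        "n_chains": config.n_chains,
        "n_iterations": config.n_iterations,
        "warmup": config.warmup,
        "n_walkers": config.n_walkers,
        "seed": config.seed,
        "sampler": f"emcee {emcee.__version__} (affine-invariant ensemble)",
        "n_individuals": engine.n_individuals,
    }
    return Posterior(draws=all_draws, rhat=rhat, meta=meta)
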