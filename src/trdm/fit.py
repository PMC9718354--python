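"""Bayesian fitting of RDM/TRDM parameters by differential-evolution MCMC.

DE-MCMC runs a population of chains; each chain proposes a jump equal to a
scaled difference of two other randomly chosen chains' states plus a small
uniform jitter, and accepts by the Metropolis rule.  The population size
is 10 chains per free parameter.  Sampling happens on an unconstrained
scale: parameters with an inverse-logit (IL) prior are logit-transformed,
parameters with a log-normal (LN) prior are log-transformed, so every
coordinate carries a plain Normal(location, scale) prior and the additive
DE proposal respects all supports by construction.

Default priors (location, scale of the underlying normal):

====================  ======  ==================
parameter             family  prior
====================  ======  ==================
omega (bias)          IL      (0, 1.4)
t0 (nondecision, s)   IL      (0, 1.4)
v0, vd, vs (drifts)   LN      (1.56, 1.5)
eta_c, eta_t (noise)  LN      (1.56, 1.5)
rho_t (timer drift)   LN      (1.56, 1.5)
gamma (mixture)       IL      (-1, 1.0)
====================  ======  ==================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .likelihood import PARAM_NAMES, DENSITY_FLOOR, ModelParams, loglik_population

__all__ = ["PriorSpec", "Schedule", "PosteriorSamples", "default_priors",
           "prior_logpdf", "de_propose", "mh_accept", "run_demcmc",
           "demcmc_sample", "rhat"]


@dataclass(frozen=True)
class PriorSpec:
    """Prior of one free parameter.

    ``family`` is ``"IL"`` (parameter = logistic of a Normal(location,
    scale) variate, support (0, 1)) or ``"LN"`` (parameter = exp of the
    normal variate, support (0, inf)).
    """

    name: str
    family: str
    location: float
    scale: float

    def __post_init__(self) -> None:
        if self.family not in ("IL", "LN"):
            raise ValueError(f"family must be 'IL' or 'LN', got {self.family!r}")
        if not (self.scale > 0):
            raise ValueError("scale must be > 0")

    def to_natural(self, z):
        return expit(z) if self.family == "IL" else np.exp(z)

    def to_unconstrained(self, theta):
        return logit(theta) if self.family == "IL" else np.log(theta)


_PRIOR_TABLE = {
    "omega": ("IL", 0.0, 1.4),
    "t0": ("IL", 0.0, 1.4),
    "v0": ("LN", 1.56, 1.5),
    "vd": ("LN", 1.56, 1.5),
    "vs": ("LN", 1.56, 1.5),
    "eta_c": ("LN", 1.56, 1.5),
    "rho_t": ("LN", 1.56, 1.5),
    "eta_t": ("LN", 1.56, 1.5),
    "gamma": ("IL", -1.0, 1.0),
}


def default_priors(kind: str) -> list[PriorSpec]:
    """Default priors for the free parameters of an RDM or TRDM."""
    return [PriorSpec(name, *_PRIOR_TABLE[name]) for name in PARAM_NAMES[kind]]


def prior_logpdf(params: ModelParams, priors: list[PriorSpec] | None = None) -> float:
    """Log prior density of a parameter set on the natural scale.

    IL(m, s): density of theta = logistic(Z), Z ~ N(m, s); LN(m, s):
    log-normal density.  Returns -inf outside a parameter's support.
    """
    priors = priors if priors is not None else default_priors(params.kind)
    by_name = {p.name: p for p in priors}
    names = params.free_names
    missing = set(names) - set(by_name)
    if missing:
        raise ValueError(f"missing priors for {sorted(missing)}")
    vec = params.to_vector()
    total = 0.0
    for name, theta in zip(names, vec):
        p = by_name[name]
        if p.family == "IL":
            if not (0.0 < theta < 1.0):
                return -np.inf
            z = logit(theta)
            jac = -np.log(theta * (1.0 - theta))
        else:
            if not (theta > 0.0):
                return -np.inf
            z = np.log(theta)
            jac = -np.log(theta)
        total += (-0.5 * ((z - p.location) / p.scale) ** 2
                  - np.log(p.scale) - 0.5 * np.log(2.0 * np.pi) + jac)
    return float(total)


@dataclass(frozen=True)
class Schedule:
    """DE-MCMC iteration schedule: 200 burn-in + 500 sampling iterations
    with 10 chains per free parameter, unless overridden."""

    burn: int = 200
    samples: int = 500
    chains_per_param: int = 10

    def __post_init__(self) -> None:
        if self.burn < 0 or self.samples <= 0 or self.chains_per_param <= 0:
            raise ValueError("schedule entries must be positive")


@dataclass
class PosteriorSamples:
    """DE-MCMC output.

    ``samples`` holds natural-scale draws with shape (chains, iterations,
    parameters) where iterations include burn-in; ``loglik`` and
    ``logprior`` (on the sampling scale) are per draw.  ``n_burn`` marks
    where sampling starts.
    """

    samples: np.ndarray
    loglik: np.ndarray
    logprior: np.ndarray
    param_names: tuple
    n_burn: int
    meta: dict = field(default_factory=dict)

    @property
    def posterior(self) -> np.ndarray:
        """Post-burn-in draws, shape (chains, samples, parameters)."""
        return self.samples[:, self.n_burn:, :]

    def pooled(self) -> np.ndarray:
        """Post-burn-in draws pooled over chains, shape (n, parameters)."""
        return self.posterior.reshape(-1, self.samples.shape[-1])

    def median(self) -> dict:
        med = np.median(self.pooled(), axis=0)
        return dict(zip(self.param_names, med.tolist()))

    def credible_interval(self, level: float = 0.95) -> dict:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        q = np.quantile(self.pooled(), [lo, hi], axis=0)
        return {n: (float(q[0, i]), float(q[1, i]))
                for i, n in enumerate(self.param_names)}

    def max_loglik(self) -> float:
        """Highest log-likelihood over all draws, burn-in included (the
        maximum-likelihood surrogate used for BIC)."""
        return float(np.max(self.loglik))

    def best_vector(self) -> np.ndarray:
        """Natural-scale parameter vector of the best-likelihood draw."""
        idx = np.unravel_index(np.argmax(self.loglik), self.loglik.shape)
        return self.samples[idx[0], idx[1], :]


def de_propose(states: np.ndarray, i: int, rng: np.random.Generator,
               g: float | None = None, jitter: float = 1e-4) -> np.ndarray:
    """DE-1 proposal for chain i: theta_i + g*(theta_a - theta_b) + eps.

    a and b are distinct chains other than i; g defaults to 2.38/sqrt(2d)
    and eps is Uniform(-jitter, jitter) per coordinate.
    """
    states = np.asarray(states, dtype=float)
    n, d = states.shape
    if n < 3:
        raise ValueError("DE proposal needs at least 3 chains")
    if g is None:
        g = 2.38 / np.sqrt(2.0 * d)
    a = (i + 1 + rng.integers(n - 1)) % n
    b = a
    while b == a:
        b = (i + 1 + rng.integers(n - 1)) % n
    eps = rng.uniform(-jitter, jitter, size=d)
    return states[i] + g * (states[a] - states[b]) + eps


def mh_accept(current, proposal, logpost_current: float, logpost_proposal: float,
              rng: np.random.Generator):
    """Metropolis rule: accept the proposal with probability
    min(1, exp(logpost_proposal - logpost_current))."""
    if np.log(rng.random()) < logpost_proposal - logpost_current:
        return proposal, True
    return current, False


def _pick_pairs(n: int, rng: np.random.Generator):
    """Vectorised (a, b) indices, distinct from each other and from i."""
    idx = np.arange(n)
    a = (idx + 1 + rng.integers(n - 1, size=n)) % n
    b = (idx + 1 + rng.integers(n - 1, size=n)) % n
    bad = b == a
    while bad.any():
        b[bad] = (idx[bad] + 1 + rng.integers(n - 1, size=int(bad.sum()))) % n
        bad = b == a
    return a, b


def demcmc_sample(logpost, init: np.ndarray, schedule: Schedule,
                  rng: np.random.Generator, jitter: float = 1e-4):
    """Generic DE-MCMC on an unconstrained target.

    ``logpost`` maps an (n_chains, d) state matrix to an (n_chains,)
    vector of log posterior densities.  Returns (chain history with shape
    (n_chains, burn+samples, d), per-draw log posterior).
    """
    states = np.array(init, dtype=float)
    n, d = states.shape
    g = 2.38 / np.sqrt(2.0 * d)
    lp = np.asarray(logpost(states), dtype=float)
    n_iter = schedule.burn + schedule.samples
    hist = np.empty((n, n_iter, d))
    lp_hist = np.empty((n, n_iter))
    for it in range(n_iter):
        a, b = _pick_pairs(n, rng)
        eps = rng.uniform(-jitter, jitter, size=(n, d))
        prop = states + g * (states[a] - states[b]) + eps
        lp_prop = np.asarray(logpost(prop), dtype=float)
        accept = np.log(rng.random(n)) < (lp_prop - lp)
        states[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        hist[:, it, :] = states
        lp_hist[:, it] = lp
    return hist, lp_hist


def run_demcmc(trials, kind: str, priors: list[PriorSpec] | None = None,
               schedule: Schedule | None = None, seed: int = 0,
               gamma_variance_mode: str = "printed",
               timer_t0: str = "shared", init: str = "optimize",
               max_init_redraws: int = 100) -> PosteriorSamples:
    """Sample the RDM/TRDM posterior for one trial dataset.

    ``init="optimize"`` (default) first locates the posterior mode with a
    seeded global differential-evolution search on the unconstrained
    scale and starts the chains in a mildly overdispersed cloud around
    it; the burn-in then relaxes the population to the posterior.  This
    matters because the TRDM posterior has a degenerate pure-timer mode
    (all evidence drifts near zero) that can trap a population started
    from raw prior draws at short schedules.  ``init="prior"`` starts the
    chains at prior draws instead; chains whose initial log-likelihood is
    fully floored (every trial at the density floor) are re-drawn up to
    ``max_init_redraws`` times.  Output is deterministic for a fixed
    seed.
    """
    if kind not in PARAM_NAMES:
        raise ValueError(f"unknown model kind {kind!r}")
    priors = priors if priors is not None else default_priors(kind)
    schedule = schedule or Schedule()
    names = PARAM_NAMES[kind]
    by_name = {p.name: p for p in priors}
    specs = [by_name[n] for n in names]
    d = len(names)
    n_chains = schedule.chains_per_param * d
    rng = np.random.default_rng(seed)

    locs = np.array([p.location for p in specs])
    scales = np.array([p.scale for p in specs])

    def to_natural(z):
        theta = np.empty_like(z)
        for j, p in enumerate(specs):
            theta[..., j] = p.to_natural(z[..., j])
        return theta

    def loglik_z(z):
        return loglik_population(to_natural(z), kind, trials,
                                 gamma_variance_mode=gamma_variance_mode,
                                 timer_t0=timer_t0)

    def logprior_z(z):
        return np.sum(-0.5 * ((z - locs) / scales) ** 2
                      - np.log(scales) - 0.5 * np.log(2.0 * np.pi), axis=-1)

    n_trials = _n_trials(trials)
    floor_ll = n_trials * np.log(DENSITY_FLOOR)

    if init == "optimize":
        from scipy.optimize import differential_evolution

        def neg_logpost(z_cols):  # scipy vectorized convention: (d, S)
            zz = np.atleast_2d(z_cols.T)
            out = -(loglik_z(zz) + logprior_z(zz))
            return out[0] if z_cols.ndim == 1 else out

        bounds = [(l - 3 * s, l + 3 * s) for l, s in zip(locs, scales)]
        opt = differential_evolution(
            neg_logpost, bounds, vectorized=True, updating="deferred",
            init="sobol", popsize=20, maxiter=150, tol=1e-6, polish=False,
            seed=int(rng.integers(2**31 - 1)))
        z = opt.x + rng.normal(0.0, 0.1 * scales, size=(n_chains, d))
        ll = loglik_z(z)
    elif init == "prior":
        z = rng.normal(locs, scales, size=(n_chains, d))
        ll = loglik_z(z)
        for _ in range(max_init_redraws):
            dead = ll <= floor_ll + 1e-6
            if not dead.any():
                break
            z[dead] = rng.normal(locs, scales, size=(int(dead.sum()), d))
            ll[dead] = loglik_z(z[dead])
        else:
            if (ll <= floor_ll + 1e-6).all():
                raise RuntimeError("could not initialise chains at a finite "
                                   "likelihood after re-draws")
    else:
        raise ValueError(f"unknown init strategy {init!r}")

    # DE loop tracking likelihood and prior separately so the stored traces
    # expose the maximum-likelihood surrogate without a second pass
    lp = logprior_z(z)
    g = 2.38 / np.sqrt(2.0 * d)
    n_iter = schedule.burn + schedule.samples
    hist_z = np.empty((n_chains, n_iter, d))
    ll_hist = np.empty((n_chains, n_iter))
    lp_hist = np.empty((n_chains, n_iter))
    for it in range(n_iter):
        a, b = _pick_pairs(n_chains, rng)
        eps = rng.uniform(-1e-4, 1e-4, size=(n_chains, d))
        prop = z + g * (z[a] - z[b]) + eps
        ll_prop = loglik_z(prop)
        lp_prop = logprior_z(prop)
        accept = np.log(rng.random(n_chains)) < (ll_prop + lp_prop) - (ll + lp)
        z[accept] = prop[accept]
        ll[accept] = ll_prop[accept]
        lp[accept] = lp_prop[accept]
        hist_z[:, it, :] = z
        ll_hist[:, it] = ll
        lp_hist[:, it] = lp

    samples_nat = to_natural(hist_z)
    meta = {"kind": kind, "seed": seed, "schedule": schedule,
            "n_chains": n_chains, "n_trials": n_trials,
            "gamma_variance_mode": gamma_variance_mode, "timer_t0": timer_t0,
            "priors": specs}
    return PosteriorSamples(samples=samples_nat, loglik=ll_hist,
                            logprior=lp_hist, param_names=names,
                            n_burn=schedule.burn, meta=meta)


def polish_max_loglik(post: PosteriorSamples, trials) -> float:
    """Refine the maximum-likelihood surrogate by a local Nelder-Mead
    search started from the best sampled draw (on the unconstrained
    scale).  Returns the polished maximum log-likelihood; never smaller
    than the sampled maximum.  Off by default throughout the pipeline:
    BIC comparisons use the best sampled likelihood unless a caller
    opts in.
    """
    from scipy.optimize import minimize

    kind = post.meta["kind"]
    specs = post.meta["priors"]
    best = post.best_vector()
    z0 = np.array([p.to_unconstrained(v) for p, v in zip(specs, best)])

    def neg(z):
        theta = np.array([p.to_natural(zz) for p, zz in zip(specs, z)])
        return -loglik_population(
            theta[None, :], kind, trials,
            gamma_variance_mode=post.meta["gamma_variance_mode"],
            timer_t0=post.meta["timer_t0"])[0]

    res = minimize(neg, z0, method="Nelder-Mead",
                   options=dict(maxiter=4000, xatol=1e-6, fatol=1e-8))
    return max(float(-res.fun), post.max_loglik())


def _n_trials(trials) -> int:
    try:
        return len(trials)
    except TypeError:
        return len(trials[0])


def rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``draws`` has shape (chains, iterations).
    """
    draws = np.asarray(draws, dtype=float)
    m, n = draws.shape
    half = n // 2
    split = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = half * chain_means.var(ddof=1)
    var_hat = (half - 1) / half * w + b / half
    return float(np.sqrt(var_hat / w))
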