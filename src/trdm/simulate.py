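"""Trial-level stochastic simulation of RDM/TRDM decisions.

Each accumulator's first-passage time is drawn exactly from its Wald law
(no path discretisation): for positive drift via the inverse-Gaussian
sampler, for negative drift via the crossing-probability/reflection
identity.  Simulated trials carry a ``source`` label recording whether an
evidence accumulator or the timer terminated the race, which is what lets
fast guesses be separated from evidence-guided responses downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import TIMER_THRESHOLD, ModelParams, timer_choice_prob
from .wald import RHO_FLOOR, StimulusPair, WaldSpec, biased_thresholds, drift_link

__all__ = ["SimTrial", "sample_fpt", "simulate_trial", "simulate_trials",
           "timer_fraction", "NEVER"]

#: sentinel for an accumulator that never reaches threshold
NEVER = np.inf


@dataclass(frozen=True)
class SimTrial:
    """One simulated decision with its generating source."""

    stim: StimulusPair
    choice: str          # "left" | "right"
    rt: float            # seconds, > t0
    source: str          # "evidence" | "timer"
    correct: bool


def sample_fpt(spec: WaldSpec, rng: np.random.Generator, size=None):
    """Draw first-passage time(s) for one accumulator; NEVER (inf) if it
    fails to cross.

    For drift > 0 the crossing time is inverse-Gaussian with mean
    alpha/rho and shape (alpha/sigma)^2, shifted by t0.  For drift < 0 the
    accumulator crosses only with probability exp(2*alpha*rho/sigma^2);
    conditional on crossing, the time has the same law as for drift |rho|
    (reflection identity).  |rho| is floored at 1e-10.
    """
    scalar = size is None
    n = 1 if scalar else int(size)
    rho = spec.drift
    arho = max(abs(rho), RHO_FLOOR)
    mean = spec.threshold / arho
    shape = (spec.threshold / spec.noise) ** 2
    t = spec.t0 + rng.wald(mean, shape, size=n)
    if rho < 0:
        p_cross = np.exp(2.0 * spec.threshold * rho / spec.noise**2)
        t = np.where(rng.random(n) < p_cross, t, NEVER)
    return float(t[0]) if scalar else t


def _race_times(params: ModelParams, stim: StimulusPair,
                rng: np.random.Generator, size: int):
    """First-passage times of all accumulators: (t_left, t_right, t_timer)."""
    rho_l, rho_r = drift_link(stim, params.coefs)
    alpha_l, alpha_r = biased_thresholds(params.omega)
    t_l = sample_fpt(WaldSpec(rho_l, params.eta_c, alpha_l, params.t0), rng, size)
    t_r = sample_fpt(WaldSpec(rho_r, params.eta_c, alpha_r, params.t0), rng, size)
    if params.kind == "TRDM":
        timer_shift = params.t0 if params.timer_t0 == "shared" else 0.0
        t_t = sample_fpt(
            WaldSpec(params.rho_t, params.eta_t, TIMER_THRESHOLD, timer_shift),
            rng, size)
    else:
        t_t = np.full(size, NEVER)
    return t_l, t_r, t_t


def simulate_trials(params: ModelParams, stim: StimulusPair,
                    rng: np.random.Generator, n: int,
                    max_resample: int = 1000) -> pd.DataFrame:
    """Simulate n decisions for one stimulus pair.

    Returns a DataFrame with columns s_l, s_r, choice, rt, source,
    correct.  Correctness is defined against the higher-contrast side;
    for equal contrasts the correct side is assigned uniformly at random,
    as in the task.  RDM trials on which neither accumulator ever crosses
    (possible when both drifts are negative) are resampled; a warning
    reports how many.
    """
    rho_l, rho_r = drift_link(stim, params.coefs)
    t_l, t_r, t_t = _race_times(params, stim, rng, n)

    # resample RDM races in which no accumulator terminates
    n_resampled = 0
    stuck = np.isinf(t_l) & np.isinf(t_r) & np.isinf(t_t)
    for _ in range(max_resample):
        if not stuck.any():
            break
        n_resampled += int(stuck.sum())
        rl, rr, rt_ = _race_times(params, stim, rng, int(stuck.sum()))
        t_l[stuck], t_r[stuck], t_t[stuck] = rl, rr, rt_
        stuck = np.isinf(t_l) & np.isinf(t_r) & np.isinf(t_t)
    if stuck.any():
        raise RuntimeError("non-terminating races persisted after resampling")
    if n_resampled:
        warnings.warn(f"resampled {n_resampled} non-terminating race(s)",
                      RuntimeWarning, stacklevel=2)

    timer_wins = (t_t < t_l) & (t_t < t_r)
    rt = np.where(timer_wins, t_t, np.minimum(t_l, t_r))

    choice_left = t_l < t_r
    if params.kind == "TRDM" and timer_wins.any():
        timer_shift = params.t0 if params.timer_t0 == "shared" else 0.0
        tau = np.maximum(t_t - timer_shift, np.finfo(float).tiny)
        p_left = timer_choice_prob(rho_l, rho_r, params.eta_c, params.gamma,
                                   tau, mode=params.gamma_variance_mode)
        choice_left = np.where(timer_wins, rng.random(n) < p_left, choice_left)

    if stim.s_l > stim.s_r:
        correct_left = np.ones(n, dtype=bool)
    elif stim.s_l < stim.s_r:
        correct_left = np.zeros(n, dtype=bool)
    else:
        correct_left = rng.random(n) < 0.5

    return pd.DataFrame({
        "s_l": stim.s_l,
        "s_r": stim.s_r,
        "choice": np.where(choice_left, "left", "right"),
        "rt": rt,
        "source": np.where(timer_wins, "timer", "evidence"),
        "correct": choice_left == correct_left,
    })


def _simulate_one(params: ModelParams, stim: StimulusPair,
                  rng: np.random.Generator,
                  max_resample: int = 1000) -> tuple[str, float, str]:
    """Scalar race without table overhead: returns (choice, rt, source).

    Used by the session generator, which must simulate trials one at a
    time because the bias-correction rule feeds each choice back into the
    next stimulus draw.
    """
    rho_l, rho_r = drift_link(stim, params.coefs)
    alpha_l, alpha_r = biased_thresholds(params.omega)

    def draw(rho, sigma, alpha, t0):
        arho = max(abs(rho), RHO_FLOOR)
        t = t0 + rng.wald(alpha / arho, (alpha / sigma) ** 2)
        if rho < 0 and rng.random() >= np.exp(2.0 * alpha * rho / sigma**2):
            return NEVER
        return float(t)

    timer_shift = (params.t0 if params.timer_t0 == "shared" else 0.0)
    for _ in range(max_resample):
        t_l = draw(rho_l, params.eta_c, alpha_l, params.t0)
        t_r = draw(rho_r, params.eta_c, alpha_r, params.t0)
        t_t = (draw(params.rho_t, params.eta_t, TIMER_THRESHOLD, timer_shift)
               if params.kind == "TRDM" else NEVER)
        if min(t_l, t_r, t_t) < NEVER:
            break
    else:
        raise RuntimeError("non-terminating race persisted after resampling")

    if t_t < min(t_l, t_r):
        tau = max(t_t - timer_shift, np.finfo(float).tiny)
        p_left = timer_choice_prob(rho_l, rho_r, params.eta_c, params.gamma,
                                   tau, mode=params.gamma_variance_mode)
        return ("left" if rng.random() < p_left else "right"), t_t, "timer"
    return ("left" if t_l < t_r else "right"), min(t_l, t_r), "evidence"


def simulate_trial(params: ModelParams, stim: StimulusPair,
                   rng: np.random.Generator) -> SimTrial:
    """Simulate a single decision (scalar convenience wrapper)."""
    choice, rt, source = _simulate_one(params, stim, rng)
    if stim.s_l == stim.s_r:
        correct = rng.random() < 0.5
    else:
        correct = choice == ("left" if stim.s_l > stim.s_r else "right")
    return SimTrial(stim=stim, choice=choice, rt=rt, source=source,
                    correct=correct)


def timer_fraction(trials) -> float:
    """Proportion of trials whose decision was triggered by the timer."""
    if isinstance(trials, pd.DataFrame):
        sources = trials["source"]
    else:
        sources = pd.Series([tr.source for tr in trials])
    if len(sources) == 0:
        raise ValueError("empty trial set")
    return float((sources == "timer").mean())
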