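"""Defective choice-RT densities for the racing diffusion model (RDM) and
the timed racing diffusion model (TRDM), and the trial-set log-likelihood.

The RDM races two independent single-boundary evidence accumulators; the
first to cross its threshold determines choice and decision time.  The TRDM
adds a third, stimulus-independent "timer" accumulator: if the timer wins
the race, the response is drawn partly (with weight ``gamma``) from the
sign of the evidence accumulated so far and otherwise at random.

The density of a *left* response at time t is

    PDF_left(t) = f_l(t) (1 - F_r(t)) (1 - F_T(t))
                  + P_T(left) f_T(t) (1 - F_l(t)) (1 - F_r(t))

where f/F are Wald first-passage densities/CDFs of the left, right and
timer accumulators and P_T(left) is the probability that a timer-triggered
response is leftward.  For the RDM only the first factor pair remains and
F_T = 0.  Each choice-conditional density is *defective*: it integrates to
the probability of that choice, not to one.

Internally everything broadcasts, so a (K, 1) parameter column against an
(N,) trial row evaluates K parameter sets on N trials at once; the DE-MCMC
sampler relies on this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .wald import DriftLinkCoefs, StimulusPair, _wald_cdf_arr, _wald_pdf_arr

__all__ = [
    "ModelParams",
    "timer_choice_prob",
    "trdm_defective_pdf",
    "rdm_defective_pdf",
    "dataset_loglik",
    "DENSITY_FLOOR",
]

# densities are floored here before taking logs, so a single impossible
# trial yields a very negative but finite log-likelihood
DENSITY_FLOOR = 1e-300

# fixed threshold of the timer accumulator
TIMER_THRESHOLD = 1.0


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of an RDM or TRDM agent.

    RDM instances carry the six choice parameters (``omega``, ``t0``,
    drift coefficients, ``eta_c``); TRDM instances add the timer drift
    ``rho_t``, timer noise ``eta_t`` and evidence-dependence mixture
    ``gamma``.

    ``gamma_variance_mode`` selects how the variance of the evidence
    difference entering P_T is computed: ``"printed"`` uses 2*(eta_c*t)^2,
    ``"diffusion"`` uses 2*eta_c^2*t.  ``timer_t0`` selects whether the
    timer runs on the shifted clock t - t0 (``"shared"``, default) or on
    the raw clock (``"zero"``).
    """

    omega: float
    t0: float
    coefs: DriftLinkCoefs
    eta_c: float
    rho_t: float | None = None
    eta_t: float | None = None
    gamma: float | None = None
    kind: str = "RDM"
    gamma_variance_mode: str = "printed"
    timer_t0: str = "shared"

    def __post_init__(self) -> None:
        if self.kind not in ("RDM", "TRDM"):
            raise ValueError(f"kind must be 'RDM' or 'TRDM', got {self.kind!r}")
        if not (0.0 < self.omega < 1.0):
            raise ValueError(f"omega must lie in (0, 1), got {self.omega}")
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if not (self.eta_c > 0):
            raise ValueError(f"eta_c must be > 0, got {self.eta_c}")
        timer_fields = (self.rho_t, self.eta_t, self.gamma)
        if self.kind == "TRDM":
            if any(v is None for v in timer_fields):
                raise ValueError("TRDM requires rho_t, eta_t and gamma")
            if not (self.rho_t > 0):
                raise ValueError(f"rho_t must be > 0, got {self.rho_t}")
            if not (self.eta_t > 0):
                raise ValueError(f"eta_t must be > 0, got {self.eta_t}")
            if not (0.0 < self.gamma < 1.0):
                raise ValueError(f"gamma must lie in (0, 1), got {self.gamma}")
        else:
            if any(v is not None for v in timer_fields):
                raise ValueError("RDM carries no timer fields")
        if self.gamma_variance_mode not in ("printed", "diffusion"):
            raise ValueError("gamma_variance_mode must be 'printed' or 'diffusion'")
        if self.timer_t0 not in ("shared", "zero"):
            raise ValueError("timer_t0 must be 'shared' or 'zero'")

    @property
    def free_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.kind]

    def to_vector(self) -> np.ndarray:
        """Natural-scale parameter vector in canonical order."""
        base = [self.omega, self.t0, self.coefs.v0, self.coefs.vd,
                self.coefs.vs, self.eta_c]
        if self.kind == "TRDM":
            base += [self.rho_t, self.eta_t, self.gamma]
        return np.asarray(base, dtype=float)

    @classmethod
    def from_vector(cls, vec, kind: str, **kwargs) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        k = len(PARAM_NAMES[kind])
        if vec.shape != (k,):
            raise ValueError(f"expected {k} parameters for {kind}, got {vec.shape}")
        coefs = DriftLinkCoefs(v0=vec[2], vd=vec[3], vs=vec[4])
        timer = dict(rho_t=vec[6], eta_t=vec[7], gamma=vec[8]) if kind == "TRDM" else {}
        return cls(omega=vec[0], t0=vec[1], coefs=coefs, eta_c=vec[5],
                   kind=kind, **timer, **kwargs)


PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "RDM": ("omega", "t0", "v0", "vd", "vs", "eta_c"),
    "TRDM": ("omega", "t0", "v0", "vd", "vs", "eta_c", "rho_t", "eta_t", "gamma"),
}


def timer_choice_prob(rho_l, rho_r, eta_c, gamma, t, mode: str = "printed"):
    """Probability of a LEFT response given that the timer won at time t.

    P_T = gamma * F_X(0) + (1 - gamma)/2, where X is the normally
    distributed right-minus-left evidence difference at the timer's
    crossing time.  ``mode="printed"`` gives X variance 2*(eta_c*t)^2
    (the crossing time then cancels); ``mode="diffusion"`` gives the
    Brownian-difference variance 2*eta_c^2*t.
    """
    rho_l = np.asarray(rho_l, dtype=float)
    rho_r = np.asarray(rho_r, dtype=float)
    t = np.asarray(t, dtype=float)
    if mode == "printed":
        z = (rho_l - rho_r) / (np.sqrt(2.0) * eta_c)
    elif mode == "diffusion":
        z = (rho_l - rho_r) * np.sqrt(t) / (np.sqrt(2.0) * eta_c)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    # F_X(0) = Phi((mu_l - mu_r)*t / sd); broadcast against t for scalars
    p = gamma * ndtr(z + 0.0 * t) + 0.5 * (1.0 - gamma)
    return float(p) if p.ndim == 0 else p


def _evidence_drifts(s_l, s_r, v0, vd, vs):
    diff = s_l - s_r
    total = s_l + s_r
    return v0 + vd * diff + vs * total, v0 - vd * diff + vs * total


def _defective_pdf_core(t, choice_left, s_l, s_r,
                        omega, t0, v0, vd, vs, eta_c,
                        rho_t=None, eta_t=None, gamma=None,
                        gamma_variance_mode="printed", timer_t0="shared"):
    """Broadcast defective density of (choice, t) trials.

    All parameter arguments may be scalars or arrays broadcastable against
    the trial arrays (e.g. shape (K, 1) parameter columns).  Timer
    arguments None selects the RDM.
    """
    t = np.asarray(t, dtype=float)
    choice_left = np.asarray(choice_left, dtype=bool)
    s_l = np.asarray(s_l, dtype=float)
    s_r = np.asarray(s_r, dtype=float)

    rho_l, rho_r = _evidence_drifts(s_l, s_r, v0, vd, vs)
    alpha_l = 2.0 * omega
    alpha_r = 2.0 * (1.0 - omega)

    f_l = _wald_pdf_arr(t, rho_l, eta_c, alpha_l, t0)
    F_l = _wald_cdf_arr(t, rho_l, eta_c, alpha_l, t0)
    f_r = _wald_pdf_arr(t, rho_r, eta_c, alpha_r, t0)
    F_r = _wald_cdf_arr(t, rho_r, eta_c, alpha_r, t0)

    f_win = np.where(choice_left, f_l, f_r)
    S_lose = np.where(choice_left, 1.0 - F_r, 1.0 - F_l)

    if rho_t is None:
        return f_win * S_lose

    timer_shift = t0 if timer_t0 == "shared" else 0.0
    f_T = _wald_pdf_arr(t, rho_t, eta_t, TIMER_THRESHOLD, timer_shift)
    F_T = _wald_cdf_arr(t, rho_t, eta_t, TIMER_THRESHOLD, timer_shift)

    tau = np.maximum(t - timer_shift, np.finfo(float).tiny)
    p_left = timer_choice_prob(rho_l, rho_r, eta_c, gamma, tau,
                               mode=gamma_variance_mode)
    p_win = np.where(choice_left, p_left, 1.0 - p_left)

    return f_win * S_lose * (1.0 - F_T) + p_win * f_T * (1.0 - F_l) * (1.0 - F_r)


def _core_kwargs(params: ModelParams) -> dict:
    kw = dict(omega=params.omega, t0=params.t0, v0=params.coefs.v0,
              vd=params.coefs.vd, vs=params.coefs.vs, eta_c=params.eta_c,
              gamma_variance_mode=params.gamma_variance_mode,
              timer_t0=params.timer_t0)
    if params.kind == "TRDM":
        kw.update(rho_t=params.rho_t, eta_t=params.eta_t, gamma=params.gamma)
    return kw


def trdm_defective_pdf(t, choice: str, params: ModelParams, stim: StimulusPair):
    """TRDM defective density of observing ``choice`` at time(s) ``t``."""
    if params.kind != "TRDM":
        raise ValueError("params must be of TRDM kind")
    out = _defective_pdf_core(t, choice == "left", stim.s_l, stim.s_r,
                              **_core_kwargs(params))
    return float(out) if np.isscalar(t) else out


def rdm_defective_pdf(t, choice: str, params: ModelParams, stim: StimulusPair):
    """RDM defective density: f_win(t) * (1 - F_lose(t))."""
    if params.kind != "RDM":
        raise ValueError("params must be of RDM kind")
    out = _defective_pdf_core(t, choice == "left", stim.s_l, stim.s_r,
                              **_core_kwargs(params))
    return float(out) if np.isscalar(t) else out


def defective_pdf(t, choice: str, params: ModelParams, stim: StimulusPair):
    """Dispatch on ``params.kind``."""
    if params.kind == "TRDM":
        return trdm_defective_pdf(t, choice, params, stim)
    return rdm_defective_pdf(t, choice, params, stim)


def _trial_arrays(trials):
    """Extract (t, choice_left, s_l, s_r) from a trial table or array tuple."""
    if isinstance(trials, pd.DataFrame):
        t = trials["rt"].to_numpy(dtype=float)
        choice_left = trials["choice"].to_numpy() == "left"
        s_l = trials["s_l"].to_numpy(dtype=float)
        s_r = trials["s_r"].to_numpy(dtype=float)
    else:
        t, choice_left, s_l, s_r = (np.asarray(a) for a in trials)
        choice_left = choice_left.astype(bool)
    if len(t) == 0:
        raise ValueError("empty trial set")
    if np.any(t <= 0):
        raise ValueError("all response times must be positive")
    return t.astype(float), choice_left, s_l.astype(float), s_r.astype(float)


def dataset_loglik(trials, params: ModelParams) -> float:
    """Sum of log defective densities over a trial table.

    ``trials`` is a DataFrame with columns rt, choice, s_l, s_r (or a
    tuple of such arrays).  Densities below ``DENSITY_FLOOR`` are floored
    before the log, so the result is always finite.
    """
    t, choice_left, s_l, s_r = _trial_arrays(trials)
    dens = _defective_pdf_core(t, choice_left, s_l, s_r, **_core_kwargs(params))
    return float(np.sum(np.log(np.maximum(dens, DENSITY_FLOOR))))


def loglik_population(theta: np.ndarray, kind: str, trials,
                      gamma_variance_mode="printed", timer_t0="shared") -> np.ndarray:
    """Log-likelihood of each row of a (K, d) natural-scale parameter matrix.

    Column order follows ``PARAM_NAMES[kind]``.  This is the hot path of
    the DE-MCMC sampler: the K parameter sets are evaluated on all N
    trials in one broadcast pass.
    """
    t, choice_left, s_l, s_r = _trial_arrays(trials)
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    cols = {name: theta[:, i][:, None] for i, name in enumerate(PARAM_NAMES[kind])}
    timer = {}
    if kind == "TRDM":
        timer = dict(rho_t=cols["rho_t"], eta_t=cols["eta_t"], gamma=cols["gamma"])
    dens = _defective_pdf_core(
        t[None, :], choice_left[None, :], s_l[None, :], s_r[None, :],
        omega=cols["omega"], t0=cols["t0"], v0=cols["v0"], vd=cols["vd"],
        vs=cols["vs"], eta_c=cols["eta_c"],
        gamma_variance_mode=gamma_variance_mode, timer_t0=timer_t0, **timer)
    return np.sum(np.log(np.maximum(dens, DENSITY_FLOOR)), axis=1)
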