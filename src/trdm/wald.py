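"""Single-boundary diffusion first-passage (Wald) distribution and the
contrast-to-drift linking function.

A single accumulator with drift ``rho``, within-trial noise ``sigma`` and
absorbing threshold ``alpha`` has a first-passage time following the
inverse-Gaussian (Wald) law, shifted by a nondecision time ``t0``.  For a
negative drift the accumulator crosses only with probability
``exp(2*alpha*rho/sigma**2)`` and the distribution is defective.

All densities are in 1/s and all times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr

__all__ = [
    "WaldSpec",
    "DriftLinkCoefs",
    "StimulusPair",
    "wald_pdf",
    "wald_cdf",
    "drift_link",
    "biased_thresholds",
]

# |rho| below this is treated as the rho -> 0 limit when sampling.
RHO_FLOOR = 1e-10


@dataclass(frozen=True)
class WaldSpec:
    """Parameters of one accumulator's first-passage distribution.

    Attributes
    ----------
    drift : float
        Mean accumulation rate (evidence units / s); may be negative or
        zero for a losing accumulator.
    noise : float
        Within-trial drift variability, > 0.
    threshold : float
        Absorbing boundary, > 0 (fixed to 1.0 in the fitted models unless
        perturbed by the bias parameter).
    t0 : float
        Nondecision time in seconds, >= 0.
    """

    drift: float
    noise: float = 1.0
    threshold: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.noise > 0):
            raise ValueError(f"noise must be > 0, got {self.noise}")
        if not (self.threshold > 0):
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")


@dataclass(frozen=True)
class DriftLinkCoefs:
    """Coefficients mapping a contrast pair to the two evidence drifts.

    ``v0`` is the baseline drift, ``vd`` weights the contrast difference
    and ``vs`` weights the contrast sum.
    """

    v0: float
    vd: float
    vs: float

    def __post_init__(self) -> None:
        for name in ("v0", "vd", "vs"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class StimulusPair:
    """Left/right stimulus contrasts, each in [0, 1]."""

    s_l: float
    s_r: float

    def __post_init__(self) -> None:
        for name, v in (("s_l", self.s_l), ("s_r", self.s_r)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _wald_pdf_arr(t, drift, noise, threshold, t0):
    """Vectorised Wald density; array-safe, 0 for t <= t0."""
    t = np.asarray(t, dtype=float)
    tau = t - t0
    pos = tau > 0
    tau_safe = np.where(pos, tau, 1.0)
    z = (threshold - drift * tau_safe) ** 2 / (2.0 * noise**2 * tau_safe)
    out = threshold / (noise * np.sqrt(2.0 * np.pi * tau_safe**3)) * np.exp(-z)
    return np.where(pos, out, 0.0)


def _wald_cdf_arr(t, drift, noise, threshold, t0):
    """Vectorised Wald CDF.

    The second term ``exp(2*alpha*rho/sigma^2) * Phi(-(rho*tau+alpha)/...)``
    is evaluated as ``exp(2*alpha*rho/sigma^2 + log Phi(.))`` so that large
    positive drifts do not overflow.
    """
    t = np.asarray(t, dtype=float)
    tau = t - t0
    pos = tau > 0
    tau_safe = np.where(pos, tau, 1.0)
    sq = noise * np.sqrt(tau_safe)
    term1 = ndtr((drift * tau_safe - threshold) / sq)
    log_term2 = 2.0 * threshold * drift / noise**2 + log_ndtr(
        -(drift * tau_safe + threshold) / sq
    )
    out = term1 + np.exp(log_term2)
    # guard against roundoff pushing the sum a hair above 1
    out = np.clip(out, 0.0, 1.0)
    return np.where(pos, out, 0.0)


def wald_pdf(t, spec: WaldSpec):
    """First-passage density f(t) of a single accumulator.

    Returns 0 for ``t <= t0``.  Accepts scalar or array ``t``.
    """
    out = _wald_pdf_arr(t, spec.drift, spec.noise, spec.threshold, spec.t0)
    return float(out) if np.isscalar(t) else out

def wald_cdf(t, spec: WaldSpec):
    """First-passage distribution F(t); defective (limit < 1) when drift < 0."""
    out = _wald_cdf_arr(t, spec.drift, spec.noise, spec.threshold, spec.t0)
    return float(out) if np.isscalar(t) else out


def crossing_probability(spec: WaldSpec) -> float:
    """Probability that the accumulator ever reaches threshold."""
    if spec.drift >= 0:
        return 1.0
    return float(np.exp(2.0 * spec.threshold * spec.drift / spec.noise**2))


def drift_link(stim: StimulusPair, coefs: DriftLinkCoefs) -> tuple[float, float]:
    """Map a contrast pair to (left, right) evidence drift rates.

    rho_l = v0 + vd*(s_l - s_r) + vs*(s_l + s_r), and mirrored for the
    right accumulator, so equal contrasts give equal drifts and swapping
    the stimuli swaps the drifts.
    """
    diff = stim.s_l - stim.s_r
    total = stim.s_l + stim.s_r
    rho_l = coefs.v0 + coefs.vd * diff + coefs.vs * total
    rho_r = coefs.v0 - coefs.vd * diff + coefs.vs * total
    return rho_l, rho_r


def biased_thresholds(omega: float) -> tuple[float, float]:
    """Map the bias parameter to (left, right) evidence thresholds.

    The bias omega in (0, 1) perturbs the two thresholds complementarily,
    alpha_l = 2*omega and alpha_r = 2*(1 - omega), so they always sum to 2
    and omega = 0.5 recovers the unbiased fixed threshold of 1.0 for both
    accumulators.  Smaller left threshold (omega < 0.5) favours left
    responses.  This linkage is a package convention; see docs/methods.md.
    """
    if not (0.0 < omega < 1.0):
        raise ValueError(f"omega must lie in (0, 1), got {omega}")
    return 2.0 * omega, 2.0 * (1.0 - omega)
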