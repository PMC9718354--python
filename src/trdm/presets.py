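"""Reference agent parameter sets.

Three TRDM agents summarise the behavioral regimes the package emulates:

* ``fast_timer_agent`` — the fast-timer reference set (timer drift 3,
  mean crossing ~1/3 s) racing strong evidence.  Around 40% of decisions
  are timer-triggered; fitting both models to its output is the
  package's model-comparison benchmark, and the timer leaves an
  overwhelming likelihood signature (very strong evidence for the TRDM).
* ``slow_timer_agent`` — the same evidence parameters with a slow, sharp
  timer (drift 0.8): the timer wins only a few percent of races, RTs are
  unimodal, and the two models fit almost equally well, so the
  parameter-count penalty leaves the simpler RDM competitive — the
  exponential-delay phenotype.
* ``fixed_delay_agent`` — a session phenotype with a high-variability
  timer (timer noise 2): its first-passage density has a sharp early
  peak plus a heavy tail, so timer wins concentrate at short RTs.
  Sessions show the fast-guess pattern: an early, chance-level RT
  component and a later, above-chance evidence component.

The timer ordering across the two delay-scheme phenotypes (faster,
noisier timer under fixed delay; slower, sharper timer under exponential
delay) follows the direction of the fitted posterior differences between
the two training groups.
"""

from __future__ import annotations

from .likelihood import ModelParams
from .wald import DriftLinkCoefs


def fast_timer_agent(**overrides) -> ModelParams:
    """Fast-timer TRDM reference agent (many timer-induced choices)."""
    kw = dict(omega=0.5, t0=0.1, coefs=DriftLinkCoefs(1.0, 3.0, 0.5),
              eta_c=1.0, rho_t=3.0, eta_t=0.5, gamma=0.2, kind="TRDM")
    kw.update(overrides)
    return ModelParams(**kw)


def slow_timer_agent(**overrides) -> ModelParams:
    """Slow-timer TRDM agent (near-zero timer share, RDM-competitive)."""
    kw = dict(omega=0.5, t0=0.1, coefs=DriftLinkCoefs(1.0, 3.0, 0.5),
              eta_c=1.0, rho_t=0.8, eta_t=0.5, gamma=0.2, kind="TRDM")
    kw.update(overrides)
    return ModelParams(**kw)


def fixed_delay_agent(**overrides) -> ModelParams:
    """Fixed-delay session phenotype: early heavy-tailed timer (fast
    guesses at chance) over slower evidence accumulation."""
    kw = dict(omega=0.5, t0=0.1, coefs=DriftLinkCoefs(0.4, 1.8, 0.3),
              eta_c=0.6, rho_t=1.0, eta_t=2.0, gamma=0.2, kind="TRDM")
    kw.update(overrides)
    return ModelParams(**kw)


def rdm_agent(**overrides) -> ModelParams:
    """Pure evidence-race agent with the shared choice parameters."""
    kw = dict(omega=0.5, t0=0.1, coefs=DriftLinkCoefs(1.0, 3.0, 0.5),
              eta_c=1.0, kind="RDM")
    kw.update(overrides)
    return ModelParams(**kw)
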