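"""Model comparison by BIC-approximated Bayes factors.

BIC = k*ln(n) - 2*ln(L_max); the Bayes factor of model i over model j is
approximated by exp(-0.5*(BIC_i - BIC_j)), and its log is read against
the conventional evidence thresholds |ln BF| > 1 / 3 / 5 for positive /
strong / very strong evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["bic", "ln_bayes_factor", "interpret", "ComparisonResult",
           "compare_models"]


def bic(max_loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion: k*ln(n) - 2*max_loglik."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(k * np.log(n) - 2.0 * max_loglik)


def ln_bayes_factor(bic_i: float, bic_j: float) -> float:
    """ln BF of model i over model j: -0.5*(BIC_i - BIC_j); positive
    favours model i."""
    return -0.5 * (bic_i - bic_j)


def interpret(ln_bf: float) -> str:
    """Evidence label at thresholds |ln BF| = 1, 3, 5.

    Returns one of 'inconclusive', 'positive (model i)', 'strong
    (model i)', 'very strong (model i)' or the model-j counterparts.
    """
    mag = abs(ln_bf)
    if mag <= 1.0:
        return "inconclusive"
    side = "model i" if ln_bf > 0 else "model j"
    if mag > 5.0:
        grade = "very strong"
    elif mag > 3.0:
        grade = "strong"
    else:
        grade = "positive"
    return f"{grade} ({side})"


@dataclass(frozen=True)
class ComparisonResult:
    """Pairwise model comparison of model i against model j."""

    name_i: str
    name_j: str
    max_loglik_i: float
    max_loglik_j: float
    k_i: int
    k_j: int
    n: int
    bic_i: float
    bic_j: float
    ln_bf: float
    verdict: str

    def to_dict(self) -> dict:
        return {
            "model_i": self.name_i, "model_j": self.name_j,
            "max_loglik_i": self.max_loglik_i, "max_loglik_j": self.max_loglik_j,
            "k_i": self.k_i, "k_j": self.k_j, "n": self.n,
            "bic_i": self.bic_i, "bic_j": self.bic_j,
            "ln_bf_ij": self.ln_bf, "verdict": self.verdict,
        }


def compare_models(max_loglik_i: float, k_i: int, max_loglik_j: float,
                   k_j: int, n: int, name_i: str = "TRDM",
                   name_j: str = "RDM") -> ComparisonResult:
    """Compare two fitted models on the same n trials."""
    b_i = bic(max_loglik_i, k_i, n)
    b_j = bic(max_loglik_j, k_j, n)
    ln_bf = ln_bayes_factor(b_i, b_j)
    return ComparisonResult(
        name_i=name_i, name_j=name_j,
        max_loglik_i=float(max_loglik_i), max_loglik_j=float(max_loglik_j),
        k_i=k_i, k_j=k_j, n=n, bic_i=b_i, bic_j=b_j,
        ln_bf=float(ln_bf), verdict=interpret(ln_bf))
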