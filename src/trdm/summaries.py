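"""Preprocessing and descriptive summaries of choice-RT data.

Covers the standard pipeline applied before model fitting: Box-Cox-based
RT outlier culling, psychometric (choice proportion vs signed contrast
difference) and chronometric (mean RT vs difficulty) tables, a binned
accuracy-vs-RT sigmoid fit, and the reward-rate curve that quantifies the
speed-accuracy trade-off imposed by a punishment-delay rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["boxcox_cull", "psychometric", "rt_by_difficulty",
           "accuracy_vs_rt", "reward_rate", "rt_contrast_slope"]


def boxcox_cull(rts, n_sd: float = 3.0) -> np.ndarray:
    """Keep-mask for RTs within ``n_sd`` SDs on the Box-Cox scale.

    The Box-Cox exponent is estimated by maximum likelihood on the RTs of
    one animal's dataset; transformed values beyond mean +/- n_sd SD are
    marked for removal.  Degenerate input (zero spread) keeps everything
    with a warning.
    """
    rts = np.asarray(rts, dtype=float)
    if np.any(rts <= 0):
        raise ValueError("all RTs must be positive")
    if len(rts) < 20:
        raise ValueError("need at least 20 RTs to estimate the transform")
    if np.allclose(rts, rts[0]):
        warnings.warn("degenerate RT distribution (zero spread); keeping all",
                      RuntimeWarning, stacklevel=2)
        return np.ones(len(rts), dtype=bool)
    z, _ = stats.boxcox(rts)
    sd = z.std(ddof=1)
    if sd == 0:
        warnings.warn("zero SD after transform; keeping all",
                      RuntimeWarning, stacklevel=2)
        return np.ones(len(rts), dtype=bool)
    return np.abs(z - z.mean()) <= n_sd * sd


def psychometric(trials: pd.DataFrame, conf: float = 0.95) -> pd.DataFrame:
    """Proportion of rightward choices per signed contrast difference.

    Returns one row per distinct s_r - s_l with the choice proportion and
    a Wilson score interval.
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    df = trials.assign(
        diff=np.round(trials["s_r"] - trials["s_l"], 6),
        right=(trials["choice"] == "right").astype(int),
    )
    g = df.groupby("diff")["right"].agg(["sum", "count"]).reset_index()
    z = stats.norm.ppf(0.5 + conf / 2)
    p = g["sum"] / g["count"]
    n = g["count"]
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return pd.DataFrame({
        "contrast_diff": g["diff"], "n": n, "p_right": p,
        "ci_low": np.clip(centre - half, 0, 1),
        "ci_high": np.clip(centre + half, 0, 1),
    })


def rt_by_difficulty(trials: pd.DataFrame, split_by_correctness: bool = False,
                     conf: float = 0.95) -> pd.DataFrame:
    """Mean RT (with normal-approximation CI) per absolute contrast
    difference, optionally split by correctness."""
    if len(trials) == 0:
        raise ValueError("empty trial set")
    df = trials.assign(abs_diff=np.round((trials["s_l"] - trials["s_r"]).abs(), 6))
    keys = ["abs_diff", "correct"] if split_by_correctness else ["abs_diff"]
    z = stats.norm.ppf(0.5 + conf / 2)
    g = df.groupby(keys)["rt"].agg(["mean", "std", "count"]).reset_index()
    sem = g["std"] / np.sqrt(g["count"])
    g["ci_low"] = g["mean"] - z * sem
    g["ci_high"] = g["mean"] + z * sem
    return g.rename(columns={"mean": "mean_rt", "count": "n"}).drop(columns="std")


def _sigmoid(t, upper, midpoint, slope):
    return 0.5 + (upper - 0.5) / (1.0 + np.exp(-(t - midpoint) / slope))


def accuracy_vs_rt(trials: pd.DataFrame, bin_width: float = 0.05,
                   min_per_bin: int = 5):
    """Fit a logistic accuracy-vs-RT curve on binned data.

    Accuracy per RT bin is fitted with a sigmoid whose lower asymptote is
    fixed at 0.5 (2AFC chance) and upper asymptote bounded by 1.  Returns
    ``(acc_fn, coefs)`` where ``acc_fn`` maps RT to fitted accuracy and
    ``coefs`` is a dict with upper/midpoint/slope.
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    rt = trials["rt"].to_numpy(dtype=float)
    correct = trials["correct"].to_numpy(dtype=bool)
    edges = np.arange(rt.min(), rt.max() + bin_width, bin_width)
    idx = np.clip(np.digitize(rt, edges) - 1, 0, max(len(edges) - 2, 0))
    centers, accs, weights = [], [], []
    for b in np.unique(idx):
        sel = idx == b
        if sel.sum() >= min_per_bin:
            centers.append(edges[b] + bin_width / 2)
            accs.append(correct[sel].mean())
            weights.append(sel.sum())
    if len(centers) < 5:
        raise ValueError("fewer than 5 usable RT bins; widen bins or add data")
    centers, accs = np.asarray(centers), np.asarray(accs)
    sigma = 1.0 / np.sqrt(np.asarray(weights, dtype=float))
    try:
        popt, _ = optimize.curve_fit(
            _sigmoid, centers, accs, sigma=sigma,
            p0=[min(max(accs.max(), 0.51), 1.0), float(np.median(centers)), 0.1],
            bounds=([0.5, centers.min() - 1.0, 1e-4],
                    [1.0, centers.max() + 1.0, 10.0]),
            maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise ValueError(f"sigmoid fit failed: {exc}") from exc
    coefs = {"upper": float(popt[0]), "midpoint": float(popt[1]),
             "slope": float(popt[2])}

    def acc_fn(t):
        return np.clip(_sigmoid(np.asarray(t, dtype=float), *popt), 0.0, 1.0)

    return acc_fn, coefs


def reward_rate(t, acc, delay):
    """Theoretical reward rate at response time t (rewards / s).

    RR(t) = Acc(t) / (Acc(t)*t + (1 - Acc(t))*(t + Delay(t))): correct
    trials cost t seconds and pay one reward; errors cost t plus the
    punishment delay and pay nothing.  ``acc`` and ``delay`` may be
    scalars, arrays matching t, or callables of t.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(acc(t) if callable(acc) else acc, dtype=float)
    d = np.asarray(delay(t) if callable(delay) else delay, dtype=float)
    rr = a / (a * t + (1.0 - a) * (t + d))
    return float(rr) if rr.ndim == 0 else rr


def rt_contrast_slope(trials: pd.DataFrame, correct_only: bool = True) -> float:
    """Descriptive per-dataset least-squares slope of RT on |contrast
    difference| (s per unit contrast).  A simple diagnostic, not a
    mixed-effects fit."""
    df = trials[trials["correct"]] if correct_only else trials
    x = (df["s_l"] - df["s_r"]).abs().to_numpy(dtype=float)
    y = df["rt"].to_numpy(dtype=float)
    if len(x) < 2 or np.allclose(x, x[0]):
        raise ValueError("need at least two distinct difficulty levels")
    return float(np.polyfit(x, y, 1)[0])
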