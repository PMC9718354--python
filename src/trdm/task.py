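"""Synthetic 2AFC contrast-discrimination sessions.

Generates complete behavioral sessions in the structure of the tree-shrew
contrast-discrimination task: six contrast levels evenly spaced on
[0.08, 0.99] crossed into 36 ordered pairs, self-paced trials answered by
a simulated RDM/TRDM agent, liquid reward on correct trials, a punishment
delay on errors (fixed 4 s scheme or an RT-dependent exponential-decay
scheme), truncated-normal intertrial intervals and reward durations, and
a real-time side-bias correction that steers the correct side away from
the agent's recent choices.

These sessions are the package's stand-in for animal data: the generating
agent's parameters are known, so fitting and model comparison can be
validated against ground truth.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .likelihood import ModelParams
from .simulate import _simulate_one
from .wald import StimulusPair

__all__ = [
    "DelayScheme", "TaskConfig", "contrast_grid", "fixed_delay",
    "exponential_delay", "next_side_prob", "draw_iti", "draw_reward",
    "generate_session", "generate_sessions", "expected_reward_volume",
    "write_trials", "read_trials",
]

TRIAL_COLUMNS = ["animal_id", "session", "trial_index", "s_l", "s_r",
                 "correct_side", "choice", "rt", "correct", "iti",
                 "delay", "reward_ul", "source"]


@dataclass(frozen=True)
class DelayScheme:
    """Punishment-delay rule applied after incorrect responses.

    ``fixed``: constant 4 s base, +0.8 s per blank-screen lick, capped at
    8 s.  ``exponential``: delay T = (1/s) * exp(-(rt - l)/s) decaying
    with the trial's RT (l = 0.1, s = 1.7), +1.5 s per lick with no cap —
    the scheme that punishes fast errors hardest.
    """

    kind: str = "fixed"
    fixed_base: float = 4.0
    fixed_lick_penalty: float = 0.8
    fixed_cap: float = 8.0
    exp_location: float = 0.1
    exp_scale: float = 1.7
    exp_lick_penalty: float = 1.5

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "exponential"):
            raise ValueError(f"kind must be 'fixed' or 'exponential', got {self.kind!r}")

    def delay(self, rt: float, n_licks: int = 0, t_passed: float = 0.0) -> float:
        if self.kind == "fixed":
            return fixed_delay(n_licks, self)
        return exponential_delay(rt, n_licks, t_passed, self)


@dataclass(frozen=True)
class TaskConfig:
    """Session-level task parameters.

    Defaults follow the task as run: 6 contrast levels evenly spaced on
    [0.08, 0.99], 550 trials/session (the middle of the 500-600/day
    range), ITI ~ TruncNormal(0.6, 1; [0.5, 0.7]) s, reward duration ~
    TruncNormal(0.1, 0.06; [0.2, 0.4]) s at 150 ul/s flow, a 10-trial
    bias-correction window, and zero blank-screen licks (no lick-rate
    model is assumed).
    """

    contrast_levels: tuple = tuple(np.round(np.linspace(0.08, 0.99, 6), 6))
    trials_per_session: int = 550
    sessions: int = 1
    delay_scheme: DelayScheme = field(default_factory=DelayScheme)
    iti_mean: float = 0.6
    iti_sd: float = 1.0
    iti_bounds: tuple = (0.5, 0.7)
    reward_mean: float = 0.1
    reward_sd: float = 0.06
    reward_bounds: tuple = (0.2, 0.4)
    flow_rate_ul_s: float = 150.0
    bias_window: int = 10
    bias_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iti_bounds[0] > self.iti_bounds[1]:
            raise ValueError("iti_bounds must be ordered")
        if self.reward_bounds[0] > self.reward_bounds[1]:
            raise ValueError("reward_bounds must be ordered")
        if list(self.contrast_levels) != sorted(self.contrast_levels):
            raise ValueError("contrast_levels must be sorted ascending")


def contrast_grid(config: TaskConfig | None = None) -> list[StimulusPair]:
    """All ordered (left, right) combinations of the contrast levels."""
    levels = config.contrast_levels if config is not None else TaskConfig().contrast_levels
    return [StimulusPair(a, b) for a, b in itertools.product(levels, levels)]


def fixed_delay(n_licks: int, scheme: DelayScheme | None = None) -> float:
    """Fixed-scheme punishment delay: min(4 + 0.8*licks, 8) seconds."""
    if n_licks < 0:
        raise ValueError("lick count must be non-negative")
    s = scheme or DelayScheme(kind="fixed")
    return min(s.fixed_base + s.fixed_lick_penalty * n_licks, s.fixed_cap)


def exponential_delay(rt: float, n_licks: int = 0, t_passed: float = 0.0,
                      scheme: DelayScheme | None = None) -> float:
    """Exponential-scheme delay: max(T, t_passed + 1.5*licks) with
    T = (1/s) * exp(-(rt - l)/s)."""
    if rt <= 0:
        raise ValueError("rt must be positive")
    s = scheme or DelayScheme(kind="exponential")
    T = (1.0 / s.exp_scale) * np.exp(-(rt - s.exp_location) / s.exp_scale)
    return float(max(T, t_passed + s.exp_lick_penalty * n_licks))


def next_side_prob(history) -> float:
    """Bias-correction rule: P(next correct side is right) = 1 - Pr,
    where Pr is the fraction of rightward choices in the recent window."""
    history = list(history)
    if not history:
        return 0.5
    pr = sum(1 for c in history if c == "right") / len(history)
    return 1.0 - pr


def _truncnorm(mean, sd, bounds):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return truncnorm(a, b, loc=mean, scale=sd)


def draw_iti(config: TaskConfig, rng: np.random.Generator, size=None):
    """Intertrial interval draw(s) in seconds."""
    dist = _truncnorm(config.iti_mean, config.iti_sd, config.iti_bounds)
    return dist.rvs(size=size, random_state=rng)


def draw_reward(config: TaskConfig, rng: np.random.Generator):
    """One reward draw: (valve-open duration s, volume ul)."""
    dist = _truncnorm(config.reward_mean, config.reward_sd, config.reward_bounds)
    duration = float(dist.rvs(random_state=rng))
    return duration, duration * config.flow_rate_ul_s


def expected_reward_volume(config: TaskConfig | None = None) -> float:
    """Analytic mean reward volume per correct trial (ul), with the valve
    duration rounded to hardware precision (10 ms)."""
    config = config or TaskConfig()
    mean_dur = _truncnorm(config.reward_mean, config.reward_sd,
                          config.reward_bounds).mean()
    return round(float(mean_dur), 2) * config.flow_rate_ul_s


def generate_session(agent: ModelParams, config: TaskConfig,
                     rng: np.random.Generator, animal_id: str = "syn01",
                     session: int = 0) -> pd.DataFrame:
    """Generate one session of TrialRecord rows.

    Each trial: a stimulus pair is drawn from the grid (re-oriented by the
    bias-correction rule when the agent's recent choices are imbalanced),
    the agent produces a choice and RT, correctness is assigned (random
    side on equal contrasts), and reward or punishment-delay plus the ITI
    are logged.
    """
    grid = contrast_grid(config)
    choices_hist: list[str] = []
    rows = []
    # pre-draw the scheduling variates in one batch per session; the
    # reward draw for an incorrect trial is simply discarded
    n = config.trials_per_session
    itis = np.atleast_1d(draw_iti(config, rng, size=n))
    rew_durs = np.atleast_1d(_truncnorm(config.reward_mean, config.reward_sd,
                                        config.reward_bounds).rvs(size=n, random_state=rng))
    for i in range(config.trials_per_session):
        pair = grid[rng.integers(len(grid))]
        if config.bias_correction and pair.s_l != pair.s_r:
            p_right = next_side_prob(choices_hist[-config.bias_window:])
            want_right = rng.random() < p_right
            hi_right = pair.s_r > pair.s_l
            if want_right != hi_right:
                pair = StimulusPair(pair.s_r, pair.s_l)

        choice, rt, source = _simulate_one(agent, pair, rng)

        if pair.s_l > pair.s_r:
            correct_side = "left"
        elif pair.s_r > pair.s_l:
            correct_side = "right"
        else:
            correct_side = "left" if rng.random() < 0.5 else "right"
        correct = choice == correct_side

        if correct:
            reward_ul = float(rew_durs[i]) * config.flow_rate_ul_s
            delay = 0.0
        else:
            reward_ul = 0.0
            delay = config.delay_scheme.delay(rt)

        rows.append({
            "animal_id": animal_id, "session": session, "trial_index": i,
            "s_l": pair.s_l, "s_r": pair.s_r, "correct_side": correct_side,
            "choice": choice, "rt": rt, "correct": correct,
            "iti": float(itis[i]), "delay": delay,
            "reward_ul": reward_ul, "source": source,
        })
        choices_hist.append(choice)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_sessions(agent: ModelParams, config: TaskConfig,
                      animal_id: str = "syn01") -> pd.DataFrame:
    """Generate ``config.sessions`` sessions with the configured seed."""
    rng = np.random.default_rng(config.seed)
    parts = [generate_session(agent, config, rng, animal_id, s)
             for s in range(config.sessions)]
    return pd.concat(parts, ignore_index=True)


def write_trials(trials: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a trial table as CSV (RTs at 6 decimals) plus a JSON sidecar."""
    out = trials.copy()
    for col in ("rt", "iti", "delay"):
        if col in out:
            out[col] = out[col].map(lambda x: f"{x:.6f}")
    out.to_csv(path, index=False)
    if metadata is not None:
        sidecar = str(path) + ".meta.json"
        with open(sidecar, "w") as fh:
            json.dump(metadata, fh, indent=2, default=str)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path)
    if "correct" in df:
        df["correct"] = df["correct"].astype(bool)
    return df
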