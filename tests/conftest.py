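import collections

import numpy as np
import pandas as pd

from trdm import simulate_trials
from trdm.task import contrast_grid


def make_trials(agent, n, seed):
    """Simulate n trials with stimuli drawn uniformly from the 36-pair
    contrast grid (no session scheduling)."""
    rng = np.random.default_rng(seed)
    grid = contrast_grid()
    idx = rng.integers(len(grid), size=n)
    parts = [simulate_trials(agent, grid[g], rng, c)
             for g, c in sorted(collections.Counter(idx).items())]
    return pd.concat(parts, ignore_index=True)
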