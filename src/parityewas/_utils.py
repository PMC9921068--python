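"""Small numeric helpers shared across modules."""
from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

BETA_EPS = 1e-6


def clip_beta(x, eps: float = BETA_EPS):
    """Clip methylation fractions into the open unit interval."""
    return np.clip(x, eps, 1.0 - eps)


def beta_logit(x):
    return logit(clip_beta(x))


def logistic(x):
    return expit(x)


def rng_for(seed: int, *stream) -> np.random.Generator:
    """A dedicated generator for one simulation stage.

    Seeding each stage from (seed, stream) keeps any one stage's draws
    stable when unrelated stages are toggled on or off.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])
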