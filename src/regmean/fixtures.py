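"""Synthetic fixture datasets emulating two published study structures.

Neither original participant-level dataset is publicly deposited, so
these generators produce synthetic stand-ins that reproduce the summary
*structure* the reanalyses operate on — sample size, measurement scales,
and the published selection counts — not the actual data values.

``smyth-like``: a contextual-cuing-style dataset.  40 participants, a
performance score X in ms (search-time advantage for repeated displays,
positive group mean), and a 4-alternative generation test scored as
proportion correct (chance 0.25) split into two 24-trial halves Y1/Y2;
exactly 14 of 40 participants score at or below chance on Y1.

``sklar-like``: a CFS subliminal-arithmetic-style dataset.  42
participants, priming X in ms, and a forced-choice awareness score
Y = proportion correct − 0.5 (chance 0); exactly 34 of 42 score above
chance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import BivariateSample

__all__ = ["generate_fixture"]

_SMYTH_N = 40
_SMYTH_TRIALS = 24          # generation trials per half (2 blocks x 12)
_SMYTH_CHANCE = 0.25        # 4-alternative generation
_SMYTH_AT_OR_BELOW = 14     # records with Y1 <= chance

_SKLAR_N = 42
_SKLAR_TRIALS = 24          # forced-choice awareness trials
_SKLAR_ABOVE = 34           # records with Y > 0 (proportion correct > .5)


def _force_count_at_or_below(k: np.ndarray, bound: int, target: int) -> np.ndarray:
    """Minimally adjust integer scores so exactly ``target`` of them are
    <= ``bound``.  Moves the records closest to the boundary, stable in
    input order, so the repair is deterministic."""
    k = k.copy()
    low = np.flatnonzero(k <= bound)
    if len(low) > target:
        # raise the highest-scoring offenders just past the bound
        order = low[np.argsort(k[low], kind="stable")]
        for i in order[::-1][: len(low) - target]:
            k[i] = bound + 1
    elif len(low) < target:
        high = np.flatnonzero(k > bound)
        order = high[np.argsort(k[high], kind="stable")]
        for i in order[: target - len(low)]:
            k[i] = bound
    return k


def _smyth_like(rng: np.random.Generator) -> pd.DataFrame:
    # latent learning signal; weakly coupled to generation accuracy so the
    # sample X-Y correlation is small, as in contextual cuing data
    s = rng.normal(1.0, 1.0, _SMYTH_N)
    e_x = rng.normal(0.0, 1.0, _SMYTH_N)
    x = 80.0 * s + 110.0 * e_x
    p_true = np.clip(0.31 + 0.03 * (s - 1.0), 0.05, 0.95)
    k1 = rng.binomial(_SMYTH_TRIALS, p_true)
    k2 = rng.binomial(_SMYTH_TRIALS, p_true)
    bound = int(_SMYTH_CHANCE * _SMYTH_TRIALS)  # 6/24 correct == chance
    k1 = _force_count_at_or_below(k1, bound, _SMYTH_AT_OR_BELOW)
    y1 = k1 / _SMYTH_TRIALS
    y2 = k2 / _SMYTH_TRIALS
    return pd.DataFrame({"id": np.arange(_SMYTH_N), "x": x, "y": y1,
                         "y1": y1, "y2": y2})


def _sklar_like(rng: np.random.Generator) -> pd.DataFrame:
    s = rng.normal(1.0, 0.5, _SKLAR_N)
    e_x = rng.normal(0.0, 1.0, _SKLAR_N)
    x = 18.0 * s + 24.0 * e_x
    p_true = np.clip(0.5 + 0.12 * s, 0.05, 0.95)
    k = rng.binomial(_SKLAR_TRIALS, p_true)
    bound = _SKLAR_TRIALS // 2  # 12/24 correct == chance
    # exactly _SKLAR_ABOVE strictly above chance <=> n - above at or below
    k = _force_count_at_or_below(k, bound, _SKLAR_N - _SKLAR_ABOVE)
    y = k / _SKLAR_TRIALS - 0.5
    return pd.DataFrame({"id": np.arange(_SKLAR_N), "x": x, "y": y})


def generate_fixture(kind: str, seed: int) -> BivariateSample:
    """Generate a seeded synthetic fixture; ``kind`` is "smyth-like" or
    "sklar-like".  Different seeds give different values but an
    identical schema and the same published selection count."""
    rng = np.random.default_rng(seed)
    if kind == "smyth-like":
        return BivariateSample(_smyth_like(rng))
    if kind == "sklar-like":
        return BivariateSample(_sklar_like(rng))
    raise ValueError(f"unknown fixture kind: {kind!r} "
                     "(expected 'smyth-like' or 'sklar-like')")
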