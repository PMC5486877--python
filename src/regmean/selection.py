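"""Post hoc selection procedures: cutoff selection, per-participant
binomial-test classification, and quantile partitioning.

These implement the analytic practices under audit -- retaining only the
participants (or trials) whose awareness score falls at or below a
chance cutoff, or whose score is not significantly above chance -- so
that the diagnostics module can quantify how much of the selected
subgroup's performance is attributable to regression to the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .models import BivariateSample

__all__ = [
    "SelectionResult",
    "AwarenessClassification",
    "select_by_cutoff",
    "classify_by_binomial_test",
    "partition_quantiles",
    "t_ci",
    "bootstrap_ci",
]

Direction = Literal["at-or-below", "above"]


def t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Student-t confidence interval for a mean; (nan, nan) when n < 2."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        return (float("nan"), float("nan"))
    m = values.mean()
    se = values.std(ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.5 + level / 2, df=n - 1) * se
    return (float(m - half), float(m + half))


def bootstrap_ci(values: np.ndarray, seed: int, level: float = 0.95,
                 n_boot: int = 2000) -> tuple[float, float]:
    """Seeded percentile-bootstrap interval for a mean."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [0.5 - level / 2, 0.5 + level / 2])
    return (float(lo), float(hi))


@dataclass
class SelectionResult:
    """Partition of a sample at a cutoff on Y, with subgroup summaries."""

    cutoff: float
    direction: Direction
    selected_ids: np.ndarray
    n_selected: int
    n_total: int
    mean_x_selected: float
    mean_y_selected: float
    ci_x_selected: tuple[float, float]
    ci_y_selected: tuple[float, float]
    mean_x_all: float
    mean_y_all: float

    @property
    def empty(self) -> bool:
        return self.n_selected == 0

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "direction": self.direction,
            "n_selected": self.n_selected,
            "n_total": self.n_total,
            "selected_ids": [int(i) if isinstance(i, (int, np.integer)) else i
                             for i in self.selected_ids.tolist()],
            "mean_x_selected": self.mean_x_selected,
            "mean_y_selected": self.mean_y_selected,
            "ci_x_selected": list(self.ci_x_selected),
            "ci_y_selected": list(self.ci_y_selected),
            "mean_x_all": self.mean_x_all,
            "mean_y_all": self.mean_y_all,
        }


def selection_mask(y: np.ndarray, cutoff: float, direction: Direction) -> np.ndarray:
    """Boolean mask of records meeting the cutoff; ties are included on
    the at-or-below side (a score exactly at chance counts as unaware)."""
    y = np.asarray(y, dtype=float)
    if direction == "at-or-below":
        return y <= cutoff
    if direction == "above":
        return y > cutoff
    raise ValueError(f"unknown direction: {direction!r}")


def select_by_cutoff(sample: BivariateSample, cutoff: float,
                     direction: Direction = "at-or-below",
                     ci_method: str = "t", seed: int = 0) -> SelectionResult:
    """Select the subgroup at one extreme of Y and summarize it.

    An empty subgroup is a flagged result (``n_selected == 0``, NaN
    summaries), not an exception, because real cutoffs routinely select
    nobody.  ``ci_method`` is "t" (default) or "bootstrap" (seeded).
    """
    if len(sample) == 0:
        raise ValueError("cannot select from an empty sample")
    mask = selection_mask(sample.y, cutoff, direction)
    x_sel = sample.x[mask]
    y_sel = sample.y[mask]
    if ci_method == "t":
        ci_x, ci_y = t_ci(x_sel), t_ci(y_sel)
    elif ci_method == "bootstrap":
        ci_x = bootstrap_ci(x_sel, seed=seed)
        ci_y = bootstrap_ci(y_sel, seed=seed + 1)
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")
    return SelectionResult(
        cutoff=cutoff,
        direction=direction,
        selected_ids=sample.data["id"].to_numpy()[mask],
        n_selected=int(mask.sum()),
        n_total=len(sample),
        mean_x_selected=float(x_sel.mean()) if mask.any() else float("nan"),
        mean_y_selected=float(y_sel.mean()) if mask.any() else float("nan"),
        ci_x_selected=ci_x,
        ci_y_selected=ci_y,
        mean_x_all=float(sample.x.mean()),
        mean_y_all=float(sample.y.mean()),
    )


@dataclass(frozen=True)
class AwarenessClassification:
    """Outcome of a one-sided exact binomial test on one participant."""

    successes: int
    trials: int
    chance_p: float
    alpha: float
    p_value: float
    label: Literal["aware", "unaware"]


def classify_by_binomial_test(k: int, m: int, chance_p: float = 0.5,
                              alpha: float = 0.05) -> AwarenessClassification:
    """Classify a participant as aware iff k successes out of m trials is
    significantly above chance by a one-sided exact binomial test.

    The label is "unaware" iff p >= alpha: failing to reject the null of
    chance-level awareness is (mis)read as absence of awareness, which
    is exactly the practice under audit.
    """
    if not (0 <= k <= m):
        raise ValueError(f"need 0 <= k <= m, got k={k}, m={m}")
    if not 0 < chance_p < 1:
        raise ValueError(f"chance_p must be in (0, 1), got {chance_p}")
    p = float(stats.binomtest(k, m, chance_p, alternative="greater").pvalue)
    return AwarenessClassification(
        successes=k, trials=m, chance_p=chance_p, alpha=alpha,
        p_value=p, label="unaware" if p >= alpha else "aware",
    )


def partition_quantiles(values, k: int) -> np.ndarray:
    """Assign each value a quantile-group index 1..k, lowest group first.

    Groups are as equal in size as possible (sizes differ by at most 1,
    larger groups at the low end); ties across a boundary are broken by
    stable input order, so the partition is deterministic and seedless.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot form {k} groups from {n} values")
    order = np.argsort(values, kind="stable")
    indices = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(order, k), start=1):
        indices[chunk] = g
    return indices
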