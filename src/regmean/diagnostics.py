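"""Audit machinery for regression-to-the-mean artifacts.

Given a bivariate sample and a selection rule, these tools quantify how
much of a selected subgroup's performance is expected from regression to
the mean alone.  The central identity: in z-score space the predicted
performance of a subgroup selected on awareness is

    z(X) = r · z(Y),

so a subgroup whose mean z(Y) is −1.0 in a sample with r = 0.3 is
expected to sit at z(X) = −0.30 — much closer to the group mean — even
when the latent process behind X and Y is one and the same.  The tests
here compare observed subgroup performance against that prediction, draw
Galton squeeze diagrams, check the implied ordering of subgroup means,
and run the split-half retest check (a subgroup selected for low scores
on one half of a measure should, under regression, score higher on the
independent second half).

Conventions fixed across the module: sample SDs use the n−1 denominator;
confidence intervals are Student-t on the relevant mean (a seeded
percentile bootstrap is available through the selection module);
correlations are Pearson's r, the quantity the regression identity is
stated in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .models import BivariateSample
from .selection import partition_quantiles, selection_mask, t_ci

__all__ = [
    "SqueezeDiagram",
    "RegressionDiagnosis",
    "OrderingReport",
    "RetestReport",
    "z_transform",
    "galton_squeeze",
    "regression_expectation",
    "regression_artifact_test",
    "ordering_check",
    "retest_regression_test",
    "split_half_reliability",
]

Direction = Literal["at-or-below", "above"]


def _zscores(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-transform a variable with zero SD")
    return (v - v.mean()) / sd


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        raise ValueError("correlation needs at least 2 records")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("correlation undefined for zero-SD variable")
    return float(np.corrcoef(x, y)[0, 1])


def z_transform(sample: BivariateSample) -> BivariateSample:
    """Return a copy of the sample with x and y in z units.

    Each variable is centered by its sample mean and scaled by its
    sample SD (n−1 denominator).  The transformation is affine per
    variable, so the sample correlation is unchanged.  Latent and
    split-half columns are carried over untouched.
    """
    if len(sample) < 2:
        raise ValueError("z-transform needs at least 2 records")
    data = sample.data.copy()
    data["x"] = _zscores(sample.x)
    data["y"] = _zscores(sample.y)
    return BivariateSample(data)


@dataclass
class SqueezeDiagram:
    """Per-band mean z of the partition variable and its companion.

    The funnel (bands extreme on the partition variable pair with less
    extreme companion means) is regression to the mean made visible.
    """

    partition_on: Literal["x", "y"]
    bands: pd.DataFrame  # columns: band, mean_z_partition, mean_z_companion, n

    def to_csv(self, path) -> None:
        self.bands.to_csv(path, index=False)

    def band(self, i: int) -> tuple[float, float]:
        row = self.bands.loc[self.bands["band"] == i].iloc[0]
        return float(row["mean_z_partition"]), float(row["mean_z_companion"])


def galton_squeeze(sample: BivariateSample, partition_on: Literal["x", "y"] = "y",
                   k: int = 4) -> SqueezeDiagram:
    """Build a Galton squeeze diagram: z-transform, partition one variable
    into k quantile bands, and take per-band means of both z variables."""
    if partition_on not in ("x", "y"):
        raise ValueError(f"partition_on must be 'x' or 'y', got {partition_on!r}")
    zs = z_transform(sample)
    part = zs.x if partition_on == "x" else zs.y
    comp = zs.y if partition_on == "x" else zs.x
    idx = partition_quantiles(part, k)
    rows = []
    for band in range(1, k + 1):
        m = idx == band
        rows.append({
            "band": band,
            "mean_z_partition": float(part[m].mean()),
            "mean_z_companion": float(comp[m].mean()),
            "n": int(m.sum()),
        })
    return SqueezeDiagram(partition_on=partition_on, bands=pd.DataFrame(rows))


def regression_expectation(r: float, mean_zY_selected: float) -> float:
    """Predicted subgroup mean z(X) from regression to the mean alone:
    r × mean z(Y | selected)."""
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    return r * mean_zY_selected


@dataclass
class RegressionDiagnosis:
    """Observed vs regression-predicted performance of a selected subgroup."""

    cutoff: float
    direction: Direction
    n_selected: int
    r: float
    mean_zY_selected: float
    predicted_zX: float
    observed_zX: float
    ci_zX: tuple[float, float]
    verdict: Literal["consistent-with-regression", "exceeds-regression",
                     "below-regression"]

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "direction": self.direction,
            "n_selected": self.n_selected,
            "r": self.r,
            "mean_zY_selected": self.mean_zY_selected,
            "predicted_zX": self.predicted_zX,
            "observed_zX": self.observed_zX,
            "ci_zX": list(self.ci_zX),
            "verdict": self.verdict,
        }


def regression_artifact_test(sample: BivariateSample, cutoff: float,
                             direction: Direction = "at-or-below",
                             ) -> RegressionDiagnosis:
    """Test whether a selected subgroup's performance exceeds the level
    regression to the mean alone predicts.

    Computes the sample r, the subgroup's mean z(Y), the prediction
    r·mean z(Y|selected), and the observed subgroup mean z(X) with a 95%
    t-interval.  The verdict is three-valued: "consistent" when the
    prediction lies inside the CI, "exceeds-regression" when the whole
    CI sits above it (candidate true effect), "below-regression" when
    the whole CI sits below (over-shrunk).  Only "exceeds" would lend
    any support to a performance effect beyond the selection artifact.
    """
    if len(sample) < 3:
        raise ValueError("diagnosis needs at least 3 records")
    zs = z_transform(sample)
    r = _pearson(zs.x, zs.y)
    # mask on the raw scale so boundary ties resolve exactly
    mask = selection_mask(sample.y, cutoff, direction)
    if not mask.any():
        raise ValueError(f"cutoff {cutoff} selects an empty subgroup")
    mean_zy = float(zs.y[mask].mean())
    predicted = regression_expectation(r, mean_zy)
    observed = float(zs.x[mask].mean())
    ci = t_ci(zs.x[mask])
    if np.isnan(ci[0]) or ci[0] <= predicted <= ci[1]:
        verdict = "consistent-with-regression"
    elif predicted < ci[0]:
        verdict = "exceeds-regression"
    else:
        verdict = "below-regression"
    return RegressionDiagnosis(
        cutoff=cutoff, direction=direction, n_selected=int(mask.sum()),
        r=r, mean_zY_selected=mean_zy, predicted_zX=predicted,
        observed_zX=observed, ci_zX=ci, verdict=verdict,
    )


@dataclass
class OrderingReport:
    """Relative ordering of mean z(X) in the above/all/below partitions."""

    cutoff: float
    r: float
    zX_above: float
    zX_all: float
    zX_below: float
    consistent: bool

    def to_dict(self) -> dict:
        return {"cutoff": self.cutoff, "r": self.r, "zX_above": self.zX_above,
                "zX_all": self.zX_all, "zX_below": self.zX_below,
                "consistent": self.consistent}


def ordering_check(sample: BivariateSample, cutoff: float) -> OrderingReport:
    """Check the ordering z(X|Y>c) > z(X) > z(X|Y<=c) implied by r > 0.

    With positive r the subgroup above the awareness cutoff should also
    lead on performance and the subgroup at or below it should trail,
    the group mean in between (mirrored for negative r).  A violation in
    real data — e.g. the "unaware" subgroup out-performing the whole
    group — is attributable to sampling error if regression is the only
    process operating, and is worth surfacing.
    """
    zs = z_transform(sample)
    below = selection_mask(sample.y, cutoff, "at-or-below")
    above = ~below
    if not below.any() or not above.any():
        raise ValueError(f"cutoff {cutoff} leaves an empty subgroup")
    r = _pearson(zs.x, zs.y)
    zx_above = float(zs.x[above].mean())
    zx_all = float(zs.x.mean())
    zx_below = float(zs.x[below].mean())
    if r >= 0:
        consistent = zx_above > zx_all > zx_below
    else:
        consistent = zx_above < zx_all < zx_below
    return OrderingReport(cutoff=cutoff, r=r, zX_above=zx_above, zX_all=zx_all,
                          zX_below=zx_below, consistent=consistent)


def split_half_reliability(y1, y2) -> float:
    """Split-half reliability: Pearson correlation of the two half scores."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if len(y1) != len(y2):
        raise ValueError("y1 and y2 must have equal length")
    if len(y1) < 3:
        raise ValueError("reliability needs at least 3 pairs")
    return _pearson(y1, y2)


@dataclass
class RetestReport:
    """Test-1 vs Test-2 awareness of a subgroup selected on Test 1.

    Under regression to the mean, a subgroup selected for extreme low
    Test-1 scores is expected to improve on the independent Test 2 (and
    a high-score subgroup to drop); under the "true (un)awareness"
    assumption the change should be nil.
    """

    cutoff: float
    direction: Direction
    select_on: Literal["y1", "y2"]
    n_selected: int
    mean_test1_selected: float
    mean_test2_selected: float
    mean_change: float
    ci_change: tuple[float, float]
    n_improved: int
    n_worsened: int
    n_tied: int
    reliability: float

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "direction": self.direction,
            "select_on": self.select_on,
            "n_selected": self.n_selected,
            "mean_test1_selected": self.mean_test1_selected,
            "mean_test2_selected": self.mean_test2_selected,
            "mean_change": self.mean_change,
            "ci_change": list(self.ci_change),
            "n_improved": self.n_improved,
            "n_worsened": self.n_worsened,
            "n_tied": self.n_tied,
            "reliability": self.reliability,
        }


def retest_regression_test(sample: BivariateSample, cutoff: float,
                           direction: Direction = "at-or-below",
                           select_on: Literal["y1", "y2"] = "y1",
                           ) -> RetestReport:
    """Select on one awareness half and measure the change on the other.

    The change is (other half − selecting half) for the selected
    subgroup, with a 95% paired t-interval and improved/worsened/tied
    counts.  ``select_on="y2"`` runs the mirrored variant (regression is
    bidirectional, so the mirrored change has the same expected size).
    Also reports the split-half reliability over the whole sample.
    """
    if not sample.has_retest:
        raise ValueError("sample has no split-half columns y1/y2")
    if select_on not in ("y1", "y2"):
        raise ValueError(f"select_on must be 'y1' or 'y2', got {select_on!r}")
    sel_col, other_col = (("y1", "y2") if select_on == "y1" else ("y2", "y1"))
    sel = sample.column(sel_col)
    other = sample.column(other_col)
    mask = selection_mask(sel, cutoff, direction)
    if not mask.any():
        raise ValueError(f"cutoff {cutoff} selects an empty subgroup on {select_on}")
    change = other[mask] - sel[mask]
    return RetestReport(
        cutoff=cutoff, direction=direction, select_on=select_on,
        n_selected=int(mask.sum()),
        mean_test1_selected=float(sel[mask].mean()),
        mean_test2_selected=float(other[mask].mean()),
        mean_change=float(change.mean()),
        ci_change=t_ci(change),
        n_improved=int((change > 0).sum()),
        n_worsened=int((change < 0).sum()),
        n_tied=int((change == 0).sum()),
        reliability=split_half_reliability(sample.column("y1"),
                                           sample.column("y2")),
    )
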