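"""Closed-form population quantities for the generative models.

These are the exact Gaussian results the simulators converge to: the
population moments implied by a model spec, truncated-normal subgroup
means under cutoff selection (via the inverse Mills ratio), band means
of the standard normal, the Bernoulli-threshold probabilities of the
binary-report model, and the true-score shrinkage of a subgroup selected
on a noisy observed score.

They serve two roles: ground truth for the Monte Carlo simulators in
tests, and the expected-value side of the regression diagnostics (the
z(X) = r·z(Y) prediction evaluated at the population level).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .models import BinaryModelSpec, LinearCommonSourceSpec

__all__ = [
    "PopulationMoments",
    "SelectionExpectation",
    "BinaryProbabilities",
    "TrueScoreSelection",
    "linear_model_moments",
    "dual_factor_moments",
    "selected_mean_expectation",
    "standard_normal_band_mean",
    "binary_model_probabilities",
    "true_score_selected_mean",
]

Direction = Literal["at-or-below", "above"]


@dataclass(frozen=True)
class PopulationMoments:
    """Population mean/SD of X and Y, their correlation, and Y's reliability."""

    mean_X: float
    sd_X: float
    mean_Y: float
    sd_Y: float
    r: float
    reliability_Y: float

    def __post_init__(self) -> None:
        if self.sd_X < 0 or self.sd_Y < 0:
            raise ValueError("standard deviations must be >= 0")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if not -1e-12 <= self.reliability_Y <= 1 + 1e-12:
            raise ValueError("reliability must be in [0, 1]")


@dataclass(frozen=True)
class SelectionExpectation:
    """Expected subgroup quantities under a single-variable cutoff."""

    cutoff: float
    direction: Direction
    selection_probability: float
    mean_Y_selected: float
    mean_X_selected: float
    mean_zY_selected: float
    mean_zX_selected: float


@dataclass(frozen=True)
class BinaryProbabilities:
    p_seen: float
    p_S1_given_seen: float
    p_S1_given_unseen: float
    mean_X_seen: float
    mean_X_unseen: float


@dataclass(frozen=True)
class TrueScoreSelection:
    mean_observed_selected: float
    mean_true_selected: float


def linear_model_moments(spec: LinearCommonSourceSpec) -> PopulationMoments:
    """Exact moments of the linear common-source model.

    mean_X = a·mu_S, sd_X = sqrt(a²σ_S² + σ_eX²) (analogously for Y with
    the intercept added to the mean), r = a·c·σ_S²/(sd_X·sd_Y), and the
    reliability of Y is the fraction of Y's variance carried by the
    latent signal, c²σ_S²/sd_Y².

    Raises ValueError when either SD is zero (r undefined).
    """
    mean_x = spec.weight_X * spec.mu_S
    mean_y = spec.weight_Y * spec.mu_S + spec.intercept_Y
    var_x = spec.weight_X**2 * spec.sigma_S**2 + spec.sigma_eX**2
    var_y = spec.weight_Y**2 * spec.sigma_S**2 + spec.sigma_eY**2
    if var_x == 0 or var_y == 0:
        raise ValueError("degenerate model: sd_X or sd_Y is zero, r undefined")
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)
    r = spec.weight_X * spec.weight_Y * spec.sigma_S**2 / (sd_x * sd_y)
    reliability = spec.weight_Y**2 * spec.sigma_S**2 / var_y
    return PopulationMoments(mean_x, sd_x, mean_y, sd_y, r, reliability)


def dual_factor_moments(spec) -> PopulationMoments:
    """Exact moments of the dual-factor model (common + unique factors)."""
    var_c = spec.weight_C**2 * spec.sigma_C**2
    var_x = var_c + spec.weight_UX**2 * spec.sigma_UX**2 + spec.sigma_eX**2
    var_y = var_c + spec.weight_UY**2 * spec.sigma_UY**2 + spec.sigma_eY**2
    if var_x == 0 or var_y == 0:
        raise ValueError("degenerate model: sd_X or sd_Y is zero, r undefined")
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)
    mean = spec.weight_C * spec.mu_C
    r = var_c / (sd_x * sd_y)
    reliability = (var_c + spec.weight_UY**2 * spec.sigma_UY**2) / var_y
    return PopulationMoments(mean, sd_x, mean, sd_y, r, reliability)


def selected_mean_expectation(moments: PopulationMoments, cutoff: float,
                              direction: Direction = "at-or-below",
                              ) -> SelectionExpectation:
    """Expected subgroup means after selecting on a cutoff applied to Y.

    For at-or-below selection the standardized cutoff is
    z_c = (c − mean_Y)/sd_Y and the selected mean of z(Y) is the lower
    truncated-normal mean −φ(z_c)/Φ(z_c) (the negative inverse Mills
    ratio); for above-selection it is φ(z_c)/(1 − Φ(z_c)).  The selected
    mean of z(X) follows from the regression identity z(X) = r·z(Y)
    applied at the population level; raw-scale means de-standardize.
    """
    if moments.sd_Y <= 0:
        raise ValueError("selection requires sd_Y > 0")
    z_c = (cutoff - moments.mean_Y) / moments.sd_Y
    if direction == "at-or-below":
        p_sel = stats.norm.cdf(z_c)
        if p_sel <= 0:
            raise ValueError(f"cutoff {cutoff} selects with probability 0")
        mean_zy = -stats.norm.pdf(z_c) / p_sel
    elif direction == "above":
        p_sel = stats.norm.sf(z_c)
        if p_sel <= 0:
            raise ValueError(f"cutoff {cutoff} selects with probability 0")
        mean_zy = stats.norm.pdf(z_c) / p_sel
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    mean_zx = moments.r * mean_zy
    return SelectionExpectation(
        cutoff=cutoff,
        direction=direction,
        selection_probability=float(p_sel),
        mean_Y_selected=float(moments.mean_Y + moments.sd_Y * mean_zy),
        mean_X_selected=float(moments.mean_X + moments.sd_X * mean_zx),
        mean_zY_selected=float(mean_zy),
        mean_zX_selected=float(mean_zx),
    )


def standard_normal_band_mean(lower_quantile: float, upper_quantile: float) -> float:
    """Mean of a standard normal restricted between two of its quantiles.

    E[z | q_lo <= F(z) <= q_hi] = (φ(z_lo) − φ(z_hi)) / (q_hi − q_lo),
    the doubly-truncated-normal mean.  The full band (0, 1) gives 0; the
    top quartile gives ≈ 1.271.
    """
    if not 0 <= lower_quantile < upper_quantile <= 1:
        raise ValueError("need 0 <= lower < upper <= 1 with a non-empty band")
    z_lo = stats.norm.ppf(lower_quantile)
    z_hi = stats.norm.ppf(upper_quantile)
    phi_lo = 0.0 if np.isinf(z_lo) else stats.norm.pdf(z_lo)
    phi_hi = 0.0 if np.isinf(z_hi) else stats.norm.pdf(z_hi)
    return float((phi_lo - phi_hi) / (upper_quantile - lower_quantile))


def binary_model_probabilities(spec: BinaryModelSpec) -> BinaryProbabilities:
    """Exact seen/unseen probabilities and conditional performance means.

    With report noise (w_Y > 0), P(seen | S=s) = Φ((s − threshold)/w_Y);
    mixing over P(S=1) = p_S and applying Bayes' rule gives P(S=1 | seen)
    and P(S=1 | unseen), hence the conditional performance means
    weight_X · P(S=1 | report).  w_Y = 0 is the deterministic limit where
    the report is simply the thresholding of S itself.
    """
    if spec.w_Y > 0:
        p_seen_s1 = float(stats.norm.cdf((1.0 - spec.threshold) / spec.w_Y))
        p_seen_s0 = float(stats.norm.cdf((0.0 - spec.threshold) / spec.w_Y))
    else:
        p_seen_s1 = 1.0 if 1.0 >= spec.threshold else 0.0
        p_seen_s0 = 1.0 if 0.0 >= spec.threshold else 0.0
    p1 = spec.p_S
    p_seen = p1 * p_seen_s1 + (1 - p1) * p_seen_s0
    p_unseen = 1.0 - p_seen
    p_s1_seen = p1 * p_seen_s1 / p_seen if p_seen > 0 else 0.0
    p_s1_unseen = p1 * (1 - p_seen_s1) / p_unseen if p_unseen > 0 else 0.0
    return BinaryProbabilities(
        p_seen=p_seen,
        p_S1_given_seen=p_s1_seen,
        p_S1_given_unseen=p_s1_unseen,
        mean_X_seen=spec.weight_X * p_s1_seen,
        mean_X_unseen=spec.weight_X * p_s1_unseen,
    )


def true_score_selected_mean(mu: float, sigma_true: float, sigma_error: float,
                             lower_quantile: float = 0.75,
                             upper_quantile: float = 1.0) -> TrueScoreSelection:
    """Observed and true means of a subgroup selected on the observed score.

    The observed score is O = T + e with T ~ N(mu, sigma_true) and
    e ~ N(0, sigma_error).  Selecting the band of O between two of its
    quantiles, the observed subgroup mean is mu + sd_O·m_band while the
    true-score mean shrinks toward mu by the reliability factor
    sigma_true²/sd_O²: the gap between the two is the bias that selecting
    and estimating on the same noisy measure produces.
    """
    if sigma_true < 0 or sigma_error < 0:
        raise ValueError("standard deviations must be >= 0")
    var_o = sigma_true**2 + sigma_error**2
    if var_o == 0:
        raise ValueError("degenerate: observed score has zero variance")
    sd_o = np.sqrt(var_o)
    m_band = standard_normal_band_mean(lower_quantile, upper_quantile)
    shrink = sigma_true**2 / var_o
    return TrueScoreSelection(
        mean_observed_selected=float(mu + sd_o * m_band),
        mean_true_selected=float(mu + shrink * sd_o * m_band),
    )
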