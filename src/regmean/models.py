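"""Generative models for bivariate performance/awareness data.

All models share one idea: a single latent source ``S`` drives both an
indirect performance measure ``X`` (e.g. priming in ms) and a direct
awareness measure ``Y`` (e.g. forced-choice proportion correct minus
chance).  Dispersion around the latent source comes from independent
Gaussian measurement noise, so ``X`` and ``Y`` are imperfectly
correlated and any subgroup selected on an extreme of ``Y`` regresses
toward the mean on ``X``.  None of the models can produce above-chance
performance when the latent signal is truly absent: the artifact they
exhibit under post hoc selection is purely statistical.

Simulators keep the latent draws (``S``, ``e_X``, ``e_Y``) alongside the
observed scores so that the error-bias bookkeeping behind the artifact
(which participants were "captured" by an extreme noise draw) can be
reconstructed exactly.

Seeding contract: each simulator consumes a single integer seed through
``numpy.random.default_rng`` and draws its variates in a fixed,
documented order -- ``S`` first, then ``e_X``, then ``e_Y`` (then the
second split-half noise for retest simulations).  Identical
``(spec, n, seed)`` therefore yields bit-identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "LinearCommonSourceSpec",
    "DualFactorSpec",
    "MixtureSpec",
    "BinaryModelSpec",
    "BivariateSample",
    "TrialSample",
    "simulate_linear_common_source",
    "simulate_dual_factor",
    "simulate_mixture",
    "simulate_binary_trials",
    "simulate_retest",
    "spec_to_dict",
    "spec_from_dict",
]

def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")


def _check_n(n: int) -> None:
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")


@dataclass(frozen=True)
class LinearCommonSourceSpec:
    """Linear common-source model X = a·S + σ_eX·e_X, Y = c·S + σ_eY·e_Y + b.

    ``S ~ N(mu_S, sigma_S)`` is the shared latent signal; ``e_X`` and
    ``e_Y`` are independent standard normal noises.  ``sigma_eX`` and
    ``sigma_eY`` absorb any printed noise scale (a "30 e_X" term with
    unit-SD e becomes ``sigma_eX=30``).  ``intercept_Y`` shifts the
    awareness scale (used e.g. for the aware subpopulation of a mixture).
    """

    mu_S: float = 1.0
    sigma_S: float = 1.0
    weight_X: float = 100.0
    sigma_eX: float = 30.0
    weight_Y: float = 0.3
    sigma_eY: float = 1.0
    intercept_Y: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_S", "sigma_eX", "sigma_eY"):
            _check_nonneg(name, getattr(self, name))


#: The two worked parameterizations used throughout: a contextual-cuing-style
#: group (priming ~100 ms, awareness d'-like around 0.3) and a CFS
#: subliminal-arithmetic-style group (priming ~18 ms, forced-choice
#: proportion correct minus chance around 0.12).
CANONICAL_SPEC = LinearCommonSourceSpec()
SKLAR_SPEC = LinearCommonSourceSpec(
    mu_S=1.0, sigma_S=0.5, weight_X=18.0, sigma_eX=24.0,
    weight_Y=0.12, sigma_eY=0.04,
)


@dataclass(frozen=True)
class DualFactorSpec:
    """Two-factor model with a common factor plus test-unique factors.

    X = w_C·C + w_UX·U_X + σ_eX·e_X and Y = w_C·C + w_UY·U_Y + σ_eY·e_Y,
    with C ~ N(mu_C, sigma_C) shared, and U_X ~ N(0, sigma_UX),
    U_Y ~ N(0, sigma_UY) constant within a participant but independent
    across the two measures.  With the unique factors switched off
    (sigma_UX = sigma_UY = 0) this reduces exactly to the common-source
    model.
    """

    mu_C: float = 1.0
    sigma_C: float = 1.0
    sigma_UX: float = 1.0
    sigma_UY: float = 1.0
    weight_C: float = 1.0
    weight_UX: float = 1.0
    weight_UY: float = 1.0
    sigma_eX: float = 1.0
    sigma_eY: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma_C", "sigma_UX", "sigma_UY", "sigma_eX", "sigma_eY"):
            _check_nonneg(name, getattr(self, name))


@dataclass(frozen=True)
class MixtureSpec:
    """Two labelled subpopulations, each its own linear common-source model.

    The canonical use is a truly-aware subgroup (Y = 2 + S + e_Y) mixed
    with a truly-unaware subgroup whose awareness is pure noise
    (Y = e_Y, i.e. weight_Y = 0).
    """

    aware_spec: LinearCommonSourceSpec
    unaware_spec: LinearCommonSourceSpec
    n_aware: int = 100
    n_unaware: int = 100

    def __post_init__(self) -> None:
        if self.n_aware < 0 or self.n_unaware < 0:
            raise ValueError("subgroup sizes must be >= 0")
        if self.n_aware + self.n_unaware < 1:
            raise ValueError("mixture must contain at least one participant")


def canonical_mixture_spec(n_aware: int = 100, n_unaware: int = 100) -> MixtureSpec:
    """The canonical aware/unaware mixture: X = S + e_X for both groups,
    Y = 2 + S + e_Y for the aware group, Y = e_Y for the unaware group,
    with S ~ N(1, 1)."""
    aware = LinearCommonSourceSpec(mu_S=1, sigma_S=1, weight_X=1, sigma_eX=1,
                                   weight_Y=1, sigma_eY=1, intercept_Y=2)
    unaware = LinearCommonSourceSpec(mu_S=1, sigma_S=1, weight_X=1, sigma_eX=1,
                                     weight_Y=0, sigma_eY=1, intercept_Y=0)
    return MixtureSpec(aware_spec=aware, unaware_spec=unaware,
                       n_aware=n_aware, n_unaware=n_unaware)


@dataclass(frozen=True)
class BinaryModelSpec:
    """Trial-level binary-report model.

    The latent per-trial state S ~ Bernoulli(p_S) drives a continuous
    performance value X = weight_X·S + sigma_eX·e_X and a binary report
    "seen" iff S + w_Y·e_Y >= threshold.  With w_Y = 0 the report equals
    the latent state on every trial; larger w_Y produces more "capture"
    trials whose report disagrees with the state.
    """

    p_S: float = 0.5
    weight_X: float = 100.0
    sigma_eX: float = 30.0
    w_Y: float = 1.0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_S <= 1.0:
            raise ValueError(f"p_S must be in [0, 1], got {self.p_S}")
        _check_nonneg("sigma_eX", self.sigma_eX)
        _check_nonneg("w_Y", self.w_Y)


@dataclass
class BivariateSample:
    """Per-participant bivariate records backed by a pandas DataFrame.

    Required columns: ``id``, ``x``, ``y``.  Optional: split-half
    awareness ``y1``/``y2`` (present for all records or none), latents
    ``s``/``e_x``/``e_y``, and a ``subpop`` label for mixture data.
    """

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ("id", "x", "y")
    OPTIONAL = ("y1", "y2", "s", "e_x", "e_y", "subpop")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"sample missing required columns: {missing}")
        have = [c for c in ("y1", "y2") if c in self.data.columns]
        if len(have) == 1:
            raise ValueError("split-half columns y1 and y2 must both be "
                             f"present or both absent; found only {have[0]}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def x(self) -> np.ndarray:
        return self.data["x"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy(dtype=float)

    @property
    def has_retest(self) -> bool:
        return "y1" in self.data.columns

    @property
    def has_latents(self) -> bool:
        return "s" in self.data.columns

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass
class TrialSample:
    """Per-trial records for the binary-report model.

    Columns: ``trial``, ``report`` ("seen"/"unseen"), ``x``; latents
    ``s``/``e_x``/``e_y`` kept when generated here.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        for c in ("trial", "report", "x"):
            if c not in self.data.columns:
                raise ValueError(f"trial sample missing column {c!r}")
        bad = set(self.data["report"].unique()) - {"seen", "unseen"}
        if bad:
            raise ValueError(f"report values must be 'seen'/'unseen', got {bad}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def seen_mask(self) -> np.ndarray:
        return (self.data["report"] == "seen").to_numpy()

    @property
    def x(self) -> np.ndarray:
        return self.data["x"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# simulators

def _draw_linear(spec: LinearCommonSourceSpec, n: int, rng: np.random.Generator,
                 start_id: int = 0, retest: bool = False) -> pd.DataFrame:
    # draw order: S, e_X, e_Y (, e_Y2) -- part of the seeding contract
    s = rng.normal(spec.mu_S, spec.sigma_S, n)
    e_x = rng.normal(0.0, 1.0, n)
    e_y = rng.normal(0.0, 1.0, n)
    x = spec.weight_X * s + spec.sigma_eX * e_x
    y = spec.weight_Y * s + spec.sigma_eY * e_y + spec.intercept_Y
    frame = {"id": np.arange(start_id, start_id + n), "x": x, "y": y}
    if retest:
        e_y2 = rng.normal(0.0, 1.0, n)
        frame["y1"] = y
        frame["y2"] = spec.weight_Y * s + spec.sigma_eY * e_y2 + spec.intercept_Y
    frame.update({"s": s, "e_x": e_x, "e_y": e_y})
    return pd.DataFrame(frame)


def simulate_linear_common_source(spec: LinearCommonSourceSpec, n: int,
                                  seed: int) -> BivariateSample:
    """Simulate ``n`` participants from the linear common-source model."""
    _check_n(n)
    rng = np.random.default_rng(seed)
    return BivariateSample(_draw_linear(spec, n, rng))


def simulate_dual_factor(spec: DualFactorSpec, n: int, seed: int) -> BivariateSample:
    """Simulate from the common-plus-unique-factors model.

    Draw order: common factor C, unique factors U_X and U_Y, then the
    noises e_X and e_Y.  Latent columns stored: ``s`` (= C), ``s_x``,
    ``s_y``, ``e_x``, ``e_y``.
    """
    _check_n(n)
    rng = np.random.default_rng(seed)
    c = rng.normal(spec.mu_C, spec.sigma_C, n)
    u_x = rng.normal(0.0, spec.sigma_UX, n)
    u_y = rng.normal(0.0, spec.sigma_UY, n)
    e_x = rng.normal(0.0, 1.0, n)
    e_y = rng.normal(0.0, 1.0, n)
    x = spec.weight_C * c + spec.weight_UX * u_x + spec.sigma_eX * e_x
    y = spec.weight_C * c + spec.weight_UY * u_y + spec.sigma_eY * e_y
    return BivariateSample(pd.DataFrame({
        "id": np.arange(n), "x": x, "y": y,
        "s": c, "s_x": u_x, "s_y": u_y, "e_x": e_x, "e_y": e_y,
    }))


def simulate_mixture(spec: MixtureSpec, seed: int) -> BivariateSample:
    """Simulate a labelled mixture of aware and unaware subpopulations.

    Aware records come first (ids 0..n_aware-1), then unaware; the
    ``subpop`` label makes the ordering immaterial for analysis.
    """
    rng = np.random.default_rng(seed)
    parts = []
    if spec.n_aware:
        aware = _draw_linear(spec.aware_spec, spec.n_aware, rng)
        aware["subpop"] = "aware"
        parts.append(aware)
    if spec.n_unaware:
        unaware = _draw_linear(spec.unaware_spec, spec.n_unaware, rng,
                               start_id=spec.n_aware)
        unaware["subpop"] = "unaware"
        parts.append(unaware)
    return BivariateSample(pd.concat(parts, ignore_index=True))


def simulate_binary_trials(spec: BinaryModelSpec, n_trials: int,
                           seed: int) -> TrialSample:
    """Simulate per-trial binary reports with a continuous performance value.

    Each trial draws S ~ Bernoulli(p_S), then e_X, then e_Y; the report
    is "seen" iff S + w_Y·e_Y >= threshold (ties count as seen).
    """
    _check_n(n_trials)
    rng = np.random.default_rng(seed)
    s = (rng.random(n_trials) < spec.p_S).astype(float)
    e_x = rng.normal(0.0, 1.0, n_trials)
    e_y = rng.normal(0.0, 1.0, n_trials)
    x = spec.weight_X * s + spec.sigma_eX * e_x
    seen = s + spec.w_Y * e_y >= spec.threshold
    return TrialSample(pd.DataFrame({
        "trial": np.arange(n_trials),
        "report": np.where(seen, "seen", "unseen"),
        "x": x, "s": s, "e_x": e_x, "e_y": e_y,
    }))


def simulate_retest(spec: LinearCommonSourceSpec, n: int, seed: int) -> BivariateSample:
    """Simulate split-half awareness: two scores Y1, Y2 per participant.

    Both halves share the participant's single latent draw S but take
    independent noise draws, so corr(Y1, Y2) estimates the measure's
    reliability.  ``y`` is set to ``y1``.
    """
    _check_n(n)
    rng = np.random.default_rng(seed)
    frame = _draw_linear(spec, n, rng, retest=True)
    frame["y"] = frame["y1"]
    return BivariateSample(frame)


# ---------------------------------------------------------------------------
# JSON (de)serialization with a `model` discriminator

_MODEL_TAGS = {
    "linear": LinearCommonSourceSpec,
    "dual_factor": DualFactorSpec,
    "mixture": MixtureSpec,
    "binary": BinaryModelSpec,
}


def spec_to_dict(spec) -> dict:
    """Serialize a model spec to a plain dict with a ``model`` tag."""
    for tag, cls in _MODEL_TAGS.items():
        if isinstance(spec, cls):
            d = asdict(spec)
            if tag == "mixture":
                d["aware_spec"] = asdict(spec.aware_spec)
                d["unaware_spec"] = asdict(spec.unaware_spec)
            d["model"] = tag
            return d
    raise TypeError(f"not a model spec: {type(spec).__name__}")


def spec_from_dict(d: dict):
    """Inverse of :func:`spec_to_dict`; validates the ``model`` tag."""
    d = dict(d)
    tag = d.pop("model", None)
    if tag not in _MODEL_TAGS:
        raise ValueError(f"unknown or missing model discriminator: {tag!r}")
    cls = _MODEL_TAGS[tag]
    if tag == "mixture":
        d["aware_spec"] = LinearCommonSourceSpec(**d["aware_spec"])
        d["unaware_spec"] = LinearCommonSourceSpec(**d["unaware_spec"])
    try:
        return cls(**d)
    except TypeError as exc:
        raise ValueError(f"invalid fields for model {tag!r}: {exc}") from exc
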