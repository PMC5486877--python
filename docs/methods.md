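# Methods

## The problem

A recurring analytic practice in research on unconscious cognition is
*post hoc data selection*: collect a performance measure X (priming in
ms, a search-time advantage, a skin-conductance response) and an
awareness measure Y (verbal report, forced-choice accuracy, a generation
test) for every participant, then retain only the participants (or
trials, or items) whose awareness score falls at or below chance, and
test whether performance in that "unaware" subgroup exceeds chance.

The difficulty is regression to the mean. Whenever X and Y correlate
imperfectly (|r| < 1), a subgroup selected for extreme scores on Y is
*necessarily* less extreme on X in standardized units. For z-transformed
variables the expected subgroup performance is

    E[z(X) | selection on Y] = r · E[z(Y) | selection on Y],

so an "unaware" subgroup sitting at mean z(Y) = −1.0 in a sample with
r = 0.3 is expected at z(X) = −0.30 — far closer to the group mean — even
when a single latent process drives both measures and no unconscious
channel exists. `regmean` packages (a) generative models that exhibit
this artifact by construction, (b) exact closed-form oracles for what
selection alone predicts, and (c) diagnostics that audit a dataset
against those predictions.

## Generative models

All models share a latent signal and independent Gaussian measurement
noises (mean 0, SD 1 before scaling). Results depend on the induced
correlation, not on distributional form, but Gaussian is the default and
the closed forms below are exact for it.

**Linear common source** (`LinearCommonSourceSpec`):
X = a·S + σ_eX·e_X, Y = c·S + σ_eY·e_Y + b, with S ~ N(μ_S, σ_S).
Two parameterizations are bundled as module constants because they are
used throughout the tests and worked examples:

- `CANONICAL_SPEC`: μ_S = σ_S = 1, a = 100, σ_eX = 30, c = 0.3,
  σ_eY = 1. Emulates a contextual-cuing-style study: mean priming
  100 ms, mean awareness 0.3, population r ≈ 0.275.
- `SKLAR_SPEC`: μ_S = 1, σ_S = 0.5, a = 18, σ_eX = 24, c = 0.12,
  σ_eY = 0.04. Emulates a CFS subliminal-arithmetic study: mean priming
  18 ms, awareness on the proportion-correct-minus-chance scale,
  r ≈ 0.292, awareness reliability ≈ 0.692.

**Dual factor** (`DualFactorSpec`): X and Y each get the common factor
plus a test-unique factor (unconscious/conscious aptitudes, say) plus
noise. Weights default to 1 and factors to standard normal, all
configurable. With unique factors at 0 it reduces exactly to the common
source model; the point of the variant is that regression survives even
when measurement noise is zero, driven by the unique factors instead.

**Mixture** (`MixtureSpec`): labelled aware/unaware subpopulations, each
a linear common-source model (`canonical_mixture_spec()` gives the canonical
version: aware Y = 2 + S + e_Y, unaware Y = e_Y). It demonstrates the
limit of the selection method: even when truly unaware participants
exist, selection output looks the same as under the one-process models,
so the method cannot distinguish them. (Aware records are emitted
first; the `subpop` column makes order immaterial.)

**Binary trials** (`BinaryModelSpec`): per-trial latent state
S ~ Bernoulli(p_S), performance X = a·S + σ_eX·e_X, and a thresholded
report: "seen" iff S + w_Y·e_Y ≥ 0.5 (ties count as seen, matching the
≥ in the defining rule). w_Y = 0 makes the report equal the state; as
w_Y grows, "capture" trials (S = 1 reported unseen) produce artifactual
priming on unseen trials.

**Retest** (`simulate_retest`): two awareness halves Y1, Y2 sharing one
S draw with independent noises; corr(Y1, Y2) is the split-half
reliability c²σ_S²/(c²σ_S² + σ_eY²).

Seeding: one integer seed per simulator through
`numpy.random.default_rng`; variates are drawn in the fixed order S,
e_X, e_Y (, e_Y2), so identical (spec, n, seed) is bit-identical and
latent bookkeeping is stable. Stored latents reproduce X and Y to
machine precision.

## Closed-form oracles

`oracles` computes, exactly for the Gaussian case:

- population moments and r per spec (and Y's reliability);
- truncated-normal subgroup means under cutoff selection via the inverse
  Mills ratio φ/Φ, de-standardized to the raw scales;
- standard-normal band (quantile-bin) means, (φ(z_lo) − φ(z_hi))/(q_hi − q_lo);
- the binary model's seen/unseen probabilities by mixing
  Φ((s − θ)/w_Y) over the Bernoulli state and applying Bayes' rule,
  with w_Y = 0 as the deterministic limit;
- true-score shrinkage for a band selected on a noisy observed score
  O = T + e: the observed subgroup mean μ + sd_O·m_band versus the true
  mean μ + (σ_T²/sd_O²)·sd_O·m_band. The worked height example
  (T ~ N(175, 10) cm, e ~ N(0, 3) cm, top quartile) gives 188.27 cm
  observed vs 187.17 cm true — the ~1.1 cm gap is the bias of selecting
  and estimating on the same noisy measure.

φ, Φ, Φ⁻¹ come from `scipy.stats.norm`; nothing is approximated in
package code. For non-Gaussian extensions the oracles would fall back to
Monte Carlo; the default distribution is Gaussian and that is what the
closed forms cover.

Two single-run values reported alongside these models elsewhere differ
from the closed forms and are treated as sampling error of one n=200 run:
a retest reliability printed as 0.76 where the formula gives 0.692, and
a 22% seen-trial rate at (w_Y = 0.6, p_S = 0.1) where the
Gaussian-threshold form gives 26.2%. Tests assert the closed forms.

## Selection and diagnostics

`selection` implements the audited procedures themselves: cutoff
selection (ties included on the at-or-below side, since "scored at or
below chance" includes the boundary), per-participant one-sided exact
binomial classification (label "unaware" iff p ≥ α, default α = 0.05 —
deliberately reproducing the evidence-of-absence fallacy under audit),
and quantile partitioning (group sizes within 1, ties broken by stable
input order, deterministic and seedless).

`diagnostics` provides the audit tools:

- `z_transform` (n−1 SDs throughout; correlation invariant);
- `galton_squeeze`: quantile-band means of both z variables; the funnel
  between the partition variable's band means (±1.27 for quartiles) and
  the companion's (±r·1.27) *is* the regression effect, and it is
  bidirectional — partitioning on X squeezes Y identically;
- `regression_artifact_test`: compares the observed subgroup mean z(X)
  (95% t-CI) against the prediction r·mean z(Y|selected). The verdict is
  deliberately three-valued — consistent / exceeds-regression /
  below-regression — so over-shrunk outcomes stay visible instead of
  being folded into "consistent". Only "exceeds" is even candidate
  evidence for an effect beyond the artifact; under null models it fires
  at roughly the CI miscoverage rate (checked at 1,000 replicates).
- `ordering_check`: r > 0 implies z(X|Y>c) > z(X) > z(X|Y≤c); violations
  (an "unaware" subgroup out-performing the whole group) are flagged;
- `retest_regression_test`: select on one awareness half, measure the
  change on the other. The regression account predicts improvement for a
  low-selected subgroup of size (1 − reliability)·|selected deviation|,
  zero under the "true unawareness" reading; a mirrored select-on-Y2 and
  a high-score variant come for free because regression is
  bidirectional.

CIs are Student-t on the relevant (sub)group mean or paired change (the
convention adopted where the method is otherwise unstated; a seeded
percentile bootstrap is available). Pearson's r is used everywhere —
the regression identity is stated in r, and silently substituting a rank
correlation would break it. Degenerate inputs (zero SD, empty subgroup
at a cutoff) raise `ValueError` in diagnostics; plain cutoff selection
returns a flagged empty result instead, since empty subgroups are a
legitimate outcome of a real cutoff.

## Fixtures

The two reanalyzed participant-level datasets are not publicly
deposited, so `generate_fixture` produces synthetic stand-ins that match
their *structure*, not their values: `smyth-like` (n = 40, priming in
ms, a 4-alternative generation test scored /24 per half with chance
0.25, exactly 14/40 at or below chance on the first half) and
`sklar-like` (n = 42, priming in ms, forced-choice proportion correct
minus 0.5, exactly 34/42 above chance). The published selection counts
are enforced by a deterministic minimal repair of binomially drawn
scores (records nearest the boundary are moved across it); everything
else is seeded. Awareness halves use 24 trials each, the session length
implied by a four-block, twelve-configuration generation test; the
forced-choice trial count is not published and 24 was fixed once as
realistic. These fixtures exercise schema, selection counts and sign
patterns; they carry no information about the real effect sizes, and
passing tests on them says nothing about the original raw data.

## Problem sizes and tolerances

Monte Carlo convergence tests run at n = 10⁵–10⁶ and assert agreement
with the closed forms within 4 Monte Carlo standard errors. Replicate
studies (sampling distributions of subgroup means, verdict rates,
quartile band means) use 300–1,000 seeded replicates of n = 200, the
sample size the simulated studies themselves use. The acceptance script
(`scripts/acceptance.py`) uses 10⁶ draws for the height experiment and
1,000 × n = 200 replicates elsewhere; at these sizes every reported
quantity is stable to well within its sampling noise.

## Known limitations

- Closed forms assume Gaussian latents and noises; the simulators could
  be extended to other distributions but the oracles would then be
  Monte Carlo.
- Only single-variable cutoff/band selection is modelled; no theory of
  selection on multiple criteria.
- No model fitting or likelihood inference — simulation and audit only.
- The regression-intercept estimation approach and multiple-testing
  layers are out of scope.
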