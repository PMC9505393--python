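# Methods

This note records the statistical models, estimation machinery, and design
choices behind `effortirt`, including the places where the underlying
methodology leaves details open and this package had to fix them.

## Response models

All models give the probability of a correct response to binary item *i* by
a person with latent ability θ (logits). With discrimination aᵢ > 0 and
difficulty bᵢ:

- **2PL**: Pᵢ(θ) = expit(aᵢ(θ − bᵢ)).
- **3PL**: Pᵢ(θ) = cᵢ + (1 − cᵢ)·expit(aᵢ(θ − bᵢ)). The lower asymptote can
  be supplied on the logit metric as a threshold γᵢ with cᵢ = expit(γᵢ);
  γᵢ = −∞ is the "no guessing" sentinel and any γᵢ < −15 is numerically a
  zero asymptote, so the model collapses to the 2PL.
- **Ability-based guessing**: the person–item guessing probability is
  cᵢⱼ = expit(γᵢ + k·θⱼ), giving Pᵢ(θ) = P₂ + (1 − P₂)·cᵢⱼ with P₂ the 2PL
  term. k ≥ 0 is a researcher-chosen slope; 0.228 is the conventional value
  for four-option multiple choice and is the package default. k = 0 recovers
  the γ-metric 3PL. The fixed-discrimination variant of this model is the
  aᵢ = 1 special case.
- **Effort-moderated (EM) mixtures**: with solution-behavior flag SBᵢⱼ,
  P = SB·P_model + (1 − SB)·g, where g = 1/n_options is the random-guessing
  rate and P_model is the 3PL (`em3pl`) or 2PL (`em2pl`). The
  informed-guessing variant (`em2pl_informed`) replaces the rapid term with
  k·θ + g, read as: a flagged high-ability examinee still ekes out
  better-than-chance success by eliminating distractors.

**Clamping.** k·θ + g is a raw linear expression and can leave [0, 1]; it is
clamped to [1e−6, 1 − 1e−6] with a runtime warning when the rapid branch is
actually affected. All EM outputs are clamped to the same band so
log-likelihoods are finite everywhere. The logistic is evaluated through
`scipy.special.expit`, which is overflow-safe for arbitrarily large
exponents.

## Effort flagging from response times

Per item, the rapid-response threshold is the empirical 10th percentile
(configurable) of that item's non-missing response times, computed with
linear interpolation between order statistics (numpy default, R type 7).
This quantile dialect is a package choice — the methodology only names "the
10th percentile" — and is pinned for reproducibility. Cells with
rt ≤ threshold get SB = 0; ties are deliberately flagged rapid
(conservative toward detecting disengagement); missing times give SB = 1,
because absent timing evidence should not impute disengagement.

RTEⱼ is the mean of person j's SB flags. Person-level classification
(rbe = 1 effortful, 0 rapid) uses an inclusive cutoff RTE ≥ 0.90 by
default. The cutoff is an exposed knob rather than a fixed rule: the
underlying methodology supplies the rapid/effortful vector externally and
never states the mapping, so this package provides a documented default
instead of guessing intent. With 20% fully-rapid examinees, the
10th-percentile rule flags only about half of the rapid cells (the
threshold falls inside the rapid RT component), yet person-level
classification is near-perfect because engaged examinees almost never fall
under the threshold — the RTE gap between groups is wide.

## Estimation

The log-likelihood of a response vector is the Bernoulli sum over
non-missing items; missing responses are dropped from both the likelihood
and the information (standard scoring practice). MLE maximizes it;
BME (Bayesian modal estimation) maximizes it plus the log density of a
normal prior, N(0, 1) by default. BME is the posterior *mode*; EAP scoring
is out of scope.

The optimizer is Newton–Raphson on the score function: start 0 (MLE) or the
prior mean (BME), step tolerance 1e−6, at most 50 iterations, search
clamped to ±log(2J). The score uses the closed-form dP/dθ of each model;
the curvature is a central finite difference of the score (h = 1e−4), whose
O(h²) error is far below the step tolerance. If a Newton step leaves the
clamped range or the curvature estimate is non-negative, the optimizer
falls back to bisection on a sign change of the score over the range; a
score that is monotone over the whole range puts the optimum at an
endpoint. Tests verify against an independent 1e−4-step grid search that
interior estimates agree within 1e−3 and the score magnitude at interior
optima is below 1e−5.

**Zero-variance vectors.** All-correct and all-incorrect vectors have no
interior MLE; the estimate is clamped to +log(2J) / −log(2J) (natural log,
J = item count) with `at_boundary` set. The log base is a package decision;
the estimation tradition this follows works in natural logs throughout. BME
needs no convention — the prior makes every vector estimable, and a vector
with no theta-informative responses returns the prior mean and sd exactly.

**Non-identifiability.** Under an EM model, items flagged SB = 0 contribute
a theta-free constant. If *every* non-missing item is flagged rapid the
likelihood is flat and MLE raises `NonIdentifiableError` rather than
reporting a spurious number; batch scoring logs the failure for that person
and continues.

**Standard errors.** SE(θ̂) = 1/√I(θ̂) with the expected (Fisher) test
information I(θ) = Σᵢ (dPᵢ/dθ)²/(PᵢQᵢ). This single expression reduces to
aᵢ²PᵢQᵢ for the 2PL and to aᵢ²(Qᵢ/Pᵢ)((Pᵢ−cᵢ)/(1−cᵢ))² for the 3PL, and
extends unchanged to the other variants; SB = 0 items contribute nothing
under `em2pl`/`em3pl`. The BME standard error adds the prior curvature:
SE = 1/√(I(θ̂) + 1/sd²), which is why BME standard errors are uniformly
smaller than MLE ones.

## Rapid-responder corrections

For a person classed rapid (rbe = 0):

- **random guessing**: θ is replaced by logit(1/n_options) — with four
  options, log(1/3) = −1.0986, i.e. the ability at which chance-level
  success is the expected score. Identical under MLE and BME.
- **ability-based**: θ = logit(1/n_options) + k·θ̂, where θ̂ is the person's
  effortful-model estimate from the same method being reported. This is the
  logit-scale reading of the ability-based guessing model's person
  asymptote; it keeps the corrected value on the theta metric and responds
  to the person's own ability.

Corrected estimates carry a NaN standard error (a replaced score has no
sampling SE) and `at_boundary = False`. Effortful persons pass through
untouched.

## Synthetic data

The generator emulates a testing session with a known disengagement
mixture, which is what makes the rest of the package testable without any
external dataset:

- abilities θ ~ N(0, 1) (mean/sd configurable); the default instrument is
  seven items with a = 1 and b = −2, −1, −.5, 0, .5, 1, 2 logits;
- a fraction of persons (default 0) are rapid responders; within them, each
  item is independently rapid with a configurable rate (default 1);
- engaged cells respond Bernoulli(2PL(θ)), rapid cells Bernoulli(1/n_options);
- response times are lognormal: engaged LogN(log 20 s, 0.5), rapid
  LogN(log 2 s, 0.4). The components sit ≥ 3 sigma apart on the log scale so
  the percentile rule has signal — chosen as a realistic fast-guess vs.
  solution-time contrast, not fitted to any dataset.

One `numpy.random.default_rng(seed)` drives all draws in a fixed order
(thetas, rapid persons, rapid cells, responses, times), so a seed
reproduces a dataset bit for bit.

What the generator does **not** emulate: 3PL or ability-based-guessing
response generation (scoring them is in scope; generating from them is
not), speed–accuracy dependence within a person, item-level time trends,
or slow careless responding ("wandering"). Passing recovery tests therefore
show correctness of the scoring machinery under the stated mixture, not
robustness to every real-world disengagement pattern.

## Recovery experiments and problem sizes

`recovery_experiment` runs simulate → flag → score and reports bias and
RMSE of estimated vs. true theta split by true rapid status. The package's
reference recovery setting is n = 500 persons, J = 30 items, a = 1,
b ~ U(−2, 2), θ ~ N(0, 1), fixed seeds — large enough for stable bias and
RMSE summaries while keeping a full suite run under a minute. At this
setting MLE mean bias is within 0.1, BME RMSE does not exceed MLE RMSE, and
with 20% injected rapid rows the full effort-moderated pipeline (EM
likelihood + RTE classification + random-guessing correction) substantially
reduces absolute bias on the contaminated subgroup relative to naive 2PL
scoring. The EM likelihood *alone* barely moves that bias here: the
10th-percentile rule catches only about half the rapid cells, and the
remaining chance-level responses dominate the estimate — the correction
step is what restores validity, which is precisely the argument for using
it.

## Known limitations

- Item parameters are consumed pre-calibrated; joint or marginal
  calibration is out of scope, so any bias in the supplied item file passes
  straight through to theta.
- The ability-based correction uses θ̂ from an effortful-model fit to the
  person's own (partly rapid) responses; with heavy contamination that θ̂
  is itself biased toward the guessing floor.
- The RTE → rbe cutoff is a policy knob; no default can be right for every
  instrument, and misclassification at the person level changes which
  correction a person receives discontinuously.
- Percentile-based flagging assumes the rapid RT component sits below the
  engaged component per item; instruments where disengagement shows as slow
  responding need a different detector (model-based RT mixtures are a
  non-goal here).
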