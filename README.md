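# effortirt

Person-ability estimation for binary test items that stays valid when some
examinees respond rapidly and without effort.

On multiple-choice and other dichotomously scored instruments, a disengaged
examinee who answers in a couple of seconds is not expressing ability — they
are guessing. Scoring such response vectors with an ordinary item response
model drags the ability estimate toward the guessing floor and invalidates
it. `effortirt` is a toolkit for psychometricians and assessment researchers
that (1) detects rapid responding from item-level response times, (2) scores
examinees under effort-moderated response models, and (3) assigns principled
corrected abilities to flagged rapid responders.

## Models

Ability θ, difficulty *b* and the guessing threshold γ live on the logit
scale. The package implements, for an item with discrimination *a*:

- **2PL** — P(θ) = expit(a(θ − b));
- **3PL** — P(θ) = c + (1 − c)·expit(a(θ − b)), with the lower asymptote
  supplied either as a probability *c* or on the logit metric as γ with
  c = expit(γ) (γ < −15 means no asymptote);
- **ability-based guessing** — the asymptote rises with ability:
  P(θ) = P₂ + (1 − P₂)·expit(γ + kθ), where P₂ is the 2PL probability and
  *k* is the guessing slope (0.228 is a common choice for four options);
- **effort-moderated (EM) mixtures** — with a per-cell solution-behavior
  flag SB, P = SB·P_model + (1 − SB)·g where g = 1/(number of options);
  the informed-guessing variant replaces the rapid term with kθ + g.

A response faster than the item's empirical 10th response-time percentile is
flagged rapid (SB = 0). The response-time-effort index RTE is each person's
mean SB; persons below a configurable RTE cutoff are classed rapid (rbe = 0).

Ability is estimated by Newton–Raphson maximum likelihood (MLE) or Bayesian
modal estimation (BME, posterior mode under a normal prior), with standard
errors from the test information function I(θ) = Σᵢ (Pᵢ′)²/(PᵢQᵢ). Zero-variance
vectors clamp to the conventional bounds θ = ±log(2J) under MLE. A rapid
responder's theta can be corrected to logit(1/n_options) (random guessing)
or logit(1/n_options) + k·θ̂ (ability-based).

## Worked example

Score one person's seven-item vector `1101110` on an instrument with unit
discriminations and difficulties −2, −1, −.5, 0, .5, 1, 2 logits:

```sh
cat > items.csv <<CSV
a,b,k
1,-2,0.228
1,-1,0.228
1,-0.5,0.228
1,0,0.228
1,0.5,0.228
1,1,0.228
1,2,0.228
CSV
printf 'i1,i2,i3,i4,i5,i6,i7\n1,1,0,1,1,1,0\n' > resp.csv

effortirt score --items items.csv --responses resp.csv --method mle --out mle.csv
effortirt score --items items.csv --responses resp.csv --method bme --out bme.csv
```

`mle.csv` reports `theta=1.1972, se=0.9449`: the person answered five of
seven items correctly, including the two hardest-but-one, so the maximum
of the likelihood sits about 1.2 logits above the mean. `bme.csv` reports
`theta=0.6517, se=0.6653` — the standard-normal prior shrinks the estimate
toward 0 and, by adding its curvature to the information, shrinks the
standard error too.

If the same person is flagged as a rapid responder
(`printf 'rbe\n0\n' > rbe.csv`), the random-guessing correction replaces
their ability with the logit of the four-option chance rate:

```sh
effortirt score --items items.csv --responses resp.csv --rbe rbe.csv \
    --nopt 4 --correction random --out corrected.csv
```

which prints `theta=-1.0986` (logit ¼ = −1.099 at three decimals) with an
empty standard-error field — a chance-level score has no sampling SE.

The `effort` subcommand turns a response-time CSV into SB/RTE/rbe flags,
and `simulate` generates synthetic datasets (engaged 2PL responding plus a
rapid-guessing mixture with lognormal response times) for pipeline testing
and recovery experiments; see `effortirt --help`.

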