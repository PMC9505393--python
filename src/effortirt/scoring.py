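"""Person-ability (theta) estimation with standard errors.

Maximum likelihood (MLE) and Bayesian modal (BME) estimation of a person's
latent ability under any of the response models in :mod:`effortirt.models`,
via Newton–Raphson on the score equation with a bracketing-bisection
fallback. Standard errors come from the test information function

    I(theta) = sum_i (dP_i/dtheta)^2 / (P_i * (1 - P_i))

(which reduces to ``a^2 P Q`` for the 2PL and to
``a^2 (Q/P) ((P - c)/(1 - c))^2`` for the 3PL); the BME standard error adds
the prior curvature ``1/sd^2``.

Zero-variance response vectors are not MLE-estimable; the scorer applies the
Baker–Kim convention and clamps theta to ``+/- log(2 * J)`` (natural log,
J items) with ``at_boundary`` set. BME has no such limitation.

Rapid responders (rbe = 0) can be assigned a corrected theta: the logit of
the random-guessing rate ``logit(1/n_options)`` (random-guessing rule), or
that logit shifted by ``k * theta_hat`` (ability-based rule, using the
person's effortful-model estimate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import logit

from .effort import EffortProfile
from .models import (
    Correction,
    GuessingConfig,
    ItemParameters,
    clamp_probability,
    model_probability,
    model_probability_and_grad,
)

__all__ = [
    "NonIdentifiableError",
    "PriorSpec",
    "ThetaEstimate",
    "bme_theta",
    "corrected_theta",
    "log_likelihood",
    "mle_theta",
    "sample_log_likelihood",
    "score_sample",
]

logger = logging.getLogger(__name__)

_STEP_TOL = 1e-6
_MAX_ITER = 50
_FD_H = 1e-4  # step for the finite-difference curvature inside Newton-Raphson


class NonIdentifiableError(ValueError):
    """The likelihood carries no information about theta (flat objective)."""


@dataclass(frozen=True)
class PriorSpec:
    """Normal prior on theta for Bayesian modal estimation."""

    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ValueError(f"prior sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class ThetaEstimate:
    """An ability estimate with its standard error and diagnostics.

    ``se`` is NaN for corrected (rapid-responder) estimates, where a
    sampling standard error is not defined.
    """

    theta: float
    se: float
    method: str                      # "MLE" or "BME"
    corrected: str = "none"
    converged: bool = True
    n_iter: int = 0
    at_boundary: bool = False


def _validate_inputs(respv, items: Sequence[ItemParameters], sb_row):
    respv = np.asarray(respv, dtype=float)
    if respv.ndim != 1 or len(respv) != len(items):
        raise ValueError(
            f"response vector length {respv.size} does not match "
            f"item count {len(items)}")
    present = ~np.isnan(respv)
    if not np.all(np.isin(respv[present], (0.0, 1.0))):
        raise ValueError("responses must be 0, 1 or missing")
    if sb_row is None:
        sb = np.ones(len(items), dtype=int)
    else:
        sb = np.asarray(sb_row, dtype=int)
        if len(sb) != len(items):
            raise ValueError("sb_row length does not match item count")
    return respv, present, sb


def log_likelihood(theta, respv, items: Sequence[ItemParameters],
                   model: str = "2pl", sb_row=None,
                   cfg: GuessingConfig | None = None) -> float:
    """Bernoulli log-likelihood of one response vector at ``theta``.

    Missing responses are skipped. Probabilities are clamped to
    ``[1e-6, 1 - 1e-6]`` so the value is always finite.
    """
    respv, present, sb = _validate_inputs(respv, items, sb_row)
    total = 0.0
    for i, item in enumerate(items):
        if not present[i]:
            continue
        p = clamp_probability(
            model_probability(theta, item, model, sb=sb[i], cfg=cfg))
        y = respv[i]
        total += y * np.log(p) + (1.0 - y) * np.log(1.0 - p)
    return float(total)


def _score_and_info(theta: float, respv, present, sb,
                    items: Sequence[ItemParameters], model: str,
                    cfg: GuessingConfig | None):
    """Score (d loglik / d theta) and expected test information at theta."""
    score = 0.0
    info = 0.0
    for i, item in enumerate(items):
        if not present[i]:
            continue
        p, dp = model_probability_and_grad(theta, item, model, sb=sb[i], cfg=cfg)
        p = float(np.clip(p, 1e-12, 1.0 - 1e-12))
        pq = p * (1.0 - p)
        score += (respv[i] - p) / pq * dp
        info += dp * dp / pq
    return score, info


def _theta_informative(respv, present, sb, items, model) -> np.ndarray:
    """Mask of items whose probability actually depends on theta."""
    informative = present.copy()
    if model in ("em2pl", "em3pl"):
        informative &= sb == 1
    return informative


def _newton_raphson(score_fn, start: float, lo: float, hi: float):
    """Maximize a concave-ish objective via NR on its score.

    Returns (theta, n_iter, converged). Falls back to bisection on a
    bracketing interval when NR steps out of [lo, hi] or the curvature
    estimate is not negative.
    """
    theta = start
    for it in range(1, _MAX_ITER + 1):
        s = score_fn(theta)
        # curvature of the log-objective via central difference of the score
        d2 = (score_fn(theta + _FD_H) - score_fn(theta - _FD_H)) / (2.0 * _FD_H)
        if d2 >= 0 or not np.isfinite(d2):
            break  # NR unusable here; fall back to bisection
        step = -s / d2
        new = theta + step
        if not (lo <= new <= hi) or not np.isfinite(new):
            break
        theta = new
        if abs(step) < _STEP_TOL:
            return theta, it, True
    # Bisection fallback on a sign change of the score.
    s_lo, s_hi = score_fn(lo), score_fn(hi)
    if s_lo > 0 and s_hi < 0:
        a_, b_ = lo, hi
        it2 = 0
        while b_ - a_ > _STEP_TOL and it2 < 200:
            mid = 0.5 * (a_ + b_)
            if score_fn(mid) > 0:
                a_ = mid
            else:
                b_ = mid
            it2 += 1
        return 0.5 * (a_ + b_), _MAX_ITER + it2, True
    # Monotone score over the range: optimum sits at an endpoint.
    endpoint = hi if s_hi >= 0 else lo
    return endpoint, _MAX_ITER, False


def mle_theta(respv, items: Sequence[ItemParameters], model: str = "2pl",
              sb_row=None, cfg: GuessingConfig | None = None) -> ThetaEstimate:
    """Maximum likelihood theta estimate with standard error.

    All-correct and all-incorrect vectors (over the theta-informative items)
    are clamped to ``+log(2J)`` and ``-log(2J)`` respectively with
    ``at_boundary=True``. Raises :class:`NonIdentifiableError` when no item
    carries information about theta (e.g. every flag rapid under an EM
    model).
    """
    respv, present, sb = _validate_inputs(respv, items, sb_row)
    if not present.any():
        raise ValueError("cannot estimate theta from an all-missing vector")
    bound = np.log(2.0 * len(items))
    informative = _theta_informative(respv, present, sb, items, model)
    if not informative.any():
        raise NonIdentifiableError(
            "likelihood is flat in theta: no effortful, non-missing responses")
    y_inf = respv[informative]

    def se_at(theta: float) -> float:
        _, info = _score_and_info(theta, respv, present, sb, items, model, cfg)
        return 1.0 / np.sqrt(info) if info > 0 else np.inf

    if np.all(y_inf == 1.0) or np.all(y_inf == 0.0):
        theta = bound if y_inf[0] == 1.0 else -bound
        return ThetaEstimate(theta=theta, se=se_at(theta), method="MLE",
                             converged=True, n_iter=0, at_boundary=True)

    def score_fn(theta: float) -> float:
        s, _ = _score_and_info(theta, respv, present, sb, items, model, cfg)
        return s

    theta, n_iter, converged = _newton_raphson(score_fn, 0.0, -bound, bound)
    at_boundary = abs(abs(theta) - bound) < 1e-12
    return ThetaEstimate(theta=theta, se=se_at(theta), method="MLE",
                         converged=converged, n_iter=n_iter,
                         at_boundary=at_boundary)


def bme_theta(respv, items: Sequence[ItemParameters], model: str = "2pl",
              prior: PriorSpec = PriorSpec(), sb_row=None,
              cfg: GuessingConfig | None = None) -> ThetaEstimate:
    """Bayesian modal (posterior mode) theta estimate under a normal prior.

    Estimable for any vector, including zero-variance ones; with no
    informative responses the posterior equals the prior and the estimate is
    the prior mean with se equal to the prior sd.
    """
    respv, present, sb = _validate_inputs(respv, items, sb_row)
    prior_var = prior.sd ** 2
    informative = _theta_informative(respv, present, sb, items, model)
    if not informative.any():
        return ThetaEstimate(theta=prior.mean, se=prior.sd, method="BME",
                             converged=True, n_iter=0)
    bound = max(np.log(2.0 * len(items)),
                abs(prior.mean) + 6.0 * prior.sd)

    def score_fn(theta: float) -> float:
        s, _ = _score_and_info(theta, respv, present, sb, items, model, cfg)
        return s - (theta - prior.mean) / prior_var

    theta, n_iter, converged = _newton_raphson(score_fn, prior.mean, -bound, bound)
    _, info = _score_and_info(theta, respv, present, sb, items, model, cfg)
    se = 1.0 / np.sqrt(info + 1.0 / prior_var)
    return ThetaEstimate(theta=theta, se=se, method="BME",
                         converged=converged, n_iter=n_iter)


def corrected_theta(theta_hat: ThetaEstimate, rbe: int,
                    cfg: GuessingConfig) -> ThetaEstimate:
    """Apply the rapid-responder correction to an ability estimate.

    Effortful persons (rbe = 1) pass through unchanged. A rapid responder
    (rbe = 0) receives the logit of the random-guessing rate,
    ``logit(1/n_options)``, under the random-guessing rule, or that logit
    shifted by ``k * theta_hat`` under the ability-based rule. Corrected
    estimates carry a NaN standard error.
    """
    if cfg.correction == Correction.NONE:
        raise ValueError("corrected_theta requires a correction rule")
    if rbe not in (0, 1):
        raise ValueError(f"rbe must be 0 or 1, got {rbe}")
    if rbe == 1:
        return theta_hat
    base = float(logit(cfg.g))  # log(1 / (n_options - 1))
    if cfg.correction == Correction.RANDOM_GUESSING:
        theta = base
    else:
        theta = base + cfg.k * theta_hat.theta
    return replace(theta_hat, theta=theta, se=np.nan,
                   corrected=cfg.correction.value, at_boundary=False)


def score_sample(responses, items: Sequence[ItemParameters],
                 method: str = "MLE", model: str = "2pl",
                 effort: EffortProfile | None = None,
                 cfg: GuessingConfig | None = None,
                 prior: PriorSpec = PriorSpec()) -> list[ThetaEstimate | None]:
    """Score every person in a responses grid.

    Applies :func:`mle_theta` or :func:`bme_theta` row by row, then the
    rapid-responder correction wherever ``effort.rbe`` is 0 and a correction
    rule is configured. Row-level failures are logged and yield ``None``
    without aborting the batch.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.ndim != 2:
        raise ValueError("responses grid must be 2-dimensional")
    method = method.upper()
    if method not in ("MLE", "BME"):
        raise ValueError(f"method must be MLE or BME, got {method!r}")
    out: list[ThetaEstimate | None] = []
    for row_idx in range(responses.shape[0]):
        sb_row = effort.sb[row_idx] if effort is not None else None
        try:
            if method == "MLE":
                est = mle_theta(responses[row_idx], items, model=model,
                                sb_row=sb_row, cfg=cfg)
            else:
                est = bme_theta(responses[row_idx], items, model=model,
                                prior=prior, sb_row=sb_row, cfg=cfg)
            if (effort is not None and cfg is not None
                    and cfg.correction != Correction.NONE):
                est = corrected_theta(est, int(effort.rbe[row_idx]), cfg)
        except (ValueError, NonIdentifiableError) as exc:
            logger.warning("person %d not scored: %s", row_idx + 1, exc)
            out.append(None)
            continue
        logger.debug("person %d: theta=%.4f se=%.4f converged=%s iter=%d",
                     row_idx + 1, est.theta, est.se, est.converged, est.n_iter)
        out.append(est)
    return out


def sample_log_likelihood(responses, items: Sequence[ItemParameters],
                          model: str = "2pl",
                          effort: EffortProfile | None = None,
                          cfg: GuessingConfig | None = None,
                          method: str = "MLE",
                          prior: PriorSpec = PriorSpec()) -> float:
    """Total log-likelihood of a sample at each person's estimated theta."""
    responses = np.asarray(responses, dtype=float)
    if responses.size == 0:
        return 0.0
    estimates = score_sample(responses, items, method=method, model=model,
                             effort=effort, cfg=cfg, prior=prior)
    total = 0.0
    for row_idx, est in enumerate(estimates):
        if est is None:
            continue
        sb_row = effort.sb[row_idx] if effort is not None else None
        total += log_likelihood(est.theta, responses[row_idx], items,
                                model=model, sb_row=sb_row, cfg=cfg)
    return total
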