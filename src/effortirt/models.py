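"""Item response probability models.

Closed-form probabilities of a correct response for the model families used
throughout the package:

* two-parameter logistic (2PL) — discrimination ``a`` and difficulty ``b``;
* three-parameter logistic (3PL) — adds a lower asymptote, either directly as
  the pseudo-guessing probability ``c`` or on the logit metric as a threshold
  ``gamma`` with ``c = expit(gamma)``;
* ability-based guessing — the guessing asymptote rises with person ability
  through a slope ``k`` inside the guessing logit;
* effort-moderated (EM) mixtures — effortful responses (solution behavior
  flag ``sb = 1``) follow the 2PL/3PL curve, rapid responses (``sb = 0``)
  follow a constant random-guessing rate ``g = 1/n_options``, optionally
  augmented by an informed-guessing term ``k * theta``.

All functions accept scalar or ``numpy`` array ``theta`` and broadcast.
Probabilities returned by the EM family are clamped to ``[EPS, 1 - EPS]`` so
downstream log-likelihoods stay finite; the plain 2PL/3PL forms are already
strictly inside ``(c, 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import expit

__all__ = [
    "EPS",
    "Correction",
    "GuessingConfig",
    "ItemParameters",
    "gamma_to_c",
    "person_guessing",
    "prob_2pl",
    "prob_3pl",
    "prob_3pl_gamma",
    "prob_ability_guessing",
    "prob_effort_moderated",
]

#: Probability clamp used by the effort-moderated mixtures.
EPS = 1e-6

#: Logit threshold below which the lower asymptote is numerically zero and
#: the 3PL collapses to the 2PL.
GAMMA_ZERO = -15.0


def _require_finite(name: str, value: float) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ItemParameters:
    """Parameters of a single binary item.

    Parameters
    ----------
    a : float
        Discrimination (slope on the logit scale); must be positive and finite.
    b : float
        Difficulty in logits.
    k : float
        Slope of the ability-based guessing process (``>= 0``); 0 disables
        the ability contribution to guessing.
    gamma : float
        Lower-asymptote threshold on the logit metric. ``-inf`` (the default)
        means no guessing asymptote; any value below −15 is numerically
        indistinguishable from none.
    """

    a: float
    b: float
    k: float = 0.0
    gamma: float = -np.inf

    def __post_init__(self) -> None:
        for name in ("a", "b", "k"):
            _require_finite(name, getattr(self, name))
        if self.a <= 0:
            raise ValueError(f"discrimination a must be > 0, got {self.a}")
        if self.k < 0:
            raise ValueError(f"guessing slope k must be >= 0, got {self.k}")
        if np.isnan(self.gamma) or self.gamma == np.inf:
            raise ValueError(f"gamma must be finite or -inf, got {self.gamma}")

    @property
    def c(self) -> float:
        """Pseudo-guessing probability derived from ``gamma``."""
        return gamma_to_c(self.gamma)

    @property
    def has_guessing(self) -> bool:
        """Whether the lower asymptote is numerically nonzero."""
        return self.gamma > GAMMA_ZERO


class Correction(str, Enum):
    """Rapid-responder theta correction rule."""

    NONE = "none"
    RANDOM_GUESSING = "random_guessing"
    ABILITY_BASED = "ability_based"


@dataclass(frozen=True)
class GuessingConfig:
    """Guessing configuration shared by the EM models and corrections.

    ``g = 1/n_options`` is the random-guessing success rate; ``k`` is the
    slope combining theta with guessing under the ability-based rule
    (default 0.228, the value suggested for four-option multiple choice).
    """

    n_options: int = 4
    correction: Correction = Correction.NONE
    k: float = 0.228

    def __post_init__(self) -> None:
        if self.n_options < 2:
            raise ValueError(f"n_options must be >= 2, got {self.n_options}")
        object.__setattr__(self, "correction", Correction(self.correction))
        if self.correction == Correction.ABILITY_BASED and not np.isfinite(self.k):
            raise ValueError("ability_based correction requires a finite k")

    @property
    def g(self) -> float:
        """Random-guessing success rate, exactly ``1/n_options``."""
        return 1.0 / self.n_options


def clamp_probability(p):
    """Clamp probabilities into ``[EPS, 1 - EPS]``."""
    return np.clip(p, EPS, 1.0 - EPS)


def prob_2pl(theta, item: ItemParameters):
    """2PL probability of success: ``expit(a * (theta - b))``.

    Overflow-safe for arbitrarily large ``|a * (theta - b)|``.
    """
    theta = np.asarray(theta, dtype=float)
    _require_finite("theta", theta)
    return expit(item.a * (theta - item.b))


def gamma_to_c(gamma: float) -> float:
    """Map the logit-metric guessing threshold to a probability.

    ``gamma = -inf`` maps to exactly 0 (no lower asymptote).
    """
    if np.isnan(gamma):
        raise ValueError("gamma must not be NaN")
    if gamma == -np.inf:
        return 0.0
    return float(expit(gamma))


def prob_3pl(theta, item: ItemParameters, c: float):
    """3PL probability: ``c + (1 - c) * prob_2pl(theta, item)``."""
    if not (0.0 <= c < 1.0):
        raise ValueError(f"pseudo-guessing c must lie in [0, 1), got {c}")
    return c + (1.0 - c) * prob_2pl(theta, item)


def prob_3pl_gamma(theta, item: ItemParameters):
    """3PL probability with the asymptote given on the logit metric.

    Algebraically identical to ``prob_3pl(theta, item, gamma_to_c(gamma))``.
    """
    if np.isnan(item.gamma):
        raise ValueError("item.gamma is required for the gamma-metric 3PL")
    return prob_3pl(theta, item, gamma_to_c(item.gamma))


def person_guessing(theta, item: ItemParameters):
    """Person-level guessing probability ``expit(gamma + k * theta)``.

    The item-level asymptote is shifted by ability: more able persons guess
    successfully more often when ``k > 0``.
    """
    theta = np.asarray(theta, dtype=float)
    _require_finite("theta", theta)
    if item.gamma == -np.inf:
        return np.zeros_like(theta) if theta.ndim else 0.0
    return expit(item.gamma + item.k * theta)


def prob_ability_guessing(theta, item: ItemParameters):
    """Ability-based guessing model.

    ``P = P2 + (1 - P2) * person_guessing(theta)`` with ``P2`` the 2PL
    probability. Setting ``k = 0`` recovers the gamma-metric 3PL; setting
    ``gamma = -inf`` recovers the plain 2PL.
    """
    p2 = prob_2pl(theta, item)
    return p2 + (1.0 - p2) * person_guessing(theta, item)


_EM_VARIANTS = ("em3pl", "em2pl", "em2pl_informed")


def prob_effort_moderated(theta, item: ItemParameters, sb, cfg: GuessingConfig,
                          variant: str = "em2pl"):
    """Effort-moderated mixture probability.

    ``sb = 1`` (solution behavior) uses the effortful model: the 3PL for
    ``em3pl`` and the 2PL for ``em2pl``/``em2pl_informed``. ``sb = 0``
    (rapid behavior) yields the constant guessing rate ``g`` or, for
    ``em2pl_informed``, the informed-guessing score ``k * theta + g``
    clamped into ``[EPS, 1 - EPS]``.
    """
    if variant not in _EM_VARIANTS:
        raise ValueError(f"unknown EM variant {variant!r}; expected one of {_EM_VARIANTS}")
    theta = np.asarray(theta, dtype=float)
    sb = np.asarray(sb)
    if not np.all(np.isin(sb, (0, 1))):
        raise ValueError("solution-behavior flags must be 0 or 1")

    if variant == "em3pl":
        solution = prob_3pl(theta, item, item.c)
    else:
        solution = prob_2pl(theta, item)

    if variant == "em2pl_informed":
        rapid_raw = cfg.k * theta + cfg.g
        out_of_range = (rapid_raw < 0.0) | (rapid_raw > 1.0)
        if np.any(out_of_range & (np.asarray(sb) == 0)):
            warnings.warn(
                "informed-guessing score k*theta + g left [0, 1]; clamped",
                RuntimeWarning, stacklevel=2)
        rapid = rapid_raw
    else:
        rapid = np.broadcast_to(cfg.g, theta.shape if theta.ndim else ())

    p = np.where(sb == 1, solution, rapid)
    p = clamp_probability(p)
    return float(p) if p.ndim == 0 else p


def model_probability(theta, item: ItemParameters, model: str,
                      sb=1, cfg: GuessingConfig | None = None):
    """Dispatch to the probability function named by ``model``.

    ``model`` is one of ``2pl``, ``3pl``, ``ability_guessing``, ``em2pl``,
    ``em3pl``, ``em2pl_informed``. EM variants require ``cfg``.
    """
    if model == "2pl":
        return prob_2pl(theta, item)
    if model == "3pl":
        return prob_3pl_gamma(theta, item)
    if model == "ability_guessing":
        return prob_ability_guessing(theta, item)
    if model in _EM_VARIANTS:
        if cfg is None:
            raise ValueError(f"model {model!r} requires a GuessingConfig")
        return prob_effort_moderated(theta, item, sb, cfg, variant=model)
    raise ValueError(f"unknown response model {model!r}")


def model_probability_and_grad(theta: float, item: ItemParameters, model: str,
                               sb=1, cfg: GuessingConfig | None = None):
    """Probability and its analytic derivative with respect to theta.

    Used by the Newton-type scorer: the Bernoulli score and the expected
    information both only need ``(P, dP/dtheta)``.
    """
    p2 = prob_2pl(theta, item)
    dp2 = item.a * p2 * (1.0 - p2)
    if model == "2pl":
        return p2, dp2
    if model == "3pl":
        c = item.c
        return c + (1.0 - c) * p2, (1.0 - c) * dp2
    if model == "ability_guessing":
        gp = person_guessing(theta, item)
        dgp = item.k * gp * (1.0 - gp) if item.gamma > -np.inf else 0.0
        p = p2 + (1.0 - p2) * gp
        dp = dp2 * (1.0 - gp) + (1.0 - p2) * dgp
        return p, dp
    if model in _EM_VARIANTS:
        if cfg is None:
            raise ValueError(f"model {model!r} requires a GuessingConfig")
        if sb == 1:
            if model == "em3pl":
                c = item.c
                return c + (1.0 - c) * p2, (1.0 - c) * dp2
            return p2, dp2
        if model == "em2pl_informed":
            raw = cfg.k * theta + cfg.g
            inside = EPS < raw < 1.0 - EPS
            return float(np.clip(raw, EPS, 1.0 - EPS)), (cfg.k if inside else 0.0)
        return cfg.g, 0.0
    raise ValueError(f"unknown response model {model!r}")


def items_from_arrays(a, b, k=None, gamma=None) -> list[ItemParameters]:
    """Build an item list from parallel parameter arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    k = np.zeros(n) if k is None else np.asarray(k, dtype=float)
    gamma = np.full(n, -np.inf) if gamma is None else np.asarray(gamma, dtype=float)
    return [ItemParameters(a=a[i], b=b[i], k=k[i], gamma=gamma[i]) for i in range(n)]
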