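"""Response-time-based effort flagging.

Implements the solution-behavior (SB) convention for detecting rapid,
disengaged responding from item-level response times: a response faster than
the item's empirical 10th percentile is flagged rapid (sb = 0), everything
else effortful (sb = 1). The per-person response-time-effort index (RTE) is
the row mean of the SB flags, and a person is classified effortful
(rbe = 1) when their RTE reaches a configurable cutoff.

Conventions fixed here for reproducibility:

* quantiles use linear interpolation between order statistics (numpy's
  default, R's type 7);
* ties at the threshold are flagged rapid (``rt <= threshold``);
* missing response times are presumed effortful (sb = 1) — absent timing
  evidence does not impute disengagement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EffortProfile",
    "classify_persons",
    "compute_effort_profile",
    "flag_solution_behavior",
    "response_time_effort",
]


@dataclass(frozen=True)
class EffortProfile:
    """Per-cell SB flags plus per-person RTE and rapid/effortful class."""

    sb: np.ndarray       # persons x items, values in {0, 1}
    rte: np.ndarray      # per-person proportion of effortful items, in [0, 1]
    rbe: np.ndarray      # per-person indicator: 1 = effortful, 0 = rapid

    def __post_init__(self) -> None:
        if self.sb.shape[0] != len(self.rte) or len(self.rte) != len(self.rbe):
            raise ValueError("sb, rte and rbe must agree on person count")


def flag_solution_behavior(rt, percentile: float = 10.0) -> np.ndarray:
    """Flag each person-item cell as rapid (0) or effortful (1).

    Parameters
    ----------
    rt : array-like, persons x items
        Response times in seconds; NaN marks a missing time.
    percentile : float
        Per-item rapid-response threshold percentile (default 10). The
        threshold is the linearly interpolated empirical percentile of the
        item's non-missing times; cells with ``rt <= threshold`` get sb = 0.

    Returns
    -------
    numpy.ndarray of int, persons x items
    """
    rt = np.asarray(rt, dtype=float)
    if rt.ndim != 2:
        raise ValueError("response-time matrix must be 2-dimensional")
    if not (0.0 <= percentile <= 100.0):
        raise ValueError(f"percentile must lie in [0, 100], got {percentile}")
    present = ~np.isnan(rt)
    if np.any(rt[present] < 0):
        raise ValueError("response times must be nonnegative")
    n_present = present.sum(axis=0)
    if np.any(n_present < 2):
        bad = int(np.argmax(n_present < 2))
        raise ValueError(
            f"item {bad + 1} has fewer than 2 non-missing response times")
    thresholds = np.nanpercentile(rt, percentile, axis=0)
    sb = np.where(present & (rt <= thresholds), 0, 1)
    return sb.astype(int)


def response_time_effort(sb_row) -> float:
    """RTE for one person: the arithmetic mean of their SB flags."""
    sb_row = np.asarray(sb_row, dtype=float)
    if sb_row.size == 0:
        raise ValueError("SB sequence must be non-empty")
    return float(sb_row.mean())


def classify_persons(rte, cutoff: float = 0.90) -> np.ndarray:
    """Classify persons as effortful (1) when RTE >= cutoff, else rapid (0).

    The boundary is inclusive: a person at exactly the cutoff counts as
    effortful.
    """
    rte = np.asarray(rte, dtype=float)
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    if np.any((rte < 0) | (rte > 1)):
        raise ValueError("RTE values must lie in [0, 1]")
    return (rte >= cutoff).astype(int)


def compute_effort_profile(rt, percentile: float = 10.0,
                           cutoff: float = 0.90) -> EffortProfile:
    """Full pipeline: response times -> SB flags -> RTE -> rbe."""
    sb = flag_solution_behavior(rt, percentile=percentile)
    rte = sb.mean(axis=1)
    rbe = classify_persons(rte, cutoff=cutoff)
    return EffortProfile(sb=sb, rte=rte, rbe=rbe)
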