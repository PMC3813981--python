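"""Conditionally unbiased (Rao-Blackwell) estimators of the selected-arm
and control means.

Conditional on the selection made at stage 1 and on the trial passing
the futility gate, the stage-2 means ``Y_S`` and ``Y_0`` are unbiased
for the selected-arm and control means (stage-2 data are independent of
the stage-1 event).  Taking their conditional expectation given the
sufficient statistics yields uniformly minimum variance conditionally
unbiased estimators.  Both conditional expectations are truncated-normal
means and come out in closed Mills-ratio form:

selected arm
    Given the pooled mean ``Z_S`` the stage-1 mean ``X_S`` is
    ``N(Z_S, sigma1^2 (1-t))`` and the selection/continuation event
    truncates it below at ``m = max(B, X_(2))`` with ``B = X_0 + b`` and
    ``X_(2)`` the runner-up stage-1 experimental mean, giving

        zS_chn = Z_S - (t/(1-t)) * s * phi(W)/Phi(W),
        W      = (Z_S - m) / s,      s = sigma1 * sqrt(1-t).

control arm
    Symmetrically, ``X_0`` is truncated above at ``B1 = X_S - b``:

        z0_chn = Z_0 + (t/(1-t)) * s * phi(W1)/Phi(W1),
        W1     = (B1 - Z_0) / s.

With no futility gate (``b = -inf``) the control correction vanishes
identically (``z0_chn = z0_mle``) and the selected-arm formula reduces
to the classical two-stage drop-the-losers estimator; with ``k = 1`` the
runner-up disappears and the truncation point is the gate alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

from .design import DesignConfig, TrialData, pooled_means

__all__ = [
    "ConditioningStats",
    "mills_ratio",
    "conditioning_stats",
    "umvue_selected",
    "umvue_control",
    "unbiased_estimate",
    "umvue_k1",
    "cohen_sackrowitz_selected",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def mills_ratio(w):
    """Inverse Mills ratio phi(w) / Phi(w), stable over the whole real line.

    Evaluated in log space via ``log_ndtr``; for w -> -inf the ratio
    grows like ``-w`` without intermediate 0/0, for w -> +inf it decays
    to 0.  Relative accuracy is ~1e-14 throughout.
    """
    w = np.asarray(w, dtype=float)
    with np.errstate(over="ignore"):
        out = np.exp(-0.5 * w * w - _LOG_SQRT_2PI - log_ndtr(w))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ConditioningStats:
    """Quantities entering the Rao-Blackwell corrections.

    ``B = x0 + b`` and ``B1 = xS - b`` are the truncation points induced
    by the futility gate on the selected-arm and control stage-1 means;
    ``x_second`` is the runner-up experimental mean (``-inf`` for k=1 so
    that ``m = max(B, x_second)`` degenerates to the gate alone); ``W_B``
    is the standardized Mills argument for the selected arm.
    """

    B: float
    B1: float
    x_second: float
    m: float
    W_B: float
    z0_mle: float
    zS_mle: float


def _shrink_sd(design: DesignConfig) -> float:
    """SD of a stage-1 arm mean given the pooled mean: sigma1 * sqrt(1-t)."""
    return math.sqrt(design.sigma1_sq * (1.0 - design.t))


def conditioning_stats(trial: TrialData) -> ConditioningStats:
    trial._require_continued()
    design = trial.design
    z0, zS = pooled_means(trial)
    B = trial.x[0] + design.b  # -inf when there is no gate
    B1 = trial.x[trial.S] - design.b
    if design.k >= 2:
        others = np.delete(trial.x[1:], trial.S - 1)
        x_second = float(np.max(others))
    else:
        x_second = -math.inf
    m = max(B, x_second)
    s = _shrink_sd(design)
    W_B = (zS - m) / s if math.isfinite(m) else math.inf
    return ConditioningStats(
        B=float(B), B1=float(B1), x_second=x_second, m=float(m),
        W_B=float(W_B), z0_mle=z0, zS_mle=zS,
    )


def umvue_selected(trial: TrialData) -> float:
    """Conditionally unbiased estimate of the selected arm's mean.

    Always strictly below ``zS_mle`` when the truncation point is
    finite: selection-plus-gating can only inflate the pooled mean, so
    the Mills-ratio correction is strictly positive.
    """
    stats = conditioning_stats(trial)
    design = trial.design
    if not math.isfinite(stats.m):
        # k = 1 and no gate: no conditioning event, the pooled mean is already unbiased
        return stats.zS_mle
    s = _shrink_sd(design)
    coef = design.t / (1.0 - design.t) * s
    return stats.zS_mle - coef * mills_ratio(stats.W_B)


def umvue_control(trial: TrialData) -> float:
    """Conditionally unbiased estimate of the control mean.

    The gate truncates the control stage-1 mean above at ``B1``; with no
    gate the correction is exactly zero and the pooled mean is returned
    unchanged.
    """
    stats = conditioning_stats(trial)
    design = trial.design
    if not design.has_gate:
        return stats.z0_mle
    s = _shrink_sd(design)
    coef = design.t / (1.0 - design.t) * s
    W1 = (stats.B1 - stats.z0_mle) / s
    return stats.z0_mle + coef * mills_ratio(W1)


def unbiased_estimate(trial: TrialData) -> float:
    """Conditionally unbiased estimate of the selected-minus-control difference."""
    return umvue_selected(trial) - umvue_control(trial)


def umvue_k1(zS_mle: float, design: DesignConfig, boundary: float | None = None) -> float:
    """Single-arm (k = 1) conditionally unbiased mean estimate.

    For a trial with one experimental arm and a continuation rule
    ``X_1 >= B`` on the stage-1 mean scale, the selected-arm formula
    specialises to a single truncation at ``B``.  ``boundary`` defaults
    to ``design.b`` (a mean-scale boundary for a trial with no control
    arm; the same algebra applies on the difference scale with the
    stage-wise difference variances).
    """
    if design.k != 1:
        raise ValueError(f"umvue_k1 requires a k=1 design, got k={design.k}")
    B = design.b if boundary is None else boundary
    if B == -math.inf:
        return float(zS_mle)
    s = _shrink_sd(design)
    coef = design.t / (1.0 - design.t) * s
    return float(zS_mle - coef * mills_ratio((zS_mle - B) / s))


def cohen_sackrowitz_selected(z: float, x_second: float) -> float:
    """Classical two-stage selected-mean estimator, unit-variance form.

    Independent reference implementation of the drop-the-losers
    conditionally unbiased estimator for unit-variance observations with
    one stage-1 and one stage-2 observation per arm and no futility
    gate:

        z - (1/sqrt(2)) * phi(sqrt(2) (z - v)) / Phi(sqrt(2) (z - v))

    with ``z`` the within-arm average of the selected arm's two
    observations and ``v`` the runner-up stage-1 value.  Used only as a
    cross-check of the general formula's limiting case.
    """
    w = math.sqrt(2.0) * (z - x_second)
    return z - mills_ratio(w) / math.sqrt(2.0)
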