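"""Trial design, observed-data containers and the reference estimators.

The setting is a two-stage adaptive seamless phase II/III trial: ``k``
experimental arms and a shared control are run in stage 1 with ``n1``
subjects per arm; the empirically best experimental arm is selected and,
if its observed stage-1 advantage over control reaches the futility
boundary ``b``, that arm and the control continue to stage 2 with ``n2``
subjects per arm.  Outcomes are normal with known common standard
deviation ``sigma``, so arm-level sample means are sufficient.

This module holds the fixed design quantities, the selection-and-gate
rule, the pooled (maximum-likelihood) means and the two reference
estimators of the selected-arm-versus-control difference: the naive MLE,
which ignores selection and gating, and the stage-2-only estimator,
which discards stage-1 data and is conditionally unbiased by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DesignConfig",
    "TrialData",
    "ParameterVector",
    "EstimateSet",
    "select_and_gate",
    "pooled_means",
    "naive_estimate",
    "stage2_estimate",
    "naive_vector",
]


@dataclass(frozen=True)
class DesignConfig:
    """Fixed quantities of a two-stage selection design.

    Parameters
    ----------
    k : int
        Number of experimental arms in stage 1 (>= 1).
    n1, n2 : int
        Per-arm sample sizes in stage 1 and stage 2.  Allocation is
        equal across arms within each stage; only the selected arm and
        the control are observed in stage 2.
    sigma : float
        Known common outcome standard deviation (outcome units).
    b : float
        Futility boundary on the stage-1 difference scale.  ``-inf``
        disables the gate (the trial always continues).
    """

    k: int
    n1: int
    n2: int
    sigma: float
    b: float = -math.inf

    def __post_init__(self) -> None:
        if not isinstance(self.k, (int, np.integer)) or self.k < 1:
            raise ValueError(f"k must be an integer >= 1, got {self.k!r}")
        for name in ("n1", "n2"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError(f"sigma must be a positive finite number, got {self.sigma!r}")
        if math.isnan(self.b) or self.b == math.inf:
            raise ValueError(f"b must be finite or -inf, got {self.b!r}")

    @property
    def t(self) -> float:
        """Selection time: fraction of selected-arm/control information at the interim."""
        return self.n1 / (self.n1 + self.n2)

    @property
    def sigma1_sq(self) -> float:
        """Variance of a stage-1 arm mean, sigma^2 / n1."""
        return self.sigma**2 / self.n1

    @property
    def sigma2_sq(self) -> float:
        """Variance of a stage-2 arm mean, sigma^2 / n2."""
        return self.sigma**2 / self.n2

    @property
    def se_unit(self) -> float:
        """SD of a single treatment-control difference pooled over both stages.

        ``sqrt(2 sigma^2 / (n1 + n2))``; bias and root-MSE summaries are
        conventionally reported in these units.
        """
        return math.sqrt(2.0 * self.sigma**2 / (self.n1 + self.n2))

    @property
    def has_gate(self) -> bool:
        return math.isfinite(self.b)


def select_and_gate(x: np.ndarray, design: DesignConfig) -> tuple[int, bool]:
    """Apply the stage-1 selection rule and futility gate.

    Parameters
    ----------
    x : array of length k+1
        Stage-1 sample means; index 0 is the control, 1..k experimental.

    Returns
    -------
    (S, continued)
        ``S`` is the selected experimental arm (1-based index into
        ``x``); ties break to the lowest index (a measure-zero event
        under the continuous model, fixed for reproducibility).
        ``continued`` is ``x[S] - x[0] >= b`` with a non-strict
        inequality.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (design.k + 1,):
        raise ValueError(
            f"stage-1 mean vector must have length k+1={design.k + 1}, got shape {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("stage-1 means must all be finite")
    S = 1 + int(np.argmax(x[1:]))  # argmax returns the first maximiser: lowest index wins
    continued = bool(x[S] - x[0] >= design.b)
    return S, continued


@dataclass(frozen=True)
class TrialData:
    """Observed arm-level summaries of one trial.

    ``x`` holds the stage-1 means (control first), ``y0``/``yS`` the
    stage-2 means for control and selected arm; the latter exist exactly
    when the trial passed the futility gate.
    """

    design: DesignConfig
    x: np.ndarray
    y0: float | None = None
    yS: float | None = None
    S: int = field(init=False)
    continued: bool = field(init=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        S, continued = select_and_gate(x, self.design)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "continued", continued)
        have_stage2 = self.y0 is not None and self.yS is not None
        if continued and not have_stage2:
            raise ValueError("trial continued to stage 2 but y0/yS are missing")
        if not continued and (self.y0 is not None or self.yS is not None):
            raise ValueError("trial stopped for futility but stage-2 means were supplied")
        if have_stage2 and not (math.isfinite(self.y0) and math.isfinite(self.yS)):
            raise ValueError("stage-2 means must be finite")

    def _require_continued(self) -> None:
        if not self.continued:
            raise ValueError(
                "trial stopped for futility at stage 1; estimation conditions on continuation"
            )


@dataclass(frozen=True)
class ParameterVector:
    """True (or working) arm means: control mean and the k experimental means."""

    mu0: float
    mu: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "mu", mu)
        if not (math.isfinite(self.mu0) and np.all(np.isfinite(mu))):
            raise ValueError("means must be finite")

    @property
    def k(self) -> int:
        return self.mu.shape[0]

    @property
    def theta(self) -> np.ndarray:
        """Treatment differences mu_i - mu0."""
        return self.mu - self.mu0

    @classmethod
    def from_theta(cls, theta: np.ndarray, mu0: float = 0.0) -> "ParameterVector":
        return cls(mu0=mu0, mu=np.asarray(theta, dtype=float) + mu0)


@dataclass(frozen=True)
class EstimateSet:
    """The four difference estimates and their per-arm components."""

    naive: float
    stage2: float
    unbiased: float
    bias_adjusted: float
    z0_mle: float
    zS_mle: float
    z0_chn: float
    zS_chn: float
    iteration_count: int

    def as_dict(self) -> dict:
        return {
            "naive": self.naive,
            "stage2": self.stage2,
            "unbiased": self.unbiased,
            "bias_adjusted": self.bias_adjusted,
            "z0_mle": self.z0_mle,
            "zS_mle": self.zS_mle,
            "z0_chn": self.z0_chn,
            "zS_chn": self.zS_chn,
            "iteration_count": self.iteration_count,
        }


def pooled_means(trial: TrialData) -> tuple[float, float]:
    """Precision-weighted means over both stages, (z0_mle, zS_mle).

    ``z_i = t x_i + (1 - t) y_i`` with t the selection time; these are
    the maximum-likelihood estimators of the control and selected-arm
    means ignoring selection.
    """
    trial._require_continued()
    t = trial.design.t
    z0 = t * trial.x[0] + (1.0 - t) * trial.y0
    zS = t * trial.x[trial.S] + (1.0 - t) * trial.yS
    return float(z0), float(zS)


def naive_estimate(trial: TrialData) -> float:
    """Naive MLE of the selected-minus-control difference, zS_mle - z0_mle."""
    z0, zS = pooled_means(trial)
    return zS - z0


def stage2_estimate(trial: TrialData) -> float:
    """Stage-2-only difference yS - y0; ignores stage-1 data entirely."""
    trial._require_continued()
    return float(trial.yS - trial.y0)


def naive_vector(trial: TrialData) -> np.ndarray:
    """Naive difference estimates for all k arms.

    The selected arm uses the pooled two-stage difference; dropped arms
    only have stage-1 data, so their entries are ``x_i - x_0``.
    """
    trial._require_continued()
    d = trial.x[1:] - trial.x[0]
    d = d.astype(float).copy()
    d[trial.S - 1] = naive_estimate(trial)
    return d
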