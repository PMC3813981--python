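"""Brute-force Monte-Carlo oracles.

These are the arbiters for every closed-form quantity in the package:
conditional expectations and biases estimated by plain rejection
sampling, and binned frequencies for the selection density.  They are
deliberately free of any analytic shortcut so that agreement with the
quadrature/Mills-ratio paths is an independent certification.

Oracle generators use a separate SeedSequence spawn-key family from the
simulator so the two never share streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .design import DesignConfig, ParameterVector
from .simulate import TrialBatch, evaluate_estimators, sample_continuing_batch

__all__ = [
    "OracleResult",
    "oracle_rng",
    "mc_conditional_mean",
    "mc_selection_histogram",
    "stat_naive",
    "stat_stage2",
    "stat_unbiased",
    "stat_bias_adjusted",
    "stat_umvue_selected",
    "stat_umvue_control",
    "stat_dropped_difference",
]


@dataclass(frozen=True)
class OracleResult:
    estimate: float
    mc_se: float
    n_used: int
    target: str

    def within(self, value: float, n_se: float = 3.0) -> bool:
        return abs(self.estimate - value) <= n_se * self.mc_se


def oracle_rng(seed: int, stream: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(1, stream))
    return np.random.Generator(np.random.Philox(ss))


# ready-made batch statistics -------------------------------------------------

def stat_naive(batch: TrialBatch) -> np.ndarray:
    return evaluate_estimators(batch, include_bias_adjusted=False)["naive"]


def stat_stage2(batch: TrialBatch) -> np.ndarray:
    return evaluate_estimators(batch, include_bias_adjusted=False)["stage2"]


def stat_unbiased(batch: TrialBatch) -> np.ndarray:
    return evaluate_estimators(batch, include_bias_adjusted=False)["unbiased"]


def stat_bias_adjusted(batch: TrialBatch) -> np.ndarray:
    return evaluate_estimators(batch, include_bias_adjusted=True)["bias_adjusted"]


def stat_umvue_selected(batch: TrialBatch) -> np.ndarray:
    """Selected-arm mean UMVUE, recomputed from the batch arrays."""
    from .umvue import mills_ratio

    design = batch.design
    t = design.t
    idx = np.arange(batch.n)
    zS = t * batch.x[idx, batch.S] + (1 - t) * batch.yS
    s = math.sqrt(design.sigma1_sq * (1 - t))
    B = batch.x[:, 0] + design.b
    if design.k >= 2:
        xe = batch.x[:, 1:].copy()
        xe[idx, batch.S - 1] = -np.inf
        m = np.maximum(B, xe.max(axis=1))
    else:
        m = B
    out = zS.copy()
    fin = np.isfinite(m)
    out[fin] -= t / (1 - t) * s * mills_ratio((zS[fin] - m[fin]) / s)
    return out


def stat_umvue_control(batch: TrialBatch) -> np.ndarray:
    from .umvue import mills_ratio

    design = batch.design
    t = design.t
    idx = np.arange(batch.n)
    z0 = t * batch.x[:, 0] + (1 - t) * batch.y0
    if not design.has_gate:
        return z0
    s = math.sqrt(design.sigma1_sq * (1 - t))
    W1 = (batch.x[idx, batch.S] - design.b - z0) / s
    return z0 + t / (1 - t) * s * mills_ratio(W1)


def stat_dropped_difference(arm: int) -> Callable[[TrialBatch], np.ndarray]:
    """Stage-1 difference x_arm - x_0 of a (dropped) arm, as a batch statistic."""

    def _stat(batch: TrialBatch) -> np.ndarray:
        return batch.x[:, arm] - batch.x[:, 0]

    return _stat


def mc_conditional_mean(
    statistic: Callable[[TrialBatch], np.ndarray],
    truth: ParameterVector,
    design: DesignConfig,
    n: int,
    seed: int,
    select_arm: int | None = None,
    target: str = "statistic",
    max_attempts: int = 10**9,
) -> OracleResult:
    """Mean of a trial-level statistic over exactly ``n`` continuing trials.

    If ``select_arm`` is given, only trials selecting that arm count,
    i.e. the expectation is conditional on {S = select_arm, continue}.
    """
    if n < 1_000:
        raise ValueError("n must be >= 1000 for a meaningful oracle run")
    rng = oracle_rng(seed)
    vals: list[np.ndarray] = []
    got = 0
    attempts = 0
    while got < n:
        want = n - got
        # oversample to cover the selection restriction in few rounds
        factor = design.k if select_arm is not None else 1
        batch, att, _ = sample_continuing_batch(
            truth, design, min(max(2_000, 2 * factor * want), 500_000), rng,
            max_attempts=max_attempts - attempts,
        )
        attempts += att
        v = np.asarray(statistic(batch), dtype=float)
        if select_arm is not None:
            v = v[batch.S == select_arm]
        vals.append(v)
        got += v.size
    allv = np.concatenate(vals)[:n]
    return OracleResult(
        estimate=float(allv.mean()),
        mc_se=float(allv.std(ddof=1) / math.sqrt(n)),
        n_used=n,
        target=target,
    )


def mc_selection_histogram(
    truth: ParameterVector,
    design: DesignConfig,
    bins: np.ndarray,
    n: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned joint frequencies of (S, D_S) over ``n`` unconditional draws.

    Returns ``(freq, freq_mc_se)`` of shape (k, len(bins)-1): the
    fraction of all draws with arm i selected and its stage-1 difference
    in each bin.  The futility gate plays no role (selection happens
    regardless); comparison target is the integral of the selection
    density over each bin.
    """
    bins = np.asarray(bins, dtype=float)
    rng = oracle_rng(seed, stream=1)
    mu = np.concatenate([[truth.mu0], truth.mu])
    s1 = math.sqrt(design.sigma1_sq)
    counts = np.zeros((design.k, len(bins) - 1))
    done = 0
    while done < n:
        m = min(500_000, n - done)
        x = rng.normal(mu, s1, size=(m, design.k + 1))
        S0 = np.argmax(x[:, 1:], axis=1)
        d = x[np.arange(m), S0 + 1] - x[:, 0]
        for i in range(design.k):
            counts[i] += np.histogram(d[S0 == i], bins=bins)[0]
        done += m
    freq = counts / n
    mc_se = np.sqrt(np.maximum(freq * (1 - freq), 1e-300) / n)
    return freq, mc_se
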