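"""Trial simulation and operating characteristics.

Replicates the conditional-on-continuation experiment used to study the
estimators: draw stage-1 arm means, apply selection and the futility
gate, keep drawing until a fixed number of continuing trials has been
collected, evaluate all four estimators on each, and summarise mean
conditional bias and root-MSE (raw and in SE units) together with the
selection/continuation probabilities.

Per-cell RNG substreams are derived from ``(seed, t-index, b-index)``
through :class:`numpy.random.SeedSequence` spawn keys on a counter-based
Philox generator, so every grid cell is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignConfig, ParameterVector, TrialData
from .bias_adjusted import SolverConfig, solve_bias_adjusted_batch
from .umvue import mills_ratio

__all__ = [
    "SimulationSpec",
    "TrialBatch",
    "simulate_trial",
    "sample_continuing_batch",
    "evaluate_estimators",
    "run_conditional",
    "operating_grid",
]

_ESTIMATORS = ("naive", "stage2", "unbiased", "bias_adjusted")


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for a conditional-on-continuation simulation grid.

    ``n_total`` is the per-comparison total sample size ``n1 + n2``;
    each selection time t in ``t_values`` is realised as
    ``n1 = round(t * n_total)``.  ``n_continuing`` continuing replicates
    are retained per (t, b) cell.
    """

    truth: ParameterVector
    t_values: tuple
    b_values: tuple
    sigma: float = 1.0
    n_total: int = 100
    n_continuing: int = 10_000
    seed: int = 0
    include_bias_adjusted: bool = True
    max_attempts: int = 10**9

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_values", tuple(float(t) for t in self.t_values))
        object.__setattr__(self, "b_values", tuple(float(b) for b in self.b_values))
        if self.n_continuing < 1:
            raise ValueError("n_continuing must be >= 1")
        for t in self.t_values:
            if not 0.0 < t < 1.0:
                raise ValueError(f"t values must lie in (0, 1), got {t}")

    def design_for(self, t: float, b: float) -> DesignConfig:
        n1 = int(round(t * self.n_total))
        n2 = self.n_total - n1
        if n1 < 1 or n2 < 1:
            raise ValueError(f"t={t} with n_total={self.n_total} gives an empty stage")
        return DesignConfig(k=self.truth.k, n1=n1, n2=n2, sigma=self.sigma, b=b)


@dataclass
class TrialBatch:
    """Vectorised continuing trials: arrays across replicates."""

    design: DesignConfig
    x: np.ndarray        # (n, k+1) stage-1 means
    S: np.ndarray        # (n,) selected arm, 1-based
    y0: np.ndarray       # (n,)
    yS: np.ndarray       # (n,)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def d_stage1(self) -> np.ndarray:
        """Selected-arm stage-1 difference x_S - x_0."""
        return self.x[np.arange(self.n), self.S] - self.x[:, 0]


def simulate_trial(
    truth: ParameterVector, design: DesignConfig, rng: np.random.Generator
) -> TrialData:
    """Draw one trial; stage-2 means exist only if the gate is passed."""
    if truth.k != design.k:
        raise ValueError("truth and design disagree on k")
    mu = np.concatenate([[truth.mu0], truth.mu])
    x = rng.normal(mu, math.sqrt(design.sigma1_sq))
    S = 1 + int(np.argmax(x[1:]))
    if x[S] - x[0] >= design.b:
        s2 = math.sqrt(design.sigma2_sq)
        y0 = float(rng.normal(truth.mu0, s2))
        yS = float(rng.normal(truth.mu[S - 1], s2))
        return TrialData(design=design, x=x, y0=y0, yS=yS)
    return TrialData(design=design, x=x)


def sample_continuing_batch(
    truth: ParameterVector,
    design: DesignConfig,
    n: int,
    rng: np.random.Generator,
    max_attempts: int = 10**9,
    chunk: int = 200_000,
) -> tuple[TrialBatch, int, int]:
    """Rejection-sample ``n`` continuing trials.

    Returns ``(batch, attempts, kept)`` where ``kept`` counts every
    continuing trial among the ``attempts`` simulated ones (including
    the surplus beyond ``n``), so ``kept / attempts`` estimates the
    continuation probability without truncation bias.
    """
    mu = np.concatenate([[truth.mu0], truth.mu])
    s1 = math.sqrt(design.sigma1_sq)
    s2 = math.sqrt(design.sigma2_sq)
    xs, Ss = [], []
    got = 0
    attempts = 0
    while got < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"attempt cap {max_attempts} reached with only {got}/{n} continuing "
                f"trials; P(continue) may be near zero for this cell"
            )
        m = min(chunk, max_attempts - attempts)
        x = rng.normal(mu, s1, size=(m, design.k + 1))
        attempts += m
        S = 1 + np.argmax(x[:, 1:], axis=1)
        keep = x[np.arange(m), S] - x[:, 0] >= design.b
        xs.append(x[keep])
        Ss.append(S[keep])
        got += int(keep.sum())
    kept = got
    x = np.concatenate(xs)[:n]
    S = np.concatenate(Ss)[:n]
    y0 = rng.normal(truth.mu0, s2, size=n)
    yS = rng.normal(truth.mu[S - 1], s2, size=n)
    return TrialBatch(design=design, x=x, S=S, y0=y0, yS=yS), attempts, kept


def evaluate_estimators(
    batch: TrialBatch,
    include_bias_adjusted: bool = True,
    solver: SolverConfig | None = None,
) -> dict[str, np.ndarray]:
    """All four difference estimates, vectorised across a batch."""
    design = batch.design
    t = design.t
    n, k = batch.n, design.k
    idx = np.arange(n)
    xS = batch.x[idx, batch.S]
    x0 = batch.x[:, 0]
    z0 = t * x0 + (1 - t) * batch.y0
    zS = t * xS + (1 - t) * batch.yS

    out: dict[str, np.ndarray] = {}
    out["naive"] = zS - z0
    out["stage2"] = batch.yS - batch.y0

    # conditionally unbiased estimator, vectorised Mills form
    s = math.sqrt(design.sigma1_sq * (1 - t))
    coef = t / (1 - t) * s
    B = x0 + design.b
    if k >= 2:
        xe = batch.x[:, 1:].copy()
        xe[idx, batch.S - 1] = -np.inf
        x_second = xe.max(axis=1)
    else:
        x_second = np.full(n, -np.inf)
    m = np.maximum(B, x_second)
    finite_m = np.isfinite(m)
    zS_chn = zS.copy()
    zS_chn[finite_m] -= coef * mills_ratio((zS[finite_m] - m[finite_m]) / s)
    if design.has_gate:
        W1 = (xS - design.b - z0) / s
        z0_chn = z0 + coef * mills_ratio(W1)
    else:
        z0_chn = z0
    out["unbiased"] = zS_chn - z0_chn

    if include_bias_adjusted:
        theta_mle = batch.x[:, 1:] - x0[:, None]
        theta_mle[idx, batch.S - 1] = out["naive"]
        theta, _ = solve_bias_adjusted_batch(theta_mle, batch.S, design, solver, on_fail="clamp")
        out["bias_adjusted"] = theta[idx, batch.S - 1]
    return out


def run_conditional(
    spec: SimulationSpec, t: float, b: float, rng: np.random.Generator | None = None
) -> dict:
    """One grid cell: collect continuing trials, summarise bias, root-MSE
    and the selection/continuation probabilities (with MC standard errors)."""
    design = spec.design_for(t, b)
    if rng is None:
        rng = _cell_rng(spec, t, b)
    batch, attempts, kept = sample_continuing_batch(
        spec.truth, design, spec.n_continuing, rng, spec.max_attempts
    )
    est = evaluate_estimators(batch, spec.include_bias_adjusted)
    theta_S = spec.truth.theta[batch.S - 1]
    n = batch.n
    cell: dict = {
        "t": t, "b": b, "n1": design.n1, "n2": design.n2,
        "se_unit": design.se_unit, "n_continuing": n,
        "pr_continue": kept / attempts,
        "pr_continue_mc_se": math.sqrt(kept / attempts * (1 - kept / attempts) / attempts),
        "estimators": {},
        "selection": {},
    }
    for name, values in est.items():
        err = values - theta_S
        bias = err.mean()
        mse = np.mean(err**2)
        rmse = math.sqrt(mse)
        bias_se = err.std(ddof=1) / math.sqrt(n)
        # delta-method MC SE of sqrt(MSE)
        rmse_se = np.std(err**2, ddof=1) / math.sqrt(n) / (2 * rmse) if rmse > 0 else 0.0
        cell["estimators"][name] = {
            "bias": bias, "bias_mc_se": bias_se,
            "rmse": rmse, "rmse_mc_se": rmse_se,
            "bias_se_units": bias / design.se_unit,
            "bias_se_units_mc_se": bias_se / design.se_unit,
            "rmse_se_units": rmse / design.se_unit,
            "rmse_se_units_mc_se": rmse_se / design.se_unit,
        }
    d_all = batch.x[:, 1:] - batch.x[:, 0][:, None]  # all stage-1 differences
    for i in range(1, design.k + 1):
        sel_i = batch.S == i
        p_i = sel_i.mean()
        others_beat = np.ones(n, dtype=bool)
        if design.has_gate and design.k >= 2:
            others = np.delete(d_all, i - 1, axis=1)
            others_beat = (others >= b).all(axis=1)
        p_joint = (sel_i & others_beat).mean()
        cell["selection"][i] = {
            "pr_select_given_continue": p_i,
            "pr_select_mc_se": math.sqrt(max(p_i * (1 - p_i), 1e-300) / n),
            "pr_select_and_others_beat_b": p_joint,
            "pr_joint_mc_se": math.sqrt(max(p_joint * (1 - p_joint), 1e-300) / n),
        }
    return cell


def _cell_rng(spec: SimulationSpec, t: float, b: float) -> np.random.Generator:
    ti = spec.t_values.index(t) if t in spec.t_values else len(spec.t_values)
    bv = spec.b_values
    bi = bv.index(b) if b in bv else len(bv)
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(0, ti, bi))
    return np.random.Generator(np.random.Philox(ss))


def operating_grid(spec: SimulationSpec) -> pd.DataFrame:
    """Map :func:`run_conditional` over the (t, b) grid.

    Returns a long-format table with columns (t, b, estimator, metric,
    value, mc_se); probability summaries appear with estimator ``""``.
    """
    rows = []
    for b in spec.b_values:
        for t in spec.t_values:
            cell = run_conditional(spec, t, b)
            for name, st in cell["estimators"].items():
                for metric in ("bias", "rmse", "bias_se_units", "rmse_se_units"):
                    rows.append(
                        dict(t=t, b=b, estimator=name, metric=metric,
                             value=st[metric], mc_se=st[f"{metric}_mc_se"])
                    )
            rows.append(dict(t=t, b=b, estimator="", metric="pr_continue",
                             value=cell["pr_continue"], mc_se=cell["pr_continue_mc_se"]))
            for i, st in cell["selection"].items():
                rows.append(dict(t=t, b=b, estimator="", metric=f"pr_select_{i}_given_continue",
                                 value=st["pr_select_given_continue"], mc_se=st["pr_select_mc_se"]))
                rows.append(dict(t=t, b=b, estimator="", metric=f"pr_select_{i}_others_beat_b",
                                 value=st["pr_select_and_others_beat_b"], mc_se=st["pr_joint_mc_se"]))
    return pd.DataFrame(rows)
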