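"""Convenience aggregator: all four estimates for one observed trial."""

from __future__ import annotations

from .bias_adjusted import SolverConfig, bias_adjusted_estimate
from .design import EstimateSet, TrialData, naive_estimate, pooled_means, stage2_estimate
from .umvue import umvue_control, umvue_selected

__all__ = ["estimate_all"]


def estimate_all(trial: TrialData, solver: SolverConfig | None = None) -> EstimateSet:
    """Naive, stage-2, conditionally unbiased and bias-adjusted estimates."""
    z0, zS = pooled_means(trial)
    zS_chn = umvue_selected(trial)
    z0_chn = umvue_control(trial)
    adj, iters = bias_adjusted_estimate(trial, solver)
    return EstimateSet(
        naive=naive_estimate(trial),
        stage2=stage2_estimate(trial),
        unbiased=zS_chn - z0_chn,
        bias_adjusted=adj,
        z0_mle=z0,
        zS_mle=zS,
        z0_chn=z0_chn,
        zS_chn=zS_chn,
        iteration_count=iters,
    )
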