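# Methods

## Model and conditioning

Stage-1 sample means `X_0, …, X_k` are independent normals with means
`μ_i` and variance `σ₁² = σ²/n1`; the selected arm `S = argmax_{i≥1} X_i`
and the control contribute stage-2 means `Y_S, Y_0` with variance
`σ₂² = σ²/n2`.  The trial continues iff `X_S − X_0 ≥ b` (non-strict;
ties at the argmax break to the lowest index — both events have
probability zero under the continuous model, but fixed rules keep runs
reproducible).  The outcome SD `σ` is a known design input; no variance
estimation happens anywhere.  Allocation is equal across arms within
each stage.  All estimation is conditional on the trial continuing: a
stopped trial carries no stage-2 data and no estimate is defined for it.

`b = −∞` is represented as the IEEE `-inf` sentinel, and every formula
treats it exactly (corrections vanish identically rather than
approximately).

## The conditionally unbiased estimator

Given continuation and the selection made, `Y_S` is unbiased for `μ_S`.
Conditioning it on the sufficient statistics yields the minimum-variance
improvement.  Given the pooled mean `Z_S = tX_S + (1−t)Y_S`, the
stage-1 mean satisfies `X_S | Z_S ~ N(Z_S, σ₁²(1−t))`, and the event
truncates it below at `m = max{X_0 + b, X_(2)}` (`X_(2)` = runner-up
experimental mean; for `k = 1` the runner-up is `−∞` and the truncation
degenerates to the gate alone, matching the single-arm futility-design
special case).  Since `Y_S = (Z_S − tX_S)/(1−t)`,

    E[Y_S | stats, event] = Z_S − (t/(1−t)) · s · φ(W)/Φ(W),
    W = (Z_S − m)/s,  s = σ₁√(1−t),

and symmetrically for the control with upper truncation at
`B₁ = X_S − b`.  Closed-form checks: at `b = −∞` the control estimator
*equals* the pooled mean, and with `σ = 1, n1 = n2 = 1` the selected-arm
formula reduces to the classical two-stage drop-the-losers estimator
(coded independently in `cohen_sackrowitz_selected` and asserted equal
at 1e−12).

The package certifies the formula by its defining property rather than
by symbolic manipulation alone: brute-force conditional Monte Carlo
(module `oracle`) confirms `E[ẑ_S | S = i, continue] = μ_i` and
`E[ẑ_0 | S = i, continue] = μ_0` per selected arm on a grid of designs
(the test suite uses 2–3×10⁴ conditional replicates per cell with
3-MC-SE tolerances; the cells cover k ∈ {1,2,3}, b ∈ {−∞, 0, 0.05},
t ∈ {0.2, 0.5, 0.8} and exchangeable/non-exchangeable means).  During
development the estimator value at the bundled example's observed data
was additionally reproduced by regression-adjusted rejection sampling of
`E[Y_S | statistics ≈ observed, event]` — the closed form and the
brute-force conditional expectation agree.

Mills ratios are evaluated in log space through `scipy.special.log_ndtr`
(relative error ~1e−14 over the whole real line), which removes the 0/0
failure mode for deeply negative arguments without a hand-rolled
asymptotic series.

## The bias-adjusted estimator

For a working difference vector `θ` the conditional bias of the naive
estimate vector is computable exactly.  Augmenting the stage-1
differences `D_i = X_i − X_0` (variance `2σ₁²`, covariance `σ₁²`) with
`W₀ = X_0 − μ₀` gives `W_i = D_i + W₀ = X_i − μ₀`: independent normals
`N(θ_i, σ₁²)` with `W₀ ~ N(0, σ₁²)` uncorrelated with all of them.  On
the event `{S = s, D_s ≥ b}` every needed expectation becomes a single
integral over `W_s` whose inner factors are normal CDFs and closed
truncated-normal moments; the selected arm's bias is
`t·(E[D_s|event] − θ_s)` and a dropped arm's is `E[D_p|event] − θ_p`.

Two conditioning conventions are possible for the dropped arms (sum
over all possible selecting arms vs. the observed selection event).
The package conditions **all** components on the observed event
`{S = s_obs, D ≥ b}`: this is the information actually available at
analysis time, and it reproduces the bundled worked example's converged
value and iteration count exactly (1.1347 after 15 iterations at
tolerance 5·10⁻⁴).

Quadrature: fixed Gauss–Legendre nodes (default 240) on ±8.5 marginal
SDs — the integrands are Gaussian-tailed, so the truncation error is
below 1e−15 and the node error below 1e−12 (asserted against adaptive
`scipy.integrate.quad` with `epsabs = 1e−12`).  The batched evaluation
used by the solver and simulator computes every expectation under
softmax-normalised log-weights with Mills-ratio inner moments, so it
remains finite even when the event probability underflows for extreme
working vectors.

Solver: plain fixed-point `θ^(r+1) = θ̂_MLE − b(θ^(r))` from
`θ^(0) = θ̂_MLE`, stopping when the Euclidean step is ≤ `tol`
(default 5·10⁻⁴), cap 500 iterations.  No damping is applied on the
primary pass — damping would change the iteration count, which is part
of the estimator's observable behaviour.  For roughly one in 10⁴–10⁵
simulated trials at late selection times the plain map diverges: the
observed configuration (a dropped arm's stage-1 estimate far above the
selected arm's pooled estimate) admits no root of the bias equation.
The solver then retries with step halving, and — in simulation runs
only — finally projects iterates into a box of ±8 stage-1-difference
SDs around the naive vector and accepts the last iterate.  The
single-trial API instead raises with the trajectory attached, since for
an individual analysis the non-existence of the adjusted estimate is
worth surfacing.  At the simulator's replicate counts the affected
fraction shifts cell summaries by far less than one MC standard error.

## Simulator

`run_conditional` rejection-samples stage-1 mean vectors until a fixed
number of continuing trials is collected (matching the
"simulate until N continuations" convention for conditional operating
characteristics), then evaluates all four estimators vectorised.  An
attempt cap (default 10⁹ per cell) guards cells with near-zero
continuation probability.  Summaries: mean conditional bias and √MSE
per estimator, each raw and divided by the SE unit
`√(2σ²/(n1+n2))`, with per-cell MC standard errors; continuation
probability; per-arm selection probabilities given continuation; and
the joint probability that an arm is selected while all other arms'
stage-1 differences also clear the boundary.  Both bias scalings are
reported because the SE-unit scaling alone does not make gated designs
sample-size invariant (the gate acts on the stage-1 scale `σ₁`, which
moves relative to the SE unit as `t` changes at fixed `b`).

Grid cells draw from counter-based Philox substreams keyed by
`(seed, t-index, b-index)` via `SeedSequence` spawn keys, so any cell
is reproducible in isolation; the Monte-Carlo oracles use a disjoint
spawn-key family so validation never shares streams with the simulator.

Default conditions: `σ = 1`, per-comparison total `n1 + n2 = 100`
(selection times realised as `n1 = round(t·(n1+n2))`), exchangeable
small effects `θ = 0.05` or the graded vector `(0.025, …, 0.05)`,
boundaries `b ∈ {−∞, 0, 0.05, 0.1}`, and 10⁴ continuing replicates per
cell in the qualitative checks (2–3×10⁴ in the unbiasedness
certifications).  These sizes keep the full suite at about a minute on
one CPU while leaving 3-MC-SE tolerances tight enough to detect a
formula error an order of magnitude smaller than the biases being
corrected.

What the generator does *not* emulate: unknown or unequal outcome
variances, non-normal endpoints, unequal allocation, overrunning
subjects recruited during the interim analysis, or data-driven changes
to `n2`.  Passing tests therefore certify the estimators under the
stated normal known-variance model, not robustness beyond it.

## Known limitations

* The variance `σ²` is assumed known; plugging in an estimate voids
  the exact unbiasedness (no small-sample correction is attempted).
* No conditionally unbiased estimator is provided for dropped arms'
  means — only their conditional bias functions, which the
  bias-adjusted iteration needs.
* Confidence intervals are out of scope; the package estimates points
  only.
* The bias-adjusted estimate may fail to exist for extreme
  configurations (see the solver notes above); the unbiased estimator
  has no such pathology.
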