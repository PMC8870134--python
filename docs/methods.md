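# Methods

## The estimation problem

Surface EMG (sEMG) records the electrical activity of muscle at the skin.
Its amplitude envelope — the slow modulation of the 20–500 Hz interference
signal — tracks contraction intensity, and proportional myoelectric
control of a prosthesis requires mapping that envelope to a continuous
estimate of intended grip force. The EMG–force relation is nonlinear
(recruitment of mixed fibre types, rate coding) and shows hysteresis, so a
single global model fitted to one condition degrades when the force
profile changes. `emgforce` addresses this with a *multimodel* estimator:
a library of local Hammerstein–Wiener (H–W) sub-models, each identified on
one measurement couple (EMG envelope, force), combined at every time step
by validity weights derived from their instantaneous residues.

## Preprocessing

Each channel is processed independently:

1. full-wave rectification,
2. low-pass Butterworth envelope (order 6, cut-off 1 Hz; both defaults
   configurable), applied zero-phase (forward–backward) by default since
   the estimator runs offline — a causal mode exists for online use,
3. min–max normalisation d_n = (d_r − d_min)/(d_max − d_min).

Force traces run through the same chain so inputs and outputs share a
dimensionless scale. Normalisation is per measurement couple by default
(`norm_scope="per_trial"` in `run_scenario`): each couple is scaled to its
own range, the convention its sub-model is identified under. The
alternative `"pooled"` mode fits one range on the pooled training trials
and freezes it for validation data. Per-couple scaling is the default
because min–max ranges absorb session-to-session gain variability
(electrode placement, skin impedance); with pooled scaling each sub-model
bakes its own trial's gain into its parameters, which biases the library
toward whichever trial happens to match the test trial. Out-of-range
normalised values on validation data are never clipped, so the mapping
stays exactly invertible.

## Hammerstein–Wiener sub-models

Each sub-model is the serial chain

    u → f(·) → B(q)/F(q), delay nk → h(·) → y

with static nonlinearities f, h and a linear transfer function between
them. Defaults: nb = 2, nf = 2, nk = 1; piecewise-linear nonlinearities
with 10 uniformly spaced breakpoints over the observed signal range
(polynomial and identity families are available). At 1 kHz the one-sample
input delay is negligible against the 1 Hz envelope bandwidth.

### Identification

With the nonlinearity shapes frozen, z = h⁻¹(y) and v = f(u) satisfy the
ARX regression z(k) = Σⱼ bⱼ v(k−nk−j) − Σₘ fₘ z(k−m), which is linear in
(b, f) and is estimated by recursive least squares (RLS) over the whole
record:

    ε(k) = y(k) − θ̂(k−1)ᵀφ(k)
    P(k) = P(k−1) − P(k−1)φφᵀP(k−1) / (1 + φᵀP(k−1)φ)
    θ̂(k) = θ̂(k−1) + P(k) φ(k) ε(k)

with no forgetting (λ = 1), P(0) = 10⁴·I and θ̂(0) = 0; this recursion is
algebraically identical to batch least squares with prior precision
P(0)⁻¹, which the tests verify to 10⁻⁸. P is re-symmetrised every step to
stay positive definite under round-off.

The input-nonlinearity node values are then refit by linear least squares
(the regression is linear in the node values once (b, f) are fixed), the
input block is renormalised to pass through (0, 0) with unit mean slope
(resolving the gain ambiguity between blocks, the scale moving into b),
and the output-nonlinearity nodes are refit against the simulated
intermediate signal. The output nodes are projected onto the increasing
cone (pool-adjacent-violators) with a minimum slope of 5% of the mean
slope so that h stays strictly monotone and h⁻¹ well conditioned.

The alternation is not monotone in training error, so the best iterate by
training SSE is kept. Ten outer iterations (tolerance 10⁻⁶ on the flat
parameter vector) are the default: five left the noise-free recovery
benchmark at R² ≈ 0.990 while ten reaches ≈ 0.9997. Numerical guards:
an unstable RLS denominator estimate has its poles shrunk to radius 0.98
before simulation, and any non-finite intermediate aborts the loop,
returning the best previous iterate. A convergence flag records whether
the RLS trajectory settled (relative change < 1% over the last 10% of the
record).

The whole-record RLS pass has an optional numba-compiled kernel whose
arithmetic is identical to the NumPy reference loop (tested to 10⁻⁸); the
reference loop is used when numba is absent.

## The decision unit

For output channel j and time k, with F_ij the output of sub-model i
driven by multimodel input channel j and F_j the reference force:

    err_ij(k)  = |F_ij(k) − F_j(k)|
    err′_ij(k) = err_ij(k) / Σᵢ err_ij(k)
    μ_ij(k)    = 1 − err′_ij(k)

Residues are absolute values so the normalised residues lie in [0, 1];
when all residues at a time step sum to below 10⁻¹² the tie rule assigns
uniform weights 1/N. Validities always sum to N − 1, so three weighting
modes are provided:

- `normalised` (default): w = μ/Σμ, a convex combination — the fused
  output lies within the per-step min/max of the sub-model outputs;
- `unnormalised`: w = μ directly, which for N > 2 scales the output by
  up to N − 1 (kept for comparison);
- `switching`: hard selection of the most valid sub-model.

The reference force is a mandatory argument: the decision unit evaluates
pertinence against a measured or desired force, which is available in
offline validation. How a runtime controller would obtain a reference is
an open problem outside this package's scope. An optional moving-average
smoothing of the residues (default 0.25 s in the scenario runner, off in
the core API) stabilises weights under noisy references.

## Fixing the number of sub-models

Per-trial envelope distribution features (quartiles, IQR, variance,
skewness, excess kurtosis) are standardised and clustered with k-means
(fixed seed, n_init = 10) for each candidate N; the N with the highest
mean silhouette is suggested. This operationalises the visual box-plot /
density comparison an analyst would otherwise do. All-identical trials
have no silhouette and fall back to N = 1. A manual sub-model count
always overrides the suggestion. One representative couple per cluster
(nearest the centroid) trains each sub-model.

## Synthetic data generator

The generator emulates a handgrip-tracking experiment: 1 subject × 5
force profiles × 4 trials, three EMG channels at 1000 Hz. Profiles
(peak 50 N):

- `step`: five 10 s levels of 10, 20, …, 50 N (50 s),
- `saw`: two back-to-back linear ramps 0 → 50 N (40 s),
- `vol`: a seeded, 0.2 Hz-smoothed random walk clipped to [0, 50] N
  (30 s) — "freely varying" made reproducible,
- `single_level`: constant 50 N (30 s),
- `circle`: one half-cosine rise and fall over 10 s.

EMG is multiplicative amplitude modulation of band-limited noise:
EMG = gain · m_h · carrier + floor · gain · noise, where the carrier and
floor noise are unit-RMS white noise band-passed to 20–500 Hz, and
m = (F/F_max)^γ is the recruitment curve, passed through a first-order
lag (τ = 0.1 s) that produces hysteresis between rising and falling
phases. Channel parameters mimic ECR/FDS/FCR: gains (1.0, 0.8, 1.2),
γ = (0.8, 1.0, 1.3), noise floor 0.05. Session variability is a 5%
lognormal per-trial gain jitter; the measured force carries 0.3 N white
sensor noise (a ±0.6 N-accuracy dynamometer). Per-trial random streams
derive from the master seed and the (subject, profile, trial) coordinates,
so regeneration is bit-identical and order-independent.

What the generator does **not** model: motor-unit action potentials,
recruitment thresholds, electrode crosstalk, fatigue, movement artifact,
powerline interference. Tests passing on this data show the estimator
machinery is correct and that the pipeline recovers known generative
structure; they do not certify performance on physiological recordings.

## ANN baseline

The comparison model is a one-hidden-layer feed-forward network: 7
tangent-sigmoid hidden neurons, linear output layer, 4 output neurons.
Inputs are the three preprocessed envelopes plus two lagged samples each
(9 features); the lag spacing is 50 ms, since 1-sample lags carry no
information at a 1 Hz envelope bandwidth. With two force targets, the two
surplus outputs are trained against zero and dropped at reporting time,
keeping the printed architecture intact.

Training is batch Levenberg–Marquardt on the analytic residual Jacobian:
solve (JᵀJ + λI)δ = −Jᵀr, accept the step if the loss decreases (λ ÷ 10)
else reject (λ × 10); the accepted-step loss history is non-increasing by
construction, and at huge fixed λ the step collapses to small-step
gradient descent (a tested limit). Training rows are subsampled to at
most 4000 by striding; evaluation is per-sample.

## Validation scenarios and metrics

- Scenario 1: three step trials train three sub-models; a fourth,
  held-out step trial is the target (same kind, distinct trials).
- Scenario 2: one step and one circle trial train two sub-models; a
  freely varying (vol) trial is the target.
- Scenario 3: step, circle and saw trials train three sub-models; a vol
  trial is the target.

The test trial never contributes to any sub-model's training data
(asserted structurally). Metrics are R² = 1 − SSres/SStot (can be
negative) and RMSE, computed on the normalised signals past the library
warm-up (the first max(nb+nk, nf) samples, affected by zero initial
conditions). Wall-clock time is hardware-dependent and is not asserted
anywhere.

## Problem sizes

Unit tests run on reduced records (100–200 Hz, hundreds to thousands of
samples); the scenario-level tests and `scripts/acceptance.py` use the
full study conditions (1 kHz, full trial durations, default noise). The
10-seed scenario comparison uses the complete pipeline per seed.

## Known limitations

- The output nonlinearity is constrained monotone increasing; a genuinely
  decreasing or non-monotone EMG→force relation would need the polynomial
  family and an external linearisation.
- Equation-error (ARX) RLS is biased under heavy output noise; at the 5%
  noise level of the recovery benchmark the bias is negligible, but very
  noisy references would favour an output-error refinement.
- The decision unit requires a reference force, so the estimator as
  shipped is an offline/validation tool, not a closed-loop controller.
- k-means with silhouette selection assumes roughly convex, similarly
  sized feature clusters; heavily imbalanced trial sets may suggest the
  wrong N (the manual override exists for this reason).
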