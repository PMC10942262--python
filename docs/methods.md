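# Methods

This note documents the models implemented in `wormflow`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions taken where the underlying
procedures leave choices open.

## Data model and preprocessing

The pipeline starts from two-channel ratiometric fluorescence (a
calcium-sensitive YFP over a calcium-insensitive CFP, ~4 volumes/s,
recordings of ~6000 time points). Cleaning proceeds in a fixed order:

1. 5-point running median on both channels (windows shrink at the
   series boundaries rather than padding with fabricated values);
2. outlier time points where filtered CFP < 1/10 of its series median
   (strict inequality; an all-zero trace flags nothing), set missing in
   both channels;
3. gap completion by the median of the two observed raw neighbours on
   each side of the gap (observed values only; a gap with no observed
   neighbour stays missing);
4. neuron exclusion when the outlier count exceeds 400 or gaps remain;
5. YFP/CFP ratio, ordinary-least-squares linear detrend against the
   time index (photobleach compensation), then z-scoring, so each kept
   trace has mean 0 and SD 1 to ~1e-9;
6. a "nonrandom" gate for the regression models: biased
   (divide-by-N) autocorrelation at lag 20 must exceed 0.3; constant
   traces fail the gate rather than erroring, since downstream treats
   gated-out neurons simply as missing.

## Motif extraction (TDE-RICA)

Each trace is delay-embedded with k = 300, τ = 1 (a 6000-point trace
gives 5701 embedded time points); embeddings are stacked neuron-major
and concatenated across the animals with complete data. Reconstruction
ICA minimizes λ‖WWᵀXᵀ − Xᵀ‖₂² + ‖g(WᵀXᵀ)‖₁ with
g(x) = ½ log cosh 2x over the occurrence matrix W; motifs are
M = WᵀXᵀ. Choices:

* **λ = 1** by default (the customary reconstruction-ICA weight),
  exposed in the API and CLI.
* **Optimizer**: L-BFGS-B with the analytic gradient
  2λ(RMᵀ + A RᵀW) + A tanh(2M)ᵀ (A = Xᵀ, R = WM − A), max 1000
  iterations, gradient tolerance 1e-6. Cost decrease over accepted
  iterates is asserted in the tests. If the optimizer stops early the
  best iterate is returned with `converged=False`.
* **Initialization**: i.i.d. Gaussian W scaled by 1/√rows, seeded;
  identical seeds give bitwise-identical fits.
* **No whitening**: the cost operates on the raw embedded data
  (inputs are already z-scored per neuron); whitening is deliberately
  not applied.
* **Component count n** is a user choice (no automatic selection); the
  factorization is identified only up to sign and permutation, so
  comparisons use Hungarian matching on absolute correlation with signs
  fixed to make matched correlations positive.

**Missing-data completion.** With (M, W) frozen, new motif columns
(unseen neurons) and occurrence rows (unseen animals) minimize
‖W_all·M_all − X_allᵀ‖² restricted to observed entries (NaN residuals
are zeroed in both cost and gradient), again by L-BFGS-B, seeded. New
blocks must have at least one observed entry per neuron and per time
block. Values at masked positions provably never influence the result
(asserted in tests by perturbing them).

**Occurrence analytics** (per-sample lagged cross-correlations of the
occurrence columns, averaged across animals, plus paired occurrence
trajectories) use mean-removed series normalized by full-series SDs; a
zero-variance component yields NaN rather than an arbitrary number.

## Connectome wiring

Chemical synapses are directed, gap junctions bidirectional; duplicate
edge-list rows aggregate by summing synapse counts. Counts are carried
but never used as weights — the models are count-agnostic. For a
target neuron the explanatory set is its observed chemical inputs, gap
partners, and always its own history; in **indirect** mode each
*unobserved* direct input is replaced by that neuron's own observed
inputs. Substitution is exactly one synaptic step deep — if the
missing neuron's inputs are also missing, that branch is dropped, not
recursed — and gap partners of the missing neuron count as its inputs
under the bidirectional rule. Salt-sensor targets (ASEL/R, AWCL/R,
BAGL/R, ASHL/R) get the stimulus series appended as a pseudo-neuron
`STIM`.

## gKDR

For predictors X ∈ R^d and response y the averaged kernel-gradient
matrix is

M̂ = (1/n) Σᵢ ∇ᵢᵀ (G_X + nεI)⁻¹ G_Y (G_X + nεI)⁻¹ ∇ᵢ ,

with Gaussian Gram matrices and ∇ᵢ the matrix of kernel partial
derivatives at Xᵢ. For the Gaussian kernel the whole sum contracts to
XᵀHX with H built from elementwise products of G_X and
F = (G_X+nεI)⁻¹G_Y(G_X+nεI)⁻¹, avoiding the O(n³d) loop. B is the
top-K eigenvector block of the symmetrized M̂; columns are sign-fixed
(largest-magnitude entry positive) so repeated fits are identical.

* **Bandwidths**: median pairwise distance (over ≤ 1000 evenly spaced
  points) for both kernels, the standard heuristic for this estimator.
* **Regularization**: ε = 1e-4/√n by default; both ε and the
  bandwidths are config-exposed because subspace recovery is the one
  place where sensitivity matters.
* **Large n**: fits beyond `max_points` (default 1000) run on an
  evenly spaced subsample — deterministic, so the convexity of the
  underlying problem still manifests as exact repeatability. The exact
  mode is the oracle in tests.

On the single-index benchmark y = (Xb)³ + 0.1·noise (n = 300, d = 10)
the leading direction aligns with b at |cos| ≈ 0.99.

## gKDR-GMM and synaptic weights

Z = (U(t), y(t+Δt)) is fit with a full-covariance Gaussian mixture
(κ = 2 by default; 5 seeded k-means initializations, best likelihood
kept, covariance floor 1e-6, up to 3 seeded restarts on degeneracy).
The conditional p(y|U) follows the standard Gaussian conditioning
identities per component with posterior component weights w_q(U);
tests verify the conditional density against brute-force numerical
conditioning of the joint (≤ 1e-6) and its normalization by
quadrature.

* **Δt = 1 thinned step** (5 raw time points at the default stride).
  The prediction horizon is a searchable hyperparameter; one thinned
  step is the natural minimum and the value used throughout.
* **Gradient of E(y|U)**: the full analytic derivative including the
  U-dependence of w_q (verified against central finite differences to
  1e-4 relative); a simplified component-slope-only variant is a flag.
* **Synaptic weight**: gradients are averaged over training time
  points first, then each presynaptic neuron's lag profile is averaged
  with weights 0.8^k (k = 0 at the most recent lag) normalized by
  Σ₀^{k′−1} 0.8^k; the two averaging steps commute, the order is fixed
  for definiteness. Positive = excitatory-like.
* Thinning uses stride 5 with offsets 0–4 (five interleaved phases of
  the data); k′ = 30, τ′ = 10 span ≈ 75 s of history.

## Simulation

Free-run advances on the thinned grid with **synchronous** updates:
every neuron's next value is computed from the state up to the current
step, then all values are written at once (asserted by a sentinel test
— a neuron never sees a same-step prediction). τ′ must be divisible by
the stride so embedding lags land on the simulation grid (true for
τ′ = 10, stride 5, and for all test settings). Modes: `probabilistic`
(conditional sampling), `deterministic` (conditional expectation),
`det_noise` (expectation plus i.i.d. Gaussian noise; the default noise
SD is each model's deterministic-residual SD on training data, with a
global-constant override). Clamped channels are never overwritten.

Virtual optogenetics clamps the driven neuron to
y = A(−e^{−t/τ₁} + e^{−t/τ₂}) with τ₁ = 3, τ₂ = 20 and A solved
numerically (bounded scalar maximization, cached) so max y = 2; onset
at t = 0 gives y = 0 and the peak sits at t ≈ 6.70. Controls clamp to
zero, share the stimulated run's seed pairwise, and responses are mean
activity over an 80-step post-onset window averaged over repeats
(default 10) and onsets, stimulated minus control.

## Validation statistics

Recordings split into three contiguous thirds (sizes within one point);
a model trained on one third is scored on each by the mean conditional
log-likelihood. The permutation null shuffles the non-self embedded
channels along time — **jointly** by default (one permutation for all
presynaptic channels, preserving their mutual structure; independent
per-channel shuffling is an option) — 100 times; the one-sided p-value
comes from a normal fit to the null scores (the exact permutation p is
also returned). Under engineered null targets the p-values are uniform
(fraction < 0.05 ≈ 0.05 over 200 targets); a lagged-copy target is
detected at p ≪ 0.01. Qualification demands p < 0.01 on both held-out
thirds; the K × offset × third grid enumerates 45 models per target.
Weight consistency uses the rank-sum test of the weight vector against
its negation exactly as specified — statistically this is a
sign-symmetry test and a signed-rank test could be argued for, but the
printed procedure is implemented — with Benjamini-Hochberg control at
FDR 0.005 (the BH step-up is cross-checked against a brute-force
implementation). Descriptive analytics (correlation-matrix MSE over
valid off-diagonal entries, best-|correlation| lags with ties broken
toward the smallest |lag|, period-folded averages, periodogram power
normalized so total power equals Σx²) follow common practice;
normalization conventions are stated in the docstrings because the
choices matter when comparing figures.

## Synthetic ground truth

* **Motif datasets** plant X_embᵀ = W₀M₀ + noise directly in embedded
  space: smooth (neuron × lag) motif patterns shared across animals,
  sparse smoothed-Laplace occurrences per animal (defaults: 12 neurons,
  3 animals, T = 1500, 3 motifs, 90% sparsity, noise SD 0.1, k = 30).
  An *exactly* low-rank delay-embedded (Hankel) matrix would force
  every trace to be a short sum of exponential modes, which contradicts
  the sparse super-Gaussian occurrence structure the motif model
  assumes — so the ground truth lives at the embedded level, raw
  traces are the newest-lag readout, and recovery tests consume the
  generator's embedded matrices. Consequently these datasets probe the
  factorization, completion and analytics machinery, not the raw-trace
  embedding path (which the network datasets and embedding tests
  cover).
* **Network datasets** simulate x(t+1) = tanh(A x + b·s(t)) + ε on a
  sparse random graph: signed directed chemical weights (35%
  inhibitory), symmetric nonnegative gap weights (20% of edges),
  spectral radius scaled to 0.9 (a requested radius ≥ 1 is rescaled to
  0.95 with a warning), i.i.d. Gaussian intrinsic noise (SD 0.15 in the
  test conditions), and an optional standardized square-wave stimulus
  (60 s period, 50↔25 mM levels) feeding designated sensory nodes. The
  emitted edge list hides signs, as an anatomical connectome does.
  These dynamics are the simplest stochastic nonlinear system showing
  the phenomena of interest — noise-sustained coordinated fluctuations
  and deterministic collapse — and make no claim to biophysical
  realism (no calcium-indicator kinetics, no conductance model).
* **Missingness** masks whole neurons per animal (matching how real
  recordings lose neurons), redrawing so every neuron stays observed in
  at least one animal; an impossible request errors.

Model tests on network data use k′ = 5, τ′ = 1, stride 1, K = 2 —
the same construction as the real-data defaults but matched to the
generator's one-step dynamics, at sizes (12 neurons, T = 1200–1500)
that keep the full suite fast. Under these conditions the deterministic
free-run variance collapses below 10⁻⁹ of the data variance while
probabilistic and det+noise modes stay within a factor of two of it,
and the signs of strong planted chemical edges are recovered with 100%
accuracy across 10 seeds (the guarantee asserted is ≥ 90%).

## Known limitations

* Passing the synthetic suites shows the algorithms are implemented
  correctly under their own assumptions; real recordings add neuron
  misidentification, nonstationarity, indicator nonlinearity and
  unmodeled extrasynaptic signaling that no test here covers.
* RICA recovery of planted motifs depends on the identifiability of
  the planted occurrences; at the default smoothing/sparsity some data
  seeds admit local optima where one component's recovery correlation
  drops below 0.9 (the cost at such optima can even be lower), which is
  why recovery guarantees are stated at fixed seeds.
* The gKDR subsample approximation trades accuracy for memory above
  1000 points; its agreement with exact mode is only spot-checked.
* The lag-weight base 0.8 and the qualification thresholds are adopted
  as given; no sensitivity analysis is provided.
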