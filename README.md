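# wormflow

Analysis and modeling toolkit for whole-brain calcium-imaging time
series of *C. elegans* head neurons: extraction of activity **motifs**
shared across animals, and **connectome-constrained probabilistic
models** of per-neuron dynamics that can simulate the whole network,
estimate synaptic interaction signs, and run virtual optogenetics.

It is written for systems-neuroscience groups that record ratiometric
(YFP/CFP) population activity under a periodic salt stimulus and want to
go from raw fluorescence tables to network-level inferences, and for
methods developers who need a tested reference implementation of the two
core algorithms on synthetic ground truth.

## Methods

**TDE-RICA.** Each neuron's trace x_i(t) is delay-embedded
(k = 300 lags, τ = 1), embeddings are stacked across neurons and
animals into X, and Reconstruction ICA finds an occurrence matrix W
minimizing

```
λ‖WWᵀXᵀ − Xᵀ‖₂² + ‖g(WᵀXᵀ)‖₁ ,   g(x) = ½ log cosh 2x ,
```

so that M = WᵀXᵀ holds the motifs (rows = neuron × lag patterns) and W
their per-animal occurrences. Because animals miss different neurons, a
matrix-factorization extension freezes (M, W) and fits new blocks
(M_new, W_new) by minimizing the reconstruction cost over observed
entries only, completing missing neurons and extra animals.

**gKDR-GMM.** For each target neuron i, the delay-embedded activity
(k′ = 30, τ′ = 10; every 5th time point) of its connectome-defined
presynaptic neurons (chemical inputs + gap partners + its own history;
unobserved inputs optionally substituted by their own observed inputs —
"indirect links"; salt sensors ASEL/R, AWCL/R, BAGL/R, ASHL/R receive
the stimulus as an extra channel) forms x(t). Gradient kernel dimension
reduction estimates an orthonormal B (K = 3–5) so that U = xB retains
the predictive information; the joint of Z = (U(t), y(t+Δt)) is fit
with a κ = 2 Gaussian mixture. Prediction is the exact conditional
mixture p(y|U); iterating it over all neurons gives free-run simulation
(sampled, expectation-only, or expectation + i.i.d. noise). The
time-averaged gradient ∂E(y)/∂x_h, lag-aggregated with weights 0.8^k,
is the model's signed synaptic weight; qualification (bootstrap
permutation p < 0.01 on both held-out thirds, over a 45-model ensemble)
and a rank-sum/Benjamini-Hochberg consistency analysis follow.

## Worked example

Generate a 12-neuron synthetic network recording, fit the whole-brain
model, and estimate interaction weights:

```
$ wormflow synth network --out demo --seed 0 --neurons 12 -T 1200 --no-stimulus
wrote network recording to demo
$ wormflow fit --activity demo/activity.csv --connectome demo/connectome.csv \
    --config demo.yml --gkdr-k 2 --seed 0 --out demo/brain.h5
fitted 12 neuron models (config 72e4f0f5ed6d)
$ wormflow weights --model demo/brain.h5 --activity demo/activity.csv \
    --out demo/weights.csv
wrote weights for 47 (pre, post) pairs
```

(`demo.yml` sets `kprime: 5`, `tauprime: 1`, `stride: 1`,
`link_mode: direct` to match the generator's one-step dynamics.)
`demo/weights.csv` then holds one row per (presynaptic, postsynaptic)
pair, e.g.

```
pre,post,weight
N02,N00,0.050379131227912474
N05,N00,0.1583844984897665
N07,N00,0.1432763117080294
...
```

A positive weight means the model's expected next activity of `post`
increases with the recent activity of `pre` (excitatory-like), negative
means inhibitory-like; on this synthetic network all 35 estimated
weights on planted edges match the planted coupling signs. `wormflow simulate` free-runs the fitted model and
`wormflow score` compares real and simulated correlation matrices (the
hyperparameter-selection score); `wormflow opto` clamps one neuron to a
calibrated double-exponential activation (peak 2, τ₁ = 3, τ₂ = 20) and
reports each neuron's mean response over an 80-step window relative to
a clamp-to-zero control.

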