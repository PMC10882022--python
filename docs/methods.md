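# Methods

## Encoding framework

A multivariate time-series is an F×T grid: F features sampled at T uniform
time-steps.  Encoding is *segment-wise and feature-local*: each 1-d signal
is split into consecutive segments of length n (default 4), each segment is
transformed by the keyed encoder, and the transformed segments are
concatenated back in time order.  Consequences relied on throughout:

* **shape conservation** — encoded output is exactly F×T;
* **feature locality** — output row i depends only on input row i, so
  per-feature semantics (which row is heart rate, which is creatinine)
  survive encoding even though the values are deformed;
* **key determinism** — identical (input, key) pairs give bit-identical
  output, which is what makes cross-site pooling of encoded data possible
  when sites share a key.

Edge policy: `strict` (default) requires T divisible by n and fails loudly
otherwise; `pad_zero_trim` zero-pads the signal to the next multiple of n
and trims the encoded output back to T.  Strict is the default because
silent padding changes the last segment's semantics.

Missing values are rejected at encoding time; imputation is an upstream
concern and encoding a NaN is undefined under either transformation.

### Input scaling

Quantum angle encoding maps a segment value x to a rotation RY(π·x), which
is injective only for x ∈ [0, 1]; the framework therefore min-max scales
each feature to [0, 1] by default.  The scaling statistics are computed
once on the training split and frozen (optionally into the key file), so
encoding is portable across sites and leaks only two summary numbers per
feature.  Constant features map to 0.5; out-of-range values at encoding
time are clipped.  Global (training-split) statistics are used rather than
per-example statistics: per-example scaling would itself destroy
inter-example level information and confound the evaluation.

## Random projection encoder

Key: an n×n matrix R with i.i.d. 𝒩(0, 1/n) entries.  Encoding is the
exact product e = R x̂ (double precision, no normalization, no rounding).
The 1/n variance makes E‖Rx̂‖²/‖x̂‖² = 1 (the ratio is χ²_n/n), so segment
geometry is preserved in expectation — deformation without systematic
shrinkage or blow-up.

Because the map is linear and square, it is **reversible**: given n
linearly independent (segment, encoded) pairs, least squares recovers R to
machine precision.  The test suite demonstrates this deliberately — it is
the structural weakness that motivates the quantum encoder.

## Random quantum encoder

Segment length n = number of wires.  Encoding of one segment:

1. all wires start in |0⟩; wire k is rotated by RY(π·x̂_k), with
   RY(ϕ) = [[cos ϕ/2, −sin ϕ/2], [sin ϕ/2, cos ϕ/2]];
2. the secret circuit runs: L layers (default 2) of one RX(ϕ) per wire,
   ϕ ~ Uniform[0, 2π) sampled at key generation, followed by a CNOT ladder
   control i → target i+1 for i = 0…n−2.  RX(ϕ) =
   [[cos ϕ/2, −i sin ϕ/2], [−i sin ϕ/2, cos ϕ/2]]; CNOT flips the target
   bit of basis states whose control bit is 1;
3. readout: e_k = ⟨Z⟩ on wire k, computed exactly from the statevector as
   P(wire k = 0) − P(wire k = 1).  No shot sampling — ⟨Z⟩ is an
   expectation, and exact simulation removes a noise source that is not
   part of the method.

The layer layout (per-wire RX then a full CNOT ladder) was chosen because
it entangles all wires, uses only the two gate families above, and is
fully serializable into a JSON key; the layer count and angle distribution
are key parameters, not fixed constants.  With an empty circuit the
encoder reduces to e_k = cos(π·x̂_k), which the tests use as an analytic
limit.

Conventions: wire 0 is the most significant bit of the basis index (so for
n=2 amplitudes are ordered |00⟩, |01⟩, |10⟩, |11⟩).  Single-qubit gates
are applied in O(2^n) by axis reshaping; the dense 2^n×2^n unitary product
exists only as an independent oracle in the tests and the acceptance
script.  State norm is preserved to 1e−12 after every gate, encoded values
are clamped-checked to [−1, 1].  `QuantumEncoder.encode_batch` simulates
all segments of a batch in one vectorized statevector array — exactly
equivalent to the per-segment path (asserted in tests) and roughly two
orders of magnitude faster, which is what makes cohort-scale encoding
practical.

Irreversibility argument: the ⟨Z⟩ readout is many-to-one (e.g. the Bell
state and the |+⟩|+⟩ product state share identical per-wire expectations),
so even with the key known the pre-measurement state is not identifiable
from the encoded values, in contrast to the projection encoder.

## Synthetic cohort generator

The generator emulates the *structure* of ICU benchmark cohorts —
F=44 features × T=48 hourly steps, binary outcome at 14% prevalence, one
binary (sex-like) and one 4-class (ethnicity-like) latent attribute,
train/validation/test split 64/16/20 — with a fully documented generative
model at desk scale (default n = 2000 examples):

* outcome y ~ Bernoulli(0.14); attributes uniform over classes,
  independent of y (their empirical correlation with y vanishes as n
  grows);
* feature f is a unit sinusoid with feature-specific frequency
  (1–4 cycles per window) and phase, plus a linear ramp r(t) = t/(T−1)
  whose per-feature coefficient carries the planted signals, plus i.i.d.
  Gaussian noise (σ = 1.0);
* the outcome adds coefficient 0.4·y on a designated block of 25% of
  features; each attribute adds a fixed class-specific random coefficient
  pattern (entries 𝒩(0, 0.5), scaled by effect size 0.8) on a block of
  the same size that overlaps the outcome block by half.

Two deliberate design points.  First, class-specific random patterns
(rather than a single coefficient scaled by the class index) make *every*
class of a multiclass attribute linearly detectable one-vs-rest; with
ordinal scaling the middle classes are inherently invisible to a linear
probe.  Second, outcome and attributes share the same ramp *template* on
overlapping features.  This is what makes leakage behave the way it does
in real cohorts: any model that extracts the temporal-drift functional for
the target task unavoidably co-extracts the attribute coefficients, so the
amount of leakage tracks how sharply the model can extract drift — and
drops when encoding blunts that extraction.  With orthogonal planted
signals a small task model simply sheds the attribute direction and the
privacy comparison degenerates.

Effect sizes and noise were calibrated once so that a linear probe on raw
flattened features attains AUROC ≥ 0.8 for the outcome and every attribute
while the target task stays below ceiling for the desk-scale models, and
then pinned.

What the generator does **not** emulate: missingness and irregular
sampling, correlated multi-label disorder structure, heavy-tailed lab
distributions, and temporal nonstationarity beyond a linear drift.
Passing the directional tests therefore shows that the pipeline reproduces
the utility/privacy ordering in a controlled linear-signal regime, not
that the same magnitudes would appear on real ICU data.

## Evaluation harness

**Target models** (desk-scale stand-ins for large sequence architectures,
which are not the object under test here):

* `mlp` (default): one 64-unit ReLU hidden layer on the flattened F·T
  input, Adam at learning rate 1e−3, batch size 64, binary cross-entropy,
  up to 30 epochs with best-on-validation weights retained.  Embedding =
  the 64-d hidden activation.
* `linear`: logistic regression; its "penultimate representation" is the
  flattened input itself (maximal-leakage reference).
* `recurrent-small`: a 32-unit vanilla tanh RNN over the T time-steps
  (numpy implementation, Adam + BPTT, validation-best); embedding = final
  hidden state.

**Probes**: a single dense layer (logistic regression, fit to convergence
by a convex solver — for a single linear layer this is the best-on-
validation configuration by construction) trained on train-split
embeddings, scored on the test split.  Binary attributes report AUROC;
multiclass attributes one-vs-rest macro-AUROC with one probe per class.
Constant embeddings degrade gracefully to AUROC 0.5 with a warning.

**AUROC** is computed by the rank-based Mann–Whitney formula with average
ranks on ties (invariant to monotone score transforms); sklearn's
implementation and an exhaustive pair-counting oracle serve as
cross-checks in the tests, never as the implementation.

**Mutual information**: KSG estimator variant 1 — Chebyshev metric in both
marginals and the joint, k = 3 nearest neighbours, strict-inequality
neighbour counts, ψ(k) + ψ(N) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩ in nats.  Duplicate
points trigger one seeded jitter pass of relative scale 1e−10.  Distances
are computed blockwise with memory-bounded chunking rather than a k-d
tree: the vectorized input reduction is 2112-dimensional, where brute
force beats tree indexing.  Inputs are reduced per the protocol either by
per-feature time-averaging (length F) or row-major flattening (length
F·T); MI is estimated on the first 512 test examples (deterministic
subset) against the model's own input representation for that condition.
KSG estimates in high dimension at these sample sizes are biased toward
zero; they are used *comparatively* across conditions, never as absolute
information measures.

**Experiment driver**: the cohort and both encoding keys are fixed by
their own seeds in the experiment config; the per-run seed list varies
model initialisation and batch order only, mirroring repeated training
runs on one fixed dataset.  Per condition (original, projection-encoded,
quantum-encoded — all min-max scaled once with train-split statistics so
the comparison isolates the encoding) the driver reports task AUROC,
per-attribute probe AUROC and both MI estimates, aggregated as mean ± sd
over seeds, plus relative drops 100·(orig − enc)/orig computed per seed
and then averaged (mean-of-drops).  For MI the summary script instead
computes the drop on seed-averaged estimates: per-seed KSG values can sit
arbitrarily close to zero, where a per-seed ratio is numerically
meaningless.

## Numerical choices and degenerate inputs

* Gate applications preserve unit norm to 1e−12; oracle equivalence is
  asserted to 1e−10; the cosine closed form to 1e−12.
* Projection: double precision throughout, no column normalization — the
  operative sampling law is 𝒩(0, 1/n) entries.
* Min-max scaling of a constant feature returns 0.5; strict edge policy
  raises on indivisible T naming both T and n.
* AUROC with a single class present raises; macro-AUROC skips classes
  absent from the evaluation split.
* Single-class training labels raise a `TrainingError` before any fitting.

## Problem sizes

Default experiment: 2000 examples × 44 features × 48 steps, 5 training
seeds, 3 conditions; MI on 512 test examples.  These sizes keep a full
directional experiment in the low minutes on one CPU while leaving all
qualitative orderings stable across seeds; larger cohorts sharpen the
margins but do not change them.

## Known limitations

* The projection/quantum comparison is made with small dense/recurrent
  models; very large models could in principle re-extract more latent
  information from encoded data (the encoders provide no tunable
  deformation-vs-retention knob).
* KSG MI values in 2112 dimensions are strongly biased and only
  comparable within an experiment.
* The per-attribute leakage direction is carried predominantly by the
  binary attribute; the 4-class attribute's probe sits closer to its
  floor and is noisier, so directional claims are made on the mean over
  attributes.
* Quantum encoding is simulated exactly; hardware execution (shot noise,
  device noise) is out of scope, as are gradients through the circuit.
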