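# Methods

## Problem and model

`fuzzyfunc` studies the *numerical* behaviour of a convolutional protein-
function predictor: how much do its class probabilities and its evaluation
metrics move when every floating-point operation of the forward pass is
perturbed at the scale of machine round-off, and how far can the
floating-point formats be narrowed before the predictions degrade?

The model is a DeepGOPlus-style CNN: one-hot encoded amino-acid sequences
(20 residues + unknown symbol `X`) pass through parallel 1-D convolution
branches with different kernel lengths, each followed by ReLU and a global
max-pool; the concatenated features feed a dense layer with a sigmoid that
emits one probability per ontology class.  The desk-scale default is 4
branches × 8 filters, 256-residue input, 64 classes; the production-scale
geometry (16 branches, 2000-residue input) is expressible through the same
`ModelConfig` but is not asserted, since its exact kernel lengths are not
public.

Every multiply, add, divide and exponential of the forward pass is routed
through an `ArithmeticBackend`.  Values belong to one of two precision
classes: convolution and dense elementwise multiplies are *single*-class,
the dense accumulation and the sigmoid are *double*-class — mirroring a
production stack where the bulk of the arithmetic is float32 but the core
dot-product accumulation runs in double.  The assignment is configurable.

## Arithmetic backends

**ieee** — plain double precision; the reference.

**mca_rr** — Monte Carlo Arithmetic, Random Rounding mode.  Each operation
result is perturbed as `inexact(x) = x + 2^(e_x − t) ξ` with
`ξ ~ U(−½, ½)` and `e_x = floor(log2 |x|)`, then rounded to the class's
working format (float32 for single, float64 for double).  Virtual
precisions default to t = 24 (relative noise `2^-24 ≈ 1e-8`) and t = 53
(`2^-53 ≈ 1e-16`).  Design points:

* the perturbation is applied to the *pre-rounding* result.  Double-class
  operations run in 80-bit extended precision internally so that t = 53
  noise — which sits below the double ulp — dithers the final rounding
  instead of being annihilated.  Consequently an exactly representable
  result (e.g. `1 + 1`) is never perturbed at t = 53, which is precisely
  the round-off being simulated.  This relies on `np.longdouble` being
  wider than float64 (true on x86-64).
* exact zeros are never perturbed: zero has no binary exponent, and
  perturbing it would inject absolute rather than relative noise into
  sparse tensors.
* comparisons (ReLU, max-pool) are evaluated on unperturbed operands and
  their result is never re-rounded; perturbing order decisions would alter
  control flow, not simulate round-off.
* only Random Rounding is implemented.  Precision Bounding and full MCA
  also perturb operation *inputs*, are far more invasive, and abort the
  very computations under study; requesting them raises an explanatory
  error.
* one seeded `PCG64` stream per run; repetition *i* of an experiment uses
  seed `base + i`, so the whole experiment is bit-reproducible.

**vprec_outbound / vprec_inbound** — emulation of custom floating-point
formats, each defined by a mantissa width (1–52 stored bits) and an
exponent width (2–11 bits).  `round_to_format` performs round-to-nearest,
ties-to-even on the format's grid with gradual underflow through the
format's subnormal range, flush-to-zero below half the smallest subnormal,
overflow to signed infinity (not saturation, so failures are observable),
and canonical quiet NaN.  For the float32 preset it is bit-identical to
the native double→single cast, which the tests verify on 10^5
wide-exponent doubles.

Outbound mode rounds every operation *result* to the class's format.
Inbound mode rounds the values each stage *reads* — the encoded input, the
weights, and the stored activations entering the stage — and computes the
stage at full double precision, leaving intermediate partial sums
untouched.  This stage-level reading is deliberate: inbound reduces what
the computation consumes, not how it calculates, and it is what makes
inbound mode systematically gentler than outbound on long accumulations
(rounding a running accumulator at every step is indistinguishable from
outbound and would erase the mode contrast the sweep is designed to
expose).  Weights are rounded at load time under both modes.

A run is marked *crashed* when a finite input produces a non-finite value
(rounding overflow, `exp` overflow) or any final score is non-finite; the
offending stage is recorded, crashes in sweeps are data rather than
errors, and crashed cells carry no metric differences.

Preset formats: float64 (52/11), float32 (23/8), float16 (10/5), bfloat16
(7/8), bfloat8 (2/5) and tf32 (10/8).  The 2-bit-mantissa/5-bit-exponent
bfloat8 is one of several 8-bit variants in circulation; this particular
parameterisation is the one implemented, and custom formats are available
as `p<bits>e<bits>` strings.

## Evaluation metrics

Function classes form a DAG with three namespace roots.  Truth annotations
are closed under ancestors (true-path rule); prediction scores are
propagated upward by maximum (a parent is at least as likely as any
descendant) before thresholding.  Over the grid t ∈ {0.01, …, 1.00}:

* `Fmax`: maximum harmonic mean of protein-averaged precision and recall;
  precision averages only over proteins with ≥ 1 predicted term (CAFA
  convention); ties report the smallest maximising threshold.
* `Smin`: minimum of `sqrt(ru² + mi²)`, where remaining uncertainty `ru`
  and misinformation `mi` weight the truth∖prediction and
  prediction∖truth class sets by information content.
* `AUPR`: trapezoidal integral of precision over recall along the same
  grid, points sorted by recall, no extrapolation beyond the observed
  endpoints.  Thresholds where nothing is predicted define no precision
  and are excluded.  Degenerate curves with a single distinct recall value
  return 0 (with a warning), except a predictor pinned at the perfect
  corner (precision = recall = 1 everywhere), which scores 1.  An
  alternative parameterisation by unique score values instead of the fixed
  grid would integrate the same staircase more finely; the fixed grid was
  chosen because the threshold metrics are defined on it.

Information content is namespace-conditional with additive smoothing:
`IC(c) = −log2((n_c + ε) / (n_root + ε))`, ε = 1 by default, `IC(root) = 0`.
Metrics are computed and reported per namespace.  Proteins without truth
annotations in the evaluated namespace are excluded (CAFA convention).

## Uncertainty quantification

For a quantity with unperturbed reference `x_IEEE` and MCA samples
`X_1..X_n`, the significant bits are the largest k ≤ cap such that every
deviation satisfies `|Z_i| < 2^-k`, with cap 24 (single) or 53 (double);
digits are `k·log10 2` (15.95 for double, 7.2247 ≈ 7.22 for single).
Deviations are relative by default — the cap is a mantissa-length bound
and only makes sense for mantissa-relative error — with absolute mode
retained and used as the fallback at `x_IEEE = 0`.  Non-finite samples
yield 0 bits (no information); zero-variance quantities report the cap
(the samples carry no evidence of any information loss; no finite-sample
deflation constant is applied).  Standard deviations are population
standard deviations, the usual convention for MCA samples.  The
non-parametric sample-size rule returns the smallest n with
`p^n ≤ 1 − c`; n = 10 corresponds to confidence 0.80 at probability 0.85.

## Synthetic benchmark

The generator produces the statistical structure the pipeline needs
without any external data:

* a random DAG per namespace (root → up to 4 internal nodes → leaves; a
  node's parents always precede it, so acyclicity and single-root
  reachability hold by construction);
* protein sequences of uniform random residues, length 50–250 in the
  packaged benchmark (within the 50–2000 range typical of real proteins,
  capped so the model's 256-residue window never truncates a motif);
* one exact k-mer motif per motif-bearing leaf (lengths 8/12/16 by
  namespace, matching three of the convolution kernel lengths);
* truth: 1–2 leaves per namespace per protein; each truth leaf's motif is
  implanted with probability `motif_strength` (0.9 in the benchmark) at a
  non-overlapping position; `label_noise` (0.1) then swaps truth leaves
  without touching the sequence;
* teacher weights wired so a full motif match scores 1.0 at its filter,
  the ReLU margin is 0.25, and one detected motif lifts the logit of every
  ancestor class from a −2 background to +1.  The fourth branch and any
  unused filters act as distractors with small dense random weights
  (kernel σ 0.15, bias 0.3, dense σ 0.15), giving *every* class
  probability a smoothly varying arithmetic path.

The teacher is deliberately well-conditioned — filter outputs sit a
quarter away from the cancellation point and logits are O(1) — because the
object under study is the arithmetic, not the classifier.  A
`truth_mode="scores"` option instead defines truth from the unperturbed
teacher's propagated scores at a threshold, yielding a perfectly separable
benchmark (reference Fmax = 1).

What the generator does **not** emulate: real amino-acid composition,
homology structure between proteins, real ontology size and annotation
frequency distributions, or the production model's 16-branch scale.
Passing tests therefore demonstrate properties of the *arithmetic
pipeline* on a faithful miniature, not predictive performance on real
proteomes; metric magnitudes are not comparable to published values for
any real predictor.

## Experiments and problem sizes

* **MCA experiment**: 1 IEEE reference + 10 repetitions at t = 24/53 on the
  full packaged benchmark (200 proteins × 64 classes); reports mean,
  population std and significant bits/digits for all 12 800 class
  probabilities and the 9 per-namespace metrics.  On this benchmark the
  median per-score std sits at ~2–3 × 10⁻⁹ — within a decade of the
  injected 2⁻²⁴/√12 ≈ 1.7 × 10⁻⁸ scale — and the metrics keep ≥ 4
  significant digits, the no-amplification behaviour expected of a
  three-layer network whose max-pool and thresholded metrics regularise
  small perturbations.
* **Format sweep**: 4 × 4 grid of {float32, float16, bfloat16, bfloat8}
  over the two precision classes, per mode.  Sweeps are deterministic, so
  they run on the first 80 benchmark proteins; the package's experiments
  accept any subset size.
* **Precision/exponent search**: single-class formats p ∈ [2, 52] ×
  e ∈ [5, 11] with double untouched; a cell is acceptable when all metrics
  stay within 1% (relative) of IEEE without crashing — the tolerance is a
  package default, exposed as a flag.  The search reports the acceptable
  region and its Pareto-minimal (p, e) cells rather than a single optimum,
  since acceptability need not be monotone.  The held-fixed double-class
  format is also a flag.

## Numerical choices and degenerate inputs

Rounding is round-to-nearest ties-to-even everywhere.  Accumulation order
is fixed (kernel position → alphabet → feature index) so deterministic
backends are bit-reproducible.  Sigmoid outputs are clipped to [0, 1] at
the prediction boundary: stochastic perturbation of `1/(1+exp(−z))` can
overshoot the interval by one ulp-scale amount.  The sign flip in
`exp(−z)` is exact and not instrumented.  Relative metric differences fall
back to absolute differences when the reference metric is exactly zero
(perfectly separable benchmarks have Smin = 0).  `fma` is provided in the
Random-Rounding API with a single rounding via the extended-precision
product; the CNN itself uses separate multiply and add operations, which
is what its operation counter models.

## Known limitations

* The t = 53 dithering (and the `fma` single rounding) depends on
  `np.longdouble` being 80-bit extended; on platforms where longdouble is
  an alias of float64 the t = 53 perturbation degenerates to a no-op for
  exactly representable results.
* Inbound mode is stage-granular by design (see above); an
  every-operand-rounded variant can be recovered by composing outbound
  rounding with the identity operation split, but is not exposed.
* Single-threaded by contract; there is no parallel RNG scheme.
* Training, back-propagation, sequence-similarity predictors and runtime/
  memory modelling of reduced formats are out of scope.
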