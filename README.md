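# fuzzyfunc

Numerical-stability analysis of CNN-based protein function inference under
stochastic and reduced-precision floating-point arithmetic.

## The problem

Deep models for protein function prediction are trusted to produce the
same annotations wherever they run — yet changing the BLAS build, the OS
or the hardware perturbs floating-point results at the scale of machine
round-off.  Are the predictions of a convolutional protein-function model
stable against such perturbations?  And if they are, how narrow can its
floating-point formats be made (to save memory and latency) before
performance drops?

`fuzzyfunc` answers both questions for a DeepGOPlus-style CNN — parallel
1-D convolutions over one-hot amino-acid sequences → ReLU → global
max-pool → dense + sigmoid, one probability per Gene-Ontology-like class —
by routing **every scalar operation** of the forward pass through a
pluggable arithmetic backend:

* `ieee` — plain double precision (the reference);
* `mca_rr` — Monte Carlo Arithmetic, Random Rounding: each operation
  result x is perturbed to `x + 2^(e_x − t) ξ`, `ξ ~ U(−½, ½)`, at virtual
  precision t (t = 24 injects the ~10⁻⁸ relative noise of single
  precision, t = 53 the ~10⁻¹⁶ of double);
* `vprec_outbound` / `vprec_inbound` — emulation of custom floating-point
  formats (mantissa × exponent widths, e.g. float16 = 10/5,
  bfloat16 = 7/8, bfloat8 = 2/5, tf32 = 10/8) by rounding operation
  results (outbound) or the values each stage reads (inbound).

Predictions are scored against a hierarchical ontology with the CAFA
metrics — Fmax (max harmonic mean of averaged precision/recall over
thresholds), Smin (min ‖(ru, mi)‖₂ of information-content-weighted
remaining uncertainty and misinformation) and AUPR — and the variability
across MCA repetitions is summarised as standard deviations and
significant bits/digits (largest k with every deviation `< 2^-k`;
53 bits ≅ 15.95 digits, 24 bits ≅ 7.22).

Everything runs on a self-contained synthetic benchmark: a random
three-namespace DAG ontology, motif-implanted sequences, and a teacher CNN
whose probabilities track the implanted truth — no downloads, fully
deterministic from a seed.

## Worked example

```python
from fuzzyfunc.simulate import benchmark_config, make_benchmark
from fuzzyfunc.experiments import run_mca_experiment, run_format_sweep

bench = make_benchmark(benchmark_config(seed=1))   # 200 proteins, 64 classes
mca = run_mca_experiment(bench, n_repetitions=10, seed=1)
print(f"median per-score std : {mca.median_class_prob_std():.3e}")
print(f"metric digits (min)  : {mca.metric_report['significant_digits'].min():.2f}")

sub = bench.subset(80)
for mode in ("inbound", "outbound"):
    sweep = run_format_sweep(sub, mode)            # 16 reduced-format cells
    print(f"{mode:8s} mean |Δmetric| vs IEEE: {sweep.mean_abs_diff():.4f}")
```

prints

```
median per-score std : 2.614e-09
metric digits (min)  : 15.95
inbound  mean |Δmetric| vs IEEE: 0.0108
outbound mean |Δmetric| vs IEEE: 0.1270
```

Reading: injecting 2⁻²⁴-scale noise into every operation leaves the class
probabilities with a median spread of ~3 × 10⁻⁹ — the same order as the
injected noise, i.e. the shallow network does not amplify round-off — and
the thresholded metrics keep full double-precision significance.  Under
reduced formats, rounding every operation result (outbound) degrades the
metrics about twelve times more than rounding only what each stage reads
(inbound), and the native-width cell (float64/float32) reproduces the IEEE
metrics exactly in both modes.

The same experiments are available from the shell:

```sh
fuzzyfunc simulate-data --seed 1 --out data/
fuzzyfunc predict --fasta data/proteins.fasta --weights data/weights.npz \
                  --backend mca --seed 11 --out pred.tsv
fuzzyfunc experiment sweep --mode outbound --seed 1 --out results/
fuzzyfunc experiment search --precisions 2:52 --exponents 5:11 --out results/
```

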