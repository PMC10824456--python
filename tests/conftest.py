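"""Shared fixtures.

The session-scoped ``benchmark`` is the packaged 200-protein study used by
the end-to-end stability checks; ``tiny_bench`` is a seconds-scale variant
for unit tests that need full forward passes.  Expensive experiment
results (the 10-repetition MCA run, the two 16-cell sweeps) are computed
once per session and shared.
"""

import numpy as np
import pytest

from fuzzyfunc.model import ModelConfig
from fuzzyfunc.simulate import SyntheticConfig, benchmark_config, make_benchmark
from fuzzyfunc.experiments import run_format_sweep, run_mca_experiment

BENCH_SEED = 1


@pytest.fixture(scope="session")
def benchmark():
    return make_benchmark(benchmark_config(seed=BENCH_SEED))


@pytest.fixture(scope="session")
def sweep_bench(benchmark):
    # the reduced-precision grids are deterministic, so a subset of the
    # proteins exercises them just as well at a fraction of the cost
    return benchmark.subset(80)


@pytest.fixture(scope="session")
def mca_result(benchmark):
    return run_mca_experiment(benchmark, n_repetitions=10, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def sweeps(sweep_bench):
    return {mode: run_format_sweep(sweep_bench, mode) for mode in ("inbound", "outbound")}


def tiny_config(**overrides) -> SyntheticConfig:
    base = dict(
        n_proteins=24,
        length_range=(120, 180),
        n_classes=33,
        motif_strength=1.0,
        label_noise=0.0,
        annotations_per_namespace=(1, 1),
        seed=7,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def tiny_model(n_classes=33) -> ModelConfig:
    return ModelConfig(n_classes=n_classes, max_seq_len=192, seed=7)


@pytest.fixture(scope="session")
def tiny_bench():
    # mild label noise keeps all three metrics strictly off their perfect
    # values, so relative differences are well defined everywhere
    return make_benchmark(tiny_config(motif_strength=0.9, label_noise=0.1),
                          model_cfg=tiny_model())
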