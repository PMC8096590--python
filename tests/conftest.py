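"""Shared fixtures: expensive trained models are session-scoped so the
clean-data benchmark, filter-analysis checks, and robustness comparison
reuse the same runs."""

import numpy as np
import pytest

from kecnet.experiments import (clean_benchmark, fusion_protocol,
                                robustness_protocol)
from kecnet.synth import rhythm_pair_specs, synth_dataset

# desk-scale protocol sizes (documented in docs/methods.md)
BENCHMARK_N_PER_CLASS = 500
BENCHMARK_EPOCHS = 8
ROBUSTNESS_N_PER_CLASS = 150
ROBUSTNESS_EPOCHS = 16
ROBUSTNESS_FLOOR_SNR_DB = 18.0  # wearable-grade recordings for the noise study
FUSION_N_PER_CLASS = 150
FUSION_EPOCHS = 12


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The default 5-class synthetic dataset at benchmark scale."""
    return synth_dataset(n_per_class=BENCHMARK_N_PER_CLASS, seed=0)


@pytest.fixture(scope="session")
def benchmark_models(benchmark_dataset):
    """KecNet and the standard-CNN baseline, matched seed and budget."""
    return clean_benchmark(benchmark_dataset, epochs=BENCHMARK_EPOCHS, seed=0)


@pytest.fixture(scope="session")
def robustness_sweep_table():
    """Train-clean/test-noisy accuracies, 3 seeds x 2 models x 3 SNRs."""
    ds = synth_dataset(n_per_class=ROBUSTNESS_N_PER_CLASS, seed=1,
                       sensor_noise_snr_db=ROBUSTNESS_FLOOR_SNR_DB)
    return robustness_protocol(ds, snrs=(60.0, 30.0, 10.0),
                               train_seeds=(0, 1, 2),
                               epochs=ROBUSTNESS_EPOCHS)


@pytest.fixture(scope="session")
def fusion_table():
    """CV-fusion ablation accuracies on the rhythm-only class pair."""
    ds = synth_dataset(rhythm_pair_specs(), n_per_class=FUSION_N_PER_CLASS,
                       seed=2)
    return fusion_protocol(ds, seeds=(0, 1, 2), epochs=FUSION_EPOCHS)
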