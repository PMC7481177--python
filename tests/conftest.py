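"""Shared fixtures.

The heavy artifacts — the benchmark dataset, the trained denoising
autoencoder and the ablation sweep — are session-scoped and built once;
every test that needs a trained model reuses them.
"""

from __future__ import annotations

import numpy as np
import pytest

from deepbeat import benchmark as bm
from deepbeat import cdae as cdae_mod
from deepbeat import model as model_mod


@pytest.fixture(scope="session")
def benchmark_data() -> bm.BenchmarkData:
    return bm.make_benchmark()


@pytest.fixture(scope="session")
def trained_cdae(benchmark_data) -> tuple[cdae_mod.Cdae, dict]:
    """CDAE trained on the unlabeled corpus (1960 window pairs, 30 epochs)."""
    model, history = bm.pretrain_encoder(benchmark_data)
    return model, history


@pytest.fixture(scope="session")
def encoder_weights(trained_cdae) -> cdae_mod.EncoderWeights:
    return cdae_mod.extract_encoder(trained_cdae[0])


@pytest.fixture(scope="session")
def ablation(benchmark_data, encoder_weights):
    """Full ablation sweep: 3 variants x 3 seeds.

    Returns (results, nets) where results maps variant name -> list of test
    F1 (one per seed) and nets maps (variant name, seed) -> trained model.
    """
    variants = (model_mod.Variant.MT_PRETRAINED, model_mod.Variant.MT_RANDOM,
                model_mod.Variant.ST_RANDOM)
    seeds = (11, 12, 13)
    results: dict[str, list[float]] = {v.value: [] for v in variants}
    nets: dict[tuple[str, int], model_mod.DeepBeatModel] = {}
    for seed in seeds:
        for variant in variants:
            net = bm.train_variant(
                variant, benchmark_data,
                encoder=encoder_weights if variant.pretrained else None,
                seed=seed)
            results[variant.value].append(bm.test_f1(net, benchmark_data))
            nets[(variant.value, seed)] = net
    return results, nets
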