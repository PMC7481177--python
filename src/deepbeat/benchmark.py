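"""Desk-scale synthetic benchmark used by the test-suite and the acceptance
script.

Study conditions (fixed):

* Records are 100-s traces stratified evenly over rhythm x the canonical
  noise-factor set.  Each record is its own subject, so record-level splits
  are subject-disjoint by construction.
* Labeled data: 168 training records cut into overlapping 25-s windows
  (12.5-s stride -> 1176 windows, the training-augmentation scheme), 140
  validation and 175 test records cut non-overlapping (560 / 700 windows;
  the validation pool doubles as the checkpoint-selection set, so it is
  sized to keep the per-epoch F1 estimate stable).
* Unlabeled pretraining corpus: 280 further records (1960 window pairs of
  preprocessed corrupted input and clean target).
* CDAE: 32/32/32 encoder filters, 30 epochs.  Classifier fine-tuning: 10
  epochs, lr 1.5e-3, batch 64, dropout 0.1, Adam warm restarts, transferred
  layers fine-tuned at a tenth of the base rate.

These sizes run in minutes on one CPU core; they are the package's desk
defaults, far below the corpus scale a production training run would use.
The record seed bases act like a printed data table: they are part of the
benchmark definition, while model/training seeds vary per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cdae as cdae_mod
from . import model as model_mod
from . import preprocess as prep_mod
from . import simulator as sim_mod
from .evaluate import evaluate_labels
from .types import QaClass, Rhythm, WindowSpec

#: Record-seed bases for the four independent data pools.
SEED_TRAIN, SEED_VAL, SEED_TEST, SEED_CORPUS = 50000, 90000, 95000, 200000

#: Desk-scale record counts (train / val / test / unlabeled corpus).
N_TRAIN_REC, N_VAL_REC, N_TEST_REC, N_CORPUS_REC = 168, 140, 175, 280

TRAIN_STRIDE_S = 12.5
RECORD_SECONDS = 100.0

_QA_INDEX = {"POOR": 0, "ACCEPTABLE": 1, "EXCELLENT": 2}


@dataclass
class BenchmarkData:
    """Preprocessed windows with labels, split subject-disjointly."""

    X_train: np.ndarray
    y_af_train: np.ndarray
    y_qa_train: np.ndarray
    X_val: np.ndarray
    y_af_val: np.ndarray
    y_qa_val: np.ndarray
    X_test: np.ndarray
    y_af_test: np.ndarray
    y_qa_test: np.ndarray
    qa_true_test: list
    subjects_test: list[str]
    corpus_clean: np.ndarray
    corpus_corrupted: np.ndarray


def _window_pool(n_records: int, stride: float, seed_base: int,
                 config: sim_mod.GenerationConfig,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                            list, list[str]]:
    """Simulate ``n_records`` and window both clean and corrupted traces."""
    spec = WindowSpec(stride=stride)
    strata = [(r, f) for r in (Rhythm.SINUS, Rhythm.AF)
              for f in config.noise_factors]
    Xc, Xx, y_af, y_qa, qa_true, subjects = [], [], [], [], [], []
    for i in range(n_records):
        rhythm, factor = strata[i % len(strata)]
        rec = sim_mod.simulate_record(rhythm, factor, config, seed_base + i,
                                      record_id=f"s{seed_base}_{i:05d}")
        wins_c = prep_mod.window_signal(rec.clean, spec)
        wins_x = prep_mod.window_signal(rec.corrupted, spec)
        for wc, wx in zip(wins_c, wins_x):
            Xc.append(wc.samples)
            Xx.append(wx.samples)
            y_af.append(int(rhythm is Rhythm.AF))
            y_qa.append(_QA_INDEX[rec.qa_true.name])
            qa_true.append(rec.qa_true)
            subjects.append(rec.record_id)
    return (np.stack(Xc), np.stack(Xx), np.array(y_af), np.array(y_qa),
            qa_true, subjects)


def make_benchmark() -> BenchmarkData:
    """Build the fixed benchmark dataset (see module docstring)."""
    config = sim_mod.GenerationConfig(duration=RECORD_SECONDS)
    _, Xtr, ytr, qtr, _, _ = _window_pool(N_TRAIN_REC, TRAIN_STRIDE_S,
                                          SEED_TRAIN, config)
    _, Xva, yva, qva, _, _ = _window_pool(N_VAL_REC, 25.0, SEED_VAL, config)
    _, Xte, yte, qte, qa_true, subj = _window_pool(N_TEST_REC, 25.0,
                                                   SEED_TEST, config)
    Cc, Cx, _, _, _, _ = _window_pool(N_CORPUS_REC, TRAIN_STRIDE_S,
                                      SEED_CORPUS, config)
    return BenchmarkData(
        X_train=Xtr, y_af_train=ytr, y_qa_train=qtr,
        X_val=Xva, y_af_val=yva, y_qa_val=qva,
        X_test=Xte, y_af_test=yte, y_qa_test=qte,
        qa_true_test=qa_true, subjects_test=subj,
        corpus_clean=Cc, corpus_corrupted=Cx)


def benchmark_cdae_config(epochs: int = 30, seed: int = 3) -> cdae_mod.CdaeConfig:
    return cdae_mod.CdaeConfig(epochs=epochs, seed=seed,
                               enc_filters=(32, 32, 32), dec_filters=(32, 32))


def benchmark_model_configs() -> tuple[model_mod.TrunkConfig,
                                       model_mod.QaArmConfig,
                                       model_mod.EventArmConfig]:
    return (model_mod.TrunkConfig(enc_filters=(32, 32, 32), dropout=0.1),
            model_mod.QaArmConfig(dropout=0.1),
            model_mod.EventArmConfig(dropout=0.1))


def pretrain_encoder(data: BenchmarkData, epochs: int = 30, seed: int = 3,
                     ) -> tuple[cdae_mod.Cdae, dict]:
    """Train the CDAE on the unlabeled corpus: preprocessed corrupted
    windows in, their clean counterparts as targets."""
    cfg = benchmark_cdae_config(epochs=epochs, seed=seed)
    model = cdae_mod.build_cdae(cfg)
    history = cdae_mod.train_cdae(model, data.corpus_corrupted,
                                  data.corpus_clean, cfg)
    return model, history


def train_variant(variant: model_mod.Variant, data: BenchmarkData,
                  encoder: cdae_mod.EncoderWeights | None = None,
                  epochs: int = 10, seed: int = 11) -> model_mod.DeepBeatModel:
    """Build, (optionally) transfer and fine-tune one ablation variant."""
    trunk, qa_arm, event_arm = benchmark_model_configs()
    net = model_mod.build_deepbeat(variant, input_length=data.X_train.shape[1],
                                   trunk=trunk, qa_arm=qa_arm,
                                   event_arm=event_arm, seed=seed)
    if variant.pretrained:
        if encoder is None:
            raise ValueError("pretrained variants need encoder weights")
        net.transfer_encoder_weights(encoder)
    cfg = model_mod.TrainConfig(
        epochs=epochs, seed=seed, lr=1.5e-3, batch=64,
        w_qa=1.0 if variant.multitask else 0.0,
        warm_restarts=True, transferred_lr_scale=0.1)
    model_mod.train(net, data.X_train, data.y_af_train,
                    data.y_qa_train if variant.multitask else None,
                    data.X_val, data.y_af_val,
                    data.y_qa_val if variant.multitask else None, cfg)
    return net


def test_f1(net: model_mod.DeepBeatModel, data: BenchmarkData) -> float:
    """Weighted-macro F1 of the rhythm task on the benchmark test split."""
    af_probs, _ = net.predict_proba(data.X_test)
    report = evaluate_labels(list(data.y_af_test),
                             list(af_probs.argmax(axis=1)), [0, 1])
    return report.aggregate["f1"]


def run_ablation(data: BenchmarkData,
                 encoder: cdae_mod.EncoderWeights,
                 variants=(model_mod.Variant.MT_PRETRAINED,
                           model_mod.Variant.MT_RANDOM,
                           model_mod.Variant.ST_RANDOM),
                 seeds=(11, 12, 13), epochs: int = 10,
                 ) -> dict[str, list[float]]:
    """Train each variant across seeds; returns per-variant test F1 lists."""
    results: dict[str, list[float]] = {v.value: [] for v in variants}
    for seed in seeds:
        for variant in variants:
            net = train_variant(
                variant, data,
                encoder=encoder if variant.pretrained else None,
                epochs=epochs, seed=seed)
            results[variant.value].append(test_f1(net, data))
    return results
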