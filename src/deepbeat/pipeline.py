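"""End-to-end pipeline: simulate -> preprocess -> pretrain -> train ->
predict -> evaluate -> explain, with one global seed fanned out into
per-stage seeds and subject-disjoint train/validation/test splits.

Every artifact directory gets a ``provenance.json`` with the config hash,
global seed and package version, so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cdae as cdae_mod
from . import evaluate as eval_mod
from . import explain as explain_mod
from . import model as model_mod
from . import preprocess as prep_mod
from . import qa as qa_mod
from . import simulator as sim_mod
from .io import config_hash, read_container, write_container
from .types import QaClass, Rhythm, ValidationError, WindowSpec, derive_seed

logger = logging.getLogger(__name__)

RHYTHM_CLASSES = ["SINUS", "AF"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "runs/run0"
    n_records: int = 700
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    cdae_epochs: int = 10
    train_epochs: int = 6
    variant: str = "MT_PRETRAINED"
    noise_factors: tuple[float, ...] = sim_mod.CANONICAL_NOISE_FACTORS
    fs: float = 128.0
    #: simulated record length; records longer than one window yield
    #: several windows each
    duration: float = 100.0
    #: analysis window length (the model input is window_seconds * fs / 4
    #: samples; 25 s at 128 Hz -> L = 800)
    window_seconds: float = 25.0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValidationError(
                f"split fractions must sum to 1, got {self.split_fractions}")


def split_subjects(subject_ids: list[str], fractions: tuple[float, float, float],
                   seed: int) -> dict[str, str]:
    """Assign each subject to train/val/test with no overlap."""
    subjects = sorted(set(subject_ids))
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    n = len(subjects)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    assign = {}
    for i, s in enumerate(subjects):
        if i < n_train:
            assign[s] = "train"
        elif i < n_train + n_val:
            assign[s] = "val"
        else:
            assign[s] = "test"
    return assign


def simulate_stage(cfg: PipelineConfig, out: Path) -> Path:
    gen_cfg = sim_mod.GenerationConfig(fs=cfg.fs, duration=cfg.duration,
                                       noise_factors=tuple(cfg.noise_factors))
    seed = derive_seed(cfg.seed, "simulate")
    records, manifest = sim_mod.generate_dataset(cfg.n_records, gen_cfg, seed)
    clean = np.stack([r.clean for r in records])
    corrupted = np.stack([r.corrupted for r in records])
    manifest = manifest.assign(subject_id=manifest["id"])
    path = out / "simulated.h5"
    write_container(path, {"clean": clean, "corrupted": corrupted}, manifest,
                    attrs={"fs": cfg.fs, "seed": seed,
                           "config_hash": config_hash(asdict(cfg))})
    return path


def preprocess_stage(cfg: PipelineConfig, sim_path: Path, out: Path) -> Path:
    """Window both the corrupted and the clean traces (one 25-s window per
    record at defaults) and write a windows container."""
    arrays, manifest, attrs = read_container(sim_path)
    spec = WindowSpec(t=cfg.window_seconds, fs_in=cfg.fs)
    win_clean, win_corr, rows = [], [], []
    for i, row in manifest.iterrows():
        rhythm = Rhythm(row["rhythm"])
        qa_true = QaClass[row["qa_true"]]
        wc = prep_mod.window_signal(arrays["clean"][i], spec, rhythm=rhythm,
                                    qa=qa_true, subject_id=row["subject_id"])
        wx = prep_mod.window_signal(arrays["corrupted"][i], spec, rhythm=rhythm,
                                    qa=qa_true, subject_id=row["subject_id"])
        for j, (c, x) in enumerate(zip(wc, wx)):
            win_clean.append(c.samples)
            win_corr.append(x.samples)
            rows.append({"id": f"{row['id']}_w{j}", "subject_id": row["subject_id"],
                         "window_index": j, "rhythm": rhythm.value,
                         "qa_true": qa_true.name,
                         "noise_factor": row["noise_factor"]})
    path = out / "windows.h5"
    write_container(path, {"clean": np.stack(win_clean),
                           "windows": np.stack(win_corr)},
                    pd.DataFrame(rows),
                    attrs={"fs_eff": spec.fs_eff, "window_length": spec.length,
                           "config_hash": config_hash(asdict(cfg))})
    return path


def _split_masks(manifest: pd.DataFrame, cfg: PipelineConfig) -> pd.Series:
    assign = split_subjects(list(manifest["subject_id"]), cfg.split_fractions,
                            derive_seed(cfg.seed, "split"))
    return manifest["subject_id"].map(assign)


def pretrain_stage(cfg: PipelineConfig, windows_path: Path, out: Path) -> Path:
    arrays, manifest, _ = read_container(windows_path)
    split = _split_masks(manifest, cfg)
    clean = arrays["clean"][np.asarray(split == "train")]
    seed = derive_seed(cfg.seed, "pretrain")
    from .benchmark import benchmark_cdae_config

    cdae_cfg = benchmark_cdae_config(epochs=cfg.cdae_epochs, seed=seed)
    model = cdae_mod.build_cdae(cdae_cfg)
    rng = np.random.default_rng(seed + 1)
    corrupted, _ = cdae_mod.corrupt_batch(clean, cfg.noise_factors, rng)
    history = cdae_mod.train_cdae(model, corrupted, clean, cdae_cfg)
    ckpt = out / "cdae.npz"
    model.save(ckpt)
    enc = cdae_mod.extract_encoder(model)
    enc.save(out / "encoder.npz")
    with open(out / "cdae_history.json", "w") as fh:
        json.dump(history, fh, indent=2)
    return out / "encoder.npz"


def _labels(manifest: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    y_af = (manifest["rhythm"] == "AF").astype(int).to_numpy()
    y_qa = manifest["qa_true"].map(
        {"POOR": 0, "ACCEPTABLE": 1, "EXCELLENT": 2}).to_numpy()
    return y_af, y_qa


def train_stage(cfg: PipelineConfig, windows_path: Path, encoder_path: Path | None,
                out: Path) -> Path:
    arrays, manifest, _ = read_container(windows_path)
    split = _split_masks(manifest, cfg)
    X = arrays["windows"]
    y_af, y_qa = _labels(manifest)
    tr = np.asarray(split == "train")
    va = np.asarray(split == "val")
    variant = model_mod.Variant(cfg.variant)
    seed = derive_seed(cfg.seed, "train")
    from .benchmark import benchmark_model_configs

    trunk, qa_arm, event_arm = benchmark_model_configs()
    net = model_mod.build_deepbeat(variant, input_length=X.shape[1],
                                   trunk=trunk, qa_arm=qa_arm,
                                   event_arm=event_arm, seed=seed)
    if variant.pretrained:
        if encoder_path is None or not Path(encoder_path).exists():
            raise ValidationError(
                "pretrained variants need a CDAE encoder checkpoint; run the "
                "pretraining stage first")
        net.transfer_encoder_weights(cdae_mod.EncoderWeights.load(encoder_path))
    model_mod.train(net, X[tr], y_af[tr], y_qa[tr], X[va], y_af[va], y_qa[va],
                    model_mod.TrainConfig(epochs=cfg.train_epochs, seed=seed,
                                          lr=1.5e-3, warm_restarts=True,
                                          transferred_lr_scale=0.1))
    ckpt = out / "deepbeat.npz"
    net.save(ckpt)
    return ckpt


def _load_model(cfg: PipelineConfig, ckpt: Path, input_length: int
                ) -> model_mod.DeepBeatModel:
    from .benchmark import benchmark_model_configs

    trunk, qa_arm, event_arm = benchmark_model_configs()
    net = model_mod.build_deepbeat(model_mod.Variant(cfg.variant),
                                   input_length=input_length,
                                   trunk=trunk, qa_arm=qa_arm,
                                   event_arm=event_arm,
                                   seed=derive_seed(cfg.seed, "train"))
    return net.load(ckpt)


def predict_stage(cfg: PipelineConfig, windows_path: Path, ckpt: Path,
                  out: Path) -> Path:
    arrays, manifest, _ = read_container(windows_path)
    split = _split_masks(manifest, cfg)
    te = np.asarray(split == "test")
    X = arrays["windows"][te]
    sub = manifest.loc[te].reset_index(drop=True)
    net = _load_model(cfg, ckpt, X.shape[1])
    af_probs, qa_probs = net.predict_proba(X)
    pred = sub[["id", "subject_id", "rhythm", "qa_true", "noise_factor"]].copy()
    pred["p_af"] = af_probs[:, 1]
    pred["af_pred"] = np.where(af_probs.argmax(axis=1) == 1, "AF", "SINUS")
    if qa_probs is not None:
        for i, name in enumerate(["POOR", "ACCEPTABLE", "EXCELLENT"]):
            pred[f"p_qa_{name.lower()}"] = qa_probs[:, i]
        pred["qa_pred"] = [["POOR", "ACCEPTABLE", "EXCELLENT"][i]
                           for i in qa_probs.argmax(axis=1)]
    path = out / "predictions.csv"
    pred.to_csv(path, index=False)
    return path


def evaluate_stage(pred_path: Path, out: Path) -> Path:
    pred = pd.read_csv(pred_path)
    report = eval_mod.evaluate_labels(pred["rhythm"], pred["af_pred"],
                                      RHYTHM_CLASSES)
    result = {"unfiltered": eval_mod.report_to_dict(report)}
    qa_labels = [QaClass[q] for q in pred["qa_true"]]
    try:
        filt, retained = eval_mod.qa_filtered_eval(
            pred["rhythm"], pred["af_pred"], qa_labels, RHYTHM_CLASSES)
        result["excellent_only"] = eval_mod.report_to_dict(filt)
    except ValidationError as exc:
        result["excellent_only"] = {"error": str(exc)}
    subj = eval_mod.per_individual_aggregate(
        pred["rhythm"], pred["af_pred"], pred["subject_id"], RHYTHM_CLASSES)
    result["per_individual"] = eval_mod.report_to_dict(subj)
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(result, fh, indent=2)
    return path


def explain_stage(cfg: PipelineConfig, windows_path: Path, ckpt: Path,
                  out: Path, n_cam: int = 8) -> dict[str, Path]:
    arrays, manifest, _ = read_container(windows_path)
    split = _split_masks(manifest, cfg)
    te = np.asarray(split == "test")
    X = arrays["windows"][te]
    sub = manifest.loc[te].reset_index(drop=True)
    net = _load_model(cfg, ckpt, X.shape[1])
    maps = [explain_mod.class_activation_map(net, X[i], target_class=1)
            for i in range(min(n_cam, len(X)))]
    cam_path = out / "cams.csv"
    explain_mod.save_cam_csv(cam_path, maps)
    emb = net.embed(X)
    coords = explain_mod.embedding_projection(
        emb, seed=derive_seed(cfg.seed, "umap"))
    emb_path = out / "embedding_2d.csv"
    pd.DataFrame({"id": sub["id"], "rhythm": sub["rhythm"],
                  "x": coords[:, 0], "y": coords[:, 1]}).to_csv(
        emb_path, index=False)
    return {"cams": cam_path, "embedding": emb_path}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in order; returns artifact paths and the final report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config": asdict(cfg), "config_hash": config_hash(asdict(cfg)),
                  "seed": cfg.seed, "version": __version__}
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    stages: dict[str, object] = {}
    t0 = time.time()
    try:
        stages["simulated"] = sim_path = simulate_stage(cfg, out)
        stages["windows"] = win_path = preprocess_stage(cfg, sim_path, out)
        variant = model_mod.Variant(cfg.variant)
        encoder_path = None
        if variant.pretrained:
            stages["encoder"] = encoder_path = pretrain_stage(cfg, win_path, out)
        stages["model"] = ckpt = train_stage(cfg, win_path, encoder_path, out)
        stages["predictions"] = pred_path = predict_stage(cfg, win_path, ckpt, out)
        stages["report"] = evaluate_stage(pred_path, out)
        stages.update(explain_stage(cfg, win_path, ckpt, out))
    except Exception:
        done = ", ".join(stages) or "none"
        logger.exception("pipeline halted after stages: %s", done)
        raise
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    stages["elapsed_s"] = time.time() - t0
    return {k: (str(v) if isinstance(v, Path) else v) for k, v in stages.items()}
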