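"""Model inspection: 1-D gradient-weighted class activation maps and 2-D
projections of the rhythm-arm embedding.

The CAM weights each feature map of the last rhythm-arm convolutional layer
by the time-averaged gradient of the target class logit, rectifies the
combination, linearly interpolates it to the input length and max-normalizes
to [0, 1].  Gradient weighting is used because the dense layers after the
convolutions preclude the classic global-average-pooling formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .model import DeepBeatModel
from .types import ValidationError


@dataclass
class SaliencyMap:
    values: np.ndarray           # length L, in [0, 1]
    target_class: int
    source_layer: str
    trained: bool = True


def _last_conv_index(head: nn.Sequential) -> int:
    idx = [i for i, l in enumerate(head.layers) if isinstance(l, nn.Conv1D)]
    if not idx:
        raise ValidationError("head has no convolutional layer for CAM")
    return idx[-1]


def class_activation_map(model: DeepBeatModel, window: np.ndarray,
                         target_class: int, trained: bool = True,
                         ) -> SaliencyMap:
    """Grad-CAM over the last rhythm-arm convolution for one window."""
    x = np.asarray(window, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.input_length:
        raise ValidationError(
            f"expected window length {model.input_length}, got {x.shape[1]}")
    head = model.event_head
    conv_idx = _last_conv_index(head)
    h = model.trunk.forward(x[:, :, None], training=False)
    # forward through the head, keeping the target conv's output
    act = head.forward_upto(h, conv_idx + 1, training=False)
    out = act
    for layer in head.layers[conv_idx + 1:]:
        out = layer.forward(out, training=False)
    n_classes = out.shape[1]
    if not 0 <= target_class < n_classes:
        raise ValidationError(
            f"target_class {target_class} outside [0, {n_classes})")
    grad = np.zeros_like(out)
    grad[:, target_class] = 1.0
    for layer in reversed(head.layers[conv_idx + 1:]):
        grad = layer.backward(grad)
    # grad now has the shape of the conv output: (1, T, C)
    channel_w = grad.mean(axis=1)                      # (1, C)
    cam = np.maximum((act * channel_w[:, None, :]).sum(axis=2), 0.0)[0]
    # stretch the T-point map to the L-sample input
    t_src = np.linspace(0.0, 1.0, num=len(cam))
    t_dst = np.linspace(0.0, 1.0, num=model.input_length)
    cam_full = np.interp(t_dst, t_src, cam)
    peak = cam_full.max()
    if peak > 0:
        cam_full = cam_full / peak
    return SaliencyMap(values=cam_full, target_class=target_class,
                       source_layer=f"event_head.conv{conv_idx}",
                       trained=trained)


def embedding_projection(embeddings: np.ndarray, seed: int = 0,
                         n_neighbors: int = 15, min_dist: float = 0.1,
                         ) -> np.ndarray:
    """Seeded 2-D UMAP of embedding vectors; one point per window."""
    E = np.asarray(embeddings, dtype=float)
    if E.ndim != 2:
        raise ValidationError("embeddings must be a 2-D array")
    n = E.shape[0]
    if n < 10:
        raise ValidationError(
            f"need at least 10 embeddings for a projection, got {n}")
    k = min(n_neighbors, n - 1)
    if k < 2:
        raise ValidationError(
            f"n_neighbors must allow >= 2 neighbours; try n_neighbors="
            f"{max(2, n - 1)}")
    import warnings

    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=k, min_dist=min_dist,
                            random_state=seed)
        coords = reducer.fit_transform(E)
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("projection produced non-finite coordinates")
    return coords


def save_cam_csv(path, maps: list[SaliencyMap]) -> None:
    import pandas as pd

    frames = {f"cam{i:04d}_class{m.target_class}": m.values
              for i, m in enumerate(maps)}
    pd.DataFrame(frames).to_csv(path, index=False)
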