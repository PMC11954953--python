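"""Minimal time-contrastive embedding of population activity.

The encoder is a small two-layer perceptron applied to sliding windows of
the cells x frames matrix (window width ``window_offset`` frames, so each
embedded point summarizes a short stretch of population activity). It is
trained with an InfoNCE-style objective: for each anchor window a positive
partner is drawn by temporal proximity (time-delta sampling) — and, in
hybrid mode, half the time by shared behavior label — while the other
positives in the batch act as negatives. Similarity is the negative
squared Euclidean distance at unit temperature.

This is deliberately a compact, dependency-free trainer: the scientific
payload downstream is the evaluation harness (structure vs shuffle,
decoding accuracy, out-of-bag error), not embedding-tool parity. A
training-free fallback (``encoder='window'``) returns the raw windowed
features so the rest of the pipeline can run without any optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import ParameterError
from .rng import stage_rng
from .types import TraceMatrix

__all__ = ["EmbeddingConfig", "Embedding", "window_features", "train_embedding"]


@dataclass
class EmbeddingConfig:
    latent_dim: int = 3
    window_offset: int = 5
    conditional: str = "time-delta"
    hybrid: bool = True
    distance: str = "euclidean"
    batch_size: int = 800  # within the 600-1200 range used for this model class
    learning_rate: float = 1e-4
    iterations: int = 8000
    seed: int = 0
    encoder: str = "contrastive"  # or 'window' (training-free fallback)
    hidden_dim: int = 32
    temperature: float = 1.0
    time_delta_max: int = 10  # frames; positive-pair horizon

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ParameterError("latent_dim must be >= 1")
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")
        if self.window_offset < 1:
            raise ParameterError("window_offset must be >= 1")
        if self.conditional != "time-delta":
            raise ParameterError(f"unknown conditional {self.conditional!r}")
        if self.distance != "euclidean":
            raise ParameterError(f"unknown distance {self.distance!r}")
        if self.encoder not in ("contrastive", "window"):
            raise ParameterError(f"unknown encoder {self.encoder!r}")


@dataclass
class Embedding:
    """Latent points aligned to frames, plus their behavior labels."""

    points: np.ndarray  # (n_points, latent_dim)
    labels: np.ndarray  # (n_points,)
    config: EmbeddingConfig
    frame_offset: int  # first frame covered by point 0
    meta: Dict = field(default_factory=dict)


def window_features(
    values: np.ndarray, window_offset: int
) -> np.ndarray:
    """Flattened sliding windows: point t = values[:, t : t + offset].

    Returns shape (n_frames - offset + 1, n_cells * offset).
    """
    n_cells, n_frames = values.shape
    if n_frames < window_offset + 1:
        raise ParameterError(
            f"need at least window_offset+1={window_offset + 1} frames"
        )
    win = np.lib.stride_tricks.sliding_window_view(
        values, window_offset, axis=1
    )  # (cells, n_points, offset)
    return win.transpose(1, 0, 2).reshape(-1, n_cells * window_offset)


def _align_labels(labels: np.ndarray, window_offset: int) -> np.ndarray:
    """Label of a window = label of its last covered frame."""
    return np.asarray(labels)[window_offset - 1 :]


class _MLPEncoder:
    """Two-layer perceptron with manual gradients and Adam updates."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator):
        self.W1 = rng.normal(0, np.sqrt(2.0 / d_in), (d_in, d_hidden))
        self.b1 = np.zeros(d_hidden)
        self.W2 = rng.normal(0, np.sqrt(2.0 / d_hidden), (d_hidden, d_out))
        self.b2 = np.zeros(d_out)
        self._adam = {
            k: (np.zeros_like(v), np.zeros_like(v))
            for k, v in self._params().items()
        }
        self._t = 0

    def _params(self) -> Dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        h = np.maximum(x @ self.W1 + self.b1, 0.0)
        return h @ self.W2 + self.b2, h

    def backward(
        self, x: np.ndarray, h: np.ndarray, dz: np.ndarray
    ) -> Dict[str, np.ndarray]:
        dW2 = h.T @ dz
        db2 = dz.sum(axis=0)
        dh = dz @ self.W2.T
        dh[h <= 0] = 0.0
        dW1 = x.T @ dh
        db1 = dh.sum(axis=0)
        return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}

    def adam_step(self, grads: Dict[str, np.ndarray], lr: float) -> None:
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, p in self._params().items():
            m, v = self._adam[k]
            g = grads[k]
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


def _sample_pairs(
    n_points: int,
    labels: np.ndarray,
    cfg: EmbeddingConfig,
    rng: np.random.Generator,
    label_index: Optional[Dict] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Anchor/positive index pairs by time-delta (and label in hybrid mode)."""
    anchors = rng.integers(0, n_points, size=cfg.batch_size)
    deltas = rng.integers(1, cfg.time_delta_max + 1, size=cfg.batch_size)
    signs = rng.choice([-1, 1], size=cfg.batch_size)
    positives = np.clip(anchors + signs * deltas, 0, n_points - 1)
    if cfg.hybrid and label_index is not None:
        use_label = rng.random(cfg.batch_size) < 0.5
        for i in np.flatnonzero(use_label):
            same = label_index[labels[anchors[i]]]
            positives[i] = same[rng.integers(len(same))]
    return anchors, positives


def train_embedding(
    traces: TraceMatrix | np.ndarray,
    labels: np.ndarray,
    config: Optional[EmbeddingConfig] = None,
) -> Embedding:
    """Train (or construct, for the fallback) an embedding of the session.

    ``labels`` must hold one behavior label per frame; points are aligned
    so that point *t* covers frames ``[t, t + window_offset)`` and carries
    the label of its last frame. Deterministic for a fixed config seed.
    """
    cfg = config or EmbeddingConfig()
    values = traces.values if isinstance(traces, TraceMatrix) else np.asarray(traces)
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[1]:
        raise ParameterError(
            f"{labels.shape[0]} labels for {values.shape[1]} frames"
        )
    feats = window_features(values, cfg.window_offset)
    point_labels = _align_labels(labels, cfg.window_offset)
    n_points = feats.shape[0]

    if cfg.encoder == "window":
        pts = feats if cfg.latent_dim >= feats.shape[1] else feats[:, : cfg.latent_dim]
        return Embedding(
            points=pts,
            labels=point_labels,
            config=cfg,
            frame_offset=0,
            meta={"encoder": "window", "clipped": cfg.latent_dim < feats.shape[1]},
        )

    uniq = np.unique(point_labels)
    if cfg.hybrid and uniq.size < 2:
        raise ParameterError("hybrid mode needs at least 2 distinct labels")
    label_index = {lab: np.flatnonzero(point_labels == lab) for lab in uniq}

    # standardize features so the loss scale is data-independent
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    x_all = (feats - mu) / sd

    rng = stage_rng(cfg.seed, "embedding/train")
    net = _MLPEncoder(x_all.shape[1], cfg.hidden_dim, cfg.latent_dim, rng)

    B = cfg.batch_size
    for _ in range(cfg.iterations):
        a_idx, p_idx = _sample_pairs(n_points, point_labels, cfg, rng, label_index)
        xa, xp = x_all[a_idx], x_all[p_idx]
        za, ha = net.forward(xa)
        zp, hp = net.forward(xp)

        # similarity S_ij = -||za_i - zp_j||^2 / temperature
        sq_a = (za**2).sum(axis=1)[:, None]
        sq_p = (zp**2).sum(axis=1)[None, :]
        S = -(sq_a + sq_p - 2.0 * za @ zp.T) / cfg.temperature

        S_shift = S - S.max(axis=1, keepdims=True)
        expS = np.exp(S_shift)
        softmax = expS / expS.sum(axis=1, keepdims=True)
        dS = (softmax - np.eye(B)) / B  # d(mean InfoNCE)/dS

        # dS_ij/dza_i = -2(za_i - zp_j)/T ; dS_ij/dzp_j = +2(za_i - zp_j)/T
        row = dS.sum(axis=1)[:, None]
        dza = (-2.0 / cfg.temperature) * (row * za - dS @ zp)
        col = dS.sum(axis=0)[:, None]
        dzp = (-2.0 / cfg.temperature) * (col * zp - dS.T @ za)

        ga = net.backward(xa, ha, dza)
        gp = net.backward(xp, hp, dzp)
        grads = {k: ga[k] + gp[k] for k in ga}
        net.adam_step(grads, cfg.learning_rate)

    points, _ = net.forward(x_all)
    if not np.isfinite(points).all():
        raise ParameterError("embedding diverged to non-finite values")
    return Embedding(
        points=points,
        labels=point_labels,
        config=cfg,
        frame_offset=0,
        meta={
            "encoder": "contrastive",
            "standardize": {"mean": mu, "sd": sd},
            "network": net,
        },
    )


def apply_encoder(
    model: Embedding, traces: TraceMatrix | np.ndarray, labels: np.ndarray
) -> Embedding:
    """Project new data through an already-trained encoder.

    Used for cross-behavior transfer: the encoder trained on behavior A is
    applied, frozen, to behavior B's traces (which must carry the same
    cells in the same order). The fallback encoder simply recomputes
    windowed features.
    """
    cfg = model.config
    values = traces.values if isinstance(traces, TraceMatrix) else np.asarray(traces)
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[1]:
        raise ParameterError(
            f"{labels.shape[0]} labels for {values.shape[1]} frames"
        )
    feats = window_features(values, cfg.window_offset)
    point_labels = _align_labels(labels, cfg.window_offset)
    if cfg.encoder == "window":
        pts = feats if cfg.latent_dim >= feats.shape[1] else feats[:, : cfg.latent_dim]
        return Embedding(pts, point_labels, cfg, 0, {"encoder": "window"})
    std = model.meta["standardize"]
    x = (feats - std["mean"]) / std["sd"]
    points, _ = model.meta["network"].forward(x)
    return Embedding(points, point_labels, cfg, 0, {"encoder": "contrastive-transfer"})
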