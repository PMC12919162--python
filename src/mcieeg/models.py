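"""Classifiers over the channel x feature representation.

Two architectures trained on the identical engineered input of shape
(channels=19, features=77):

* ``FeatureTransformer`` — the primary model: a 1-D convolutional
  embedding along the channel sequence projects each channel's feature
  vector into a latent token, a trainable positional embedding is added,
  and a stack of vanilla post-norm Transformer encoder blocks
  (multi-head self-attention + position-wise feed-forward, residual +
  layer norm + dropout around each sub-layer) models cross-channel
  interactions; global average pooling over tokens feeds a small dense
  head with a 2-way softmax.

* ``FeatureEEGNet`` — a compact convolutional baseline adapted from the
  raw-EEG EEGNet recipe, with the 77-feature axis playing the role of
  the time axis: shared temporal convolution, depthwise spatial
  convolution over the 19 channels, separable convolution, pooling and
  a dense softmax head.

The shared trainer uses Adam with per-epoch exponential learning-rate
decay, categorical cross-entropy, early stopping on validation accuracy
(patience 10) and checkpointing of the best-validation-accuracy weights.
Training refuses subject overlap between the train and validation sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .features import FeatureTensor

__all__ = [
    "CLASS_ORDER",
    "TransformerConfig",
    "EEGNetConfig",
    "FeatureTransformer",
    "FeatureEEGNet",
    "TrainState",
    "build_transformer",
    "build_eegnet_features",
    "train",
    "predict_proba",
    "count_parameters",
]

#: Fixed class order of the softmax output: column 0 = HC, column 1 = MCI.
CLASS_ORDER = ("HC", "MCI")


@dataclass(frozen=True)
class TransformerConfig:
    n_channels: int = 19
    n_features: int = 77
    n_blocks: int = 6
    n_heads: int = 5
    ff_dim: int = 64
    conv_filters: int = 128
    conv_kernel: int = 5
    dropout: float = 0.1
    l2: float = 0.0005
    lr: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 50

    def __post_init__(self) -> None:
        if min(self.n_blocks, self.n_heads, self.ff_dim, self.conv_filters,
               self.batch_size, self.max_epochs) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.conv_filters < self.n_heads:
            raise ValueError("embedding width smaller than the head count")


@dataclass(frozen=True)
class EEGNetConfig:
    n_channels: int = 19
    n_features: int = 77
    f1: int = 8
    depth_multiplier: int = 2
    f2: int = 16
    temporal_kernel: int = 31
    separable_kernel: int = 15
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.4
    lr: float = 1e-5
    batch_size: int = 4
    max_epochs: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class _EncoderBlock(nn.Module):
    """Post-norm Transformer encoder block.

    The embedding width need not divide the head count: queries, keys and
    values are projected to heads x floor(width / heads) and the attention
    output is projected back to the full width.
    """

    def __init__(self, emb: int, heads: int, ff_dim: int, dropout: float,
                 rng: np.random.Generator):
        self.heads = heads
        self.head_dim = emb // heads
        inner = self.heads * self.head_dim
        self.wq = nn.Dense(emb, inner, rng)
        self.wk = nn.Dense(emb, inner, rng)
        self.wv = nn.Dense(emb, inner, rng)
        self.wo = nn.Dense(inner, emb, rng)
        self.ff1 = nn.Dense(emb, ff_dim, rng)
        self.ff2 = nn.Dense(ff_dim, emb, rng)
        self.ln1 = nn.LayerNorm(emb)
        self.ln2 = nn.LayerNorm(emb)
        self.drop1 = nn.Dropout(dropout, rng)
        self.drop2 = nn.Dropout(dropout, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        b, t, _ = x.shape
        h, dh = self.heads, self.head_dim

        def split(z):
            return z.reshape(b, t, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        att = nn.softmax(scores, axis=-1)
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(b, t, h * dh)
        x = self.ln1(x + self.drop1(self.wo(ctx)))
        ff = self.ff2(nn.relu(self.ff1(x)))
        return self.ln2(x + self.drop2(ff))


class FeatureTransformer(nn.Module):
    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        self.cfg = cfg
        emb = cfg.conv_filters
        self.embed = nn.Conv1dSame(cfg.conv_kernel, cfg.n_features, emb, rng)
        self.bn = nn.BatchNorm(emb)
        self.pos = nn.Parameter(rng.normal(0.0, 0.02, (cfg.n_channels, emb)))
        self.blocks = [
            _EncoderBlock(emb, cfg.n_heads, cfg.ff_dim, cfg.dropout, rng)
            for _ in range(cfg.n_blocks)
        ]
        self.head = nn.Dense(emb, 64, rng)
        self.drop = nn.Dropout(cfg.dropout, rng)
        self.out = nn.Dense(64, 2, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        """(batch, channels, features) -> logits (batch, 2)."""
        h = self.embed(x)  # tokens = channels
        h = self.bn(h)
        h = h + self.pos
        for blk in self.blocks:
            h = blk(h)
        h = nn.mean_axis(h, 1)
        h = self.drop(nn.relu(self.head(h)))
        return self.out(h)


class FeatureEEGNet(nn.Module):
    def __init__(self, cfg: EEGNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        c, t = cfg.n_channels, cfg.n_features
        self.temporal = nn.Conv1dSame(cfg.temporal_kernel, 1, cfg.f1, rng)
        self.bn1 = nn.BatchNorm(cfg.f1)
        scale = np.sqrt(2.0 / (c + cfg.depth_multiplier))
        self.depthwise = nn.Parameter(
            rng.normal(0.0, scale, (c, cfg.f1, cfg.depth_multiplier))
        )
        m = cfg.f1 * cfg.depth_multiplier
        self.bn2 = nn.BatchNorm(m)
        self.sep_depth = nn.Parameter(
            rng.normal(0.0, np.sqrt(1.0 / cfg.separable_kernel),
                       (cfg.separable_kernel, m))
        )
        self.sep_point = nn.Dense(m, cfg.f2, rng)
        self.bn3 = nn.BatchNorm(cfg.f2)
        self.drop1 = nn.Dropout(cfg.dropout, rng)
        self.drop2 = nn.Dropout(cfg.dropout, rng)
        t1 = (t // cfg.pool1) * cfg.pool1
        t2 = t1 // cfg.pool1
        t3 = (t2 // cfg.pool2) * cfg.pool2
        self._t1, self._t3 = t1, t3
        self.out = nn.Dense((t3 // cfg.pool2) * cfg.f2, 2, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        """(batch, channels, features) -> logits (batch, 2)."""
        cfg = self.cfg
        b, c, t = x.shape
        h = x.reshape(b * c, t, 1)
        h = self.temporal(h)  # shared temporal filters per channel
        h = h.reshape(b, c, t, cfg.f1)
        h = self.bn1(h)
        h = nn.depthwise_spatial(h, self.depthwise)  # (b, t, f1, d)
        h = h.reshape(b, t, cfg.f1 * cfg.depth_multiplier)
        h = self.bn2(h)
        h = nn.elu(h)
        h = h.slice_axis1(0, self._t1)
        h = nn.avg_pool_axis1(h, cfg.pool1)
        h = self.drop1(h)
        h = nn.depthwise_temporal(h, self.sep_depth)
        h = self.sep_point(h)
        h = self.bn3(h)
        h = nn.elu(h)
        h = h.slice_axis1(0, self._t3)
        h = nn.avg_pool_axis1(h, cfg.pool2)
        h = self.drop2(h)
        h = h.reshape(b, -1)
        return self.out(h)


def build_transformer(
    cfg: TransformerConfig = TransformerConfig(), seed: int = 0
) -> FeatureTransformer:
    return FeatureTransformer(cfg, np.random.default_rng(seed))


def build_eegnet_features(
    cfg: EEGNetConfig = EEGNetConfig(), seed: int = 0
) -> FeatureEEGNet:
    return FeatureEEGNet(cfg, np.random.default_rng(seed))


def count_parameters(model: nn.Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainState:
    model: nn.Module
    config: object
    history: dict[str, list[float]]
    best_epoch: int
    best_val_accuracy: float
    early_stop_epoch: int | None
    seed: int
    feature_names: list[str] = field(default_factory=list)
    best_checkpoint: list[np.ndarray] = field(default_factory=list)


def _labels_to_int(labels: np.ndarray) -> np.ndarray:
    y = np.asarray([CLASS_ORDER.index(l) for l in labels])
    return y


def _forward_batches(model: nn.Module, x: np.ndarray, batch: int) -> np.ndarray:
    """Eval-mode class probabilities, batched."""
    model.set_training(False)
    out = []
    for i in range(0, len(x), batch):
        logits = model(nn.Tensor(x[i : i + batch]))
        z = logits.data - logits.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        out.append(e / e.sum(axis=-1, keepdims=True))
    return np.concatenate(out)


def train(
    model: nn.Module,
    ft_train: FeatureTensor,
    ft_val: FeatureTensor,
    cfg,
    seed: int = 0,
    patience: int = 10,
    lr_decay: float = 0.96,
    verbose: bool = False,
) -> TrainState:
    """Adam + exponential LR decay + early stopping + best checkpointing.

    The checkpoint with the highest validation accuracy is restored into
    the model before returning.  Raises if any subject contributes epochs
    to both the training and validation sets.
    """
    if len(ft_train) == 0 or len(ft_val) == 0:
        raise ValueError("training and validation sets must be nonempty")
    overlap = set(ft_train.subject_ids) & set(ft_val.subject_ids)
    if overlap:
        raise ValueError(f"subject leakage between train and val: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(seed)
    x_tr, y_tr = ft_train.values, _labels_to_int(ft_train.labels)
    x_va, y_va = ft_val.values, _labels_to_int(ft_val.labels)

    opt = nn.Adam(model.parameters(), lr=cfg.lr,
                  weight_decay_l2=getattr(cfg, "l2", 0.0))
    history: dict[str, list[float]] = {
        "train_loss": [], "train_accuracy": [],
        "val_loss": [], "val_accuracy": [], "lr": [],
    }
    best_acc, best_epoch, best_state = -np.inf, -1, None
    early_stop_epoch = None
    n = len(x_tr)
    for ep in range(cfg.max_epochs):
        opt.set_epoch(ep, decay=lr_decay)
        model.set_training(True)
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model(nn.Tensor(x_tr[idx]))
            loss = nn.softmax_cross_entropy(logits, y_tr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y_tr[idx]).sum())
        p_va = _forward_batches(model, x_va, max(cfg.batch_size, 64))
        val_loss = float(
            -np.mean(np.log(p_va[np.arange(len(y_va)), y_va] + 1e-12))
        )
        val_acc = float((p_va.argmax(axis=1) == y_va).mean())
        history["train_loss"].append(float(np.mean(losses)))
        history["train_accuracy"].append(correct / n)
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        history["lr"].append(opt.lr)
        if verbose:
            print(f"epoch {ep:3d} loss {np.mean(losses):.4f} "
                  f"val_acc {val_acc:.3f} lr {opt.lr:.2e}")
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, ep
            best_state = model.state_dict()
        elif ep - best_epoch >= patience:
            early_stop_epoch = ep
            break
    model.load_state_dict(best_state)
    return TrainState(
        model=model,
        config=cfg,
        history=history,
        best_epoch=best_epoch,
        best_val_accuracy=float(best_acc),
        early_stop_epoch=early_stop_epoch,
        seed=seed,
        feature_names=list(ft_train.feature_names),
        best_checkpoint=best_state,
    )


def predict_proba(state: TrainState, ft: FeatureTensor) -> np.ndarray:
    """Per-epoch class probabilities in CLASS_ORDER; rows sum to one."""
    if state.feature_names and list(ft.feature_names) != state.feature_names:
        raise ValueError("feature registry mismatch between training and input")
    batch = max(getattr(state.config, "batch_size", 32), 64)
    return _forward_batches(state.model, ft.values, batch)


# ---------------------------------------------------------------------------
# checkpoint persistence


def save_train_state(state: TrainState, prefix: str,
                     norm_stats: dict | None = None) -> None:
    """Write ``<prefix>.npz`` (checkpoint arrays) + ``<prefix>.json``
    (model kind, config, history, and optionally the feature
    normalization statistics the checkpoint was trained under)."""
    import json
    from dataclasses import asdict

    np.savez(f"{prefix}.npz",
             **{f"p{i}": a for i, a in enumerate(state.best_checkpoint)})
    meta = {
        "model": type(state.model).__name__,
        "config": asdict(state.config),
        "history": state.history,
        "best_epoch": state.best_epoch,
        "best_val_accuracy": state.best_val_accuracy,
        "early_stop_epoch": state.early_stop_epoch,
        "seed": state.seed,
        "feature_names": state.feature_names,
        "norm_stats": None if norm_stats is None else {
            "mean": np.asarray(norm_stats["mean"]).tolist(),
            "sd": np.asarray(norm_stats["sd"]).tolist(),
        },
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh)


def load_train_state(prefix: str) -> tuple[TrainState, dict | None]:
    """Rebuild the model from a saved checkpoint; returns the state and
    the stored normalization statistics (or None)."""
    import json

    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    arrays = np.load(f"{prefix}.npz")
    checkpoint = [arrays[f"p{i}"] for i in range(len(arrays.files))]
    if meta["model"] == "FeatureTransformer":
        cfg = TransformerConfig(**meta["config"])
        model = build_transformer(cfg, seed=meta["seed"])
    elif meta["model"] == "FeatureEEGNet":
        cfg = EEGNetConfig(**meta["config"])
        model = build_eegnet_features(cfg, seed=meta["seed"])
    else:
        raise ValueError(f"unknown model kind {meta['model']!r}")
    model.load_state_dict(checkpoint)
    state = TrainState(
        model=model, config=cfg, history=meta["history"],
        best_epoch=meta["best_epoch"],
        best_val_accuracy=meta["best_val_accuracy"],
        early_stop_epoch=meta["early_stop_epoch"], seed=meta["seed"],
        feature_names=meta["feature_names"], best_checkpoint=checkpoint,
    )
    ns = meta["norm_stats"]
    if ns is not None:
        ns = {"mean": np.array(ns["mean"]), "sd": np.array(ns["sd"])}
    return state, ns
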