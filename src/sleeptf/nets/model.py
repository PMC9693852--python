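"""Sleep-stage classifier architectures.

Two variants over 224x224x3 time-frequency images:

* ``cnn``      backbone -> dropout -> fully connected -> softmax(5)
* ``cnn_rnn``  backbone -> feature sequence (image time axis) ->
               BiLSTM + dropout -> BiLSTM + dropout -> softmax(5)

The backbone is a pluggable contract mapping 224x224x3 to a feature map
(H_f, W_f, C_f) with W_f >= 4 so the RNN variant has a usable sequence
axis.  The default "compact" backbone (four conv blocks) trains at desk
scale; a "pretrained-adapter" slot exists for an externally supplied
GoogLeNet-class feature extractor but is never required.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from .layers import Conv2D, MaxPool2, ReLU, Dense, Dropout, softmax
from .lstm import BiLSTMLayer

__all__ = [
    "BackboneSpec",
    "SleepNetConfig",
    "CompactBackbone",
    "SleepNet",
    "build_model",
    "feature_sequence",
]

IMAGE_SHAPE = (224, 224, 3)


def feature_sequence(feature_map: np.ndarray) -> np.ndarray:
    """Unfold a (H_f, W_f, C_f) feature map into W_f vectors of length H_f*C_f.

    Element t is the flattened column t (the image's time axis becomes the
    sequence axis).  Flattening order is frequency-major, then channel:
    vector index h*C_f + c holds feature_map[h, t, c].
    """
    fm = np.asarray(feature_map)
    if fm.ndim != 3:
        raise ValueError("feature_map must be (H_f, W_f, C_f)")
    H, W, C = fm.shape
    return fm.transpose(1, 0, 2).reshape(W, H * C)


def feature_map_from_sequence(seq: np.ndarray, H: int, C: int) -> np.ndarray:
    """Inverse of :func:`feature_sequence` (used in tests)."""
    W = seq.shape[0]
    return seq.reshape(W, H, C).transpose(1, 0, 2)


@dataclass(frozen=True)
class BackboneSpec:
    """Which feature extractor to use and what it produces."""

    kind: str = "compact"  # or "pretrained-adapter"
    widths: tuple[int, int, int, int] = (16, 32, 64, 64)
    weights_path: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("compact", "pretrained-adapter"):
            raise ValueError(f"unknown backbone kind {self.kind!r}")


@dataclass(frozen=True)
class SleepNetConfig:
    variant: str = "cnn_rnn"  # or "cnn"
    n_classes: int = 5
    dropout_head: float = 0.5
    dropout_rnn: float = 0.3
    hidden_sizes: tuple[int, int] = (128, 128)
    freeze_backbone: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("cnn", "cnn_rnn"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_classes != 5:
            raise ValueError("the staging head is five-way (W, N1, N2, N3, REM)")
        for r in (self.dropout_head, self.dropout_rnn):
            if not 0 <= r < 1:
                raise ValueError("dropout rates must be in [0, 1)")


class CompactBackbone:
    """Four conv blocks: 224x224x3 -> (widths[3], 7, 7) feature map.

    conv7/s4 -> ReLU -> pool2 -> conv3 -> ReLU -> pool2 -> conv3 -> ReLU
    -> pool2 -> conv3 -> ReLU, yielding a 7-column sequence axis.
    """

    def __init__(self, widths: tuple[int, int, int, int], rng: np.random.Generator) -> None:
        w1, w2, w3, w4 = widths
        self.layers = [
            Conv2D(3, w1, kernel=7, stride=4, pad=2, rng=rng, input_grad=False), ReLU(), MaxPool2(),
            Conv2D(w1, w2, kernel=3, stride=1, pad=1, rng=rng), ReLU(), MaxPool2(),
            Conv2D(w2, w3, kernel=3, stride=1, pad=1, rng=rng), ReLU(), MaxPool2(),
            Conv2D(w3, w4, kernel=3, stride=1, pad=1, rng=rng), ReLU(),
        ]
        self.out_shape = (7, 7, w4)  # (H_f, W_f, C_f)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class SleepNet:
    """Five-way sleep-stage classifier over time-frequency images.

    ``forward`` takes a (N, 224, 224, 3) float batch in [0, 1] and returns
    (N, 5) probabilities.  Dropout is active only during training steps, so
    inference is deterministic.
    """

    def __init__(self, config: SleepNetConfig, backbone: BackboneSpec | None = None) -> None:
        backbone = backbone or BackboneSpec()
        if backbone.kind == "pretrained-adapter":
            if backbone.weights_path is None or not os.path.exists(backbone.weights_path):
                raise FileNotFoundError(
                    "pretrained-adapter backbone requested but no weights are available; "
                    "use BackboneSpec(kind='compact') for the download-free backbone"
                )
            raise NotImplementedError(
                "no pretrained weight container is shipped; use the compact backbone"
            )
        self.config = config
        self.backbone_spec = backbone
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(config.seed, 17)))
        self.dropout_rng = np.random.default_rng(np.random.SeedSequence(entropy=(config.seed, 23)))
        self.backbone = CompactBackbone(backbone.widths, rng)
        Hf, Wf, Cf = self.backbone.out_shape
        if Wf < 4:
            raise ValueError("backbone must keep a sequence axis of width >= 4")
        self.variant = config.variant
        if self.variant == "cnn":
            self.head_dropout = Dropout(config.dropout_head, self.dropout_rng)
            self.fc = Dense(Hf * Wf * Cf, config.n_classes, rng)
            self.head_layers = [self.fc]
        else:
            h1, h2 = config.hidden_sizes
            self.rnn1 = BiLSTMLayer(Hf * Cf, h1, rng)
            self.drop1 = Dropout(config.dropout_rnn, self.dropout_rng)
            self.rnn2 = BiLSTMLayer(2 * h1, h2, rng)
            self.drop2 = Dropout(config.dropout_rnn, self.dropout_rng)
            self.fc = Dense(2 * h2, config.n_classes, rng)
            self.head_layers = [self.rnn1.fwd, self.rnn1.bwd, self.rnn2.fwd, self.rnn2.bwd, self.fc]

    # -- parameter plumbing -------------------------------------------------
    def parameter_groups(self) -> dict[str, list]:
        """Named (layer, key) handles, split backbone vs head for the optimizer."""
        backbone = [
            (layer, k)
            for layer in self.backbone.layers
            for k in getattr(layer, "params", {})
        ]
        head = [(layer, k) for layer in self.head_layers for k in layer.params]
        return {"backbone": backbone, "head": head}

    def parameter_hash(self, group: str = "all") -> str:
        import hashlib

        groups = self.parameter_groups()
        items = groups["backbone"] + groups["head"] if group == "all" else groups[group]
        h = hashlib.sha256()
        for layer, k in items:
            h.update(np.ascontiguousarray(layer.params[k]).tobytes())
        return h.hexdigest()

    # -- forward / backward -------------------------------------------------
    def _to_nchw(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim != 4 or x.shape[1:] != IMAGE_SHAPE:
            raise ValueError(f"expected batch of shape (N, {IMAGE_SHAPE}), got {x.shape}")
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def logits(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        x = self.backbone.forward(self._to_nchw(images), train)
        N, Cf, Hf, Wf = x.shape
        self._fm_shape = x.shape
        if self.variant == "cnn":
            flat = x.reshape(N, -1)
            flat = self.head_dropout.forward(flat, train)
            return self.fc.forward(flat, train)
        # image time axis -> sequence axis; frequency-major then channel
        seq = np.ascontiguousarray(x.transpose(0, 3, 2, 1)).reshape(N, Wf, Hf * Cf)
        out1 = self.drop1.forward(self.rnn1.forward(seq, train), train)
        out2 = self.drop2.forward(self.rnn2.forward(out1, train), train)
        h2 = self.rnn2.H
        # sequence summary: final state of each direction
        summary = np.concatenate([out2[:, -1, :h2], out2[:, 0, h2:]], axis=1)
        self._T = out2.shape[1]
        return self.fc.forward(summary, train)

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        return softmax(self.logits(images, train))

    predict_proba = forward

    def predict(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(images), batch_size):
            out.append(np.argmax(self.forward(images[i : i + batch_size]), axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=np.int64)

    def backward(self, dlogits: np.ndarray) -> None:
        N, Cf, Hf, Wf = self._fm_shape
        d = self.fc.backward(dlogits)
        if self.variant == "cnn":
            d = self.head_dropout.backward(d)
            dfm = d.reshape(N, Cf, Hf, Wf)
        else:
            h2 = self.rnn2.H
            dseq2 = np.zeros((N, self._T, 2 * h2), dtype=d.dtype)
            dseq2[:, -1, :h2] = d[:, :h2]
            dseq2[:, 0, h2:] = d[:, h2:]
            d1 = self.rnn2.backward(self.drop2.backward(dseq2))
            dseq = self.rnn1.backward(self.drop1.backward(d1))
            dfm = np.ascontiguousarray(
                dseq.reshape(N, Wf, Hf, Cf).transpose(0, 3, 2, 1)
            )
        if not self.config.freeze_backbone:
            self.backbone.backward(dfm)

    # -- checkpointing ------------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        """Save weights + config as a versioned .npz container."""
        arrays = {}
        groups = self.parameter_groups()
        for gname, items in groups.items():
            for j, (layer, k) in enumerate(items):
                arrays[f"{gname}.{j}.{k}"] = layer.params[k]
        meta = {
            "format": "sleeptf-checkpoint-1",
            "config": asdict(self.config),
            "backbone": asdict(self.backbone_spec),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "SleepNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format") != "sleeptf-checkpoint-1":
                raise ValueError(f"unrecognized checkpoint format in {path}")
            cfg_d = meta["config"]
            cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
            bb_d = meta["backbone"]
            bb_d["widths"] = tuple(bb_d["widths"])
            model = cls(SleepNetConfig(**cfg_d), BackboneSpec(**bb_d))
            groups = model.parameter_groups()
            for gname, items in groups.items():
                for j, (layer, k) in enumerate(items):
                    layer.params[k] = data[f"{gname}.{j}.{k}"]
        return model


def build_model(config: SleepNetConfig | None = None, backbone: BackboneSpec | None = None) -> SleepNet:
    """Build one of the two classifier variants."""
    return SleepNet(config or SleepNetConfig(), backbone)
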