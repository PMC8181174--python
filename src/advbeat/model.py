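"""Encoder / classifier / adversary network for beat classification.

The encoder maps the 3 x 128 x 2 beat tensor to a 64-dimensional
representation h through 7 convolution layers: an opening 3x3 valid
convolution that collapses the (beat, pre-RR, near-pre-RR) row axis,
then three residual blocks of two width-3 convolutions each (the second
with dilation 3 to widen the receptive field), every convolution
followed by batch normalisation and ReLU. Blocks 2 and 3 halve the
temporal axis with stride 2; downsampling shortcuts use average pooling,
zero-padding any new channels. A channel + temporal attention module
follows each block, and global average pooling produces h.

Intermediate shapes (channels-last notation): input 3x128x2 ->
conv1 1x126x16 -> block1 1x126x16 -> block2 1x63x64 -> block3 1x32x64
-> h in R^64.

Two affine softmax heads read h: the classifier over the 5 AAMI beat
classes and the adversary over the S training-subject IDs. The heads are
independent given h; the adversary is attached through a
gradient-reversal identity during training (see `training`).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .mitdb import N_CLASSES
from .preprocess import BEAT_LENGTH, flatten_for_encoder

CHECKPOINT_SCHEMA = 1
FEATURE_DIM = 64


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture knobs; defaults are the reference configuration."""

    stem_filters: int = 16
    block_filters: tuple[int, int, int] = (16, 64, 64)
    block_strides: tuple[int, int, int] = (1, 2, 2)
    dilation: int = 3
    attention_reduction: int = 8
    attention_kernel: int = 7
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5


class ChannelAttention(nn.Module):
    """Squeeze-and-gate over channels: average- and max-pooled channel
    descriptors pass through a shared two-layer bottleneck; the summed
    logits are squashed to per-channel weights in (0, 1)."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Dense(channels, hidden, rng)
        self.fc2 = nn.Dense(hidden, channels, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        avg = x.mean(axis=2)
        mx = x.max(axis=2)
        logits = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        n, c = logits.shape
        return x * logits.sigmoid().reshape(n, c, 1)


class TemporalAttention(nn.Module):
    """Gate over the temporal axis: channel-wise mean and max maps are
    convolved (width 7, same padding) into per-position weights."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        self.conv = nn.Conv1d(2, 1, kernel, rng, padding="same")

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return x * self.conv(nn.concat([avg, mx], axis=1)).sigmoid()


class SpatiotemporalAttention(nn.Module):
    """Channel attention followed by temporal attention (shape-preserving)."""

    def __init__(self, channels: int, reduction: int, kernel: int,
                 rng: np.random.Generator):
        self.channel = ChannelAttention(channels, reduction, rng)
        self.temporal = TemporalAttention(kernel, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.temporal(self.channel(x))

    def weights(self, x: nn.Tensor) -> tuple[np.ndarray, np.ndarray]:
        """The (channel, temporal) gate values for a given input."""
        avg, mx = x.mean(axis=2), x.max(axis=2)
        logits = (self.channel.fc2(self.channel.fc1(avg).relu())
                  + self.channel.fc2(self.channel.fc1(mx).relu()))
        cw = logits.sigmoid().data
        gated = x * nn.Tensor(cw[:, :, None])
        tmap = nn.concat([gated.mean(axis=1, keepdims=True),
                          gated.max(axis=1, keepdims=True)], axis=1)
        tw = self.temporal.conv(tmap).sigmoid().data
        return cw, tw


class ResidualBlock(nn.Module):
    """conv(s) -> BN -> ReLU -> dilated conv -> BN, residual add, ReLU.

    A stride-2 block downsamples the shortcut with average pooling
    (kernel 2, stride 2, ceil length); extra output channels are
    zero-padded onto the shortcut.
    """

    def __init__(self, cin: int, cout: int, stride: int, dilation: int,
                 cfg: EncoderConfig, rng: np.random.Generator):
        self.conv1 = nn.Conv1d(cin, cout, 3, rng, stride=stride, padding="same")
        self.bn1 = nn.BatchNorm1d(cout, cfg.bn_momentum, cfg.bn_eps)
        self.conv2 = nn.Conv1d(cout, cout, 3, rng, dilation=dilation,
                               padding="same")
        self.bn2 = nn.BatchNorm1d(cout, cfg.bn_momentum, cfg.bn_eps)
        self.stride, self.cin, self.cout = stride, cin, cout

    def shortcut(self, x: nn.Tensor) -> nn.Tensor:
        s = x
        if self.stride != 1:
            s = nn.avg_pool1d(s, kernel=2, stride=2)
        if self.cout != self.cin:
            s = nn.pad_channels(s, self.cout - self.cin)
        return s

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        return (y + self.shortcut(x)).relu()


class Encoder(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        # 3x3 valid kernel over the 3-row, 2-lead input == width-3 conv
        # over 6 interleaved channels (see preprocess.flatten_for_encoder)
        self.conv1 = nn.Conv1d(6, cfg.stem_filters, 3, rng, padding="valid")
        self.bn1 = nn.BatchNorm1d(cfg.stem_filters, cfg.bn_momentum, cfg.bn_eps)
        blocks, attns = [], []
        cin = cfg.stem_filters
        for cout, stride in zip(cfg.block_filters, cfg.block_strides):
            blocks.append(ResidualBlock(cin, cout, stride, cfg.dilation, cfg, rng))
            attns.append(SpatiotemporalAttention(
                cout, cfg.attention_reduction, cfg.attention_kernel, rng))
            cin = cout
        self.blocks = blocks
        self.attentions = attns

    @property
    def n_conv_layers(self) -> int:
        """Convolutions on the main path (stem + 2 per residual block)."""
        return 1 + 2 * len(self.blocks)

    @property
    def n_attention_modules(self) -> int:
        return len(self.attentions)

    def forward_with_intermediates(
        self, x: nn.Tensor
    ) -> tuple[nn.Tensor, dict[str, tuple[int, ...]]]:
        shapes: dict[str, tuple[int, ...]] = {}
        y = self.bn1(self.conv1(x)).relu()
        shapes["conv1"] = y.shape
        for i, (block, attn) in enumerate(zip(self.blocks, self.attentions), 1):
            y = attn(block(y))
            shapes[f"block{i}"] = y.shape
        h = y.mean(axis=2)
        shapes["features"] = h.shape
        return h, shapes

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.forward_with_intermediates(x)[0]


class AdversarialModel(nn.Module):
    """Encoder plus classifier (C classes) and adversary (S subjects) heads."""

    def __init__(self, n_subjects: int, cfg: EncoderConfig | None = None,
                 seed: int = 0, n_classes: int = N_CLASSES):
        if n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        self.cfg = cfg or EncoderConfig()
        self.n_subjects = n_subjects
        self.n_classes = n_classes
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(self.cfg, rng)
        feat = self.cfg.block_filters[-1]
        self.classifier_head = nn.Dense(feat, n_classes, rng)
        self.adversary_head = nn.Dense(feat, n_subjects, rng)

    # -- forward passes -----------------------------------------------------
    @staticmethod
    def _to_tensor(x: np.ndarray) -> nn.Tensor:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] == (3, BEAT_LENGTH, 2):
            x = flatten_for_encoder(x)
        if x.shape[1:] != (6, BEAT_LENGTH):
            raise ValueError(f"bad input shape {x.shape}")
        return nn.Tensor(x)

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Batch of inputs -> feature matrix (n, 64). Inference path:
        batch norm uses running statistics."""
        self.set_training(False)
        return self.encoder(self._to_tensor(x)).data

    def forward(self, x: np.ndarray, lambda_adv: float = 0.0
                ) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor]:
        """-> (h, class logits, adversary logits-through-gradient-reversal)."""
        h = self.encoder(self._to_tensor(x))
        class_logits = self.classifier_head(h)
        adv_logits = self.adversary_head(nn.grad_reverse(h, lambda_adv))
        return h, class_logits, adv_logits

    def classify(self, h: np.ndarray) -> np.ndarray:
        """Feature matrix -> class probabilities (softmax of affine map)."""
        logits = self.classifier_head(nn.Tensor(np.atleast_2d(h)))
        return nn.softmax(logits.data)

    def discriminate_subject(self, h: np.ndarray) -> np.ndarray:
        """Feature matrix -> subject-ID probabilities."""
        logits = self.adversary_head(nn.Tensor(np.atleast_2d(h)))
        return nn.softmax(logits.data)

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Predicted class codes for a batch of inputs (eval mode)."""
        self.set_training(False)
        x = np.asarray(x, dtype=np.float64)
        preds = []
        for i in range(0, len(x), batch_size):
            h = self.encode(x[i:i + batch_size])
            preds.append(np.argmax(self.classify(h), axis=1))
        return np.concatenate(preds) if preds else np.zeros(0, dtype=np.int64)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        self.set_training(False)
        x = np.asarray(x, dtype=np.float64)
        out = [self.classify(self.encode(x[i:i + batch_size]))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out) if out else np.zeros((0, self.n_classes))

    # -- state --------------------------------------------------------------
    def _bn_modules(self) -> list[nn.BatchNorm1d]:
        mods = [self.encoder.bn1]
        for b in self.encoder.blocks:
            mods += [b.bn1, b.bn2]
        return mods

    def state_arrays(self) -> list[np.ndarray]:
        arrs = [p.data for p in self.parameters()]
        for bn in self._bn_modules():
            arrs += [bn.running_mean, bn.running_var]
        return arrs

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        live = self.state_arrays()
        if len(live) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(live, state):
            if dst.shape != src.shape:
                raise ValueError(f"state shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src

    def save(self, path: str) -> None:
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "n_subjects": self.n_subjects,
            "n_classes": self.n_classes,
            "seed": self.seed,
            "config": asdict(self.cfg),
        }
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "AdversarialModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta["schema"] != CHECKPOINT_SCHEMA:
                raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
            cfg_d = dict(meta["config"])
            for key in ("block_filters", "block_strides"):
                cfg_d[key] = tuple(cfg_d[key])
            model = cls(meta["n_subjects"], EncoderConfig(**cfg_d),
                        seed=meta["seed"], n_classes=meta["n_classes"])
            state = [z[f"arr_{i}"] for i in range(len(model.state_arrays()))]
        model.set_state(state)
        model.set_training(False)
        return model
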