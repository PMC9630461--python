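"""UNet encoder-decoder with configurable convolution kind and dropout placement.

The contracting path has ``depth`` blocks of two 3x3 convolutions + ReLU
followed by 2x2 max pooling; channels double at each downsampling.  The
expansive path mirrors it with 2x2 up-convolutions that halve the channels and
skip concatenations.  Dropout sits right after the pooling layer (contracting)
and right after the up-convolution (expansive), and stays active during
Monte-Carlo sampling.  Convolutions use same padding, so the output label map
matches the input size; a final 1x1 convolution + softmax yields per-pixel
class probabilities.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ..errors import ConfigurationError, ShapeError
from .layers import (
    Conv2d,
    Dropout,
    Layer,
    MaxPool2x2,
    Param,
    ReLU,
    SeparableConv2d,
    UpConv2x2,
)

CONV_KINDS = ("conventional", "separable")
DROPOUT_PLACEMENTS = ("none", "contracting", "expansive", "both")


@dataclass
class ModelConfig:
    depth: int = 4
    base_channels: int = 16
    n_classes: int = 2
    in_channels: int = 3
    conv_kind: str = "conventional"
    dropout_placement: str = "both"
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigurationError("depth", "must be >= 1")
        if self.base_channels < 1:
            raise ConfigurationError("base_channels", "must be >= 1")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes", "must be >= 2")
        if self.conv_kind not in CONV_KINDS:
            raise ConfigurationError("conv_kind", f"must be one of {CONV_KINDS}")
        if self.dropout_placement not in DROPOUT_PLACEMENTS:
            raise ConfigurationError("dropout_placement", f"must be one of {DROPOUT_PLACEMENTS}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate", "must be in [0, 1)")


def _conv(kind: str, in_ch: int, out_ch: int, rng: np.random.Generator, name: str) -> Layer:
    if kind == "separable":
        return SeparableConv2d(in_ch, out_ch, 3, rng, name)
    return Conv2d(in_ch, out_ch, 3, rng, name)


class SegmentationModel:
    """A built UNet; ``forward`` maps NHWC images to NHWC softmax probabilities."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, base, kind = config.depth, config.base_channels, config.conv_kind
        ch = [base * 2 ** i for i in range(d + 1)]

        self.enc_convs: list[tuple[Layer, ReLU, Layer, ReLU]] = []
        self.pools: list[MaxPool2x2] = []
        self.enc_drops: list[Dropout | None] = []
        in_ch = config.in_channels
        use_c = config.dropout_placement in ("contracting", "both")
        use_e = config.dropout_placement in ("expansive", "both")
        for i in range(d):
            c1 = _conv(kind, in_ch, ch[i], rng, f"enc{i}.conv1")
            c2 = _conv(kind, ch[i], ch[i], rng, f"enc{i}.conv2")
            self.enc_convs.append((c1, ReLU(), c2, ReLU()))
            self.pools.append(MaxPool2x2())
            self.enc_drops.append(Dropout(config.dropout_rate) if use_c else None)
            in_ch = ch[i]

        self.bott = (
            _conv(kind, ch[d - 1], ch[d], rng, "bottleneck.conv1"), ReLU(),
            _conv(kind, ch[d], ch[d], rng, "bottleneck.conv2"), ReLU(),
        )

        self.upconvs: list[UpConv2x2] = []
        self.dec_drops: list[Dropout | None] = []
        self.dec_convs: list[tuple[Layer, ReLU, Layer, ReLU]] = []
        for i in reversed(range(d)):
            self.upconvs.append(UpConv2x2(ch[i + 1], ch[i], rng, f"dec{i}.upconv"))
            self.dec_drops.append(Dropout(config.dropout_rate) if use_e else None)
            c1 = _conv(kind, 2 * ch[i], ch[i], rng, f"dec{i}.conv1")
            c2 = _conv(kind, ch[i], ch[i], rng, f"dec{i}.conv2")
            self.dec_convs.append((c1, ReLU(), c2, ReLU()))

        self.head = Conv2d(ch[0], config.n_classes, 1, rng, "head")

    # ------------------------------------------------------------------ params
    def params(self) -> list[Param]:
        out: list[Param] = []
        for c1, _, c2, _ in self.enc_convs:
            out += c1.params() + c2.params()
        out += self.bott[0].params() + self.bott[2].params()
        for up, (c1, _, c2, _) in zip(self.upconvs, self.dec_convs):
            out += up.params() + c1.params() + c2.params()
        out += self.head.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]

    # ----------------------------------------------------------------- forward
    def _check_input(self, x: np.ndarray, pad: bool) -> tuple[np.ndarray, tuple[int, int]]:
        b, h, w, c = x.shape
        if c != self.config.in_channels:
            raise ShapeError(f"expected {self.config.in_channels} channels, got {c}")
        div = 2 ** self.config.depth
        if h % div or w % div:
            if not pad:
                raise ShapeError(
                    f"input spatial size ({h}, {w}) must be divisible by 2**depth = {div}; "
                    "pass pad=True to reflect-pad"
                )
            ph, pw = (-h) % div, (-w) % div
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="reflect")
        return x, (h, w)

    def forward(
        self,
        images: np.ndarray,
        stochastic: bool = False,
        rng: np.random.Generator | None = None,
        pad: bool = False,
    ) -> np.ndarray:
        """Softmax probabilities for a batch of NHWC images in [0,1].

        ``stochastic=True`` keeps the dropout layers active (MC mode); the
        dropout masks are drawn from ``rng``.
        """
        logits = self._forward_logits(np.asarray(images, dtype=np.float32), stochastic, rng, pad)
        return _softmax(logits).transpose(0, 2, 3, 1)

    def _forward_logits(
        self,
        images: np.ndarray,
        stochastic: bool,
        rng: np.random.Generator | None,
        pad: bool = False,
    ) -> np.ndarray:
        if stochastic and rng is None:
            rng = np.random.default_rng()
        drop_rng = rng if stochastic else None
        x, (h0, w0) = self._check_input(images, pad)
        h = np.ascontiguousarray(x.transpose(0, 3, 1, 2))

        self._skips: list[np.ndarray] = []
        for (c1, r1, c2, r2), pool, drop in zip(self.enc_convs, self.pools, self.enc_drops):
            h = r2.forward(c2.forward(r1.forward(c1.forward(h))))
            self._skips.append(h)
            h = pool.forward(h)
            if drop is not None:
                h = drop.forward(h, drop_rng)
        c1, r1, c2, r2 = self.bott
        h = r2.forward(c2.forward(r1.forward(c1.forward(h))))
        for up, drop, (c1, r1, c2, r2), skip in zip(
            self.upconvs, self.dec_drops, self.dec_convs, reversed(self._skips)
        ):
            h = up.forward(h)
            if drop is not None:
                h = drop.forward(h, drop_rng)
            h = np.concatenate([skip, h], axis=1)
            h = r2.forward(c2.forward(r1.forward(c1.forward(h))))
        logits = self.head.forward(h)
        return logits[:, :, :h0, :w0]

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the logits; accumulates into param grads."""
        dh = self.head.backward(dlogits)
        depth = len(self._skips)
        dskips: list[np.ndarray] = [None] * depth  # type: ignore[list-item]
        # decoder blocks run shallow->deep in backward (reverse of forward order)
        for j in reversed(range(depth)):
            up, drop = self.upconvs[j], self.dec_drops[j]
            c1, r1, c2, r2 = self.dec_convs[j]
            i = depth - 1 - j  # encoder level of this decoder block
            dh = c1.backward(r1.backward(c2.backward(r2.backward(dh))))
            n_skip = self._skips[i].shape[1]
            dskip, dh = dh[:, :n_skip], dh[:, n_skip:]
            dskips[i] = dskip
            if drop is not None:
                dh = drop.backward(dh)
            dh = up.backward(dh)
        c1, r1, c2, r2 = self.bott
        dh = c1.backward(r1.backward(c2.backward(r2.backward(dh))))
        for i in reversed(range(len(self.enc_convs))):
            ec1, er1, ec2, er2 = self.enc_convs[i]
            if self.enc_drops[i] is not None:
                dh = self.enc_drops[i].backward(dh)
            dh = self.pools[i].backward(dh)
            dh = dh + dskips[i]
            dh = ec1.backward(er1.backward(ec2.backward(er2.backward(dh))))
        self._skips = []

    # --------------------------------------------------------------- train step
    def loss_and_grad(
        self,
        images: np.ndarray,
        masks: np.ndarray,
        stochastic: bool = True,
        rng: np.random.Generator | None = None,
    ) -> float:
        """Pixel-wise cross-entropy loss; accumulates parameter gradients."""
        logits = self._forward_logits(np.asarray(images, dtype=np.float32), stochastic, rng)
        probs = _softmax(logits)
        b, c, h, w = probs.shape
        onehot = np.eye(c, dtype=np.float32)[masks].transpose(0, 3, 1, 2)
        eps = 1e-9
        loss = float(-(onehot * np.log(probs + eps)).sum() / (b * h * w))
        self.backward((probs - onehot) / np.float32(b * h * w))
        return loss

    def loss(self, images: np.ndarray, masks: np.ndarray) -> float:
        """Deterministic (dropout-off) cross-entropy loss, no gradients kept."""
        probs = self.forward(images, stochastic=False)
        c = probs.shape[-1]
        onehot = np.eye(c, dtype=np.float32)[masks]
        n = masks.size
        return float(-(onehot * np.log(probs + 1e-9)).sum() / n)

    def clone(self) -> "SegmentationModel":
        m = SegmentationModel(copy.deepcopy(self.config))
        m.load_state_dict(self.state_dict())
        return m


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(config: ModelConfig, seed: int = 0) -> SegmentationModel:
    """Build a UNet per the configuration with seeded He-normal initialization."""
    return SegmentationModel(config, seed=seed)


def parameter_count(config: ModelConfig) -> int:
    """Exact number of trainable scalars of the configured network."""
    return sum(p.value.size for p in SegmentationModel(config, seed=0).params())


def save_checkpoint(model: SegmentationModel, path: str | Path) -> Path:
    """Save weights (.npz) plus a JSON sidecar with the full ModelConfig."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2))
    return path


def load_checkpoint(path: str | Path) -> SegmentationModel:
    path = Path(path)
    config = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = SegmentationModel(config, seed=0)
    with np.load(path) as data:
        model.load_state_dict(dict(data))
    return model
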