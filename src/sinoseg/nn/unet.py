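"""U-Net encoder–decoder for sinogram-domain lesion segmentation.

Four encoder levels of [3x3 conv, batch-norm, ReLU] x2 with dropout and 2x2
max-pooling, a bottleneck double-conv, and a symmetric decoder of
[2x upsample, 3x3 conv] blocks with skip concatenation; a 1x1 convolution
with sigmoid produces the per-pixel lesion probability. Channel widths
double per level from ``base_channels``. Trained from scratch — no
pretrained weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    Dropout,
    MaxPool2,
    Param,
    ReLU,
    Sequential,
    Sigmoid,
    Upsample2,
)


@dataclass(frozen=True)
class UNetConfig:
    in_channels: int = 1
    depth: int = 4
    base_channels: int = 32
    dropout_p: float = 0.2
    upsample_mode: str = "nearest"
    input_size: int = 128

    def __post_init__(self) -> None:
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size must be divisible by 2^depth = {2**self.depth}"
            )
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.upsample_mode not in ("nearest", "bilinear"):
            raise ValueError("upsample_mode must be 'nearest' or 'bilinear'")


def _double_conv(cin: int, cout: int, p: float, rng, dtype) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, 3, rng, dtype),
        BatchNorm2d(cout, dtype=dtype),
        ReLU(),
        Conv2d(cout, cout, 3, rng, dtype),
        BatchNorm2d(cout, dtype=dtype),
        ReLU(),
        Dropout(p, rng),
    )


class UNet:
    def __init__(self, config: UNetConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self.rng = np.random.default_rng(seed)
        c, d, p = config.base_channels, config.depth, config.dropout_p
        rng = self.rng

        self.encoders: list[Sequential] = []
        cin = config.in_channels
        for lvl in range(d):
            self.encoders.append(_double_conv(cin, c * 2**lvl, p, rng, dtype))
            cin = c * 2**lvl
        self.pool = MaxPool2()
        self.bottleneck = _double_conv(c * 2 ** (d - 1), c * 2**d, p, rng, dtype)

        self.up = Upsample2(config.upsample_mode)
        self.up_convs: list[Sequential] = []
        self.dec_blocks: list[Sequential] = []
        for lvl in reversed(range(d)):
            ch = c * 2**lvl
            self.up_convs.append(
                Sequential(
                    Conv2d(ch * 2, ch, 3, rng, dtype),
                    BatchNorm2d(ch, dtype=dtype),
                    ReLU(),
                )
            )
            self.dec_blocks.append(_double_conv(ch * 2, ch, p, rng, dtype))
        self.head = Conv2d(c, 1, 1, rng, dtype)
        self.out_act = Sigmoid()

    # -- plumbing ----------------------------------------------------------
    def _modules(self):
        yield from self.encoders
        yield self.bottleneck
        yield from self.up_convs
        yield from self.dec_blocks
        yield self.head

    def params(self) -> list[Param]:
        return [p for m in self._modules() for p in m.params()]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 1, S, S) input in [0, 1] -> (N, 1, S, S) probabilities.

        Internally activations are channel-first (C, N, H, W); the public
        interface stays batch-first.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[2] != x.shape[3] or \
                x.shape[2] != self.config.input_size:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, "
                f"{self.config.input_size}, {self.config.input_size}) input"
            )
        x = np.ascontiguousarray(x.transpose(1, 0, 2, 3))
        self._pools: list[MaxPool2] = []
        skips = []
        for enc in self.encoders:
            x = enc.forward(x, train)
            skips.append(x)
            pool = MaxPool2()
            x = pool.forward(x, train)
            self._pools.append(pool)
        x = self.bottleneck.forward(x, train)
        self._ups: list[Upsample2] = []
        self._skip_channels: list[int] = []
        for upc, dec, skip in zip(self.up_convs, self.dec_blocks, reversed(skips)):
            up = Upsample2(self.config.upsample_mode)
            x = up.forward(x, train)
            self._ups.append(up)
            x = upc.forward(x, train)
            self._skip_channels.append(skip.shape[0])
            x = np.concatenate([skip, x], axis=0)
            x = dec.forward(x, train)
        x = self.head.forward(x, train)
        x = self.out_act.forward(x, train)
        return x.transpose(1, 0, 2, 3)

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probabilities) from a train-mode forward."""
        g = np.ascontiguousarray(
            dprob.astype(self.dtype).transpose(1, 0, 2, 3)
        )
        g = self.out_act.backward(g)
        g = self.head.backward(g)
        # decoder stage i consumed skips[d-1-i]; unwinding from the last
        # (shallowest) stage therefore yields skip grads in skips order
        skip_grads = []
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            g = self.dec_blocks[i].backward(g)
            cs = self._skip_channels[i]
            skip_grads.append(g[:cs])
            g = np.ascontiguousarray(g[cs:])
            g = self.up_convs[i].backward(g)
            g = self._ups[i].backward(g)
        g = self.bottleneck.backward(g)
        for i in range(len(self.encoders) - 1, -1, -1):
            g = self._pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.encoders[i].backward(g)

    # -- checkpointing -----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrs = [p.value for p in self.params()]
        for m in self._modules():
            for layer in m.layers if isinstance(m, Sequential) else [m]:
                if isinstance(layer, BatchNorm2d):
                    arrs += [layer.running_mean, layer.running_var]
        return arrs

    def save(self, path) -> None:
        cfg_json = json.dumps(asdict(self.config), sort_keys=True)
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(
            path,
            __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
            __config_hash__=np.frombuffer(
                hashlib.sha256(cfg_json.encode()).digest(), dtype=np.uint8
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path, seed: int = 0) -> "UNet":
        with np.load(path) as zf:
            cfg_json = bytes(zf["__config__"]).decode()
            stored_hash = bytes(zf["__config_hash__"])
            if hashlib.sha256(cfg_json.encode()).digest() != stored_hash:
                raise ValueError("checkpoint config hash mismatch")
            config = UNetConfig(**json.loads(cfg_json))
            model = cls(config)
            for i, target in enumerate(model.state_arrays()):
                target[...] = zf[f"arr_{i}"]
        return model

    def get_weights(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for target, w in zip(self.state_arrays(), weights):
            target[...] = w


def build_unet(config: UNetConfig, seed: int = 0, dtype=np.float32) -> UNet:
    """Construct a randomly initialized U-Net (He init, zero biases)."""
    return UNet(config, seed=seed, dtype=dtype)


def predict_mask(model: UNet, sino_input: np.ndarray, threshold: float = 0.5
                 ) -> np.ndarray:
    """Binary lesion mask for one normalized sinogram grid (eval mode)."""
    x = np.asarray(sino_input, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("sino_input must be a 2D grid")
    prob = model.forward(x[None, None], train=False)[0, 0]
    return (prob >= threshold).astype(np.uint8)
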