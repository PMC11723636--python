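"""The customized U-Net used by both cascade subnetworks.

Topology for ``depth`` pooling levels (``n_conv3 = 4*depth + 2``):
two 3x3 conv blocks per encoder level (each conv followed by ReLU then BN),
2x2 max pooling between levels, two bottleneck conv blocks, and per decoder
level a 2x nearest upsampling followed by a 3x3 conv block, concatenation
with the matching encoder skip, and one more 3x3 conv block.  The head is a
1x1 convolution followed by BN with no activation.  All convolutions are
bias-free with normally distributed initial weights.

The same architecture serves as K-Net (operating on k-space arrays) or I-Net
(operating on image arrays); the domain is a property of the surrounding
cascade, not of the network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .layers import BatchNorm2d, Conv2d, ConvBlock, MaxPool2, Upsample2

__all__ = ["UNetConfig", "UNet", "build_unet", "save_model", "load_model"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyper-parameters.

    ``n_conv3`` counts the 3x3 convolution layers (the 1x1 head is extra) and
    must equal ``4*depth + 2`` so the census distributes as ``2*depth``
    encoder + 2 bottleneck + ``2*depth`` decoder convolutions.
    """

    n_conv3: int = 10
    base_filters: int = 64
    depth: int = 2
    in_channels: int = 2
    out_channels: int = 2
    init_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_conv3 != 4 * self.depth + 2:
            raise ValueError(
                f"n_conv3 must equal 4*depth + 2 = {4 * self.depth + 2}, got {self.n_conv3}"
            )


class UNet:
    """Encoder-decoder with skip concatenations; see module docstring."""

    def __init__(self, config: UNetConfig):
        self.config = config
        self.dtype = np.float32  # activation dtype; float64 only for debugging
        rng = np.random.default_rng(config.seed)
        f, d, s = config.base_filters, config.depth, config.init_sigma

        self.enc: list[list[ConvBlock]] = []
        self.pools: list[MaxPool2] = []
        in_ch = config.in_channels
        for lvl in range(d):
            out_ch = f * 2 ** lvl
            self.enc.append([ConvBlock(in_ch, out_ch, rng, s),
                             ConvBlock(out_ch, out_ch, rng, s)])
            self.pools.append(MaxPool2())
            in_ch = out_ch
        bch = f * 2 ** d
        self.bott = [ConvBlock(in_ch, bch, rng, s), ConvBlock(bch, bch, rng, s)]

        self.ups: list[Upsample2] = []
        self.upconvs: list[ConvBlock] = []
        self.dec: list[ConvBlock] = []
        in_ch = bch
        for lvl in reversed(range(d)):
            skip_ch = f * 2 ** lvl
            self.ups.append(Upsample2())
            self.upconvs.append(ConvBlock(in_ch, skip_ch, rng, s))
            self.dec.append(ConvBlock(2 * skip_ch, skip_ch, rng, s))
            in_ch = skip_ch
        self.head = Conv2d(in_ch, config.out_channels, 1, rng, s)
        self.head_bn = BatchNorm2d(config.out_channels)

    # -- introspection -----------------------------------------------------
    def conv_census(self) -> dict[str, int]:
        """Count of 3x3 and 1x1 convolution layers."""
        n3 = 2 * len(self.enc) + len(self.bott) + len(self.upconvs) + len(self.dec)
        return {"conv3x3": n3, "conv1x1": 1}

    def _all_layers(self):
        for pair in self.enc:
            yield from pair
        yield from self.bott
        yield from self.upconvs
        yield from self.dec
        yield self.head
        yield self.head_bn

    def params(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())

    def get_weights(self) -> dict[str, np.ndarray]:
        """Snapshot of the full persistent state (weights and BN statistics)."""
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        state = self.state_arrays()
        for k, v in weights.items():
            state[k][...] = v

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All persistent arrays (weights plus BN running statistics)."""
        out = {}
        for i, (p, _) in enumerate(self.params()):
            out[f"param_{i}"] = p
        bns = [l.bn for l in self._all_layers() if isinstance(l, ConvBlock)]
        bns.append(self.head_bn)
        for i, bn in enumerate(bns):
            out[f"bn_{i}_mean"] = bn.run_mean
            out[f"bn_{i}_var"] = bn.run_var
        return out

    # -- execution ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"input must be (batch, {self.config.in_channels}, H, W), got {x.shape}"
            )
        div = 2 ** self.config.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by 2^depth = {div}"
            )
        skips = []
        h = x
        for lvl in range(self.config.depth):
            for blk in self.enc[lvl]:
                h = blk.forward(h, training)
            skips.append(h)
            h = self.pools[lvl].forward(h, training)
        for blk in self.bott:
            h = blk.forward(h, training)
        self._skip_ch = []
        for i, lvl in enumerate(reversed(range(self.config.depth))):
            h = self.ups[i].forward(h, training)
            h = self.upconvs[i].forward(h, training)
            skip = skips[lvl]
            self._skip_ch.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = self.dec[i].forward(h, training)
        h = self.head.forward(h, training)
        return self.head_bn.forward(h, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.head.backward(self.head_bn.backward(dy))
        dskips = [None] * self.config.depth
        for i, lvl in zip(reversed(range(len(self.dec))), range(self.config.depth)):
            dy = self.dec[i].backward(dy)
            sc = self._skip_ch[i]
            dskips[lvl], dy = dy[:, :sc], dy[:, sc:]
            dy = self.upconvs[i].backward(dy)
            dy = self.ups[i].backward(dy)
        for blk in reversed(self.bott):
            dy = blk.backward(dy)
        for lvl in reversed(range(self.config.depth)):
            dy = self.pools[lvl].backward(dy)
            dy = dy + dskips[lvl]
            for blk in reversed(self.enc[lvl]):
                dy = blk.backward(dy)
        return dy


def build_unet(config: UNetConfig) -> UNet:
    """Instantiate the customized U-Net for the given configuration."""
    return UNet(config)


def save_model(net: UNet, path: str | Path) -> None:
    """Save weights (npz) with a JSON sidecar recording the configuration."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **net.state_arrays())
    path.with_suffix(".json").write_text(json.dumps(asdict(net.config)))


def load_model(path: str | Path) -> UNet:
    path = Path(path)
    cfg = UNetConfig(**json.loads(path.with_suffix(".json").read_text()))
    net = UNet(cfg)
    data = np.load(path.with_suffix(".npz"))
    state = net.state_arrays()
    for key, arr in state.items():
        arr[...] = data[key]
    return net
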