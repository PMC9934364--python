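"""The CNN architecture family and its analytic parameter accounting.

Every model in the family is N repetitions of the same block — stride-1
"same" convolution with ReLU, 2x2 max pooling, dropout 0.2 — followed by a
flatten and a single linear dense layer with one neuron per target (4 by
default: scaled long axis, scaled short axis, cos 2a, sin 2a; 2 for the
axes-only variant).  An architecture is therefore fully described by the
ordered list of (n_filters, kernel_size) pairs of its convolutional blocks.

``count_params`` computes the trainable parameter count analytically; it is
guaranteed (and tested) to match the weight arrays of the built network
exactly.  The module also accounts for the transfer-learning reference
architecture: a frozen 16-conv/5-pool VGG19-style base with a trainable
dense-128 + dense-4 head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "ArchSpec",
    "ParamCount",
    "TransferArchSpec",
    "build_cnn",
    "count_params",
    "count_transfer_params",
]


@dataclass(frozen=True)
class ArchSpec:
    """One architecture: conv blocks plus the fixed head.

    ``blocks`` is an ordered list of (n_filters, kernel_size); kernel sizes
    must be odd and >= 3 and the input must survive one 2x2 pooling per block.
    """

    blocks: tuple
    dropout_rate: float = 0.2
    pool_size: int = 2
    input_size: int = 128
    n_outputs: int = 4
    n_channels: int = 1

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        if len(self.blocks) < 1:
            raise ValueError("need at least one convolutional block")
        for nf, k in self.blocks:
            if nf < 1:
                raise ValueError(f"n_filters must be >= 1, got {nf}")
            if k < 3 or k % 2 != 1:
                raise ValueError(f"kernel size must be odd and >= 3, got {k}")
        size = self.input_size
        for _ in self.blocks:
            if size % self.pool_size != 0:
                raise ValueError(
                    f"input size {self.input_size} not divisible by "
                    f"{self.pool_size}^{len(self.blocks)}"
                )
            size //= self.pool_size
        if size < 1:
            raise ValueError("too many poolings for the input size")

    @property
    def n_layers(self):
        return len(self.blocks)

    def final_spatial_size(self):
        return self.input_size // self.pool_size ** len(self.blocks)

    def flatten_size(self):
        return self.final_spatial_size() ** 2 * self.blocks[-1][0]

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None):
        d = dict(blocks=[list(b) for b in self.blocks], n_outputs=self.n_outputs,
                 input_size=self.input_size, n_channels=self.n_channels,
                 dropout_rate=self.dropout_rate, pool_size=self.pool_size)
        if path is None:
            return json.dumps(d)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, src):
        src = Path(src).read_text() if Path(str(src)).is_file() else str(src)
        d = json.loads(src)
        return cls(**{**d, "blocks": tuple(tuple(b) for b in d["blocks"])})


@dataclass(frozen=True)
class ParamCount:
    trainable: int
    total: int

    def __post_init__(self):
        if self.trainable > self.total:
            raise ValueError("trainable count exceeds total")


def count_params(arch: ArchSpec) -> ParamCount:
    """Analytic parameter count of the built network.

    Block i contributes ``n_i * (k_i^2 * c_{i-1} + 1)`` (weights + biases,
    with c_0 = input channels); the dense head contributes
    ``flatten * n_outputs + n_outputs``.  All parameters are trainable.
    """
    c_prev = arch.n_channels
    total = 0
    for nf, k in arch.blocks:
        total += nf * (k * k * c_prev + 1)
        c_prev = nf
    total += arch.flatten_size() * arch.n_outputs + arch.n_outputs
    return ParamCount(trainable=total, total=total)


def build_cnn(arch: ArchSpec, seed: int = 0, dtype=np.float32) -> nn.Network:
    """Instantiate a trainable network from an architecture spec."""
    rng = np.random.default_rng(seed)
    layers = []
    c_prev = arch.n_channels
    for nf, k in arch.blocks:
        layers.append(nn.Conv2D(c_prev, nf, k, rng, dtype=dtype))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool2())
        layers.append(nn.Dropout(arch.dropout_rate))
        c_prev = nf
    layers.append(nn.Flatten())
    layers.append(nn.Dense(arch.flatten_size(), arch.n_outputs, rng, dtype=dtype))
    return nn.Network(layers)


@dataclass(frozen=True)
class TransferArchSpec:
    """Topology of the frozen-base transfer architecture.

    The base is the 16-conv/5-pool VGG19 convolutional stack — channel blocks
    (2x64, 2x128, 4x256, 4x512, 4x512), all 3x3 kernels, a 2x2 pooling after
    each block — applied to a 128x128x3 input, frozen.  The trainable head is
    dense(128, ReLU) then dense(n_outputs, linear) on the flattened 4x4x512
    base output.
    """

    conv_blocks: tuple = ((64, 2), (128, 2), (256, 4), (512, 4), (512, 4))
    kernel_size: int = 3
    input_size: int = 128
    input_channels: int = 3
    head_units: int = 128
    n_outputs: int = 4

    def base_output_size(self):
        return self.input_size // 2 ** len(self.conv_blocks)


def count_transfer_params(spec: TransferArchSpec = TransferArchSpec()) -> ParamCount:
    """Frozen-base + trainable-head parameter accounting.

    The base convolutions are counted but not trainable; only the two head
    dense layers are.
    """
    c_prev = spec.input_channels
    frozen = 0
    for channels, repeats in spec.conv_blocks:
        for _ in range(repeats):
            frozen += channels * (spec.kernel_size**2 * c_prev + 1)
            c_prev = channels
    flat = spec.base_output_size() ** 2 * spec.conv_blocks[-1][0]
    head = flat * spec.head_units + spec.head_units
    head += spec.head_units * spec.n_outputs + spec.n_outputs
    return ParamCount(trainable=head, total=frozen + head)
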