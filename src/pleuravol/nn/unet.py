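"""2D U-Net: contracting path with doubling filter counts, expanding path
with bilinear upsampling and concatenation skip connections, sigmoid output.

Filter counts double per encoder level starting from ``base_filters``
(24, 48, ... at full scale); dropout follows each block of the descending
path; the decoder mirrors the encoder with two 3x3 convolutions per level
after each upsample+concat; a final 1x1 convolution maps to one logit per
pixel.
"""

from __future__ import annotations

import numpy as np

from .layers import BilinearUp2, Conv2d, Dropout, MaxPool2, ReLU

__all__ = ["UNet2D", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _ConvBlock:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.relu2 = ReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x, training=False):
        x = self.relu1.forward(self.conv1.forward(x, training), training)
        return self.relu2.forward(self.conv2.forward(x, training), training)

    def backward(self, g):
        g = self.conv2.backward(self.relu2.backward(g))
        return self.conv1.backward(self.relu1.backward(g))


class UNet2D:
    """U-Net over single-channel square images.

    Parameters
    ----------
    base_filters:
        Channels of the first encoder block; doubled at each deeper level.
    depth:
        Number of blocks on the descending path (including the bottleneck);
        the input side length must be divisible by ``2**(depth-1)``.
    dropout:
        Dropout rate applied after each descending-path block.
    seed:
        Seeds weight initialisation and the dropout stream.
    """

    def __init__(
        self,
        in_channels: int = 1,
        base_filters: int = 24,
        depth: int = 5,
        dropout: float = 0.5,
        seed: int = 0,
    ):
        if depth < 2:
            raise ValueError(f"depth must be >= 2, got {depth}")
        rng = np.random.default_rng(seed)
        self.rng = rng
        self.depth = depth
        self.channels = [base_filters * 2**i for i in range(depth)]
        n_enc = depth - 1
        self.enc = []
        cin = in_channels
        for i in range(n_enc):
            self.enc.append(
                dict(block=_ConvBlock(cin, self.channels[i], rng), drop=Dropout(dropout, rng), pool=MaxPool2())
            )
            cin = self.channels[i]
        self.bottleneck = _ConvBlock(cin, self.channels[-1], rng)
        self.bdrop = Dropout(dropout, rng)
        self.dec = []
        for i in reversed(range(n_enc)):
            self.dec.insert(
                0,
                dict(
                    up=BilinearUp2(),
                    block=_ConvBlock(self.channels[i] + self.channels[i + 1], self.channels[i], rng),
                ),
            )
        self.out_conv = Conv2d(self.channels[0], 1, 1, rng)
        self._logits = None

    # -- introspection ------------------------------------------------------

    @property
    def encoder_channels(self) -> list[int]:
        """Output channel count of each descending-path block, in order."""
        return self.channels[:-1] + [self.channels[-1]]

    def params(self):
        ps = []
        for lvl in self.enc:
            ps += lvl["block"].params()
        ps += self.bottleneck.params()
        for lvl in self.dec:
            ps += lvl["block"].params()
        ps += self.out_conv.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, arrays) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.value.shape} vs {a.shape}")
            p.value = np.asarray(a, dtype=np.float32).copy()
            p.grad = np.zeros_like(p.value)

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Probability map in [0, 1] for one (H, W) or (H, W, 1) image."""
        if x.ndim == 2:
            x = x[:, :, None]
        H, W, _ = x.shape
        stride = 2 ** (self.depth - 1)
        if H % stride or W % stride:
            raise ValueError(f"input size {(H, W)} not divisible by 2**(depth-1)={stride}")
        a = x.astype(np.float32)
        skips = []
        for lvl in self.enc:
            a = lvl["block"].forward(a, training)
            a = lvl["drop"].forward(a, training)
            skips.append(a)
            a = lvl["pool"].forward(a, training)
        a = self.bottleneck.forward(a, training)
        a = self.bdrop.forward(a, training)
        for i in reversed(range(len(self.dec))):
            a = self.dec[i]["up"].forward(a, training)
            a = np.concatenate([skips[i], a], axis=2)
            a = self.dec[i]["block"].forward(a, training)
        z = self.out_conv.forward(a, training)[:, :, 0]
        self._logits = z
        return sigmoid(z)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output logits."""
        g = self.out_conv.backward(dlogits[:, :, None].astype(np.float32))
        skip_grads = [None] * len(self.dec)
        for i in range(len(self.dec)):
            g = self.dec[i]["block"].backward(g)
            c_skip = self.channels[i]
            skip_grads[i] = g[:, :, :c_skip]
            g = self.dec[i]["up"].backward(g[:, :, c_skip:])
        g = self.bottleneck.backward(self.bdrop.backward(g))
        for i in reversed(range(len(self.enc))):
            g = self.enc[i]["pool"].backward(g) + skip_grads[i]
            g = self.enc[i]["drop"].backward(g)
            g = self.enc[i]["block"].backward(g)
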