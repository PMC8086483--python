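"""Network architectures for the two staining routes.

Supervised route (paired translation): a U-Net generator — 8 encoder /
8 decoder blocks at full scale, kernel 4, stride 2, LeakyReLU(0.2) encoder,
ReLU + 50% dropout decoder, skip connections, tanh output — against a
PatchGAN discriminator (filters 64/128/256/512, 16×16 sigmoid map on a
256×256 input in the default stride layout).

Unsupervised route (unpaired translation): ResNet generators
(c7s1-64, d128, d256, 6 residual blocks, u128, u64, c7s1-3, instance
normalization, tanh output) with discriminators of the same PatchGAN family.

The published description of the discriminator is internally inconsistent:
a 16×16 output map on a 256×256 input forces four stride-2 convolutions,
whose receptive field is 94, while the stated 70-pixel receptive field
requires the canonical three-stride-2 layout whose map is larger.  Both are
provided: ``paper_strides`` (default, honors the 16×16 map) and ``rf70``
(honors the 70×70 receptive field); :func:`compute_receptive_field` and
:func:`empirical_receptive_field` verify either analytically and by a
gradient-footprint probe.

A ``scale`` factor on every spec divides the filter counts (with a
correspondingly shallower U-Net for smaller inputs), giving a reduced
profile that trains in minutes on one CPU while obeying the same
architectural rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .nn import (
    Concat,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    LeakyReLU,
    Param,
    ReLU,
    Sequential,
    Sigmoid,
    SpatialNorm,
    Tanh,
)

__all__ = [
    "GeneratorSpecUNet",
    "DiscriminatorSpecPatchGAN",
    "GeneratorSpecResNet",
    "UNetGenerator",
    "PatchGANDiscriminator",
    "ResNetGenerator",
    "build_unet_generator",
    "build_patchgan_discriminator",
    "build_resnet_generator",
    "compute_receptive_field",
    "empirical_receptive_field",
    "init_weights",
    "aggregate_map",
]

FULL_ENCODER_FILTERS = (64, 128, 256, 512, 512, 512, 512, 512)
FULL_DISC_FILTERS = (64, 128, 256, 512)
FULL_RESNET_FILTERS = (64, 128, 256)


def _scaled(filters: Sequence[int], scale: int) -> Tuple[int, ...]:
    return tuple(max(1, f // scale) for f in filters)


@dataclass
class GeneratorSpecUNet:
    encoder_filters: Tuple[int, ...] = FULL_ENCODER_FILTERS
    kernel: int = 4
    stride: int = 2
    leaky_slope: float = 0.2
    dropout_rate: float = 0.5
    in_channels: int = 3
    output_channels: int = 3

    @classmethod
    def reduced(cls, scale: int = 8, depth: int = 6) -> "GeneratorSpecUNet":
        """CPU test profile: filters divided by ``scale``, ``depth`` blocks
        (a 64×64 input needs a 6-deep encoder to reach a 1×1 bottleneck)."""
        return cls(encoder_filters=_scaled(FULL_ENCODER_FILTERS[:depth], scale))

    @property
    def depth(self) -> int:
        return len(self.encoder_filters)

    @property
    def decoder_filters_post_concat(self) -> Tuple[int, ...]:
        f = self.encoder_filters
        d = self.depth
        return (f[d - 1],) + tuple(2 * f[d - 2 - j] for j in range(d - 1))


@dataclass
class DiscriminatorSpecPatchGAN:
    conv_filters: Tuple[int, ...] = FULL_DISC_FILTERS
    kernel: int = 4
    leaky_slope: float = 0.2
    variant: str = "paper_strides"  # or "rf70"
    in_channels: int = 3

    def __post_init__(self) -> None:
        if self.variant not in ("paper_strides", "rf70"):
            raise ValueError(f"unknown discriminator variant {self.variant!r}")

    @classmethod
    def reduced(cls, scale: int = 8, variant: str = "paper_strides") -> "DiscriminatorSpecPatchGAN":
        return cls(conv_filters=_scaled(FULL_DISC_FILTERS, scale), variant=variant)

    @property
    def strides(self) -> Tuple[int, ...]:
        return (2, 2, 2, 2) if self.variant == "paper_strides" else (2, 2, 2, 1)

    @property
    def layer_stack(self) -> List[Tuple[int, int]]:
        """(kernel, stride) of every conv, input-to-output, incl. final k4/s1."""
        return [(self.kernel, s) for s in self.strides] + [(self.kernel, 1)]


@dataclass
class GeneratorSpecResNet:
    base_filters: Tuple[int, ...] = FULL_RESNET_FILTERS  # c7s1-k, d-k, d-k
    n_res_blocks: int = 6
    in_channels: int = 3
    output_channels: int = 3

    @classmethod
    def reduced(cls, scale: int = 8) -> "GeneratorSpecResNet":
        return cls(base_filters=_scaled(FULL_RESNET_FILTERS, scale))


class _Net:
    """Common parameter bookkeeping for the hand-rolled networks."""

    def params(self) -> List[Param]:  # pragma: no cover - overridden
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict) -> None:
        ps = self.params()
        if len(state) != len(ps):
            raise ValueError("state does not match network parameterization")
        for i, p in enumerate(ps):
            arr = np.asarray(state[f"p{i}"], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p.data = arr.copy()

    def copy_state(self) -> dict:
        return self.state_dict()


class UNetGenerator(_Net):
    """Encoder/decoder with skip connections mapping [-1,1] RGB to [-1,1] RGB.

    Normalization is omitted on the first encoder block, the bottleneck and
    the first decoder block; all decoder blocks carry 50% dropout (active in
    training mode only).
    """

    def __init__(self, spec: Optional[GeneratorSpecUNet] = None, dropout_rng: Optional[np.random.Generator] = None):
        self.spec = spec or GeneratorSpecUNet()
        s = self.spec
        d = s.depth
        rng = dropout_rng if dropout_rng is not None else np.random.default_rng(0)
        self._dropouts: List[Dropout] = []

        self.enc_convs: List[Conv2d] = []
        self.enc_norms: List[Optional[SpatialNorm]] = []
        cin = s.in_channels
        for i, f in enumerate(s.encoder_filters):
            self.enc_convs.append(Conv2d(cin, f, s.kernel, s.stride, name=f"enc{i}"))
            self.enc_norms.append(SpatialNorm(f, name=f"enc{i}.norm") if 0 < i < d - 1 else None)
            cin = f

        self.dec_convs: List[ConvTranspose2d] = []
        self.dec_norms: List[Optional[SpatialNorm]] = []
        cin = s.encoder_filters[d - 1]
        for j in range(d - 1):
            fout = s.encoder_filters[d - 2 - j]
            self.dec_convs.append(ConvTranspose2d(cin, fout, s.kernel, s.stride, name=f"dec{j}"))
            self.dec_norms.append(SpatialNorm(fout, name=f"dec{j}.norm") if j > 0 else None)
            drop = Dropout(s.dropout_rate, rng)
            self._dropouts.append(drop)
            cin = 2 * fout  # after skip concatenation

        self.out_conv = ConvTranspose2d(cin, s.output_channels, s.kernel, s.stride, name="out")
        self.act_enc = LeakyReLU(s.leaky_slope)
        self.tanh = Tanh()
        self._cache = None

    def seed_dropout(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for dr in self._dropouts:
            dr.rng = rng

    def params(self) -> List[Param]:
        out: List[Param] = []
        for conv, norm in zip(self.enc_convs, self.enc_norms):
            out.extend(conv.params())
            if norm:
                out.extend(norm.params())
        for conv, norm in zip(self.dec_convs, self.dec_norms):
            out.extend(conv.params())
            if norm:
                out.extend(norm.params())
        out.extend(self.out_conv.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        s = self.spec
        d = s.depth
        h, w = x.shape[1:]
        if h % (2**d) or w % (2**d):
            raise ValueError(f"input spatial size must be divisible by 2^{d}")
        slope = s.leaky_slope
        enc_acts: List[np.ndarray] = []
        enc_masks: List[np.ndarray] = []
        a = x
        for conv, norm in zip(self.enc_convs, self.enc_norms):
            a = conv.forward(a, train)
            if norm:
                a = norm.forward(a, train)
            mask = a >= 0
            enc_masks.append(mask)
            a = np.where(mask, a, slope * a)
            enc_acts.append(a)

        dec_masks: List[np.ndarray] = []
        g = enc_acts[-1]
        for j, (conv, norm, drop) in enumerate(zip(self.dec_convs, self.dec_norms, self._dropouts)):
            g = conv.forward(g, train)
            if norm:
                g = norm.forward(g, train)
            g = drop.forward(g, train)
            mask = g >= 0
            dec_masks.append(mask)
            g = np.where(mask, g, 0.0)  # ReLU
            g = Concat.forward(g, enc_acts[self.spec.depth - 2 - j])
        y = self.tanh.forward(self.out_conv.forward(g, train), train)
        self._cache = (enc_masks, dec_masks)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self.spec
        d = s.depth
        enc_masks, dec_masks = self._cache
        slope = s.leaky_slope
        dg = self.out_conv.backward(self.tanh.backward(dy))
        skip_grads: List[Optional[np.ndarray]] = [None] * d
        for j in reversed(range(d - 1)):
            fout = self.dec_convs[j].cout
            dg_dec, dg_skip = Concat.backward(dg, fout)
            tgt = d - 2 - j
            skip_grads[tgt] = dg_skip if skip_grads[tgt] is None else skip_grads[tgt] + dg_skip
            dg_dec = np.where(dec_masks[j], dg_dec, 0.0)
            dg_dec = self._dropouts[j].backward(dg_dec)
            if self.dec_norms[j]:
                dg_dec = self.dec_norms[j].backward(dg_dec)
            dg = self.dec_convs[j].backward(dg_dec)
        # dg is now the gradient at the bottleneck (encoder block d-1 output)
        for i in reversed(range(d)):
            if skip_grads[i] is not None:
                dg = dg + skip_grads[i]
            dg = np.where(enc_masks[i], dg, slope * dg)
            if self.enc_norms[i]:
                dg = self.enc_norms[i].backward(dg)
            dg = self.enc_convs[i].backward(dg)
        return dg


class PatchGANDiscriminator(_Net):
    """Convolutional patch classifier emitting a sigmoid probability map."""

    def __init__(self, spec: Optional[DiscriminatorSpecPatchGAN] = None):
        self.spec = spec or DiscriminatorSpecPatchGAN()
        s = self.spec
        layers: List = []
        cin = s.in_channels
        for i, (f, st) in enumerate(zip(s.conv_filters, s.strides)):
            layers.append(Conv2d(cin, f, s.kernel, st, name=f"d{i}"))
            if i > 0:
                layers.append(SpatialNorm(f, name=f"d{i}.norm"))
            layers.append(LeakyReLU(s.leaky_slope))
            cin = f
        layers.append(Conv2d(cin, 1, s.kernel, 1, name="d_out"))
        layers.append(Sigmoid())
        self.net = Sequential(*layers)

    def params(self) -> List[Param]:
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.net.forward(x, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)


class _ResBlock:
    """conv-norm-relu-conv-norm with an additive identity skip."""

    def __init__(self, c: int, name: str):
        self.conv1 = Conv2d(c, c, 3, 1, name=f"{name}.c1")
        self.n1 = SpatialNorm(c, name=f"{name}.n1")
        self.relu = ReLU()
        self.conv2 = Conv2d(c, c, 3, 1, name=f"{name}.c2")
        self.n2 = SpatialNorm(c, name=f"{name}.n2")

    def params(self) -> List[Param]:
        return self.conv1.params() + self.n1.params() + self.conv2.params() + self.n2.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.relu.forward(self.n1.forward(self.conv1.forward(x, train), train), train)
        return x + self.n2.forward(self.conv2.forward(h, train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.conv1.backward(self.n1.backward(self.relu.backward(self.conv2.backward(self.n2.backward(dy)))))
        return dy + dh


class ResNetGenerator(_Net):
    """c7s1-k / d / d / R×n / u / u / c7s1-3 translation generator."""

    def __init__(self, spec: Optional[GeneratorSpecResNet] = None):
        self.spec = spec or GeneratorSpecResNet()
        f0, f1, f2 = self.spec.base_filters
        s = self.spec
        self.head = Sequential(
            Conv2d(s.in_channels, f0, 7, 1, name="c7s1_in"),
            SpatialNorm(f0, name="c7_in.norm"),
            ReLU(),
            Conv2d(f0, f1, 3, 2, name="down1"),
            SpatialNorm(f1, name="down1.norm"),
            ReLU(),
            Conv2d(f1, f2, 3, 2, name="down2"),
            SpatialNorm(f2, name="down2.norm"),
            ReLU(),
        )
        self.blocks = [_ResBlock(f2, f"res{i}") for i in range(s.n_res_blocks)]
        self.tail = Sequential(
            ConvTranspose2d(f2, f1, 3, 2, name="up1"),
            SpatialNorm(f1, name="up1.norm"),
            ReLU(),
            ConvTranspose2d(f1, f0, 3, 2, name="up2"),
            SpatialNorm(f0, name="up2.norm"),
            ReLU(),
            Conv2d(f0, s.output_channels, 7, 1, name="c7s1_out"),
            Tanh(),
        )

    def params(self) -> List[Param]:
        out = self.head.params()
        for b in self.blocks:
            out.extend(b.params())
        out.extend(self.tail.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.head.forward(x, train)
        for b in self.blocks:
            h = b.forward(h, train)
        return self.tail.forward(h, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.tail.backward(dy)
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        return self.head.backward(dh)


def build_unet_generator(spec: Optional[GeneratorSpecUNet] = None) -> UNetGenerator:
    return UNetGenerator(spec)


def build_patchgan_discriminator(spec: Optional[DiscriminatorSpecPatchGAN] = None) -> PatchGANDiscriminator:
    return PatchGANDiscriminator(spec)


def build_resnet_generator(spec: Optional[GeneratorSpecResNet] = None) -> ResNetGenerator:
    return ResNetGenerator(spec)


def compute_receptive_field(layer_stack: Sequence[Tuple[int, int]]) -> int:
    """Receptive field of a conv stack given (kernel, stride) input-to-output.

    Standard backward recursion from a single output unit:
    ``r <- (r - 1) * s + k`` applied output-to-input, starting at ``r = 1``.
    """
    if not layer_stack:
        raise ValueError("empty layer stack")
    r = 1
    for k, s in reversed(list(layer_stack)):
        r = (r - 1) * s + k
    return r


def aggregate_map(prob_map: np.ndarray) -> float:
    """Combine the discriminator's sigmoid map into one probability (mean)."""
    return float(np.mean(prob_map))


def empirical_receptive_field(disc: PatchGANDiscriminator, input_size: int = 128, seed: int = 0) -> int:
    """Measure the receptive field by a gradient-footprint probe.

    Backpropagates from the single most central output unit and returns the
    width of the bounding box of nonzero input gradient, which for an
    interior unit equals the analytic receptive field.  Normalization
    statistics are frozen during the probe — their spatial coupling would
    otherwise spread gradient over the whole input and hide the
    convolutional footprint being measured.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1, 1, size=(disc.spec.in_channels, input_size, input_size)).astype(np.float32)
    norms = [l for l in disc.net.layers if isinstance(l, SpatialNorm)]
    y = disc.forward(x, train=True)
    dy = np.zeros_like(y)
    _, oh, ow = y.shape
    dy[0, oh // 2, ow // 2] = 1.0
    disc.zero_grad()
    for l in norms:
        l.detach_stats = True
    try:
        dx = disc.backward(dy)
    finally:
        for l in norms:
            l.detach_stats = False
    foot = np.abs(dx).sum(axis=0) > 0
    rows = np.nonzero(foot.any(axis=1))[0]
    cols = np.nonzero(foot.any(axis=0))[0]
    return int(max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1))


def init_weights(net: _Net, sigma: float = 0.02, seed: int = 0) -> _Net:
    """Gaussian N(0, sigma²) init of all conv kernels (norm gains N(1, sigma²),
    biases zero); identical seed gives bit-identical parameters."""
    rng = np.random.default_rng(seed)
    for p in net.params():
        if p.data.ndim == 4:  # conv / transposed-conv kernels
            p.data = rng.normal(0.0, sigma, p.data.shape).astype(np.float32)
        elif p.name.endswith(".gamma"):
            p.data = rng.normal(1.0, sigma, p.data.shape).astype(np.float32)
        else:
            p.data = np.zeros_like(p.data)
    return net
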