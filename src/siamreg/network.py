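"""The cross-scale Siamese U-Net.

Two weight-shared convolutional encoders digest the fixed and the moving
input (image, optionally concatenated with its anatomical label, as a
second channel).  Because the weights are shared, both branches measure
features on the same scale; because the net is fully convolutional, the
branches accept different grid extents.  At every resolution level the
moving branch's feature grids are zero-padded out to the fixed branch's
extents (see :mod:`siamreg.padding`), after which a single decoder with
skip connections from *both* branches up-samples back to the fixed grid
and a final convolution reduces to 3 channels: the dense displacement
vector field, in voxel units, on the fixed grid.

Encoder recipe: a 7x7x7 first convolution (large receptive field), then
per level two 3x3x3 convolutions followed by 2x2x2 max-pooling; channel
counts start at ``base_channels`` and double per level.  The decoder
mirrors this with nearest-neighbour up-sampling + 3x3x3 convolutions.  The
final layer is zero-initialized so an untrained network emits the identity
transform.  All convolutions are same-padded (edge zero-value), so extents
only change at pool/up-sample steps; every input extent must be divisible
by ``pool ** levels``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .core_volumes import LabelMap, ValidationError, Volume
from .padding import compute_pad_spec, pad_features
from .transform import DisplacementField

__all__ = ["NetworkConfig", "SiameseUNet", "build_network", "forward"]


@dataclass
class NetworkConfig:
    levels: int = 3
    base_channels: int = 16
    first_kernel: int = 7
    inner_kernel: int = 3
    pool: int = 2
    use_label_channels: bool = True
    pad_mode: str = "symmetric"
    activation: str = "leaky_relu"  # leaky_relu | relu
    dtype: str = "float32"

    def __post_init__(self):
        if self.levels < 1:
            raise ValidationError(f"levels must be >= 1, got {self.levels}")
        if self.base_channels < 1:
            raise ValidationError("base_channels must be >= 1")
        if self.first_kernel % 2 == 0 or self.inner_kernel % 2 == 0:
            raise ValidationError("kernel extents must be odd")
        if self.pool != 2:
            raise ValidationError("only 2x2x2 pooling is supported")
        if self.activation not in ("leaky_relu", "relu"):
            raise ValidationError(f"unknown activation {self.activation!r}")

    @property
    def in_channels(self) -> int:
        return 2 if self.use_label_channels else 1

    @property
    def divisor(self) -> int:
        return self.pool**self.levels


def _he_init(rng, shape, fan_in, dtype):
    return Tensor(
        (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype),
        requires_grad=True,
    )


class SiameseUNet:
    """Parameter container plus the forward pass.

    Parameters live in ``self.params`` (an ordered name -> Tensor mapping);
    both encoder branches reference the same tensors, so gradients from
    either branch accumulate into one weight set.
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        dtype = np.dtype(cfg.dtype).type
        k1, k3 = cfg.first_kernel, cfg.inner_kernel

        def conv(name, c_in, c_out, k):
            self.params[f"{name}.w"] = _he_init(
                rng, (c_out, c_in, k, k, k), c_in * k**3, dtype
            )
            self.params[f"{name}.b"] = Tensor(
                np.zeros(c_out, dtype=dtype), requires_grad=True
            )

        c = cfg.base_channels
        conv("enc.first", cfg.in_channels, c, k1)
        for lvl in range(cfg.levels):
            ch = c * 2**lvl
            prev = c * 2 ** max(lvl - 1, 0) if lvl else c
            conv(f"enc.l{lvl}.c0", prev, ch, k3)
            conv(f"enc.l{lvl}.c1", ch, ch, k3)
        bott = c * 2**cfg.levels
        conv("enc.bott.c0", c * 2 ** (cfg.levels - 1), bott, k3)
        conv("enc.bott.c1", bott, bott, k3)
        # decoder: at level lvl the up-sampled stream concatenates with the
        # fixed-branch and (padded) moving-branch skips of that level
        up_in = 2 * bott  # fused bottlenecks of the two branches
        for lvl in reversed(range(cfg.levels)):
            ch = c * 2**lvl
            conv(f"dec.l{lvl}.c0", up_in + 2 * ch, ch, k3)
            conv(f"dec.l{lvl}.c1", ch, ch, k3)
            up_in = ch
        conv("dec.final", up_in, 3, k3)
        # zero-init the output layer: the initial transform is the identity
        self.params["dec.final.w"].data[:] = 0.0
        self.params["dec.final.b"].data[:] = 0.0

    # -- plumbing ---------------------------------------------------------
    def parameters(self):
        return list(self.params.values())

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def _conv(self, name, x, activate=True):
        y = ad.conv3d(x, self.params[f"{name}.w"], self.params[f"{name}.b"])
        if not activate:
            return y
        if self.cfg.activation == "relu":
            return ad.relu(y)
        return ad.leaky_relu(y)

    # -- the two stages ---------------------------------------------------
    def encode(self, x: Tensor):
        """Shared-weight encoder: returns per-level skip features and the
        bottleneck."""
        cfg = self.cfg
        x = self._conv("enc.first", x)
        skips = []
        for lvl in range(cfg.levels):
            x = self._conv(f"enc.l{lvl}.c0", x)
            x = self._conv(f"enc.l{lvl}.c1", x)
            skips.append(x)
            x = ad.maxpool3d(x)
        x = self._conv("enc.bott.c0", x)
        x = self._conv("enc.bott.c1", x)
        return skips, x

    def decode(self, fused: Tensor, skips_f, skips_m_padded) -> Tensor:
        cfg = self.cfg
        x = fused
        for lvl in reversed(range(cfg.levels)):
            x = ad.upsample_nearest3d(x, cfg.pool)
            x = ad.concat_channels([x, skips_f[lvl], skips_m_padded[lvl]])
            x = self._conv(f"dec.l{lvl}.c0", x)
            x = self._conv(f"dec.l{lvl}.c1", x)
        return self._conv("dec.final", x, activate=False)

    # -- forward ----------------------------------------------------------
    def _check_extents(self, fixed_ext, moving_ext):
        div = self.cfg.divisor
        for name, ext in (("fixed", fixed_ext), ("moving", moving_ext)):
            for axis, e in enumerate(ext):
                if e % div:
                    raise ValidationError(
                        f"{name} extent {e} on axis {axis} is not divisible by "
                        f"pool**levels = {div}"
                    )
        for axis, (fe, me) in enumerate(zip(fixed_ext, moving_ext)):
            if me > fe:
                raise ValidationError(
                    f"moving extent {me} exceeds fixed extent {fe} on axis {axis}; "
                    "the fixed branch must carry the larger-or-equal grid"
                )

    def forward_tensor(self, fixed_in: np.ndarray, moving_in: np.ndarray) -> Tensor:
        """Run the network on prepared (C, D, H, W) input stacks and return
        the displacement field as a Tensor on the tape."""
        self._check_extents(fixed_in.shape[1:], moving_in.shape[1:])
        dtype = np.dtype(self.cfg.dtype).type
        skips_f, bott_f = self.encode(Tensor(fixed_in.astype(dtype)))
        skips_m, bott_m = self.encode(Tensor(moving_in.astype(dtype)))
        # align the moving branch to the fixed branch at feature scale
        mode = self.cfg.pad_mode
        bott_m = pad_features(
            bott_m, compute_pad_spec(bott_m.shape[1:], bott_f.shape[1:], mode)
        )
        skips_m_padded = [
            pad_features(sm, compute_pad_spec(sm.shape[1:], sf.shape[1:], mode))
            for sm, sf in zip(skips_m, skips_f)
        ]
        fused = ad.concat_channels([bott_f, bott_m])
        return self.decode(fused, skips_f, skips_m_padded)


def build_network(cfg: NetworkConfig | None = None, seed: int = 0) -> SiameseUNet:
    """Construct a Siamese U-Net with freshly initialized shared weights."""
    return SiameseUNet(cfg or NetworkConfig(), seed=seed)


def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img, dtype=np.float64)
    return (img - lo) / (hi - lo)


def prepare_input(vol: Volume, label: LabelMap | None, cfg: NetworkConfig) -> np.ndarray:
    """Stack a (min-max normalized) image and, when configured, its label
    into the network's (C, D, H, W) input layout."""
    channels = [_normalize(vol.data)]
    if cfg.use_label_channels:
        if label is None:
            raise ValidationError(
                "network configured with label input channels but no label given"
            )
        channels.append(np.asarray(label.data, dtype=np.float64))
    return np.stack(channels)


def forward(
    net: SiameseUNet,
    fixed: Volume,
    moving: Volume,
    fixed_label: LabelMap | None = None,
    moving_label: LabelMap | None = None,
) -> DisplacementField:
    """Predict the dense displacement field aligning ``moving`` onto the
    fixed grid.  Output extents always equal the fixed volume's extents."""
    fin = prepare_input(fixed, fixed_label, net.cfg)
    min_ = prepare_input(moving, moving_label, net.cfg)
    dvf_t = net.forward_tensor(fin, min_)
    return DisplacementField(
        np.asarray(dvf_t.data, dtype=np.float64), fixed.spacing.copy(), fixed.origin.copy()
    )
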