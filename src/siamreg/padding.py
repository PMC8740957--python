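"""Cross-scale feature alignment by zero-value padding.

When the fixed and moving inputs have different grid extents, the two
weight-shared encoder branches emit feature grids of different spatial
sizes at every level.  Before decoder fusion, the smaller (moving-branch)
features are zero-padded out to the fixed-branch extents.  Padding happens
strictly at feature scale, between encoder and decoder — padding the raw
input would contaminate the low-level features of the original image.

Two placement dialects exist per axis: ``symmetric`` splits the extent
difference across both edges (an odd difference puts the extra cell on the
trailing edge), while ``leading``/``trailing`` put the whole difference on
one edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, pad_spatial
from .core_volumes import ValidationError

__all__ = ["PadSpec", "compute_pad_spec", "pad_features"]

_MODES = ("symmetric", "leading", "trailing")


@dataclass(frozen=True)
class PadSpec:
    """Per-axis (before, after) pad amounts in feature-grid cells."""

    pads: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self):
        for before, after in self.pads:
            if before < 0 or after < 0:
                raise ValidationError(f"negative pad amounts in {self.pads}")

    @property
    def is_zero(self) -> bool:
        return all(b == 0 and a == 0 for b, a in self.pads)

    def compose(self, other: "PadSpec") -> "PadSpec":
        return PadSpec(
            tuple(
                (b1 + b2, a1 + a2)
                for (b1, a1), (b2, a2) in zip(self.pads, other.pads)
            )
        )


def compute_pad_spec(source_extents, target_extents, mode="symmetric") -> PadSpec:
    """Pad amounts taking ``source_extents`` to ``target_extents``.

    ``mode`` is a single dialect or a per-axis triple of dialects.  Padding
    never crops: a target smaller than the source on any axis is an error.
    """
    src = tuple(int(s) for s in source_extents)
    tgt = tuple(int(t) for t in target_extents)
    if len(src) != 3 or len(tgt) != 3:
        raise ValidationError("extents must be triples")
    modes = (mode,) * 3 if isinstance(mode, str) else tuple(mode)
    if len(modes) != 3 or any(m not in _MODES for m in modes):
        raise ValidationError(f"pad mode must be one of {_MODES} per axis, got {mode}")
    pads = []
    for axis, (s, t, m) in enumerate(zip(src, tgt, modes)):
        diff = t - s
        if diff < 0:
            raise ValidationError(
                f"target extent {t} < source extent {s} on axis {axis}; "
                "padding never crops"
            )
        if m == "symmetric":
            before = diff // 2
            pads.append((before, diff - before))  # odd diff: extra on trailing edge
        elif m == "leading":
            pads.append((diff, 0))
        else:
            pads.append((0, diff))
    return PadSpec(tuple(pads))


def pad_features(f, spec: PadSpec):
    """Zero-pad a feature grid (``(C, D, H, W)`` array or Tensor) spatially.

    Original values keep their relative positions (shifted by the leading
    pads); new cells are exactly zero; the channel count is unchanged.
    """
    if isinstance(f, Tensor):
        return pad_spatial(f, spec.pads)
    f = np.asarray(f)
    if f.ndim == 3:
        return np.pad(f, spec.pads)
    if f.ndim == 4:
        return np.pad(f, ((0, 0),) + spec.pads)
    raise ValidationError(f"feature grid must be 3-D or 4-D, got shape {f.shape}")
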