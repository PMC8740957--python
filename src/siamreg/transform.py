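"""Applying displacement fields: warping volumes/labels and transporting
landmarks.

A displacement field ``u`` lives on the fixed grid in voxel units; the
transform is backward-mapping, ``T(x) = x + u(x)``: output voxel ``x`` of a
warp takes the moving image's value at ``x + u(x)``.  The moving grid may
have different extents (the cross-scale case); sampling coordinates are
simply interpreted on the moving grid.  Out-of-bounds policy defaults to
border-clamp for images (avoids dark rims) and zero for labels
(anatomy outside the field of view is genuinely absent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .autodiff import trilinear_sample
from .core_volumes import LabelMap, LandmarkSet, Landmark, ValidationError, Volume

__all__ = [
    "DisplacementField",
    "identity_dvf",
    "warp",
    "transport_landmarks",
    "read_dvf",
    "write_dvf",
]


@dataclass
class DisplacementField:
    """Per-voxel 3-vectors ``u(x)`` in voxel units on the fixed grid."""

    vectors: np.ndarray  # (3, D, H, W)
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise ValidationError(
                f"displacement field must be (3, D, H, W), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("displacement field contains non-finite values")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValidationError(f"spacing must be three positive mm values")

    @property
    def extents(self) -> tuple[int, int, int]:
        return self.vectors.shape[1:]

    def magnitude_mm(self) -> np.ndarray:
        """Per-voxel displacement magnitude in millimetres."""
        return np.sqrt(((self.vectors * self.spacing[:, None, None, None]) ** 2).sum(0))


def identity_dvf(extents, spacing) -> DisplacementField:
    """The zero field: every voxel maps to itself."""
    extents = tuple(int(e) for e in extents)
    if min(extents) < 1:
        raise ValidationError(f"extents must be positive, got {extents}")
    return DisplacementField(np.zeros((3,) + extents), np.asarray(spacing, dtype=float))


def _base_coords(extents) -> np.ndarray:
    return np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float64) for n in extents], indexing="ij")
    ).reshape(3, -1)


def warp(moving, dvf: DisplacementField, interp: str = "trilinear", oob: str | None = None):
    """Resample ``moving`` (Volume or LabelMap) at ``x + u(x)`` on the fixed
    grid defined by ``dvf``.

    ``interp='trilinear'`` gives soft values (labels become soft masks in
    [0, 1], as consumed by the Dice losses); ``'nearest'`` keeps values
    crisp for evaluation masks.  ``oob`` defaults to ``'zero'`` for labels
    and ``'border'`` for images.
    """
    if interp not in ("trilinear", "nearest"):
        raise ValidationError(f"unknown interpolation {interp!r}")
    is_label = isinstance(moving, LabelMap)
    if oob is None:
        oob = "zero" if is_label else "border"
    extents = dvf.extents
    coords = _base_coords(extents) + dvf.vectors.reshape(3, -1)
    if interp == "nearest":
        idx = np.rint(coords).astype(np.int64)
        dims = np.array(moving.extents)
        valid = np.all((idx >= 0) & (idx < dims[:, None]), axis=0)
        idxc = np.minimum(np.maximum(idx, 0), (dims - 1)[:, None])
        out = moving.data[idxc[0], idxc[1], idxc[2]]
        if oob == "zero":
            out = np.where(valid, out, 0.0)
        out = out.reshape(extents)
    else:
        sampled = trilinear_sample(
            moving.data[None].astype(np.float64), coords, oob=oob
        )
        out = sampled[0].reshape(extents)
    cls = LabelMap if is_label else Volume
    if is_label:
        out = np.clip(out, 0.0, 1.0)
    return cls(out, dvf.spacing.copy(), getattr(dvf, "origin", np.zeros(3)).copy())


def transport_landmarks(
    pts: LandmarkSet, dvf: DisplacementField, moving_origin=None
) -> LandmarkSet:
    """Map each fixed-grid landmark ``x`` to ``x + u(x)`` (``u`` trilinearly
    interpolated at the point), giving its corresponding moving-space
    position.  Points outside the fixed grid are dropped with a warning.

    ``x + u(x)`` is a voxel coordinate on the moving grid; ``moving_origin``
    (defaulting to the field's own origin) anchors it in world mm when the
    moving grid is offset from the fixed one."""
    origin = dvf.origin if moving_origin is None else np.asarray(moving_origin, float)
    out = []
    ext = np.array(dvf.extents)
    for lm in pts:
        vox = (np.asarray(lm.position_mm) - dvf.origin) / dvf.spacing
        if np.any(vox < 0) or np.any(vox > ext - 1):
            warnings.warn(
                f"landmark {lm.name!r} outside the fixed grid, excluded", stacklevel=2
            )
            continue
        u = trilinear_sample(dvf.vectors, vox[:, None], oob="border")[:, 0]
        new_vox = vox + u
        new_mm = origin + new_vox * dvf.spacing
        out.append(Landmark(lm.name, tuple(float(c) for c in new_mm), lm.kind))
    return LandmarkSet(out)


# ---------------------------------------------------------------------------
# NIfTI I/O: fields stored as 4-D volumes, components in the 4th dimension
# ---------------------------------------------------------------------------

_DVF_DESCRIP = b"siamreg DVF v1; voxel-unit displacements, component axis last"


def write_dvf(dvf: DisplacementField, path) -> None:
    affine = np.eye(4)
    affine[[0, 1, 2], [0, 1, 2]] = dvf.spacing
    affine[:3, 3] = dvf.origin
    img = nib.Nifti1Image(np.moveaxis(dvf.vectors, 0, -1), affine)
    img.header["descrip"] = _DVF_DESCRIP
    nib.save(img, str(path))


def read_dvf(path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValidationError(
            f"{path}: expected a 4-D field with 3 components, got shape {data.shape}"
        )
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return DisplacementField(np.moveaxis(data, -1, 0), spacing, origin)
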