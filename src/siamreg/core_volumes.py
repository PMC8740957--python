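"""Volumes, label maps, landmarks and geometric preprocessing.

The data model mirrors how a registration pair is handled in practice: a
fixed image :math:`I_F` on grid :math:`\\Omega_F`, a moving image
:math:`I_M` on :math:`\\Omega_M` (possibly with different extents), binary
lumen label maps aligned to each, and a set of named anatomical landmarks
(bifurcation, plaque, generic) stored in world millimetres so they survive
resampling and cropping without re-annotation.

Conventions: 0-based voxel indices, half-open crop boxes, and
``world_mm = origin + index * spacing``.  Volumes loaded from NIfTI are
reoriented to the closest canonical (RAS) axis order so that axis 0 is the
left-right axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "ValidationError",
    "Volume",
    "LabelMap",
    "Landmark",
    "LandmarkSet",
    "RegistrationPair",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "resample_isotropic",
    "crop",
    "crop_landmarks",
    "split_left_right",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _check_grid(data: np.ndarray, spacing, origin):
    data = np.asarray(data)
    if data.ndim != 3 or min(data.shape) < 1:
        raise ValidationError(f"grid must be 3-D with positive extents, got {data.shape}")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValidationError(f"spacing must be three positive mm values, got {spacing}")
    if origin.shape != (3,) or not np.all(np.isfinite(origin)):
        raise ValidationError(f"origin must be three finite mm values, got {origin}")
    if not np.all(np.isfinite(data)):
        raise ValidationError("grid contains non-finite intensities")
    return data, spacing, origin


@dataclass
class Volume:
    """A 3-D scalar grid with isotropic-capable spacing (mm) and world origin."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data, self.spacing, self.origin = _check_grid(
            self.data, self.spacing, self.origin
        )

    @property
    def extents(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_voxel(self, pts_mm: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts_mm) - self.origin) / self.spacing

    def voxel_to_world(self, pts_vox: np.ndarray) -> np.ndarray:
        return self.origin + np.atleast_2d(pts_vox) * self.spacing


@dataclass
class LabelMap(Volume):
    """A grid of values in [0, 1]; ``binary`` records whether it is crisp."""

    def __post_init__(self):
        super().__post_init__()
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValidationError("label values must lie in [0, 1]")

    @property
    def binary(self) -> bool:
        return bool(np.all((self.data == 0) | (self.data == 1)))


@dataclass(frozen=True)
class Landmark:
    name: str
    position_mm: tuple[float, float, float]
    kind: str = "generic"  # bifurcation | plaque | generic


class LandmarkSet:
    """Named anatomical points in world mm coordinates."""

    def __init__(self, landmarks=()):
        self.landmarks = list(landmarks)
        names = [lm.name for lm in self.landmarks]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate landmark names in {names}")
        for lm in self.landmarks:
            if not np.all(np.isfinite(lm.position_mm)):
                raise ValidationError(f"non-finite coordinates for landmark {lm.name}")

    def __len__(self):
        return len(self.landmarks)

    def __iter__(self):
        return iter(self.landmarks)

    def __getitem__(self, name: str) -> Landmark:
        for lm in self.landmarks:
            if lm.name == name:
                return lm
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [lm.name for lm in self.landmarks]

    def positions(self) -> np.ndarray:
        if not self.landmarks:
            return np.zeros((0, 3))
        return np.array([lm.position_mm for lm in self.landmarks], dtype=float)


@dataclass
class RegistrationPair:
    """A fixed/moving pair with labels, landmarks and (synthetic case) the
    ground-truth displacement field that aligns moving onto fixed."""

    fixed: Volume
    fixed_label: LabelMap
    moving: Volume
    moving_label: LabelMap
    fixed_landmarks: LandmarkSet = field(default_factory=LandmarkSet)
    moving_landmarks: LandmarkSet = field(default_factory=LandmarkSet)
    gt_dvf: "object | None" = None  # transform.DisplacementField
    group_id: str = ""
    pair_id: str = ""

    def __post_init__(self):
        if not np.allclose(self.fixed.spacing, self.moving.spacing):
            raise ValidationError(
                "fixed and moving volumes must share voxel spacing: "
                f"{self.fixed.spacing} vs {self.moving.spacing}"
            )
        for vol, lab, side in (
            (self.fixed, self.fixed_label, "fixed"),
            (self.moving, self.moving_label, "moving"),
        ):
            if lab is not None and lab.extents != vol.extents:
                raise ValidationError(
                    f"{side} label extents {lab.extents} != volume extents {vol.extents}"
                )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _load_canonical(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several flavours
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return data, spacing, origin


def read_volume(path, with_label=None):
    """Read a NIfTI volume (and optionally its label map).

    Returns a :class:`Volume`, or ``(Volume, LabelMap)`` when ``with_label``
    is given.  The label grid must match the volume's extents.
    """
    data, spacing, origin = _load_canonical(path)
    vol = Volume(data, spacing, origin)
    if with_label is None:
        return vol
    ldata, lspacing, lorigin = _load_canonical(with_label)
    if ldata.shape != data.shape:
        raise ValidationError(
            f"label extents {ldata.shape} do not match volume extents {data.shape}"
        )
    return vol, LabelMap(np.clip(ldata, 0.0, 1.0), lspacing, lorigin)


def write_volume(vol: Volume, path) -> None:
    affine = np.eye(4)
    affine[[0, 1, 2], [0, 1, 2]] = vol.spacing
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def read_landmarks(path) -> LandmarkSet:
    """Read a plain-text landmark table: ``name x_mm y_mm z_mm kind`` per
    line, ``#`` comments."""
    landmarks = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (4, 5):
            raise ValidationError(
                f"{path}:{lineno}: expected 'name x y z [kind]', got {line!r}"
            )
        name, x, y, z = parts[:4]
        kind = parts[4] if len(parts) == 5 else "generic"
        landmarks.append(Landmark(name, (float(x), float(y), float(z)), kind))
    return LandmarkSet(landmarks)


def write_landmarks(lms: LandmarkSet, path) -> None:
    lines = ["# name x_mm y_mm z_mm kind"]
    for lm in lms:
        x, y, z = lm.position_mm
        lines.append(f"{lm.name} {x:.6f} {y:.6f} {z:.6f} {lm.kind}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# geometric preprocessing
# ---------------------------------------------------------------------------


def resample_isotropic(v: Volume, target_spacing: float) -> Volume:
    """Trilinearly resample ``v`` onto an isotropic grid of ``target_spacing``
    mm; new extents are ``round(extent * spacing / target)`` per axis."""
    if target_spacing <= 0:
        raise ValidationError(f"target spacing must be positive, got {target_spacing}")
    new_extents = np.maximum(
        np.round(np.array(v.extents) * v.spacing / target_spacing).astype(int), 1
    )
    # output voxel j sits at world origin + j*target; sample input there
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in new_extents], indexing="ij")
    coords = [g * target_spacing / sp for g, sp in zip(grids, v.spacing)]
    out = map_coordinates(v.data, coords, order=1, mode="nearest")
    cls = LabelMap if isinstance(v, LabelMap) else Volume
    return cls(out, np.full(3, float(target_spacing)), v.origin.copy())


def crop(v: Volume, lo, hi) -> Volume:
    """Half-open crop ``[lo, hi)`` in 0-based voxel indices; the origin
    shifts by ``lo * spacing`` so world coordinates are preserved."""
    lo = np.asarray(lo, dtype=int)
    hi = np.asarray(hi, dtype=int)
    ext = np.array(v.extents)
    if np.any(lo < 0) or np.any(hi > ext) or np.any(lo >= hi):
        raise ValidationError(f"crop box [{lo}, {hi}) out of range for extents {tuple(ext)}")
    out = v.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].copy()
    cls = LabelMap if isinstance(v, LabelMap) else Volume
    return cls(out, v.spacing.copy(), v.origin + lo * v.spacing)


def crop_landmarks(lms: LandmarkSet, cropped: Volume) -> LandmarkSet:
    """Keep only landmarks whose world position falls inside the cropped
    volume's voxel box; dropped points are reported with a warning."""
    kept = []
    ext = np.array(cropped.extents)
    for lm in lms:
        vox = cropped.world_to_voxel(np.array(lm.position_mm))[0]
        if np.all(vox >= 0) and np.all(vox <= ext - 1):
            kept.append(lm)
        else:
            warnings.warn(f"landmark {lm.name!r} outside crop box, dropped", stacklevel=2)
    return LandmarkSet(kept)


def split_left_right(v: Volume) -> tuple[Volume, Volume]:
    """Split along the left-right axis (axis 0) at ``floor(extent / 2)``;
    an odd extent gives the extra slice to the second half."""
    n = v.extents[0]
    if n < 2:
        raise ValidationError(f"left-right extent must be >= 2 to split, got {n}")
    mid = n // 2
    ext = v.extents
    first = crop(v, (0, 0, 0), (mid, ext[1], ext[2]))
    second = crop(v, (mid, 0, 0), ext)
    return first, second
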