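"""Synthetic vessel phantoms, elastic ground-truth deformations and
augmentations.

The generator stands in for clinical multi-sequence vascular MR data.  A
phantom is a curved tube that bifurcates into two branches (a Y-shaped
lumen, the synthetic analogue of a carotid artery), rendered in two
contrast "modalities" that share identical geometry but have inverted
foreground/background intensities plus independent noise — the condition
that makes intensity-based similarity unusable and motivates label-driven
(weakly supervised) training.  Each phantom carries a binary lumen label,
a bifurcation landmark and wall points standing in for plaques.

Mis-aligned pairs are produced by warping the moving-modality rendering
with a random elastic displacement field (coarse random control vectors,
trilinear up-sampling, Gaussian smoothing, amplitude-normalized).  The
stored ground truth is the field that aligns the deformed moving image
back onto the fixed geometry (the approximate inverse of the applied
field, computed by fixed-point iteration), expressed — like everything
else — in voxel units on the fixed grid, so warping the moving label with
it recovers the fixed label and network predictions are directly
comparable to it.  An optional centered crop of the moving side emulates
the cross-scale acquisition regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter, map_coordinates
from scipy.spatial import cKDTree

from .autodiff import trilinear_sample
from .core_volumes import (
    LabelMap,
    Landmark,
    LandmarkSet,
    RegistrationPair,
    ValidationError,
    Volume,
    crop,
    crop_landmarks,
)
from .transform import DisplacementField, warp

__all__ = [
    "PhantomConfig",
    "DeformConfig",
    "make_phantom",
    "random_elastic_dvf",
    "invert_dvf",
    "make_deformed_pair",
    "augment",
    "apply_affine",
]


@dataclass
class PhantomConfig:
    """Geometry and rendering of a bifurcating-vessel phantom.

    ``fixed_contrast`` / ``moving_contrast`` are (foreground, background)
    mean intensities; the defaults invert between the two modalities.
    """

    extents: tuple[int, int, int] = (48, 48, 48)
    spacing: float = 0.6  # mm, isotropic
    radius_range: tuple[float, float] = (3.0, 4.5)  # voxels (~2-3 mm lumen)
    bifurcation_fraction: float = 0.45
    fixed_contrast: tuple[float, float] = (0.75, 0.15)
    moving_contrast: tuple[float, float] = (0.20, 0.70)
    noise_sd: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if self.radius_range[0] < 1:
            raise ValidationError("vessel radius must be >= 1 voxel")
        if self.radius_range[1] >= min(self.extents) / 4:
            raise ValidationError(
                f"max radius {self.radius_range[1]} too large for extents {self.extents}"
            )
        if not 0.1 < self.bifurcation_fraction < 0.9:
            raise ValidationError("bifurcation fraction must be in (0.1, 0.9)")


@dataclass
class DeformConfig:
    """Random elastic deformation: control-point spacing, peak displacement
    amplitude (voxels) and the Gaussian smoothing applied afterwards.

    The defaults give the field a correlation length comfortably above the
    peak displacement, which keeps the deformation fold-free and accurately
    invertible."""

    control_spacing: int = 4
    amplitude: float = 3.0
    smooth_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0 or self.smooth_sigma < 0:
            raise ValidationError("amplitude and smoothing sigma must be >= 0")
        if self.control_spacing < 1:
            raise ValidationError("control spacing must be >= 1 voxel")


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------


def _centerline(cfg: PhantomConfig, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense centerline points + per-point radii for trunk and branches.

    Returns (points (N, 3) in voxel coords, radii (N,), bifurcation point).
    The vessel runs along axis 2; the trunk curves gently in-plane and
    splits at the bifurcation fraction into two diverging branches.
    """
    nx, ny, nz = cfg.extents
    n_samples = 6 * nz
    t = np.linspace(0.0, 1.0, n_samples)
    z = t * (nz - 1)
    phase = rng.uniform(0, 2 * np.pi)
    bend = rng.uniform(0.05, 0.09) * nx
    cx = nx / 2 + bend * np.sin(np.pi * t + phase) * 0.5
    cy = ny / 2 + bend * np.cos(1.5 * np.pi * t + phase) * 0.4
    r_lo, r_hi = cfg.radius_range
    radii = r_hi - (r_hi - r_lo) * t  # tapers distally, like a real artery

    tb = cfg.bifurcation_fraction
    trunk = t <= tb
    pts = [np.stack([cx[trunk], cy[trunk], z[trunk]], axis=1)]
    rads = [radii[trunk]]
    bif_point = np.array([np.interp(tb, t, cx), np.interp(tb, t, cy), tb * (nz - 1)])
    spread = rng.uniform(0.22, 0.3) * nx
    for sign in (-1.0, 1.0):
        s = t[~trunk]
        frac = (s - tb) / (1.0 - tb)
        bx = cx[~trunk] + sign * spread * frac
        by = cy[~trunk] + 0.3 * spread * frac * rng.uniform(-0.5, 0.5)
        pts.append(np.stack([bx, by, z[~trunk]], axis=1))
        rads.append(0.75 * radii[~trunk])
    return np.concatenate(pts), np.concatenate(rads), bif_point


def make_phantom(cfg: PhantomConfig | None = None) -> RegistrationPair:
    """Generate an undeformed two-modality phantom pair (identical geometry).

    The lumen label is the tube interior; landmarks are the bifurcation and
    two wall points ("plaques") on the trunk.  Deterministic given the seed.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    points, radii, bif = _centerline(cfg, rng)

    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in cfg.extents], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    dist, idx = cKDTree(points).query(grid, k=1)
    label = (dist <= radii[idx]).astype(np.float64).reshape(cfg.extents)
    spacing = np.full(3, float(cfg.spacing))

    soft = gaussian_filter(label, sigma=0.8)

    def render(contrast, noise_seed):
        fg, bg = contrast
        local = np.random.default_rng(noise_seed)
        img = bg + (fg - bg) * soft + cfg.noise_sd * local.standard_normal(cfg.extents)
        return Volume(img, spacing.copy())

    fixed = render(cfg.fixed_contrast, cfg.seed * 7919 + 1)
    moving = render(cfg.moving_contrast, cfg.seed * 7919 + 2)

    # landmarks: the bifurcation plus two wall-adjacent "plaque" points on
    # the trunk, placed just inside the lumen surface
    lms = [Landmark("bifurcation", tuple(bif * spacing), "bifurcation")]
    for i, frac in enumerate((0.2, 0.35)):
        j = int(frac * len(points) * cfg.bifurcation_fraction)
        p = points[j] + np.array([0.6 * radii[j], 0.0, 0.0])
        lms.append(Landmark(f"plaque_{i}", tuple(p * spacing), "plaque"))
    landmarks = LandmarkSet(lms)

    return RegistrationPair(
        fixed=fixed,
        fixed_label=LabelMap(label, spacing.copy()),
        moving=moving,
        moving_label=LabelMap(label.copy(), spacing.copy()),
        fixed_landmarks=landmarks,
        moving_landmarks=LandmarkSet(list(lms)),
        group_id=f"phantom{cfg.seed}",
        pair_id=f"phantom{cfg.seed}",
    )


# ---------------------------------------------------------------------------
# elastic deformation fields
# ---------------------------------------------------------------------------


def random_elastic_dvf(extents, cfg: DeformConfig, spacing=0.6) -> DisplacementField:
    """Random smooth field: i.i.d. normal vectors on a coarse control grid,
    trilinearly up-sampled, Gaussian-smoothed, then scaled so the maximum
    displacement magnitude equals ``cfg.amplitude`` voxels exactly."""
    extents = tuple(int(e) for e in extents)
    rng = np.random.default_rng(cfg.seed)
    n_ctrl = [max(int(np.ceil(e / cfg.control_spacing)) + 1, 2) for e in extents]
    ctrl = rng.standard_normal((3, *n_ctrl))
    coords = np.meshgrid(
        *[np.arange(e, dtype=float) / cfg.control_spacing for e in extents],
        indexing="ij",
    )
    vec = np.stack(
        [map_coordinates(ctrl[c], coords, order=1, mode="nearest") for c in range(3)]
    )
    if cfg.smooth_sigma > 0:
        vec = np.stack([gaussian_filter(v, cfg.smooth_sigma) for v in vec])
    maxnorm = float(np.sqrt((vec**2).sum(axis=0)).max())
    if cfg.amplitude == 0 or maxnorm == 0:
        vec = np.zeros_like(vec)
    else:
        vec *= cfg.amplitude / maxnorm
    return DisplacementField(vec, np.full(3, float(spacing)))


def invert_dvf(dvf: DisplacementField, iterations: int = 15) -> DisplacementField:
    """Approximate inverse displacement by fixed-point iteration
    ``u <- -psi(x + u)``; accurate for the smooth, moderate-amplitude
    fields the generator produces."""
    ext = dvf.extents
    base = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in ext], indexing="ij")
    ).reshape(3, -1)
    psi = dvf.vectors
    u = np.zeros_like(base)
    for _ in range(iterations):
        u = -trilinear_sample(psi, base + u, oob="border")
    return DisplacementField(u.reshape((3,) + tuple(ext)), dvf.spacing.copy(), dvf.origin.copy())


def make_deformed_pair(
    phantom: RegistrationPair,
    cfg: DeformConfig,
    crop_to=None,
    divisible_by: int | None = None,
) -> RegistrationPair:
    """Deform the moving-modality rendering with a random elastic field and
    record the aligning ground truth.

    The moving image/label are produced by backward-warping the rendering
    with the generated field ``psi``; the stored ``gt_dvf`` is the inverse
    of ``psi``, i.e. exactly the field that warps the deformed moving image
    back onto the fixed geometry.  Moving landmarks are the fixed landmarks
    transported through ``gt_dvf``.  ``crop_to`` applies a centered crop to
    the moving side (the cross-scale regime); the ground truth is shifted
    into the cropped grid's voxel coordinates.
    """
    ext = phantom.moving.extents
    psi = random_elastic_dvf(ext, cfg, spacing=phantom.moving.spacing[0])
    moving = warp(phantom.moving, psi, interp="trilinear", oob="border")
    # the stored moving label is crisp binary, like a clinical annotation
    moving_label = warp(phantom.moving_label, psi, interp="nearest", oob="zero")
    gt = invert_dvf(psi)
    if cfg.amplitude == 0:
        moving = Volume(
            phantom.moving.data.copy(),
            phantom.moving.spacing.copy(),
            phantom.moving.origin.copy(),
        )
        moving_label = LabelMap(
            phantom.moving_label.data.copy(),
            phantom.moving_label.spacing.copy(),
            phantom.moving_label.origin.copy(),
        )

    # moving landmark y for fixed landmark x satisfies y = x + u(x)
    moving_lms = []
    for lm in phantom.fixed_landmarks:
        vox = (np.asarray(lm.position_mm) - phantom.fixed.origin) / phantom.fixed.spacing
        u = trilinear_sample(gt.vectors, vox[:, None], oob="border")[:, 0]
        pos = phantom.fixed.origin + (vox + u) * phantom.fixed.spacing
        moving_lms.append(Landmark(lm.name, tuple(float(c) for c in pos), lm.kind))
    moving_landmarks = LandmarkSet(moving_lms)

    if crop_to is not None:
        crop_to = tuple(int(c) for c in crop_to)
        if any(c > e for c, e in zip(crop_to, ext)):
            raise ValidationError(f"crop_to {crop_to} exceeds moving extents {ext}")
        if divisible_by and any(c % divisible_by for c in crop_to):
            raise ValidationError(
                f"crop_to {crop_to} violates the network's divisibility "
                f"requirement ({divisible_by})"
            )
        lo = tuple((e - c) // 2 for e, c in zip(ext, crop_to))
        hi = tuple(l + c for l, c in zip(lo, crop_to))
        moving = crop(moving, lo, hi)
        moving_label = crop(moving_label, lo, hi)
        moving_landmarks = crop_landmarks(moving_landmarks, moving)
        gt = DisplacementField(
            gt.vectors - np.asarray(lo, dtype=float)[:, None, None, None],
            gt.spacing.copy(),
            gt.origin.copy(),
        )

    return RegistrationPair(
        fixed=phantom.fixed,
        fixed_label=phantom.fixed_label,
        moving=moving,
        moving_label=moving_label,
        fixed_landmarks=phantom.fixed_landmarks,
        moving_landmarks=moving_landmarks,
        gt_dvf=gt,
        group_id=phantom.group_id,
        pair_id=phantom.pair_id + "_def",
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _flip_volume(v: Volume):
    cls = LabelMap if isinstance(v, LabelMap) else Volume
    return cls(np.ascontiguousarray(v.data[::-1]), v.spacing.copy(), v.origin.copy())


def _flip_landmarks(lms: LandmarkSet, v: Volume) -> LandmarkSet:
    n = v.extents[0]
    out = []
    for lm in lms:
        vox = (np.asarray(lm.position_mm) - v.origin) / v.spacing
        vox[0] = (n - 1) - vox[0]
        pos = v.origin + vox * v.spacing
        out.append(Landmark(lm.name, tuple(float(c) for c in pos), lm.kind))
    return LandmarkSet(out)


def _flip_pair(pair: RegistrationPair) -> RegistrationPair:
    gt = pair.gt_dvf
    if gt is not None:
        n_f = pair.fixed.extents[0]
        n_m = pair.moving.extents[0]
        vec = np.ascontiguousarray(gt.vectors[:, ::-1])
        vec[0] = (n_m - n_f) - vec[0]
        gt = DisplacementField(vec, gt.spacing.copy(), gt.origin.copy())
    return RegistrationPair(
        fixed=_flip_volume(pair.fixed),
        fixed_label=_flip_volume(pair.fixed_label),
        moving=_flip_volume(pair.moving),
        moving_label=_flip_volume(pair.moving_label),
        fixed_landmarks=_flip_landmarks(pair.fixed_landmarks, pair.fixed),
        moving_landmarks=_flip_landmarks(pair.moving_landmarks, pair.moving),
        gt_dvf=gt,
        group_id=pair.group_id,
        pair_id=pair.pair_id + "_flip",
    )


def _affine_matrix(rotation_deg, scale, translation, center):
    """Voxel-space matrix/offset mapping output coordinates to input
    coordinates (the convention scipy's affine_transform uses): rotation
    about axis 2 through ``center``, isotropic scale, then translation."""
    th = np.deg2rad(rotation_deg)
    rot = np.array(
        [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]]
    )
    lam = rot / float(scale)
    center = np.asarray(center, dtype=float)
    offset = center - lam @ center + np.asarray(translation, dtype=float)
    return lam, offset


def apply_affine(
    pair: RegistrationPair,
    rotation_deg: float = 0.0,
    scale: float = 1.0,
    translation=(0.0, 0.0, 0.0),
) -> RegistrationPair:
    """Apply one affine transform identically to both members (and
    consistently to landmarks and the ground-truth field)."""
    if rotation_deg == 0.0 and scale == 1.0 and not np.any(np.asarray(translation)):
        return pair

    def tx_volume(v, is_label):
        lam, off = _affine_matrix(
            rotation_deg, scale, translation, (np.array(v.extents) - 1) / 2.0
        )
        out = affine_transform(
            v.data,
            lam,
            offset=off,
            order=1,
            mode="constant" if is_label else "nearest",
            cval=0.0,
        )
        cls = LabelMap if is_label else Volume
        if is_label:
            out = np.clip(out, 0.0, 1.0)
        return cls(out, v.spacing.copy(), v.origin.copy())

    def tx_landmarks(lms, v):
        lam, off = _affine_matrix(
            rotation_deg, scale, translation, (np.array(v.extents) - 1) / 2.0
        )
        inv = np.linalg.inv(lam)
        out = []
        for lm in lms:
            vox = (np.asarray(lm.position_mm) - v.origin) / v.spacing
            new_vox = inv @ (vox - off)
            pos = v.origin + new_vox * v.spacing
            out.append(Landmark(lm.name, tuple(float(c) for c in pos), lm.kind))
        return LandmarkSet(out)

    gt = pair.gt_dvf
    if gt is not None:
        lam_f, off_f = _affine_matrix(
            rotation_deg, scale, translation, (np.array(pair.fixed.extents) - 1) / 2.0
        )
        lam_m, off_m = _affine_matrix(
            rotation_deg, scale, translation, (np.array(pair.moving.extents) - 1) / 2.0
        )
        ext = gt.extents
        base = np.stack(
            np.meshgrid(*[np.arange(n, dtype=float) for n in ext], indexing="ij")
        ).reshape(3, -1)
        # new fixed voxel x' samples old fixed at A_f(x'); correspondence in
        # the new moving frame is A_m^{-1}(A_f(x') + u(A_f(x')))
        x_old = lam_f @ base + off_f[:, None]
        u_old = trilinear_sample(gt.vectors, x_old, oob="border")
        y_new = np.linalg.inv(lam_m) @ (x_old + u_old - off_m[:, None])
        gt = DisplacementField(
            (y_new - base).reshape((3,) + tuple(ext)), gt.spacing.copy(), gt.origin.copy()
        )

    return RegistrationPair(
        fixed=tx_volume(pair.fixed, False),
        fixed_label=tx_volume(pair.fixed_label, True),
        moving=tx_volume(pair.moving, False),
        moving_label=tx_volume(pair.moving_label, True),
        fixed_landmarks=tx_landmarks(pair.fixed_landmarks, pair.fixed),
        moving_landmarks=tx_landmarks(pair.moving_landmarks, pair.moving),
        gt_dvf=gt,
        group_id=pair.group_id,
        pair_id=pair.pair_id + "_aff",
    )


def augment(pair: RegistrationPair, mode: str, seed: int = 0) -> RegistrationPair:
    """Data augmentation: ``lr_flip`` mirrors everything across the
    left-right axis (an involution; applied offline it doubles a dataset),
    ``affine`` applies a small random rotation/scale/translation to both
    members identically (intended on-the-fly during training)."""
    if mode == "lr_flip":
        return _flip_pair(pair)
    if mode == "affine":
        rng = np.random.default_rng(seed)
        return apply_affine(
            pair,
            rotation_deg=float(rng.uniform(-5.0, 5.0)),
            scale=float(rng.uniform(0.95, 1.05)),
            translation=tuple(rng.uniform(-1.5, 1.5, size=3)),
        )
    raise ValidationError(f"unknown augmentation mode {mode!r}")
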