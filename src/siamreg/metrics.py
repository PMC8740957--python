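"""Registration evaluation: Dice overlap, landmark distance, and target
registration error against ground-truth fields.

Evaluation is deliberately distinct from the training losses: masks are
hard-binarized here (threshold 0.5), whereas the loss path keeps labels
soft for differentiability.
"""

from __future__ import annotations

import numpy as np

from .core_volumes import LabelMap, LandmarkSet, ValidationError
from .transform import DisplacementField, transport_landmarks

__all__ = ["dsc", "landmark_distance", "tre"]


def _mask(x, threshold):
    data = x.data if isinstance(x, LabelMap) else np.asarray(x)
    return data >= threshold


def dsc(a, b, threshold: float = 0.5) -> float:
    """Dice similarity coefficient ``2|A ∩ B| / (|A| + |B|)`` after
    binarizing at ``threshold``.  Two empty masks agree vacuously: 1.0."""
    am = _mask(a, threshold)
    bm = _mask(b, threshold)
    if am.shape != bm.shape:
        raise ValidationError(f"mask extents differ: {am.shape} vs {bm.shape}")
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((am & bm).sum()) / denom


def landmark_distance(
    fixed_pts: LandmarkSet,
    moving_pts: LandmarkSet,
    dvf: DisplacementField,
    moving_origin=None,
) -> float:
    """Mean Euclidean distance (mm) between fixed landmarks transported
    through the field and the like-named moving landmarks.

    ``moving_origin`` places the transported voxel coordinates in the
    moving image's world frame when its grid is offset from the fixed grid
    (the cross-scale cropped case); it defaults to the fixed-grid origin.
    """
    transported = transport_landmarks(pts=fixed_pts, dvf=dvf, moving_origin=moving_origin)
    common = [n for n in transported.names if n in moving_pts.names]
    if not common:
        raise ValidationError("no landmark names shared between the two sets")
    dists = [
        float(
            np.linalg.norm(
                np.asarray(transported[n].position_mm)
                - np.asarray(moving_pts[n].position_mm)
            )
        )
        for n in common
    ]
    return float(np.mean(dists))


def tre(
    pred: DisplacementField,
    truth: DisplacementField,
    mask: LabelMap | None = None,
) -> float:
    """Target registration error: mean Euclidean norm (mm) of the
    voxel-wise difference between predicted and ground-truth fields,
    averaged over the mask (foreground by default when given)."""
    if pred.extents != truth.extents:
        raise ValidationError(f"field extents differ: {pred.extents} vs {truth.extents}")
    if not np.allclose(pred.spacing, truth.spacing):
        raise ValidationError("field spacings differ")
    diff_mm = (pred.vectors - truth.vectors) * pred.spacing[:, None, None, None]
    norms = np.sqrt((diff_mm**2).sum(axis=0))
    if mask is not None:
        if mask.extents != pred.extents:
            raise ValidationError("mask extents do not match the fields")
        sel = mask.data >= 0.5
        if not sel.any():
            raise ValidationError("empty evaluation mask")
        return float(norms[sel].mean())
    return float(norms.mean())
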