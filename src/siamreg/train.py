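"""Weakly supervised training, grouped cross-validation splitting,
checkpointing, dataset (de)serialization and registration/evaluation
drivers.

Training minimizes ``gdsc_loss(warp(moving_label, u), fixed_label)
+ alpha * smoothness_loss(u)`` with Adam; image intensities enter only as
network inputs, never the loss.  Cross-scale pairs cannot share a dense
minibatch, so a "batch" is a gradient accumulation over ``batch_size``
single-pair passes before one optimizer step.  All randomness (pair
sampling, on-the-fly affine augmentation) flows through one seeded
generator whose state is checkpointed, making runs resumable bit-for-bit.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from .core_volumes import (
    LandmarkSet,
    RegistrationPair,
    ValidationError,
    read_landmarks,
    read_volume,
    write_landmarks,
    write_volume,
)
from .losses import LossConfig, gdsc_loss, smoothness_loss
from .metrics import dsc, landmark_distance, tre
from .network import NetworkConfig, SiameseUNet, build_network, forward, prepare_input
from .synthetic import augment
from .transform import identity_dvf, read_dvf, warp, write_dvf

__all__ = [
    "TrainConfig",
    "Adam",
    "grouped_kfold",
    "train",
    "register",
    "evaluate_pairs",
    "save_checkpoint",
    "load_checkpoint",
    "select_best_checkpoint",
    "write_dataset",
    "load_dataset",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    iterations: int = 10_000
    batch_size: int = 2
    checkpoint_interval: int = 15
    folds: int = 4
    seed: int = 0
    augment_affine: bool = True
    loss: LossConfig = field(default_factory=LossConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        for name in ("learning_rate", "iterations", "batch_size", "checkpoint_interval"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if isinstance(self.loss, dict):
            self.loss = LossConfig(**self.loss)
        if isinstance(self.network, dict):
            self.network = NetworkConfig(**self.network)


class Adam:
    """Adam over the network's parameter tensors."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, grad_scale: float = 1.0):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = (p.grad if p.grad is not None else np.zeros_like(p.data)) * grad_scale
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)


# ---------------------------------------------------------------------------
# grouped cross-validation
# ---------------------------------------------------------------------------


def _pair_meta(p):
    if isinstance(p, dict):
        return p.get("pair_id", ""), p["group_id"]
    return p.pair_id, p.group_id


def grouped_kfold(pairs, folds: int = 4, seed: int = 0):
    """Partition pairs into folds by *group* (e.g. patient), so that the
    left and right sides of one subject never straddle train and test.

    Returns a list of ``(train_pair_ids, test_pair_ids)`` tuples, one per
    fold; every pair appears in exactly one test fold.
    """
    metas = [_pair_meta(p) for p in pairs]
    for pid, gid in metas:
        if not gid:
            raise ValidationError(f"pair {pid!r} has no group_id")
    groups = sorted({gid for _, gid in metas})
    if len(groups) < folds:
        raise ValidationError(f"{len(groups)} groups cannot fill {folds} folds")
    rng = np.random.default_rng(seed)
    rng.shuffle(groups)
    chunks = np.array_split(np.array(groups, dtype=object), folds)
    splits = []
    for chunk in chunks:
        test_groups = set(chunk.tolist())
        test_ids = [pid for pid, gid in metas if gid in test_groups]
        train_ids = [pid for pid, gid in metas if gid not in test_groups]
        splits.append((train_ids, test_ids))
    return splits


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_checkpoint(path, net: SiameseUNet, opt: Adam | None, iteration: int,
                    rng: np.random.Generator | None, train_cfg: TrainConfig | None):
    arrays = {f"param/{k}": p.data for k, p in net.params.items()}
    if opt is not None:
        for (k, _), m, v in zip(net.params.items(), opt.m, opt.v):
            arrays[f"adam_m/{k}"] = m
            arrays[f"adam_v/{k}"] = v
    meta = {
        "version": _CKPT_VERSION,
        "iteration": iteration,
        "adam_t": opt.t if opt is not None else 0,
        "network": asdict(net.cfg),
        "train": _cfg_to_jsonable(train_cfg) if train_cfg is not None else None,
        "rng_state": rng.bit_generator.state if rng is not None else None,
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def _cfg_to_jsonable(cfg: TrainConfig):
    d = asdict(cfg)
    return d


def load_checkpoint(path):
    """Returns (net, meta, adam_state) where adam_state is (t, m, v) dicts
    or None."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        net = build_network(NetworkConfig(**meta["network"]))
        m, v = {}, {}
        for key in z.files:
            if key.startswith("param/"):
                name = key[len("param/"):]
                net.params[name].data = z[key].copy()
            elif key.startswith("adam_m/"):
                m[key[len("adam_m/"):]] = z[key].copy()
            elif key.startswith("adam_v/"):
                v[key[len("adam_v/"):]] = z[key].copy()
    adam_state = (meta.get("adam_t", 0), m, v) if m else None
    return net, meta, adam_state


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _pair_loss(net: SiameseUNet, pair: RegistrationPair, loss_cfg: LossConfig):
    """Forward + composite loss for one pair; returns the loss Tensor and
    its components."""
    fin = prepare_input(pair.fixed, pair.fixed_label, net.cfg)
    min_ = prepare_input(pair.moving, pair.moving_label, net.cfg)
    dvf_t = net.forward_tensor(fin, min_)
    warped = ad.grid_sample(pair.moving_label.data, dvf_t, oob="zero")
    overlap = gdsc_loss(warped, pair.fixed_label.data.astype(dvf_t.dtype), loss_cfg)
    smooth = smoothness_loss(dvf_t, loss_cfg.smooth_variant)
    total = overlap + loss_cfg.alpha * smooth
    return total, float(overlap.data), float(smooth.data)


def _check_divisibility(pairs, cfg: NetworkConfig):
    for p in pairs:
        for side, ext in (("fixed", p.fixed.extents), ("moving", p.moving.extents)):
            bad = [e for e in ext if e % cfg.divisor]
            if bad:
                raise ValidationError(
                    f"pair {p.pair_id!r}: {side} extents {ext} not divisible by "
                    f"pool**levels = {cfg.divisor}"
                )


def train(
    cfg: TrainConfig,
    pairs,
    out_dir,
    resume=None,
    log_every: int = 1,
):
    """Train on a list of :class:`RegistrationPair` (or a manifest path).

    Writes checkpoints ``ckpt_NNNNNN.npz`` and a ``loss_log.csv`` with
    per-iteration loss components to ``out_dir``; returns the path of the
    final checkpoint.
    """
    if isinstance(pairs, (str, Path)):
        pairs = load_dataset(pairs)
    if not pairs:
        raise ValidationError("no training pairs")
    _check_divisibility(pairs, cfg.network)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if resume is not None:
        net, meta, adam_state = load_checkpoint(resume)
        start_iter = meta["iteration"]
        rng = np.random.default_rng(cfg.seed)
        if meta.get("rng_state"):
            rng.bit_generator.state = meta["rng_state"]
        opt = Adam(net.parameters(), lr=cfg.learning_rate)
        if adam_state is not None:
            t, m, v = adam_state
            opt.t = t
            opt.m = [m[k] for k in net.params]
            opt.v = [v[k] for k in net.params]
    else:
        net = build_network(cfg.network, seed=cfg.seed)
        opt = Adam(net.parameters(), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed)
        start_iter = 0

    log_path = out_dir / "loss_log.csv"
    log_f = open(log_path, "a", newline="")
    logger = csv.writer(log_f)
    if start_iter == 0:
        logger.writerow(["iteration", "total", "gdsc", "smooth"])

    final_path = None
    for it in range(start_iter, cfg.iterations):
        idx = rng.integers(0, len(pairs), size=cfg.batch_size)
        opt.zero_grad()
        totals, overlaps, smooths = [], [], []
        for i in idx:
            pair = pairs[int(i)]
            if cfg.augment_affine:
                pair = augment(pair, "affine", seed=int(rng.integers(1 << 31)))
            loss_t, ov, sm = _pair_loss(net, pair, cfg.loss)
            if not np.isfinite(loss_t.data):
                raise RuntimeError(f"non-finite loss at iteration {it}")
            loss_t.backward()
            totals.append(float(loss_t.data))
            overlaps.append(ov)
            smooths.append(sm)
        opt.step(grad_scale=1.0 / cfg.batch_size)
        if (it + 1) % log_every == 0:
            logger.writerow(
                [it + 1, np.mean(totals), np.mean(overlaps), np.mean(smooths)]
            )
            log_f.flush()
        if (it + 1) % cfg.checkpoint_interval == 0 or (it + 1) == cfg.iterations:
            final_path = out_dir / f"ckpt_{it + 1:06d}.npz"
            save_checkpoint(final_path, net, opt, it + 1, rng, cfg)
    log_f.close()
    return final_path


def select_best_checkpoint(checkpoint_paths, val_pairs) -> Path:
    """Pick the saved checkpoint with the highest mean post-registration
    lumen Dice on validation pairs."""
    best, best_score = None, -1.0
    for path in checkpoint_paths:
        net, _, _ = load_checkpoint(path)
        scores = []
        for pair in val_pairs:
            dvf = forward(net, pair.fixed, pair.moving, pair.fixed_label, pair.moving_label)
            warped = warp(pair.moving_label, dvf, interp="nearest")
            scores.append(dsc(warped, pair.fixed_label))
        score = float(np.mean(scores))
        if score > best_score:
            best, best_score = path, score
    return Path(best)


# ---------------------------------------------------------------------------
# registration and evaluation drivers
# ---------------------------------------------------------------------------


def register(
    checkpoint,
    fixed_path,
    moving_path,
    out_dir,
    fixed_label_path=None,
    moving_label_path=None,
):
    """Load a checkpoint, predict the DVF for one pair of NIfTI volumes and
    write the field plus warped image/label; returns a result dict."""
    net, _, _ = load_checkpoint(checkpoint)
    t0 = time.perf_counter()
    if fixed_label_path is not None:
        fixed, fixed_label = read_volume(fixed_path, with_label=fixed_label_path)
    else:
        fixed, fixed_label = read_volume(fixed_path), None
    if moving_label_path is not None:
        moving, moving_label = read_volume(moving_path, with_label=moving_label_path)
    else:
        moving, moving_label = read_volume(moving_path), None
    try:
        dvf = forward(net, fixed, moving, fixed_label, moving_label)
    except ValidationError as exc:
        raise ValidationError(
            f"{exc}  (crop or pad the inputs so every extent is divisible by "
            f"{net.cfg.divisor} and the moving grid fits inside the fixed grid)"
        ) from exc
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = {"dvf": out_dir / "dvf.nii.gz", "warped": out_dir / "warped.nii.gz"}
    write_dvf(dvf, result["dvf"])
    write_volume(warp(moving, dvf, interp="trilinear"), result["warped"])
    if moving_label is not None:
        result["warped_label"] = out_dir / "warped_label.nii.gz"
        write_volume(warp(moving_label, dvf, interp="nearest"), result["warped_label"])
    result["seconds"] = time.perf_counter() - t0
    return result


def evaluate_pairs(net_or_checkpoint, pairs):
    """Per-pair and aggregate metrics for a trained network.

    Returns ``(rows, aggregate)``: each row has pre/post lumen DSC,
    landmark distance, TRE against the ground-truth field when available,
    and wall time.
    """
    if isinstance(net_or_checkpoint, (str, Path)):
        net, _, _ = load_checkpoint(net_or_checkpoint)
    else:
        net = net_or_checkpoint
    rows = []
    for pair in pairs:
        t0 = time.perf_counter()
        dvf = forward(net, pair.fixed, pair.moving, pair.fixed_label, pair.moving_label)
        elapsed = time.perf_counter() - t0
        ident = identity_dvf(pair.fixed.extents, pair.fixed.spacing)
        pre = dsc(warp(pair.moving_label, ident, interp="nearest"), pair.fixed_label)
        post = dsc(warp(pair.moving_label, dvf, interp="nearest"), pair.fixed_label)
        row = {
            "pair_id": pair.pair_id,
            "dsc_pre": pre,
            "dsc_post": post,
            "seconds": elapsed,
        }
        if len(pair.fixed_landmarks) and len(pair.moving_landmarks):
            row["lm_dist_pre"] = landmark_distance(
                pair.fixed_landmarks, pair.moving_landmarks, ident,
                moving_origin=pair.moving.origin,
            )
            row["lm_dist_post"] = landmark_distance(
                pair.fixed_landmarks, pair.moving_landmarks, dvf,
                moving_origin=pair.moving.origin,
            )
        if pair.gt_dvf is not None:
            row["tre_pre"] = tre(ident, pair.gt_dvf, mask=pair.fixed_label)
            row["tre_post"] = tre(dvf, pair.gt_dvf, mask=pair.fixed_label)
        rows.append(row)
    keys = [k for k in rows[0] if k != "pair_id"]
    aggregate = {k: float(np.mean([r[k] for r in rows if k in r])) for k in keys}
    return rows, aggregate


# ---------------------------------------------------------------------------
# dataset directories
# ---------------------------------------------------------------------------


def write_dataset(pairs, out_dir) -> Path:
    """Serialize pairs to a directory of NIfTI volumes/labels/fields and
    landmark tables, indexed by a ``manifest.yaml``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for pair in pairs:
        pid = pair.pair_id or f"pair{len(entries):03d}"
        files = {
            "fixed": f"{pid}_fixed.nii.gz",
            "fixed_label": f"{pid}_fixed_label.nii.gz",
            "moving": f"{pid}_moving.nii.gz",
            "moving_label": f"{pid}_moving_label.nii.gz",
        }
        write_volume(pair.fixed, out_dir / files["fixed"])
        write_volume(pair.fixed_label, out_dir / files["fixed_label"])
        write_volume(pair.moving, out_dir / files["moving"])
        write_volume(pair.moving_label, out_dir / files["moving_label"])
        if len(pair.fixed_landmarks):
            files["fixed_landmarks"] = f"{pid}_fixed_landmarks.txt"
            write_landmarks(pair.fixed_landmarks, out_dir / files["fixed_landmarks"])
        if len(pair.moving_landmarks):
            files["moving_landmarks"] = f"{pid}_moving_landmarks.txt"
            write_landmarks(pair.moving_landmarks, out_dir / files["moving_landmarks"])
        if pair.gt_dvf is not None:
            files["gt_dvf"] = f"{pid}_gt_dvf.nii.gz"
            write_dvf(pair.gt_dvf, out_dir / files["gt_dvf"])
        entries.append({"pair_id": pid, "group_id": pair.group_id, "files": files})
    manifest = out_dir / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"pairs": entries}, sort_keys=False))
    return manifest


def load_dataset(manifest_path):
    """Load a dataset directory written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    spec = yaml.safe_load(manifest_path.read_text())
    pairs = []
    for entry in spec["pairs"]:
        f = entry["files"]
        fixed, fixed_label = read_volume(root / f["fixed"], with_label=root / f["fixed_label"])
        moving, moving_label = read_volume(
            root / f["moving"], with_label=root / f["moving_label"]
        )
        pairs.append(
            RegistrationPair(
                fixed=fixed,
                fixed_label=fixed_label,
                moving=moving,
                moving_label=moving_label,
                fixed_landmarks=(
                    read_landmarks(root / f["fixed_landmarks"])
                    if "fixed_landmarks" in f
                    else LandmarkSet()
                ),
                moving_landmarks=(
                    read_landmarks(root / f["moving_landmarks"])
                    if "moving_landmarks" in f
                    else LandmarkSet()
                ),
                gt_dvf=read_dvf(root / f["gt_dvf"]) if "gt_dvf" in f else None,
                group_id=entry["group_id"],
                pair_id=entry["pair_id"],
            )
        )
    return pairs
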