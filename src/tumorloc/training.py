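"""Training procedures for the two architectures.

The dual-path patch CNN trains on class-balanced patches (centers drawn half
from lesion voxels, half from in-brain background), flip+noise augmentation,
and plain multi-class cross-entropy; Adam with AMSGrad, initial learning
rate 1e-3, L2 weight decay 1e-4.  The encoder-decoder CNN trains on random
crops with hard-negative-mined cross-entropy (the selected background voxels
are at most three times the lesion voxel count) and no augmentation.

The learning-rate schedule decays the initial rate by one decade over the
run by default (``l0 * 0.1^(epoch/epochs)``); the literal per-epoch form
``l0 * 0.1^epoch`` is available as ``lr_schedule_mode="literal"`` but
underflows within a handful of epochs and is kept for fidelity only.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nncore as nc
from .atlas import ParcellationAtlas, build_fused_input
from .networks import (DeepMedicConfig, UNet3DConfig, build_deepmedic,
                       build_unet3d, extract_patch_pair)
from .volume_io import LabelVolume, MultimodalVolume, clip_and_normalize, load_subject, load_nifti


class TrainingError(RuntimeError):
    pass


@dataclasses.dataclass
class TrainConfig:
    model_kind: str = "deepmedic"        # "deepmedic" | "unet"
    epochs: int = 500                    # paper-scale default; 300 for unet
    batch_size: int = 50                 # 2 for unet
    patches_per_subject: int = 20
    initial_lr: float = 1e-3
    weight_decay: float = 1e-4
    lr_schedule_mode: str = "normalized"  # "normalized" | "literal"
    augmentation: bool = True             # flips + noise (deepmedic only)
    augment_noise_sd: float = 0.1         # in normalized-intensity units
    hard_negative_ratio: int = 3
    crop_size: int = 128                  # unet training crop side
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("deepmedic", "unet"):
            raise TrainingError(f"unknown model_kind {self.model_kind!r}")
        if min(self.epochs, self.batch_size, self.patches_per_subject) < 1:
            raise TrainingError("all counts must be positive")
        if self.hard_negative_ratio < 1:
            raise TrainingError("hard_negative_ratio must be >= 1")
        if self.lr_schedule_mode not in ("normalized", "literal"):
            raise TrainingError(f"unknown lr_schedule_mode {self.lr_schedule_mode!r}")


@dataclasses.dataclass
class SubjectData:
    """In-memory training subject: input channel stack + targets."""

    inputs: np.ndarray           # (C, X, Y, Z) float32
    labels: np.ndarray           # (X, Y, Z) int in {0,1,2,4}
    brain_mask: np.ndarray       # (X, Y, Z) bool
    subject_id: str = ""


def subject_from_phantom(mmv: MultimodalVolume, atlas: ParcellationAtlas | None,
                         labels: LabelVolume, subject_id: str = "") -> SubjectData:
    """Preprocess one subject (clip+normalize, optional atlas fusion) into
    training form."""
    fused = build_fused_input(clip_and_normalize(mmv), atlas)
    return SubjectData(inputs=fused.data, labels=labels.data.astype(np.int64),
                       brain_mask=mmv.brain_mask, subject_id=subject_id)


def load_manifest_subjects(manifest: dict | str | Path,
                           fuse_atlas: bool = True) -> list[SubjectData]:
    """Load and preprocess every subject of a phantom-dataset manifest."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    out = []
    for sub in manifest["subjects"]:
        files = sub["files"]
        mmv = load_subject({m: files[m] for m in ("t1", "t1gd", "t2", "flair")})
        atl = None
        if fuse_atlas:
            grid, _ = load_nifti(files["atlas"])
            n = int(grid.max())
            atl = ParcellationAtlas(
                label_grid=np.asarray(grid, dtype=np.int32),
                label_table={i + 1: f"parcel_{i + 1:02d}" for i in range(n)},
                space_tag="subject")
        lab, _ = load_nifti(files["labels"])
        lv = LabelVolume(data=np.asarray(lab, dtype=np.int16))
        out.append(subject_from_phantom(mmv, atl, lv, subject_id=sub["id"]))
    return out


def sample_balanced_centers(labels: np.ndarray | LabelVolume, n: int,
                            rng: np.random.Generator,
                            brain_mask: np.ndarray | None = None
                            ) -> np.ndarray:
    """Draw ``n`` patch centers, each Bernoulli(0.5) from lesion voxels
    (label != 0) vs in-brain background voxels; all-background when the
    subject has no lesion."""
    lab = labels.data if isinstance(labels, LabelVolume) else labels
    if brain_mask is None:
        brain_mask = np.ones(lab.shape, dtype=bool)
    if not brain_mask.any():
        raise TrainingError("brain mask is empty")
    fg = np.argwhere((lab != 0) & brain_mask)
    bg = np.argwhere((lab == 0) & brain_mask)
    if len(bg) == 0:
        bg = fg
    centers = np.empty((n, 3), dtype=np.int64)
    take_fg = (rng.random(n) < 0.5) if len(fg) else np.zeros(n, dtype=bool)
    n_fg = int(take_fg.sum())
    if n_fg:
        centers[take_fg] = fg[rng.integers(len(fg), size=n_fg)]
    if n - n_fg:
        centers[~take_fg] = bg[rng.integers(len(bg), size=n - n_fg)]
    return centers


def augment(arrays: Sequence[np.ndarray], rng: np.random.Generator,
            image_channels: Sequence[int], noise_sd: float = 0.1
            ) -> list[np.ndarray]:
    """Random axis flips (p=0.5 each, identical for all arrays) plus Gaussian
    noise on image channels only.

    ``arrays`` share their last three (spatial) axes semantics but may have
    different sizes (centered patches flip consistently).
    ``image_channels[i]`` is the number of leading channels of ``arrays[i]``
    that receive noise (0 for atlas masks and label targets).
    """
    flips = rng.random(3) < 0.5
    out = []
    for arr, n_img in zip(arrays, image_channels):
        a = arr
        for ax_i, f in enumerate(flips):
            if f:
                a = np.flip(a, axis=a.ndim - 3 + ax_i)
        a = a.copy()
        if n_img > 0 and noise_sd > 0:
            lead = (slice(0, n_img),) if a.ndim == 4 else ()
            a[lead] = a[lead] + rng.normal(0.0, noise_sd, size=a[lead].shape)
        out.append(a)
    return out


def hard_negative_ce_loss(logits: np.ndarray, targets: np.ndarray,
                          ratio: int = 3, fallback_frac: float = 0.01
                          ) -> tuple[float, np.ndarray]:
    """Cross-entropy over all positive voxels plus the K highest-loss
    negatives, K = min(#neg, ratio * #pos); mean over selected voxels.

    With zero positives, K falls back to ``fallback_frac`` of the negatives
    (at least 1) so gradients stay non-degenerate.  Returns (loss, dlogits).
    """
    lsm = nc.log_softmax(logits, axis=1)
    nll = -np.take_along_axis(lsm, np.expand_dims(targets, 1), axis=1)[:, 0]
    pos = targets != 0
    n_pos = int(pos.sum())
    n_neg = nll.size - n_pos
    if n_pos:
        k = min(n_neg, ratio * n_pos)
    else:
        k = max(1, int(fallback_frac * n_neg))
    select = pos.copy()
    if k and n_neg:
        neg_losses = np.where(pos, -np.inf, nll)
        flat = neg_losses.reshape(-1)
        idx = np.argpartition(flat, -k)[-k:]
        sel_flat = select.reshape(-1)
        sel_flat[idx] = True
    return nc.softmax_cross_entropy(logits, targets, select=select)


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate for ``epoch`` in [0, cfg.epochs)."""
    if not 0 <= epoch <= cfg.epochs:
        raise TrainingError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    if cfg.lr_schedule_mode == "literal":
        return cfg.initial_lr * 0.1**epoch
    return cfg.initial_lr * 0.1 ** (epoch / cfg.epochs)


def _deepmedic_epoch(net, subjects, cfg, rng, lr, opt):
    dm_cfg = net.cfg
    normals, lows, tgts = [], [], []
    for sub in subjects:
        centers = sample_balanced_centers(sub.labels, cfg.patches_per_subject,
                                          rng, sub.brain_mask)
        for c in centers:
            normal, low, tslc = extract_patch_pair(sub.inputs, tuple(c), dm_cfg)
            tgt = np.zeros((dm_cfg.out_patch,) * 3, dtype=np.int64)
            src = tuple(slice(max(s.start, 0), min(s.stop, dim))
                        for s, dim in zip(tslc, sub.labels.shape))
            dst = tuple(slice(s2.start - s.start, s2.stop - s.start)
                        for s, s2 in zip(tslc, src))
            tgt[dst] = sub.labels[src]
            if cfg.augmentation:
                n_img = 4  # noise on modality channels only, not atlas masks
                normal, low, tgt = augment(
                    [normal, low, tgt], rng, image_channels=(n_img, n_img, 0),
                    noise_sd=cfg.augment_noise_sd)
            normals.append(normal)
            lows.append(low)
            tgts.append(tgt)
    order = rng.permutation(len(normals))
    losses = []
    for start in range(0, len(order), cfg.batch_size):
        sel = order[start:start + cfg.batch_size]
        xb = np.stack([normals[i] for i in sel])
        lb = np.stack([lows[i] for i in sel])
        tb = np.stack([tgts[i] for i in sel]).astype(np.int64)
        # map label values to class indices (identity for class order 0..4)
        logits = net.forward(xb, lb, train=True)
        loss, dlog = nc.softmax_cross_entropy(logits, tb)
        opt.zero_grad()
        net.backward(dlog)
        opt.step(lr)
        losses.append(loss)
    return float(np.mean(losses))


def _unet_epoch(net, subjects, cfg, rng, lr, opt):
    losses = []
    for sub in subjects:
        side = min(cfg.crop_size, *sub.labels.shape)
        side -= side % net.cfg.divisor
        lo = [rng.integers(0, dim - side + 1) for dim in sub.labels.shape]
        slc = tuple(slice(l, l + side) for l in lo)
        x = sub.inputs[(slice(None),) + slc][None]
        t = sub.labels[slc][None].astype(np.int64)
        logits = net.forward(x, train=True)
        loss, dlog = hard_negative_ce_loss(logits, t, ratio=cfg.hard_negative_ratio)
        opt.zero_grad()
        net.backward(dlog)
        opt.step(lr)
        losses.append(loss)
    return float(np.mean(losses))


def train_model(subjects: Sequence[SubjectData] | dict | str | Path,
                model_cfg: DeepMedicConfig | UNet3DConfig,
                cfg: TrainConfig,
                log_path: str | Path | None = None):
    """Train one network; returns ``(net, log)`` where ``log`` is a list of
    per-epoch records ``{"epoch", "lr", "loss"}``.

    ``subjects`` may be preprocessed :class:`SubjectData`, a phantom dataset
    manifest (dict or path), or a callable ``epoch -> list[SubjectData]``
    supplying fresh subjects every epoch (streaming regime, e.g. unlimited
    synthetic data).  Aborts with epoch/batch context if the loss goes
    non-finite.
    """
    provider = None
    if callable(subjects):
        provider = subjects
        subjects = provider(0)
    elif not isinstance(subjects, (list, tuple)):
        fuse = model_cfg.in_channels > 4
        subjects = load_manifest_subjects(subjects, fuse_atlas=fuse)
    if not subjects:
        raise TrainingError("no training subjects")
    c0 = subjects[0].inputs.shape[0]
    if c0 != model_cfg.in_channels:
        raise TrainingError(
            f"model expects {model_cfg.in_channels} input channels but "
            f"subjects have {c0}")
    rng = np.random.default_rng(cfg.seed)
    if cfg.model_kind == "deepmedic":
        net = build_deepmedic(model_cfg, seed=cfg.seed)
        epoch_fn = _deepmedic_epoch
    else:
        net = build_unet3d(model_cfg, seed=cfg.seed)
        epoch_fn = _unet_epoch
    opt = nc.AdamAMSGrad(net.param_layers(), lr=cfg.initial_lr,
                         weight_decay=cfg.weight_decay)
    log: list[dict] = []
    fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(cfg.epochs):
            if provider is not None and epoch > 0:
                subjects = provider(epoch)
            lr = lr_at_epoch(cfg, epoch)
            loss = epoch_fn(net, subjects, cfg, rng, lr, opt)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch} (lr={lr:.3g})")
            rec = {"epoch": epoch, "lr": lr, "loss": loss}
            log.append(rec)
            if fh:
                fh.write(json.dumps(rec) + "\n")
    finally:
        if fh:
            fh.close()
    return net, log


def epochs_to_threshold(log: Sequence[dict], threshold: float) -> int:
    """First epoch (0-based) whose mean loss is <= threshold; ``len(log)``
    if the run never reached it."""
    for rec in log:
        if rec["loss"] <= threshold:
            return rec["epoch"]
    return len(log)
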