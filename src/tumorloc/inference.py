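"""Whole-volume prediction from trained networks.

The dual-path patch CNN predicts 9^3 output windows tiled with step 9 over
the brain bounding box (final windows shifted flush to the edge, overlaps
averaged in probability space); the encoder-decoder CNN takes the whole
padded volume in one forward pass.  Voxels outside the brain mask are forced
to background in both cases.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nncore as nc
from .atlas import FusedInput
from .labels import LEGACY
from .networks import extract_patch_pair
from .volume_io import LabelVolume


@dataclasses.dataclass
class SubjectPrediction:
    """Per-voxel class probabilities plus their argmax label volume."""

    prob: np.ndarray                # (n_classes, X, Y, Z)
    argmax_labels: LabelVolume
    provenance: dict = dataclasses.field(default_factory=dict)


def _labels_from_prob(prob: np.ndarray) -> LabelVolume:
    lab = prob.argmax(axis=0).astype(np.int16)
    lab[lab == LEGACY] = 0  # legacy channel is never a real region
    return LabelVolume(data=lab)


def _window_starts(lo: int, hi: int, step: int) -> list[int]:
    """Tile [lo, hi) with ``step``-sized windows; the last window is shifted
    flush to the edge when the extent is not a multiple of the step."""
    if hi - lo <= step:
        return [max(0, min(lo, hi - step))]
    starts = list(range(lo, hi - step + 1, step))
    if starts[-1] + step < hi:
        starts.append(hi - step)
    return starts


def sliding_window_predict(volume: FusedInput, model, batch_size: int = 64
                           ) -> SubjectPrediction:
    """Tile the brain bounding box with the model's output windows
    (step = window side), averaging overlapping probabilities."""
    cfg = model.cfg
    step = cfg.out_patch
    mask = volume.brain_mask
    shape = mask.shape
    bbox = [(int(idx.min()), int(idx.max()) + 1)
            for idx in np.nonzero(mask)] if mask.any() else [(0, s) for s in shape]
    starts = [_window_starts(lo, min(hi, shape[ax]), step)
              for ax, (lo, hi) in enumerate(bbox)]
    centers = [(a + step // 2, b + step // 2, c + step // 2)
               for a in starts[0] for b in starts[1] for c in starts[2]]

    prob_sum = np.zeros((cfg.n_classes,) + shape, dtype=np.float64)
    count = np.zeros(shape, dtype=np.int32)
    for i0 in range(0, len(centers), batch_size):
        chunk = centers[i0:i0 + batch_size]
        normals, lows, tslcs = [], [], []
        for c in chunk:
            normal, low, tslc = extract_patch_pair(volume.data, c, cfg)
            normals.append(normal)
            lows.append(low)
            tslcs.append(tslc)
        logits = model.forward(np.stack(normals), np.stack(lows), train=False)
        probs = nc.softmax(logits, axis=1)
        for p, tslc in zip(probs, tslcs):
            # clip the window to the volume (flush-shifted windows stay inside)
            src = tuple(slice(max(s.start, 0), min(s.stop, dim))
                        for s, dim in zip(tslc, shape))
            win = tuple(slice(s2.start - s.start, s2.stop - s.start)
                        for s, s2 in zip(tslc, src))
            prob_sum[(slice(None),) + src] += p[(slice(None),) + win]
            count[src] += 1
    prob = np.zeros_like(prob_sum)
    covered = count > 0
    prob[:, covered] = prob_sum[:, covered] / count[covered]
    prob[0, ~covered] = 1.0
    prob[:, ~mask] = 0.0
    prob[0, ~mask] = 1.0
    return SubjectPrediction(
        prob=prob, argmax_labels=_labels_from_prob(prob),
        provenance={"model": model.kind, "seed": model.seed,
                    "mode": "sliding_window", "n_windows": len(centers),
                    "in_channels": cfg.in_channels})


def whole_volume_predict(volume: FusedInput, model) -> SubjectPrediction:
    """One forward pass over the (padded) full grid; padding is stripped from
    the output."""
    cfg = model.cfg
    x = volume.data
    shape = x.shape[1:]
    div = cfg.divisor
    pads = [(0, (-s) % div) for s in shape]
    xp = np.pad(x, [(0, 0)] + pads)[None]
    logits = model.forward(xp, train=False)[0]
    prob = nc.softmax(logits, axis=0)
    prob = prob[:, : shape[0], : shape[1], : shape[2]].astype(np.float64)
    mask = volume.brain_mask
    prob[:, ~mask] = 0.0
    prob[0, ~mask] = 1.0
    return SubjectPrediction(
        prob=prob, argmax_labels=_labels_from_prob(prob),
        provenance={"model": model.kind, "seed": model.seed,
                    "mode": "whole_volume", "in_channels": cfg.in_channels})


def predict(volume: FusedInput, model) -> SubjectPrediction:
    """Dispatch on architecture: window tiling for the dual-path patch CNN,
    one padded pass for the encoder-decoder."""
    if model.kind == "deepmedic":
        return sliding_window_predict(volume, model)
    return whole_volume_predict(volume, model)
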