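"""Segmentation evaluation: Dice similarity and 95th-percentile Hausdorff
distance over the three nested tumor regions (ET, WT, TC).

DSC = 2|G∩P| / (|G|+|P|); two empty masks score 1 by convention.  HD95 pools
the directed surface-to-surface Euclidean distances of both masks and takes
their 95th percentile (the alternative max-of-directed-95th-percentiles
convention is available via ``mode="max_directed"``).  Surfaces are mask
voxels with at least one face-adjacent (6-connectivity) background
neighbour.  With exactly one empty mask HD95 returns a sentinel, by default
the physical grid diagonal.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .ensemble import derive_region_masks
from .volume_io import LabelVolume

REGIONS = ("ET", "WT", "TC")

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def dice(gt: np.ndarray, pred: np.ndarray) -> float:
    """Dice similarity of two binary masks; 1.0 when both are empty."""
    gt = np.asarray(gt, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if gt.shape != pred.shape:
        raise ValueError("masks must share one grid")
    denom = int(gt.sum()) + int(pred.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((gt & pred).sum()) / denom


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >= 1 face-adjacent non-mask neighbour (the volume
    border counts as background)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~interior


def hd95(gt: np.ndarray, pred: np.ndarray,
         spacing: Sequence[float] = (1.0, 1.0, 1.0),
         mode: str = "pooled", empty_sentinel: float | None = None) -> float:
    """95th-percentile surface distance in physical units.

    ``mode="pooled"`` takes the percentile of both directed distance sets
    pooled together (symmetric by construction); ``mode="max_directed"``
    takes the max of the two directed 95th percentiles.
    """
    gt = np.asarray(gt, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if gt.shape != pred.shape:
        raise ValueError("masks must share one grid")
    if mode not in ("pooled", "max_directed"):
        raise ValueError(f"unknown mode {mode!r}")
    g_empty, p_empty = not gt.any(), not pred.any()
    if g_empty and p_empty:
        return 0.0
    if g_empty or p_empty:
        if empty_sentinel is None:
            empty_sentinel = float(np.linalg.norm(
                (np.asarray(gt.shape) - 1) * np.asarray(spacing, dtype=float)))
        return float(empty_sentinel)
    gs, ps = surface_voxels(gt), surface_voxels(pred)
    # distance of every voxel to the nearest surface voxel of the other mask
    d_to_p = ndimage.distance_transform_edt(~ps, sampling=spacing)
    d_to_g = ndimage.distance_transform_edt(~gs, sampling=spacing)
    d_gp = d_to_p[gs]   # gt surface -> pred surface
    d_pg = d_to_g[ps]   # pred surface -> gt surface
    if mode == "pooled":
        return float(np.percentile(np.concatenate([d_gp, d_pg]), 95))
    return float(max(np.percentile(d_gp, 95), np.percentile(d_pg, 95)))


def evaluate_subject(gt: LabelVolume, pred: LabelVolume,
                     spacing: Sequence[float] = (1.0, 1.0, 1.0),
                     hd95_mode: str = "pooled") -> dict[str, float]:
    """Region-wise DSC/HD95 of one subject (keys DSC_ET ... HD95_TC)."""
    g = derive_region_masks(gt)
    p = derive_region_masks(pred)
    out: dict[str, float] = {}
    for region in REGIONS:
        gm, pm = getattr(g, region), getattr(p, region)
        out[f"DSC_{region}"] = dice(gm, pm)
        out[f"HD95_{region}"] = hd95(gm, pm, spacing=spacing, mode=hd95_mode)
    return out


@dataclasses.dataclass
class MetricsReport:
    """Per-subject metrics plus cohort mean and standard deviation."""

    per_subject: pd.DataFrame    # index: subject id; columns DSC_*/HD95_*

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.per_subject.mean(),
                             "sd": self.per_subject.std(ddof=1)}).T

    def to_csv(self, path) -> None:
        df = pd.concat([self.per_subject, self.summary()])
        df.to_csv(path, index_label="subject")


def evaluate_cohort(pairs: Sequence[tuple[str, LabelVolume, LabelVolume]],
                    spacing: Sequence[float] = (1.0, 1.0, 1.0),
                    hd95_mode: str = "pooled") -> MetricsReport:
    """Evaluate (subject_id, ground truth, prediction) triples."""
    rows = {sid: evaluate_subject(gt, pred, spacing=spacing, hd95_mode=hd95_mode)
            for sid, gt, pred in pairs}
    return MetricsReport(per_subject=pd.DataFrame.from_dict(rows, orient="index"))
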