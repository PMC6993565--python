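"""Two-level ensemble: seed-averaged probability maps boosted by voxelwise
gradient-boosted fusion classifiers.

Level one averages the probability maps of seed replicas of one
architecture (arithmetic mean).  Level two concatenates the two averaged
5-class maps into 10-dimensional per-voxel feature vectors and fits XGBoost
classifiers in one of three ways:

* **TLMC** — one multi-class classifier over all labels;
* **TLBC** — a binary cascade model_WT (whole tumor vs background, all
  voxels), model_TC (tumor core vs rest-of-WT, trained on WT voxels only)
  and model_ET (enhancing vs rest-of-TC, trained on TC voxels only); at
  prediction time the second stage is gated by the arithmetic-mean WT mask
  (optionally by model_WT's own prediction);
* **TLFC** — model_WT and model_TC from the cascade plus the multi-class
  model for the necrosis/non-enhancing class, merged by priority
  NCR/NET > TC > WT > background.

Region convention: WT = edema + enhancing + necrosis/non-enhancing,
TC = enhancing + necrosis/non-enhancing, ET = enhancing.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage
from xgboost import XGBClassifier

from .labels import (EDEMA, ENHANCING_TUMOR, LEGACY, NECROSIS_NET,
                     N_CLASSES)
from .volume_io import LabelVolume


class EnsembleError(ValueError):
    pass


# ------------------------------------------------------------- level one


def mean_ensemble(preds: Sequence[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of probability maps: P = (1/n) sum_i p_i."""
    if len(preds) == 0:
        raise EnsembleError("need at least one probability map")
    shape = preds[0].shape
    for p in preds:
        if p.shape != shape:
            raise EnsembleError(f"probability map shapes differ: {p.shape} vs {shape}")
    return np.mean(np.stack([np.asarray(p, dtype=np.float64) for p in preds]), axis=0)


# ---------------------------------------------------------------- regions


@dataclasses.dataclass
class RegionMasks:
    """Nested evaluation regions: enhancing ⊆ core ⊆ whole tumor."""

    WT: np.ndarray
    TC: np.ndarray
    ET: np.ndarray

    def __post_init__(self) -> None:
        if (self.ET & ~self.TC).any() or (self.TC & ~self.WT).any():
            raise EnsembleError("region nesting ET ⊆ TC ⊆ WT violated")


def derive_region_masks(labels: LabelVolume | np.ndarray) -> RegionMasks:
    """WT = {edema, ET, NCR/NET}; TC = {ET, NCR/NET}; ET = {ET}."""
    lab = labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)
    known = {0, ENHANCING_TUMOR, EDEMA, NECROSIS_NET}
    bad = set(np.unique(lab)) - known
    if bad:
        raise EnsembleError(f"unknown labels {sorted(bad)}")
    et = lab == ENHANCING_TUMOR
    tc = et | (lab == NECROSIS_NET)
    wt = tc | (lab == EDEMA)
    return RegionMasks(WT=wt, TC=tc, ET=et)


# --------------------------------------------------------------- features


@dataclasses.dataclass
class SamplingPolicy:
    """Training-voxel selection: all lesion voxels, a dilated lesion border,
    and a uniform background subsample capped at ``background_cap_ratio``
    times the lesion count."""

    border_dilation: int = 3
    background_cap_ratio: float = 3.0
    seed: int = 0


@dataclasses.dataclass
class VoxelFeatureTable:
    """Per-voxel 10-dim features: 5-class mean map of ensemble A followed by
    the 5-class mean map of ensemble B."""

    features: np.ndarray          # (n_voxels, 10)
    coords: np.ndarray            # (n_voxels, 3)
    grid_shape: tuple[int, int, int]
    gt: np.ndarray | None = None  # (n_voxels,) labels in {0,1,2,4}

    def __post_init__(self) -> None:
        if self.features.shape[1] != 2 * N_CLASSES:
            raise EnsembleError(
                f"feature dimension {self.features.shape[1]} != {2 * N_CLASSES}")


def _check_maps(meanA: np.ndarray, meanB: np.ndarray) -> None:
    if meanA.shape != meanB.shape:
        raise EnsembleError("ensemble mean maps must share one grid")
    if meanA.shape[0] != N_CLASSES:
        raise EnsembleError(f"expected {N_CLASSES}-class maps, got {meanA.shape[0]}")


def build_feature_table(meanA: np.ndarray, meanB: np.ndarray,
                        gt: LabelVolume | np.ndarray | None = None,
                        sampling: SamplingPolicy | None = None,
                        voxel_mask: np.ndarray | None = None
                        ) -> VoxelFeatureTable:
    """Concatenate the two mean maps into per-voxel feature rows.

    Without ``sampling``/``voxel_mask`` every voxel becomes a row (prediction
    table).  With ground truth and a sampling policy, rows are the lesion
    voxels, their dilated border and a capped background subsample (training
    table).  ``voxel_mask`` restricts rows to an explicit voxel set.
    """
    _check_maps(meanA, meanB)
    shape = meanA.shape[1:]
    gt_arr = gt.data if isinstance(gt, LabelVolume) else gt
    if voxel_mask is not None:
        sel = np.asarray(voxel_mask, dtype=bool)
    elif sampling is not None:
        if gt_arr is None:
            raise EnsembleError("sampling policy requires ground truth")
        lesion = gt_arr != 0
        border = ndimage.binary_dilation(lesion, iterations=sampling.border_dilation)
        sel = border.copy()
        bg = ~border
        n_bg = int(bg.sum())
        cap = int(sampling.background_cap_ratio * max(int(lesion.sum()), 1))
        if n_bg > cap:
            rng = np.random.default_rng(sampling.seed)
            bg_idx = np.flatnonzero(bg.reshape(-1))
            keep = rng.choice(bg_idx, size=cap, replace=False)
            bg = np.zeros(bg.size, dtype=bool)
            bg[keep] = True
            bg = bg.reshape(shape)
        sel = sel | bg
    else:
        sel = np.ones(shape, dtype=bool)
    coords = np.argwhere(sel)
    fa = meanA[:, sel].T
    fb = meanB[:, sel].T
    feats = np.concatenate([fa, fb], axis=1).astype(np.float32)
    gt_rows = gt_arr[sel].astype(np.int64) if gt_arr is not None else None
    return VoxelFeatureTable(features=feats, coords=coords,
                             grid_shape=tuple(shape), gt=gt_rows)


# ------------------------------------------------------------- level two


@dataclasses.dataclass
class XGBParams:
    n_estimators: int = 300
    max_depth: int = 6
    learning_rate: float = 0.1
    seed: int = 0

    #: exact greedy split finding places thresholds midway between class
    #: clusters rather than at histogram bin edges, which generalizes better
    #: on the modest voxel tables the sampling policy produces
    tree_method: str = "exact"

    def classifier(self, **kw) -> XGBClassifier:
        return XGBClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            learning_rate=self.learning_rate, random_state=self.seed,
            n_jobs=1, tree_method=self.tree_method, verbosity=0, **kw)


@dataclasses.dataclass
class FusionModel:
    kind: str                           # "TLMC" | "TLBC" | "TLFC"
    classifiers: dict
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"TLMC": {"multiclass"},
                "TLBC": {"model_WT", "model_TC", "model_ET"},
                "TLFC": {"model_WT", "model_TC", "multiclass"}}
        if self.kind not in need:
            raise EnsembleError(f"unknown fusion kind {self.kind!r}")
        missing = need[self.kind] - set(self.classifiers)
        if missing:
            raise EnsembleError(f"{self.kind} missing classifiers {sorted(missing)}")


def _fit_multiclass(feats, labels, params: XGBParams):
    classes = np.unique(labels)
    if len(classes) < 2:
        raise EnsembleError("training table contains a single class")
    enc = {c: i for i, c in enumerate(classes)}
    y = np.vectorize(enc.get)(labels)
    clf = params.classifier(objective="multi:softprob", num_class=len(classes))
    clf.fit(feats, y)
    return {"clf": clf, "classes": classes}


def _fit_binary(feats, y, params: XGBParams, name: str):
    if len(np.unique(y)) < 2:
        raise EnsembleError(f"stratum for {name} contains a single class")
    clf = params.classifier(objective="binary:logistic")
    clf.fit(feats, y.astype(np.int64))
    return clf


def fit_tlmc(table: VoxelFeatureTable, params: XGBParams | None = None) -> FusionModel:
    """Multi-class second-level classifier (softmax objective)."""
    if table.gt is None:
        raise EnsembleError("training table needs ground truth")
    params = params or XGBParams()
    mc = _fit_multiclass(table.features, table.gt, params)
    return FusionModel(kind="TLMC", classifiers={"multiclass": mc},
                       metadata={"params": dataclasses.asdict(params),
                                 "n_rows": len(table.features)})


def fit_tlbc(table: VoxelFeatureTable, params: XGBParams | None = None) -> FusionModel:
    """Binary cascade: WT vs background on all rows, TC vs WT-rest on the
    ground-truth WT rows, ET vs TC-rest on the ground-truth TC rows."""
    if table.gt is None:
        raise EnsembleError("training table needs ground truth")
    params = params or XGBParams()
    regions = derive_region_masks_rows(table.gt)
    f = table.features
    clfs = {
        "model_WT": _fit_binary(f, regions["WT"], params, "model_WT"),
        "model_TC": _fit_binary(f[regions["WT"]], regions["TC"][regions["WT"]],
                                params, "model_TC"),
        "model_ET": _fit_binary(f[regions["TC"]], regions["ET"][regions["TC"]],
                                params, "model_ET"),
    }
    return FusionModel(kind="TLBC", classifiers=clfs,
                       metadata={"params": dataclasses.asdict(params),
                                 "n_rows": len(f)})


def fit_tlfc(table: VoxelFeatureTable, params: XGBParams | None = None) -> FusionModel:
    """Fusion model: the cascade's model_WT and model_TC plus the
    multi-class classifier (used for the NCR/NET class)."""
    if table.gt is None:
        raise EnsembleError("training table needs ground truth")
    params = params or XGBParams()
    regions = derive_region_masks_rows(table.gt)
    f = table.features
    clfs = {
        "model_WT": _fit_binary(f, regions["WT"], params, "model_WT"),
        "model_TC": _fit_binary(f[regions["WT"]], regions["TC"][regions["WT"]],
                                params, "model_TC"),
        "multiclass": _fit_multiclass(f, table.gt, params),
    }
    return FusionModel(kind="TLFC", classifiers=clfs,
                       metadata={"params": dataclasses.asdict(params),
                                 "n_rows": len(f)})


def derive_region_masks_rows(gt_rows: np.ndarray) -> dict[str, np.ndarray]:
    """Row-wise region membership for a flat ground-truth vector."""
    et = gt_rows == ENHANCING_TUMOR
    tc = et | (gt_rows == NECROSIS_NET)
    wt = tc | (gt_rows == EDEMA)
    return {"WT": wt, "TC": tc, "ET": et}


def _predict_multiclass(mc: dict, feats: np.ndarray) -> np.ndarray:
    pred = mc["clf"].predict(feats)
    lab = mc["classes"][pred]
    lab[lab == LEGACY] = 0
    return lab


def predict_tlmc(model: FusionModel, meanA: np.ndarray, meanB: np.ndarray
                 ) -> LabelVolume:
    """Per-voxel multi-class prediction mapped back to labels {0,1,2,4}."""
    table = build_feature_table(meanA, meanB)
    lab = _predict_multiclass(model.classifiers["multiclass"], table.features)
    return LabelVolume(data=lab.reshape(table.grid_shape).astype(np.int16))


def _binary_mask(clf, meanA, meanB, voxel_mask=None) -> np.ndarray:
    table = build_feature_table(meanA, meanB, voxel_mask=voxel_mask)
    out = np.zeros(table.grid_shape, dtype=bool)
    if len(table.features) == 0:
        return out
    pred = clf.predict(table.features).astype(bool)
    out[tuple(table.coords.T)] = pred
    return out


def predict_tlbc(model: FusionModel, meanA: np.ndarray, meanB: np.ndarray,
                 gate: np.ndarray | None = None) -> LabelVolume:
    """Cascade prediction.  ``gate`` is the whole-tumor mask restricting the
    second stage — by default the arithmetic-mean WT prediction should be
    passed; with ``gate=None`` the cascade self-gates on model_WT's output.
    """
    _check_maps(meanA, meanB)
    wt_hat = _binary_mask(model.classifiers["model_WT"], meanA, meanB)
    gate = wt_hat if gate is None else np.asarray(gate, dtype=bool)
    tc_hat = _binary_mask(model.classifiers["model_TC"], meanA, meanB,
                          voxel_mask=gate)
    et_hat = _binary_mask(model.classifiers["model_ET"], meanA, meanB,
                          voxel_mask=tc_hat)
    lab = np.zeros(meanA.shape[1:], dtype=np.int16)
    lab[wt_hat] = EDEMA
    lab[tc_hat] = NECROSIS_NET
    lab[et_hat] = ENHANCING_TUMOR
    return LabelVolume(data=lab)


def predict_tlfc(model: FusionModel, meanA: np.ndarray, meanB: np.ndarray,
                 gate: np.ndarray | None = None) -> LabelVolume:
    """Fusion prediction: WT and TC from the cascade, NCR/NET from the
    multi-class model, merged by priority."""
    _check_maps(meanA, meanB)
    wt_hat = _binary_mask(model.classifiers["model_WT"], meanA, meanB)
    gate = wt_hat if gate is None else np.asarray(gate, dtype=bool)
    tc_hat = _binary_mask(model.classifiers["model_TC"], meanA, meanB,
                          voxel_mask=gate)
    table = build_feature_table(meanA, meanB)
    mc_lab = _predict_multiclass(model.classifiers["multiclass"], table.features)
    ncr_hat = (mc_lab == NECROSIS_NET).reshape(table.grid_shape)
    background = ~(wt_hat | tc_hat | ncr_hat)
    return priority_merge(background, wt_hat, tc_hat, ncr_hat)


def priority_merge(background: np.ndarray, wt: np.ndarray, tc: np.ndarray,
                   ncrnet: np.ndarray) -> LabelVolume:
    """Merge claims with priority NCR/NET > TC > WT > background.

    A voxel claimed as both whole tumor and tumor core receives the tumor
    core outcome (enhancing-tumor label); NCR/NET claims beat everything.
    Order-independent and deterministic.
    """
    shapes = {a.shape for a in (background, wt, tc, ncrnet)}
    if len(shapes) != 1:
        raise EnsembleError("claim masks must share one grid")
    lab = np.zeros(wt.shape, dtype=np.int16)
    lab[np.asarray(wt, dtype=bool)] = EDEMA
    lab[np.asarray(tc, dtype=bool)] = ENHANCING_TUMOR
    lab[np.asarray(ncrnet, dtype=bool)] = NECROSIS_NET
    return LabelVolume(data=lab)
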