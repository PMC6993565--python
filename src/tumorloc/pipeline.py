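"""End-to-end pipeline: phantom dataset -> preprocessing/fusion -> training
(seed replicas of both architectures) -> whole-volume prediction ->
ensemble -> evaluation.

Every stage persists its artifacts under the run directory and is skipped on
re-run when the artifacts already exist; a resolved-config snapshot is
written next to the outputs so any stage is reproducible from disk.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
import numpy as np

from .atlas import parcel_lesion_distribution, ParcellationAtlas
from .ensemble import (SamplingPolicy, XGBParams, build_feature_table,
                       derive_region_masks, fit_tlbc, fit_tlfc, fit_tlmc,
                       mean_ensemble, predict_tlbc, predict_tlfc, predict_tlmc)
from .inference import predict as predict_volume
from .metrics import MetricsReport, evaluate_cohort
from .networks import DeepMedicConfig, UNet3DConfig, load_model, save_model
from .phantom import PhantomSpec, write_phantom_dataset
from .training import (SubjectData, TrainConfig, load_manifest_subjects,
                       train_model)
from .volume_io import LabelVolume, load_nifti


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (tiny-scale defaults)."""

    out_dir: str = "runs/demo"
    seed: int = 0
    n_subjects: int = 8
    n_heldout: int = 2
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    n_parcels: int = 21
    noise_sd: float = 10.0
    fuse_atlas: bool = True
    n_seeds: int = 3                      # seed replicas per architecture
    deepmedic_widths: tuple[int, ...] = (4, 4, 4, 4, 4, 4, 4, 4)
    deepmedic_head: int = 8
    deepmedic_epochs: int = 18
    deepmedic_batch: int = 16
    patches_per_subject: int = 16
    unet_depth: int = 3
    unet_base_width: int = 8
    unet_epochs: int = 36
    unet_crop: int = 32
    ensemble_method: str = "mean"          # mean | tlmc | tlbc | tlfc
    xgb_estimators: int = 100
    xgb_depth: int = 4
    n_folds: int = 0                       # 0 = plain train/held-out split
    fold: int = 0                          # evaluated fold when n_folds > 0

    def validate(self) -> None:
        errors = []
        if self.n_folds == 0 and self.n_heldout >= self.n_subjects:
            errors.append("n_heldout must be smaller than n_subjects")
        if self.ensemble_method not in ("mean", "tlmc", "tlbc", "tlfc"):
            errors.append(f"unknown ensemble_method {self.ensemble_method!r}")
        if self.n_seeds < 1:
            errors.append("n_seeds must be >= 1")
        if self.n_folds:
            if self.n_folds < 2 or self.n_folds > self.n_subjects:
                errors.append("n_folds must be in [2, n_subjects]")
            elif not 0 <= self.fold < self.n_folds:
                errors.append(f"fold must be in [0, {self.n_folds})")
        if errors:
            raise PipelineError("invalid config: " + "; ".join(errors))


def _subject_split(cfg: RunConfig) -> tuple[list[int], list[int]]:
    """Train/evaluation indices: the trailing ``n_heldout`` subjects, or a
    seeded fold assignment when cross-validation is configured."""
    if cfg.n_folds:
        rng = np.random.default_rng(cfg.seed)
        folds = np.array_split(rng.permutation(cfg.n_subjects), cfg.n_folds)
        test_idx = sorted(int(i) for i in folds[cfg.fold])
        train_idx = [i for i in range(cfg.n_subjects) if i not in set(test_idx)]
        return train_idx, test_idx
    train_idx = list(range(cfg.n_subjects - cfg.n_heldout))
    test_idx = list(range(cfg.n_subjects - cfg.n_heldout, cfg.n_subjects))
    return train_idx, test_idx


def stage_phantom(cfg: RunConfig, out: Path) -> dict:
    manifest_path = out / "phantom" / "manifest.json"
    if manifest_path.exists():
        return json.loads(manifest_path.read_text())
    spec = PhantomSpec(grid_shape=tuple(cfg.grid_shape), n_parcels=cfg.n_parcels,
                       noise_sd=cfg.noise_sd, seed=cfg.seed)
    return write_phantom_dataset(cfg.n_subjects, spec, out / "phantom")


def _model_cfgs(cfg: RunConfig, in_channels: int):
    dm = DeepMedicConfig(in_channels=in_channels,
                         conv_widths=tuple(cfg.deepmedic_widths),
                         head_width=cfg.deepmedic_head)
    un = UNet3DConfig(in_channels=in_channels, depth=cfg.unet_depth,
                      base_width=cfg.unet_base_width)
    return dm, un


def stage_train(cfg: RunConfig, out: Path, subjects: list[SubjectData]) -> dict[str, list[Path]]:
    train_idx, _ = _subject_split(cfg)
    train_subjects = [subjects[i] for i in train_idx]
    in_channels = subjects[0].inputs.shape[0]
    dm_cfg, un_cfg = _model_cfgs(cfg, in_channels)
    models: dict[str, list[Path]] = {"deepmedic": [], "unet": []}
    mdir = out / "models"
    mdir.mkdir(parents=True, exist_ok=True)
    for kind, model_cfg, epochs, batch in (
            ("deepmedic", dm_cfg, cfg.deepmedic_epochs, cfg.deepmedic_batch),
            ("unet", un_cfg, cfg.unet_epochs, 1)):
        for s in range(cfg.n_seeds):
            path = mdir / f"{kind}_seed{s}.bin"
            models[kind].append(path)
            if path.exists():
                continue
            tc = TrainConfig(model_kind=kind, epochs=epochs, batch_size=batch,
                             patches_per_subject=cfg.patches_per_subject,
                             crop_size=cfg.unet_crop, augmentation=(kind == "deepmedic"),
                             seed=cfg.seed * 1000 + s)
            net, _ = train_model(train_subjects, model_cfg, tc,
                                 log_path=mdir / f"{kind}_seed{s}.log.jsonl")
            save_model(net, path)
    return models


def stage_predict(cfg: RunConfig, out: Path, subjects: list[SubjectData],
                  models: dict[str, list[Path]]) -> None:
    pdir = out / "probs"
    pdir.mkdir(parents=True, exist_ok=True)
    for kind, paths in models.items():
        for mpath in paths:
            net = None
            for i, sub in enumerate(subjects):
                ppath = pdir / f"{sub.subject_id}_{mpath.stem}.npz"
                if ppath.exists():
                    continue
                if net is None:
                    net = load_model(mpath)
                fused = _as_fused(sub)
                pred = predict_volume(fused, net)
                np.savez_compressed(ppath, prob=pred.prob.astype(np.float32))


def _as_fused(sub: SubjectData):
    from .atlas import FusedInput
    return FusedInput(data=sub.inputs, atlas_labels=[], brain_mask=sub.brain_mask)


def _mean_maps(out: Path, sub: SubjectData, models: dict[str, list[Path]]):
    pdir = out / "probs"
    means = {}
    for kind, paths in models.items():
        maps = [np.load(pdir / f"{sub.subject_id}_{p.stem}.npz")["prob"].astype(np.float64)
                for p in paths]
        means[kind] = mean_ensemble(maps)
    return means["deepmedic"], means["unet"]


def stage_ensemble(cfg: RunConfig, out: Path, subjects: list[SubjectData],
                   models: dict[str, list[Path]]) -> dict[str, LabelVolume]:
    train_idx, test_idx = _subject_split(cfg)
    method = cfg.ensemble_method
    fusion = None
    if method != "mean":
        feats, gts = [], []
        for i in train_idx:
            sub = subjects[i]
            meanA, meanB = _mean_maps(out, sub, models)
            t = build_feature_table(meanA, meanB, gt=sub.labels,
                                    sampling=SamplingPolicy(seed=cfg.seed))
            feats.append(t.features)
            gts.append(t.gt)
        from .ensemble import VoxelFeatureTable
        table = VoxelFeatureTable(
            features=np.concatenate(feats), coords=np.zeros((sum(map(len, feats)), 3), dtype=int),
            grid_shape=tuple(cfg.grid_shape), gt=np.concatenate(gts))
        params = XGBParams(n_estimators=cfg.xgb_estimators,
                           max_depth=cfg.xgb_depth, seed=cfg.seed)
        fusion = {"tlmc": fit_tlmc, "tlbc": fit_tlbc, "tlfc": fit_tlfc}[method](table, params)
    preds: dict[str, LabelVolume] = {}
    for i in test_idx:
        sub = subjects[i]
        meanA, meanB = _mean_maps(out, sub, models)
        if method == "mean":
            overall = mean_ensemble([meanA, meanB])
            lab = overall.argmax(axis=0).astype(np.int16)
            lab[lab == 3] = 0
            preds[sub.subject_id] = LabelVolume(data=lab)
        else:
            gate = derive_region_masks(
                LabelVolume(data=_argmax_labels(mean_ensemble([meanA, meanB])))).WT
            if method == "tlmc":
                preds[sub.subject_id] = predict_tlmc(fusion, meanA, meanB)
            elif method == "tlbc":
                preds[sub.subject_id] = predict_tlbc(fusion, meanA, meanB, gate=gate)
            else:
                preds[sub.subject_id] = predict_tlfc(fusion, meanA, meanB, gate=gate)
    return preds


def _argmax_labels(prob: np.ndarray) -> np.ndarray:
    lab = prob.argmax(axis=0).astype(np.int16)
    lab[lab == 3] = 0
    return lab


def stage_evaluate(cfg: RunConfig, out: Path, subjects: list[SubjectData],
                   preds: dict[str, LabelVolume]) -> MetricsReport:
    pairs = []
    for sub in subjects:
        if sub.subject_id in preds:
            pairs.append((sub.subject_id, LabelVolume(data=sub.labels.astype(np.int16)),
                          preds[sub.subject_id]))
    report = evaluate_cohort(pairs)
    report.to_csv(out / "metrics.csv")
    return report


def stage_distribution(cfg: RunConfig, out: Path, manifest: dict) -> None:
    """Cohort lesion-per-parcel distribution over the atlas of the first
    subject (phantom atlases share the template role here)."""
    first = manifest["subjects"][0]
    grid, _ = load_nifti(first["files"]["atlas"])
    atl = ParcellationAtlas(
        label_grid=np.asarray(grid, dtype=np.int32),
        label_table={i + 1: f"parcel_{i + 1:02d}" for i in range(int(grid.max()))})
    labels = []
    for sub in manifest["subjects"]:
        lab, _ = load_nifti(sub["files"]["labels"])
        labels.append(LabelVolume(data=np.asarray(lab, dtype=np.int16)))
    dist = parcel_lesion_distribution(labels, atl)
    dist.to_csv(out / "lesion_distribution.csv")


def run_pipeline(cfg: RunConfig) -> MetricsReport:
    """Execute all stages in dependency order; returns the metrics report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(dataclasses.asdict(cfg), indent=2))
    manifest = stage_phantom(cfg, out)
    subjects = load_manifest_subjects(manifest, fuse_atlas=cfg.fuse_atlas)
    models = stage_train(cfg, out, subjects)
    stage_predict(cfg, out, subjects, models)
    preds = stage_ensemble(cfg, out, subjects, models)
    report = stage_evaluate(cfg, out, subjects, preds)
    stage_distribution(cfg, out, manifest)
    return report
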