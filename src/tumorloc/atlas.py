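"""Parcellation-atlas handling and location-information fusion.

A subcortical parcellation atlas (integer label grid + label table) supplies
location information to the patch-based networks: the subject-space atlas is
split into one binary mask per region and those masks are concatenated with
the four normalized modalities, giving a fused input of 4 + K channels
(25 for the 21-region Harvard-Oxford subcortical table).

The same module computes the cohort lesion-distribution statistic: for every
(parcel, lesion class) pair, the total lesion volume accumulated over
subjects divided by the parcel volume, plus per-class voxelwise heatmaps.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .labels import HARVARD_OXFORD_SUBCORTICAL, MODALITIES
from .volume_io import LabelVolume, MultimodalVolume, NormalizedVolume


class AtlasError(ValueError):
    pass


@dataclasses.dataclass
class ParcellationAtlas:
    """Integer-labeled brain parcellation.

    ``label_grid`` assigns every voxel a region id (0 = not covered);
    ``label_table`` maps region id -> region name; ``space_tag`` records
    whether the grid lives in template or subject space.
    """

    label_grid: np.ndarray
    label_table: dict[int, str] = dataclasses.field(
        default_factory=lambda: dict(HARVARD_OXFORD_SUBCORTICAL)
    )
    space_tag: str = "subject"

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid)
        if not np.issubdtype(self.label_grid.dtype, np.integer):
            raise AtlasError("label_grid must be integer-typed")
        present = set(np.unique(self.label_grid)) - {0}
        unknown = present - set(self.label_table)
        if unknown:
            raise AtlasError(f"grid labels {sorted(unknown)} missing from label_table")

    @property
    def labels(self) -> list[int]:
        """Table labels in ascending order (fixed channel order)."""
        return sorted(self.label_table)


def load_label_table(path: str | Path) -> dict[int, str]:
    """Read a two-column TSV ``label_id<TAB>region name`` into a label table."""
    table: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, name = line.partition("\t")
        table[int(key)] = name.strip()
    return table


def load_affine_matrix(path: str | Path) -> np.ndarray:
    """Read a whitespace-separated 4x4 voxel-to-voxel affine (FLIRT-style
    plain-text matrix)."""
    mat = np.loadtxt(path)
    if mat.shape != (4, 4):
        raise AtlasError(f"{path}: expected a 4x4 matrix, got {mat.shape}")
    return mat


def register_atlas_to_subject(
    atlas: ParcellationAtlas,
    subject: MultimodalVolume,
    transform: np.ndarray | Callable[[], np.ndarray] | None,
) -> ParcellationAtlas:
    """Resample a template-space atlas onto the subject grid.

    ``transform`` supplies a 4x4 voxel-to-voxel affine mapping template
    coordinates to subject coordinates (a matrix, or a zero-argument callable
    returning one).  Labels are resampled with nearest-neighbour
    interpolation; the label set can only shrink, never grow.
    """
    if transform is None:
        raise AtlasError(
            "no affine transform provider available; supply a 4x4 template-to-"
            "subject voxel affine, or pass an atlas already in subject space")
    mat = np.asarray(transform() if callable(transform) else transform, dtype=float)
    if mat.shape != (4, 4):
        raise AtlasError(f"transform must be 4x4, got {mat.shape}")
    inv = np.linalg.inv(mat)  # map output (subject) voxels back to template
    out = ndimage.affine_transform(
        atlas.label_grid, inv[:3, :3], offset=inv[:3, 3],
        output_shape=subject.shape, order=0, mode="constant", cval=0,
        prefilter=False)
    return ParcellationAtlas(label_grid=out.astype(atlas.label_grid.dtype),
                             label_table=dict(atlas.label_table),
                             space_tag="subject")


def split_atlas_masks(atlas: ParcellationAtlas) -> list[np.ndarray]:
    """One boolean mask per label-table entry, ascending label order.

    Masks for table labels absent from the grid are all-zero but still
    emitted, so downstream channel arity depends on the table alone.
    """
    return [atlas.label_grid == lab for lab in atlas.labels]


@dataclasses.dataclass
class FusedInput:
    """Network input stack: 4 normalized modalities + one binary channel per
    atlas label (ascending label order)."""

    data: np.ndarray  # (4 + K, X, Y, Z) float32
    atlas_labels: list[int]
    brain_mask: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def build_fused_input(norm: NormalizedVolume, atlas: ParcellationAtlas | None) -> FusedInput:
    """Concatenate modalities with per-region location channels.

    With ``atlas=None`` the stack holds the four modalities only (the
    location-free baseline input).
    """
    stack = [np.asarray(norm.channels[m], dtype=np.float32) for m in MODALITIES]
    labels: list[int] = []
    if atlas is not None:
        if atlas.label_grid.shape != norm.shape:
            raise AtlasError(
                f"atlas grid {atlas.label_grid.shape} does not match subject "
                f"grid {norm.shape}")
        if atlas.space_tag != "subject":
            raise AtlasError("atlas must be in subject space; register it first")
        labels = atlas.labels
        stack.extend(m.astype(np.float32) for m in split_atlas_masks(atlas))
    return FusedInput(data=np.stack(stack), atlas_labels=labels,
                      brain_mask=norm.brain_mask)


@dataclasses.dataclass
class ParcelLesionDistribution:
    """Per (parcel, lesion class) ratio of accumulated lesion volume to
    parcel volume; the label-0 row collects voxels outside every parcel."""

    ratios: pd.DataFrame        # index: parcel id (incl. 0); columns: lesion class
    parcel_volumes: pd.Series   # voxels per parcel

    def to_csv(self, path: str | Path) -> None:
        self.ratios.to_csv(path)


def parcel_lesion_distribution(
    labels: Sequence[LabelVolume], atlas: ParcellationAtlas,
    lesion_classes: Sequence[int] = (1, 2, 4),
) -> ParcelLesionDistribution:
    """Lesion load per parcel: sum of class-c voxels inside parcel p over all
    subjects, divided by |p|.  Ratios can exceed 1 for multi-subject cohorts
    since lesion volume accumulates while the parcel volume does not."""
    grid = atlas.label_grid
    parcels = [0] + atlas.labels
    vol = {}
    for p in parcels:
        vol[p] = int((grid == p).sum())
        if p != 0 and vol[p] == 0:
            raise AtlasError(f"parcel {p} ({atlas.label_table[p]}) is empty")
    counts = {p: {c: 0 for c in lesion_classes} for p in parcels}
    for lv in labels:
        if lv.shape != grid.shape:
            raise AtlasError("label volume grid does not match atlas grid")
        for c in lesion_classes:
            cmask = lv.data == c
            ids, cnt = np.unique(grid[cmask], return_counts=True)
            for i, n in zip(ids, cnt):
                counts[int(i)][c] += int(n)
    rows = {}
    for p in parcels:
        rows[p] = {c: (counts[p][c] / vol[p] if vol[p] > 0 else 0.0)
                   for c in lesion_classes}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "parcel"
    return ParcelLesionDistribution(
        ratios=df, parcel_volumes=pd.Series(vol, name="voxels").sort_index())


def lesion_heatmap(labels: Sequence[LabelVolume], lesion_class: int) -> np.ndarray:
    """Voxelwise count of subjects whose class mask covers each voxel."""
    if not labels:
        raise AtlasError("need at least one label volume")
    shape = labels[0].shape
    heat = np.zeros(shape, dtype=np.int64)
    for lv in labels:
        if lv.shape != shape:
            raise AtlasError("label volumes must share one grid")
        heat += (lv.data == lesion_class).astype(np.int64)
    return heat
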