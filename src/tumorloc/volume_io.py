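"""NIfTI volume containers, loading, and intensity preprocessing.

Multimodal subjects are four co-registered, skull-stripped scalar volumes
(T1, T1Gd, T2, FLAIR) on one grid.  Preprocessing clips each modality at the
(0.2, 99.8) percentiles of its non-zero voxels and z-scores it with the mean
and standard deviation of the voxels inside the brain, so every channel has
in-brain mean 0 and standard deviation 1; voxels outside the brain mask are
exactly 0.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .labels import DEFAULT_LABEL_SEMANTICS, MODALITIES


class VolumeError(ValueError):
    """Raised on geometric or intensity inconsistencies in input volumes."""


@dataclasses.dataclass
class MultimodalVolume:
    """Four modality grids plus brain mask and geometry.

    ``channels`` maps modality name -> 3D float array; all channels share one
    shape.  ``brain_mask`` is boolean; a valid subject has a non-empty mask.
    """

    channels: dict[str, np.ndarray]
    brain_mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        shapes = {k: v.shape for k, v in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise VolumeError(f"channel shapes differ: {shapes}")
        if self.brain_mask.shape != self.shape:
            raise VolumeError("brain_mask shape does not match channels")
        if not self.brain_mask.any():
            raise VolumeError("brain_mask is empty: no non-zero voxels in any modality")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    def stack(self) -> np.ndarray:
        """Channels as a (4, X, Y, Z) array in canonical modality order."""
        return np.stack([self.channels[m] for m in MODALITIES])


@dataclasses.dataclass
class NormalizedVolume(MultimodalVolume):
    """A MultimodalVolume after clipping + z-scoring, with the per-channel
    (clip_low, clip_high, mu, sigma) actually applied."""

    norm_params: dict[str, tuple[float, float, float, float]] = dataclasses.field(
        default_factory=dict
    )


@dataclasses.dataclass
class LabelVolume:
    """Integer lesion labels on a 3D grid, values restricted to {0,1,2,4}."""

    data: np.ndarray
    label_semantics: Mapping[int, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LABEL_SEMANTICS)
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise VolumeError("label volume must be integer-typed")
        bad = set(np.unique(self.data)) - set(self.label_semantics)
        if bad:
            raise VolumeError(f"labels {sorted(bad)} outside configured set "
                              f"{sorted(self.label_semantics)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def save_nifti(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine); raises VolumeError naming the path on failure."""
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such file: {path}")
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def load_subject(paths: Mapping[str, str | Path]) -> MultimodalVolume:
    """Load the four modality files of one subject.

    ``paths`` maps each modality in :data:`~tumorloc.labels.MODALITIES` to a
    NIfTI file.  All files must agree in shape and affine; the brain mask is
    the union of non-zero voxels across modalities.
    """
    missing = [m for m in MODALITIES if m not in paths]
    if missing:
        raise VolumeError(f"missing modalities: {missing}")
    channels: dict[str, np.ndarray] = {}
    ref_shape = ref_affine = None
    ref_name = None
    for m in MODALITIES:
        data, affine = load_nifti(paths[m])
        data = np.asarray(data, dtype=np.float64)
        if ref_shape is None:
            ref_shape, ref_affine, ref_name = data.shape, affine, str(paths[m])
        else:
            if data.shape != ref_shape:
                raise VolumeError(
                    f"shape mismatch: {paths[m]} has {data.shape}, "
                    f"{ref_name} has {ref_shape}")
            if not np.allclose(affine, ref_affine, atol=1e-4):
                raise VolumeError(f"affine mismatch: {paths[m]} vs {ref_name}")
        channels[m] = data
    mask = np.zeros(ref_shape, dtype=bool)
    for arr in channels.values():
        mask |= arr != 0
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(ref_affine))
    return MultimodalVolume(channels=channels, brain_mask=mask,
                            spacing=spacing, affine=ref_affine)


def clip_and_normalize(v: MultimodalVolume, p_low: float = 0.2,
                       p_high: float = 99.8) -> NormalizedVolume:
    """Percentile-clip and z-score each modality independently.

    Clipping bounds are the ``p_low``/``p_high`` percentiles (linear
    interpolation between order statistics) of the channel's *non-zero*
    voxels; the mean and standard deviation are computed over *brain-mask*
    voxels of the clipped channel.  Output voxels outside the brain mask are
    exactly 0.

    Raises :class:`VolumeError` when a channel is constant inside the brain
    (sigma = 0).
    """
    out: dict[str, np.ndarray] = {}
    params: dict[str, tuple[float, float, float, float]] = {}
    mask = v.brain_mask
    for name, arr in v.channels.items():
        nz = arr[arr != 0]
        if nz.size == 0:
            raise VolumeError(f"channel {name!r} is all zero")
        lo = float(np.percentile(nz, p_low))
        hi = float(np.percentile(nz, p_high))
        clipped = np.clip(arr, lo, hi)
        mu = float(clipped[mask].mean())
        sigma = float(clipped[mask].std())
        if sigma == 0.0:
            raise VolumeError(f"channel {name!r} constant inside brain (sigma=0)")
        z = (clipped - mu) / sigma
        z[~mask] = 0.0
        out[name] = z
        params[name] = (lo, hi, mu, sigma)
    return NormalizedVolume(channels=out, brain_mask=mask.copy(),
                            spacing=v.spacing, affine=v.affine.copy(),
                            norm_params=params)
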