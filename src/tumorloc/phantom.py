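"""Synthetic 3D phantom subjects for end-to-end testing without data access.

Each phantom emulates the structure of a multimodal glioma study subject:

* an ellipsoidal brain inside the grid, zero intensity outside;
* a parcellation of the brain into ``n_parcels`` regions (Voronoi cells of
  uniformly sampled in-brain points), label 0 outside the brain;
* a nested lesion — an outer edema ellipsoid containing an enhancing-tumor
  shell around a necrotic core — seeded in a parcel drawn from a per-parcel
  prior, so that location carries real information about lesion placement;
* per-modality intensities from a contrast table (edema bright on FLAIR/T2,
  enhancing tumor bright on T1Gd, necrosis dark on T1/T1Gd) plus Gaussian
  noise, drawn on the raw intensity scale so that percentile clipping and
  z-scoring downstream are exercised non-trivially.

The generator is bit-deterministic in (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .atlas import ParcellationAtlas
from .labels import EDEMA, ENHANCING_TUMOR, MODALITIES, NECROSIS_NET
from .volume_io import LabelVolume, MultimodalVolume, save_nifti


class PhantomError(ValueError):
    pass


#: mean raw intensity per modality for each tissue class
DEFAULT_CONTRAST: dict[str, dict[str | int, float]] = {
    "t1":    {"background": 0.0, "brain": 100.0, EDEMA: 90.0,  NECROSIS_NET: 70.0, ENHANCING_TUMOR: 110.0},
    "t1gd":  {"background": 0.0, "brain": 100.0, EDEMA: 90.0,  NECROSIS_NET: 60.0, ENHANCING_TUMOR: 160.0},
    "t2":    {"background": 0.0, "brain": 100.0, EDEMA: 145.0, NECROSIS_NET: 125.0, ENHANCING_TUMOR: 115.0},
    "flair": {"background": 0.0, "brain": 100.0, EDEMA: 155.0, NECROSIS_NET: 120.0, ENHANCING_TUMOR: 125.0},
}


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    ``lesion_prior`` gives the per-parcel probability weight of seeding the
    lesion there (values in [0, 1]; all zero means no lesion).  ``noise_sd``
    is the Gaussian intensity noise inside the brain, in raw intensity units.
    ``lesion_radius_frac`` bounds the whole-tumor radius as a fraction of the
    smallest grid dimension.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    n_parcels: int = 21
    lesion_prior: np.ndarray | None = None
    contrast_table: dict[str, dict[str | int, float]] = dataclasses.field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_CONTRAST.items()})
    noise_sd: float = 10.0
    lesion_radius_frac: tuple[float, float] = (0.16, 0.24)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 16 for s in self.grid_shape):
            raise PhantomError(f"grid_shape entries must be >= 16, got {self.grid_shape}")
        if self.n_parcels < 1:
            raise PhantomError("n_parcels must be >= 1")
        if self.lesion_prior is None:
            self.lesion_prior = np.full(self.n_parcels, 1.0 / self.n_parcels)
        self.lesion_prior = np.asarray(self.lesion_prior, dtype=float)
        if self.lesion_prior.shape != (self.n_parcels,):
            raise PhantomError("lesion_prior must have one entry per parcel")
        if ((self.lesion_prior < 0) | (self.lesion_prior > 1)).any():
            raise PhantomError("lesion_prior entries must lie in [0, 1]")
        for m in MODALITIES:
            if m not in self.contrast_table:
                raise PhantomError(f"contrast_table missing modality {m!r}")
        lo, hi = self.lesion_radius_frac
        if not (0 < lo <= hi < 0.5):
            raise PhantomError("lesion_radius_frac must satisfy 0 < lo <= hi < 0.5")


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    c = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * np.array([0.42, 0.40, 0.38])
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    q = sum(((g - ci) / ai) ** 2 for g, ci, ai in zip(grids, c, semi))
    return q <= 1.0


def _voronoi_parcellation(mask: np.ndarray, n_parcels: int,
                          rng: np.random.Generator) -> np.ndarray:
    coords = np.argwhere(mask)
    if len(coords) < n_parcels:
        raise PhantomError("brain too small for the requested parcel count")
    idx = rng.choice(len(coords), size=n_parcels, replace=False)
    seeds = coords[idx]
    tree = cKDTree(seeds)
    _, nearest = tree.query(coords, k=1)
    grid = np.zeros(mask.shape, dtype=np.int32)
    grid[tuple(coords.T)] = nearest + 1  # labels 1..n_parcels
    return grid


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


_MIN_RADIUS = 6.0  # voxels; smallest whole-tumor radius with all three shells


def _place_lesion(parcel_grid: np.ndarray, brain: np.ndarray,
                  spec: PhantomSpec, rng: np.random.Generator
                  ) -> tuple[np.ndarray, dict]:
    """Draw a seed parcel from the prior, place a nested three-shell lesion
    around a seed voxel of that parcel, return (label grid, info)."""
    labels = np.zeros(brain.shape, dtype=np.int16)
    prior = spec.lesion_prior
    total = prior.sum()
    if total == 0:
        return labels, {"seed_parcel": None}
    parcel = int(rng.choice(spec.n_parcels, p=prior / total)) + 1

    edt = ndimage.distance_transform_edt(brain)
    lo, hi = spec.lesion_radius_frac
    if lo * min(spec.grid_shape) > 0.95 * float(edt.max()):
        raise PhantomError(
            f"lesion larger than brain: smallest requested radius "
            f"{lo * min(spec.grid_shape):.1f} voxels exceeds the maximum "
            f"brain depth {edt.max():.1f}")
    r_wt = float(rng.uniform(lo, hi) * min(spec.grid_shape))

    eligible = np.argwhere((parcel_grid == parcel) & (edt >= _MIN_RADIUS))
    if len(eligible) == 0:
        cand = np.argwhere(parcel_grid == parcel)
        best = cand[np.argmax(edt[tuple(cand.T)])]
        if edt[tuple(best)] < 3.0:
            raise PhantomError(
                f"lesion cannot fit inside the brain: parcel {parcel} has no "
                f"voxel deeper than 3 voxels from the brain boundary")
        seed_vox = best
    else:
        seed_vox = eligible[rng.integers(len(eligible))]
    depth = float(edt[tuple(seed_vox)])
    # keep the lesion strictly inside the brain; refuse degenerate shrinkage
    r_eff = min(r_wt, 0.95 * depth)
    if r_eff < 3.0:
        raise PhantomError(
            f"lesion of radius {r_wt:.1f} voxels larger than the brain allows "
            f"at parcel {parcel} (max depth {depth:.1f})")

    rot = _random_rotation(rng)
    a_wt = r_eff * rng.uniform(0.85, 1.15, size=3)
    a_wt *= min(1.0, 0.95 * depth / a_wt.max())
    a_et = a_wt * rng.uniform(0.55, 0.68)
    a_ncr = a_et * rng.uniform(0.5, 0.65)

    grids = np.ogrid[: brain.shape[0], : brain.shape[1], : brain.shape[2]]
    rel = [np.asarray(g - s, dtype=np.float64) for g, s in zip(grids, seed_vox)]
    # rotated coordinates u = R^T (x - seed), broadcast over the grid
    u = [rot[0, i] * rel[0] + rot[1, i] * rel[1] + rot[2, i] * rel[2]
         for i in range(3)]

    def inside(a: np.ndarray) -> np.ndarray:
        return (u[0] / a[0]) ** 2 + (u[1] / a[1]) ** 2 + (u[2] / a[2]) ** 2 <= 1.0

    wt, et, ncr = inside(a_wt), inside(a_et), inside(a_ncr)
    if (wt & ~brain).any():
        raise PhantomError("lesion extends outside the brain (degenerate spec)")
    labels[wt] = EDEMA
    labels[et] = ENHANCING_TUMOR
    labels[ncr] = NECROSIS_NET
    info = {"seed_parcel": parcel, "seed_voxel": tuple(int(v) for v in seed_vox),
            "radius_wt": float(a_wt.max())}
    return labels, info


def generate_phantom(spec: PhantomSpec, *, return_info: bool = False):
    """Generate one phantom subject.

    Returns ``(MultimodalVolume, ParcellationAtlas, LabelVolume)``; with
    ``return_info=True`` a fourth dict describes lesion placement (seed
    parcel/voxel and radius).
    """
    rng = np.random.default_rng(spec.seed)
    brain = _brain_mask(spec.grid_shape)
    parcels = _voronoi_parcellation(brain, spec.n_parcels, rng)
    lesion, info = _place_lesion(parcels, brain, spec, rng)

    channels: dict[str, np.ndarray] = {}
    for m in MODALITIES:
        table = spec.contrast_table[m]
        vals = np.full(spec.grid_shape, float(table["background"]))
        vals[brain] = float(table["brain"])
        for cls in (EDEMA, ENHANCING_TUMOR, NECROSIS_NET):
            vals[lesion == cls] = float(table[cls])
        noise = rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        vals[brain] += noise[brain]
        # keep in-brain intensities strictly positive so the brain mask is
        # recoverable as the non-zero support
        vals[brain] = np.maximum(vals[brain], 1.0)
        channels[m] = vals

    mmv = MultimodalVolume(channels=channels, brain_mask=brain)
    atlas = ParcellationAtlas(
        label_grid=parcels,
        label_table={i + 1: f"parcel_{i + 1:02d}" for i in range(spec.n_parcels)},
        space_tag="subject")
    lv = LabelVolume(data=lesion)
    if return_info:
        return mmv, atlas, lv, info
    return mmv, atlas, lv


def subject_seed(base_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the dataset seed."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def write_phantom_dataset(n_subjects: int, spec: PhantomSpec,
                          out_dir: str | Path) -> dict:
    """Write ``n_subjects`` phantoms as NIfTI files plus a JSON manifest.

    Each subject gets six files (four modalities, atlas, labels); the
    manifest records every path and the per-subject seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = []
    for i in range(n_subjects):
        sid = f"sub-{i:03d}"
        s = dataclasses.replace(spec, seed=subject_seed(spec.seed, i))
        mmv, atl, lv = generate_phantom(s)
        files: dict[str, str] = {}
        try:
            for m in MODALITIES:
                p = out_dir / f"{sid}_{m}.nii.gz"
                save_nifti(mmv.channels[m].astype(np.float32), p)
                files[m] = str(p)
            p = out_dir / f"{sid}_atlas.nii.gz"
            save_nifti(atl.label_grid, p)
            files["atlas"] = str(p)
            p = out_dir / f"{sid}_labels.nii.gz"
            save_nifti(lv.data, p)
            files["labels"] = str(p)
        except OSError as e:
            raise PhantomError(f"failed writing {p}: {e}") from e
        subjects.append({"id": sid, "seed": s.seed, "files": files})
    manifest = {
        "n_subjects": n_subjects,
        "base_seed": spec.seed,
        "grid_shape": list(spec.grid_shape),
        "n_parcels": spec.n_parcels,
        "subjects": subjects,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
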