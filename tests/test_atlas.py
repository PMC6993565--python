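"""Atlas splitting, location-channel fusion, registration, and the
lesion-per-parcel distribution statistic."""

import numpy as np
import pytest

from tumorloc.atlas import (AtlasError, ParcellationAtlas, build_fused_input,
                            lesion_heatmap, load_affine_matrix,
                            parcel_lesion_distribution,
                            register_atlas_to_subject, split_atlas_masks)
from tumorloc.labels import HARVARD_OXFORD_SUBCORTICAL
from tumorloc.phantom import PhantomSpec, generate_phantom, subject_seed
from tumorloc.volume_io import LabelVolume, clip_and_normalize


def test_split_masks_partition_support(phantom_subject):
    _, atlas, _ = phantom_subject
    masks = split_atlas_masks(atlas)
    assert len(masks) == len(atlas.label_table)
    total = np.zeros(atlas.label_grid.shape, dtype=int)
    for m in masks:
        total += m.astype(int)
    # pairwise disjoint and union equals atlas support, exactly
    np.testing.assert_array_equal(total, (atlas.label_grid > 0).astype(int))


def test_split_masks_single_label():
    grid = np.zeros((6, 6, 6), dtype=np.int32)
    grid[2:4, 2:4, 2:4] = 1
    atlas = ParcellationAtlas(label_grid=grid, label_table={1: "only"})
    masks = split_atlas_masks(atlas)
    assert len(masks) == 1
    np.testing.assert_array_equal(masks[0], grid == 1)


def test_fused_input_has_25_channels_for_harvard_oxford(phantom_subject_48):
    mmv, atlas, _ = phantom_subject_48
    assert atlas.label_table.keys() == HARVARD_OXFORD_SUBCORTICAL.keys()
    fused = build_fused_input(clip_and_normalize(mmv), atlas)
    assert fused.n_channels == 25
    # atlas channels binary, at most one active per voxel
    atlas_block = fused.data[4:]
    assert set(np.unique(atlas_block)) <= {0.0, 1.0}
    assert atlas_block.sum(axis=0).max() <= 1.0


def test_fused_input_channel_count_follows_label_table(phantom_subject):
    mmv, atlas, _ = phantom_subject
    norm = clip_and_normalize(mmv)
    fused = build_fused_input(norm, atlas)
    assert fused.n_channels == 4 + len(atlas.label_table)
    # a table label absent from the grid still yields an (all-zero) channel
    bigger = ParcellationAtlas(label_grid=atlas.label_grid,
                               label_table={**atlas.label_table, 99: "ghost"})
    fused2 = build_fused_input(norm, bigger)
    assert fused2.n_channels == fused.n_channels + 1
    assert (fused2.data[-1] == 0).all()  # ascending order puts 99 last


def test_fused_channels_match_parcel_support(phantom_subject):
    mmv, atlas, _ = phantom_subject
    fused = build_fused_input(clip_and_normalize(mmv), atlas)
    for i, lab in enumerate(atlas.labels):
        np.testing.assert_array_equal(fused.data[4 + i] == 1,
                                      atlas.label_grid == lab)


def test_register_identity_and_translation(phantom_subject):
    mmv, atlas, _ = phantom_subject
    template = ParcellationAtlas(label_grid=atlas.label_grid,
                                 label_table=dict(atlas.label_table),
                                 space_tag="template")
    out = register_atlas_to_subject(template, mmv, np.eye(4))
    np.testing.assert_array_equal(out.label_grid, atlas.label_grid)
    assert out.space_tag == "subject"

    t = np.eye(4)
    t[:3, 3] = (2, -1, 3)  # integer-voxel translation
    shifted = register_atlas_to_subject(template, mmv, t)
    expect = np.zeros_like(atlas.label_grid)
    expect[2:, :-1, 3:] = atlas.label_grid[:-2, 1:, :-3]
    np.testing.assert_array_equal(shifted.label_grid, expect)


def test_register_roundtrip_interior_agreement(phantom_subject):
    """Random affine then its inverse recovers interior labels (>= 99%)."""
    mmv, atlas, _ = phantom_subject
    template = ParcellationAtlas(label_grid=atlas.label_grid,
                                 label_table=dict(atlas.label_table),
                                 space_tag="template")
    rng = np.random.default_rng(4)
    aff = np.eye(4)
    aff[:3, :3] += rng.normal(0, 0.02, size=(3, 3))
    aff[:3, 3] = rng.uniform(-1.5, 1.5, size=3)
    fwd = register_atlas_to_subject(template, mmv, aff)
    fwd_t = ParcellationAtlas(label_grid=fwd.label_grid,
                              label_table=dict(fwd.label_table),
                              space_tag="template")
    back = register_atlas_to_subject(fwd_t, mmv, np.linalg.inv(aff))
    interior = mmv.brain_mask.copy()
    from scipy import ndimage
    interior = ndimage.binary_erosion(interior, iterations=3)
    agree = (back.label_grid[interior] == atlas.label_grid[interior]).mean()
    assert agree >= 0.99
    assert set(np.unique(back.label_grid)) <= set(np.unique(atlas.label_grid))


def test_register_without_transform_raises(phantom_subject):
    mmv, atlas, _ = phantom_subject
    with pytest.raises(AtlasError, match="subject space"):
        register_atlas_to_subject(atlas, mmv, None)


def test_load_affine_matrix(tmp_path):
    mat = np.arange(16, dtype=float).reshape(4, 4)
    path = tmp_path / "xfm.mat"
    np.savetxt(path, mat)
    np.testing.assert_array_equal(load_affine_matrix(path), mat)
    np.savetxt(path, mat[:3])
    with pytest.raises(AtlasError):
        load_affine_matrix(path)


def test_parcel_distribution_analytic_cases():
    grid = np.zeros((6, 6, 6), dtype=np.int32)
    grid[:3] = 1
    grid[3:] = 3
    atlas = ParcellationAtlas(label_grid=grid, label_table={1: "a", 3: "b"})
    empty = LabelVolume(data=np.zeros_like(grid, dtype=np.int16))
    dist = parcel_lesion_distribution([empty], atlas)
    assert (dist.ratios.values == 0).all()

    # lesion class 2 exactly fills parcel 3
    lab = np.where(grid == 3, 2, 0).astype(np.int16)
    dist = parcel_lesion_distribution([LabelVolume(data=lab)], atlas)
    assert dist.ratios.loc[3, 2] == 1.0
    assert dist.ratios.loc[1, 2] == 0.0
    assert dist.ratios.drop(columns=[2]).values.sum() == 0


def test_parcel_distribution_matches_voxel_count_oracle():
    subjects, labels = [], []
    for i in range(5):
        spec = PhantomSpec(grid_shape=(32, 32, 32), n_parcels=5,
                           seed=subject_seed(50, i))
        _, atlas, lv = generate_phantom(spec)
        if i == 0:
            ref_atlas = atlas
        labels.append(LabelVolume(data=lv.data))
    dist = parcel_lesion_distribution(labels, ref_atlas)
    grid = ref_atlas.label_grid
    for p in [0] + ref_atlas.labels:
        vol = (grid == p).sum()
        for c in (1, 2, 4):
            brute = sum(((lv.data == c) & (grid == p)).sum() for lv in labels)
            expected = brute / vol if vol else 0.0
            assert dist.ratios.loc[p, c] == pytest.approx(expected)


def test_parcel_distribution_empty_parcel_raises():
    grid = np.zeros((4, 4, 4), dtype=np.int32)
    grid[:] = 1
    atlas = ParcellationAtlas(label_grid=grid, label_table={1: "a", 2: "missing"})
    lv = LabelVolume(data=np.zeros_like(grid, dtype=np.int16))
    with pytest.raises(AtlasError, match="missing"):
        parcel_lesion_distribution([lv], atlas)


def test_lesion_heatmap_counts():
    rng = np.random.default_rng(8)
    vols = []
    for _ in range(4):
        lab = (rng.random((10, 10, 10)) < 0.3).astype(np.int16) * 2
        vols.append(LabelVolume(data=lab))
    heat = lesion_heatmap(vols, 2)
    brute = sum((v.data == 2).astype(int) for v in vols)
    np.testing.assert_array_equal(heat, brute)
    assert heat.max() <= 4
    one = lesion_heatmap(vols[:1], 2)
    np.testing.assert_array_equal(one, (vols[0].data == 2).astype(int))
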