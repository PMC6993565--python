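"""Mean ensemble, region masks, fusion feature tables, XGBoost fusion
classifiers and priority merge."""

import numpy as np
import pytest

from tumorloc.ensemble import (EnsembleError, FusionModel, SamplingPolicy,
                               XGBParams, build_feature_table,
                               derive_region_masks, fit_tlbc, fit_tlfc,
                               fit_tlmc, mean_ensemble, predict_tlbc,
                               predict_tlfc, predict_tlmc, priority_merge)
from tumorloc.phantom import PhantomSpec, generate_phantom
from tumorloc.metrics import dice
from tumorloc.volume_io import LabelVolume
from conftest import make_complementary_maps

FAST_XGB = XGBParams(n_estimators=40, max_depth=4, seed=0)


def _random_prob_maps(n, shape, seed):
    rng = np.random.default_rng(seed)
    maps = []
    for _ in range(n):
        raw = rng.random((5,) + shape)
        maps.append(raw / raw.sum(axis=0, keepdims=True))
    return maps


def test_mean_ensemble_identity_closed_form_and_validity():
    maps = _random_prob_maps(3, (4, 4, 4), seed=0)
    np.testing.assert_array_equal(mean_ensemble([maps[0]]), maps[0])
    a = np.zeros((5, 1, 1, 1)); a[0] = 1
    b = np.zeros((5, 1, 1, 1)); b[1] = 1
    np.testing.assert_allclose(mean_ensemble([a, b])[:, 0, 0, 0],
                               [0.5, 0.5, 0, 0, 0])
    mean = mean_ensemble(maps)
    np.testing.assert_allclose(mean.sum(axis=0), 1.0, atol=1e-12)
    # permutation invariance
    np.testing.assert_allclose(mean, mean_ensemble(maps[::-1]))


def test_mean_ensemble_rejects_mismatched_grids():
    with pytest.raises(EnsembleError):
        mean_ensemble([np.zeros((5, 4, 4, 4)), np.zeros((5, 5, 4, 4))])


def test_region_masks_nesting_and_counts(phantom_subject):
    _, _, lv = phantom_subject
    rm = derive_region_masks(lv)
    assert not (rm.ET & ~rm.TC).any()
    assert not (rm.TC & ~rm.WT).any()
    lab = lv.data
    assert rm.WT.sum() == ((lab == 1).sum() + (lab == 2).sum() + (lab == 4).sum())
    assert rm.TC.sum() == ((lab == 1).sum() + (lab == 4).sum())
    assert rm.ET.sum() == (lab == 1).sum()


def test_region_masks_empty_and_unknown():
    empty = derive_region_masks(np.zeros((3, 3, 3), dtype=np.int16))
    assert empty.WT.sum() == 0
    with pytest.raises(EnsembleError):
        derive_region_masks(np.full((2, 2, 2), 7, dtype=np.int16))


def test_feature_table_layout():
    a = np.zeros((5, 1, 1, 1)); a[0] = 1
    b = np.zeros((5, 1, 1, 1)); b[4] = 1
    t = build_feature_table(a, b)
    assert t.features.shape == (1, 10)
    np.testing.assert_allclose(t.features[0], [1, 0, 0, 0, 0, 0, 0, 0, 0, 1])
    # each 5-block of a valid probability pair sums to 1
    maps = _random_prob_maps(2, (3, 3, 3), seed=1)
    t = build_feature_table(maps[0], maps[1])
    np.testing.assert_allclose(t.features[:, :5].sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_allclose(t.features[:, 5:].sum(axis=1), 1.0, atol=1e-6)


def test_feature_table_sampling_policy_caps_background(phantom_subject):
    _, _, lv = phantom_subject
    maps = _random_prob_maps(2, lv.shape, seed=2)
    pol = SamplingPolicy(border_dilation=2, background_cap_ratio=2.0, seed=3)
    t = build_feature_table(maps[0], maps[1], gt=lv, sampling=pol)
    from scipy import ndimage
    lesion = lv.data != 0
    border = ndimage.binary_dilation(lesion, iterations=2)
    n_lesion = int(lesion.sum())
    n_bg_rows = int((t.gt == 0).sum()) - int((border & (lv.data == 0)).sum())
    assert n_bg_rows <= 2 * n_lesion
    # all lesion voxels present
    assert int((t.gt != 0).sum()) == n_lesion


@pytest.fixture(scope="module")
def separable_fixture():
    """Training and held-out phantoms with complementary probability maps."""
    rng = np.random.default_rng(0)
    spec_tr = PhantomSpec(grid_shape=(32, 32, 32), n_parcels=4, seed=31)
    spec_te = PhantomSpec(grid_shape=(32, 32, 32), n_parcels=4, seed=32)
    _, _, lv_tr = generate_phantom(spec_tr)
    _, _, lv_te = generate_phantom(spec_te)
    a_tr, b_tr = make_complementary_maps(lv_tr.data, rng)
    a_te, b_te = make_complementary_maps(lv_te.data, rng)
    table = build_feature_table(a_tr, b_tr, gt=lv_tr,
                                sampling=SamplingPolicy(seed=1))
    return {"table": table, "lv_tr": lv_tr, "lv_te": lv_te,
            "a_te": a_te, "b_te": b_te}


def test_tlmc_fits_separable_fixture_and_is_deterministic(separable_fixture):
    f = separable_fixture
    model = fit_tlmc(f["table"], FAST_XGB)
    pred = predict_tlmc(model, f["a_te"], f["b_te"])
    assert set(np.unique(pred.data)) <= {0, 1, 2, 4}
    agree = (pred.data == f["lv_te"].data).mean()
    assert agree > 0.99
    model2 = fit_tlmc(f["table"], FAST_XGB)
    pred2 = predict_tlmc(model2, f["a_te"], f["b_te"])
    np.testing.assert_array_equal(pred.data, pred2.data)


def test_tlmc_near_chance_on_permuted_labels(separable_fixture):
    t = separable_fixture["table"]
    rng = np.random.default_rng(9)
    import dataclasses
    shuffled = dataclasses.replace(t, gt=rng.permutation(t.gt))
    model = fit_tlmc(shuffled, FAST_XGB)
    pred = model.classifiers["multiclass"]["clf"].predict(t.features)
    lab = model.classifiers["multiclass"]["classes"][pred]
    acc = (lab == t.gt).mean()
    # majority-class rate bounds chance performance on this table
    majority = max(np.bincount(np.searchsorted(np.unique(t.gt), t.gt))) / len(t.gt)
    assert acc < majority + 0.05


def test_tlmc_rejects_single_class_table():
    feats = np.random.default_rng(0).random((50, 10)).astype(np.float32)
    from tumorloc.ensemble import VoxelFeatureTable
    t = VoxelFeatureTable(features=feats, coords=np.zeros((50, 3), dtype=int),
                          grid_shape=(50, 1, 1), gt=np.zeros(50, dtype=np.int64))
    with pytest.raises(EnsembleError):
        fit_tlmc(t, FAST_XGB)


def test_tlbc_strata_and_cascade_recovery(separable_fixture):
    f = separable_fixture
    model = fit_tlbc(f["table"], FAST_XGB)
    assert set(model.classifiers) == {"model_WT", "model_TC", "model_ET"}
    gt_regions = derive_region_masks(f["lv_te"])
    gate = gt_regions.WT  # a clean whole-tumor gate
    pred = predict_tlbc(model, f["a_te"], f["b_te"], gate=gate)
    pr = derive_region_masks(pred)
    for region in ("WT", "TC", "ET"):
        assert dice(getattr(gt_regions, region), getattr(pr, region)) > 0.99
    # nesting invariant of the cascade output
    assert not (pr.ET & ~pr.TC).any() and not (pr.TC & ~pr.WT).any()


def test_tlbc_empty_gate_yields_no_core(separable_fixture):
    f = separable_fixture
    model = fit_tlbc(f["table"], FAST_XGB)
    gate = np.zeros(f["lv_te"].shape, dtype=bool)
    pred = predict_tlbc(model, f["a_te"], f["b_te"], gate=gate)
    assert not np.isin(pred.data, (1, 4)).any()


def test_tlfc_structure_and_recovery(separable_fixture):
    f = separable_fixture
    model = fit_tlfc(f["table"], FAST_XGB)
    assert set(model.classifiers) == {"model_WT", "model_TC", "multiclass"}
    gt_regions = derive_region_masks(f["lv_te"])
    pred = predict_tlfc(model, f["a_te"], f["b_te"], gate=gt_regions.WT)
    pr = derive_region_masks(pred)
    for region in ("WT", "TC", "ET"):
        assert dice(getattr(gt_regions, region), getattr(pr, region)) > 0.99


def test_fusion_model_validates_classifier_sets():
    with pytest.raises(EnsembleError):
        FusionModel(kind="TLBC", classifiers={"model_WT": None})
    with pytest.raises(EnsembleError):
        FusionModel(kind="WRONG", classifiers={})


def test_priority_merge_example_and_oracle():
    rng = np.random.default_rng(11)
    shape = (6, 6, 6)
    wt = rng.random(shape) < 0.5
    tc = rng.random(shape) < 0.3
    ncr = rng.random(shape) < 0.2
    bg = ~(wt | tc | ncr)
    merged = priority_merge(bg, wt, tc, ncr)
    # brute-force per-voxel max-priority scan
    for idx in np.ndindex(shape):
        if ncr[idx]:
            expect = 4
        elif tc[idx]:
            expect = 1
        elif wt[idx]:
            expect = 2
        else:
            expect = 0
        assert merged.data[idx] == expect
    # a voxel in both WT and TC resolves to the TC branch
    both = wt & tc & ~ncr
    if both.any():
        assert (merged.data[both] == 1).all()


def test_priority_merge_empty_claims():
    z = np.zeros((3, 3, 3), dtype=bool)
    merged = priority_merge(~z, z, z, z)
    assert (merged.data == 0).all()


def test_two_level_methods_beat_single_maps_on_some_region(separable_fixture):
    """On complementary-error maps every fused method improves on each
    single mean map for at least one region."""
    f = separable_fixture
    gt = derive_region_masks(f["lv_te"])
    gate = gt.WT

    def region_dices(lab):
        pr = derive_region_masks(lab)
        return {r: dice(getattr(gt, r), getattr(pr, r)) for r in ("WT", "TC", "ET")}

    def argmax_labels(prob):
        lab = prob.argmax(axis=0).astype(np.int16)
        lab[lab == 3] = 0
        return LabelVolume(data=lab)

    single_a = region_dices(argmax_labels(f["a_te"]))
    single_b = region_dices(argmax_labels(f["b_te"]))
    for fit, predict in ((fit_tlmc, lambda m: predict_tlmc(m, f["a_te"], f["b_te"])),
                         (fit_tlbc, lambda m: predict_tlbc(m, f["a_te"], f["b_te"], gate=gate)),
                         (fit_tlfc, lambda m: predict_tlfc(m, f["a_te"], f["b_te"], gate=gate))):
        fused = region_dices(predict(fit(f["table"], FAST_XGB)))
        assert any(fused[r] > single_a[r] for r in fused)
        assert any(fused[r] > single_b[r] for r in fused)


# ------------------------------------------------------- property tests

from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp


@settings(max_examples=30, deadline=None, derandomize=True)
@given(hnp.arrays(bool, (3, 4, 4, 4)))
def test_priority_merge_matches_max_priority_scan(claims):
    """priority_merge equals a per-voxel max-priority scan for arbitrary
    claim masks."""
    wt, tc, ncr = claims
    merged = priority_merge(~(wt | tc | ncr), wt, tc, ncr).data
    expect = np.zeros(wt.shape, dtype=np.int16)
    expect[wt] = 2
    expect[tc] = 1
    expect[ncr] = 4
    np.testing.assert_array_equal(merged, expect)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(1, 5), st.integers(0, 10**6))
def test_mean_ensemble_preserves_probability_simplex(n_models, seed):
    """The mean of valid probability maps is a valid probability map."""
    maps = _random_prob_maps(n_models, (3, 3, 3), seed=seed)
    mean = mean_ensemble(maps)
    assert (mean >= 0).all()
    np.testing.assert_allclose(mean.sum(axis=0), 1.0, atol=1e-12)
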