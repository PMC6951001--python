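import numpy as np
import pytest

import naive_reference as ref
from t1quant import (
    ImhCoreSpec,
    MapKind,
    MaskRole,
    MvoCoreSpec,
    MyoMask,
    NoiseSpec,
    ParametricMap,
    PhantomSpec,
    generate_phantom,
    place_remote_roi,
    segment_aar,
    segment_imh,
    segment_lge,
    segment_study,
)
from t1quant.segmentation import remote_stats, segment_mvo


def ring_mask(n=40, endo=8.0, epi=14.0):
    rr, cc = np.indices((n, n), dtype=float)
    r = np.hypot(rr - (n - 1) / 2, cc - (n - 1) / 2)
    return (r >= endo) & (r <= epi)


# --- remote ROI placement ---------------------------------------------------

def test_roi_sits_opposite_the_injury(noiseless_phantom):
    ph = noiseless_phantom
    roi = place_remote_roi(ph.myocardium, 90.0, 60.0, ph.t1.pixel_spacing)
    assert roi.n_pixels > 0
    assert not np.any(roi.grid & ph.truth_aar.grid)


def test_roi_disjoint_from_wide_injured_sector():
    from t1quant.core import AngularSector

    ph = generate_phantom(PhantomSpec(aar_sector=AngularSector(0.0, 90.0), seed=1))
    roi = place_remote_roi(ph.myocardium, 0.0, 60.0, ph.t1.pixel_spacing)
    assert not np.any(roi.grid & ph.truth_aar.grid)


def test_full_width_roi_degenerates_with_warning():
    myo = ring_mask()
    with pytest.warns(UserWarning):
        roi = place_remote_roi(myo, 90.0, 360.0)
    assert np.array_equal(roi.grid, myo)


def test_empty_ring_is_an_error():
    with pytest.raises(ValueError):
        place_remote_roi(np.zeros((10, 10), dtype=bool), 90.0, 60.0)


# --- AAR --------------------------------------------------------------------

def test_aar_threshold_is_mean_plus_two_sample_sd():
    myo = ring_mask()
    roi_grid = np.zeros_like(myo)
    rows, cols = np.where(myo)
    roi_grid[rows[:8], cols[:8]] = True
    z = np.array([-1.5, -0.5, 0.5, 1.5, -1.0, 1.0, -0.5, 0.5])
    z = (z - z.mean()) / z.std(ddof=1)
    t1 = np.full(myo.shape, 1000.0)
    t1[roi_grid] = 1200.0 + 50.0 * z
    _, thr = segment_aar(t1, myo, roi_grid)
    assert thr == pytest.approx(1300.0, abs=1e-9)


def test_aar_requires_two_roi_pixels():
    myo = ring_mask()
    roi = np.zeros_like(myo)
    roi[np.where(myo)[0][0], np.where(myo)[1][0]] = True
    with pytest.raises(ValueError):
        segment_aar(np.ones(myo.shape), myo, roi)


def test_noiseless_phantom_segmented_exactly(noiseless_full_phantom):
    ph = noiseless_full_phantom
    seg = segment_study(ph.t1, ph.t2star, ph.lge_si, ph.myocardium, injured_center=90.0)
    assert np.array_equal(seg.aar.grid, ph.truth_aar.grid)
    assert np.array_equal(seg.lge.grid, ph.truth_lge.grid)
    assert np.array_equal(seg.mvo.grid, ph.truth_mvo.grid)
    assert np.array_equal(seg.imh.grid, ph.truth_imh.grid)
    assert seg.aar_threshold_ms == pytest.approx(1200.0)
    assert seg.lge_threshold_si == pytest.approx(100.0)
    assert seg.imh_core_mean_t2star == pytest.approx(12.0)


def test_raising_the_multiplier_never_enlarges_the_aar():
    ph = generate_phantom(PhantomSpec(seed=21))
    myo = ph.myocardium
    roi = place_remote_roi(myo, 90.0, 60.0, ph.t1.pixel_spacing)
    prev, _ = segment_aar(ph.t1, myo, roi, multiplier=2.0)
    for mult in (2.5, 3.0, 4.0):
        cur, _ = segment_aar(ph.t1, myo, roi, multiplier=mult)
        assert not np.any(cur.grid & ~prev.grid)
        prev = cur


def test_hole_filling_recovers_enclosed_step_down_core():
    # a deep step-down drops the core below the 2SD threshold; the raw mask
    # excludes it, the filled mask restores it
    spec = PhantomSpec(
        noise_sd=NoiseSpec.none(),
        mvo_core=MvoCoreSpec(t1_offset=-350.0),
    )
    ph = generate_phantom(spec)
    seg_raw = segment_study(ph.t1, ph.t2star, ph.lge_si, ph.myocardium, injured_center=90.0)
    seg_fill = segment_study(
        ph.t1, ph.t2star, ph.lge_si, ph.myocardium, injured_center=90.0, fill_aar_holes=True
    )
    core = ph.truth_mvo.grid
    assert not np.any(seg_raw.aar.grid & core)
    assert np.array_equal(seg_fill.aar.grid, ph.truth_aar.grid)


# --- LGE / MVO ---------------------------------------------------------------

def test_lge_threshold_is_mean_plus_five_sd():
    myo = ring_mask()
    roi = np.zeros_like(myo)
    rows, cols = np.where(myo)
    roi[rows[:4], cols[:4]] = True
    z = np.array([-1.0, 1.0, -1.0, 1.0])
    z = (z - z.mean()) / z.std(ddof=1)
    si = np.zeros(myo.shape)
    si[roi] = 100.0 + 10.0 * z
    _, thr, _ = segment_lge(si, myo, roi)
    assert thr == pytest.approx(150.0, abs=1e-9)


def test_constructed_dark_hole_is_recovered_exactly():
    # 3 dark pixels walled in by enhanced tissue inside a small ring
    myo = ring_mask(n=30, endo=4.0, epi=12.0)
    si = np.full(myo.shape, 100.0)
    lge_block = np.zeros_like(myo)
    lge_block[8:21, 8:21] = True
    lge_block &= myo
    si[lge_block] = 300.0
    hole = np.zeros_like(myo)
    hole[9, 13:16] = True
    assert np.all(lge_block[9, 13:16])
    si[hole] = 50.0
    roi = myo & ~lge_block
    final, thr, mvo = segment_lge(si, myo, roi)
    assert np.array_equal(mvo.grid, hole)
    assert np.array_equal(final.grid, lge_block)


def test_no_subthreshold_pixels_means_empty_mvo():
    myo = ring_mask()
    si = np.where(myo, 300.0, 0.0)
    roi = np.zeros_like(myo)
    rows, cols = np.where(myo)
    roi[rows[:10], cols[:10]] = True
    si[roi] = 100.0
    stats = remote_stats(si, roi)
    initial = myo & (si > stats.threshold(5.0))
    mvo = segment_mvo(si, myo, initial, stats)
    assert not mvo.grid.any()


def test_non_enclosed_hypointensity_is_not_mvo(noiseless_full_phantom):
    # the remote myocardium is below the 2SD candidate threshold everywhere
    # but reaches the outside of the ring, so it is never MVO
    ph = noiseless_full_phantom
    seg = segment_study(ph.t1, ph.t2star, ph.lge_si, ph.myocardium, injured_center=90.0)
    remote = ph.myocardium.grid & ~ph.truth_aar.grid
    assert not np.any(seg.mvo.grid & remote)


def test_noisy_mvo_recovery_dice():
    dices = []
    for seed in range(20):
        ph = generate_phantom(PhantomSpec(mvo_core=MvoCoreSpec(), imh_core=ImhCoreSpec(), seed=seed))
        seg = segment_study(ph.t1, ph.t2star, ph.lge_si, ph.myocardium, injured_center=90.0)
        a, b = seg.mvo.grid, ph.truth_mvo.grid
        dices.append(2 * np.sum(a & b) / (np.sum(a) + np.sum(b)))
    assert min(dices) >= 0.8


# --- IMH ---------------------------------------------------------------------

def _uniform_aar_setup(core_value=None, core_slice=None):
    aar = np.zeros((30, 30), dtype=bool)
    aar[5:25, 5:25] = True
    t2 = np.full(aar.shape, 35.0)
    # a faint texture so the periphery SD is nonzero but small
    t2[::2, ::2] += 0.01
    if core_value is not None:
        t2[core_slice] = core_value
    return aar, t2


def test_uniform_t2star_has_no_imh():
    aar, t2 = _uniform_aar_setup()
    mask, core_mean = segment_imh(t2, aar)
    assert not mask.grid.any()
    assert core_mean is None


def test_cold_core_detected_with_mean_reported():
    aar, t2 = _uniform_aar_setup(12.0, (slice(12, 16), slice(12, 16)))
    mask, core_mean = segment_imh(t2, aar)
    expected = np.zeros_like(aar)
    expected[12:16, 12:16] = True
    assert np.array_equal(mask.grid, expected)
    assert core_mean == pytest.approx(12.0)


def test_dark_but_warm_component_excluded_by_dual_criterion():
    aar, t2 = _uniform_aar_setup(25.0, (slice(12, 16), slice(12, 16)))
    mask, core_mean = segment_imh(t2, aar)
    assert not mask.grid.any()
    assert core_mean is None


def test_tiny_aar_periphery_is_an_error():
    aar = np.zeros((10, 10), dtype=bool)
    aar[5, 5] = True
    with pytest.raises(ValueError):
        segment_imh(np.full(aar.shape, 35.0), aar)


# --- oracle equivalence -------------------------------------------------------

def test_vectorized_operators_match_naive_reference():
    from conftest import random_phantom_spec

    for seed in range(10):
        spec = random_phantom_spec(seed)
        ph = generate_phantom(spec)
        injured = spec.aar_sector.center_angle
        seg = segment_study(ph.t1, ph.t2star, ph.lge_si, ph.myocardium, injured_center=injured)

        myo = ph.myocardium.grid
        sp = ph.t1.pixel_spacing
        roi = ref.naive_place_remote_roi(myo, injured, 60.0, sp)
        assert np.array_equal(seg.remote_roi.grid, roi)

        aar, thr = ref.naive_segment_aar(ph.t1.values, myo, roi)
        assert thr == seg.aar_threshold_ms
        assert np.array_equal(seg.aar.grid, aar)

        lge, lge_thr, mvo = ref.naive_segment_lge(ph.lge_si.values, myo, roi)
        assert lge_thr == seg.lge_threshold_si
        assert np.array_equal(seg.lge.grid, lge)
        assert np.array_equal(seg.mvo.grid, mvo)

        aar_filled = aar | ref.naive_ring_holes(aar, myo)
        imh = ref.naive_segment_imh(ph.t2star.values, aar_filled)
        assert np.array_equal(seg.imh.grid, imh)


def test_determinism_of_the_segmentation_chain():
    ph = generate_phantom(PhantomSpec(mvo_core=MvoCoreSpec(), seed=33))
    a = segment_study(ph.t1, ph.t2star, ph.lge_si, ph.myocardium, injured_center=90.0)
    b = segment_study(ph.t1, ph.t2star, ph.lge_si, ph.myocardium, injured_center=90.0)
    for attr in ("remote_roi", "aar", "lge", "mvo", "imh"):
        assert np.array_equal(getattr(a, attr).grid, getattr(b, attr).grid)
    assert a.aar_threshold_ms == b.aar_threshold_ms
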