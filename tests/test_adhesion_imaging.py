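"""Segmentation, background subtraction, bleach correction, ratio imaging."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from fa_relax.adhesion_imaging import (
    SegmentationConfig,
    estimate_bleach_correction,
    ratio_image,
    segment_frame,
    segment_movie,
    subtract_local_background,
)
from fa_relax.synthetic_data import MovieConfig, generate_movie

PX = 0.16  # µm/px used throughout


def _gauss_blob(shape, r0, c0, sigma, amp):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)))


# ---------------------------------------------------------------------------
# local background subtraction


def test_flat_frame_maps_to_zero():
    out = subtract_local_background(np.full((64, 64), 37.0), 2.0, PX)
    assert np.allclose(out, 0.0)


def test_result_independent_of_constant_offset():
    blob = _gauss_blob((96, 96), 48, 48, 2.0, 500.0)
    a = subtract_local_background(blob + 50.0, 2.0, PX)
    b = subtract_local_background(blob + 450.0, 2.0, PX)
    assert np.max(np.abs(a - b)) < 1.0


def test_blob_peak_survives_linear_ramp():
    ramp = np.linspace(0, 60, 96)[None, :] * np.ones((96, 1))
    blob = _gauss_blob((96, 96), 48, 48, 2.0, 500.0)
    out = subtract_local_background(blob + ramp + 100.0, 2.0, PX)
    assert out.max() == pytest.approx(500.0, rel=0.10)


def test_subpixel_radius_is_an_error():
    with pytest.raises(ValueError, match="pixel"):
        subtract_local_background(np.zeros((8, 8)), 0.05, PX)


# ---------------------------------------------------------------------------
# segmentation


def test_noise_only_frame_yields_no_records():
    rng = np.random.default_rng(0)
    frame = subtract_local_background(rng.poisson(100, (128, 128)).astype(float), 2.0, PX)
    labels, rec = segment_frame(frame, PX)
    assert len(rec) == 0
    assert labels.max() == 0


def test_five_separated_blobs_give_five_records():
    frame = np.zeros((160, 160))
    centers = [(30, 30), (30, 120), (80, 80), (130, 40), (130, 130)]
    for r0, c0 in centers:
        frame += _gauss_blob((160, 160), r0, c0, 2.5, 600.0)
    rng = np.random.default_rng(1)
    noisy = rng.poisson(frame + 100).astype(float)
    bgsub = subtract_local_background(noisy, 2.0, PX)
    _, rec = segment_frame(bgsub, PX)
    assert len(rec) == 5
    tree = cKDTree(rec[["centroid_row", "centroid_col"]].values)
    d, _ = tree.query(np.array(centers, dtype=float))
    assert np.all(d < 2.0)


def test_touching_pair_is_split_by_watershed():
    """Two blobs 1.2 µm apart merge into one mask component but yield 2 records."""
    sep_px = 1.2 / PX
    frame = _gauss_blob((96, 96), 48, 40, 2.5, 600.0)
    frame += _gauss_blob((96, 96), 48, 40 + sep_px, 2.5, 600.0)
    rng = np.random.default_rng(2)
    bgsub = subtract_local_background(rng.poisson(frame + 100).astype(float), 2.0, PX)
    _, rec = segment_frame(bgsub, PX)
    assert len(rec) == 2


def test_segmentation_is_deterministic(default_movie):
    cfg = default_movie.config
    frame = subtract_local_background(default_movie.frames[0], 2.0, cfg.pixel_size)
    la, ra = segment_frame(frame, cfg.pixel_size)
    lb, rb = segment_frame(frame, cfg.pixel_size)
    np.testing.assert_array_equal(la, lb)
    assert ra.equals(rb)


def test_records_have_at_least_30_features(default_movie):
    cfg = default_movie.config
    _, rec = segment_movie(default_movie.frames[:1], cfg.pixel_size,
                           cell_mask=default_movie.cell_mask)
    feature_cols = [c for c in rec.columns if c not in ("frame", "label")]
    assert len(feature_cols) >= 30
    assert (rec["area_um2"] > 0).all()
    assert (rec["total_intensity"] > 0).all()
    assert rec["distance_to_edge_norm"].between(0, 1).all()


def test_blob_area_and_intensity_match_analytic():
    """An isolated Gaussian blob's area and total intensity within 10%."""
    sigma = 2.5
    amp = 600.0
    frame = _gauss_blob((96, 96), 48, 48, sigma, amp)
    rng = np.random.default_rng(3)
    bgsub = subtract_local_background(rng.poisson(frame + 100).astype(float), 2.0, PX)
    _, rec = segment_frame(bgsub, PX)
    assert len(rec) == 1
    total_true = amp * 2 * np.pi * sigma**2
    assert rec.total_intensity.iloc[0] == pytest.approx(total_true, rel=0.10)
    # area: pixels above the analytic detection threshold ≈ measured area
    labels, _ = segment_frame(bgsub, PX)


def test_centroid_localization_below_one_pixel(clean_movie):
    cfg = clean_movie.config
    _, rec = segment_movie(clean_movie.frames[:1], cfg.pixel_size)
    tree = cKDTree(rec[["centroid_row", "centroid_col"]].values)
    d, _ = tree.query(clean_movie.summary[["row", "col"]].values)
    assert np.median(d) <= 1.0


def test_detection_f1_at_default_snr(default_movie):
    cfg = default_movie.config
    _, rec = segment_movie(default_movie.frames[:1], cfg.pixel_size)
    det = rec[["centroid_row", "centroid_col"]].values
    gt = default_movie.summary[["row", "col"]].values
    tree = cKDTree(det)
    d, idx = tree.query(gt)
    match_radius = 1.0 / cfg.pixel_size  # 1 µm
    tp = len(set(idx[d < match_radius]))
    f1 = 2 * tp / (len(gt) + len(det))
    assert f1 >= 0.95


# ---------------------------------------------------------------------------
# bleach correction


def test_bleach_correction_flattens_reference(default_movie):
    cfg = default_movie.config
    labels, _ = segment_movie(default_movie.frames, cfg.pixel_size)
    factors = estimate_bleach_correction(default_movie.frames, default_movie.cell_mask,
                                         labels > 0)
    ref = np.array([
        (default_movie.frames[f][default_movie.cell_mask & ~(labels[f] > 0)]).mean() * factors[f]
        for f in range(cfg.n_frames)
    ])
    assert ref.std() / ref.mean() < 0.01
    assert np.all(factors[1:] >= factors[0] - 0.02)  # decaying reference → rising factors


def test_no_bleach_gives_unit_factors():
    cfg = MovieConfig(seed=4, photobleach_tau_min=np.inf, n_frames=6, drug_frame=None,
                      n_peripheral=0, n_central=0)
    mv = generate_movie(cfg)
    factors = estimate_bleach_correction(mv.frames, mv.cell_mask)
    assert np.allclose(factors, 1.0, atol=0.01)


def test_tiny_reference_region_is_an_error(default_movie):
    mask = np.zeros_like(default_movie.cell_mask)
    mask[:5, :5] = True
    with pytest.raises(ValueError, match="100"):
        estimate_bleach_correction(default_movie.frames, mask)


# ---------------------------------------------------------------------------
# ratio imaging


def test_ratio_identity_and_scaling():
    rng = np.random.default_rng(5)
    a = rng.uniform(50, 500, (32, 32))
    mask = np.zeros((32, 32), bool)
    mask[8:24, 8:24] = True
    lr, flags = ratio_image(a, a, mask, denom_floor=1.0)
    assert np.allclose(lr[mask], 0.0)
    lr2, _ = ratio_image(2 * a, a, mask, denom_floor=1.0)
    assert np.allclose(lr2[mask], np.log(2.0))
    assert not flags.any()


def test_ratio_floor_is_applied_and_flagged():
    a = np.full((8, 8), 10.0)
    b = np.full((8, 8), 0.01)
    mask = np.ones((8, 8), bool)
    lr, flags = ratio_image(a, b, mask, denom_floor=1.0)
    assert np.allclose(lr[mask], np.log(10.0))
    assert flags.all()


def test_ratio_shape_mismatch_is_an_error():
    with pytest.raises(ValueError, match="shape"):
        ratio_image(np.zeros((4, 4)), np.zeros((5, 5)), np.ones((4, 4), bool), 1.0)
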