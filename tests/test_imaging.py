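"""Synthetic ticket rendering and the spot-detection / decay / binarize pipeline."""

import numpy as np
import pytest

from hyentag.ecc import identity_code
from hyentag.imaging import (
    DecayMatrix,
    PipelineConfig,
    RenderMeta,
    SpotDetectionError,
    TicketImage,
    TicketLayout,
    binarize,
    decay_matrix,
    detect_spots,
    images_from_decays,
    measure_spots,
    read_ticket,
    render_ticket,
)

NOISELESS = RenderMeta(noise_sigma=0.0)


def _layout(**kw):
    return TicketLayout(**kw)


# ---------------------------------------------------------------------------
# rendering and measurement

def test_noiseless_render_spot_mean_exact():
    layout = _layout()
    img = render_ticket(layout, [200.0] * 25, NOISELESS, rng_seed=None)
    centers, masks = detect_spots(img)
    means = measure_spots(img, masks)
    assert np.allclose(means, 200.0)


def test_equal_spots_measure_equal_within_noise():
    layout = _layout()
    img = render_ticket(layout, [180.0] * 25, RenderMeta(noise_sigma=2.0), rng_seed=1)
    _, masks = detect_spots(img)
    means = measure_spots(img, masks)
    assert means.std() < 1.0


def test_mean_intensity_invariant_to_radius():
    # intensity (not integrated flux) is modeled: doubling the radius leaves
    # the measured mean unchanged
    for radius in (6, 12):
        layout = _layout(spot_radius_px=radius, pitch_px=44)
        img = render_ticket(layout, [150.0] * 25, NOISELESS, rng_seed=None)
        _, masks = detect_spots(img)
        assert np.allclose(measure_spots(img, masks), 150.0)


def test_render_geometry_overflow_rejected():
    with pytest.raises(ValueError):
        render_ticket(_layout(origin_px=(5, 5)), [100.0] * 25, NOISELESS)


def test_render_below_background_rejected():
    with pytest.raises(ValueError):
        render_ticket(_layout(), [5.0] * 25, NOISELESS)


def test_measure_constant_image():
    layout = _layout()
    img = TicketImage(np.full(layout.canvas_shape(), 77, dtype=np.uint8), layout, "pre")
    masks = np.zeros((1,) + layout.canvas_shape(), dtype=bool)
    masks[0, 10:20, 10:20] = True
    assert measure_spots(img, masks)[0] == 77.0
    with pytest.raises(ValueError):
        measure_spots(img, np.zeros_like(masks))


# ---------------------------------------------------------------------------
# spot detection

def test_detection_centers_within_2px_noiseless():
    layout = _layout()
    img = render_ticket(layout, [220.0] * 25, NOISELESS, rng_seed=None)
    centers, _ = detect_spots(img)
    assert np.linalg.norm(centers - layout.centers(), axis=1).max() <= 2.0


def test_detection_robust_to_pixel_noise():
    # sigma up to 10% of the dynamic range, several seeds
    layout = _layout()
    for seed in range(5):
        img = render_ticket(layout, [220.0] * 25, RenderMeta(noise_sigma=21.0), seed)
        centers, _ = detect_spots(img)
        assert np.linalg.norm(centers - layout.centers(), axis=1).max() <= 2.0


def test_dark_spots_recovered_by_grid_fallback():
    layout = _layout()
    rng = np.random.default_rng(4)
    decays = np.zeros(25)
    dark = rng.choice(25, size=12, replace=False)
    decays[dark] = 1.0  # fully reacted: post spots sit at background
    _, post = images_from_decays(layout, decays, NOISELESS, rng_seed=None)
    centers, _ = detect_spots(post)
    assert np.linalg.norm(centers - layout.centers(), axis=1).max() <= 2.0


def test_blank_image_is_structured_failure():
    layout = _layout()
    img = TicketImage(
        np.full(layout.canvas_shape(), 20, dtype=np.uint8), layout, "post"
    )
    with pytest.raises(SpotDetectionError):
        detect_spots(img)


# ---------------------------------------------------------------------------
# decay matrix and binarization

def test_identical_images_zero_decay():
    layout = _layout()
    pre = render_ticket(layout, [220.0] * 25, NOISELESS, rng_seed=None)
    dm = decay_matrix(pre, pre)
    assert np.allclose(dm.raw_decay, 0.0)
    assert np.allclose(dm.normalized_decay, 0.0)


def test_full_decay_normalizes_to_one():
    layout = _layout()
    pre, post = images_from_decays(layout, np.ones(25), NOISELESS, rng_seed=None)
    dm = decay_matrix(pre, post)
    assert np.allclose(dm.normalized_decay, 1.0, atol=0.02)


def test_planted_decays_recovered_relative_mode():
    layout = _layout()
    rng = np.random.default_rng(8)
    planted = rng.uniform(0, 1, size=25)
    pre, post = images_from_decays(layout, planted, NOISELESS, rng_seed=None)
    dm = decay_matrix(pre, post)
    assert np.abs(dm.normalized_decay - planted).max() < 0.02
    assert np.all((dm.normalized_decay >= 0) & (dm.normalized_decay <= 1))


def test_normalization_bounds_under_noise():
    layout = _layout()
    rng = np.random.default_rng(2)
    planted = rng.uniform(0, 1, size=25)
    pre, post = images_from_decays(layout, planted, RenderMeta(noise_sigma=8.0), 3)
    dm = decay_matrix(pre, post)
    assert np.all((dm.normalized_decay >= 0) & (dm.normalized_decay <= 1))


def test_minmax_mode_spans_unit_interval():
    layout = _layout()
    planted = np.linspace(0, 1, 25)
    pre, post = images_from_decays(layout, planted, NOISELESS, rng_seed=None)
    dm = decay_matrix(pre, post, PipelineConfig(normalization="minmax"))
    assert dm.normalized_decay.min() == 0.0
    assert dm.normalized_decay.max() == 1.0


def test_binarize_boundary_is_strictly_greater():
    layout = _layout()
    dm = DecayMatrix(
        raw_decay=np.zeros(25),
        normalized_decay=np.full(25, 0.38),
        spot_centers=layout.centers(),
        layout=layout,
    )
    assert not binarize(dm).any()  # exactly at threshold reads 0
    dm.normalized_decay[:] = 0.3800001
    assert binarize(dm).all()


def test_binarize_threshold_monotonicity():
    layout = _layout()
    rng = np.random.default_rng(1)
    dm = DecayMatrix(
        raw_decay=np.zeros(25),
        normalized_decay=rng.uniform(0, 1, 25),
        spot_centers=layout.centers(),
        layout=layout,
    )
    prev = binarize(dm, PipelineConfig(threshold=0.1))
    for thr in (0.3, 0.5, 0.7, 0.9):
        cur = binarize(dm, PipelineConfig(threshold=thr))
        assert np.all(cur <= prev)  # raising the cut never flips 0 -> 1
        prev = cur


def test_unmapped_spots_excluded_and_order_is_bit_order():
    layout = TicketLayout.for_bits(24)
    vals = np.linspace(0, 1, 25)
    dm = DecayMatrix(np.zeros(25), vals, layout.centers(), layout)
    bits = binarize(dm, PipelineConfig(threshold=0.5))
    assert len(bits) == 24
    assert np.array_equal(bits, (vals[:24] > 0.5).astype(int))


# ---------------------------------------------------------------------------
# end-to-end ticket reads

def test_full_capacity_raw_pattern_roundtrip():
    code = identity_code(25)
    layout = TicketLayout.for_bits(25)
    rng = np.random.default_rng(6)
    pattern = rng.integers(0, 2, 25).astype(np.uint8)
    pre, post = images_from_decays(layout, pattern.astype(float), NOISELESS, None)
    result = read_ticket(pre, post, code)
    assert np.array_equal(result.codeword_bits, pattern)
    assert result.decode.distance == 0
    assert np.array_equal(result.decode.dataword, pattern)


def test_readout_json_report(tmp_path):
    code = identity_code(25)
    layout = TicketLayout.for_bits(25)
    pattern = np.zeros(25)
    pre, post = images_from_decays(layout, pattern, NOISELESS, None)
    result = read_ticket(pre, post, code)
    text = result.to_json(tmp_path / "r.json")
    import json

    payload = json.loads(text)
    assert payload["hamming_distance"] == 0
    assert (tmp_path / "r.json").exists()


def test_image_png_roundtrip(tmp_path):
    layout = _layout()
    img = render_ticket(layout, [200.0] * 25, RenderMeta(noise_sigma=1.0), 5)
    img.save(tmp_path / "t.png")
    back = TicketImage.load(tmp_path / "t.png", layout, "pre")
    assert np.array_equal(back.pixels, img.pixels)


def test_mismatched_layouts_rejected():
    a = render_ticket(_layout(), [200.0] * 25, NOISELESS, None)
    b = render_ticket(TicketLayout.for_bits(24), [200.0] * 25, NOISELESS, None)
    with pytest.raises(ValueError):
        decay_matrix(a, b)
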