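"""Structure-tensor orientation field, histograms, alignment and spread."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytoquant import (ImageFrame, OrientationField, OrientationHistogram,
                       align_histogram, dominant_orientation, group_average,
                       normalize_minmax, orientation_histogram,
                       orientation_spread, render_hsb, structure_tensor_field,
                       wrap_axial)
from cytoquant.orientation import mean_orientation_arithmetic

from conftest import axial_diff, interior_mask, stripe_image


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_minmax_maps_extremes_to_unit_interval():
    img = ImageFrame(np.array([[0, 32768], [65535, 65535]], dtype=np.uint16))
    out = normalize_minmax(img).values
    assert out.min() == 0.0 and out.max() == 1.0
    assert out[0, 1] == pytest.approx(0.5, abs=1e-4)


def test_minmax_constant_image_gives_zeros_with_warning(caplog):
    with caplog.at_level("WARNING", logger="cytoquant"):
        out = normalize_minmax(ImageFrame(np.full((8, 8), 7.0)))
    assert np.all(out.values == 0.0)
    assert any("constant" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# structure tensor
# ---------------------------------------------------------------------------

def test_constant_image_has_zero_energy_and_coherency():
    f = structure_tensor_field(ImageFrame(np.full((64, 64), 0.5)))
    assert np.all(f.energy == 0.0)
    assert np.all(f.coherency == 0.0)


@pytest.mark.parametrize("angle", [0.0, 30.0, -60.0, 45.0, 89.0, -89.0])
def test_stripes_recover_orientation_within_one_degree(angle):
    img = stripe_image(angle)
    f = structure_tensor_field(img)
    mask = interior_mask(img.shape)
    assert abs(axial_diff(dominant_orientation(f, mask), angle)) < 1.0
    assert np.median(f.coherency[mask]) > 0.95


def test_grid_rotation_shifts_orientation_by_ninety_degrees():
    img = stripe_image(20.0)
    mask = interior_mask(img.shape)
    d0 = dominant_orientation(structure_tensor_field(img), mask)
    rot = ImageFrame(np.rot90(img.values).copy(), img.pixel_size_nm)
    d90 = dominant_orientation(structure_tensor_field(rot), mask)
    assert abs(axial_diff(d90, d0 + 90.0)) < 1e-6


def test_stripes_keep_coherency_under_rotation():
    img = stripe_image(0.0)
    c0 = structure_tensor_field(img).coherency
    rot = ImageFrame(np.rot90(img.values).copy(), img.pixel_size_nm)
    c90 = structure_tensor_field(rot).coherency
    assert np.allclose(np.rot90(c0), c90, atol=1e-6)


def test_iid_noise_has_low_coherency(rng):
    img = ImageFrame(rng.uniform(0, 1, size=(128, 128)))
    f = structure_tensor_field(img)
    mask = interior_mask(img.shape)
    assert np.all((0.0 <= f.coherency) & (f.coherency <= 1.0))
    assert np.median(f.coherency[mask]) < 0.3


def test_rejects_unnormalized_input_and_bad_sigma():
    with pytest.raises(ValueError, match="normalized"):
        structure_tensor_field(ImageFrame(np.full((8, 8), 2.0)))
    with pytest.raises(ValueError, match="positive"):
        structure_tensor_field(ImageFrame(np.zeros((8, 8))), sigma_gradient=0.0)


# ---------------------------------------------------------------------------
# histogram and exclusion
# ---------------------------------------------------------------------------

def _uniform_field(theta, coherency, shape=(32, 32)):
    t = np.full(shape, float(theta))
    c = np.full(shape, float(coherency))
    return OrientationField(t, c, np.ones(shape))


def test_uniform_field_concentrates_in_one_bin():
    f = _uniform_field(0.0, 1.0)
    h = orientation_histogram(f, np.ones(f.theta.shape, bool))
    assert h.weights[np.argmax(h.weights)] == pytest.approx(h.total_weight)
    assert -1.0 <= h.bin_centers[np.argmax(h.weights)] <= 1.0


def test_two_equal_populations_give_two_equal_bins():
    shape = (32, 32)
    theta = np.zeros(shape)
    theta[:, 16:] = 45.0
    f = OrientationField(theta, np.ones(shape), np.ones(shape))
    h = orientation_histogram(f, np.ones(shape, bool))
    top = np.sort(h.weights)[-2:]
    assert top[0] == top[1]
    assert top.sum() == pytest.approx(h.total_weight)


def test_low_coherency_pixels_are_excluded():
    shape = (16, 16)
    c = np.full(shape, 1.0)
    c[0, :] = 0.05  # below 10% of max coherency
    theta = np.zeros(shape)
    theta[0, :] = 60.0
    f = OrientationField(theta, c, np.ones(shape))
    h = orientation_histogram(f, np.ones(shape, bool), exclusion_fraction=0.10)
    assert h.weights[h.bin_centers > 30.0].sum() == 0.0


def test_structureless_image_is_excluded_by_energy_criterion():
    f = structure_tensor_field(ImageFrame(np.full((32, 32), 0.5)))
    with pytest.raises(ValueError, match="energy"):
        orientation_histogram(f, np.ones((32, 32), bool))


# ---------------------------------------------------------------------------
# dominant orientation
# ---------------------------------------------------------------------------

def _axial_mean_bruteforce(angles, weights):
    """Independent oracle: maximize mean axial alignment over a 0.1-deg grid."""
    grid = np.arange(-90.0, 90.0, 0.1)
    score = [np.sum(weights * np.cos(np.radians(2 * (angles - g)))) for g in grid]
    return grid[int(np.argmax(score))]


def test_uniform_orientation_is_its_own_mean():
    f = _uniform_field(30.0, 1.0)
    assert dominant_orientation(f, np.ones(f.theta.shape, bool)) == pytest.approx(30.0)


def test_axial_mean_across_the_wrap_is_ninety_not_zero():
    theta = np.tile(np.array([[80.0, -80.0]]), (8, 8))
    f = OrientationField(theta, np.ones_like(theta), np.ones_like(theta))
    d = dominant_orientation(f, np.ones(theta.shape, bool))
    oracle = _axial_mean_bruteforce(theta.ravel(), np.ones(theta.size))
    assert abs(axial_diff(d, oracle)) < 0.2
    assert abs(axial_diff(d, 90.0)) < 1e-6
    assert abs(d) > 80.0  # decisively not the arithmetic 0


def test_dominant_orientation_is_rotation_equivariant(rng):
    theta = wrap_axial(rng.uniform(-20, 20, size=(16, 16)))
    c = rng.uniform(0.5, 1.0, size=theta.shape)
    f = OrientationField(theta, c, np.ones_like(theta))
    f10 = OrientationField(wrap_axial(theta + 10.0), c, np.ones_like(theta))
    mask = np.ones(theta.shape, bool)
    d, d10 = dominant_orientation(f, mask), dominant_orientation(f10, mask)
    assert abs(axial_diff(d10, d + 10.0)) < 1e-9


def test_arithmetic_mean_variant_matches_on_wrap_free_data(rng):
    theta = rng.uniform(-30, 30, size=(16, 16))
    c = rng.uniform(0.5, 1.0, size=theta.shape)
    f = OrientationField(theta, c, np.ones_like(theta))
    mask = np.ones(theta.shape, bool)
    circ = dominant_orientation(f, mask)
    arith = mean_orientation_arithmetic(f, mask)
    assert abs(circ - arith) < 1.0  # agree away from the wrap


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _hist(weights, n_bins=180):
    edges = np.linspace(-90, 90, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return OrientationHistogram(centers, np.asarray(weights, float))


def test_align_at_zero_is_identity():
    w = np.arange(180, dtype=float)
    h = align_histogram(_hist(w), 0.0)
    assert np.array_equal(h.weights, w)
    assert h.alignment_offset == 0.0


def test_align_moves_spike_to_zero_bin():
    w = np.zeros(180)
    w[np.searchsorted(np.linspace(-90, 90, 181), 30.0) - 1] = 5.0
    aligned = align_histogram(_hist(w), 30.0)
    assert abs(aligned.bin_centers[int(np.argmax(aligned.weights))]) <= 1.0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(ref=st.floats(-90.0, 89.9),
       seed=st.integers(0, 2**16))
def test_alignment_conserves_total_weight(ref, seed):
    w = np.random.default_rng(seed).uniform(0, 1, size=180)
    h = _hist(w)
    aligned = align_histogram(h, ref)
    # a whole-bin shift permutes the weights without touching any value
    assert np.array_equal(np.sort(aligned.weights), np.sort(h.weights))
    assert aligned.total_weight == pytest.approx(h.total_weight, rel=1e-12)


# ---------------------------------------------------------------------------
# group averaging
# ---------------------------------------------------------------------------

def test_identical_histograms_average_to_themselves_with_zero_ci():
    h = _hist(np.arange(1.0, 181.0))
    g = group_average([h, h, h])
    assert np.allclose(g.mean, h.normalized().weights)
    assert np.allclose(g.ci_upper - g.ci_lower, 0.0)
    assert g.mean.sum() == pytest.approx(1.0, abs=1e-9)


def test_two_complementary_histograms_average_to_half():
    a = OrientationHistogram(np.array([-45.0, 45.0]), np.array([1.0, 0.0]))
    b = OrientationHistogram(np.array([-45.0, 45.0]), np.array([0.0, 1.0]))
    g = group_average([a, b])
    assert np.allclose(g.mean, [0.5, 0.5])


def test_mixed_bin_grids_are_rejected():
    a = _hist(np.ones(180))
    b = _hist(np.ones(90), n_bins=90)
    with pytest.raises(ValueError, match="grids"):
        group_average([a, b])


def test_ci_width_shrinks_like_inverse_sqrt_n(rng):
    """Monte-Carlo check of the t-interval: width ratio between n and 4n
    samples follows 2 * t(n-1)/t(4n-1)."""
    from scipy.stats import t as tdist
    n = 8
    hists = [_hist(rng.dirichlet(np.ones(180)) + 1e-3) for _ in range(4 * n)]
    g_small = group_average(hists[:n])
    g_big = group_average(hists)
    w_small = np.mean(g_small.ci_upper - g_small.ci_lower)
    w_big = np.mean(g_big.ci_upper - g_big.ci_lower)
    predicted = 2.0 * tdist.ppf(0.975, n - 1) / tdist.ppf(0.975, 4 * n - 1)
    assert w_small / w_big == pytest.approx(predicted, rel=0.25)


# ---------------------------------------------------------------------------
# spread
# ---------------------------------------------------------------------------

def test_single_bin_has_zero_spread():
    w = np.zeros(180)
    w[100] = 3.0
    assert orientation_spread(_hist(w)) == 0.0


def test_symmetric_two_point_spread_is_the_offset():
    h = OrientationHistogram(np.array([-30.0, 30.0]), np.array([2.0, 2.0]))
    assert orientation_spread(h) == pytest.approx(30.0)


def test_spread_matches_expansion_oracle(rng):
    """Weighted std equals the std of the sample in which each bin center is
    repeated proportionally to its (integer) weight."""
    for _ in range(100):
        w = rng.integers(0, 20, size=180).astype(float)
        if w.sum() == 0:
            w[0] = 1.0
        h = _hist(w)
        expanded = np.repeat(h.bin_centers, w.astype(int))
        assert orientation_spread(h) == pytest.approx(np.std(expanded), rel=1e-9, abs=1e-12)


def test_zero_weight_histogram_is_an_error():
    with pytest.raises(ValueError, match="weight"):
        orientation_spread(_hist(np.zeros(180)))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def test_zero_coherency_renders_grayscale():
    shape = (8, 8)
    f = OrientationField(np.zeros(shape), np.zeros(shape), np.ones(shape))
    img = ImageFrame(np.full(shape, 0.5))
    rgb = render_hsb(f, img)
    assert rgb.shape == shape + (3,)
    assert np.allclose(rgb[..., 0], rgb[..., 1]) and np.allclose(rgb[..., 1], rgb[..., 2])


def test_saturated_uniform_orientation_gives_single_hue():
    shape = (8, 8)
    f = OrientationField(np.full(shape, 30.0), np.ones(shape), np.ones(shape))
    rgb = render_hsb(f, ImageFrame(np.ones(shape)))
    assert np.allclose(rgb, rgb[0, 0])
    assert rgb[0, 0].max() == 1.0 and rgb[0, 0].min() == 0.0  # fully saturated
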