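"""Co-localization metrics against brute-force oracles and their
mathematical bounds."""

import numpy as np
import pytest

from colocquant import (
    ChannelImage, ROIMask, compute_all_metrics, costes_thresholds,
    expression_fraction, manders_coefficients, overlap_fraction,
    overlap_image, triple_manders,
)
from colocquant.config import PipelineConfig
from colocquant.metrics import DegenerateChannelError
from oracles import costes_scan_naive, manders_naive, positive_count_naive, \
    product_naive, tls_naive


def chan(arr, label="other"):
    return ChannelImage(np.asarray(arr, float), label=label)


# ------------------------------------------------------ expression fraction

def test_expression_fraction_counts_strictly_positive_pixels():
    roi = ROIMask(np.ones((1, 4), bool))
    assert expression_fraction(chan([[0.0, 0.5, 0.2, 0.0]]), roi) == 0.5
    assert expression_fraction(chan([[0.0, 0.0, 0.0, 0.0]]), roi) == 0.0


def test_expression_fraction_matches_loop_oracle(rng):
    img = (rng.random((32, 32)) < 0.3).astype(float)
    roi = ROIMask.full((32, 32))
    want = positive_count_naive(img, roi.mask) / 1024
    assert expression_fraction(chan(img), roi) == want


def test_expression_fraction_respects_roi():
    mask = np.zeros((4, 4), bool)
    mask[0, :2] = True
    img = np.zeros((4, 4))
    img[0, 0] = 0.9  # inside ROI
    img[3, 3] = 0.9  # outside ROI
    assert expression_fraction(chan(img), ROIMask(mask)) == 0.5


# ----------------------------------------------------------- overlap image

def test_overlap_image_trivial_cases():
    ones = chan(np.ones((4, 4)))
    assert np.all(overlap_image([ones, ones]).pixels == 1.0)
    a = np.zeros((2, 2)); a[0, 0] = 1.0
    b = np.zeros((2, 2)); b[1, 1] = 1.0
    assert np.all(overlap_image([chan(a), chan(b)]).pixels == 0.0)


def test_overlap_image_matches_loop_oracle(rng):
    chans = [rng.random((16, 16)) for _ in range(3)]
    got = overlap_image([chan(c) for c in chans]).pixels
    assert np.abs(got - product_naive(chans)).max() < 1e-12


def test_overlap_image_rejects_mismatched_shapes():
    with pytest.raises(ValueError):
        overlap_image([chan(np.zeros((4, 4))), chan(np.zeros((4, 5)))])


# -------------------------------------------------------- overlap fraction

def test_overlap_fraction_examples():
    roi = ROIMask(np.ones((1, 4), bool))
    r = chan([[1.0, 1.0, 0.0, 0.0]])
    g = chan([[1.0, 0.0, 1.0, 0.0]])
    assert overlap_fraction([r, g], roi) == 0.25
    # x*x > 0 iff x > 0: overlap of a channel with itself = its expression
    assert overlap_fraction([r, r], roi) == expression_fraction(r, roi)


def test_overlap_fraction_matches_loop_oracle(rng):
    chans = [(rng.random((32, 32)) < 0.2) * rng.random((32, 32))
             for _ in range(3)]
    roi = ROIMask.full((32, 32))
    prod = product_naive(chans)
    want = positive_count_naive(prod, roi.mask) / roi.n_pixels
    assert overlap_fraction([chan(c) for c in chans], roi) == want


def test_overlap_fraction_permutation_invariant(rng):
    chans = [chan(rng.random((16, 16))) for _ in range(3)]
    roi = ROIMask.full((16, 16))
    base = overlap_fraction(chans, roi)
    assert overlap_fraction(chans[::-1], roi) == base
    assert overlap_fraction([chans[1], chans[2], chans[0]], roi) == base


# ------------------------------------------------------------------ Costes

def test_costes_recovers_exact_linear_slope():
    rng = np.random.default_rng(0)
    a = rng.random((24, 24))
    res = costes_thresholds(chan(a), chan(0.5 * a), ROIMask.full(a.shape))
    assert abs(res.slope - 0.5) < 1e-9


def test_costes_matches_exhaustive_scan_oracle():
    step = 1 / 255
    for seed in range(10):
        rng = np.random.default_rng(seed)
        a = rng.random((32, 32))
        b = np.clip(0.6 * a + 0.2 * rng.random((32, 32)), 0, 1)
        roi = ROIMask.full((32, 32))
        res = costes_thresholds(chan(a), chan(b), roi, step=step)
        t_a_oracle, t_b_oracle = costes_scan_naive(a, b, roi.mask, step)
        assert abs(res.t_a - t_a_oracle) <= step + 1e-12
        assert abs(res.t_b - t_b_oracle) <= abs(res.slope) * step + 1e-12


def test_costes_tls_matches_eigen_oracle(rng):
    a = rng.random((32, 32))
    b = np.clip(0.7 * a + 0.1 * rng.random((32, 32)), 0, 1)
    roi = ROIMask.full((32, 32))
    res = costes_thresholds(chan(a), chan(b), roi)
    slope, intercept = tls_naive(a[roi.mask], b[roi.mask])
    assert abs(res.slope - slope) < 1e-9
    assert abs(res.intercept - intercept) < 1e-9


def test_costes_anti_correlated_pair_flagged():
    rng = np.random.default_rng(1)
    a = rng.random((16, 16))
    res = costes_thresholds(chan(a), chan(1.0 - a), ROIMask.full(a.shape))
    assert res.anti_correlated
    assert res.slope < 0
    assert 0.0 <= res.t_a <= 1.0 and 0.0 <= res.t_b <= 1.0


def test_costes_constant_channel_is_degenerate():
    rng = np.random.default_rng(2)
    a = rng.random((8, 8))
    with pytest.raises(DegenerateChannelError):
        costes_thresholds(chan(a), chan(np.full((8, 8), 0.5)),
                          ROIMask.full((8, 8)))


def test_costes_terminating_correlation_nonpositive_or_floor():
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        res = costes_thresholds(chan(a), chan(b), ROIMask.full((32, 32)))
        assert res.anti_correlated or res.at_floor or res.r_below <= 0.0


# ----------------------------------------------------------------- Manders

def test_manders_direct_substitution():
    roi = ROIMask(np.ones((1, 2), bool))
    m = manders_coefficients(chan([[0.5, 0.5]]), chan([[1.0, 0.0]]), roi,
                             (0.0, 0.0))
    assert m.m1 == 0.5 and m.m2 == 1.0


def test_manders_disjoint_supports_are_zero():
    a = np.zeros((2, 2)); a[0, 0] = 0.7
    b = np.zeros((2, 2)); b[1, 1] = 0.7
    m = manders_coefficients(chan(a), chan(b), ROIMask.full((2, 2)),
                             (0.0, 0.0))
    assert m.m1 == 0.0 and m.m2 == 0.0


def test_manders_zero_channel_flags_zero_denominator():
    roi = ROIMask.full((2, 2))
    m = manders_coefficients(chan(np.zeros((2, 2))),
                             chan(np.full((2, 2), 0.5)), roi, (0.0, 0.0))
    assert m.m1 == 0.0 and m.zero_denom_a and not m.zero_denom_b


def test_manders_matches_loop_oracle_with_costes_thresholds(rng):
    a = (rng.random((16, 16)) < 0.4) * rng.random((16, 16))
    b = np.clip(0.8 * a + 0.1 * rng.random((16, 16)), 0, 1)
    roi = ROIMask.full((16, 16))
    res = costes_thresholds(chan(a), chan(b), roi)
    m = manders_coefficients(chan(a), chan(b), roi, res)
    w1, w2 = manders_naive(a, b, roi.mask, res.t_a, res.t_b)
    assert abs(m.m1 - w1) < 1e-12 and abs(m.m2 - w2) < 1e-12


def test_manders_binary_images_reduce_to_overlap_counts(rng):
    a = (rng.random((16, 16)) < 0.4).astype(float)
    b = (rng.random((16, 16)) < 0.4).astype(float)
    roi = ROIMask.full((16, 16))
    m = manders_coefficients(chan(a), chan(b), roi, (0.0, 0.0))
    inter = float(np.sum((a > 0) & (b > 0)))
    assert m.m1 == pytest.approx(inter / a.sum())
    assert m.m2 == pytest.approx(inter / b.sum())


# ------------------------------------------------------------ triple MCC

def test_triple_saturated_markers_give_unity():
    c = chan(np.full((8, 8), 0.6))
    m1, m2, costes = triple_manders(c, c, c, ROIMask.full((8, 8)))
    assert m1 == 1.0 and m2 == 1.0
    assert costes.t_a == 0.0 and costes.t_b == 0.0


def test_triple_disjoint_green_gives_zero_m1():
    rf = np.zeros((8, 8)); rf[:4] = 0.8
    g = np.zeros((8, 8)); g[6:] = 0.8
    m1, _, _ = triple_manders(chan(rf), chan(rf), chan(g),
                              ROIMask.full((8, 8)))
    assert m1 == 0.0


def test_triple_composes_component_oracles(rng):
    r = (rng.random((16, 16)) < 0.5) * rng.random((16, 16))
    f = np.clip(r + 0.05 * rng.random((16, 16)), 0, 1)
    g = np.clip(0.5 * r + 0.2 * rng.random((16, 16)), 0, 1)
    roi = ROIMask.full((16, 16))
    m1, m2, costes = triple_manders(chan(r), chan(f), chan(g), roi)
    i_fr = product_naive([f, r])
    t_a, t_b = costes_scan_naive(i_fr, g, roi.mask, 1 / 255)
    assert abs(costes.t_a - t_a) <= 1 / 255 + 1e-12
    w1, w2 = manders_naive(i_fr, g, roi.mask, costes.t_a, costes.t_b)
    assert abs(m1 - w1) < 1e-12 and abs(m2 - w2) < 1e-12


# ---------------------------------------------------- orchestrated metrics

def _raw_config():
    cfg = PipelineConfig()
    cfg.wavelet.enabled = False
    return cfg


def test_two_channel_scene_has_no_triple_metrics(rng):
    scene = [chan(rng.random((32, 32)), "R"), chan(rng.random((32, 32)), "G")]
    m = compute_all_metrics(scene, ROIMask.full((32, 32)), _raw_config())
    assert m.of_rfg is None and m.triple_m1 is None and m.f_f is None
    assert m.of_rg is not None and m.m1 is not None


def test_all_zero_scene_is_flagged_not_fabricated():
    z = np.zeros((32, 32))
    scene = [chan(z, "R"), chan(z, "G"), chan(z, "F")]
    m = compute_all_metrics(scene, ROIMask.full((32, 32)), _raw_config())
    assert m.f_r == m.f_g == m.f_f == 0.0
    assert m.of_rg == m.of_rfg == 0.0
    assert "zero_denominator_manders" in m.flags
    assert m.m1 == 0.0 and m.m2 == 0.0


def test_compute_all_matches_standalone_operations(triple_scene):
    scene, _ = triple_scene
    roi = ROIMask.full(scene[0].shape)
    cfg = _raw_config()
    m = compute_all_metrics(scene, roi, cfg)
    by = {c.label: c for c in scene}
    assert m.f_r == expression_fraction(by["R"], roi)
    assert m.of_rg == overlap_fraction([by["R"], by["G"]], roi)
    assert m.of_rfg == overlap_fraction([by["R"], by["F"], by["G"]], roi)
    res = costes_thresholds(by["R"], by["G"], roi)
    mm = manders_coefficients(by["R"], by["G"], roi, res)
    assert m.m1 == mm.m1 and m.m2 == mm.m2
    t1, t2, _ = triple_manders(by["R"], by["F"], by["G"], roi)
    assert m.triple_m1 == t1 and m.triple_m2 == t2


def test_fewer_than_two_marker_channels_rejected(rng):
    with pytest.raises(ValueError):
        compute_all_metrics([chan(rng.random((16, 16)), "R")],
                            ROIMask.full((16, 16)))


def test_subset_bound_and_ranges_on_random_scenes():
    """OF_RFG <= min pairwise OF; all metrics within [0, 1]."""
    for seed in range(30):
        rng = np.random.default_rng(seed)
        sparse = rng.random(3)
        scene = [chan((rng.random((32, 32)) < p) * rng.random((32, 32)), lab)
                 for p, lab in zip(sparse, ("R", "G", "F"))]
        m = compute_all_metrics(scene, ROIMask.full((32, 32)), _raw_config())
        vals = [m.f_r, m.f_g, m.f_f, m.of_rg, m.of_rf, m.of_fg, m.of_rfg,
                m.m1, m.m2, m.triple_m1, m.triple_m2]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert m.of_rfg <= min(m.of_rg, m.of_rf, m.of_fg) + 1e-15
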