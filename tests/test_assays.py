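"""Recycling- and invasion-assay quantifiers."""

import numpy as np
import pytest

from colocquant import (
    AssayCount, InvasionProfile, count_positive_cells, invasion_fraction,
    recycling_timecourse,
)
from colocquant.images import ChannelImage
from colocquant.simulate import generate_cell_field


def make_count(t, n_pos, n_nuc=100, condition="c", compartment="total"):
    return AssayCount(scene_id="s", condition=condition,
                      time_point_min=t, compartment=compartment,
                      n_nuclei=n_nuc, n_positive=n_pos)


# ---------------------------------------------------- cell counting

def test_empty_nuclei_channel_returns_zero_with_flag():
    z = ChannelImage(np.zeros((64, 64)))
    out = count_positive_cells(z, z)
    assert out.n_nuclei == 0 and out.n_positive == 0
    assert "no_nuclei" in out.flags


def test_marker_free_field_counts_no_positives():
    rng = np.random.default_rng(0)
    nuc, _ = generate_cell_field(9, [False] * 9, rng)
    zero_marker = ChannelImage(np.zeros(nuc.shape))
    out = count_positive_cells(nuc, zero_marker)
    assert out.n_nuclei == 9 and out.n_positive == 0


@pytest.mark.parametrize("n_cells,n_pos", [(10, 4), (16, 16), (12, 0)])
def test_counts_recover_generator_ground_truth(n_cells, n_pos):
    rng = np.random.default_rng(42)
    flags = [i < n_pos for i in range(n_cells)]
    nuc, mk = generate_cell_field(n_cells, flags, rng)
    out = count_positive_cells(nuc, mk)
    assert out.n_nuclei == n_cells
    assert out.n_positive == n_pos


def test_counts_recover_truth_across_seeds_and_compartments():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        comp = ("cell_surface", "internalized", "total")[seed % 3]
        n_pos = int(rng.integers(0, 13))
        flags = [i < n_pos for i in range(12)]
        rng.shuffle(flags)
        nuc, mk = generate_cell_field(12, flags, rng, compartment=comp)
        out = count_positive_cells(nuc, mk, compartment=comp)
        assert out.n_nuclei == 12
        assert out.n_positive == n_pos


# -------------------------------------------------- recycling time course

def test_percent_of_t0_arithmetic():
    counts = [make_count(0.0, 50), make_count(40.0, 25)]
    (tc,) = recycling_timecourse(counts)
    assert tc.percent_at(0.0) == 100.0
    assert tc.percent_at(40.0) == 50.0


def test_flat_counts_give_flat_series_at_100():
    counts = [make_count(t, 33) for t in (0.0, 40.0, 120.0)]
    (tc,) = recycling_timecourse(counts)
    assert all(pct == 100.0 for _, pct in tc.series)


def test_timecourse_is_scale_invariant():
    counts = [make_count(0.0, 50), make_count(40.0, 15), make_count(120.0, 40)]
    doubled = [make_count(c.time_point_min, 2 * c.n_positive, 200)
               for c in counts]
    base = recycling_timecourse(counts)[0].series
    scaled = recycling_timecourse(doubled)[0].series
    assert base == scaled


def test_missing_or_zero_t0_raises():
    with pytest.raises(ValueError, match="time-zero"):
        recycling_timecourse([make_count(40.0, 10)])
    with pytest.raises(ValueError, match="percent-of-t0 undefined"):
        recycling_timecourse([make_count(0.0, 0), make_count(40.0, 10)])


def test_conditions_and_compartments_kept_separate():
    counts = [make_count(0.0, 50, condition="a"),
              make_count(0.0, 20, condition="b"),
              make_count(40.0, 25, condition="a"),
              make_count(40.0, 20, condition="b")]
    out = {(tc.condition, tc.compartment): tc
           for tc in recycling_timecourse(counts)}
    assert out[("a", "total")].percent_at(40.0) == 50.0
    assert out[("b", "total")].percent_at(40.0) == 100.0


# ---------------------------------------------------------- invasion assay

def profile(depths, intensities, threshold=40.0):
    return InvasionProfile(insert_id="i", condition="c",
                           sections=tuple(zip(depths, intensities)),
                           depth_threshold_um=threshold)


def test_invasion_fraction_strictly_beyond_threshold():
    p = profile([0, 20, 40, 60], [10, 10, 10, 10])
    assert invasion_fraction(p) == 0.25  # only depth 60 is beyond 40


def test_invasion_all_intensity_at_surface_is_zero():
    p = profile([0, 20, 40, 60], [40, 0, 0, 0])
    assert invasion_fraction(p) == 0.0


def test_invasion_matches_hand_summed_oracle(rng):
    depths = [20.0 * k for k in range(8)]
    intensities = rng.random(8) * 100
    p = profile(depths, intensities)
    beyond = sum(i for d, i in zip(depths, intensities) if d > 40.0)
    assert invasion_fraction(p) == pytest.approx(beyond / intensities.sum())


def test_invasion_monotone_in_threshold(rng):
    intensities = rng.random(10) * 50
    depths = [20.0 * k for k in range(10)]
    fracs = [invasion_fraction(profile(depths, intensities, thr))
             for thr in (120.0, 80.0, 40.0, 0.0)]
    assert all(0.0 <= f <= 1.0 for f in fracs)
    assert all(a <= b for a, b in zip(fracs, fracs[1:]))


def test_invasion_profile_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        profile([0, 0, 20], [1, 1, 1])
    with pytest.raises(ValueError, match="constant"):
        profile([0, 20, 60], [1, 1, 1])
    with pytest.raises(ValueError, match="zero"):
        invasion_fraction(profile([0, 20], [0, 0]))
    with pytest.raises(ValueError, match="2 sections"):
        invasion_fraction(InvasionProfile(
            insert_id="i", condition="c", sections=((0.0, 1.0),)))
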