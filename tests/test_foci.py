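import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from granulescope.foci import (
    CellFoci,
    build_demograph,
    count_fractions,
    flip_for_foci_histogram,
    fraction_cells_exceeding,
    ideal_positions,
    match_foci_channels,
    normalize_positions,
    paired_position_correlation,
    spacing_deviation,
)
from granulescope.synthetic import FociSimConfig, simulate_foci_cells


def make_cell(length=1.0, **channels):
    foci = {ch: [(p, 1.0) for p in positions]
            for ch, positions in channels.items()}
    return CellFoci(cell_id="c", length=length, foci=foci)


def oracle_match(a, b, max_dist):
    """Exhaustive search over all injective pairings; lexicographic optimum
    (max pairs within max_dist, then min total distance)."""
    a, b = list(a), list(b)
    best = (0, 0.0, [])
    small, large, swapped = (a, b, False) if len(a) <= len(b) else (b, a, True)
    for subset in itertools.permutations(range(len(large)), len(small)):
        pairs = []
        total = 0.0
        for i, j in enumerate(subset):
            d = abs(small[i] - large[j])
            if d <= max_dist:
                x, y = (small[i], large[j]) if not swapped else (large[j], small[i])
                pairs.append((x, y))
                total += d
        key = (len(pairs), -total, pairs)
        if (key[0], key[1]) > (best[0], -best[1]):
            best = (len(pairs), total, pairs)
    return best[0], best[1]


# ---------------------------------------------------------------------------
# normalization and flipping
# ---------------------------------------------------------------------------

def test_normalize_positions_examples():
    cell = make_cell(length=4.0, dapi=[2.0])
    assert normalize_positions(cell, "dapi") == pytest.approx([0.5])
    cell = make_cell(length=3.0, dapi=[0.0, 0.75, 2.25, 3.0])
    assert normalize_positions(cell, "dapi") == pytest.approx(
        [0.0, 0.25, 0.75, 1.0])


def test_normalize_rejects_position_beyond_length():
    with pytest.raises(ValueError, match="outside"):
        make_cell(length=1.0, dapi=[1.5])


@pytest.mark.parametrize("positions, expected, flipped", [
    ([0.3], [0.7], True),
    ([0.2, 0.4], [0.8, 0.6], True),
    ([0.3, 0.7], [0.3, 0.7], False),
    ([0.5], [0.5], False),            # focus exactly at mid-cell: no flip
])
def test_flip_rule(positions, expected, flipped):
    out, was_flipped = flip_for_foci_histogram(np.array(positions))
    assert sorted(out) == pytest.approx(sorted(expected))
    assert was_flipped is flipped


@given(st.lists(st.floats(0.0, 1.0 - 1e-9), min_size=1, max_size=6))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_flip_is_involution_and_isometry(positions):
    """Flipping twice restores the set; pairwise distances are preserved."""
    x = np.array(positions)
    once, flipped = flip_for_foci_histogram(x)
    if flipped:
        twice, again = flip_for_foci_histogram(once)
        assert not again  # flipped cells land in the right half
        np.testing.assert_allclose(np.sort(1 - once), np.sort(x), atol=1e-12)
    dist = lambda v: np.abs(v[:, None] - v[None, :])
    np.testing.assert_allclose(dist(once), dist(x), atol=1e-12)


# ---------------------------------------------------------------------------
# demographs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("segments, expected, flipped", [
    ([4, 2, 1], [0.25, 0.5, 1.0], True),
    ([1, 2, 4], [0.25, 0.5, 1.0], False),
    ([3, 3, 3], [1.0, 1.0, 1.0], False),   # argmax tie: no flip
])
def test_demograph_single_profile(segments, expected, flipped):
    demo = build_demograph([("c", 2.0, np.array(segments, float))], n_bins=3)
    np.testing.assert_allclose(demo.matrix[0], expected)
    assert demo.flipped[0] is flipped


def test_demograph_rows_sorted_by_length_and_max_one():
    profiles = [("long", 5.0, np.array([1.0, 2.0])),
                ("short", 2.0, np.array([9.0, 1.0]))]
    demo = build_demograph(profiles, n_bins=4)
    assert demo.cell_ids == ("short", "long")
    np.testing.assert_allclose(demo.matrix.max(axis=1), 1.0)


def test_demograph_excludes_zero_profiles_with_warning():
    profiles = [("dark", 1.0, np.zeros(3)), ("lit", 1.0, np.array([1., 2.]))]
    with pytest.warns(UserWarning, match="dark"):
        demo = build_demograph(profiles)
    assert demo.cell_ids == ("lit",)


@given(st.lists(st.floats(0.01, 100), min_size=2, max_size=12),
       st.integers(5, 60))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_demograph_flip_symmetry(segments, n_bins):
    """Reversing the input segment order leaves the output row unchanged."""
    forward = build_demograph([("c", 1.0, np.array(segments))], n_bins=n_bins)
    reverse = build_demograph([("c", 1.0, np.array(segments[::-1]))],
                              n_bins=n_bins)
    np.testing.assert_allclose(forward.matrix, reverse.matrix, atol=1e-12)
    assert forward.matrix.max(axis=1) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# count fractions
# ---------------------------------------------------------------------------

def test_count_fractions_excludes_zero_foci_cells():
    cells = [make_cell(dapi=[0.5] * k) for k in (0, 1, 1, 2, 3)]
    out = count_fractions(cells, "dapi")
    assert out.n_cells_with_foci == 4
    assert (out.f1, out.f2, out.f_gt2) == (0.5, 0.25, 0.25)
    assert out.f1 + out.f2 + out.f_gt2 == pytest.approx(1.0, abs=1e-12)


def test_count_fractions_all_single():
    cells = [make_cell(dapi=[0.5]) for _ in range(3)]
    assert count_fractions(cells, "dapi").f1 == 1.0


def test_count_fractions_errors_without_foci():
    with pytest.raises(ValueError):
        count_fractions([make_cell(dapi=[])], "dapi")


@pytest.mark.parametrize("counts, threshold, expected", [
    ([1, 2, 2, 1], 1, 0.5),
    ([0, 1], 0, 0.5),
    ([0, 0, 0], 0, 0.0),
])
def test_fraction_cells_exceeding_includes_zero_cells(counts, threshold,
                                                      expected):
    assert fraction_cells_exceeding(np.array(counts), threshold) == expected


def test_fraction_cells_exceeding_rejects_empty():
    with pytest.raises(ValueError):
        fraction_cells_exceeding(np.array([]), 1)


# ---------------------------------------------------------------------------
# cross-channel matching
# ---------------------------------------------------------------------------

def test_match_examples():
    cell = make_cell(a=[0.30], b=[0.32, 0.90])
    out = match_foci_channels(cell, "a", "b", 0.1)
    assert out.pairs == ((0.30, 0.32),)
    assert out.unmatched_b == (0.90,)

    cell = make_cell(a=[0.2, 0.8], b=[0.8, 0.2])
    out = match_foci_channels(cell, "a", "b", 1.0)
    assert set(out.pairs) == {(0.2, 0.2), (0.8, 0.8)}

    cell = make_cell(a=[], b=[0.4, 0.6])
    out = match_foci_channels(cell, "a", "b", 0.1)
    assert out.pairs == () and set(out.unmatched_b) == {0.4, 0.6}


def test_match_beats_greedy_order():
    """Optimal assignment pairs 0.5 with its nearer partner even when a
    greedy scan by input order would grab it first."""
    cell = make_cell(a=[0.45, 0.50], b=[0.50, 0.58])
    out = match_foci_channels(cell, "a", "b", 0.1)
    assert set(out.pairs) == {(0.45, 0.50), (0.50, 0.58)}


def test_match_equals_exhaustive_oracle(rng):
    for _ in range(300):
        na, nb = rng.integers(0, 5, size=2)
        a = np.sort(rng.uniform(0, 1, na))
        b = np.sort(rng.uniform(0, 1, nb))
        cell = make_cell(a=list(a), b=list(b))
        out = match_foci_channels(cell, "a", "b", 0.1)
        n_pairs, total = oracle_match(a, b, 0.1)
        assert len(out.pairs) == n_pairs
        got_total = sum(abs(x - y) for x, y in out.pairs)
        assert got_total == pytest.approx(total, abs=1e-12)
        for x, y in out.pairs:
            assert abs(x - y) <= 0.1


def test_paired_correlation_trivials():
    identical = match_foci_channels(
        make_cell(a=[0.2, 0.5, 0.8], b=[0.2, 0.5, 0.8]), "a", "b", 0.05)
    assert paired_position_correlation([identical]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        paired_position_correlation([])


def test_paired_correlation_anticorrelated():
    xs = [0.1, 0.3, 0.45]
    results = [match_foci_channels(
        make_cell(a=[x], b=[1 - x]), "a", "b", 1.0) for x in xs]
    assert paired_position_correlation(results) == pytest.approx(-1.0)


def test_generative_two_channel_correlation_high():
    """Both channels image the same granules: matched positions correlate."""
    cells = simulate_foci_cells(FociSimConfig(
        n_cells=500, noise_sd=0.02, dropout=0.1, seed=21))
    results = [match_foci_channels(c, "dapi", "mapple") for c in cells
               if c.n_foci("dapi") and c.n_foci("mapple")]
    assert paired_position_correlation(results) > 0.9


# ---------------------------------------------------------------------------
# spacing deviation
# ---------------------------------------------------------------------------

def test_ideal_positions_models():
    np.testing.assert_allclose(ideal_positions(2, "equal_gap"), [1/3, 2/3])
    np.testing.assert_allclose(ideal_positions(2, "quarter"), [1/4, 3/4])
    with pytest.raises(ValueError):
        ideal_positions(2, "golden")


@pytest.mark.parametrize("positions, model, expected", [
    ([1/3, 2/3], "equal_gap", 0.0),
    ([1/4, 3/4], "quarter", 0.0),
    ([0.25, 0.35], "equal_gap", (abs(0.25 - 1/3) + abs(0.35 - 2/3)) / 2),
])
def test_spacing_deviation_values(positions, model, expected):
    assert spacing_deviation(np.array(positions), model) == \
        pytest.approx(expected)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=5),
       st.sampled_from(["equal_gap", "quarter"]))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_spacing_deviation_mirror_invariant(positions, model):
    x = np.array(positions)
    assert spacing_deviation(x, model) == pytest.approx(
        spacing_deviation(1 - x, model), abs=1e-12)
    assert spacing_deviation(x, model) >= 0


def test_spacing_discriminates_even_from_uniform():
    """Evenly placed cells score lower deviation than uniform ones."""
    base = dict(n_cells=500, foci_count_weights=(0, 0, 1, 0, 0),
                noise_sd=0.02, dropout=0.0, channels=("dapi",), seed=31)
    even = simulate_foci_cells(FociSimConfig(placement="even_equal_gap",
                                             **base))
    uniform = simulate_foci_cells(FociSimConfig(placement="uniform", **base))

    def deviations(cells):
        return np.array([
            spacing_deviation(normalize_positions(c, "dapi"), "equal_gap")
            for c in cells if c.n_foci("dapi") == 2
        ])

    d_even, d_uniform = deviations(even), deviations(uniform)
    assert d_even.mean() < d_uniform.mean()
    assert stats.mannwhitneyu(d_even, d_uniform,
                              alternative="less").pvalue < 1e-6
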