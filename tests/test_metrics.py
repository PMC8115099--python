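import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bqsim import genotypes as gt
from bqsim.metrics import (
    MOORE_WEIGHTS,
    CommunitySnapshot,
    alpha_diversity,
    classify_pattern,
    competition_timing,
    genotype_abundances,
    pad,
    pai,
    region_size,
    steady_state_reached,
)


def grid_from(entries, L=10):
    g = np.full((L, L), gt.EMPTY, dtype=np.int8)
    for (r, c), code in entries.items():
        g[r, c] = code
    return g


def brute_force_pad(grid, focal, weights=MOORE_WEIGHTS):
    """Independent neighborhood-enumeration oracle (explicit loops)."""
    L = grid.shape[0]
    partner = gt.complement(focal)
    vals = []
    for i in range(L):
        for j in range(L):
            if grid[i, j] != focal:
                continue
            acc = 0.0
            for (dr, dc), w in weights.items():
                if grid[(i + dr) % L, (j + dc) % L] == partner:
                    acc += w
            vals.append(acc)
    return float(np.mean(vals)) if vals else float("nan")


# -- census and diversity ---------------------------------------------------

def test_abundances_census():
    g = grid_from({(0, 0): 7, (1, 1): 7, (2, 2): 1, (3, 3): 6,
                   (4, 4): 6, (5, 5): 6, (0, 9): 0, (9, 0): 2,
                   (9, 9): 4, (5, 0): 3})
    counts, frac = genotype_abundances(g)
    assert counts.tolist() == [1, 1, 1, 1, 1, 0, 3, 2]
    assert frac.sum() == pytest.approx(1.0)


def test_abundances_empty_flagged():
    counts, frac = genotype_abundances(grid_from({}))
    assert counts.sum() == 0
    assert np.isnan(frac).all()


@pytest.mark.parametrize("counts,expected", [
    ([10, 0, 0, 0, 0, 0, 0, 0], 0.0),
    ([5] * 8, math.log(8)),
    ([75, 25, 0, 0, 0, 0, 0, 0],
     -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))),
])
def test_shannon_values(counts, expected):
    assert alpha_diversity(counts) == pytest.approx(expected, abs=1e-6)


def test_shannon_permutation_invariant_and_maximal(rng):
    counts = rng.integers(1, 50, size=8)
    h = alpha_diversity(counts)
    assert alpha_diversity(rng.permutation(counts)) == pytest.approx(h)
    assert h <= alpha_diversity([counts.sum()] * 8) + 1e-12
    assert math.isnan(alpha_diversity([0] * 8))


# -- PAD / PAI --------------------------------------------------------------

def test_pad_no_partner_is_zero():
    g = grid_from({(5, 5): 1})
    assert pad(g, 1) == 0.0


def test_pad_four_edge_partners():
    g = grid_from({(5, 5): 1, (4, 5): 6, (6, 5): 6, (5, 4): 6, (5, 6): 6})
    assert pad(g, 1) == pytest.approx(4.0)


def test_pad_diagonal_weight():
    g = grid_from({(5, 5): 1, (4, 4): 6})
    assert pad(g, 1) == pytest.approx(1 / math.sqrt(2))


def test_pad_requires_tflg_focal():
    with pytest.raises(ValueError):
        pad(grid_from({}), 6)


def test_pad_undefined_without_focal_cells():
    assert math.isnan(pad(grid_from({(0, 0): 7}), 1))


def test_pad_periodic_wraparound():
    g = grid_from({(0, 0): 1, (9, 0): 6, (0, 9): 6})
    assert pad(g, 1) == pytest.approx(2.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(5, 20))
def test_pad_matches_brute_force_on_random_mosaics(seed, L):
    r = np.random.default_rng(seed)
    grid = r.integers(-1, 8, size=(L, L)).astype(np.int8)
    for focal in gt.TFLGS:
        expected = brute_force_pad(grid, focal)
        got = pad(grid, focal)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)


def test_pai_ratio_and_antisymmetry(rng):
    grid = rng.integers(-1, 8, size=(15, 15)).astype(np.int8)
    v = pai(grid, 1, 2)
    w = pai(grid, 2, 1)
    if not math.isnan(v) and v != 0:
        assert w == pytest.approx(1.0 / v)
    assert pai(grid, 1, 2) == pytest.approx(
        brute_force_pad(grid, 1) / brute_force_pad(grid, 2))


def test_pai_symmetric_configuration_is_one():
    # pair B's layout is a translated relabeling of pair A's
    g = grid_from({(1, 1): 1, (1, 2): 6, (6, 1): 2, (6, 2): 5})
    assert pai(g, 1, 2) == pytest.approx(1.0)


def test_pai_flagged_on_zero_denominator():
    g = grid_from({(0, 0): 1, (0, 1): 6, (5, 5): 2})  # PAD(2) = 0
    assert math.isnan(pai(g, 1, 2))


# -- region size ------------------------------------------------------------

def test_region_size_counts_pair_members():
    entries = {}
    k = 0
    for i in range(25):
        entries[(i // 5, i % 5)] = 1 if k < 12 else 6
        k += 1
    g = grid_from(entries, L=20)
    assert region_size(g, (1, 6)) == 25
    assert region_size(g, (2, 5)) == 0


def test_region_size_129_split():
    g = np.full((20, 20), gt.EMPTY, dtype=np.int8)
    flat = g.ravel()
    flat[:60] = 1
    flat[60:129] = 6
    assert region_size(g, (1, 6)) == 129


# -- classification ---------------------------------------------------------

def census_grid(counts, L=40):
    g = np.full(L * L, gt.EMPTY, dtype=np.int8)
    i = 0
    for code, n in counts.items():
        g[i:i + n] = code
        i += n
    return g.reshape(L, L)


def test_classify_cascade():
    assert classify_pattern(census_grid({7: 100})).label == "ancestor_dominated"
    assert classify_pattern(census_grid({1: 55, 6: 45})).label == "AFC_001_110"
    assert classify_pattern(
        census_grid({1: 33, 2: 33, 4: 34})).label == "complete_functional_division"
    assert classify_pattern(census_grid({7: 60, 0: 40})).label == "one_way_dependency"
    assert classify_pattern(census_grid({})).label == "collapsed"
    assert classify_pattern(
        census_grid({1: 40, 6: 30, 2: 30})).label == "unresolved"


def test_classify_tolerates_cheaters_in_afc():
    call = classify_pattern(census_grid({1: 50, 6: 40, 0: 10}))
    assert call.label == "AFC_001_110"
    assert call.cheater_fraction == pytest.approx(0.1)


def test_classify_translation_invariant(rng):
    g = census_grid({1: 120, 6: 90, 0: 12})
    base = classify_pattern(g).label
    for _ in range(5):
        shifted = np.roll(g, rng.integers(1, 40, size=2), axis=(0, 1))
        assert classify_pattern(shifted).label == base


# -- timing and steady state ------------------------------------------------

def snapshot(step, counts_dict, L=30):
    g = census_grid(counts_dict, L)
    return CommunitySnapshot(step, g, gt.census(g))


def test_competition_timing_scripted():
    colos = [(50, 6), (80, 5), (100, 1), (400, 2)]
    snaps = [
        snapshot(0, {7: 100}),
        snapshot(400, {1: 60, 6: 69, 7: 200, 5: 50}),
        snapshot(5000, {1: 300, 6: 200, 2: 150, 5: 100, 7: 10}),
    ]
    out = competition_timing(snaps, colos)
    assert out["t1"] == 100 and out["t2"] == 400
    assert out["timegap"] == 300
    assert out["first_pair"] == 1 and out["second_pair"] == 2
    assert out["prior_space_at_t2"] == 129
    assert out["t3"] == 5000


def test_competition_timing_simultaneous_emergence():
    colos = [(100, 1), (100, 2)]
    out = competition_timing([snapshot(100, {1: 5, 2: 5})], colos)
    assert out["timegap"] == 0


def test_competition_timing_single_pair_flagged():
    out = competition_timing([snapshot(0, {1: 5, 6: 5})], [(100, 1)])
    assert out["t2"] is None and math.isnan(out["timegap"])
    with pytest.raises(ValueError):
        competition_timing([snapshot(0, {7: 5})], [(0, 7)])


def test_steady_state_detection(rng):
    const = np.tile([0.5, 0.5, 0, 0, 0, 0, 0, 0], (200, 1))
    assert steady_state_reached(const, window=100, tol=0.01)
    drift = const.copy()
    drift[:, 0] = np.linspace(0.5, 0.54, 200)  # 0.02 per trailing window
    drift[:, 1] = 1 - drift[:, 0]
    assert not steady_state_reached(drift, window=100, tol=0.01)
    noisy = const + rng.normal(0, 0.001, size=const.shape)
    assert steady_state_reached(noisy, window=100, tol=0.01)
    with pytest.raises(ValueError):
        steady_state_reached(const, window=500)
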