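"""Unit tests of the scalar update rules (cost, benefit, growth, division)."""

import numpy as np
import pytest

from bqsim import Cell, LatticeState, LocalEnvironment, SimConfig
from bqsim import genotypes as gt
from bqsim.engine import (
    benefit,
    check_death,
    check_division,
    consume_goods,
    cost,
    divide,
    growth_step,
    mutate,
    nutrient_limited_growth,
    produce_goods,
)


@pytest.fixture
def cfg():
    return SimConfig(L=8, alpha=0.001, beta=0.8, d_max=0.1, g_max=0.2,
                     eps_amplitude=0.0)


def env(S=0.0, goods=(0.0, 0.0, 0.0)):
    return LocalEnvironment(substrate=S, goods=np.array(goods, dtype=float))


@pytest.mark.parametrize("bits,alpha,expected", [
    ([1, 1, 1], 0.001, 0.003),
    ([0, 0, 0], 0.05, 0.0),
    ([1, 0, 0], 0.0005, 0.0005),
])
def test_cost_is_linear_in_carried_functions(bits, alpha, expected):
    assert cost(gt.bits_to_code(bits), alpha) == pytest.approx(expected)


def test_benefit_zero_without_goods(cfg):
    assert benefit(env(), cfg, gt.CHEATER) == 0.0
    # any missing essential good forces zero benefit
    assert benefit(env(goods=(1e12, 1e12, 0.0)), cfg, gt.CHEATER) == 0.0


def test_benefit_saturates_at_d_max(cfg):
    assert benefit(env(goods=(1e9, 1e9, 1e9)), cfg, gt.CHEATER) == \
        pytest.approx(cfg.d_max)
    # carried goods are satisfied internally regardless of the environment
    assert benefit(env(), cfg, gt.ANCESTOR) == pytest.approx(cfg.d_max)


def test_benefit_monod_half_saturation():
    cfg = SimConfig(L=8, benefit_mode="monod", K_P=0.1, d_max=0.1)
    e = env(goods=(cfg.K_P, cfg.K_P, cfg.K_P))
    assert benefit(e, cfg, gt.CHEATER) == pytest.approx(0.05)


@pytest.mark.parametrize("S,expected_factor", [
    (0.0, 0.0), (1.0, 0.5), (1e12, 1.0)])
def test_monod_substrate_limitation(cfg, S, expected_factor):
    assert nutrient_limited_growth(env(S=S), cfg) == \
        pytest.approx(cfg.g_max * expected_factor, rel=1e-6)


def test_growth_step_pure_decay(cfg):
    # no substrate, no goods: a non-producer decays at the full death rate
    cell = Cell(gt.CHEATER, 150.0)
    assert growth_step(cell, env(), cfg) == pytest.approx(135.0)


def test_growth_step_euler_arithmetic():
    # hand-derived: X' = X * (1 + (g - C) - (d_max - G))
    # cheater in monod mode with P = K_P: G = 0.05; saturating substrate:
    # g ~ 0.2; C = 0  ->  X' = 150 * 1.15 = 172.5
    cfg = SimConfig(L=8, benefit_mode="monod", K_P=0.1)
    e = env(S=1e12, goods=(0.1, 0.1, 0.1))
    out = growth_step(Cell(gt.CHEATER, 150.0), e, cfg)
    assert out == pytest.approx(172.5, rel=1e-6)


def test_growth_step_zero_net_rate(cfg):
    # g exactly cancels cost, benefit exactly cancels death
    c = cfg.replace(alpha=0.0)
    cell = Cell(gt.ANCESTOR, 200.0)
    assert growth_step(cell, env(S=0.0), c.replace(d_max=0.0)) == \
        pytest.approx(200.0)


def test_growth_consumes_substrate(cfg):
    e = env(S=5.0)
    growth_step(Cell(gt.ANCESTOR, 150.0), e, cfg)
    assert e.substrate < 5.0


def test_produce_goods_secretes_alpha_X(cfg):
    e = env()
    produce_goods(Cell(gt.ANCESTOR, 150.0), e, cfg)
    np.testing.assert_allclose(e.goods, 0.15)
    e2 = env()
    produce_goods(Cell(gt.bits_to_code([1, 0, 0]), 150.0), e2, cfg)
    np.testing.assert_allclose(e2.goods, [0.15, 0.0, 0.0])
    e3 = env()
    produce_goods(Cell(gt.CHEATER, 150.0), e3, cfg)
    np.testing.assert_allclose(e3.goods, 0.0)


def test_consume_goods_requirement_and_cap(cfg):
    # requirement per non-carried good: beta * alpha * X * dt = 0.12
    e = env(goods=(1.0, 1.0, 1.0))
    consume_goods(Cell(gt.CHEATER, 150.0), e, cfg)
    np.testing.assert_allclose(e.goods, 0.88)
    # uptake capped at availability, never below zero
    e2 = env(goods=(0.05, 0.0, 1.0))
    consume_goods(Cell(gt.CHEATER, 150.0), e2, cfg)
    np.testing.assert_allclose(e2.goods, [0.0, 0.0, 0.88])
    # carried goods are not drawn from the box
    e3 = env(goods=(1.0, 1.0, 1.0))
    consume_goods(Cell(gt.ANCESTOR, 150.0), e3, cfg)
    np.testing.assert_allclose(e3.goods, 1.0)


def test_consumption_linear_in_beta(cfg):
    e_hi = env(goods=(1.0, 1.0, 1.0))
    e_lo = env(goods=(1.0, 1.0, 1.0))
    consume_goods(Cell(gt.CHEATER, 150.0), e_hi, cfg)
    consume_goods(Cell(gt.CHEATER, 150.0), e_lo, cfg.replace(beta=0.4))
    assert (1.0 - e_lo.goods[0]) == pytest.approx((1.0 - e_hi.goods[0]) / 2)


def test_division_threshold(cfg, rng):
    assert check_division(Cell(gt.ANCESTOR, 300.0), cfg, rng)[0]
    assert not check_division(Cell(gt.ANCESTOR, 299.9), cfg, rng)[0]


def test_division_probability_with_noise(rng):
    # at X = 2*X0 exactly, the uniform threshold noise gives P(divide) = 1/2
    cfg = SimConfig(L=8, eps_amplitude=15.0)
    cell = Cell(gt.ANCESTOR, 300.0)
    hits = sum(check_division(cell, cfg, rng)[0] for _ in range(40_000))
    assert hits / 40_000 == pytest.approx(0.5, abs=0.01)


def test_death_threshold_strict(cfg, rng):
    assert check_death(Cell(gt.ANCESTOR, 29.9), cfg, rng)
    assert not check_death(Cell(gt.ANCESTOR, 30.0), cfg, rng)
    assert check_death(Cell(gt.ANCESTOR, -1.0), cfg.replace(eps_amplitude=50.0),
                       rng)


def test_mutate_loss_only(rng):
    assert mutate(gt.CHEATER, 0.9, rng) == gt.CHEATER
    assert mutate(gt.ANCESTOR, 1.0, rng) == gt.CHEATER
    assert mutate(gt.ANCESTOR, 0.0, rng) == gt.ANCESTOR


def test_mutate_rate_and_partial_order(rng):
    # over 1e6 divisions: children are subsets of parents and the mean
    # number of losses matches 3 * mut
    mut, n = 1e-3, 1_000_000
    losses = 0
    for _ in range(n):
        child = mutate(gt.ANCESTOR, mut, rng)
        assert gt.is_subset(child, gt.ANCESTOR)
        losses += 3 - gt.n_functions(child)
    expected = 3 * mut * n
    assert abs(losses - expected) < 4 * np.sqrt(expected)


def test_divide_splits_biomass_equally(cfg, rng):
    state = LatticeState.empty(cfg.L)
    state.genotype[2, 2] = gt.ANCESTOR
    state.biomass[2, 2] = 300.0
    cell = Cell(gt.ANCESTOR, 300.0, (2, 2))
    daughter = divide(cell, state, cfg.replace(mut=0.0), rng)
    assert daughter is not None
    assert cell.biomass == daughter.biomass == 150.0
    dr = abs(daughter.position[0] - 2) + abs(daughter.position[1] - 2)
    assert dr == 1  # von Neumann adjacency
    assert daughter.genotype == gt.ANCESTOR


def test_divide_deferred_when_surrounded(cfg, rng):
    state = LatticeState.empty(cfg.L)
    for r, c in ((2, 2), (1, 2), (3, 2), (2, 1), (2, 3)):
        state.genotype[r, c] = gt.ANCESTOR
        state.biomass[r, c] = 700.0
    cell = Cell(gt.ANCESTOR, 700.0, (2, 2))
    before = state.genotype.copy()
    assert divide(cell, state, cfg, rng) is None
    np.testing.assert_array_equal(state.genotype, before)
    assert cell.biomass == cfg.biomass_cap  # capped at 2 * (2 X0)
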