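import numpy as np
import pytest
from click.testing import CliRunner

from bqsim import SimConfig, Simulation
from bqsim import genotypes as gt
from bqsim.cli import main as cli_main
from bqsim.experiments import (
    PAIR_A,
    PAIR_B,
    ExperimentPlan,
    init_ancestor,
    init_premixed,
    init_symmetric,
    premix_counts,
    run_disturbance,
    run_sweep,
    run_well_mixed,
    score_pair_competition,
)
from bqsim.metrics import pai


def test_init_ancestor_counts_and_replay():
    cfg = SimConfig(L=100, seed=5)
    state = init_ancestor(cfg, n=100, rng=np.random.default_rng(5))
    assert state.n_cells == 100
    assert (state.counts()[gt.ANCESTOR]) == 100
    assert np.all(state.biomass[state.genotype >= 0] == cfg.X0)
    replay = init_ancestor(cfg, n=100, rng=np.random.default_rng(5))
    np.testing.assert_array_equal(state.genotype, replay.genotype)


def test_init_ancestor_full_and_overfull():
    cfg = SimConfig(L=10, seed=0)
    full = init_ancestor(cfg, n=100)
    assert full.n_cells == 100
    with pytest.raises(Exception):
        init_ancestor(cfg, n=101)


def test_premix_exact_full_scale_census():
    cfg = SimConfig(L=100, seed=3)
    state, p = init_premixed(cfg, np.random.default_rng(3))
    counts = state.counts()
    assert counts[PAIR_A[0]] == 3000 and counts[PAIR_B[0]] == 3000
    assert counts[PAIR_A[1]] == 1500 and counts[PAIR_B[1]] == 1500
    # the two pairs have equal total abundance
    assert counts[PAIR_A[0]] + counts[PAIR_A[1]] == \
        counts[PAIR_B[0]] + counts[PAIR_B[1]]
    assert 0.8 < p < 1.2
    assert premix_counts(100)[PAIR_A[0]] == 3000


def test_init_symmetric_mirror_and_pai_one():
    cfg = SimConfig(L=40, seed=1)
    state = init_symmetric(cfg, rng=np.random.default_rng(1))
    g = state.genotype
    L = cfg.L
    left, right = g[:, :L // 2], g[:, L // 2:]
    # mirrored occupancy with pair labels swapped
    relabel = {PAIR_A[0]: PAIR_B[0], PAIR_A[1]: PAIR_B[1], gt.EMPTY: gt.EMPTY}
    np.testing.assert_array_equal(
        np.vectorize(relabel.get)(left[:, ::-1]), right)
    counts = state.counts()
    assert counts[PAIR_A[0]] == counts[PAIR_B[0]]
    assert counts[PAIR_A[1]] == counts[PAIR_B[1]]
    assert pai(g, PAIR_A[0], PAIR_B[0]) == pytest.approx(1.0)


def test_init_symmetric_requires_even_side():
    with pytest.raises(Exception):
        init_symmetric(SimConfig(L=15, seed=0))


def test_sweep_frequencies_sum_to_one_per_cell():
    cfg = SimConfig(L=12, mut=1e-3, n_steps=300)
    plan = ExperimentPlan("sweep", cfg, replicates=2, seed=1)
    table = run_sweep(plan, alphas=(0.001,), betas=(0.8,))
    assert table.frequency.sum() == pytest.approx(1.0)
    assert (table.n == 2).all()
    assert ((table.ci_low <= table.frequency)
            & (table.frequency <= table.ci_high)).all()
    assert np.allclose(table.scale_factor, (12 / 100) ** 2)


def test_sweep_mut_zero_stays_ancestral():
    cfg = SimConfig(L=12, mut=0.0, n_steps=400)
    plan = ExperimentPlan("sweep", cfg, replicates=2, seed=3)
    table = run_sweep(plan, alphas=(0.001,), betas=(0.8,))
    assert set(table.label) == {"ancestor_dominated"}


def test_disturbance_zero_window_is_identity():
    cfg = SimConfig(L=12, seed=6, mut=0.0)
    state, _ = init_premixed(cfg, np.random.default_rng(6))
    ts = run_disturbance(cfg, state, seed=6, t_before=150, hours_off=0.0,
                         t_after=0)
    control = Simulation(cfg, state.copy(), seed=6, record_events=False)
    control.run(150, stop_when_empty=False)
    ref = control.timeseries()
    assert (ts.phase == "before").all()
    assert ts.n_cells.tolist() == ref.n_cells.tolist()
    assert ts.total_biomass.tolist() == ref.total_biomass.tolist()


def test_disturbance_substrate_non_increasing_in_window():
    cfg = SimConfig(L=12, seed=6, mut=0.0, substrate_decay=0.01)
    state, _ = init_premixed(cfg, np.random.default_rng(6))
    ts = run_disturbance(cfg, state, seed=6, t_before=100, hours_off=2.0,
                         t_after=50)
    window = ts[ts.phase == "disturbance"].total_substrate.to_numpy()
    assert np.all(np.diff(window) <= 1e-9)


def test_well_mixed_fields_uniform_every_step():
    cfg = SimConfig(L=12, seed=2, mut=0.0)
    sim = run_well_mixed(cfg, state=init_ancestor(cfg, n=6), seed=2,
                         n_steps=30)
    assert np.ptp(sim.state.substrate) == pytest.approx(0.0, abs=1e-12)
    for j in range(3):
        assert np.ptp(sim.state.goods[j]) == pytest.approx(0.0, abs=1e-12)


def test_score_pair_competition_region_fallback():
    from bqsim.engine import LatticeState

    st = LatticeState.empty(10)
    st.genotype[0, :5] = PAIR_A[0]
    st.genotype[1, :3] = PAIR_A[1]
    st.genotype[5, :2] = PAIR_B[0]
    st.biomass[st.genotype >= 0] = 150.0
    winner, terminal = score_pair_competition(st)
    assert winner == "A" and not terminal


def test_replicate_seeds_distinct():
    plan = ExperimentPlan("sweep", SimConfig(L=12), replicates=50, seed=0)
    seeds = plan.replicate_seeds()
    assert len(set(seeds)) == 50
    assert plan.replicate_seeds() == seeds


def test_cli_run_and_analyze(tmp_path):
    runner = CliRunner()
    out = tmp_path / "run"
    res = runner.invoke(cli_main, [
        "run", "--seed", "3", "--out", str(out), "--steps", "200",
        "--cells", "5"])
    assert res.exit_code == 0, res.output
    for name in ("config.yaml", "final_snapshot.txt", "events.tsv",
                 "timeseries.tsv", "manifest.json"):
        assert (out / name).exists()
    res2 = runner.invoke(cli_main, ["analyze", "--run-dir", str(out)])
    assert res2.exit_code == 0, res2.output
    assert "pattern:" in res2.output
    assert (out / "lineage.nwk").exists()
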