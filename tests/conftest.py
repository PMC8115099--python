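"""Shared fixtures.

The heavy simulation batches used by the acceptance suite are
session-scoped so several tests can share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from bqsim import SimConfig, Simulation
from bqsim.experiments import ExperimentPlan, analyze_run, init_ancestor, run_sweep


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_config():
    return SimConfig(L=16, seed=1, n_steps=100)


def run_evolution(seed: int, L: int, mut: float, n_steps: int,
                  alpha: float = 0.001, beta=0.8, n0: int | None = None,
                  record_events: bool = True) -> Simulation:
    cfg = SimConfig(L=L, seed=seed, mut=mut, alpha=alpha, beta=beta)
    n0 = n0 if n0 is not None else max(4, L * L // 100)
    sim = Simulation(cfg, init_ancestor(cfg, n=n0), record_events=record_events)
    sim.run(n_steps)
    return sim


@pytest.fixture(scope="session")
def lineage_batch():
    """12 evolutionary runs at the typical interdependent condition.

    Desk-scale profile: 48 x 48 lattice, per-function loss probability
    5e-5 (the full-scale 1e-5 scaled up by the lattice-area ratio so the
    per-community mutant supply is comparable), alpha = 0.001, beta = 0.8,
    150,000 steps.
    """
    results = []
    for seed in range(12):
        sim = run_evolution(seed, L=48, mut=5e-5, n_steps=150_000, n0=23)
        results.append(analyze_run(sim))
    return results


@pytest.fixture(scope="session")
def sweep_tables():
    """Desk-scale alpha x beta sweep: low-cost row and interdependent rows.

    The cheap-cost row (alpha = 1e-4) is assessed after 40,000 steps with
    5 replicates; the rows where interdependent patterns can evolve run
    150,000 steps with 3 replicates each (32 x 32 lattice, loss
    probability 1e-4).
    """
    base = SimConfig(L=32, mut=1e-4)
    low = run_sweep(
        ExperimentPlan("sweep", base.replace(n_steps=40_000),
                       replicates=5, seed=42),
        alphas=(0.0001,))
    high = run_sweep(
        ExperimentPlan("sweep", base.replace(n_steps=150_000),
                       replicates=3, seed=42),
        alphas=(0.0005, 0.001))
    return low, high
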