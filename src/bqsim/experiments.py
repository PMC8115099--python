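"""Experiment protocols: initializations, sweeps, competitions, disturbance.

Five reproducible drivers around the simulator:

* ``run_sweep`` — outcome frequencies across a grid of function cost
  (alpha) and requirement ratio (beta) values, each cell replicated.
* ``run_premix_study`` — communities premixed from the two AFCPs
  [0,0,1]&[1,1,0] and [0,1,0]&[1,0,1], binned by their initial partner
  association index, competed with mutation off, and scored by which pair
  wins.
* ``init_symmetric`` / ``run_competition`` — the mirror-image control in
  which neither pair has any initial positioning advantage.
* ``run_disturbance`` — a substrate shut-off window (specified in hours)
  applied to an evolved or control community.
* ``run_well_mixed`` — the same engine with diffusion replaced by even
  redistribution of all fields each step.

Two condition profiles are provided: ``PAPER_PROFILE`` mirrors the
full-scale study conditions (100 x 100 lattice, per-function loss
probability 1e-5, >= 1.5 M steps); ``DESK_PROFILE`` is the package's
scaled-down profile for desk-scale statistics (32 x 32 lattice, loss
probability 1e-4 — the smaller lattice supports ~1/10 the division flux,
so the loss probability is scaled up to keep the per-community mutant
supply comparable — and 1e5 steps).  Every driver stamps the profile's
scale factor into its outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import stats

from . import genotypes as gt
from .config import ConfigError, SimConfig
from .engine import LatticeState, Simulation
from .lineage import colonization_events, detect_key_events
from .metrics import CommunitySnapshot, classify_pattern, pai, region_size

__all__ = [
    "PAPER_PROFILE",
    "DESK_PROFILE",
    "ExperimentPlan",
    "init_ancestor",
    "init_premixed",
    "init_symmetric",
    "run_sweep",
    "run_premix_study",
    "run_competition",
    "run_disturbance",
    "run_well_mixed",
    "score_pair_competition",
]

PAPER_PROFILE: dict = {"L": 100, "mut": 1e-5, "n_steps": 1_500_000}
DESK_PROFILE: dict = {"L": 32, "mut": 1e-4, "n_steps": 100_000}

#: The two competing pairs of the premix/symmetric protocols, by TFLG code.
PAIR_A = (gt.bits_to_code([0, 0, 1]), gt.bits_to_code([1, 1, 0]))
PAIR_B = (gt.bits_to_code([0, 1, 0]), gt.bits_to_code([1, 0, 1]))


@dataclass
class ExperimentPlan:
    """A protocol, its base configuration and its replication settings."""

    protocol: str  # sweep | premix | symmetric | disturbance | well_mixed
    config: SimConfig
    replicates: int = 20
    seed: int = 0
    knobs: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = {"sweep", "premix", "symmetric", "disturbance", "well_mixed"}
        if self.protocol not in allowed:
            raise ConfigError(f"unknown protocol {self.protocol!r}")

    @property
    def scale_factor(self) -> float:
        """Lattice-area ratio relative to the full-scale study conditions."""
        return (self.config.L / PAPER_PROFILE["L"]) ** 2

    def replicate_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.seed)
        return [int(s) % 2**31 for s in ss.generate_state(self.replicates)]


# ---------------------------------------------------------------------------
# Initializations
# ---------------------------------------------------------------------------

def init_ancestor(config: SimConfig, n: int = 100,
                  rng: np.random.Generator | None = None) -> LatticeState:
    """``n`` ancestor cells at biomass X0 on uniformly random distinct boxes."""
    if n > config.L**2:
        raise ConfigError(f"{n} cells do not fit on a {config.L}x{config.L} grid")
    rng = rng or np.random.default_rng(config.seed)
    state = LatticeState.empty(config.L)
    pos = rng.choice(config.L**2, size=n, replace=False)
    state.genotype.flat[pos] = gt.ANCESTOR
    state.biomass.flat[pos] = config.X0
    return state


def premix_counts(L: int) -> dict[int, int]:
    """Premix cell numbers for lattice side L.

    At the full scale (L = 100) these are exactly 3000 cells of each TFLG
    and 1500 of each OFLG; other sizes keep the same densities (0.30 and
    0.15 of the boxes), so the two pairs always have equal abundance and
    each pair keeps the 2:1 TFLG:OFLG ratio of evolved communities.
    """
    n_tfg = round(0.30 * L * L)
    n_ofg = round(0.15 * L * L)
    return {PAIR_A[0]: n_tfg, PAIR_B[0]: n_tfg,
            PAIR_A[1]: n_ofg, PAIR_B[1]: n_ofg}


def init_premixed(config: SimConfig,
                  rng: np.random.Generator | None = None
                  ) -> tuple[LatticeState, float]:
    """Randomly premixed four-genotype community plus its initial PAI.

    Returns ``(state, pai_001_010)``: the partner association index of pair
    [0,0,1]&[1,1,0] relative to pair [0,1,0]&[1,0,1] in the placement.
    """
    rng = rng or np.random.default_rng(config.seed)
    counts = premix_counts(config.L)
    total = sum(counts.values())
    if total > config.L**2:
        raise ConfigError("premix does not fit on the lattice")
    state = LatticeState.empty(config.L)
    pos = rng.choice(config.L**2, size=total, replace=False)
    codes = np.repeat(list(counts.keys()), list(counts.values()))
    state.genotype.flat[pos] = codes
    state.biomass.flat[pos] = config.X0
    return state, pai(state.genotype, PAIR_A[0], PAIR_B[0])


def init_symmetric(config: SimConfig, fill: float = 0.9,
                   rng: np.random.Generator | None = None) -> LatticeState:
    """Mirror-symmetric two-pair layout: no pair has a positioning advantage.

    The left half of the (even-sided) lattice is seeded with pair
    [0,0,1]&[1,1,0] (TFLG:OFLG 2:1, ``fill`` of the boxes occupied); the
    right half is its exact mirror image carrying pair [0,1,0]&[1,0,1], so
    occupancy is mirror-symmetric and the initial PAI is exactly 1.
    """
    L = config.L
    if L % 2:
        raise ConfigError("symmetric initialization needs an even lattice side")
    rng = rng or np.random.default_rng(config.seed)
    half_boxes = L * (L // 2)
    n_cells = round(fill * half_boxes)
    n_tfg = round(n_cells * 2 / 3)
    n_ofg = n_cells - n_tfg
    state = LatticeState.empty(L)
    pos = rng.choice(half_boxes, size=n_cells, replace=False)
    codes = np.repeat([PAIR_A[0], PAIR_A[1]], [n_tfg, n_ofg])
    left = np.full((L, L // 2), gt.EMPTY, dtype=np.int8)
    left.flat[pos] = codes
    state.genotype[:, :L // 2] = left
    # mirror occupancy, relabel pair A -> pair B
    relabel = {PAIR_A[0]: PAIR_B[0], PAIR_A[1]: PAIR_B[1]}
    mirrored = left[:, ::-1]
    right = np.full_like(mirrored, gt.EMPTY)
    for src, dst in relabel.items():
        right[mirrored == src] = dst
    state.genotype[:, L // 2:] = right
    state.biomass[state.genotype >= 0] = config.X0
    return state


# ---------------------------------------------------------------------------
# Protocol drivers
# ---------------------------------------------------------------------------

def _binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval for a frequency."""
    a = (1 - level) / 2
    lo = stats.beta.ppf(a, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - a, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def run_sweep(plan: ExperimentPlan, alphas=(0.0001, 0.0005, 0.001),
              betas=(0.4, 0.6, 0.8), n_init: int = 100,
              theta: float = 0.95) -> pd.DataFrame:
    """Outcome frequencies over the alpha x beta grid.

    Each grid cell runs ``plan.replicates`` independent ancestor-seeded
    simulations, classifies the final pattern, and reports per-label
    frequencies with Clopper-Pearson confidence intervals.  The plan's
    lattice-area scale factor is stamped on every row.
    """
    seeds = plan.replicate_seeds()
    rows = []
    for a in alphas:
        for b in betas:
            labels = []
            for seed in seeds:
                cfg = plan.config.replace(alpha=a, beta=b, seed=seed)
                rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
                n0 = min(n_init, max(4, cfg.L**2 // 100))
                sim = Simulation(cfg, init_ancestor(cfg, n=n0, rng=rng),
                                 record_events=False)
                sim.run()
                labels.append(classify_pattern(sim.state, theta).label)
            n = len(labels)
            for lab in sorted(set(labels)):
                k = labels.count(lab)
                lo, hi = _binomial_ci(k, n)
                rows.append({"alpha": a, "beta": b, "label": lab,
                             "count": k, "n": n, "frequency": k / n,
                             "ci_low": lo, "ci_high": hi,
                             "scale_factor": plan.scale_factor})
    return pd.DataFrame(rows)


def score_pair_competition(state: LatticeState, theta: float = 0.95
                           ) -> tuple[str, bool]:
    """Which of the two premix pairs holds the lattice.

    Returns ``(winner, terminal)``: winner is ``"A"`` ([0,0,1]&[1,1,0]),
    ``"B"`` ([0,1,0]&[1,0,1]) or ``"none"`` (empty / exact tie).  Terminal
    means the winner satisfies the dominance threshold; otherwise the pair
    currently occupying more space is reported as leading.
    """
    label = classify_pattern(state, theta).label
    if label == f"AFC_{gt.compact_label(PAIR_A[0])}_{gt.compact_label(PAIR_A[1])}":
        return "A", True
    if label == f"AFC_{gt.compact_label(PAIR_B[0])}_{gt.compact_label(PAIR_B[1])}":
        return "B", True
    size_a = region_size(state, PAIR_A)
    size_b = region_size(state, PAIR_B)
    if size_a == size_b:
        return "none", False
    return ("A" if size_a > size_b else "B"), False


def run_competition(config: SimConfig, state: LatticeState, seed: int,
                    n_steps: int | None = None,
                    theta: float = 0.95) -> tuple[str, bool]:
    """Run one premixed/symmetric competition (mutation off) and score it."""
    cfg = config.replace(mut=0.0)
    sim = Simulation(cfg, state.copy(), seed=seed, record_events=False)
    sim.run(n_steps)
    return score_pair_competition(sim.state, theta)


def run_premix_study(plan: ExperimentPlan, n_init: int = 3000,
                     n_bins: int = 15, min_per_bin: int = 40,
                     n_steps: int | None = None) -> pd.DataFrame:
    """Winning frequency of pair [0,0,1]&[1,1,0] versus initial PAI.

    Generates ``n_init`` random premixed communities, bins them into
    ``n_bins`` uniform bins over the observed PAI range, keeps up to
    ``min_per_bin`` per bin, runs each selected community once with
    mutation off (replication across communities within a bin), and
    reports the per-bin winning frequency of pair A.  Empty bins are
    skipped.
    """
    ss = np.random.SeedSequence(plan.seed)
    gen_rng = np.random.default_rng(ss.spawn(1)[0])
    run_seeds = iter(int(s) % 2**31 for s in ss.generate_state(n_init + 8))
    states, pais = [], []
    for _ in range(n_init):
        st, p = init_premixed(plan.config, rng=gen_rng)
        states.append(st)
        pais.append(p)
    pais = np.asarray(pais)
    edges = np.linspace(pais.min(), pais.max() + 1e-12, n_bins + 1)
    which = np.digitize(pais, edges) - 1
    rows = []
    for b in range(n_bins):
        idx = np.nonzero(which == b)[0][:min_per_bin]
        if len(idx) == 0:
            continue
        wins_a = ties = 0
        for i in idx:
            winner, _ = run_competition(plan.config, states[i],
                                        next(run_seeds), n_steps)
            wins_a += winner == "A"
            ties += winner == "none"
        n = len(idx) - ties
        rows.append({"bin": b, "pai_low": edges[b], "pai_high": edges[b + 1],
                     "pai_mean": float(pais[idx].mean()), "n_runs": len(idx),
                     "wins_a": wins_a,
                     "win_freq_a": wins_a / n if n else np.nan,
                     "scale_factor": plan.scale_factor})
    return pd.DataFrame(rows)


def run_disturbance(config: SimConfig, state: LatticeState, seed: int,
                    t_before: int, hours_off: float = 12.0,
                    t_after: int | None = None) -> pd.DataFrame:
    """Substrate shut-off protocol applied to an existing community.

    Runs ``t_before`` steps normally, then sets the substrate supply to
    zero for ``hours_off * steps_per_hour`` steps, restores it and runs
    ``t_after`` recovery steps (default: the window length).  Returns the
    per-step time series with a ``phase`` column; a zero-length window
    reproduces the undisturbed trajectory exactly.
    """
    window = int(round(hours_off * config.steps_per_hour))
    t_after = window if t_after is None else int(t_after)
    sim = Simulation(config, state.copy(), seed=seed, record_events=False)
    sim.run(t_before, stop_when_empty=False)
    sim.config = config.replace(supply_rate=0.0) if window else sim.config
    sim.run(window, stop_when_empty=False)
    sim.config = config
    sim.run(t_after, stop_when_empty=False)
    ts = sim.timeseries()
    phase = np.full(len(ts), "recovery", dtype=object)
    phase[ts.step <= t_before] = "before"
    phase[(ts.step > t_before) & (ts.step <= t_before + window)] = "disturbance"
    ts["phase"] = phase
    return ts


def run_well_mixed(config: SimConfig, state: LatticeState | None = None,
                   seed: int | None = None,
                   n_steps: int | None = None) -> Simulation:
    """Run with all fields evenly redistributed each step (no spatial refuge)."""
    cfg = config.replace(well_mixed=True)
    if state is None:
        state = init_ancestor(cfg, n=max(4, cfg.L**2 // 100))
    sim = Simulation(cfg, state.copy(), seed=seed)
    sim.run(n_steps)
    return sim


def analyze_run(sim: Simulation, theta: float = 0.95,
                colonization_threshold: float = 0.05) -> dict:
    """Lineage summary of a finished run: colonizations, key events, label."""
    abundance = sim.abundance_array()
    steps = sim.steps_array()
    colos = colonization_events(abundance, steps, colonization_threshold)
    label = classify_pattern(sim.state, theta).label
    sig = detect_key_events(sim.event_dataframe(), colos, final_pattern=label)
    return {"colonizations": colos, "signature": sig, "final_pattern": label,
            "final_counts": sim.state.counts()}
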