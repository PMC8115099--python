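"""Core individual-based model of Black Queen reductive evolution.

Cells live on an L x L periodic lattice, at most one per box, above four
concentration fields (one growth substrate, three essential public goods).
Each cell carries a 3-bit genotype saying which goods it produces.  Per
time step, occupied boxes are visited in a fresh random order and each cell

1. secretes ``alpha * X * dt`` of every carried good into its box,
2. draws its requirement ``beta_j * alpha * X * dt`` of every NON-carried
   good from the box (capped at availability); carried goods are satisfied
   internally by the cell's own production,
3. takes up substrate and grows by forward Euler,

       dX/dt = [(g_i - C_i) - (d_max - G_i)] * X,

   with Monod substrate limitation ``g_i = g_max * S/(K_S + S)``, linear
   cost ``C_i = alpha * (functions carried)`` and benefit
   ``G_i = d_max * min_j s_j`` where ``s_j`` is the fulfillment of good j
   (1 for carried goods),
4. dies when biomass falls below ``0.2 X0 + eps`` and divides into a free
   adjacent box when it exceeds ``2 X0 + eps`` (eps a fresh uniform noise
   draw); the daughter may lose carried functions with probability ``mut``
   per function.

After the sweep the substrate supply is added, first-order field decay is
applied, and all four fields diffuse (or are evenly redistributed in the
well-mixed variant).  Every stochastic choice flows from one seeded
generator per run, so trajectories replay bit-identically.

The scalar functions (:func:`cost`, :func:`benefit`, ...) are the readable
reference implementations of the update rules; :class:`Simulation` runs the
same rules in a compiled sweep over the whole lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import genotypes as gt
from .config import SimConfig
from .diffusion import well_mixed_redistribute
from ._kernel import diffuse_inplace, seed_kernel, sweep_kernel

__all__ = [
    "Cell",
    "LocalEnvironment",
    "LatticeState",
    "Simulation",
    "cost",
    "benefit",
    "nutrient_limited_growth",
    "growth_step",
    "produce_goods",
    "consume_goods",
    "check_division",
    "check_death",
    "mutate",
    "divide",
]


_N_FUNCS = np.array([gt.n_functions(g) for g in range(8)], dtype=float)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Cell:
    """One individual: genotype code (0..7), biomass (fg), lattice position."""

    genotype: int
    biomass: float
    position: tuple[int, int] = (0, 0)


@dataclass
class LocalEnvironment:
    """Concentrations in the focal box: substrate and the three goods (fg)."""

    substrate: float
    goods: np.ndarray  # length-3

    def __post_init__(self) -> None:
        self.goods = np.asarray(self.goods, dtype=float)
        if self.substrate < 0 or np.any(self.goods < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass
class LatticeState:
    """Full lattice state: occupancy plus the four concentration fields."""

    genotype: np.ndarray  # (L, L) int8, -1 = empty
    biomass: np.ndarray  # (L, L) float64, 0 where empty
    substrate: np.ndarray  # (L, L) float64
    goods: np.ndarray  # (3, L, L) float64
    step: int = 0

    @classmethod
    def empty(cls, L: int, substrate: float = 0.0) -> "LatticeState":
        return cls(
            genotype=np.full((L, L), gt.EMPTY, dtype=np.int8),
            biomass=np.zeros((L, L)),
            substrate=np.full((L, L), float(substrate)),
            goods=np.zeros((3, L, L)),
        )

    @property
    def L(self) -> int:
        return self.genotype.shape[0]

    @property
    def n_cells(self) -> int:
        return int(np.count_nonzero(self.genotype >= 0))

    def counts(self) -> np.ndarray:
        return gt.census(self.genotype)

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.genotype.copy(), self.biomass.copy(),
            self.substrate.copy(), self.goods.copy(), self.step,
        )

    def validate(self) -> None:
        L = self.L
        if self.genotype.shape != (L, L) or self.biomass.shape != (L, L):
            raise ValueError("grid shape mismatch")
        if self.goods.shape != (3, L, L) or self.substrate.shape != (L, L):
            raise ValueError("field shape mismatch")
        if np.any(self.substrate < 0) or np.any(self.goods < 0):
            raise ValueError("negative concentrations")
        occ = self.genotype >= 0
        if np.any(self.biomass[occ] <= 0):
            raise ValueError("occupied box with non-positive biomass")
        if np.any(self.biomass[~occ] != 0):
            raise ValueError("empty box with nonzero biomass")


# ---------------------------------------------------------------------------
# Scalar reference operations
# ---------------------------------------------------------------------------

def cost(genotype: int, alpha: float) -> float:
    """Total per-step cost rate C_i = alpha x (functions carried)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return alpha * gt.n_functions(genotype)


def _fulfillments(genotype: int, env: LocalEnvironment,
                  params: SimConfig, X: float) -> np.ndarray:
    """Per-good satisfaction s_j in [0, 1]; carried goods are fully met."""
    beta = params.beta_vec
    s = np.ones(3)
    for j in range(3):
        if gt.carries(genotype, j):
            continue
        if params.benefit_mode == "monod":
            s[j] = env.goods[j] / (params.K_P + env.goods[j])
        else:
            R = beta[j] * params.alpha * X * params.dt
            s[j] = 1.0 if R <= 0 else min(env.goods[j], R) / R
    return s


def benefit(env: LocalEnvironment, params: SimConfig,
            genotype: int = gt.CHEATER, X: float | None = None) -> float:
    """Growth benefit G_i = d_max * min_j s_j from the local public goods.

    All three goods are essential: if any non-carried good is absent the
    benefit is zero and the cell suffers the full death rate ``d_max``.
    Defaults describe a non-producer, for which every good must come from
    the environment.
    """
    X = params.X0 if X is None else X
    s = _fulfillments(genotype, env, params, X)
    return params.d_max * float(s.min())


def nutrient_limited_growth(env: LocalEnvironment, params: SimConfig) -> float:
    """Monod-limited realized maximum growth rate g_i = g_max*S/(K_S+S)."""
    S = env.substrate
    return params.g_max * S / (params.K_S + S)


def growth_step(cell: Cell, env: LocalEnvironment,
                params: SimConfig) -> float:
    """Forward-Euler biomass update; also consumes substrate from ``env``.

    Returns the updated biomass (<= 0 means the cell is already dead).
    Substrate uptake equals gross growth divided by the yield, capped at
    the amount present in the box.
    """
    X = cell.biomass
    g = nutrient_limited_growth(env, params)
    uptake = g * X * params.dt / params.yield_S
    if uptake > env.substrate:
        uptake = env.substrate
        g = uptake * params.yield_S / (X * params.dt) if X > 0 else 0.0
    env.substrate -= uptake
    C = cost(cell.genotype, params.alpha)
    G = benefit(env, params, cell.genotype, X)
    net = (g - C) - (params.d_max - G)
    return X + net * X * params.dt


def produce_goods(cell: Cell, env: LocalEnvironment,
                  params: SimConfig) -> None:
    """Secrete alpha*X*dt of every carried good into the local box."""
    for j in range(3):
        if gt.carries(cell.genotype, j):
            env.goods[j] += params.alpha * cell.biomass * params.dt

def consume_goods(cell: Cell, env: LocalEnvironment,
                  params: SimConfig) -> np.ndarray:
    """Draw the requirement of every non-carried good from the local box.

    The requirement of good j is ``beta_j * alpha * X * dt`` — the beta
    fraction of what a producer of the cell's size secretes per step.
    Uptake is capped at availability; returns the per-good uptake.
    """
    beta = params.beta_vec
    uptake = np.zeros(3)
    for j in range(3):
        if gt.carries(cell.genotype, j):
            continue
        R = beta[j] * params.alpha * cell.biomass * params.dt
        uptake[j] = min(env.goods[j], R)
        env.goods[j] -= uptake[j]
    return uptake


def check_division(cell: Cell, params: SimConfig,
                   rng: np.random.Generator) -> tuple[bool, float]:
    """Division check against the noisy upper threshold 2*X0 + eps."""
    eps = rng.uniform(-params.eps_amplitude, params.eps_amplitude) \
        if params.eps_amplitude > 0 else 0.0
    thr = params.division_threshold + eps
    return cell.biomass >= thr, thr


def check_death(cell: Cell, params: SimConfig,
                rng: np.random.Generator) -> bool:
    """Death check against the noisy lower threshold 0.2*X0 + eps."""
    if cell.biomass <= 0:
        return True
    eps = rng.uniform(-params.eps_amplitude, params.eps_amplitude) \
        if params.eps_amplitude > 0 else 0.0
    return cell.biomass < params.death_threshold + eps


def mutate(genotype: int, mut: float, rng: np.random.Generator) -> int:
    """Loss-only mutation: each carried function flips to 0 w.p. ``mut``."""
    if not 0 <= mut <= 1:
        raise ValueError("mut must be in [0, 1]")
    if mut == 0 or genotype == 0:
        return genotype
    out = genotype
    for j in range(3):
        if gt.carries(genotype, j) and rng.random() < mut:
            out &= ~(1 << (2 - j))
    return out


_VN_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))
_MOORE_OFFSETS = _VN_OFFSETS + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def divide(cell: Cell, state: LatticeState, params: SimConfig,
           rng: np.random.Generator) -> Cell | None:
    """Split the mother into an empty adjacent box (periodic wrap).

    Returns the daughter, or None when every neighbor is occupied, in which
    case the division is deferred and the mother's biomass capped at
    ``2 * (2 X0)``.  The daughter's genotype passes through :func:`mutate`.
    """
    L = state.L
    r, c = cell.position
    offsets = _MOORE_OFFSETS if params.neighborhood == "moore" else _VN_OFFSETS
    empties = [((r + dr) % L, (c + dc) % L) for dr, dc in offsets
               if state.genotype[(r + dr) % L, (c + dc) % L] == gt.EMPTY]
    if not empties:
        cell.biomass = min(cell.biomass, params.biomass_cap)
        state.biomass[r, c] = cell.biomass
        return None
    nr, nc = empties[rng.integers(len(empties))]
    cell.biomass /= 2.0
    state.biomass[r, c] = cell.biomass
    child_geno = mutate(cell.genotype, params.mut, rng)
    daughter = Cell(child_geno, cell.biomass, (nr, nc))
    state.genotype[nr, nc] = child_geno
    state.biomass[nr, nc] = daughter.biomass
    return daughter


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

@dataclass
class StepRecord:
    """Per-step summary row of a running simulation."""

    step: int
    counts: np.ndarray
    total_biomass: float
    total_substrate: float
    goods_totals: np.ndarray
    substrate_per_cell: float
    production_cost: float


class Simulation:
    """Drives a :class:`LatticeState` forward under a :class:`SimConfig`.

    Parameters
    ----------
    config
        Model parameters; ``config.seed`` is the master seed unless ``seed``
        overrides it.
    state
        Initial lattice state.  The object is advanced in place (take a
        ``.copy()`` first to keep the original).
    record_events
        Keep the per-event log (births, mutations, extinctions) needed for
        lineage analysis.

    Attributes
    ----------
    events : list[tuple]
        ``(step, type, genotype, parent_genotype, row, col)`` records.
    history : list[StepRecord]
        One summary row per executed step (plus the initial state).
    """

    def __init__(self, config: SimConfig, state: LatticeState,
                 seed: int | None = None, record_events: bool = True):
        config.validate()
        state.validate()
        self.config = config
        self.state = state
        self.record_events = record_events
        master = config.seed if seed is None else seed
        ss = np.random.SeedSequence(master)
        # the per-step kernel stream is reseeded from (run seed, step), so
        # several live simulations never share RNG state and a run can be
        # resumed or replayed bit-identically from any step
        self._kernel_seed = int(ss.generate_state(1)[0] % 2**31)
        self.events: list[tuple] = []
        self.history: list[StepRecord] = []
        self._ever_seen: set[int] = set()
        self._ev_buf = np.empty((state.L * state.L, 4), dtype=np.int64)
        self._scratch = np.empty_like(state.substrate)
        counts = state.counts()
        if record_events:
            self._log_initial_births(counts)
        self._prev_counts = counts
        self._record(counts)

    # -- bookkeeping --------------------------------------------------------

    def _log_initial_births(self, counts: np.ndarray) -> None:
        for code in np.nonzero(counts)[0]:
            rr, cc = np.argwhere(self.state.genotype == code)[0]
            self.events.append(
                (self.state.step, "birth", int(code), gt.EMPTY, int(rr), int(cc))
            )
            self._ever_seen.add(int(code))

    def _record(self, counts: np.ndarray) -> None:
        s = self.state
        occ = s.genotype >= 0
        n = int(counts.sum())
        prod_cost = 0.0
        sub_per_cell = np.nan
        if n:
            geno_occ = s.genotype[occ]
            prod_cost = float(
                self.config.alpha
                * np.sum(s.biomass[occ] * _N_FUNCS[geno_occ.astype(np.int64)])
            )
            sub_per_cell = float(s.substrate[occ].mean())
        self.history.append(StepRecord(
            step=s.step,
            counts=counts.copy(),
            total_biomass=float(s.biomass.sum()),
            total_substrate=float(s.substrate.sum()),
            goods_totals=s.goods.reshape(3, -1).sum(axis=1),
            substrate_per_cell=sub_per_cell,
            production_cost=prod_cost,
        ))

    # -- stepping -----------------------------------------------------------

    def lattice_step(self) -> None:
        """Advance one full time step (sweep + supply + decay + transport)."""
        cfg = self.config
        s = self.state
        beta = cfg.beta_vec
        step_seed = np.random.SeedSequence(
            [self._kernel_seed, s.step]).generate_state(1)[0]
        seed_kernel(int(step_seed) % 2**31)
        n_ev = sweep_kernel(
            s.genotype, s.biomass, s.substrate, s.goods,
            cfg.alpha, beta[0], beta[1], beta[2], cfg.mut,
            cfg.g_max, cfg.d_max, cfg.base_death_rate, cfg.eps_amplitude,
            cfg.K_S, cfg.K_P, cfg.yield_S, cfg.dt,
            cfg.division_threshold, cfg.death_threshold, cfg.biomass_cap,
            1 if cfg.neighborhood == "moore" else 0,
            1 if cfg.benefit_mode == "monod" else 0,
            self._ev_buf,
        )
        s.step += 1
        counts = s.counts()
        if self.record_events:
            for k in range(n_ev):
                child, parent, r, c = self._ev_buf[k]
                self.events.append(
                    (s.step, "mutation", int(child), int(parent), int(r), int(c))
                )
                if int(child) not in self._ever_seen:
                    self._ever_seen.add(int(child))
                    self.events.append(
                        (s.step, "birth", int(child), int(parent), int(r), int(c))
                    )
            gone = (self._prev_counts > 0) & (counts == 0)
            for code in np.nonzero(gone)[0]:
                self.events.append((s.step, "extinction", int(code), gt.EMPTY, -1, -1))
        self._prev_counts = counts

        # substrate supply, field decay, transport (operator splitting)
        if cfg.supply_rate > 0:
            s.substrate += cfg.supply_rate * cfg.dt
        if cfg.substrate_decay > 0:
            s.substrate *= 1.0 - cfg.substrate_decay * cfg.dt
        if cfg.goods_decay > 0:
            s.goods *= 1.0 - cfg.goods_decay * cfg.dt
        if cfg.well_mixed:
            well_mixed_redistribute(s.substrate, out=s.substrate)
            for j in range(3):
                well_mixed_redistribute(s.goods[j], out=s.goods[j])
        else:
            # jitted fast path; arithmetic identical to diffusion.diffuse
            if cfg.D_S > 0:
                diffuse_inplace(s.substrate,
                                cfg.D_S * cfg.dt / cfg.dx**2, self._scratch)
            if cfg.D_P > 0:
                lam = cfg.D_P * cfg.dt / cfg.dx**2
                for j in range(3):
                    diffuse_inplace(s.goods[j], lam, self._scratch)

        self._record(counts)

    def run(self, n_steps: int | None = None,
            stop_when_empty: bool = True) -> LatticeState:
        """Run ``n_steps`` (default ``config.n_steps``) and return the state."""
        n = self.config.n_steps if n_steps is None else int(n_steps)
        for _ in range(n):
            self.lattice_step()
            if stop_when_empty and self.history[-1].counts.sum() == 0:
                break
        return self.state

    # -- views --------------------------------------------------------------

    def abundance_array(self) -> np.ndarray:
        """(n_recorded, 8) genotype counts over time."""
        return np.stack([r.counts for r in self.history])

    def steps_array(self) -> np.ndarray:
        return np.array([r.step for r in self.history])

    def timeseries(self):
        """History as a tidy :class:`pandas.DataFrame` (one row per step)."""
        import pandas as pd

        rows = []
        for r in self.history:
            row = {"step": r.step, "n_cells": int(r.counts.sum()),
                   "total_biomass": r.total_biomass,
                   "total_substrate": r.total_substrate,
                   "substrate_per_cell": r.substrate_per_cell,
                   "production_cost": r.production_cost}
            for code in range(8):
                row[f"n_{gt.compact_label(code)}"] = int(r.counts[code])
            for j in range(3):
                row[f"goods_{j + 1}"] = float(r.goods_totals[j])
            rows.append(row)
        return pd.DataFrame(rows)

    def event_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.events,
            columns=["step", "event_type", "genotype", "parent_genotype",
                     "row", "col"],
        )
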