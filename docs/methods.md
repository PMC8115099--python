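# Model and methods

`bqsim` simulates reductive (loss-of-function) evolution in a microbial
community whose members secrete and share three essential public goods.
It is built to study the Black Queen dynamic: losing a costly, leaky
function is individually advantageous as long as someone nearby still
produces the good, and repeated loss can carry a community from one
autonomous ancestor to a web of obligate cross-feeders.

## The individual-based model

Cells occupy at most one box each of an L x L lattice with periodic
boundaries.  Four concentration fields live on the same lattice: a growth
substrate and public goods 1-3.  A genotype is a 3-bit string; bit j says
whether the cell produces good j.  Eight genotypes are possible: the
autonomous ancestor `[1,1,1]`, three one-function-loss genotypes (OFLGs),
three two-function-loss genotypes (TFLGs) and the non-producing cheater
`[0,0,0]`.  Mutation only ever clears bits, so the genotype lattice of a
run is a sub-poset of the loss order.

Per time step, occupied boxes are visited in a fresh random permutation
(randomized sequential update: each cell sees fields already modified by
cells visited earlier in the same sweep).  A cell of biomass `X` (fg
carbon) with genotype `g`:

1. **Production.** Secretes `alpha * X * dt` of every carried good into
   its box.  `alpha` is the function cost: the biomass fraction spent per
   unit time per carried function.
2. **Requirement and uptake.** Needs `beta_j * alpha * X * dt` of every
   good j; `beta` is the required-to-produced ratio, so `1 - beta` of a
   producer's output is redundant and shareable.  Carried goods are
   satisfied internally by the cell's own synthesis; each non-carried
   good is drawn from the local box, capped at what is present.  The
   fulfillment `s_j` of good j is the fraction of the requirement met
   (1 for carried goods).
3. **Growth.** Forward Euler on

       dX/dt = [(g_i - C_i) - (d_max - G_i)] * X,

   with `g_i = g_max * S/(K_S + S)` (Monod substrate limitation; uptake
   `g_i * X * dt / yield` capped at the substrate present in the box),
   cost `C_i = alpha * (functions carried)` and benefit
   `G_i = d_max * min_j s_j`.  The `min` encodes essentiality: all three
   goods are required, and a cell whose scarcest good is absent suffers
   the full death rate `d_max`.
4. **Death.** The cell dies when `X < 0.2 * X0 + eps`, or immediately if
   `X <= 0`, or with basal probability `base_death_rate` per step
   regardless of biomass (see *Turnover*, below).  `eps` is a fresh
   `Uniform(-eps_amplitude, +eps_amplitude)` draw at every threshold
   check (cell-cycle noise).
5. **Division.** When `X >= 2 * X0 + eps` the cell splits its biomass
   equally with a daughter placed uniformly at random on an empty box of
   the von Neumann neighborhood (a Moore neighborhood is a config
   switch).  If no neighbor is free the division is deferred and the
   biomass capped at `2 * (2 X0)` (contact inhibition).  Each carried
   function of the daughter is lost independently with probability
   `mut`.

After the sweep, substrate influx `supply_rate` is added to every box,
both field families decay at small first-order rates, and all four fields
take one explicit 5-point-Laplacian diffusion step (`lam = D dt/dx^2 <=
1/4` enforced).  The well-mixed variant replaces diffusion by spreading
each field's total evenly over the lattice, which removes the spatial
privatization of goods around producers.

### Why carriers satisfy their own requirement internally

Pair feasibility follows from mass balance.  If every cell - producers
included - drew `beta * alpha * X` of every good from the environment,
sustaining good j would need producer fraction `f_j >= beta`; summing
over the three goods needs a mean of `3 * beta = 2.4` carried functions
per cell at `beta = 0.8`, which no loss-genotype community (mean <= 2)
can reach.  With internal self-supply the constraint relaxes to
`f_j >= beta/(1 + beta)`: 0.44 at `beta = 0.8` - a TFLG+OFLG pair is
feasible but a three-TFLG community (`f_j = 1/3`) is not - and 0.29 at
`beta = 0.4`, where the three-TFLG division of labor becomes possible
and enough surplus exists to carry cheaters.  This reproduces the
qualitative phase structure of interdependent patterns as a function of
cost and redundancy.  The same bookkeeping caps the TFLG share of a pair
at `1/(1 + beta)` (about 0.56 at `beta = 0.8`), which is where simulated
communities indeed settle.

An alternative benefit form, `s_j = P_j/(K_P + P_j)` for non-carried
goods, is available as `benefit_mode="monod"`.

### Turnover

Under threshold birth/death and deterministic growth alone, a crowded
community relaxes to a frozen fixed point: each cell's biomass stabilizes
at (local substrate flux)/(cost rate), divisions stop, and with them the
supply of new mutants.  Real microbial populations keep turning over
(death by predation, lysis, dilution, damage), so the model includes a
basal per-step mortality `base_death_rate` (default 1e-3, i.e. a mean
cell span of 1000 steps at the crowded steady state).  Freed boxes let
neighbors grow and divide, which sustains the mutation supply that
long-run evolutionary dynamics require.  Setting it to 0 recovers the
literal threshold-only ruleset.

## Default parameters

| parameter | default | units | role |
|---|---|---|---|
| `alpha` | 0.001 | /step | cost of one function; production rate `alpha*X` |
| `beta` | 0.8 | - | required/produced ratio per good (scalar or triple) |
| `mut` | 1e-5 | /function/division | loss probability |
| `g_max` | 0.2 | /step | maximum growth rate |
| `d_max` | 0.1 | /step | maximum death rate (fully offset at `G = d_max`) |
| `base_death_rate` | 1e-3 | /step | basal mortality (turnover) |
| `X0` | 150 | fg | initial/reference biomass; divide at `2 X0`, die at `0.2 X0` |
| `eps_amplitude` | 7.5 | fg | threshold noise half-width (0.05 `X0`) |
| `K_S` | 1.0 | fg/box | substrate half-saturation |
| `supply_rate` | 0.4 | fg/box/step | substrate influx |
| `D_S`, `D_P` | 0.2, 0.1 | box^2/step | diffusion coefficients |
| `substrate_decay`, `goods_decay` | 0.005 | /step | first-order field loss |
| `steps_per_hour` | 80 | steps | wall-clock mapping for hour-based protocols |

Values not derivable from the published description (growth/death rates,
half-saturations, supply, diffusion, decay) were fixed once so that (a) an
uncrowded cell divides within a few steps, (b) the lattice equilibrates
below full occupancy, so birth-death turnover continues at steady state,
(c) a producer's goods plume spans a few boxes (diffusion length
`sqrt(4 D_P / goods_decay)` is ~9 boxes), and (d) a 12 h substrate
shut-off (960 steps) is severe - roughly one basal lifetime - but
survivable for communities with low production costs.  With these
choices an ancestor-seeded 32x32 community passes through the expected
succession: OFLG invasion, ancestor exclusion, TFLG emergence, and
resolution to a single asymmetric functional complementation pair (AFCP)
within ~1e5 steps.

## Analysis machinery

* **Census metrics**: per-genotype counts/fractions and Shannon
  alpha-diversity (natural log) over the eight genotypes.
* **PAD/PAI**: the partner association degree of a TFLG is the mean,
  over its cells, of the distance-weighted count of complement-OFLG
  cells in the Moore 8-neighborhood (weight 1 edge, `1/sqrt(2)`
  diagonal; the weight table is configurable).  The partner association
  index is the PAD ratio of two competing pairs; values above 1 mean the
  first pair is more tightly mixed.  Both agree exactly with a
  brute-force neighborhood enumeration (tested).
* **Pattern classification**: a rule cascade at dominance threshold 0.95
  labels a snapshot `ancestor_dominated`, one of three `AFC_*` pair
  labels, `complete_functional_division`, `one_way_dependency`,
  `collapsed` or `unresolved`; accompanying cheaters are tolerated in
  the AFC/division rules and reported as a fraction.
* **Lineage**: every run logs birth (first emergence), mutation,
  extinction and colonization events.  Colonization - the first time a
  genotype holds >= 5% of cells - is the package's operational notion of
  "emergence" for the two key random events (single mutants usually die
  without issue; raw first-birth mode is available).  A run reduces to a
  branch signature: which OFLGs colonized before the ancestor's
  extinction (key event 1), and in what order complement-covered TFLGs
  colonized (key event 2).
* **Competition timing**: t1/t2 are the colonization steps of the first
  two TFLGs, TIMEGAP their lag, t3 the first step the two pairs jointly
  hold 95% of cells, and the prior occupied space is the first pair's
  region size at t2.

## Experiment protocols and scaled-down conditions

The package ships two profiles.  The full-scale profile mirrors the
published conditions (100x100 lattice, `mut = 1e-5`, >= 1.5M steps,
hundreds of replicates) and is meant for cluster time.  The desk-scale
profile used by the test suite shrinks the lattice and shortens runs;
because the division flux scales with lattice area, the loss probability
is scaled up by the area ratio to keep the per-community mutant supply
comparable.  Concretely:

* lineage statistics: 12 runs, L = 48, `mut = 5e-5`, 150,000 steps;
* cost x redundancy sweep: L = 32, `mut = 1e-4`, 150,000 steps
  (40,000 for the cheap-cost row, which only needs to show retained
  ancestor dominance), 3-5 replicates per cell;
* premixed-pair competitions and the mirror-symmetric fairness control:
  mutation off, lead scored by region size when neither pair has reached
  full dominance by run end;
* well-mixed vs spatial comparison: L = 24, `beta = 0.4`, with 10%
  cheaters seeded into the premix (long-run mutation would generate them
  anyway; seeding makes the desk-scale run feasible);
* disturbance: a premixed pair community self-organizes for 20,000 steps
  and is then subjected to a 12 h substrate shut-off, against an
  ancestor-only control.

What desk scale does and does not show: the succession mechanism, the
key-event structure, the PAI statistics, fairness, disturbance ordering
and the collapse contrast all reproduce.  The published branch-frequency
values do not: a 12-run batch carries a sampling error of roughly +-15
percentage points on any frequency (the original analysis pooled 296
runs), and beyond that three quantities face structural limits:

* the 50/50 split of key event 1 requires the third OFLG to colonize
  before the ancestor is excluded; exclusion time scales with lattice
  size while the mutant supply is held fixed, so small lattices bias
  toward the two-OFLG path;
* the three-TFLG complete functional division needs three interleaved
  genotype domains and was never observed on lattices up to 48x48;
* the published ~70% TFLG share exceeds the `1/(1+beta)` pair mass-balance
  cap (~56%) implied by this package's consumption bookkeeping; whatever
  stoichiometry produced 70% is not recoverable from the available text.

The well-mixed system crashes by >90% rather than strictly to zero:
once the population is tiny, the per-capita substrate flux is so large
that `g ~ g_max > d_max` and even goods-starved cells grow, so a small
rump (typically a handful of cheaters) persists at the bottom of the
crash.  Strict extinction would require `g_max <= d_max` under
starvation of goods, a regime the available text does not pin down.

## Numerical notes

* Explicit diffusion requires `D dt/dx^2 <= 1/4`; configurations
  violating it are rejected at load time.  Diffusion conserves mass to
  round-off and preserves non-negativity within the stability bound.
* Division uses `>=` against its noisy threshold and death uses strict
  `<`, so exact-threshold biomass behaves deterministically when the
  noise amplitude is zero.
* All randomness in the per-step sweep (visit order, threshold noise,
  daughter placement, mutation) flows from one stream reseeded from
  (run seed, step index), so runs replay bit-identically, can be resumed
  from any step, and concurrent simulations never share RNG state.
  Placement randomness in initializers comes from separate,
  caller-provided generators.
* Goods and substrate decay keep concentrations bounded where nothing
  consumes them; dead cells' biomass is not recycled.
* The hot loop is numba-compiled; a pure-Python fallback with the same
  code path keeps the package functional (slowly) without numba.

## Known limitations

* No gain-of-function mutation, horizontal transfer, or cell motility;
  no inherent (non-spatial) privatization parameter.
* The exact published forms of the benefit function, substrate kinetics
  and consumption (supplementary material) were not available; the forms
  above are this package's own, declared and configurable.
* Event positions for extinctions are recorded as (-1, -1): no cell of
  the genotype remains to anchor a position.
* Newick export keeps only first-parent edges (a tree); the full
  multi-parent edge set is in the event table.
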