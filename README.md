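# bqsim

Individual-based simulation of **Black Queen reductive evolution** in
spatially structured microbial communities.

Many microbial metabolites — siderophores, degradative enzymes, amino
acids, vitamins — are *public goods*: costly to make, but usable by every
neighbor once secreted.  The Black Queen Hypothesis predicts that
individuals which mutate away a costly, leaky function gain a selective
advantage as long as someone nearby still produces the good.  When a
community's ancestor carries **several** such functions, repeated loss
can carve it into networks of obligate cross-feeders.  `bqsim` simulates
this process and ships the analysis machinery to study which
interdependent community patterns emerge, when, and why — for modelers
of microbial ecology and evolution, and for designers of synthetic
division-of-labor communities.

## The model in brief

Cells live one-per-box on an L×L periodic lattice above four diffusing
concentration fields (substrate S and public goods P₁..P₃).  A genotype
is a 3-bit string (bit j = produces good j), giving 8 genotypes between
the autonomous ancestor `[1,1,1]` and the cheater `[0,0,0]`.  Each time
step every cell, in random order:

* secretes `α·X` of each carried good (α = function cost, X = biomass),
* needs `β·α·X` of every good — carried goods internally, non-carried
  goods from its box (1−β of production is redundant, shareable surplus),
* grows by `dX/dt = [(g − C) − (d_max − G)]·X`, with Monod substrate
  limitation `g = g_max·S/(K_S+S)`, cost `C = α·(functions carried)` and
  benefit `G = d_max·min_j s_j` over the per-good fulfillments (all three
  goods are essential),
* divides into an empty adjacent box at `X ≥ 2X₀+ε` (daughters lose each
  carried function with probability *mut*) and dies at `X < 0.2X₀+ε`.

Loss-only mutation plus spatially privatized goods sharing produce the
emergent outcomes of interest: **asymmetric functional complementation
pairs** (AFCP: a two-function-loss genotype feeding on its bitwise
complement, e.g. `[0,0,1]` + `[1,1,0]`), **complete functional
division** (three single-function specialists), **one-way dependency**
(ancestor + cheater), or retained ancestor dominance — depending on the
cost α and the redundancy 1−β.

## Worked example

```bash
python examples/01_reductive_evolution_run.py
```

seeds 10 ancestor cells on a 32×32 lattice (α = 0.001, β = 0.8) and
prints the succession:

```
step   cells  H      census (cells per genotype)
 10000    474  0.63  011:46, 101:47, 111:381
 20000    496  1.14  011:156, 100:4, 101:168, 111:168
 30000    530  1.22  011:225, 100:45, 101:185, 111:75
 40000    576  1.17  011:260, 100:112, 101:182, 111:22
 50000    584  1.00  011:260, 100:241, 101:83
 60000    578  0.79  011:253, 100:311, 101:14

final pattern: AFC_100_011 (dominant fraction 0.98)
```

Read bottom-up: one-function-loss genotypes `[0,1,1]` and `[1,0,1]`
invade the ancestor on its redundant goods (diversity H rises), the
ancestor `111` is excluded, the two-function-loss genotype `[1,0,0]`
emerges and pairs with its complement `[0,1,1]`, and by step 60,000 that
pair holds 98% of cells — an asymmetric functional complementation
community, the modal outcome at this cost/redundancy combination.

Further examples: `02_partner_association.py` (PAD/PAI spatial
statistics), `03_lineage_tracing.py` (event logs, key random events,
Newick lineage trees), `04_nutrient_disturbance.py` (12 h famine
resistance), `05_well_mixed_vs_spatial.py` (cheater-driven collapse
without spatial structure).

## Library layout

| module | contents |
|---|---|
| `bqsim.engine` | cell/lattice state, the update rules, `Simulation` driver |
| `bqsim.diffusion` | explicit periodic 5-point diffusion + well-mixed variant |
| `bqsim.genotypes` | 3-bit genotype codes, loss partial order, AFCP pairs |
| `bqsim.metrics` | census, Shannon diversity, PAD/PAI, region sizes, t1/t2/TIMEGAP/t3, pattern classification |
| `bqsim.lineage` | event logs, colonization, lineage trees, branch signatures |
| `bqsim.experiments` | initializers (ancestor / premixed / symmetric), α×β sweep, premix competition study, disturbance, well-mixed runs |
| `bqsim.io` / `bqsim.config` | YAML configs, text snapshots, TSV event/time series, run manifests |
| `bqsim.cli` | `bqsim run/sweep/premix/symmetric/disturb/wellmixed/analyze` |

A scientific account of the model — functional forms, parameter
defaults and their rationale, the desk-scale study conditions, and known
limitations — is in [`docs/methods.md`](docs/methods.md).

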