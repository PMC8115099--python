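"""Community stability under a 12 h substrate shut-off.

Compares a self-organized AFCP community against an ancestor-only
control.  The interdependent community spends less biomass on public
goods production (each member carries fewer functions), so it decays
more slowly through the famine and retains more of its population.
"""

import numpy as np

from bqsim import SimConfig, Simulation
from bqsim.experiments import init_ancestor, init_premixed, run_disturbance

cfg = SimConfig(L=32, seed=9, mut=0.0)

state, _ = init_premixed(cfg, np.random.default_rng(9))
mature = Simulation(cfg, state, seed=99, record_events=False)
mature.run(20_000)  # let the pair community self-organize
afc = mature.state.copy()
afc.step = 0
ancestor = init_ancestor(cfg, n=round(0.9 * cfg.L**2),
                         rng=np.random.default_rng(9))

for name, st in (("AFCP community", afc), ("ancestor control", ancestor)):
    ts = run_disturbance(cfg, st, seed=1, t_before=500, hours_off=12.0)
    pre = ts[ts.phase == "before"].n_cells.iloc[-1]
    cost = ts[ts.phase == "before"].production_cost.iloc[-1] / pre
    final = ts.n_cells.iloc[-1]
    print(f"{name:18s} pre-famine {pre:4d} cells, "
          f"production cost {cost:.3f} fg/step/cell, "
          f"retained {final / pre:.1%} after recovery")

print("\nLower per-cell production cost = more biomass available for"
      "\nmaintenance during starvation, hence the better resistance of"
      "\nthe interdependent community.")
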