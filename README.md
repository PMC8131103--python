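# adhesim

Stochastic simulators for two questions about Ihog-mediated adhesion in
*Drosophila* Hedgehog signalling:

1. **Do homophilic trans interactions stabilise cytonemes?** A 1-D lattice
   model of cytoneme elongation, shrinkage and translocation in which
   aligned segments of neighbouring cytonemes form contacts of energy
   `E_ii`, with elongation weight `p₀·e^(−αx)`, contact-protected
   shrinkage `s₀·e^(−T·E_ii)`, quasi-equilibrium contact assignment
   `p = e^(E_ii)/(1+e^(E_ii))`, and Metropolis translocation.
2. **How much stronger is heterotypic Ihog–Hh adhesion than homotypic
   Ihog–Ihog adhesion?** A Voronoi/vertex Monte Carlo model of a cell
   monolayer with energy
   `e_i = a(A_i−A0)² + bP_i² − ½Σ γ(q_i,q_j) l_ij`,
   mixing Ihog- and Hh-expressing cells among energy-free gap polygons.
   The steady-state pattern (honeycomb vs checkerboard) as a function of
   the adhesion ratio γ_IH : γ_II brackets the relative interaction
   strength.

The package is aimed at quantitative biologists who want to re-run,
modify, or extend these in-silico experiments: both simulators are
compiled (numba) and run the full study schedules in seconds to minutes on
one CPU.

## Worked example

```python
import numpy as np
from adhesim.cytoneme_sim import CytonemeParams, simulate
from adhesim import cytoneme_metrics as cm

snaps = simulate(CytonemeParams(e_ii=15.0, seed=1))   # 5M steps, 1001 snapshots
mean, sd = cm.mean_length(snaps)
r = cm.length_interaction_correlation(snaps)
print(f"mean length {mean:.1f} ± {sd:.1f}, length-contact Pearson r = {r:.3f}")
```

prints

```
mean length 86.8 ± 0.5, length-contact Pearson r = 0.690
```

— at `E_ii = 15` contact-protected tips shrink with weight `0.5·e⁻¹⁵`, so
bundled cytonemes elongate until the elongation decay balances it at
about 87 segments, and length correlates with the number of established
contacts. With `e_ii=0.0` the same call gives a mean length of about 11.5
(the isolated birth–death balance point) and near-zero bundling.

For the tissue model:

```python
from adhesim.experiments import run_mixed
run, stats, branch = run_mixed(ratio=30.0, seed=3)
print(branch, f"{stats.mean_neighbors:.2f} neighbours, {stats.mean_like:.2f} like")
```

```
checkerboard-seed 4.42 neighbours, 0.42 like
```

— at γ_IH : γ_II = 30 the lower-energy phase is the square-packed
checkerboard: each interior cell has ≈ 4.4 counted neighbours of which
≈ 0.4 share its type. At ratio 1 the same protocol selects the hexagonal
honeycomb with ≈ 6 neighbours, half of them like.

A CLI mirrors the library (`adhesim run-cytoneme`, `run-vertex`,
`run-invasion`, `sweep-gamma`, `analyze-cytoneme`, and
`adhesim experiment <name>` for the six named, persisted experiments).

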