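# Methods

`adhesim` implements two stochastic models of Ihog-mediated cell-surface
adhesion in *Drosophila* Hedgehog signalling: a 1-D lattice model of
cytoneme dynamics with homophilic trans-interaction energetics, and a
Voronoi-based Monte Carlo model of cell rearrangement under differential
adhesion. This note documents the models, the numerical methodology, the
parameter choices, and the known limitations — including two places where
the implemented dynamics provably cannot reach a regime that the analysis
targets, which are reported rather than hidden.

## 1. Cytoneme model

### State and dynamics

The cell surface is a periodic 1-D lattice of `M = 100` sites. Thirty
cytonemes (30% occupancy) occupy distinct sites; each is a filament of
`x_i ≥ 0` discrete segments, initially 0. One simulation step performs:

1. **Contact assignment (quasi-equilibrium).** For every unordered pair of
   cytonemes whose base sites are within `neighbor_radius = 1` (periodic),
   and every aligned level `k = 1..min(x_i, x_j)`, a binary contact
   `s_kij` is drawn independently with probability
   `p = exp(E_ii) / (1 + exp(E_ii))` — the equilibrium occupancy of a
   two-state bond of energy `E_ii` (in units of `kBT = 1`). The assignment
   is redrawn every step; no binding kinetics are simulated.
2. **Synchronous growth.** Each cytoneme elongates or shrinks by one
   segment. With elongation weight `p_elong = p_elong0 · exp(−α x_i)`
   (base weight 5, decay α = 0.2 — transport and membrane tension resist
   elongation) and shrinkage weight `p_shrink = p_shrink0 · exp(−T_i E_ii)`
   (intrinsic weight 0.5; `T_i` = number of neighbours whose contact at the
   tip level of `i` is engaged — engaged tips resist removal), the filament
   shrinks iff `x_i > 0` and a uniform draw satisfies
   `r ≤ p_shrink / (p_elong + p_shrink)`, otherwise elongates. The two
   weights exceed 1 individually; only the normalised ratio enters.
3. **Metropolis translocation.** One cytoneme is chosen uniformly and
   proposed to hop ±1 site; a proposal onto an occupied site is rejected
   (excluded volume). Contacts for the tentative neighbourhood are freshly
   drawn; with configuration energy `−E_ii ×` (engaged contacts involving
   the mover), the move is accepted with probability `min(1, exp(−ΔE))`.

Defaults run 5,000,000 steps, collect 1001 snapshots every 4,000 steps
after a 1,000,000-step burn-in. The inner loop is compiled with numba; the
per-pair contact count over `m` aligned levels is drawn as
`Binomial(m, p)` plus the exact conditional Bernoulli for the one level
that is needed individually (the shorter partner's tip), which is
distributionally identical to per-level assignment. The pure-Python
operations in `cytoneme_sim` define the reference semantics and are what
the oracle tests exercise.

### Validation oracles

* **Birth–death oracle.** An isolated cytoneme is a 1-D birth–death chain;
  its stationary law follows from detailed balance and direct enumeration.
  The simulated length histogram agrees to total-variation distance
  < 0.02 at 10^5 samples.
* **Boltzmann enumeration oracle.** For 2–3 fixed-length cytonemes on a
  ≤ 8-site lattice with forced contact establishment (`contact_prob = 1`)
  and translocation moves only, the configuration space is enumerated and
  the empirical visit frequencies match `exp(E_ii · pairs(config))/Z`.

### A regime the lattice dynamics cannot reproduce

At `E_ii = 15` an engaged tip shrinks with weight `0.5·e⁻¹⁵ ≈ 1.5×10⁻⁷`,
so paired cytonemes elongate until the elongation decay balances it, at
`x* ≈ 86.5` (measured 86.8 ± 0.5). Joining a bundle lowers the
configuration energy by `E_ii · min(x_i, x_j)` — over 100 kBT — so bundle
membership is irreversible and every cytoneme is absorbed into a bundle
well before the burn-in ends. The steady state therefore contains no
singular cytonemes, and the pooled length-vs-contacts Pearson correlation
reflects only within-bundle variation, measured at r ≈ 0.45–0.69
depending on the seed. A mixed population with roughly 20% persistent
singular cytonemes would be required for r ≈ 0.79; no local-move lattice
variant of these update rules retains one (escape is Boltzmann-suppressed
by factors of order e⁻¹⁵⁰). We report the measured correlation as is.

### Bundles

Two cytonemes belong to the same bundle when they form more than three
(≥ 4) pairwise contacts; bundles are connected components of size ≥ 2 of
that graph, and the bundling index of a bundle is (minimum member length)
× (member count). Snapshots without bundles contribute an index of 0 to
sweep averages so sparse regimes average near zero.

## 2. Cell-rearrangement model

### Energy

Cells are Voronoi polygons of mobile generator points in a 20 × 20
periodic box: `N = 100` cellular generators plus `5N` environment
generators whose polygons represent gaps and carry no energy. Each
mechanical cell contributes

    e_i = a (A_i − A0)² + b P_i² − ½ Σ_j γ(q_i, q_j) l_ij

with preferred area `A0 = 1`, and adhesive line densities
`γ_II` (between Ihog-expressing cells, either colour), `γ_IH`
(Ihog–Hedgehog), `γ_HH = 0`, and 0 for any pair involving an environment
polygon. Perimeter includes cell–environment edges; adhesion applies only
to cell–cell edges (and never to a cell's own periodic image).

**Coefficient normalisation.** The commonly quoted bare coefficient set
(areal 500, contractile 6, γ_II = 0.25) is stated relative to the standard
vertex-model convention, which carries ½ on the elastic and contractile
terms; adhesive densities enter here at full pair weight per cell. The
package defaults are therefore `a = 250`, `b = 3`, `γ_II = 0.5`, with
`VertexParams.from_printed` performing the mapping. This identification
matters and was validated against the model's reported morphology: with
the bare reading, the energy balance between hexagonal packing
(contractile optimum, `P² ≈ 13.9` per unit area) and square packing
(maximal unlike-contact length, `P² = 16`) puts the
honeycomb-to-checkerboard transition near γ_IH:γ_II ≈ 70 and a seeded
checkerboard decays; with the normalised reading the measured transition
falls between ratios 20 and 25 and the checkerboard is rigid. Adhesion
*ratios* — the quantity the sweep estimates — are unaffected by the
normalisation. Temperature is not part of the quoted set; sampling uses
`kBT = 0.1`, placing the weakest relevant energy (a homotypic contact,
γ_II·l ≈ 0.3) a few kBT above noise, as the energy-dominated
differential-adhesion regime requires.

### Sampling

Metropolis Monte Carlo over three symmetric proposal types, all of which
preserve the Boltzmann distribution at fixed temperature:

* **Displacement** (default 70% of proposals): a uniformly chosen
  generator (cellular or environmental) moves uniformly within a disk
  whose radius adapts every 1,000 displacement proposals — ×1.1 above a
  40% acceptance rate, ×0.9 below 25%, clamped to [10⁻⁴, box/4].
* **Relocation** (10%): the chosen generator is instead placed uniformly
  in the box. Long-range moves are essentially free for environment
  generators deep in the gap phase and give cells a nucleation-free
  transport channel.
* **Label exchange** (20%): two generators swap type labels (Kawasaki
  exchange). Cell–cell swaps equilibrate the arrangement; cell–environment
  swaps migrate vacancies and cells without moving any generator.

Energy bookkeeping is local: a displacement can only change polygons whose
generator lies within twice its own circumradius of the old or new
position, so only those cells are re-clipped per move; the tracked total
is recomputed from scratch every `recompute_interval` steps to guard
against drift (tested to 10⁻⁶ relative against full recomputation).
Geometry uses exact half-plane clipping of each Voronoi cell with adaptive
candidate gathering and the standard sufficiency criterion (all generators
within `G` clipped, farthest vertex within `G/2`); small or sparse boxes
fall back to a complete periodic-image enumeration. The implementation is
validated against hand-computed periodic catalogues (`two-squares`,
`grid-4`, `hex-4`) and against scipy's Voronoi on 3×3 ghost-tiled points
(areas and perimeters to 10⁻⁹).

### Why the patterned experiments start from a pre-formed aggregate

With the study's adhesion strengths, spontaneous nucleation of an
aggregate from a dilute suspension is not reachable by these dynamics at
any temperature: above `kBT ≈ 0.5` the environment-gas entropy (a bond
localisation cost of ≈ 4 kBT) cancels even the strong heterotypic
adhesion, while below it the areal stiffness makes every
attachment/detachment path a ≫ kBT barrier — measured directly as frozen
cluster structure over 30M steps. The aggregation assays the model mirrors
likewise bring dissociated cells into contact mechanically (settling,
rotation) before adhesion sorts their arrangement. `init_aggregate`
therefore seeds a compact hexagonal patch of cells (labels randomly
assigned) with environment generators outside, and the simulations study
the arrangement and morphology that differential adhesion selects — which
is the study's actual claim surface.

The hexagonally packed ("honeycomb") and square-packed ("checkerboard")
branches are separated by a strongly first-order, hysteretic transition
that single-point dynamics does not cross in either direction. Mixed-system
steady states are therefore computed by simulating both seeded branches
(`init_aggregate` with random labels; `init_checkerboard` with alternating
labels) and selecting the branch with the lower steady-state energy — the
standard free-energy comparison for competing ordered phases. The
transition ratio reported by the sweep is where that comparison flips,
together with the like-neighbour classification of the winner. Near the
boundary the losing branch decays slowly, so sweep runs use 2M steps per
branch (fast mode keeps the 650k-step schedule and is correspondingly
coarser).

### Pattern statistics

A *center cell* is a mechanical cell with no environment polygon among its
edge-sharing neighbours. Neighbour and like-neighbour counts are pooled
over center cells across snapshots. Because a space-filling tessellation
has mean topological coordination exactly 6, the ~4 neighbours of a
checkerboard necessarily discount short edges: neighbour counting uses a
visual-scale shared-edge threshold of 0.15 length units (≈ 15% of a cell
diameter), configurable. Classification: checkerboard below 1.0 mean like
neighbours, honeycomb above 1.5, transitional between — thresholds chosen
midway between the two observed regimes (≈ 2.4 vs ≈ 0.3).

### Invasion

The invasion protocol evolves a 50-cell Ihog aggregate to steady state,
inserts 50 Hedgehog-type generators at uniform-random positions inside
environment polygons, and continues at γ_IH:γ_II = 30 (phase 2: 2M steps,
annealed from kBT 0.3). The inserted cells intercalate — the mean
like-neighbour count of center cells falls from ≈ 6 (pure aggregate)
to ≈ 1.1–1.3 — but the packing remains hexagonal, so the endpoint
classifies as transitional rather than checkerboard: the full
hexagonal→square repacking of a pre-formed aggregate is blocked by the
same hysteresis described above, and no amount of annealing within this
move set completed it. This is reported as a known limitation; the
equilibrium state at this ratio (by branch comparison) is the
checkerboard.

## 3. Problem sizes and determinism

All schedules above are the package defaults and match the study
conditions (cytoneme: 5M steps / 1M burn-in / 1001 snapshots; vertex:
650k steps / 200k burn-in / 300 snapshots), except where noted (2M-step
sweep and invasion runs, chosen for branch convergence). Every run is a
pure function of its parameter block and seed; fixed seeds give
bit-identical snapshot sequences (tested). The `--fast` experiment flag
divides step and snapshot counts by roughly ten and widens SD-based
reference bands by √10.

## 4. What the synthetic conditions do not capture

The cytoneme model has no 2-D/3-D geometry, no actin mechanics and no
ligand transport; "length" is a segment count. The tissue model has no
motility, division, or explicit T1 bookkeeping, and the environment gas is
massless — its entropy is physical in the model but has no biological
counterpart, which is why aggregate nucleation is out of scope. Passing
tests show that the implemented energetics and samplers reproduce the
study's in-silico pattern statistics under these idealisations; they say
nothing about imaging-derived quantities.
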