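"""Voronoi-based Metropolis Monte Carlo model of cell rearrangement.

Cells are Voronoi polygons of mobile generator points in a periodic square
box.  Each mechanical cell carries the energy

    e_i = alpha * (A_i - A0)^2 + beta * P_i^2
          - 1/2 * sum_j gamma[q_i, q_j] * l_ij

(areal elasticity, perimeter contractility, and adhesion along shared edges;
the sum runs over neighbours sharing an edge).  Gaps between cells are
represented by environment generator points whose polygons carry no energy.
Moves displace a uniformly chosen generator (cellular or environmental)
within a disk and are accepted by the Metropolis criterion at temperature
``k_bt``; the maximum displacement adapts to hold the acceptance rate inside
a target band.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from . import _voronoi_kernel as vk

__all__ = [
    "CellType",
    "VertexParams",
    "Tessellation",
    "TissueState",
    "VertexRun",
    "gamma_matrix",
    "tessellate",
    "cell_energy",
    "total_energy",
    "metropolis_accept",
    "mc_move",
    "adapt_step",
    "init_random",
    "init_aggregate",
    "init_checkerboard",
    "insert_invaders",
    "simulate",
    "invasion_protocol",
]


class CellType(IntEnum):
    """Generator-point labels: two colours of Ihog-expressing cells,
    Hh-expressing cells, and the energy-free environment (gap) points."""

    IHOG_RED = 0
    IHOG_GREEN = 1
    HH = 2
    ENV = 3


@dataclass(frozen=True)
class VertexParams:
    """Parameters of the cell-rearrangement model.

    Adhesive line densities: ``gamma_ii`` applies between any two
    Ihog-expressing cells regardless of colour label, ``gamma_ih`` between an
    Ihog- and an Hh-expressing cell, ``gamma_hh`` between Hh cells; any pair
    involving an environment polygon adheres with strength 0.
    """

    box_size: float = 20.0
    n_cells: int = 100
    env_factor: int = 5
    pref_area: float = 1.0
    #: elastic/contractile coefficients in the halved convention of the
    #: standard vertex model (K/2 (A-A0)^2 + Gamma/2 P^2): the commonly
    #: quoted bare coefficients 500 and 6 map to 250 and 3 here; see
    #: :meth:`from_printed`
    area_coeff: float = 250.0
    contract_coeff: float = 3.0
    #: adhesive line densities at full pair weight per cell (a quoted
    #: per-edge density of 0.25 maps to 0.5); only ratios matter for the
    #: pattern selection
    gamma_ii: float = 0.5
    gamma_ih: float = 0.5
    gamma_hh: float = 0.0
    #: sampling temperature; adhesion-driven pattern selection is an
    #: energy-dominated (low-temperature) regime
    k_bt: float = 0.1
    #: annealing: cool geometrically from k_bt_start to k_bt over
    #: anneal_steps, then sample at k_bt (set equal / 0 to disable)
    k_bt_start: float = 0.1
    anneal_steps: int = 0
    #: fraction of proposals that relocate the point uniformly in the box
    #: (symmetric long-range moves; unfreeze low-temperature kinetics)
    relocate_frac: float = 0.1
    #: fraction of proposals that exchange the labels of two cellular
    #: generators (Kawasaki moves; equilibrate the arrangement degrees of
    #: freedom across the elastic barriers that block physical swaps)
    swap_frac: float = 0.2
    total_steps: int = 650_000
    burn_in: int = 200_000
    snapshot_count: int = 300
    snapshot_interval: int = 1_500
    max_disp: float = 0.5
    accept_window: tuple[float, float] = (0.25, 0.40)
    adapt_interval: int = 1_000
    recompute_interval: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_size <= 0 or self.n_cells < 1 or self.env_factor < 0:
            raise ValueError("invalid geometry parameters")
        if min(self.area_coeff, self.contract_coeff, self.pref_area) < 0:
            raise ValueError("mechanical coefficients must be non-negative")
        if min(self.gamma_ii, self.gamma_ih, self.gamma_hh) < 0:
            raise ValueError("adhesion strengths must be non-negative")
        lo, hi = self.accept_window
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("accept_window must be an increasing pair in (0, 1)")
        if self.burn_in >= self.total_steps:
            raise ValueError("burn_in must be smaller than total_steps")
        if self.k_bt <= 0 or self.k_bt_start < self.k_bt:
            raise ValueError("need 0 < k_bt <= k_bt_start")
        if not 0.0 <= self.relocate_frac <= 1.0 or not 0.0 <= self.swap_frac < 1.0:
            raise ValueError("relocate_frac / swap_frac out of range")
        if self.anneal_steps > self.burn_in:
            raise ValueError("annealing must finish within the burn-in")
        last = self.burn_in + (self.snapshot_count - 1) * self.snapshot_interval
        if self.snapshot_count > 0 and last > self.total_steps:
            raise ValueError(
                f"snapshot schedule exceeds total_steps (last at {last})"
            )

    @property
    def n_points(self) -> int:
        return self.n_cells * (1 + self.env_factor)

    @property
    def edge_eps(self) -> float:
        """Minimum shared-edge length counted as a real contact."""
        return 1e-6 * self.box_size

    def replace(self, **changes) -> "VertexParams":
        return dataclasses.replace(self, **changes)

    def with_ratio(self, ratio: float) -> "VertexParams":
        """Set the heterotypic strength via the ratio gamma_ih : gamma_ii."""
        return self.replace(gamma_ih=ratio * self.gamma_ii)

    @classmethod
    def from_printed(
        cls,
        alpha: float = 500.0,
        beta: float = 6.0,
        gamma_ii: float = 0.25,
        gamma_ih: float = 0.25,
        gamma_hh: float = 0.0,
        **kwargs,
    ) -> "VertexParams":
        """Build params from bare published-style coefficients.

        Maps ``alpha * (A-A0)^2`` and ``beta * P^2`` onto the halved
        convention and per-edge adhesive densities onto full pair weight.
        """
        return cls(
            area_coeff=alpha / 2.0,
            contract_coeff=beta / 2.0,
            gamma_ii=2.0 * gamma_ii,
            gamma_ih=2.0 * gamma_ih,
            gamma_hh=2.0 * gamma_hh,
            **kwargs,
        )


def gamma_matrix(params: VertexParams) -> np.ndarray:
    """Symmetric 4x4 adhesion matrix over CellType, zero for ENV pairs."""
    g = np.zeros((4, 4))
    ihog = (CellType.IHOG_RED, CellType.IHOG_GREEN)
    for a in ihog:
        for b in ihog:
            g[a, b] = params.gamma_ii
        g[a, CellType.HH] = params.gamma_ih
        g[CellType.HH, a] = params.gamma_ih
    g[CellType.HH, CellType.HH] = params.gamma_hh
    return g


@dataclass
class Tessellation:
    """Derived periodic Voronoi partition: per-polygon areas, perimeters and
    shared-edge lengths with each neighbour (summed over periodic images)."""

    areas: np.ndarray
    perimeters: np.ndarray
    circumradii: np.ndarray
    n_neighbors: np.ndarray
    neighbor_idx: np.ndarray  # (m, MAXN), -1 padded
    neighbor_len: np.ndarray  # (m, MAXN)

    def neighbors_of(self, i: int, edge_eps: float = 0.0) -> dict[int, float]:
        """Shared-edge lengths of polygon ``i`` keyed by neighbour index."""
        out = {}
        for w in range(int(self.n_neighbors[i])):
            j = int(self.neighbor_idx[i, w])
            l = float(self.neighbor_len[i, w])
            if l >= edge_eps:
                out[j] = l
        return out

    def shared_edge(self, i: int, j: int) -> float:
        return self.neighbors_of(i).get(j, 0.0)


@dataclass
class TissueState:
    """Generator points, labels and (lazily derived) tessellation."""

    points: np.ndarray  # (m, 2) in [0, box_size)^2
    labels: np.ndarray  # (m,) CellType values
    box_size: float
    step: int = 0
    _tess: Tessellation | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float) % self.box_size
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (m, 2)")
        if len(self.labels) != len(self.points):
            raise ValueError("labels must match points")

    @property
    def m(self) -> int:
        return len(self.points)

    @property
    def tessellation(self) -> Tessellation:
        if self._tess is None:
            self._tess = tessellate(self.points, self.box_size)
        return self._tess

    def copy(self) -> "TissueState":
        return TissueState(self.points.copy(), self.labels.copy(), self.box_size, self.step)


def _small_mode(box_size: float, m: int) -> bool:
    return box_size < 8.0 or m < 30


def tessellate(points: np.ndarray, box_size: float) -> Tessellation:
    """Periodic Voronoi tessellation of generator points.

    Raises on duplicate generators (degenerate geometry).  Polygon areas sum
    to ``box_size**2`` up to floating-point tolerance.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 1:
        raise ValueError("need at least one generator point")
    rounded = np.round(points % box_size, 12)
    if len(np.unique(rounded, axis=0)) != len(points):
        raise ValueError("duplicate generator points (degenerate geometry)")
    areas, perims, rmaxs, n_neigh, n_idx, n_len = vk.tessellate_arrays(
        np.ascontiguousarray(points % box_size),
        float(box_size),
        _small_mode(box_size, len(points)),
        1.0,
    )
    return Tessellation(areas, perims, rmaxs, n_neigh, n_idx, n_len)


def cell_energy(
    i: int, tess: Tessellation, labels: np.ndarray, params: VertexParams
) -> float:
    """Mechanical energy of one (non-environment) cell."""
    if labels[i] == CellType.ENV:
        raise ValueError("environment polygons carry no mechanical energy")
    g = gamma_matrix(params)
    adh = 0.0
    for j, l in tess.neighbors_of(i, params.edge_eps).items():
        adh += g[int(labels[i]), int(labels[j])] * l
    a = float(tess.areas[i])
    p = float(tess.perimeters[i])
    return (
        params.area_coeff * (a - params.pref_area) ** 2
        + params.contract_coeff * p**2
        - 0.5 * adh
    )


def total_energy(state: TissueState, params: VertexParams) -> float:
    """Total mechanical energy: sum of cell energies over non-ENV cells."""
    tess = state.tessellation
    return sum(
        cell_energy(i, tess, state.labels, params)
        for i in range(state.m)
        if state.labels[i] != CellType.ENV
    )


def metropolis_accept(d_u: float, k_bt: float, rng: np.random.Generator) -> bool:
    """Accept a move with probability ``min(1, exp(-dU / kBT))``."""
    if d_u <= 0.0:
        return True
    return rng.random() <= np.exp(-d_u / k_bt)


def mc_move(
    state: TissueState,
    params: VertexParams,
    rng: np.random.Generator,
    max_disp: float | None = None,
) -> tuple[TissueState, bool]:
    """One Metropolis move, reference implementation with full recomputation.

    A uniformly chosen generator is displaced uniformly within a disk of
    radius ``max_disp``; the whole tessellation and total energy are
    recomputed for the tentative configuration.  Used for small systems and
    as the contract reference for the compiled incremental loop.
    """
    if max_disp is None:
        max_disp = params.max_disp
    idx = int(rng.integers(state.m))
    r = max_disp * np.sqrt(rng.random())
    th = 2.0 * np.pi * rng.random()
    u_before = total_energy(state, params)
    tentative = state.copy()
    tentative.points[idx] = (state.points[idx] + [r * np.cos(th), r * np.sin(th)]) % params.box_size
    u_after = total_energy(tentative, params)
    if metropolis_accept(u_after - u_before, params.k_bt, rng):
        tentative.step = state.step + 1
        return tentative, True
    out = state.copy()
    out.step = state.step + 1
    return out, False


def adapt_step(recent_accept_rate: float, params: VertexParams, max_disp: float) -> float:
    """Adapt the maximum displacement to hold acceptance in the target band."""
    if not 0.0 <= recent_accept_rate <= 1.0:
        raise ValueError("acceptance rate must be in [0, 1]")
    lo, hi = params.accept_window
    if recent_accept_rate > hi:
        max_disp *= 1.1
    elif recent_accept_rate < lo:
        max_disp *= 0.9
    return float(np.clip(max_disp, 1e-4, params.box_size / 4.0))


def init_random(
    params: VertexParams,
    composition: dict[CellType, int],
    rng: np.random.Generator,
) -> TissueState:
    """Uniform-random generator points with labels drawn from ``composition``.

    ``composition`` maps cell types to counts and must sum to ``n_cells``;
    the remaining ``env_factor * n_cells`` points are environment.
    """
    counts = {CellType(k): int(v) for k, v in composition.items()}
    if sum(counts.values()) != params.n_cells:
        raise ValueError("composition counts must sum to n_cells")
    if counts.get(CellType.ENV, 0):
        raise ValueError("composition is for cellular points only")
    m = params.n_points
    points = rng.random((m, 2)) * params.box_size
    labels = np.full(m, int(CellType.ENV), dtype=np.int64)
    i = 0
    for t, c in counts.items():
        labels[i : i + c] = int(t)
        i += c
    return TissueState(points, labels, params.box_size)


def init_aggregate(
    params: VertexParams,
    composition: dict[CellType, int],
    rng: np.random.Generator,
    spacing: float = 1.05,
    jitter: float = 0.05,
) -> TissueState:
    """Pre-formed cell aggregate: a compact hexagonal patch of cellular
    generators centred in the box (labels assigned at random within the
    patch), environment generators uniform outside.

    This mimics the experimental situation the model addresses — dissociated
    cells brought into contact as a clump, whose *arrangement* then evolves
    under differential adhesion.  Spontaneous nucleation of an aggregate
    from a dilute suspension is not reachable by local Metropolis dynamics
    at the adhesion strengths used here (see the methods note).
    """
    counts = {CellType(k): int(v) for k, v in composition.items()}
    if sum(counts.values()) != params.n_cells:
        raise ValueError("composition counts must sum to n_cells")
    if counts.get(CellType.ENV, 0):
        raise ValueError("composition is for cellular points only")
    n_cells = params.n_cells
    box = params.box_size
    cx = cy = box / 2.0
    rows = int(np.ceil(np.sqrt(n_cells))) + 4
    cand = []
    for iy in range(-rows, rows + 1):
        for ix in range(-rows, rows + 1):
            x = cx + (ix + 0.5 * (iy % 2)) * spacing
            y = cy + iy * spacing * np.sqrt(3.0) / 2.0
            cand.append((float(np.hypot(x - cx, y - cy)), x, y))
    cand.sort()
    cells = np.array([[x, y] for _, x, y in cand[:n_cells]])
    cells += rng.normal(0.0, jitter, cells.shape)
    radius = float(np.hypot(cells[:, 0] - cx, cells[:, 1] - cy).max()) + 1.0
    n_env = params.n_points - n_cells
    env = []
    while len(env) < n_env:
        p = rng.random(2) * box
        if np.hypot(p[0] - cx, p[1] - cy) > radius:
            env.append(p)
    labels = np.concatenate(
        [
            rng.permutation(
                np.concatenate([np.full(c, int(t)) for t, c in counts.items()])
            ),
            np.full(n_env, int(CellType.ENV)),
        ]
    ).astype(np.int64)
    points = np.vstack([cells, np.array(env)])
    return TissueState(points, labels, box)


def init_checkerboard(
    params: VertexParams,
    rng: np.random.Generator,
    type_a: CellType = CellType.IHOG_RED,
    type_b: CellType = CellType.HH,
    spacing: float = 1.0,
    jitter: float = 0.03,
) -> TissueState:
    """Pre-formed square-lattice aggregate with alternating labels.

    The seeded counterpart of :func:`init_aggregate` for the 4-coordinated
    checkerboard branch; ``n_cells`` must be a perfect square so the two
    labels alternate exactly.  Environment generators are placed uniformly
    outside the patch.
    """
    n_side = int(round(np.sqrt(params.n_cells)))
    if n_side * n_side != params.n_cells:
        raise ValueError("checkerboard seed needs a square cell count")
    box = params.box_size
    c0 = box / 2.0 - n_side * spacing / 2.0 + spacing / 2.0
    pts = []
    labs = []
    for iy in range(n_side):
        for ix in range(n_side):
            pts.append([c0 + ix * spacing, c0 + iy * spacing])
            labs.append(int(type_a) if (ix + iy) % 2 == 0 else int(type_b))
    pts = np.asarray(pts) + rng.normal(0.0, jitter, (n_side * n_side, 2))
    lo = c0 - 1.5 * spacing
    hi = c0 + (n_side + 0.5) * spacing
    n_env = params.n_points - params.n_cells
    env = []
    while len(env) < n_env:
        p = rng.random(2) * box
        if not (lo < p[0] < hi and lo < p[1] < hi):
            env.append(p)
    points = np.vstack([pts, np.array(env)])
    labels = np.array(labs + [int(CellType.ENV)] * n_env, dtype=np.int64)
    return TissueState(points, labels, box)


@dataclass
class VertexRun:
    """Result of a Monte Carlo run: snapshots plus sampling diagnostics."""

    snapshots: list[TissueState]
    energy_trace: np.ndarray
    acceptance_rate: float
    final_max_disp: float
    params: VertexParams


def simulate(params: VertexParams, initial: TissueState) -> VertexRun:
    """Run the Metropolis schedule from ``initial`` and collect snapshots.

    Fixed seed implies an identical trajectory.  Snapshots are recorded every
    ``snapshot_interval`` accepted-or-rejected steps starting at ``burn_in``.
    """
    if initial.m < 4:
        raise ValueError("need at least 4 generator points")
    snaps, snap_labels, trace, final_disp, acc, att = vk.run_mc(
        np.ascontiguousarray(initial.points, dtype=float),
        np.ascontiguousarray(initial.labels, dtype=np.int64),
        float(params.box_size),
        gamma_matrix(params),
        params.pref_area,
        params.area_coeff,
        params.contract_coeff,
        params.k_bt,
        params.edge_eps,
        params.total_steps,
        params.burn_in,
        params.snapshot_interval,
        params.snapshot_count,
        params.max_disp,
        params.accept_window[0],
        params.accept_window[1],
        params.adapt_interval,
        params.recompute_interval,
        params.seed,
        params.k_bt_start,
        params.anneal_steps,
        params.relocate_frac,
        params.swap_frac,
    )
    states = [
        TissueState(
            snaps[s],
            snap_labels[s].copy(),
            params.box_size,
            step=params.burn_in + s * params.snapshot_interval,
        )
        for s in range(params.snapshot_count)
    ]
    return VertexRun(
        snapshots=states,
        energy_trace=trace,
        acceptance_rate=acc / max(att, 1),
        final_max_disp=final_disp,
        params=params,
    )


def insert_invaders(
    state: TissueState,
    n_new: int,
    rng: np.random.Generator,
    label: CellType = CellType.HH,
) -> TissueState:
    """Add ``n_new`` cellular generators at uniform-random positions whose
    current Voronoi region belongs to an environment polygon."""
    pts = state.points
    labels = state.labels
    box = state.box_size
    new_pts: list[np.ndarray] = []
    while len(new_pts) < n_new:
        cand = rng.random(2) * box
        d = pts - cand
        d -= box * np.round(d / box)
        nearest = int(np.argmin((d**2).sum(axis=1)))
        if labels[nearest] == CellType.ENV and (d[nearest] ** 2).sum() > 1e-8:
            new_pts.append(cand)
    points2 = np.vstack([pts, np.array(new_pts)])
    labels2 = np.concatenate([labels, np.full(n_new, int(label), dtype=np.int64)])
    return TissueState(points2, labels2, box)


def invasion_protocol(
    params: VertexParams,
    rng: np.random.Generator,
    n_ihog: int = 50,
    n_hh: int = 50,
    phase1_params: VertexParams | None = None,
) -> tuple[VertexRun, VertexRun]:
    """Two-phase invasion experiment.

    Phase 1 evolves an aggregate of ``n_ihog`` Ihog-expressing cells (plus
    environment points) to steady state.  Phase 2 inserts ``n_hh``
    Hh-expressing generators at uniform-random positions currently inside
    environment polygons and continues the simulation with the same
    mechanical parameters.  Returns the two runs.
    """
    if phase1_params is None:
        phase1_params = params.replace(n_cells=n_ihog)
    init1 = init_aggregate(phase1_params, {CellType.IHOG_RED: n_ihog}, rng)
    run1 = simulate(phase1_params, init1)
    init2 = insert_invaders(run1.snapshots[-1], n_hh, rng, CellType.HH)

    phase2 = params.replace(
        n_cells=n_ihog + n_hh,
        seed=params.seed + 1,
        max_disp=run1.final_max_disp,
    )
    run2 = simulate(phase2, init2)
    return run1, run2
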