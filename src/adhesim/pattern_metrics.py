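"""Neighbour-graph statistics on tessellation snapshots.

A *center cell* is a mechanical cell none of whose edge-sharing neighbours is
an environment polygon; the neighbour and like-neighbour counts of center
cells, pooled over snapshots, distinguish the honeycomb regime (about six
neighbours, roughly half of them like) from the checkerboard regime (about
four neighbours, almost none like).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .vertex_sim import (
    CellType,
    TissueState,
    VertexParams,
    VertexRun,
    init_aggregate,
    init_checkerboard,
    simulate,
)

__all__ = [
    "NeighborStats",
    "SweepResult",
    "center_cells",
    "neighbor_stats",
    "classify_pattern",
    "mixed_steady_state",
    "gamma_sweep",
    "HONEYCOMB_MIN_LIKE",
    "CHECKERBOARD_MAX_LIKE",
    "NEIGHBOR_EDGE_THRESHOLD",
]

#: classification thresholds on the mean like-neighbour count, chosen midway
#: between the two observed regimes (about 2.4 like neighbours for honeycomb
#: vs about 0.3 for checkerboard)
CHECKERBOARD_MAX_LIKE = 1.0
HONEYCOMB_MIN_LIKE = 1.5

#: shared-edge length below which two polygons are not counted as visual
#: neighbours.  A space-filling tessellation has mean topological
#: coordination exactly 6, so neighbour counts below 6 (e.g. the ~4 of a
#: checkerboard) necessarily discount short edges; 0.15 length units is
#: about 15% of a cell diameter.
NEIGHBOR_EDGE_THRESHOLD = 0.15


@dataclass
class NeighborStats:
    """Pooled center-cell neighbour statistics over snapshots."""

    n_center: int
    mean_neighbors: float
    sd_neighbors: float
    mean_like: float
    sd_like: float

    @property
    def empty(self) -> bool:
        return self.n_center == 0


@dataclass
class SweepResult:
    """Summary statistics along a swept control parameter.

    ``transition`` is ``(largest control value classified honeycomb,
    smallest classified checkerboard)``, ``None`` when not estimated, and
    carries ``ambiguous=True`` when the classification is not monotone along
    the grid.
    """

    control_values: list[float]
    records: list[dict]
    transition: tuple[float, float] | None
    ambiguous: bool = False


def center_cells(snapshot: TissueState, edge_eps: float | None = None) -> list[int]:
    """Mechanical cells whose edge-sharing neighbours are all mechanical.

    Edges shorter than ``edge_eps`` (default the visual-scale
    ``NEIGHBOR_EDGE_THRESHOLD``) do not count as contacts.
    """
    if edge_eps is None:
        edge_eps = NEIGHBOR_EDGE_THRESHOLD
    tess = snapshot.tessellation
    labels = snapshot.labels
    out = []
    for i in range(snapshot.m):
        if labels[i] == CellType.ENV:
            continue
        neigh = tess.neighbors_of(i, edge_eps)
        if neigh and all(labels[j] != CellType.ENV for j in neigh):
            out.append(i)
    return out


def neighbor_stats(
    snapshots: Sequence[TissueState], edge_eps: float | None = None
) -> NeighborStats:
    """Neighbour and like-neighbour counts per center cell, pooled over snapshots."""
    totals: list[int] = []
    likes: list[int] = []
    for snap in snapshots:
        eps = NEIGHBOR_EDGE_THRESHOLD if edge_eps is None else edge_eps
        tess = snap.tessellation
        labels = snap.labels
        for i in center_cells(snap, eps):
            neigh = tess.neighbors_of(i, eps)
            totals.append(len(neigh))
            likes.append(sum(1 for j in neigh if labels[j] == labels[i]))
    if not totals:
        return NeighborStats(0, float("nan"), float("nan"), float("nan"), float("nan"))
    t = np.asarray(totals, dtype=float)
    l = np.asarray(likes, dtype=float)
    sd = lambda a: float(a.std(ddof=1)) if len(a) > 1 else 0.0  # noqa: E731
    return NeighborStats(len(t), float(t.mean()), sd(t), float(l.mean()), sd(l))


def classify_pattern(
    stats: NeighborStats,
    checkerboard_max_like: float = CHECKERBOARD_MAX_LIKE,
    honeycomb_min_like: float = HONEYCOMB_MIN_LIKE,
) -> str:
    """Classify a steady state by its mean like-neighbour count."""
    if stats.empty or np.isnan(stats.mean_like):
        return "transitional"
    if stats.mean_like < checkerboard_max_like:
        return "checkerboard"
    if stats.mean_like > honeycomb_min_like:
        return "honeycomb"
    return "transitional"


def mixed_steady_state(
    params: VertexParams,
    rng: np.random.Generator,
    n_ihog: int = 50,
    n_hh: int = 50,
) -> tuple[VertexRun, NeighborStats, str]:
    """Steady state of the mixed Ihog/Hh system at the params' adhesion.

    The honeycomb (hexagonal packing) and checkerboard (square packing)
    branches are separated by a strongly first-order, hysteretic transition
    that single-point dynamics does not cross, so both seeded branches are
    simulated and the one with the lower steady-state energy is selected —
    the standard free-energy comparison for competing ordered phases.
    Returns the selected run, its pooled neighbour statistics, and the
    branch name.
    """
    comp = {CellType.IHOG_RED: n_ihog, CellType.HH: n_hh}
    runs = {}
    for branch in ("honeycomb-seed", "checkerboard-seed"):
        p = params.replace(seed=int(rng.integers(2**31 - 1)))
        if branch == "honeycomb-seed":
            init = init_aggregate(p, comp, rng)
        else:
            init = init_checkerboard(p, rng)
        runs[branch] = simulate(p, init)
    tail = max(1, params.snapshot_count // 3)
    u = {b: float(np.mean(r.energy_trace[-tail:])) for b, r in runs.items()}
    branch = min(u, key=u.get)
    run = runs[branch]
    stats = neighbor_stats(run.snapshots[-tail:])
    return run, stats, branch


def gamma_sweep(
    ratios: Sequence[float],
    params: VertexParams,
    rng: np.random.Generator,
    n_ihog: int = 50,
    n_hh: int = 50,
) -> SweepResult:
    """Mixed Ihog/Hh simulations across heterotypic:homotypic adhesion ratios.

    For each ratio the mixed 50/50 steady state is computed (branch
    selection as in :func:`mixed_steady_state`) and classified.  The
    transition interval is ``[largest honeycomb ratio, smallest checkerboard
    ratio]``; a non-monotone classification along the grid is flagged
    ambiguous rather than silently interpolated.
    """
    ratios = list(ratios)
    if any(b <= a for a, b in zip(ratios, ratios[1:])):
        raise ValueError("ratios must be strictly increasing")
    records = []
    classes = []
    for ratio in ratios:
        run, stats, branch = mixed_steady_state(
            params.with_ratio(ratio), rng, n_ihog, n_hh
        )
        cls = classify_pattern(stats)
        classes.append(cls)
        records.append(
            {
                "control": ratio,
                "mean_neighbors": stats.mean_neighbors,
                "sd_neighbors": stats.sd_neighbors,
                "mean_like": stats.mean_like,
                "sd_like": stats.sd_like,
                "n_center": stats.n_center,
                "classification": cls,
                "branch": branch,
                "steady_energy": float(np.mean(run.energy_trace[-10:])),
            }
        )
    honeys = [r for r, c in zip(ratios, classes) if c == "honeycomb"]
    checkers = [r for r, c in zip(ratios, classes) if c == "checkerboard"]
    transition = None
    ambiguous = False
    if honeys and checkers:
        transition = (max(honeys), min(checkers))
        if transition[0] > transition[1]:
            ambiguous = True
    return SweepResult(
        control_values=ratios, records=records, transition=transition, ambiguous=ambiguous
    )
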