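"""Seeded initial states and small enumerable toy systems.

The toy systems exist so that tests can check the samplers against exact,
independently computed references: a 2-3 cytoneme system whose configuration
space is fully enumerable (Boltzmann weights), and hand-computed periodic
tessellation layouts with literal coordinates and energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .cytoneme_sim import CytonemeParams, CytonemeState

__all__ = [
    "make_initial_cytonemes",
    "ToyCytonemeSystem",
    "enumerate_toy_boltzmann",
    "ToyTissue",
    "make_toy_tissue",
]


def make_initial_cytonemes(
    params: CytonemeParams, rng: np.random.Generator
) -> CytonemeState:
    """Seed ``floor(occupancy_fraction * surface_length)`` cytonemes of length 0.

    Base sites are picked uniformly at random without replacement along the
    periodic surface lattice.
    """
    n = params.n_cytonemes
    if n < 1:
        raise ValueError("occupancy_fraction * surface_length must be >= 1")
    sites = rng.choice(params.surface_length, size=n, replace=False)
    return CytonemeState(
        positions=np.sort(sites),
        lengths=np.zeros(n, dtype=np.int64),
        surface_length=params.surface_length,
    )


# ---------------------------------------------------------------------------
# toy cytoneme system: translocation-only, fixed lengths, enumerable


@dataclass(frozen=True)
class ToyCytonemeSystem:
    """Fixed-length cytonemes on a tiny periodic lattice, translocation only.

    With contacts forced established (``contact_prob = 1``) the number of
    engaged segment pairs is a deterministic function of the positions, so
    the stationary law of the translocation chain is an exact Boltzmann
    distribution over position configurations.
    """

    surface_length: int
    lengths: tuple[int, ...]
    neighbor_radius: int = 1

    def __post_init__(self) -> None:
        if self.surface_length > 8:
            raise ValueError("toy systems are meant to stay enumerable (M <= 8)")
        if len(self.lengths) < 2 or len(self.lengths) > 3:
            raise ValueError("toy systems use 2-3 cytonemes")

    @property
    def n(self) -> int:
        return len(self.lengths)

    def configurations(self) -> list[tuple[int, ...]]:
        """All ordered placements of the distinguishable cytonemes."""
        return list(permutations(range(self.surface_length), self.n))

    def pair_segments(self, positions: tuple[int, ...]) -> int:
        """Engaged segment pairs when every aligned level is established."""
        m = self.surface_length
        total = 0
        for i in range(self.n):
            for j in range(i + 1, self.n):
                d = abs(positions[i] - positions[j])
                if min(d, m - d) <= self.neighbor_radius:
                    total += min(self.lengths[i], self.lengths[j])
        return total

    def state(self, positions: tuple[int, ...]) -> CytonemeState:
        return CytonemeState(
            positions=np.array(positions),
            lengths=np.array(self.lengths),
            surface_length=self.surface_length,
        )


def enumerate_toy_boltzmann(
    toy: ToyCytonemeSystem, e_ii: float, k_bt: float = 1.0
) -> dict[tuple[int, ...], float]:
    """Exact Boltzmann weights ``exp(E_ii * pairs(config) / kBT) / Z``.

    Full enumeration over the toy configuration space; refuses systems with
    more than 10^4 configurations.
    """
    configs = toy.configurations()
    if len(configs) > 10_000:
        raise ValueError("toy configuration space too large to enumerate")
    logw = np.array([e_ii * toy.pair_segments(c) / k_bt for c in configs])
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return dict(zip(configs, w))


# ---------------------------------------------------------------------------
# toy tissues: literal coordinates with hand-computed geometry and energy


@dataclass(frozen=True)
class ToyTissue:
    """A small periodic point layout with hand-computed reference geometry.

    ``ref_area``/``ref_perimeter`` are per-cell; ``ref_edges`` maps unordered
    point-index pairs to the total shared Voronoi edge length (summed over
    periodic images).  All values were derived with pencil and paper from the
    literal coordinates, independently of any tessellation code.
    """

    name: str
    box_size: float
    points: np.ndarray
    labels: np.ndarray  # int labels, see vertex_sim.CellType
    ref_area: np.ndarray
    ref_perimeter: np.ndarray
    ref_edges: dict[tuple[int, int], float] = field(default_factory=dict)


_SQRT5 = float(np.sqrt(5.0))


def make_toy_tissue(name: str) -> ToyTissue:
    """Fixed catalogue: ``two-squares``, ``grid-4``, ``hex-4``.

    * ``two-squares`` — 2 points in a 2x2 periodic box; cells are 1x2 columns
      (area 2, perimeter 6) sharing two vertical edges of length 2 each.
    * ``grid-4`` — 4 points on a unit grid in a 2x2 box; four unit squares
      (area 1, perimeter 4), laterally/vertically adjacent pairs share two
      unit edges (total length 2), diagonal pairs touch only at corners.
    * ``hex-4`` — 4 points in offset rows in a 2x2 box; exact hexagons with
      area 1 and perimeter ``1.5 + sqrt(5)``, lateral edge total 1.5 and four
      slanted edges of length ``sqrt(5)/4`` (two per diagonal neighbour).
    """
    if name == "two-squares":
        pts = np.array([[0.5, 0.5], [1.5, 0.5]])
        return ToyTissue(
            name=name,
            box_size=2.0,
            points=pts,
            labels=np.zeros(2, dtype=np.int64),
            ref_area=np.array([2.0, 2.0]),
            ref_perimeter=np.array([6.0, 6.0]),
            ref_edges={(0, 1): 4.0},
        )
    if name == "grid-4":
        pts = np.array([[0.5, 0.5], [1.5, 0.5], [0.5, 1.5], [1.5, 1.5]])
        edges = {(0, 1): 2.0, (2, 3): 2.0, (0, 2): 2.0, (1, 3): 2.0}
        return ToyTissue(
            name=name,
            box_size=2.0,
            points=pts,
            labels=np.zeros(4, dtype=np.int64),
            ref_area=np.ones(4),
            ref_perimeter=np.full(4, 4.0),
            ref_edges=edges,
        )
    if name == "hex-4":
        pts = np.array([[0.5, 0.5], [1.5, 0.5], [1.0, 1.5], [0.0, 1.5]])
        per = 1.5 + _SQRT5
        # lateral pairs share both vertical edges (2 x 0.75); each diagonal
        # pair shares two slanted edges of length sqrt(5)/4
        edges = {
            (0, 1): 1.5,
            (2, 3): 1.5,
            (0, 2): _SQRT5 / 2.0,
            (0, 3): _SQRT5 / 2.0,
            (1, 2): _SQRT5 / 2.0,
            (1, 3): _SQRT5 / 2.0,
        }
        return ToyTissue(
            name=name,
            box_size=2.0,
            points=pts,
            labels=np.zeros(4, dtype=np.int64),
            ref_area=np.ones(4),
            ref_perimeter=np.full(4, per),
            ref_edges=edges,
        )
    raise ValueError(f"unknown toy tissue {name!r}")
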