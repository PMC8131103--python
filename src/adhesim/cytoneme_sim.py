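"""1-D stochastic cytoneme model with homophilic trans-interaction energetics.

Cytonemes are filaments of discrete segments anchored at distinct sites of a
periodic 1-D lattice (the cell surface).  Each simulation step

1. re-assigns every pairwise segment contact between neighbouring cytonemes as
   an independent Bernoulli variable with the quasi-equilibrium occupancy
   probability ``exp(E_ii)/(1+exp(E_ii))``,
2. synchronously grows or shrinks every cytoneme by one segment, with the
   normalised shrink probability ``p_shrink/(p_elong+p_shrink)`` where
   ``p_elong = p_elong0*exp(-alpha*x)`` and ``p_shrink = p_shrink0*exp(-T*E_ii)``
   (``T`` = number of neighbours contacting the tip segment),
3. attempts one Metropolis translocation of a uniformly chosen cytoneme to an
   adjacent free site, with contact variables re-sampled for the tentative
   configuration and ``dE = -E_ii * (contacts after - contacts before)``.

The module-level functions are the reference implementation of the individual
operations; :func:`simulate` runs the full schedule through a compiled kernel
(:mod:`adhesim._cytoneme_kernel`) that samples the same process.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.special import expit

__all__ = [
    "CytonemeParams",
    "CytonemeState",
    "ContactAssignment",
    "CytonemeSnapshot",
    "elongation_prob",
    "shrink_prob",
    "interaction_prob",
    "neighbor_pairs",
    "assign_contacts",
    "tip_contact_count",
    "total_interaction_energy",
    "growth_update",
    "translocation_update",
    "simulate",
]


@dataclass(frozen=True)
class CytonemeParams:
    """Parameters of the cytoneme model.

    ``p_elong0`` and ``p_shrink0`` are dimensionless rate weights (only their
    normalised ratio enters the update rule); ``e_ii`` is the per-segment-pair
    trans-interaction strength in units of ``k_bt``.
    """

    surface_length: int = 100
    occupancy_fraction: float = 0.30
    p_elong0: float = 5.0
    p_shrink0: float = 0.5
    alpha: float = 0.2
    e_ii: float = 0.0
    k_bt: float = 1.0
    neighbor_radius: int = 1
    total_steps: int = 5_000_000
    burn_in_steps: int = 1_000_000
    snapshot_interval: int = 4_000
    snapshot_count: int = 1001
    seed: int = 0
    #: override of the contact-establishment probability; ``None`` means the
    #: logistic quasi-equilibrium value for ``e_ii``.  Used by toy systems that
    #: force deterministic contacts while keeping a finite interaction energy.
    contact_prob: float | None = None

    def __post_init__(self) -> None:
        if self.surface_length <= 0:
            raise ValueError("surface_length must be positive")
        if not 0.0 < self.occupancy_fraction <= 1.0:
            raise ValueError("occupancy_fraction must be in (0, 1]")
        if self.p_elong0 <= 0 or self.p_shrink0 <= 0:
            raise ValueError("p_elong0 and p_shrink0 must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.e_ii < 0:
            raise ValueError("e_ii must be non-negative")
        if self.k_bt <= 0:
            raise ValueError("k_bt must be positive")
        if self.neighbor_radius < 1:
            raise ValueError("neighbor_radius must be >= 1")
        if self.burn_in_steps >= self.total_steps:
            raise ValueError("burn_in_steps must be smaller than total_steps")
        if self.contact_prob is not None and not 0.0 <= self.contact_prob <= 1.0:
            raise ValueError("contact_prob must be in [0, 1]")
        last = self.burn_in_steps + (self.snapshot_count - 1) * self.snapshot_interval
        if self.snapshot_count > 0 and last > self.total_steps:
            raise ValueError(
                "snapshot schedule exceeds total_steps "
                f"(last snapshot at step {last} > {self.total_steps})"
            )

    @property
    def n_cytonemes(self) -> int:
        return int(np.floor(self.occupancy_fraction * self.surface_length))

    @property
    def p_contact(self) -> float:
        """Effective contact-establishment probability."""
        if self.contact_prob is not None:
            return self.contact_prob
        return interaction_prob(self.e_ii)

    def replace(self, **changes) -> "CytonemeParams":
        return dataclasses.replace(self, **changes)


@dataclass
class CytonemeState:
    """Positions (distinct lattice sites) and segment counts of all cytonemes."""

    positions: np.ndarray  # (n,) int
    lengths: np.ndarray  # (n,) int, >= 0
    surface_length: int
    step: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if self.positions.shape != self.lengths.shape:
            raise ValueError("positions and lengths must have equal shape")
        if len(np.unique(self.positions % self.surface_length)) != len(self.positions):
            raise ValueError("cytoneme positions must be pairwise distinct")
        if np.any(self.lengths < 0):
            raise ValueError("lengths must be non-negative")
        self.positions = self.positions % self.surface_length

    @property
    def n(self) -> int:
        return len(self.positions)

    def copy(self) -> "CytonemeState":
        return CytonemeState(
            self.positions.copy(), self.lengths.copy(), self.surface_length, self.step
        )


class ContactAssignment:
    """Binary trans-interaction variables per neighbouring pair and level.

    For each unordered neighbouring pair ``(i, j)`` (``i < j``) holds a 0/1
    array over the aligned segment levels ``1..min(x_i, x_j)``; entry ``k-1``
    is the state of the level-``k`` segment pair.
    """

    def __init__(self, entries: dict[tuple[int, int], np.ndarray]):
        self._entries: dict[tuple[int, int], np.ndarray] = {}
        for (i, j), arr in entries.items():
            key = (min(i, j), max(i, j))
            arr = np.asarray(arr, dtype=np.uint8)
            if arr.ndim != 1 or np.any(arr > 1):
                raise ValueError("contact entries must be a 1-D 0/1 array")
            self._entries[key] = arr

    def pairs(self) -> Iterator[tuple[int, int]]:
        return iter(self._entries)

    def levels(self, i: int, j: int) -> np.ndarray:
        """Entries for pair (i, j); empty array if not neighbours."""
        return self._entries.get((min(i, j), max(i, j)), np.zeros(0, dtype=np.uint8))

    def pair_count(self, i: int, j: int) -> int:
        """Number of established contacts between i and j."""
        return int(self.levels(i, j).sum())

    def cytoneme_count(self, i: int) -> int:
        """Established contacts involving cytoneme i (summed over its pairs)."""
        return sum(int(arr.sum()) for (a, b), arr in self._entries.items() if i in (a, b))

    def total(self) -> int:
        """Total established pairwise interactions (each unordered pair once)."""
        return sum(int(arr.sum()) for arr in self._entries.values())

    def copy(self) -> "ContactAssignment":
        return ContactAssignment({k: v.copy() for k, v in self._entries.items()})


@dataclass
class CytonemeSnapshot:
    """One recorded configuration: per-cytoneme state plus contact summaries.

    ``contact_counts[i]`` counts established contacts involving cytoneme ``i``
    (each unordered pair contributes its full count to both members);
    ``pair_counts`` maps each contacting unordered pair to its count, so
    ``total_contacts`` is the plain sum over pairs.
    """

    step: int
    positions: np.ndarray
    lengths: np.ndarray
    contact_counts: np.ndarray
    pair_counts: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def total_contacts(self) -> int:
        return int(sum(self.pair_counts.values()))

    @property
    def mean_length(self) -> float:
        return float(np.mean(self.lengths))


# ---------------------------------------------------------------------------
# elementary rates


def elongation_prob(length: int, params: CytonemeParams) -> float:
    """Elongation weight ``p_elong0 * exp(-alpha * length)``."""
    if length < 0:
        raise ValueError("length must be non-negative")
    return params.p_elong0 * float(np.exp(-params.alpha * length))


def shrink_prob(tip_contacts: int, params: CytonemeParams) -> float:
    """Shrinkage weight ``p_shrink0 * exp(-tip_contacts * E_ii)``.

    Tip contacts act as additional energy barriers to removal of the tip
    segment; with no contacts (or ``E_ii = 0``) the intrinsic rate applies.
    """
    if tip_contacts < 0:
        raise ValueError("tip_contacts must be non-negative")
    return params.p_shrink0 * float(np.exp(-tip_contacts * params.e_ii))


def interaction_prob(e_ii: float) -> float:
    """Quasi-equilibrium contact probability ``exp(E_ii) / (1 + exp(E_ii))``."""
    if e_ii < 0:
        raise ValueError("e_ii must be non-negative")
    return float(expit(e_ii))


# ---------------------------------------------------------------------------
# contacts


def neighbor_pairs(state: CytonemeState, params: CytonemeParams) -> list[tuple[int, int]]:
    """Unordered pairs whose base sites are within ``neighbor_radius`` (periodic)."""
    m = state.surface_length
    pos = state.positions
    out = []
    for i in range(state.n):
        for j in range(i + 1, state.n):
            d = abs(int(pos[i]) - int(pos[j]))
            if min(d, m - d) <= params.neighbor_radius:
                out.append((i, j))
    return out


def assign_contacts(
    state: CytonemeState, params: CytonemeParams, rng: np.random.Generator
) -> ContactAssignment:
    """Draw a fresh independent Bernoulli contact state for every aligned level."""
    p = params.p_contact
    entries = {}
    for i, j in neighbor_pairs(state, params):
        m = int(min(state.lengths[i], state.lengths[j]))
        if m > 0:
            entries[(i, j)] = (rng.random(m) < p).astype(np.uint8)
    return ContactAssignment(entries)


def tip_contact_count(state: CytonemeState, contacts: ContactAssignment, i: int) -> int:
    """Number of neighbours whose aligned segment at i's tip level is engaged.

    The tip of cytoneme ``i`` sits at level ``x_i``; a neighbour ``j``
    contributes only if ``x_j >= x_i`` (otherwise no aligned tip-level pair
    exists) and the level-``x_i`` entry for the pair is 1.
    """
    xi = int(state.lengths[i])
    if xi < 1:
        raise ValueError("cytoneme has no tip segment (length 0)")
    t = 0
    for a, b in contacts.pairs():
        if i not in (a, b):
            continue
        j = b if a == i else a
        if int(state.lengths[j]) >= xi:
            arr = contacts.levels(a, b)
            # aligned levels run 1..min(xi, xj) = 1..xi here
            if len(arr) >= xi and arr[xi - 1]:
                t += 1
    return t


def total_interaction_energy(
    state: CytonemeState,
    contacts: ContactAssignment,
    i: int,
    params: CytonemeParams,
) -> float:
    """Total trans-interaction energy of cytoneme i: ``E_ii * sum_j sum_k s_kij``."""
    return params.e_ii * contacts.cytoneme_count(i)


# ---------------------------------------------------------------------------
# updates


def growth_update(
    state: CytonemeState,
    contacts: ContactAssignment,
    params: CytonemeParams,
    rng: np.random.Generator,
) -> CytonemeState:
    """Synchronously elongate or shrink every cytoneme by one segment.

    With ``r`` uniform in [0, 1]: shrink iff the length is positive and
    ``r <= p_shrink / (p_elong + p_shrink)``; otherwise elongate.  Tip-contact
    counts are evaluated on the pre-update lengths.
    """
    new = state.copy()
    for i in range(state.n):
        x = int(state.lengths[i])
        pe = elongation_prob(x, params)
        t = tip_contact_count(state, contacts, i) if x > 0 else 0
        ps = shrink_prob(t, params)
        r = rng.random()
        if x > 0 and r <= ps / (pe + ps):
            new.lengths[i] = x - 1
        else:
            new.lengths[i] = x + 1
    return new


def _contacts_with(state, params, rng, i) -> dict[tuple[int, int], np.ndarray]:
    """Freshly drawn entries for the pairs involving cytoneme i only."""
    p = params.p_contact
    entries = {}
    for a, b in neighbor_pairs(state, params):
        if i in (a, b):
            m = int(min(state.lengths[a], state.lengths[b]))
            if m > 0:
                entries[(a, b)] = (rng.random(m) < p).astype(np.uint8)
    return entries


def translocation_update(
    state: CytonemeState,
    contacts: ContactAssignment,
    params: CytonemeParams,
    rng: np.random.Generator,
) -> tuple[CytonemeState, ContactAssignment]:
    """One Metropolis translocation attempt of a uniformly chosen cytoneme.

    The proposal is +-1 site (periodic); a proposal onto an occupied site is
    rejected outright.  Contacts for the tentative neighbour set are freshly
    re-sampled; with configuration energy ``-E_ii * (established contacts
    involving the mover)`` the move is accepted iff
    ``r <= min(1, exp(-dE / k_bt))``.  On rejection the pre-move state and
    assignment are returned unchanged.
    """
    i = int(rng.integers(state.n))
    direction = 1 if rng.random() < 0.5 else -1
    m = state.surface_length
    target = (int(state.positions[i]) + direction) % m
    if np.any(state.positions == target):
        return state, contacts

    before = contacts.cytoneme_count(i)
    tentative = state.copy()
    tentative.positions[i] = target
    new_entries = _contacts_with(tentative, params, rng, i)
    after = sum(int(v.sum()) for v in new_entries.values())

    d_e = -params.e_ii * (after - before)
    if d_e <= 0 or rng.random() <= np.exp(-d_e / params.k_bt):
        merged = {
            k: v for k, v in ((p, contacts.levels(*p)) for p in contacts.pairs()) if i not in k
        }
        merged.update(new_entries)
        return tentative, ContactAssignment(merged)
    return state, contacts


def step(
    state: CytonemeState, params: CytonemeParams, rng: np.random.Generator
) -> tuple[CytonemeState, ContactAssignment]:
    """One full simulation step: assign contacts, grow/shrink all, translocate one."""
    contacts = assign_contacts(state, params, rng)
    state = growth_update(state, contacts, params, rng)
    state, contacts = translocation_update(state, contacts, params, rng)
    state.step += 1
    return state, contacts


# ---------------------------------------------------------------------------
# full run


def simulate(params: CytonemeParams, initial: CytonemeState | None = None) -> list[CytonemeSnapshot]:
    """Run the full schedule and return the recorded snapshots.

    Uses the compiled kernel; the sampled process is the one defined by the
    module-level operations.  Snapshots are taken every ``snapshot_interval``
    steps starting at ``burn_in_steps``.
    """
    from . import _cytoneme_kernel as k
    from .fixtures import make_initial_cytonemes

    if initial is None:
        initial = make_initial_cytonemes(params, np.random.default_rng(params.seed))
    pos0 = initial.positions.astype(np.int64)
    len0 = initial.lengths.astype(np.int64)

    (lens, poss, counts, pair_n, pair_i, pair_j, pair_c) = k.run(
        pos0,
        len0,
        params.surface_length,
        params.neighbor_radius,
        params.p_elong0,
        params.p_shrink0,
        params.alpha,
        params.e_ii,
        params.p_contact,
        params.k_bt,
        params.total_steps,
        params.burn_in_steps,
        params.snapshot_interval,
        params.snapshot_count,
        params.seed,
    )
    snaps = []
    for s in range(params.snapshot_count):
        pc = {
            (int(pair_i[s, q]), int(pair_j[s, q])): int(pair_c[s, q])
            for q in range(pair_n[s])
        }
        snaps.append(
            CytonemeSnapshot(
                step=params.burn_in_steps + s * params.snapshot_interval,
                positions=poss[s].copy(),
                lengths=lens[s].copy(),
                contact_counts=counts[s].copy(),
                pair_counts=pc,
            )
        )
    return snaps
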