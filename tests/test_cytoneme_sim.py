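"""Unit and oracle tests for the 1-D cytoneme simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adhesim import cytoneme_sim as cs
from adhesim.cytoneme_sim import CytonemeParams
from adhesim.fixtures import ToyCytonemeSystem, enumerate_toy_boltzmann
from tests.conftest import make_state


class TestRates:
    @pytest.mark.parametrize(
        "length,p_elong0,alpha,expected",
        [
            (0, 5.0, 0.2, 5.0),
            (7, 3.0, 0.0, 3.0),
            (10, 5.0, 0.2, 5.0 * np.exp(-2.0)),
        ],
    )
    def test_elongation_values(self, length, p_elong0, alpha, expected):
        p = CytonemeParams(p_elong0=p_elong0, alpha=alpha)
        assert cs.elongation_prob(length, p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "tips,p_shrink0,e_ii,expected",
        [
            (0, 0.5, 15.0, 0.5),
            (3, 0.7, 0.0, 0.7),
            (1, 0.5, 15.0, 0.5 * np.exp(-15.0)),
        ],
    )
    def test_shrink_values(self, tips, p_shrink0, e_ii, expected):
        p = CytonemeParams(p_shrink0=p_shrink0, e_ii=e_ii)
        assert cs.shrink_prob(tips, p) == pytest.approx(expected, rel=1e-12)

    def test_negative_arguments_rejected(self):
        p = CytonemeParams()
        with pytest.raises(ValueError):
            cs.elongation_prob(-1, p)
        with pytest.raises(ValueError):
            cs.shrink_prob(-1, p)

    @pytest.mark.parametrize(
        "e_ii,expected",
        [(0.0, 0.5), (15.0, np.exp(15) / (1 + np.exp(15))), (1000.0, 1.0)],
    )
    def test_interaction_prob(self, e_ii, expected):
        assert cs.interaction_prob(e_ii) == pytest.approx(expected, abs=1e-9)

    @given(
        x=st.integers(min_value=0, max_value=200),
        alpha=st.floats(min_value=1e-3, max_value=2.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_elongation_strictly_decreasing(self, x, alpha):
        p = CytonemeParams(alpha=alpha)
        assert cs.elongation_prob(x + 1, p) < cs.elongation_prob(x, p)

    @given(e=st.floats(min_value=0.0, max_value=700.0))
    @settings(deadline=None, max_examples=50)
    def test_interaction_prob_bounded_monotone(self, e):
        v = cs.interaction_prob(e)
        assert 0.5 <= v <= 1.0
        assert cs.interaction_prob(e + 1.0) >= v


class TestContacts:
    def test_neighbor_pairs_periodic(self):
        state = make_state([0, 9, 5], [1, 1, 1], 10)
        pairs = cs.neighbor_pairs(state, CytonemeParams(neighbor_radius=1))
        assert pairs == [(0, 1)]  # wraps around the periodic boundary

    def test_far_pair_has_no_entries(self, rng):
        state = make_state([0, 5], [4, 4], 20)
        contacts = cs.assign_contacts(state, CytonemeParams(), rng)
        assert contacts.total() == 0

    def test_expected_count_at_zero_strength(self, pair_state):
        # min length 4 -> 4 Bernoulli(1/2) per step
        p = CytonemeParams(e_ii=0.0, surface_length=10)
        totals = [
            cs.assign_contacts(pair_state, p, np.random.default_rng(s)).pair_count(0, 1)
            for s in range(3000)
        ]
        assert np.mean(totals) == pytest.approx(2.0, abs=0.1)

    def test_saturated_strength_establishes_all(self, pair_state, rng):
        p = CytonemeParams(e_ii=50.0, surface_length=10)
        contacts = cs.assign_contacts(pair_state, p, rng)
        assert contacts.pair_count(0, 1) == 4

    def test_tip_contact_counting(self):
        # three in a row; middle cytoneme shortest
        state = make_state([4, 5, 6], [3, 2, 5], 10)
        entries = {
            (0, 1): np.array([1, 1], dtype=np.uint8),
            (1, 2): np.array([1, 0], dtype=np.uint8),
        }
        contacts = cs.ContactAssignment(entries)
        # tip of 1 is level 2: engaged with 0 (len 3 >= 2), not with 2
        assert cs.tip_contact_count(state, contacts, 1) == 1
        # tip of 0 is level 3: no aligned entry with the shorter middle one
        assert cs.tip_contact_count(state, contacts, 0) == 0
        with pytest.raises(ValueError):
            cs.tip_contact_count(make_state([0], [0], 10), cs.ContactAssignment({}), 0)

    def test_interaction_energy(self, pair_state):
        p = CytonemeParams(e_ii=15.0)
        contacts = cs.ContactAssignment({(0, 1): np.array([1, 0, 1, 1], dtype=np.uint8)})
        assert cs.total_interaction_energy(pair_state, contacts, 0, p) == pytest.approx(45.0)
        p0 = CytonemeParams(e_ii=0.0)
        assert cs.total_interaction_energy(pair_state, contacts, 0, p0) == 0.0


class TestUpdates:
    def test_zero_length_always_elongates(self, rng):
        state = make_state([0, 10], [0, 0], 20)
        p = CytonemeParams(surface_length=20)
        for _ in range(50):
            new = cs.growth_update(state, cs.ContactAssignment({}), p, rng)
            assert np.all(new.lengths == 1)

    def test_blocked_translocation_leaves_state(self, rng):
        # full lattice: every proposal lands on an occupied site
        state = make_state([0, 1, 2], [1, 1, 1], 3)
        p = CytonemeParams(surface_length=3, occupancy_fraction=1.0)
        contacts = cs.assign_contacts(state, p, rng)
        new, _ = cs.translocation_update(state, contacts, p, rng)
        assert np.array_equal(np.sort(new.positions), [0, 1, 2])

    def test_zero_strength_moves_always_accepted(self, rng):
        # single cytoneme: every proposal is unblocked and dE = 0
        state = make_state([5], [2], 20)
        p = CytonemeParams(surface_length=20, e_ii=0.0)
        for _ in range(200):
            contacts = cs.assign_contacts(state, p, rng)
            new, _ = cs.translocation_update(state, contacts, p, rng)
            assert not np.array_equal(new.positions, state.positions)
            state = new

    def test_state_invariants_preserved(self, base_params):
        snaps = cs.simulate(base_params)
        n = base_params.n_cytonemes
        for s in snaps:
            assert len(np.unique(s.positions)) == n
            assert np.all(s.lengths >= 0)


def birth_death_stationary(params: CytonemeParams, x_max: int = 400) -> np.ndarray:
    """Exact stationary law of the isolated-cytoneme length chain.

    Detailed balance of the birth-death chain with up-rate
    ``pe/(pe+ps)`` (from 0: always up) and down-rate ``ps/(pe+ps)``.
    """
    pe = params.p_elong0 * np.exp(-params.alpha * np.arange(x_max + 1))
    ps = params.p_shrink0
    up = pe / (pe + ps)
    up[0] = 1.0
    down = ps / (pe + ps)
    logpi = np.concatenate([[0.0], np.cumsum(np.log(up[:-1]) - np.log(down[1:]))])
    pi = np.exp(logpi - logpi.max())
    return pi / pi.sum()


class TestOracles:
    def test_single_cytoneme_matches_birth_death(self):
        """Length histogram of one isolated cytoneme vs the enumerated
        stationary distribution (total variation < 0.02)."""
        params = CytonemeParams(
            surface_length=10,
            occupancy_fraction=0.1,  # one cytoneme
            total_steps=505_000,
            burn_in_steps=5_000,
            snapshot_interval=5,
            snapshot_count=100_000,
            seed=11,
        )
        snaps = cs.simulate(params)
        lengths = np.array([s.lengths[0] for s in snaps])
        pi = birth_death_stationary(params)
        hist = np.bincount(lengths, minlength=len(pi)) / len(lengths)
        tv = 0.5 * np.abs(hist[: len(pi)] - pi).sum()
        assert tv < 0.02

    def test_simulate_mean_matches_birth_death_at_zero_strength(self):
        params = CytonemeParams(
            surface_length=50,
            occupancy_fraction=0.3,
            e_ii=0.0,
            total_steps=300_000,
            burn_in_steps=50_000,
            snapshot_interval=250,
            snapshot_count=1_000,
            seed=3,
        )
        snaps = cs.simulate(params)
        mean_len = np.mean([s.mean_length for s in snaps])
        pi = birth_death_stationary(params)
        expected = float(np.arange(len(pi)) @ pi)
        # contacts carry no energy at E_ii = 0; only exclusion perturbs
        assert mean_len == pytest.approx(expected, rel=0.05)

    def test_translocation_samples_boltzmann(self):
        """Two fixed-length cytonemes, deterministic contacts, moves only:
        empirical configuration frequencies vs enumerated weights."""
        toy = ToyCytonemeSystem(surface_length=6, lengths=(3, 2))
        e_ii = 1.0
        params = CytonemeParams(
            surface_length=6,
            occupancy_fraction=0.34,
            e_ii=e_ii,
            contact_prob=1.0,  # forced establishment; finite energy
            total_steps=10,
            burn_in_steps=1,
            snapshot_interval=1,
            snapshot_count=1,
        )
        target = enumerate_toy_boltzmann(toy, e_ii)
        state = toy.state((0, 3))
        rng = np.random.default_rng(5)
        counts: dict = {}
        n_samp = 120_000
        for _ in range(n_samp):
            contacts = cs.assign_contacts(state, params, rng)
            state, _ = cs.translocation_update(state, contacts, params, rng)
            key = tuple(int(x) for x in state.positions)
            counts[key] = counts.get(key, 0) + 1
        emp = {k: v / n_samp for k, v in counts.items()}
        tv = 0.5 * sum(abs(emp.get(k, 0.0) - w) for k, w in target.items())
        assert tv < 0.05

    def test_fixed_seed_reproducibility(self, base_params):
        a = cs.simulate(base_params)
        b = cs.simulate(base_params)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.lengths, sb.lengths)
            assert np.array_equal(sa.positions, sb.positions)
            assert sa.pair_counts == sb.pair_counts


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"surface_length": 0},
            {"occupancy_fraction": 0.0},
            {"occupancy_fraction": 1.5},
            {"alpha": -0.1},
            {"e_ii": -1.0},
            {"burn_in_steps": 10, "total_steps": 10},
            {"snapshot_count": 10_000, "snapshot_interval": 10_000},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            CytonemeParams(**kwargs)
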