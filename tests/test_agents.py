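"""Agent walks and state transitions."""

import numpy as np
import pytest

from elnsim.agents import (CellArrays, Kind, MotilityParams, random_walk_step,
                           tactic_step, transition_cells)

RNG = lambda s=0: np.random.default_rng(s)


class TestRandomWalk:
    def test_zero_speed_stays_put(self):
        p = np.array([[3.0, 4.0]])
        np.testing.assert_array_equal(random_walk_step(p, 0.0, 1.0, RNG()), p)

    def test_step_length_bounded_by_speed(self):
        p = np.zeros((5000, 2))
        q = random_walk_step(p, 12.0, 1.0, RNG(1))
        lengths = np.linalg.norm(q - p, axis=1)
        assert lengths.max() <= 12.0 + 1e-12

    def test_mean_step_length_is_half_max(self):
        # E|step| for Uniform(0, v dt) lengths is v dt / 2
        n = 100_000
        q = random_walk_step(np.zeros((n, 2)), 10.0, 1.0, RNG(2))
        lengths = np.linalg.norm(q, axis=1)
        se = 10.0 / np.sqrt(12 * n)
        assert abs(lengths.mean() - 5.0) < 3 * se

    def test_isotropic(self):
        n = 100_000
        q = random_walk_step(np.zeros((n, 2)), 10.0, 1.0, RNG(3))
        # mean displacement vector vanishes
        assert np.all(np.abs(q.mean(axis=0)) < 3 * 10.0 / np.sqrt(n))


class TestTacticStep:
    def test_zero_bias_stays_put(self):
        p = np.array([[1.0, 1.0]])
        d = np.array([[1.0, 0.0]])
        np.testing.assert_array_equal(
            tactic_step(p, d, 10.0, 0.0, 1.0, RNG()), p)

    def test_moves_only_along_direction(self):
        p = np.zeros((1000, 2))
        d = np.tile([1.0, 0.0], (1000, 1))
        q = tactic_step(p, d, 10.0, 1.0, 1.0, RNG(4))
        assert np.all(q[:, 1] == 0.0)
        assert np.all((q[:, 0] >= 0.0) & (q[:, 0] <= 10.0))

    def test_zero_direction_means_no_displacement(self):
        p = np.array([[2.0, 3.0]])
        np.testing.assert_array_equal(
            tactic_step(p, np.zeros((1, 2)), 100.0, 1.0, 1.0, RNG()), p)

    def test_mean_tactic_displacement(self):
        n = 100_000
        d = np.tile([0.0, 1.0], (n, 1))
        q = tactic_step(np.zeros((n, 2)), d, 8.0, 0.5, 1.0, RNG(5))
        mean = 0.5 * 8.0 / 2.0
        se = 0.5 * 8.0 / np.sqrt(12 * n)
        assert abs(q[:, 1].mean() - mean) < 3 * se

    def test_bias_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            tactic_step(np.zeros((1, 2)), np.ones((1, 2)), 1.0, 1.5, 1.0,
                        RNG())


def test_motility_params_validation():
    MotilityParams(10.0, 0.0)
    with pytest.raises(ValueError):
        MotilityParams(-1.0, 0.0)


def make_cells(entries):
    """entries: list of (kind, (x, y)) -> CellArrays with those cells."""
    cells = CellArrays()
    for kind, xy in entries:
        cells.append(kind, np.array([xy]))
    return cells


NO_RFC = (np.empty((0, 2)), np.zeros(0, dtype=bool))


class TestTransitions:
    def test_apc_inside_tumor_collects_antigen(self):
        cells = make_cells([(Kind.APC_OFF, (50.0, 0.0)),
                            (Kind.APC_OFF, (500.0, 0.0))])
        ev = transition_cells(cells, 200.0, *NO_RFC)
        assert ev.n_apc_converted == 1
        assert list(cells.kind) == [int(Kind.APC_M), int(Kind.APC_OFF)]

    def test_degenerate_radius_converts_nothing(self):
        cells = make_cells([(Kind.APC_OFF, (0.0, 0.0))])
        ev = transition_cells(cells, 0.0, *NO_RFC)
        assert ev.n_apc_converted == 0

    @pytest.mark.parametrize("dist,expect", [(14.0, True), (15.0, True),
                                             (16.0, False)])
    def test_t_activation_range(self, dist, expect):
        cells = make_cells([(Kind.T_INACTIVE, (1000.0, 0.0)),
                            (Kind.APC_M, (1000.0 + dist, 0.0))])
        ev = transition_cells(cells, 200.0, *NO_RFC)
        assert (ev.n_t_activated == 1) == expect
        assert bool(cells.kind[0] == int(Kind.T_ACTIVE)) == expect

    def test_one_apc_per_t_and_nearest_wins(self):
        cells = make_cells([(Kind.T_INACTIVE, (1000.0, 0.0)),
                            (Kind.APC_M, (1010.0, 0.0)),
                            (Kind.APC_M, (1005.0, 0.0))])
        ev = transition_cells(cells, 200.0, *NO_RFC)
        assert ev.n_t_activated == 1
        # the nearer APC (id 2) did the activating
        assert cells.nact[cells.ids == 2][0] == 1
        assert cells.nact[cells.ids == 1][0] == 0

    def test_tie_broken_by_lower_id(self):
        cells = make_cells([(Kind.T_INACTIVE, (1000.0, 0.0)),
                            (Kind.APC_M, (1010.0, 0.0)),
                            (Kind.APC_M, (990.0, 0.0))])
        transition_cells(cells, 200.0, *NO_RFC)
        assert cells.nact[cells.ids == 1][0] == 1

    def test_apc_m_removed_at_capacity(self):
        entries = [(Kind.APC_M, (1000.0, 0.0))]
        entries += [(Kind.T_INACTIVE, (1000.0 + i, 0.0)) for i in (1, 2, 3)]
        cells = make_cells(entries)
        ev = transition_cells(cells, 200.0, *NO_RFC, apc_m_capacity=3)
        assert ev.n_t_activated == 3
        assert ev.n_apc_m_exhausted == 1
        assert int(Kind.APC_M) not in cells.kind

    def test_capacity_limits_activations_per_step(self):
        entries = [(Kind.APC_M, (1000.0, 0.0))]
        entries += [(Kind.T_INACTIVE, (1000.0 + i, 0.0)) for i in (1, 2, 3, 4)]
        cells = make_cells(entries)
        ev = transition_cells(cells, 200.0, *NO_RFC, apc_m_capacity=2)
        assert ev.n_t_activated == 2
        assert np.count_nonzero(cells.kind == int(Kind.T_INACTIVE)) == 2

    def test_sequential_capacity_exhaustion(self):
        cells = make_cells([(Kind.APC_M, (1000.0, 0.0))])
        for i in range(3):
            cells.append(Kind.T_INACTIVE, np.array([[1005.0, 0.0]]))
            ev = transition_cells(cells, 200.0, *NO_RFC, apc_m_capacity=3)
            assert ev.n_t_activated == 1
        assert int(Kind.APC_M) not in cells.kind  # removed after 3rd

    def test_active_t_becomes_til_and_expires(self):
        cells = make_cells([(Kind.T_ACTIVE, (100.0, 0.0))])
        ev = transition_cells(cells, 200.0, *NO_RFC)
        assert ev.n_til_formed == 1
        cells.age[:] = 1440.0
        ev = transition_cells(cells, 200.0, *NO_RFC, til_lifespan=1440.0)
        assert ev.n_til_expired == 0  # exactly at lifespan: still alive
        cells.age[:] = 1441.0
        ev = transition_cells(cells, 200.0, *NO_RFC, til_lifespan=1440.0)
        assert ev.n_til_expired == 1
        assert len(cells) == 0

    def test_rfc_activation_by_contact(self):
        rfc_pos = np.array([[2000.0, 0.0], [2500.0, 0.0]])
        rfc_on = np.zeros(2, dtype=bool)
        cells = make_cells([(Kind.APC_M, (2010.0, 0.0))])
        ev = transition_cells(cells, 200.0, rfc_pos, rfc_on)
        assert ev.new_rfc_indices == [0]
        assert list(rfc_on) == [True, False]

    def test_fresh_apc_m_acts_same_step(self):
        # order (a) then (c)/(b): conversion inside the tumor precedes contact
        rfc_pos = np.array([[150.0, 0.0]])
        rfc_on = np.zeros(1, dtype=bool)
        cells = make_cells([(Kind.APC_OFF, (140.0, 0.0)),
                            (Kind.T_INACTIVE, (145.0, 0.0))])
        ev = transition_cells(cells, 200.0, rfc_pos, rfc_on)
        assert ev.n_apc_converted == 1
        assert ev.n_t_activated == 1
        assert rfc_on[0]

    def test_bookkeeping_conserves_t_cells(self):
        rng = np.random.default_rng(11)
        cells = CellArrays()
        cells.append(Kind.T_INACTIVE, rng.uniform(-300, 300, (40, 2)))
        cells.append(Kind.APC_M, rng.uniform(-300, 300, (30, 2)))
        cells.append(Kind.T_ACTIVE, rng.uniform(-300, 300, (10, 2)))
        before = cells.counts()
        ev = transition_cells(cells, 200.0, *NO_RFC)
        after = cells.counts()
        total_before = (before[Kind.T_INACTIVE] + before[Kind.T_ACTIVE]
                        + before[Kind.TIL])
        total_after = (after[Kind.T_INACTIVE] + after[Kind.T_ACTIVE]
                       + after[Kind.TIL] + ev.n_til_expired)
        assert total_before == total_after


class TestCellArrays:
    def test_append_and_ids_monotone(self):
        cells = CellArrays(capacity=2)
        for i in range(5):
            cells.append(Kind.APC_OFF, np.random.default_rng(i).random((7, 2)))
        assert len(cells) == 35
        assert np.array_equal(cells.ids, np.arange(35))

    def test_remove_preserves_order(self):
        cells = CellArrays()
        cells.append(Kind.APC_OFF, np.arange(20, dtype=float).reshape(10, 2))
        cells.remove(np.arange(10) % 2 == 0)
        assert np.array_equal(cells.ids, [1, 3, 5, 7, 9])
        assert cells.pos[0, 0] == 2.0
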