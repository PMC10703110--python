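import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emsrank import hypercube as hc
from emsrank.enumeration import Configuration
from emsrank.system_model import Fleet, SystemDescription, generate_synthetic_system

from conftest import make_single_group_system, make_two_atom_system, single_group_config
from _oracles import exact_hypercube_measures


def erlang_b(n: int, a: float) -> float:
    """Closed-form Erlang loss probability, the classic recursion."""
    b = 1.0
    for k in range(1, n + 1):
        b = a * b / (k + a * b)
    return b


def solve_single_group(n, offered_load, queue_capacity=0, policy="no_queue"):
    sys = make_single_group_system(n, offered_load, queue_capacity=queue_capacity)
    cfg = single_group_config(n)
    groups = hc.build_server_groups(cfg, sys)
    pol = hc.make_dispatch_policy(cfg, sys, 0, groups=groups)
    space = hc.build_state_space(groups, queue_capacity, policy)
    struct = hc.build_generator(space, pol, sys)
    sol = hc.solve_steady_state(struct.rate_matrix(np.array([30.0])))
    pm = hc.compute_response_times(
        sol, space, pol, sys, structure=struct, service_times=np.array([30.0])
    )
    return sol, space, pm


class TestGrouping:
    def test_colocated_servers_form_one_group(self, bauru):
        cfg = Configuration(1, {"BSU": (7, 0, 0, 0, 0, 0)})
        groups = hc.build_server_groups(cfg, bauru)
        bsu = [g for g in groups if g.type == "BSU"]
        assert len(bsu) == 1 and bsu[0].size == 7

    def test_one_group_per_occupied_atom(self, bauru):
        cfg = Configuration(1, {"BSU": (2, 1, 1, 1, 1, 1)})
        groups = hc.build_server_groups(cfg, bauru)
        assert [g.size for g in groups if g.type == "BSU"] == [2, 1, 1, 1, 1, 1]

    def test_pinned_dedicated_fleet_included(self, bauru):
        cfg = Configuration(1, {"BSU": (7, 0, 0, 0, 0, 0)})
        groups = hc.build_server_groups(cfg, bauru)
        asu = [g for g in groups if g.dedicated]
        assert len(asu) == 1 and asu[0].size == 2 and asu[0].atom == 0


class TestStateSpace:
    def test_single_group_no_queue(self):
        g = [hc.ServerGroup(0, 0, "BSU", 3, False)]
        assert hc.build_state_space(g, 0, "no_queue").n_states == 4

    def test_two_groups_no_queue(self):
        g = [hc.ServerGroup(0, 0, "BSU", 2, False),
             hc.ServerGroup(1, 1, "BSU", 1, False)]
        assert hc.build_state_space(g, 0, "no_queue").n_states == 6

    def test_queue_state_count_with_dedicated_unit(self):
        # one dedicated server, Q_l = 2: |Q| = 1*2 + C(4,2) - 1 = 7
        g = [hc.ServerGroup(0, 0, "BSU", 2, False),
             hc.ServerGroup(1, 0, "ASU", 1, True)]
        space = hc.build_state_space(g, 2, "queue")
        assert space.n_queue_states == 7
        assert space.n_states == 3 * 2 + 7

    @given(
        st.lists(st.integers(1, 3), min_size=1, max_size=3),
        st.integers(0, 1),
        st.integers(0, 3),
    )
    @settings(deadline=None, max_examples=60)
    def test_counts_match_closed_formulas(self, sizes, n_ded, Q_l):
        """|M| = prod(n_t+1) + |Q| and |Q| = n_ds*Q_l + C(2+Q_l, Q_l) - 1."""
        groups = [hc.ServerGroup(i, i % 2, "BSU", s, False)
                  for i, s in enumerate(sizes)]
        n_ds = 0
        if n_ded:
            n_ds = 2
            groups.append(hc.ServerGroup(len(groups), 0, "ASU", n_ds, True))
        space = hc.build_state_space(groups, Q_l, "queue")
        expected_q = n_ds * Q_l + math.comb(2 + Q_l, Q_l) - 1 if Q_l else 0
        assert space.n_queue_states == expected_q
        assert space.n_states == math.prod(s + 1 for s in sizes) * (n_ds + 1) \
            + expected_q

    def test_state_cap_enforced(self):
        g = [hc.ServerGroup(i, 0, "BSU", 9, False) for i in range(8)]
        with pytest.raises(hc.StateSpaceSizeError):
            hc.build_state_space(g, 5, "queue", state_cap=1000)


class TestDispatchPolicy:
    def test_same_atom_group_ranked_first_for_regular(self, bauru):
        cfg = Configuration(1, {"BSU": (2, 1, 1, 1, 1, 1)})
        groups = hc.build_server_groups(cfg, bauru)
        pol = hc.make_dispatch_policy(cfg, bauru, 0, groups=groups)
        for j in range(6):
            first = pol.groups[pol.preference[(j, "regular")][0]]
            assert first.atom == j and not first.dedicated

    def test_serious_prefers_dedicated_then_local_basic(self, bauru):
        cfg = Configuration(1, {"BSU": (2, 1, 1, 1, 1, 1)})
        pol = hc.make_dispatch_policy(cfg, bauru, 0)
        for j in range(6):
            lst = [pol.groups[t] for t in pol.preference[(j, "serious")]]
            assert lst[0].dedicated
            assert lst[1].atom == j and not lst[1].dedicated

    def test_asu_never_serves_regular_calls(self, bauru):
        cfg = Configuration(1, {"BSU": (2, 1, 1, 1, 1, 1)})
        pol = hc.make_dispatch_policy(cfg, bauru, 0)
        for j in range(6):
            assert all(not pol.groups[t].dedicated
                       for t in pol.preference[(j, "regular")])

    def test_regular_backups_sorted_by_travel_time(self, bauru):
        cfg = Configuration(1, {"BSU": (2, 1, 1, 1, 1, 1)})
        pol = hc.make_dispatch_policy(cfg, bauru, 0)
        for j in range(6):
            backups = [pol.groups[t] for t in pol.preference[(j, "regular")][1:]]
            tts = [bauru.travel_time[g.atom, j] for g in backups]
            assert tts == sorted(tts)

    def test_deterministic_under_seed(self, bauru):
        cfg = Configuration(1, {"BSU": (1, 1, 1, 1, 1, 2)})
        a = hc.make_dispatch_policy(cfg, bauru, 7)
        b = hc.make_dispatch_policy(cfg, bauru, 7)
        assert a.preference == b.preference


class TestSteadyState:
    def test_generator_rows_sum_to_zero(self, bauru):
        cfg = Configuration(1, {"BSU": (2, 1, 1, 1, 1, 1)})
        groups = hc.build_server_groups(cfg, bauru)
        pol = hc.make_dispatch_policy(cfg, bauru, 0, groups=groups)
        space = hc.build_state_space(groups, 3, "queue")
        Q = hc.build_generator(space, pol, bauru).rate_matrix(
            np.array([b := 43.9] * 6 + [55.5])
        )
        np.testing.assert_allclose(np.asarray(Q.sum(axis=1)).ravel(), 0,
                                   atol=1e-12)

    def test_probabilities_normalized(self):
        sol, *_ = solve_single_group(3, 1.5)
        assert sol.p.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(sol.p >= 0)

    def test_mm1_empty_probability(self):
        # lambda/mu = 0.5 with a long queue: P(empty) ~ 1 - rho
        sol, space, pm = solve_single_group(1, 0.5, queue_capacity=60,
                                            policy="queue")
        assert pm.empty_prob == pytest.approx(0.5, abs=1e-6)
        assert pm.workload[0] == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("a", [0.5, 1.0, 2.0])
    def test_erlang_b_blocking(self, n, a):
        _, _, pm = solve_single_group(n, a)
        assert pm.loss_prob == pytest.approx(erlang_b(n, a), abs=1e-10)

    def test_gauss_seidel_agrees_with_direct(self):
        sys = make_two_atom_system()
        cfg = Configuration(1, {"BSU": (1, 1)})
        groups = hc.build_server_groups(cfg, sys)
        pol = hc.make_dispatch_policy(cfg, sys, 0, groups=groups)
        space = hc.build_state_space(groups, 3, "queue")
        Q = hc.build_generator(space, pol, sys).rate_matrix(np.array([30.0, 30.0]))
        direct = hc.solve_steady_state(Q)
        gs = hc.solve_steady_state(Q, direct_limit=0)
        assert gs.method == "gauss_seidel"
        np.testing.assert_allclose(gs.p, direct.p, atol=1e-8)


class TestWorkloads:
    def test_direct_substitution(self):
        # group of 2 with P(0)=0.4, P(1)=0.4, P(2)=0.2 -> rho = 0.4
        g = [hc.ServerGroup(0, 0, "BSU", 2, False)]
        space = hc.build_state_space(g, 0, "no_queue")
        sol = hc.SteadyStateSolution(np.array([0.4, 0.4, 0.2]), 0.0, 1, "given")
        assert hc.compute_workloads(sol, space)[0] == pytest.approx(0.4)

    def test_symmetric_system_equal_workloads(self):
        sys = SystemDescription(
            atoms=("Z1", "Z2"),
            arrival_rate={(0, "regular"): 0.01, (1, "regular"): 0.01},
            travel_time=np.array([[8.0, 12.0], [12.0, 8.0]]),
            service_time={"BSU": 30.0},
            fleets=(Fleet("BSU", 2),),
        )
        cfg = Configuration(1, {"BSU": (1, 1)})
        groups = hc.build_server_groups(cfg, sys)
        pol = hc.make_dispatch_policy(cfg, sys, 0, groups=groups)
        space = hc.build_state_space(groups, 0, "no_queue")
        struct = hc.build_generator(space, pol, sys)
        sol = hc.solve_steady_state(struct.rate_matrix(np.array([30.0, 30.0])))
        rho = hc.compute_workloads(sol, space)
        assert rho[0] == pytest.approx(rho[1], abs=1e-12)


class TestNonPreemption:
    def test_arrivals_never_reduce_busy_counts(self):
        """A high-priority arrival may start service or wait, never displace."""
        sys = make_two_atom_system(with_asu=True)
        cfg = Configuration(1, {"BSU": (1, 1)})
        groups = hc.build_server_groups(cfg, sys)
        pol = hc.make_dispatch_policy(cfg, sys, 0, groups=groups)
        space = hc.build_state_space(groups, 2, "queue")
        struct = hc.build_generator(space, pol, sys)
        for r, c in zip(struct.arr_rows, struct.arr_cols):
            b0, s0, g0 = space.states[r]
            b1, s1, g1 = space.states[c]
            assert all(x1 >= x0 for x0, x1 in zip(b0, b1))
            assert s1 >= s0 and g1 >= g0


class TestAggregationExactness:
    """The aggregated chain must match the exact per-server hypercube."""

    @pytest.mark.parametrize("with_asu,Q_l,policy", [
        (False, 0, "no_queue"),
        (False, 3, "queue"),
        (True, 0, "no_queue"),
        (True, 3, "queue"),
    ])
    def test_two_atom_toys(self, with_asu, Q_l, policy):
        sys = make_two_atom_system(queue_capacity=Q_l, with_asu=with_asu,
                                   util=0.6)
        cfg = Configuration(1, {"BSU": (1, 1)})
        self._compare(sys, cfg, Q_l, policy)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_small_systems(self, seed):
        sys = generate_synthetic_system(3, 3, 1, seed=seed)
        vec = [0, 0, 0]
        rng = np.random.default_rng(seed)
        for _ in range(3):
            vec[rng.integers(3)] += 1
        cfg = Configuration(1, {"BSU": tuple(vec)})
        self._compare(sys, cfg, 2, "queue")

    @staticmethod
    def _compare(sys, cfg, Q_l, policy_kind):
        groups = hc.build_server_groups(cfg, sys)
        pol = hc.make_dispatch_policy(cfg, sys, 5, groups=groups)
        space = hc.build_state_space(groups, Q_l, policy_kind)
        struct = hc.build_generator(space, pol, sys)
        st_times = np.array([sys.service_time[g.type] for g in groups])
        sol = hc.solve_steady_state(struct.rate_matrix(st_times))
        pm = hc.compute_response_times(sol, space, pol, sys, structure=struct,
                                       service_times=st_times)
        rho_x, freq_x, loss_x, empty_x = exact_hypercube_measures(
            space, pol, sys, st_times
        )
        np.testing.assert_allclose(pm.workload, rho_x, atol=1e-8)
        np.testing.assert_allclose(pm.loss_prob_sub, loss_x, atol=1e-8)
        assert pm.empty_prob == pytest.approx(empty_x, abs=1e-8)
        # immediate dispatch frequencies: strip the queue attribution
        imm = np.zeros_like(freq_x)
        for m in range(len(pm.sub_atoms)):
            for t in range(len(groups)):
                imm[t, m] = sol.p[struct.outcome[m] == t].sum()
        np.testing.assert_allclose(imm, freq_x, atol=1e-8)


class TestResponseTimes:
    def test_single_path_travel_component(self, bauru):
        """All calls in atom 1, one basic group there: travel part is the
        intra-atom journey time 8.2."""
        cfg = Configuration(1, {"BSU": (7, 0, 0, 0, 0, 0)})
        rates = {k: (v if k[0] == 0 else 0.0)
                 for k, v in bauru.arrival_rate.items()}
        from dataclasses import replace
        sys = replace(bauru, arrival_rate=rates)
        cal = hc.calibrate(cfg, sys, queue_policy="no_queue", seed=0)
        pm = cal.measures
        onsc = hc.on_scene_times(sys)
        # regular calls from atom 1 can only be served from atom 1
        m = pm.sub_atoms.index((0, "regular"))
        assert pm.response_time_sub[m] == pytest.approx(8.2 + onsc["BSU"],
                                                        abs=1e-9)

    def test_dispatch_frequencies_sum_to_one_minus_loss(self, bauru):
        cfg = Configuration(1, {"BSU": (1, 1, 1, 1, 1, 2)})
        cal = hc.calibrate(cfg, bauru, queue_policy="no_queue", seed=1)
        pm = cal.measures
        np.testing.assert_allclose(
            pm.dispatch_freq.sum(axis=0) + pm.loss_prob_sub, 1.0, atol=1e-10
        )


class TestCalibration:
    def test_constant_travel_matrix_converges_first_pass(self):
        sys = SystemDescription(
            atoms=("Z1", "Z2"),
            arrival_rate={(0, "regular"): 0.01, (1, "regular"): 0.008},
            travel_time=np.full((2, 2), 9.0),
            service_time={"BSU": 40.0},
            fleets=(Fleet("BSU", 2),),
        )
        cfg = Configuration(1, {"BSU": (1, 1)})
        cal = hc.calibrate(cfg, sys, seed=0)
        assert cal.converged and cal.iterations == 1
        np.testing.assert_allclose(cal.service_times, 40.0, atol=1e-9)

    def test_stopping_rule(self, bauru):
        cfg = Configuration(1, {"BSU": (2, 1, 1, 1, 1, 1)})
        tol = 1e-6
        cal = hc.calibrate(cfg, bauru, tol=tol, seed=0)
        assert cal.converged
        # one more solve changes service times by less than tol
        again = hc.calibrate(cfg, bauru, tol=tol, seed=0, max_iter=cal.iterations)
        np.testing.assert_allclose(cal.service_times, again.service_times,
                                   atol=10 * tol)

    def test_rejects_bad_tolerance(self, bauru):
        with pytest.raises(ValueError):
            hc.calibrate(Configuration(1, {"BSU": (7, 0, 0, 0, 0, 0)}), bauru,
                         tol=0.0)
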