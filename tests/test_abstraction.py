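"""Timed-automaton abstraction: sampling, clustering, automaton semantics,
hysteresis preservation, trajectory distances."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from crossscale.abstraction import (
    SamplingReport,
    TransitionSample,
    build_automaton,
    check_hysteresis,
    cluster_states,
    lift_automaton_events,
    sample_transitions,
    simulate_automaton,
    trajectory_distance,
)
from crossscale.models import ReactionModel, Trace, simulate
from crossscale.zoo import make_bistable_switch

from conftest import GRID


def _relax_model(k=0.5):
    """d x/dt = -k (x - u): settles exponentially onto the input level."""
    return ReactionModel(
        "relax", ["x"], [0.0], parameters={"k": k}, inputs={"u": 0.0},
        rates={"x": "-k * (x - u)"}, input_ranges={"u": (0.0, 1.0)},
    )


class TestSampleTransitions:
    def test_deterministic_without_jitter(self):
        m = _relax_model()
        samples = sample_transitions(
            m, "u", [0.0, 1.0], 5, input_jitter_fraction=0.0,
            state_jitter_sd=0.0, seed=1, steady_tol=1e-6,
        )
        up = [s for s in samples if s.nominal_input == 1.0]
        assert len(up) == 5
        times = {round(s.transition_time, 9) for s in up}
        assert len(times) == 1

    def test_settling_time_matches_closed_form(self):
        # x(t) = 1 - e^(-kt); normalized residual k e^(-kt) / x(t) hits tol
        # at t* solving k e^(-kt) = tol (x ~ 1 near the end)
        k, tol = 0.5, 1e-6
        m = _relax_model(k)
        samples = sample_transitions(
            m, "u", [0.0, 1.0], 1, input_jitter_fraction=0.0,
            state_jitter_sd=0.0, seed=0, steady_tol=tol,
        )
        up = [s for s in samples if s.nominal_input == 1.0][0]
        t_star = np.log(k / tol) / k
        assert up.transition_time == pytest.approx(t_star, rel=0.05)

    def test_grid_outside_declared_range_rejected(self):
        with pytest.raises(ValueError, match="outside declared range"):
            sample_transitions(_relax_model(), "u", [0.0, 5.0], 1, seed=0)

    def test_report_counts_requested_traces(self):
        rep = SamplingReport()
        sample_transitions(
            _relax_model(), "u", [0.0, 1.0], 3, seed=0, report=rep
        )
        assert rep.n_requested == rep.n_converged == 6
        assert rep.dropped == []


def _gaussian_samples(rng, centers, n_per, sd):
    samples = []
    per_sample = []
    for li, c in enumerate(centers):
        for _ in range(n_per):
            a = rng.normal(c, sd)
            b = rng.normal(c, sd)
            samples.append(TransitionSample(a, b, 1.0, 1.0, 0.0, 1.0))
            per_sample.append(li)
    # pooled point order is all starts then all ends
    return samples, per_sample + per_sample


class TestClusterStates:
    def test_three_separated_gaussians_recovered(self):
        rng = np.random.default_rng(0)
        centers = [np.zeros(2), np.full(2, 10.0), np.array([0.0, 20.0])]
        samples, labels = _gaussian_samples(rng, centers, 40, sd=1.0)
        states = cluster_states(samples, k_max=6, sd_threshold=0.5, seed=0)
        assert len(states) == 3
        # assignment matches generative labels exactly
        points = np.vstack([s.start_state for s in samples]
                           + [s.end_state for s in samples])
        order = [s.start_state for s in samples] + [s.end_state for s in samples]
        assigned = []
        centroids = np.array([st.centroid for st in states])
        for p in order:
            assigned.append(int(np.argmin(np.linalg.norm(centroids - p, axis=1))))
        assert adjusted_rand_score(labels, assigned) == 1.0

    def test_identical_endpoints_single_state(self):
        p = np.array([1.0, 2.0])
        samples = [TransitionSample(p, p, 1.0, 1.0, 0.0, 1.0) for _ in range(5)]
        states = cluster_states(samples, k_max=4, seed=0)
        assert len(states) == 1
        assert np.allclose(states[0].per_species_sd, 0.0)

    def test_bistable_fixture_yields_two_states(self, bistable_automaton):
        automaton, _ = bistable_automaton
        assert len(automaton.states) == 2

    def test_centroid_equals_member_mean(self, bistable_automaton):
        automaton, _ = bistable_automaton
        for s in automaton.states:
            assert np.allclose(s.centroid, s.members.mean(axis=0))
            assert np.allclose(s.per_species_sd, s.members.std(axis=0))

    def test_partition_invariant_under_sample_order(self):
        rng = np.random.default_rng(4)
        centers = [np.zeros(2), np.full(2, 8.0)]
        samples, _ = _gaussian_samples(rng, centers, 30, sd=0.5)
        states_a = cluster_states(samples, seed=3)
        shuffled = list(samples)
        rng.shuffle(shuffled)
        states_b = cluster_states(shuffled, seed=3)

        def canon(states):
            return sorted(
                tuple(sorted(map(tuple, np.round(s.members, 9)))) for s in states
            )

        assert canon(states_a) == canon(states_b)


class TestBuildAutomaton:
    def test_unsupported_pairs_have_no_edge(self, bistable_automaton):
        automaton, _ = bistable_automaton
        for key, dist in automaton.edges.items():
            assert dist.support_count >= 1

    def test_edge_statistics_recomputable(self, bistable_automaton):
        automaton, _ = bistable_automaton
        for dist in automaton.edges.values():
            assert dist.time_mean == pytest.approx(np.mean(dist.samples))
            assert dist.time_sd == pytest.approx(np.std(dist.samples))
            assert dist.input_mean == pytest.approx(np.mean(dist.input_values))
            assert dist.support_count == len(dist.samples)

    def test_transition_time_decreases_with_input(self, bistable_automaton):
        """Higher growth signal drives the low-to-high switch faster."""
        automaton, _ = bistable_automaton
        hys = check_hysteresis(
            make_bistable_switch(), automaton, "S", (0.5, 1.0)
        )
        lo, hi = hys["low_state"], hys["high_state"]
        t15 = automaton.edges[(lo, hi, 1.5)].time_mean
        t20 = automaton.edges[(lo, hi, 2.0)].time_mean
        assert t20 < t15

    def test_empty_states_rejected(self):
        with pytest.raises(ValueError):
            build_automaton([], [])


class TestSimulateAutomaton:
    def test_absorbing_state_stays_put(self, bistable_automaton):
        automaton, _ = bistable_automaton
        hys = check_hysteresis(make_bistable_switch(), automaton, "S", (0.5, 1.0))
        events = simulate_automaton(
            automaton, hys["high_state"], [(0.0, 2.0)], seed=0, t_end=500.0
        )
        assert events == [(0.0, hys["high_state"])]

    def test_switch_time_resampled_from_edge_distribution(self, bistable_automaton):
        automaton, _ = bistable_automaton
        hys = check_hysteresis(make_bistable_switch(), automaton, "S", (0.5, 1.0))
        lo, hi = hys["low_state"], hys["high_state"]
        dist = automaton.edges[(lo, hi, 2.0)]
        times = []
        for seed in range(2000):
            events = simulate_automaton(automaton, lo, [(0.0, 2.0)], seed=seed,
                                        t_end=1000.0)
            switches = [t for t, s in events[1:] if s == hi]
            assert len(switches) == 1  # exactly one low-to-high event
            times.append(switches[0])
        se = dist.time_sd / np.sqrt(len(times)) + 1e-12
        assert abs(np.mean(times) - dist.time_mean) <= 3 * se + 1e-9

    def test_invalid_start_rejected(self, bistable_automaton):
        automaton, _ = bistable_automaton
        with pytest.raises(ValueError):
            simulate_automaton(automaton, 99, [(0.0, 2.0)], seed=0)


class TestCheckHysteresis:
    def test_preserved_on_default_fixture(self, bistable, bistable_automaton):
        automaton, _ = bistable_automaton
        report = check_hysteresis(bistable, automaton, "S", (0.5, 1.0))
        assert report["preserved"]
        assert report["violating_edges"] == []
        assert report["concrete_high_branch_persists"]

    def test_monostable_model_vacuously_unpreserved(self):
        m = make_bistable_switch(aE=0.0, aR=0.0)
        samples = sample_transitions(m, "S", [0.0, 2.0], 10, seed=2)
        states = cluster_states(samples, seed=2)
        automaton = build_automaton(samples, states, m.species)
        report = check_hysteresis(m, automaton, "S", (0.5, 1.0))
        assert not report["preserved"]

    def test_hysteresis_is_finite_below_window(self, bistable, bistable_automaton):
        """Lowering the input below the bistable window does revert the switch."""
        from crossscale.models import find_steady_state

        automaton, _ = bistable_automaton
        hys = check_hysteresis(bistable, automaton, "S", (0.5, 1.0))
        high = find_steady_state(bistable.with_inputs(S=2.0), tol=1e-7,
                                 t_max=5000).state
        res = find_steady_state(bistable.with_inputs(S=0.1), high, tol=1e-7,
                                t_max=5000)
        assert automaton.state_for(res.state) == hys["low_state"]

    def test_window_outside_grid_rejected(self, bistable, bistable_automaton):
        automaton, _ = bistable_automaton
        with pytest.raises(ValueError, match="outside the sampled"):
            check_hysteresis(bistable, automaton, "S", (-1.0, 5.0))


class TestTrajectoryDistance:
    def test_identical_traces_zero(self, decay_model):
        tr = simulate(decay_model, 10.0)
        assert trajectory_distance(tr, tr) == 0.0

    def test_decay_pair_matches_closed_form(self):
        a = ReactionModel("a", ["x"], [1.0], parameters={"k": 0.5},
                          rates={"x": "-k * x"})
        b = ReactionModel("b", ["x"], [1.0], parameters={"k": 0.505},
                          rates={"x": "-k * x"})
        ta = simulate(a, 10.0, n_points=800)
        tb = simulate(b, 10.0, n_points=800)
        d = trajectory_distance(ta, tb, norm="sup", n_grid=4096)
        grid = np.linspace(0, 10, 200001)
        oracle = np.max(np.abs(np.exp(-0.5 * grid) - np.exp(-0.505 * grid)))
        assert d == pytest.approx(oracle, abs=1e-6)

    def test_pseudometric_on_sampled_triples(self, decay_model):
        rng = np.random.default_rng(7)
        traces = []
        for k in rng.uniform(0.2, 1.0, size=5):
            m = ReactionModel("d", ["x"], [1.0], parameters={"k": float(k)},
                              rates={"x": "-k * x"})
            traces.append(simulate(m, 8.0, n_points=200))
        for norm in ("sup", "L2"):
            for a in traces:
                assert trajectory_distance(a, a, norm=norm) == 0.0
            for a in traces:
                for b in traces:
                    dab = trajectory_distance(a, b, norm=norm)
                    dba = trajectory_distance(b, a, norm=norm)
                    assert dab == pytest.approx(dba, rel=1e-12)
                    for c in traces:
                        dac = trajectory_distance(a, c, norm=norm)
                        dcb = trajectory_distance(c, b, norm=norm)
                        assert dab <= dac + dcb + 1e-12

    def test_disjoint_supports_rejected(self, decay_model):
        tr = simulate(decay_model, 10.0)
        shifted = Trace(times=tr.times + 100.0, states=tr.states,
                        species=tr.species)
        with pytest.raises(ValueError, match="disjoint"):
            trajectory_distance(tr, shifted)

    def test_abstraction_error_bounded_by_cluster_geometry(
        self, bistable, bistable_automaton
    ):
        """Automaton trace vs. concrete trace: the sup distance in E stays
        below the cluster radius plus the inter-state separation (the switch
        transient can misalign by at most one inter-state excursion)."""
        from crossscale.models import find_steady_state

        automaton, _ = bistable_automaton
        hys = check_hysteresis(bistable, automaton, "S", (0.5, 1.0))
        lo, hi = hys["low_state"], hys["high_state"]
        iE = bistable.index("E")
        radius = max(
            np.abs(s.members[:, iE] - s.centroid[iE]).max()
            for s in automaton.states
        )
        separation = abs(
            automaton.states[hi].centroid[iE] - automaton.states[lo].centroid[iE]
        )
        low_state = find_steady_state(bistable.with_inputs(S=0.0), tol=1e-7,
                                      t_max=5000).state
        concrete = simulate(bistable.with_inputs(S=2.0), 120.0,
                            from_state=low_state, n_points=400)
        for seed in range(100):
            events = simulate_automaton(automaton, lo, [(0.0, 2.0)], seed=seed,
                                        t_end=120.0)
            lifted = lift_automaton_events(automaton, events, concrete.times)
            abstract_trace = Trace(times=concrete.times, states=lifted,
                                   species=bistable.species)
            d = trajectory_distance(concrete, abstract_trace,
                                    observables=["E"], norm="sup")
            assert d <= radius + separation + 1e-9
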