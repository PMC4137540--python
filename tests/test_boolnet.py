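"""Asynchronous Boolean networks, checked against brute-force oracles."""

import numpy as np
import pytest

from crossscale.boolnet import (
    HARD_CAP,
    BooleanNetwork,
    async_successors,
    check_safety,
    find_attractors,
    int_to_state,
    make_pathway_network,
    parse_rules,
    reachable,
    state_to_int,
)

TOGGLE = parse_rules("A = !B\nB = !A\n")
RING = parse_rules("A = !C\nB = A\nC = B\n")
CONSTANTS = parse_rules("A = True\nB = False\n")


def _random_network(n, seed):
    """Random AND/OR/NOT update rules over two regulators per node."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n)]
    rules = {}
    for i in range(n):
        a, b = rng.choice(n, size=2, replace=False)
        na = "!" if rng.random() < 0.5 else ""
        nb = "!" if rng.random() < 0.5 else ""
        op = "&" if rng.random() < 0.5 else "|"
        rules[nodes[i]] = f"{na}{nodes[a]} {op} {nb}{nodes[b]}"
    return BooleanNetwork(nodes, rules)


# --- brute-force oracle -----------------------------------------------------


def _oracle_successors(net, code):
    state = int_to_state(code, net.n)
    succ = set()
    for i in range(net.n):
        if net.update_node(state, i) != state[i]:
            succ.add(code ^ (1 << i))
    return succ or {code}


def _oracle_adjacency(net):
    return {c: _oracle_successors(net, c) for c in range(1 << net.n)}


def _tarjan_sccs(adj):
    """Iterative Tarjan over the explicit adjacency map."""
    index, low, on_stack = {}, {}, set()
    stack, sccs, counter = [], [], [0]
    for root in adj:
        if root in index:
            continue
        work = [(root, iter(adj[root]))]
        index[root] = low[root] = counter[0]
        counter[0] += 1
        stack.append(root)
        on_stack.add(root)
        while work:
            v, it = work[-1]
            advanced = False
            for w in it:
                if w not in index:
                    index[w] = low[w] = counter[0]
                    counter[0] += 1
                    stack.append(w)
                    on_stack.add(w)
                    work.append((w, iter(adj[w])))
                    advanced = True
                    break
                if w in on_stack:
                    low[v] = min(low[v], index[w])
            if advanced:
                continue
            work.pop()
            if work:
                low[work[-1][0]] = min(low[work[-1][0]], low[v])
            if low[v] == index[v]:
                comp = set()
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.add(w)
                    if w == v:
                        break
                sccs.append(comp)
    return sccs


def _oracle_attractors(net):
    adj = _oracle_adjacency(net)
    sccs = _tarjan_sccs(adj)
    attractors = []
    for comp in sccs:
        if all(t in comp for c in comp for t in adj[c]):
            attractors.append(frozenset(comp))
    return set(attractors)


# --- tests ------------------------------------------------------------------


class TestAsyncSuccessors:
    def test_toggle_both_updates_applicable(self):
        succ = async_successors(TOGGLE, (True, True))
        assert succ == {(False, True), (True, False)}

    def test_fixed_point_self_loop(self):
        assert async_successors(CONSTANTS, (True, False)) == {(True, False)}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_successors_within_hamming_one(self, seed):
        net = _random_network(6, seed)
        for code in range(1 << net.n):
            s = int_to_state(code, net.n)
            for t in async_successors(net, s):
                assert sum(a != b for a, b in zip(s, t)) <= 1


class TestReachable:
    def test_target_in_init_zero_length_path(self):
        hit, path = reachable(TOGGLE, [(True, True)],
                              lambda s: s == (True, True), bound=0)
        assert hit and path == [(True, True)]

    def test_toggle_one_step_witness(self):
        hit, path = reachable(TOGGLE, [(True, True)],
                              lambda s: s[0] and not s[1])
        assert hit
        assert len(path) == 2
        assert path[-1] == (True, False)

    def test_unreachable_component(self):
        # from the (0,1) fixed point nothing else is reachable
        hit, path = reachable(TOGGLE, [(False, True)],
                              lambda s: s == (True, False))
        assert not hit and path is None

    def test_unbounded_search_capped(self):
        n = HARD_CAP + 1
        nodes = [f"x{i}" for i in range(n)]
        net = BooleanNetwork(nodes, {m: m for m in nodes})
        with pytest.raises(ValueError, match="bound"):
            reachable(net, [tuple([False] * n)], lambda s: any(s))

    @pytest.mark.parametrize("seed", [3, 4])
    def test_reachability_matches_transitive_closure(self, seed):
        net = _random_network(5, seed)
        adj = _oracle_adjacency(net)
        # oracle: BFS closure on the explicit graph
        start = 0
        seen = {start}
        frontier = [start]
        while frontier:
            frontier = [t for c in frontier for t in adj[c] if t not in seen
                        and not seen.add(t)]
        for target_code in range(1 << net.n):
            hit, _ = reachable(
                net, [int_to_state(start, net.n)],
                lambda s, tc=target_code: state_to_int(s) == tc,
            )
            assert hit == (target_code in seen)


class TestAttractors:
    def test_toggle_two_fixed_points(self):
        attractors = find_attractors(TOGGLE)
        assert {a.kind for a in attractors} == {"fixed_point"}
        states = {next(iter(a.states)) for a in attractors}
        assert states == {(False, True), (True, False)}

    def test_negative_feedback_ring_single_cycle(self):
        attractors = find_attractors(RING)
        assert len(attractors) == 1
        assert attractors[0].kind == "cyclic"
        assert len(attractors[0]) > 1

    def test_constants_single_fixed_point(self):
        attractors = find_attractors(CONSTANTS)
        assert len(attractors) == 1
        assert next(iter(attractors[0].states)) == (True, False)

    @pytest.mark.parametrize("net", [TOGGLE, RING, make_pathway_network()]
                             + [_random_network(6, s) for s in range(5)],
                             ids=["toggle", "ring", "pathway", "r0", "r1", "r2",
                                  "r3", "r4"])
    def test_matches_brute_force_oracle(self, net):
        found = {
            frozenset(state_to_int(s) for s in a.states)
            for a in find_attractors(net)
        }
        assert found == _oracle_attractors(net)

    def test_every_state_reaches_an_attractor(self):
        net = make_pathway_network()
        adj = _oracle_adjacency(net)
        attractor_states = set().union(*_oracle_attractors(net))
        # reverse-BFS basin from attractor states must cover the state space
        rev = {c: set() for c in adj}
        for c, ts in adj.items():
            for t in ts:
                rev[t].add(c)
        basin = set(attractor_states)
        frontier = list(basin)
        while frontier:
            frontier = [p for t in frontier for p in rev[t]
                        if p not in basin and not basin.add(p)]
        assert basin == set(adj)

    def test_pathway_fixture_has_oscillatory_attractor(self):
        """The P53-MDM2 negative feedback sustains a cyclic attractor."""
        attractors = find_attractors(make_pathway_network())
        assert any(a.kind == "cyclic" for a in attractors)


class TestSafety:
    def test_trivial_invariant_holds(self):
        safe, cex = check_safety(TOGGLE, [(True, True)], lambda s: True)
        assert safe and cex is None

    def test_toggle_exclusion_invariant(self):
        safe, _ = check_safety(TOGGLE, [(False, True)],
                               lambda s: not (s[0] and s[1]))
        assert safe

    def test_proliferation_off_without_ligand(self):
        net = make_pathway_network()
        i_lig = net.nodes.index("ligand")
        i_prolif = net.nodes.index("proliferation")
        init = tuple(False for _ in net.nodes)
        safe, _ = check_safety(net, [init], lambda s: not s[i_prolif])
        assert safe

    def test_mutated_rules_counterexample_is_valid_path(self):
        """Breaking the cyclin gate exposes proliferation; the counterexample
        must be a legal asynchronous execution."""
        rules = dict(make_pathway_network().update_expressions)
        rules["cyclin"] = "!p21"  # no longer requires ERK signaling
        net = BooleanNetwork(list(rules), rules)
        i_prolif = net.nodes.index("proliferation")
        init = tuple(False for _ in net.nodes)
        safe, cex = check_safety(net, [init], lambda s: not s[i_prolif])
        assert not safe
        assert cex[0] == init and cex[-1][i_prolif]
        for a, b in zip(cex, cex[1:]):
            assert b in async_successors(net, a)


class TestFormats:
    def test_rules_roundtrip(self, tmp_path):
        path = tmp_path / "net.bnet"
        net = make_pathway_network()
        net.save(path)
        again = BooleanNetwork.load(path)
        assert again.nodes == net.nodes
        assert again.update_expressions == net.update_expressions

    def test_json_roundtrip(self, tmp_path):
        path = tmp_path / "net.json"
        TOGGLE.save(path)
        again = BooleanNetwork.load(path)
        assert find_attractors(again) == find_attractors(TOGGLE)

    def test_malformed_rule_rejected(self):
        with pytest.raises(ValueError):
            parse_rules("A = B +\n")
        with pytest.raises(ValueError, match="unknown node"):
            parse_rules("A = missing\n")
        with pytest.raises(ValueError, match="malformed"):
            parse_rules("just text\n")
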