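import networkx as nx
import numpy as np
import pytest

import pollinet as pn

from conftest import brute_force_priority, uniform_mrdpn


def mrdpn_from_edges(edges, timestamp=1):
    g = nx.Graph()
    g.add_edges_from(edges)
    return uniform_mrdpn(g, 0.5, timestamp=timestamp)


def core(members, seed=None):
    members = frozenset(members)
    return pn.CoreSet(members=members, density=1.0, seed=seed or min(members))


class TestPollinationPriority:
    def test_sums_component_ecc(self):
        # pollen p adjacent to core members a, b of a 4-clique core
        edges = [(u, v) for u in "abcd" for v in "abcd" if u < v]
        edges += [("p", "a"), ("p", "b")]
        net = mrdpn_from_edges(edges)
        cs = core("abcd")
        expected = brute_force_priority(net.graph, "p", cs.members)
        assert pn.pollination_priority("p", cs, net) == pytest.approx(expected)
        assert expected > 0

    def test_disconnected_pollen_zero(self):
        net = mrdpn_from_edges([("a", "b"), ("b", "c"), ("p", "q")])
        assert pn.pollination_priority("p", core("abc"), net) == 0.0

    def test_additive_over_core_partition(self):
        edges = [(u, v) for u in "abcdef" for v in "abcdef" if u < v]
        edges += [("p", "a"), ("p", "b"), ("p", "e")]
        net = mrdpn_from_edges(edges)
        whole = pn.pollination_priority("p", core("abcdef"), net)
        part = pn.pollination_priority("p", core("abc"), net) + pn.pollination_priority(
            "p", core("def"), net
        )
        assert whole == pytest.approx(part)


class TestInitializeAndUpdate:
    def setup_net(self):
        edges = [(u, v) for u in "abc" for v in "abc" if u < v]
        edges += [(u, v) for u in "xyz" for v in "xyz" if u < v]
        edges += [("p1", "a"), ("p1", "b"), ("p2", "x"), ("p2", "y"),
                  ("q1", "a"), ("q2", "c")]
        return mrdpn_from_edges(edges), [core("abc"), core("xyz")]

    def test_pollen_is_non_core_set(self):
        net, cores = self.setup_net()
        state = pn.initialize_pollen(cores, net, pn.IFPAConfig(rng_seed=5))
        assert set(state.assignment) == {"p1", "p2", "q1", "q2"}

    def test_same_seed_same_init(self):
        net, cores = self.setup_net()
        s1 = pn.initialize_pollen(cores, net, pn.IFPAConfig(rng_seed=5))
        s2 = pn.initialize_pollen(cores, net, pn.IFPAConfig(rng_seed=5))
        assert s1.assignment == s2.assignment

    def test_single_core_forces_index_zero(self):
        net, _ = self.setup_net()
        state = pn.initialize_pollen([core("abc")], net, pn.IFPAConfig(rng_seed=5))
        assert set(state.assignment.values()) == {0}

    def test_no_cores_empty_state(self):
        net, _ = self.setup_net()
        state = pn.initialize_pollen([], net, pn.IFPAConfig())
        assert state.assignment == {}

    def test_satisfied_pollen_fixed(self):
        net, cores = self.setup_net()
        cfg = pn.IFPAConfig(rng_seed=5)
        state = pn.initialize_pollen(cores, net, cfg)
        # force every pollen onto its best core -> update must be the identity
        for p in state.assignment:
            best = int(np.argmax(state.priority_table[p]))
            state.assignment[p] = best
            state.priority[p] = state.priority_table[p][best]
        satisfied = {p for p in state.assignment if state.priority[p] > cfg.thr}
        before = dict(state.assignment)
        pn.update_positions(state, cores, net, cfg, np.random.default_rng(99))
        for p in satisfied:
            assert state.assignment[p] == before[p]


class TestRunIfpa:
    def test_single_pollen_attaches(self):
        # p1 adjacent to 2 members of the triangle core -> priority > 0.2
        edges = [("a", "b"), ("b", "c"), ("c", "a"), ("p1", "a"), ("p1", "b")]
        net = mrdpn_from_edges(edges)
        out = pn.run_ifpa([core("abc")], net, pn.IFPAConfig(rng_seed=1))
        assert len(out) == 1
        assert out[0].members == frozenset({"a", "b", "c", "p1"})
        assert out[0].attachments == frozenset({"p1"})

    def test_no_pollen_returns_cores(self):
        edges = [("a", "b"), ("b", "c"), ("c", "a")]
        net = mrdpn_from_edges(edges)
        out = pn.run_ifpa([core("abc")], net, pn.IFPAConfig(rng_seed=1))
        assert out[0].members == frozenset("abc")
        assert out[0].attachments == frozenset()

    def test_unattachable_pollen_discarded(self):
        edges = [("a", "b"), ("b", "c"), ("c", "a"), ("p", "a")]
        net = mrdpn_from_edges(edges)
        out = pn.run_ifpa([core("abc")], net, pn.IFPAConfig(rng_seed=1, max_iter=20))
        # p touches one core member only: priority 0 -> discarded
        assert all("p" not in c.members for c in out)

    def test_attachments_respect_threshold(self, noiseless_mrdpns):
        cfg = pn.IFPAConfig(rng_seed=3, max_iter=200)
        for net in noiseless_mrdpns:
            cores = pn.find_cores(net, pn.MiningConfig())
            for c in pn.run_ifpa(cores, net, cfg):
                for p in c.attachments:
                    assert pn.pollination_priority(p, c.core, net) > cfg.thr

    def test_deterministic_given_seed(self, noiseless_mrdpns):
        cfg = pn.IFPAConfig(rng_seed=17)
        for net in noiseless_mrdpns[:4]:
            cores = pn.find_cores(net, pn.MiningConfig())
            assert pn.run_ifpa(cores, net, cfg) == pn.run_ifpa(cores, net, cfg)


class TestMergeAndFilter:
    def make(self, members, t=1):
        return pn.PredictedComplex(core=frozenset(members), attachments=frozenset(), source_timestamp=t)

    def test_exact_duplicates_collapse(self):
        cat = pn.merge_and_filter(
            [[self.make("abc", 1)], [self.make("abc", 2)]], pn.IFPAConfig()
        )
        assert len(cat) == 1

    def test_overlap_threshold_boundary(self):
        # OS({a,b,c,d},{a,b,c}) = 9/12 = 0.75
        big, small = self.make("abcd"), self.make("abc")
        keep_both = pn.merge_and_filter([[big, small]], pn.IFPAConfig(overlap_filter=0.8))
        assert keep_both.member_sets() == {frozenset("abcd"), frozenset("abc")}
        keep_one = pn.merge_and_filter([[big, small]], pn.IFPAConfig(overlap_filter=0.7))
        assert keep_one.member_sets() == {frozenset("abcd")}

    def test_disjoint_always_kept(self):
        cs = [self.make(m) for m in ("ab", "cd", "ef")]
        cat = pn.merge_and_filter([cs], pn.IFPAConfig(overlap_filter=0.2))
        assert len(cat) == 3

    def test_pairwise_os_below_filter(self, noiseless_mrdpns):
        cfg = pn.IFPAConfig(rng_seed=3)
        per_t = [pn.run_ifpa(pn.find_cores(n, pn.MiningConfig()), n, cfg) for n in noiseless_mrdpns]
        cat = pn.merge_and_filter(per_t, cfg)
        for i, a in enumerate(cat.complexes):
            for b in cat.complexes[i + 1:]:
                assert pn.overlapping_score(a, b) < cfg.overlap_filter


class TestOracleEquivalence:
    """Exhaustive-search oracle on small random instances."""

    @staticmethod
    def random_instance(seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 31))
        g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(0, 2**31)))
        g = nx.relabel_nodes(g, {i: f"P{i:02d}" for i in g.nodes})
        nodes = sorted(g.nodes)
        n_cores = int(rng.integers(1, 5))
        cores, used = [], set()
        for _ in range(n_cores):
            avail = [v for v in nodes if v not in used]
            if len(avail) < 2:
                break
            size = int(rng.integers(2, min(5, len(avail)) + 1))
            members = frozenset(str(v) for v in rng.choice(avail, size=size, replace=False))
            used |= members
            cores.append(pn.CoreSet(members=members, density=1.0, seed=min(members)))
        return uniform_mrdpn(g, 0.5), cores

    @pytest.mark.parametrize("seed", range(25))
    def test_attached_set_matches_exhaustive_search(self, seed):
        net, cores = self.random_instance(seed)
        cfg = pn.IFPAConfig(rng_seed=seed, max_iter=500)
        out = pn.run_ifpa(cores, net, cfg)
        attached = set().union(*(c.attachments for c in out)) if out else set()
        pollen = set(net.graph.nodes) - set().union(*(c.members for c in cores))
        expected = {
            p for p in pollen
            if max(brute_force_priority(net.graph, p, c.members) for c in cores) > cfg.thr
        }
        assert attached == expected
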