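from itertools import combinations, product

import networkx as nx
import numpy as np
import pytest

from balsel import ld_hap
from balsel.popgen_core import HaplotypeMatrix


def _dprime_oracle(a, b):
    """Exhaustive 2x2 contingency-table computation, coded independently."""
    n = len(a)
    n11 = sum(1 for x, y in zip(a, b) if x == 1 and y == 1)
    pA = sum(a) / n
    pB = sum(b) / n
    D = n11 / n - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dp = abs(D) / dmax if dmax else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return D, dp, r2


class TestDprime:
    def test_perfect_ld_hand_count(self):
        a = np.array([1] * 5 + [0] * 5)
        pr = ld_hap.dprime(a, a.copy())
        assert pr.D == pytest.approx(0.25)
        assert pr.Dprime == pytest.approx(1.0)
        assert pr.r2 == pytest.approx(1.0)

    def test_independent_sites_zero(self):
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 0, 1, 0])
        pr = ld_hap.dprime(a, b)
        assert pr.D == pytest.approx(0.0)
        assert pr.Dprime == pytest.approx(0.0)

    def test_matches_contingency_oracle_on_random_pairs(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            a = rng.integers(0, 2, size=n)
            b = rng.integers(0, 2, size=n)
            if a.sum() in (0, n) or b.sum() in (0, n):
                continue
            pr = ld_hap.dprime(a, b)
            D, dp, r2 = _dprime_oracle(a, b)
            assert pr.D == pytest.approx(D, abs=1e-12)
            assert pr.Dprime == pytest.approx(dp, abs=1e-12)
            assert pr.r2 == pytest.approx(r2, abs=1e-12)

    def test_monomorphic_is_error(self):
        with pytest.raises(ValueError):
            ld_hap.dprime(np.ones(4, dtype=int), np.array([1, 0, 1, 0]))


class TestDprimeCI:
    def test_perfect_ld_large_sample_concentrates(self):
        a = np.array([1] * 50 + [0] * 50)
        lo, hi = ld_hap.dprime_ci(a, a.copy())
        assert lo > 0.9

    def test_point_estimate_inside_interval(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 60))
            a = rng.integers(0, 2, size=n)
            b = rng.integers(0, 2, size=n)
            if a.sum() in (0, n) or b.sum() in (0, n):
                continue
            pr = ld_hap.dprime(a, b)
            lo, hi = ld_hap.dprime_ci(a, b)
            assert lo - 1e-9 <= pr.Dprime <= hi + 1e-9

    def test_grid_refinement_stable(self, rng):
        a = rng.integers(0, 2, size=40)
        b = (a ^ (rng.random(40) < 0.2)).astype(int)
        lo1, hi1 = ld_hap.dprime_ci(a, b, grid=1001)
        lo2, hi2 = ld_hap.dprime_ci(a, b, grid=501)
        assert abs(lo1 - lo2) < 0.01 and abs(hi1 - hi2) < 0.01


def _blocks_oracle(pairs, n_sites, cfg):
    """All-intervals check + greedy longest-first, written independently."""
    klass = {}
    for _, r in pairs.iterrows():
        klass[(int(r["i"]), int(r["j"]))] = r["klass"]
    ok = []
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            sub = [
                klass.get((x, y))
                for x, y in combinations(range(i, j + 1), 2)
            ]
            inf = [k for k in sub if k in ("strong", "recomb")]
            if not inf:
                continue
            if sum(k == "strong" for k in inf) / len(inf) >= cfg.frac_strong:
                ok.append((i, j))
    ok.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
    chosen = []
    for i, j in ok:
        if all(j < a or i > b for a, b in chosen):
            chosen.append((i, j))
    return sorted(chosen)


def _hapmatrix_from_strings(strings, span=2000, rng=None):
    m = np.array([[int(c) for c in s] for s in strings], dtype=np.uint8)
    pos = np.arange(m.shape[1]) * (span // max(1, m.shape[1]))
    return HaplotypeMatrix(m, pos)


class TestGabrielBlocks:
    def test_perfect_ld_single_block(self):
        # 100 haplotypes, 6 sites all in complete LD at frequency 0.5
        h1 = "111111"
        h0 = "000000"
        H = _hapmatrix_from_strings([h1] * 50 + [h0] * 50)
        pairs = ld_hap.ld_pairs(H)
        assert (pairs["klass"] == "strong").all()
        blocks = ld_hap.gabriel_blocks(pairs, 6)
        assert blocks == [(0, 5)]

    def test_all_recombination_no_blocks(self, rng):
        # independent sites at moderate n: CIs wide of 0 -> classify by hand
        import pandas as pd

        rows = []
        for i, j in combinations(range(5), 2):
            rows.append({"i": i, "j": j, "klass": "recomb"})
        pairs = pd.DataFrame(rows)
        assert ld_hap.gabriel_blocks(pairs, 5) == []

    def test_matches_all_intervals_oracle_on_mixed_case(self, rng):
        cfg = ld_hap.LDBlockConfig()
        # two tight blocks separated by a shuffled middle
        core = np.array([1] * 30 + [0] * 30)
        cols = []
        for _ in range(8):
            cols.append(core.copy())
        mid = core.copy()
        rng.shuffle(mid)
        cols.insert(4, mid)
        m = np.stack(cols, axis=1).astype(np.uint8)
        H = HaplotypeMatrix(m, np.arange(m.shape[1]) * 100)
        pairs = ld_hap.ld_pairs(H, cfg)
        got = ld_hap.gabriel_blocks(pairs, m.shape[1], cfg)
        want = _blocks_oracle(pairs, m.shape[1], cfg)
        assert got == want

    def test_relabelling_invariance(self, rng):
        """Swapping 0/1 at every site leaves the block structure unchanged."""
        core = np.array([1] * 25 + [0] * 25)
        noise = (rng.random((50, 6)) < 0.08).astype(np.uint8)
        m = (np.stack([core] * 6, axis=1) ^ noise).astype(np.uint8)
        H1 = HaplotypeMatrix(m, np.arange(6) * 50)
        H2 = HaplotypeMatrix(1 - m, np.arange(6) * 50)
        cfg = ld_hap.LDBlockConfig(maf_min=0.0)
        b1 = ld_hap.gabriel_blocks(ld_hap.ld_pairs(H1, cfg), 6, cfg)
        b2 = ld_hap.gabriel_blocks(ld_hap.ld_pairs(H2, cfg), 6, cfg)
        assert b1 == b2

    def test_fewer_than_two_sites_empty(self):
        import pandas as pd

        assert ld_hap.gabriel_blocks(pd.DataFrame(), 1) == []


def _steiner_oracle(seqs):
    """Minimum total MST length over all subsets of added binary vectors."""
    L = len(seqs[0])
    universe = ["".join(bits) for bits in product("01", repeat=L)]
    extra = [u for u in universe if u not in seqs]

    def mst_len(nodes):
        G = nx.Graph()
        G.add_nodes_from(range(len(nodes)))
        for i, j in combinations(range(len(nodes)), 2):
            w = sum(a != b for a, b in zip(nodes[i], nodes[j]))
            G.add_edge(i, j, weight=w)
        return sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(G, data=True))

    best_len = mst_len(list(seqs))
    best_sets = [frozenset()]
    for r in range(1, 3):
        for add in combinations(extra, r):
            ln = mst_len(list(seqs) + list(add))
            if ln < best_len:
                best_len, best_sets = ln, [frozenset(add)]
            elif ln == best_len:
                best_sets.append(frozenset(add))
    return best_len, best_sets


class TestMedianJoiningNetwork:
    def test_identical_haplotypes_single_node(self):
        net = ld_hap.median_joining_network(["0101"] * 7)
        assert len(net.nodes) == 1 and net.nodes[0][1] == 7
        assert net.edges == []

    def test_two_haplotypes_one_edge(self):
        net = ld_hap.median_joining_network(["0000", "0011"])
        assert len(net.nodes) == 2
        assert [e[2] for e in net.edges] == [2]

    def test_three_haplotype_median_inserted(self):
        net = ld_hap.median_joining_network(["000", "011", "101"])
        seqs = [s for s, _ in net.nodes]
        assert "001" in seqs  # the majority-consensus Steiner point
        inferred = [s for s, f in net.nodes if f == 0]
        assert inferred == ["001"]
        # star topology: three unit edges to the median
        assert sorted(e[2] for e in net.edges) == [1, 1, 1]

    def test_matches_steiner_enumeration_on_small_cases(self, rng):
        cases = [
            ["000", "011", "101"],
            ["0000", "1100", "0011", "1111"],
            ["0000", "1110", "0111"],
        ]
        for seqs in cases:
            net = ld_hap.median_joining_network(seqs)
            G = net.graph()
            mst = sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(G, data=True))
            best_len, best_sets = _steiner_oracle(seqs)
            assert mst == best_len
            added = frozenset(s for s, f in net.nodes if f == 0)
            assert added in best_sets

    def test_contains_every_mst_edge(self, rng):
        seqs = ["".join(map(str, rng.integers(0, 2, size=8))) for _ in range(10)]
        net = ld_hap.median_joining_network(seqs)
        G = net.graph()
        edge_set = {frozenset((a, b)) for a, b, _ in net.edges}
        mst = nx.minimum_spanning_tree(G, weight="weight")
        assert all(frozenset((u, v)) in edge_set for u, v in mst.edges())

    def test_observed_frequencies_conserved(self, rng):
        seqs = ["0011", "0011", "1100", "0000", "0000", "0000"]
        net = ld_hap.median_joining_network(seqs)
        assert net.sample_size == 6
        freq = {s: f for s, f in net.nodes}
        assert freq["0000"] == 3 and freq["0011"] == 2 and freq["1100"] == 1

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            ld_hap.median_joining_network(["01", "011"])


class TestTwoGroupSeparation:
    def test_single_node_undefined(self):
        net = ld_hap.HapNetwork(nodes=[("00", 5)], edges=[])
        assert not ld_hap.two_group_separation(net).defined

    def test_star_network_unit_bridge(self):
        net = ld_hap.HapNetwork(
            nodes=[("000", 3), ("001", 2), ("010", 1), ("100", 1)],
            edges=[(0, 1, 1), (0, 2, 1), (0, 3, 1)],
        )
        assert ld_hap.two_group_separation(net).bridge_weight == 1

    def test_two_clusters_bridge_weight(self):
        # two tight clusters of observed haplotypes 10 mutations apart
        a = "0" * 12
        b = "1" * 10 + "00"
        a2 = "1" + "0" * 11
        b2 = "01" + "1" * 8 + "00"
        net = ld_hap.median_joining_network([a, a, a2, b, b, b2])
        summ = ld_hap.two_group_separation(net)
        assert summ.defined and summ.bridge_weight >= 8
        assert {summ.group_a_count, summ.group_b_count} == {3}

    def test_balanced_simulation_recovers_class_labels(self, rng):
        """Cutting the heaviest backbone edge recovers the two allelic
        classes on most balanced-model replicates."""
        from balsel.synthetic_data import SimParams, simulate_balanced_locus

        p = SimParams(
            n_hap=24, locus_len=3000, theta_bp=0.004, model="balanced",
            f_eq=0.5, t_balance=8.0, m_switch=0.01,
        )
        hits = trials = 0
        while trials < 40:
            loc = simulate_balanced_locus(p, rng)
            lab = loc.class_labels
            if lab.sum() in (0, len(lab)) or loc.haplotypes.n_sites < 4:
                continue
            trials += 1
            seqs = ["".join(map(str, row)) for row in loc.haplotypes.matrix]
            net = ld_hap.median_joining_network(seqs)
            summ = ld_hap.two_group_separation(net)
            if not summ.defined:
                continue
            side = {s for i in summ.group_a_nodes for s, f in [net.nodes[i]] if f > 0}
            pred = np.array([seqs[i] in side for i in range(len(seqs))])
            agree = max(np.mean(pred == (lab == 1)), np.mean(pred == (lab == 0)))
            # allow one haplotype per replicate whose class switched since
            # its lineage crossed sides (a genuine feature of the model)
            if agree >= 1.0 - 1.5 / len(seqs):
                hits += 1
        assert hits / trials >= 0.9
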