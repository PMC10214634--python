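"""Pairwise D', Gabriel-style haplotype blocks and median-joining networks.

D' is the coefficient of linkage disequilibrium normalised by its maximum
attainable value given the allele frequencies, estimated by direct haplotype
counting on phased data. Confidence bounds on D' come from the multinomial
likelihood of the observed two-site haplotype counts evaluated on a D' grid
at fixed allele-frequency margins, normalised to a weight distribution whose
5th and 95th percentiles bound the estimate. Blocks follow the
confidence-interval classification of Gabriel et al.: pairs are "strong LD"
when the lower bound clears 0.70 and the upper bound clears 0.98, "strong
recombination" when the upper bound falls below 0.90, and a run of SNPs is a
block when at least 95% of its informative pairs are strong LD.

Haplotype networks use the Bandelt median-joining construction with
epsilon = 0: the minimum-spanning network (the union of all minimum spanning
trees) is augmented with majority-consensus median vectors of triplets
whenever doing so shortens the network, iterated to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "LDPair",
    "LDBlockConfig",
    "HapNetwork",
    "dprime",
    "dprime_ci",
    "ld_pairs",
    "gabriel_blocks",
    "median_joining_network",
    "two_group_separation",
]


@dataclass
class LDPair:
    site_a: int
    site_b: int
    D: float
    Dprime: float
    r2: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass(frozen=True)
class LDBlockConfig:
    strong_low: float = 0.70
    strong_high: float = 0.98
    recomb_high: float = 0.90
    frac_strong: float = 0.95
    maf_min: float = 0.15


def _freqs(hapA: np.ndarray, hapB: np.ndarray):
    hapA = np.asarray(hapA, dtype=np.int8)
    hapB = np.asarray(hapB, dtype=np.int8)
    if hapA.shape != hapB.shape:
        raise ValueError("sites must have the same haplotype count")
    n = len(hapA)
    pA = hapA.mean()
    pB = hapB.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic site passed to LD computation")
    pAB = np.mean((hapA == 1) & (hapB == 1))
    return n, pA, pB, pAB


def dprime(hapA, hapB, pos_a: int = 0, pos_b: int = 0) -> LDPair:
    """D, D' and r^2 between two phased biallelic sites by direct counting."""
    n, pA, pB, pAB = _freqs(hapA, hapB)
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dp = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDPair(site_a=pos_a, site_b=pos_b, D=float(D), Dprime=float(dp), r2=float(r2))


def dprime_ci(hapA, hapB, grid: int = 1001) -> tuple[float, float]:
    """Likelihood-weighted confidence bounds on D'.

    The two-site haplotype counts are multinomial with cell probabilities
    determined by the margins and D = sign(D_hat) * D' * D_max; the
    likelihood on a D' grid in [0, 1], normalised to unit mass, yields the
    5th/95th percentile bounds. Deterministic; resolution-stable by
    construction of the grid.
    """
    n, pA, pB, pAB = _freqs(hapA, hapB)
    hapA = np.asarray(hapA, dtype=np.int8)
    hapB = np.asarray(hapB, dtype=np.int8)
    n11 = int(np.sum((hapA == 1) & (hapB == 1)))
    n10 = int(np.sum((hapA == 1) & (hapB == 0)))
    n01 = int(np.sum((hapA == 0) & (hapB == 1)))
    n00 = n - n11 - n10 - n01
    D_hat = pAB - pA * pB
    sign = 1.0 if D_hat >= 0 else -1.0
    if sign > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax <= 0:
        raise ValueError("degenerate margins")
    dp_grid = np.linspace(0.0, 1.0, grid)
    D_grid = sign * dp_grid * dmax
    eps = 1e-12
    p11 = np.clip(pA * pB + D_grid, eps, 1.0)
    p10 = np.clip(pA * (1 - pB) - D_grid, eps, 1.0)
    p01 = np.clip((1 - pA) * pB - D_grid, eps, 1.0)
    p00 = np.clip((1 - pA) * (1 - pB) + D_grid, eps, 1.0)
    logL = (
        n11 * np.log(p11) + n10 * np.log(p10) + n01 * np.log(p01) + n00 * np.log(p00)
    )
    w = np.exp(logL - logL.max())
    w /= w.sum()
    cum = np.cumsum(w)
    lo = float(dp_grid[np.searchsorted(cum, 0.05)])
    hi = float(dp_grid[np.searchsorted(cum, 0.95)])
    # the interval always contains the point estimate, by construction
    point = abs(D_hat) / dmax
    return min(lo, point), max(hi, point)


def ld_pairs(H, cfg: LDBlockConfig = LDBlockConfig(), grid: int = 1001) -> pd.DataFrame:
    """All pairwise D' results with CIs over the MAF-filtered sites of a matrix.

    ``H`` is a HaplotypeMatrix; rows carry the retained site indices and
    positions plus a Gabriel classification column.
    """
    n = H.n_hap
    counts = H.alt_counts()
    folded = np.minimum(counts, n - counts) / n
    keep = (counts > 0) & (counts < n) & (folded >= cfg.maf_min - 1e-12)
    idx = np.where(keep)[0]
    rows = []
    for a, b in combinations(range(len(idx)), 2):
        ia, ib = idx[a], idx[b]
        pr = dprime(H.matrix[:, ia], H.matrix[:, ib], H.positions[ia], H.positions[ib])
        lo, hi = dprime_ci(H.matrix[:, ia], H.matrix[:, ib], grid=grid)
        rows.append(
            {
                "i": a,
                "j": b,
                "pos_a": int(H.positions[ia]),
                "pos_b": int(H.positions[ib]),
                "D": pr.D,
                "Dprime": pr.Dprime,
                "r2": pr.r2,
                "ci_low": lo,
                "ci_high": hi,
                "klass": classify_pair(lo, hi, cfg),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["i", "j", "pos_a", "pos_b", "D", "Dprime", "r2", "ci_low", "ci_high", "klass"],
    )


def classify_pair(ci_low: float, ci_high: float, cfg: LDBlockConfig) -> str:
    if ci_low >= cfg.strong_low and ci_high >= cfg.strong_high:
        return "strong"
    if ci_high < cfg.recomb_high:
        return "recomb"
    return "intermediate"


def gabriel_blocks(pairs: pd.DataFrame, n_sites: int, cfg: LDBlockConfig = LDBlockConfig()) -> list[tuple[int, int]]:
    """Haplotype blocks from classified pairs.

    A candidate block [i, j] (site indices, inclusive) qualifies when among
    its informative pairs (strong LD or strong recombination; intermediate
    pairs are uninformative) at least ``frac_strong`` are strong LD and at
    least one informative pair exists. Qualifying intervals are accepted
    greedily, longest first (leftmost on ties), without overlap.
    """
    if n_sites < 2:
        return []
    strong = np.zeros((n_sites, n_sites), dtype=bool)
    informative = np.zeros((n_sites, n_sites), dtype=bool)
    for _, r in pairs.iterrows():
        i, j = int(r["i"]), int(r["j"])
        if r["klass"] == "strong":
            strong[i, j] = informative[i, j] = True
        elif r["klass"] == "recomb":
            informative[i, j] = True
    candidates = []
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            sub_inf = informative[i:j + 1, i:j + 1].sum()
            if sub_inf == 0:
                continue
            sub_strong = strong[i:j + 1, i:j + 1].sum()
            if sub_strong / sub_inf >= cfg.frac_strong:
                candidates.append((i, j))
    candidates.sort(key=lambda ij: (-(ij[1] - ij[0]), ij[0]))
    chosen: list[tuple[int, int]] = []
    for i, j in candidates:
        if all(j < ci or i > cj for ci, cj in chosen):
            chosen.append((i, j))
    return sorted(chosen)


@dataclass
class HapNetwork:
    """Nodes are (sequence, observed frequency); inferred medians have freq 0.

    Edges are (node_index_a, node_index_b, hamming_weight).
    """

    nodes: list[tuple[str, int]] = field(default_factory=list)
    edges: list[tuple[int, int, int]] = field(default_factory=list)

    def graph(self) -> nx.Graph:
        G = nx.Graph()
        for i, (seq, f) in enumerate(self.nodes):
            G.add_node(i, sequence=seq, frequency=f)
        for a, b, w in self.edges:
            G.add_edge(a, b, weight=w)
        return G

    @property
    def sample_size(self) -> int:
        return sum(f for _, f in self.nodes)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(seqs: list[str]) -> list[tuple[int, int, int]]:
    """Minimum-spanning network: union of all minimum spanning trees.

    Kruskal by distance rank; an edge at distance d joins the network iff its
    endpoints are not already connected using edges of distance < d.
    """
    m = len(seqs)
    if m == 1:
        return []
    dist = {}
    for i, j in combinations(range(m), 2):
        dist[(i, j)] = _hamming(seqs[i], seqs[j])
    edges = []
    uf = list(range(m))

    def find(x):
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    for d in sorted(set(dist.values())):
        tier = [(i, j) for (i, j), dd in dist.items() if dd == d]
        admitted = [(i, j) for i, j in tier if find(i) != find(j)]
        for i, j in admitted:
            edges.append((i, j, d))
        for i, j in admitted:
            uf[find(i)] = find(j)
    return edges


def _mst_length(seqs: list[str]) -> int:
    G = nx.Graph()
    G.add_nodes_from(range(len(seqs)))
    for i, j in combinations(range(len(seqs)), 2):
        G.add_edge(i, j, weight=_hamming(seqs[i], seqs[j]))
    if len(seqs) < 2:
        return 0
    return int(sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(G, data=True)))


def _median(a: str, b: str, c: str) -> str:
    out = []
    for x, y, z in zip(a, b, c):
        ones = (x == "1") + (y == "1") + (z == "1")
        out.append("1" if ones >= 2 else "0")
    return "".join(out)


def median_joining_network(
    haplotypes: Sequence[str],
    counts: Optional[Sequence[int]] = None,
    epsilon: int = 0,
) -> HapNetwork:
    """Median-joining network of binary haplotype strings (epsilon = 0).

    Each round builds the minimum-spanning network of the current node set,
    forms the per-column majority median of every feasible triplet (two of
    its three pairs linked in the network) and inserts the median that most
    reduces the minimum-spanning-tree length, repeating until no median
    shortens the network. Inferred nodes that end up peripheral (degree <= 1)
    are deleted. Observed haplotype frequencies are conserved.
    """
    if epsilon != 0:
        raise NotImplementedError("only epsilon = 0 is supported")
    haplotypes = list(haplotypes)
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    L = {len(h) for h in haplotypes}
    if len(L) != 1:
        raise ValueError("haplotypes must have equal length")
    if counts is None:
        counts = [1] * len(haplotypes)
    freq: dict[str, int] = {}
    for h, c in zip(haplotypes, counts):
        freq[h] = freq.get(h, 0) + int(c)
    observed = sorted(freq)
    seqs = list(observed)

    while True:
        edges = _msn_edges(seqs)
        adj: dict[int, set[int]] = {i: set() for i in range(len(seqs))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        base = _mst_length(seqs)
        existing = set(seqs)
        candidates = set()
        for v, nbrs in adj.items():
            for a, b in combinations(sorted(nbrs), 2):
                med = _median(seqs[a], seqs[v], seqs[b])
                if med not in existing:
                    candidates.add(med)
        best, best_len = None, base
        for med in sorted(candidates):
            ln = _mst_length(seqs + [med])
            if ln < best_len:  # strict: lexicographically first on ties
                best, best_len = med, ln
        if best is None:
            break
        seqs.append(best)

    # prune peripheral inferred vectors
    while True:
        edges = _msn_edges(seqs)
        deg = {i: 0 for i in range(len(seqs))}
        for i, j, _ in edges:
            deg[i] += 1
            deg[j] += 1
        drop = [
            i
            for i in range(len(seqs))
            if seqs[i] not in freq and deg.get(i, 0) <= 1
        ]
        if not drop:
            break
        seqs = [s for i, s in enumerate(seqs) if i not in set(drop)]

    edges = _msn_edges(seqs)
    nodes = [(s, freq.get(s, 0)) for s in seqs]
    return HapNetwork(nodes=nodes, edges=sorted(edges))


@dataclass
class TwoGroupSummary:
    defined: bool
    bridge_weight: int = 0
    group_a_count: int = 0
    group_b_count: int = 0
    group_a_nodes: list[int] = field(default_factory=list)
    group_b_nodes: list[int] = field(default_factory=list)


def two_group_separation(network: HapNetwork) -> TwoGroupSummary:
    """Largest-weight bridge on the network's minimum spanning backbone.

    Cuts the backbone at its heaviest edge and reports the observed-frequency
    totals on either side — a descriptive statistic of two-group structure,
    not a test. Undefined for single-node networks.
    """
    observed = [i for i, (_, f) in enumerate(network.nodes) if f > 0]
    if len(observed) < 2:
        return TwoGroupSummary(defined=False)
    G = network.graph()
    T = nx.minimum_spanning_tree(G, weight="weight")
    u, v, data = max(T.edges(data=True), key=lambda e: (e[2]["weight"], e[0], e[1]))
    T.remove_edge(u, v)
    comps = list(nx.connected_components(T))
    side_a = comps[0] if u in comps[0] else comps[1]
    side_b = comps[1] if u in comps[0] else comps[0]
    fa = sum(network.nodes[i][1] for i in side_a)
    fb = sum(network.nodes[i][1] for i in side_b)
    return TwoGroupSummary(
        defined=True,
        bridge_weight=int(data["weight"]),
        group_a_count=fa,
        group_b_count=fb,
        group_a_nodes=sorted(side_a),
        group_b_nodes=sorted(side_b),
    )
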