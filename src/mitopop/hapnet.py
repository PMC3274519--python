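"""Median-joining haplotype networks.

Builds the Bandelt-Forster-Roehl network: an epsilon-relaxed minimum
spanning network over observed haplotypes, iteratively augmented with
quasi-median (consensus) vectors that reduce connection cost, then
optionally cleaned to the links lying on minimum-cost spanning subgraphs
(maximum-parsimony pruning). Distances weight transversions more heavily
than transitions (default 5:1), reflecting their rarity in mitochondrial
data. All tie-breaks are lexicographic so output is deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .alignment_io import (
    HaplotypeTable,
    UNAMBIGUOUS,
    is_transition,
)

logger = logging.getLogger(__name__)


@dataclass
class NetworkConfig:
    weight_transversion: int = 5
    weight_transition: int = 1
    epsilon: int = 0
    mp_prune: bool = True
    max_iter: int = 50
    median_cap_factor: int = 10

    def __post_init__(self) -> None:
        if self.weight_transversion < 1 or self.weight_transition < 1:
            raise ValueError("substitution-class weights must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


# network coding: A=0 C=1 G=2 T=3, gap/ambiguity=4 (weightless)
_NET_CODE = {c: i for i, c in enumerate("ACGT")}


def _net_encode(seq: str) -> np.ndarray:
    return np.array([_NET_CODE.get(c, 4) for c in seq], dtype=np.uint8)


def _weight_matrix(cfg: NetworkConfig) -> np.ndarray:
    W = np.zeros((5, 5), dtype=np.int64)
    for a in range(4):
        for b in range(4):
            if a == b:
                continue
            transition = {a, b} in ({0, 2}, {1, 3})
            W[a, b] = cfg.weight_transition if transition else cfg.weight_transversion
    return W


def site_weight(a: str, b: str, cfg: NetworkConfig) -> int:
    if a == b:
        return 0
    if a not in UNAMBIGUOUS or b not in UNAMBIGUOUS:
        return 0  # gaps/ambiguity carry no network signal
    return cfg.weight_transition if is_transition(a, b) else cfg.weight_transversion


def weighted_distance(seq_a: str, seq_b: str, cfg: NetworkConfig | None = None) -> int:
    """Sum of per-site class weights over differing sites."""
    if cfg is None:
        cfg = NetworkConfig()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    W = _weight_matrix(cfg)
    return int(W[_net_encode(seq_a.upper()), _net_encode(seq_b.upper())].sum())


def _pair_classes(seq_a: str, seq_b: str) -> tuple[int, int]:
    """(transitions, transversions) over differing unambiguous sites."""
    ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a != b and a in UNAMBIGUOUS and b in UNAMBIGUOUS:
            if is_transition(a, b):
                ts += 1
            else:
                tv += 1
    return ts, tv


def variable_positions(seqs: list[str]) -> list[int]:
    """Positions with >= 2 distinct unambiguous states across sequences."""
    L = len(seqs[0])
    out = []
    for site in range(L):
        states = {s[site] for s in seqs if s[site] in UNAMBIGUOUS}
        if len(states) >= 2:
            out.append(site)
    return out


class _DistCache:
    """Weighted distances between named nodes, from encoded sequences."""

    def __init__(self, cfg: NetworkConfig):
        self.W = _weight_matrix(cfg)
        self.enc: dict[str, np.ndarray] = {}
        self.cache: dict[tuple[str, str], int] = {}

    def add(self, name: str, seq: str) -> None:
        self.enc[name] = _net_encode(seq)

    def d(self, u: str, v: str) -> int:
        key = (u, v) if u <= v else (v, u)
        val = self.cache.get(key)
        if val is None:
            val = int(self.W[self.enc[u], self.enc[v]].sum())
            self.cache[key] = val
        return val

    def edges(self, nodes) -> list[tuple[int, str, str]]:
        return [(self.d(u, v), u, v) for u, v in itertools.combinations(nodes, 2)]


class _DSU:
    def __init__(self, items):
        self.p = {x: x for x in items}

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.p[ra] = rb
        return True


def _connection_thresholds(nodes, edges):
    """Minimax connection weight T(u,v) for every pair, via Kruskal merging:
    when two components first join at weight w, all cross pairs get T = w."""
    T = {}
    dsu = _DSU(nodes)
    comp = {x: {x} for x in nodes}
    for w, u, v in sorted(edges):
        ru, rv = dsu.find(u), dsu.find(v)
        if ru != rv:
            for a in comp[ru]:
                for b in comp[rv]:
                    T[frozenset((a, b))] = w
            comp[rv] = comp[rv] | comp[ru]
            del comp[ru]
            dsu.union(u, v)
    return T


def _msn_edges(nodes, dc: _DistCache, epsilon: int):
    """Edges (w, u, v) with w <= T(u, v) + epsilon, T the minimax connection
    weight. At epsilon = 0 this is the union of all minimum spanning trees."""
    all_edges = dc.edges(nodes)
    T = _connection_thresholds(nodes, all_edges)
    return [(w, u, v) for w, u, v in all_edges if w <= T[frozenset((u, v))] + epsilon]


def minimum_spanning_network(nodes, dist, epsilon: int = 0):
    """MSN from an explicit ``dist[u][v]`` table; returns (u, v, w) tuples."""
    all_edges = [(dist[u][v], u, v) for u, v in itertools.combinations(nodes, 2)]
    T = _connection_thresholds(nodes, all_edges)
    return [(u, v, w) for w, u, v in all_edges if w <= T[frozenset((u, v))] + epsilon]


def _kruskal(nodes, edge_list) -> tuple[int, list]:
    """(MST cost, MST edges) over an explicit (w, u, v) edge list."""
    dsu = _DSU(nodes)
    cost = 0
    keep = []
    for w, u, v in sorted(edge_list):
        if dsu.union(u, v):
            cost += w
            keep.append((w, u, v))
    return cost, keep


def quasi_medians(a: str, b: str, c: str) -> set[str]:
    """Consensus vectors of a triplet: per site the majority state, or all
    three states when the site is a three-way tie (quasi-median set)."""
    per_site: list[tuple[str, ...]] = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            per_site.append((x,))
        elif y == z:
            per_site.append((y,))
        else:
            per_site.append((x, y, z))
    n_comb = 1
    for opts in per_site:
        n_comb *= len(opts)
        if n_comb > 729:  # 3^6: a pathological triplet, keep majority-only
            per_site = [opts[:1] for opts in per_site]
            break
    return {"".join(p) for p in itertools.product(*per_site)}


def median_joining(haps: HaplotypeTable, cfg: NetworkConfig | None = None) -> nx.Graph:
    """Construct the median-joining network for a haplotype table.

    Returns a networkx Graph whose nodes carry ``sequence`` (full length),
    ``frequency``, ``populations`` and ``inferred`` attributes, and whose
    edges carry ``weight``, ``transitions`` and ``transversions``. Median
    vectors have frequency 0. Raises if the median iteration fails to
    reach a fixpoint within ``cfg.max_iter`` rounds.

    Each round: build the epsilon-relaxed minimum spanning network,
    generate quasi-medians of linked triplets, and insert those within
    epsilon of the minimal connection cost lambda that do not increase the
    parsimony (minimum spanning) cost of the node set — so the network
    cost is non-increasing across rounds and the iteration terminates.
    """
    if cfg is None:
        cfg = NetworkConfig()
    if haps.n_haplotypes < 2:
        raise ValueError("a network needs at least 2 haplotypes")
    var_pos = variable_positions(haps.seqs)
    full_by_obs = dict(zip(haps.ids, haps.seqs))
    recoded = {h: "".join(haps.seqs[i][p] for p in var_pos)
               for i, h in enumerate(haps.ids)}
    # distinct haplotypes can share a recoded string only via ambiguity codes
    seq_to_node: dict[str, str] = {}
    observed: list[str] = []
    for h in haps.ids:
        s = recoded[h]
        if s in seq_to_node:
            logger.warning("haplotypes %s and %s identical over variable sites",
                           seq_to_node[s], h)
            continue
        seq_to_node[s] = h
        observed.append(h)
    node_seq = {h: recoded[h] for h in observed}
    median_cap = cfg.median_cap_factor * len(observed)

    dc = _DistCache(cfg)
    for h in observed:
        dc.add(h, node_seq[h])
    Wm = dc.W

    nodes = list(observed)
    n_medians = 0
    for _round in range(cfg.max_iter):
        edges = _msn_edges(nodes, dc, cfg.epsilon)
        adj: dict[str, set[str]] = {u: set() for u in nodes}
        for _w, u, v in edges:
            adj[u].add(v)
            adj[v].add(u)
        # candidate medians from linked triplets (u with two linked neighbors)
        candidates: dict[str, int] = {}
        for u in nodes:
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                for m_seq in quasi_medians(node_seq[u], node_seq[v], node_seq[w]):
                    if m_seq in seq_to_node:
                        continue
                    m_enc = _net_encode(m_seq)
                    lam = sum(int(Wm[m_enc, dc.enc[x]].sum()) for x in (u, v, w))
                    if m_seq not in candidates or lam < candidates[m_seq]:
                        candidates[m_seq] = lam
        if not candidates:
            break
        lam_min = min(candidates.values())
        added = False
        base_cost, mst_edges = _kruskal(nodes, dc.edges(nodes))
        for m_seq in sorted(s for s, lam in candidates.items()
                            if lam <= lam_min + cfg.epsilon):
            if n_medians >= median_cap:
                logger.warning("median-vector cap reached (%d)", median_cap)
                break
            # MST(V + m) computed incrementally from MST(V) plus m's edges
            m_enc = _net_encode(m_seq)
            cand_edges = mst_edges + [
                (int(Wm[m_enc, dc.enc[x]].sum()), "\x00cand", x) for x in nodes
            ]
            new_cost, new_mst = _kruskal(nodes + ["\x00cand"], cand_edges)
            if new_cost > base_cost + cfg.epsilon:
                continue
            n_medians += 1
            mid = f"mv{n_medians}"
            seq_to_node[m_seq] = mid
            node_seq[mid] = m_seq
            dc.add(mid, m_seq)
            nodes.append(mid)
            base_cost = new_cost
            mst_edges = [(w, (mid if u == "\x00cand" else u),
                          (mid if v == "\x00cand" else v)) for w, u, v in new_mst]
            added = True
        if not added:
            break
    else:
        raise RuntimeError(
            f"median-joining did not converge in {cfg.max_iter} rounds; "
            f"nodes={len(nodes)}, medians={n_medians}"
        )

    nodes = _drop_obsolete(nodes, set(observed), dc, cfg)
    edges = _msn_edges(nodes, dc, cfg.epsilon)
    net = _as_graph(nodes, edges, node_seq, set(observed), haps, full_by_obs, var_pos)
    if cfg.mp_prune:
        net = mp_prune(net, cfg)
    return net


def _drop_obsolete(nodes, observed, dc: _DistCache, cfg):
    """Iteratively remove inferred vectors of degree <= 1, or of degree 2
    sitting cost-neutrally on a geodesic between their two neighbors."""
    nodes = list(nodes)
    changed = True
    while changed:
        changed = False
        edges = _msn_edges(nodes, dc, cfg.epsilon)
        neigh: dict[str, list[str]] = {u: [] for u in nodes}
        for _w, u, v in edges:
            neigh[u].append(v)
            neigh[v].append(u)
        for u in sorted(nodes):
            if u in observed:
                continue
            nb = neigh[u]
            if len(nb) <= 1:
                nodes.remove(u)
                changed = True
                break
            if len(nb) == 2:
                a, b = nb
                if dc.d(a, b) == dc.d(a, u) + dc.d(u, b):
                    nodes.remove(u)
                    changed = True
                    break
    return nodes


def _as_graph(nodes, edges, node_seq, observed, haps: HaplotypeTable,
              full_by_obs, var_pos) -> nx.Graph:
    net = nx.Graph()
    template = haps.seqs[0]
    for u in nodes:
        if u in observed:
            full = full_by_obs[u]
            freq = haps.total_count(u)
            pops = dict(haps.counts[u])
            inferred = False
        else:
            full_list = list(template)
            for pos, ch in zip(var_pos, node_seq[u]):
                full_list[pos] = ch
            full = "".join(full_list)
            freq, pops, inferred = 0, {}, True
        net.add_node(u, sequence=full, frequency=freq,
                     populations=";".join(f"{p}:{c}" for p, c in sorted(pops.items())),
                     inferred=inferred)
    for w, u, v in edges:
        ts, tv = _pair_classes(node_seq[u], node_seq[v])
        net.add_edge(u, v, weight=int(w), transitions=ts, transversions=tv)
    return net


def mp_prune(net: nx.Graph, cfg: NetworkConfig | None = None,
             exhaustive_limit: int = 12) -> nx.Graph:
    """Maximum-parsimony cleaning: keep only nodes/links lying on some
    minimum-cost spanning subgraph that connects all observed haplotypes.

    Candidate Steiner points are the network's median vectors. Up to
    ``exhaustive_limit`` medians every subset is scored by its MST cost
    (exact); beyond that medians are greedily discarded while the cost
    does not increase. The retained graph is the union, over all optimal
    median subsets, of all minimum spanning trees (equivalently the
    epsilon=0 minimum spanning network of each optimal node set).
    """
    if cfg is None:
        cfg = NetworkConfig()
    observed = sorted(u for u, d in net.nodes(data=True) if not d["inferred"])
    medians = sorted(u for u, d in net.nodes(data=True) if d["inferred"])
    dc = _DistCache(cfg)
    for u, d in net.nodes(data=True):
        dc.add(u, d["sequence"])

    if len(medians) <= exhaustive_limit and len(observed) + len(medians) <= 30:
        best_cost = None
        best_sets: list[list[str]] = []
        for r in range(len(medians) + 1):
            for sub in itertools.combinations(medians, r):
                node_set = observed + list(sub)
                cost, _ = _kruskal(node_set, dc.edges(node_set))
                if best_cost is None or cost < best_cost:
                    best_cost = cost
                    best_sets = [node_set]
                elif cost == best_cost:
                    best_sets.append(node_set)
    else:
        keep = list(medians)
        cost, _ = _kruskal(observed + keep, dc.edges(observed + keep))
        improved = True
        while improved:
            improved = False
            for m in sorted(keep):
                trial = [x for x in observed + keep if x != m]
                c, _ = _kruskal(trial, dc.edges(trial))
                if c <= cost:
                    keep.remove(m)
                    cost = c
                    improved = True
                    break
        best_sets = [observed + keep]

    kept_edges: set[frozenset] = set()
    for node_set in best_sets:
        for w, u, v in _msn_edges(node_set, dc, 0):
            kept_edges.add(frozenset((u, v)))
    # keep only observed nodes plus medians incident to retained links
    incident = {x for e in kept_edges for x in e}
    kept_nodes = set(observed) | incident
    seqs = nx.get_node_attributes(net, "sequence")
    out = nx.Graph()
    for u in kept_nodes:
        out.add_node(u, **net.nodes[u])
    for e in kept_edges:
        u, v = sorted(e)
        ts, tv = _pair_classes(seqs[u], seqs[v])
        out.add_edge(u, v, weight=dc.d(u, v), transitions=ts, transversions=tv)
    return out


def network_cost(net: nx.Graph) -> int:
    return int(sum(d["weight"] for _, _, d in net.edges(data=True)))


def parsimony_cost(net: nx.Graph, cfg: NetworkConfig | None = None) -> int:
    """Cost of a minimum spanning tree over the network's node set (the
    cost of one optimal spanning subgraph; the network itself is the union
    of all of them, so its total edge weight can be larger)."""
    if cfg is None:
        cfg = NetworkConfig()
    dc = _DistCache(cfg)
    for u, d in net.nodes(data=True):
        dc.add(u, d["sequence"])
    nodes = list(net.nodes)
    cost, _ = _kruskal(nodes, dc.edges(nodes))
    return cost


def steiner_cost_exhaustive(haps: HaplotypeTable, cfg: NetworkConfig | None = None,
                            max_candidates: int = 4096) -> int:
    """Exact minimum Steiner cost over the full candidate median-vector
    space (every combination of observed states per variable site), by the
    Dreyfus-Wagner dynamic program with terminals = observed haplotypes.
    Exponential in terminals/sites; an oracle for tiny inputs."""
    if cfg is None:
        cfg = NetworkConfig()
    var_pos = variable_positions(haps.seqs)
    states = [sorted({s[p] for s in haps.seqs if s[p] in UNAMBIGUOUS}) for p in var_pos]
    n_cand = 1
    for st in states:
        n_cand *= len(st)
    if n_cand > max_candidates:
        raise ValueError(f"candidate space too large for exhaustive search ({n_cand})")
    vertices = ["".join(c) for c in itertools.product(*states)]
    terminals = list(dict.fromkeys("".join(s[p] for p in var_pos) for s in haps.seqs))
    if len(terminals) <= 1:
        return 0
    V = len(vertices)
    vi = {v: i for i, v in enumerate(vertices)}
    enc = np.vstack([_net_encode(v) for v in vertices])
    Wm = _weight_matrix(cfg)
    W = np.zeros((V, V), dtype=np.int64)
    for i in range(V):
        W[i] = Wm[enc[i], enc].sum(axis=1)
    term_idx = [vi[t] for t in terminals]
    k = len(term_idx)
    INF = np.int64(1) << 60
    dp = np.full((1 << k, V), INF)
    for t_bit, t in enumerate(term_idx):
        dp[1 << t_bit] = W[t]
    for S in range(1, 1 << k):
        if S & (S - 1) == 0:
            continue
        sub = (S - 1) & S
        while sub:
            comp = S ^ sub
            if sub < comp:  # each split once
                np.minimum(dp[S], dp[sub] + dp[comp], out=dp[S])
            sub = (sub - 1) & S
        # relax through the complete metric graph (direct edges are geodesics)
        np.minimum(dp[S], (dp[S][:, None] + W).min(axis=0), out=dp[S])
    return int(dp[(1 << k) - 1].min())


def export_network(net: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the network as GraphML, DOT, or a TSV edge list."""
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("graph haplotype_network {\n")
            for u, d in sorted(net.nodes(data=True)):
                shape = "point" if d.get("inferred") else "circle"
                fh.write(
                    f'  "{u}" [label="{u} ({d.get("frequency", 0)})", shape={shape}];\n'
                )
            for u, v, d in sorted(net.edges(data=True)):
                fh.write(f'  "{u}" -- "{v}" [label="{d["weight"]}"];\n')
            fh.write("}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tweight\ttransitions\ttransversions\n")
            for u, v, d in sorted(net.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']}\t{d['transitions']}\t{d['transversions']}\n")
    else:
        raise ValueError(f"unknown export format: {fmt}")
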