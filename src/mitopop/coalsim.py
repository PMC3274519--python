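"""Coalescent simulation of mitochondrial-like sequence samples.

Genealogies are simulated under constant-size, sudden-expansion, or
two-deme-split demographies, with all times expressed in *mutational
units*: a branch of length b accumulates Poisson(b) mutations, and a pair
of sequences from a constant-size population with scaled mutation rate
theta has expected difference theta. Under the sudden-expansion model with
expansion age tau (in units of pairwise mutational distance, the same tau
the mismatch distribution estimates), the size change sits at depth tau/2
per lineage.

Mutation is finite-sites over L positions with transition:transversion
odds kappa:1, so simulated data exercise multiple hits and distance
saturation the way a real 1,140-bp locus would. An infinite-sites mode is
provided for neutrality-test null distributions, where each mutation is a
new segregating site; ``fixed_S`` conditions on an exact mutation count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alignment_io import Alignment, PopulationMap


@dataclass
class DemographyModel:
    """Demographic scenario for the simulator.

    kind="constant": single population, theta = theta0 throughout.
    kind="sudden_expansion": theta1 (post-expansion, recent) until depth
        tau/2, theta0 (pre-expansion) beyond.
    kind="two_deme_split": two demes with thetas ``deme_thetas`` exchanging
        migrants at rate ``migration`` (per lineage per unit time), merging
        into an ancestral population of theta0 at depth ``split_time``.
    """

    kind: str = "constant"
    theta0: float = 1.0
    theta1: float = 100.0
    tau: float = 0.0
    split_time: float = 0.0
    deme_thetas: tuple[float, float] = (1.0, 1.0)
    migration: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sudden_expansion", "two_deme_split"):
            raise ValueError(f"unknown demography kind: {self.kind}")
        if self.theta0 <= 0:
            raise ValueError("theta0 must be positive")
        if self.kind == "sudden_expansion" and (self.theta1 <= 0 or self.tau < 0):
            raise ValueError("sudden_expansion requires theta1 > 0 and tau >= 0")
        if self.kind == "two_deme_split":
            if self.split_time <= 0 or min(self.deme_thetas) <= 0:
                raise ValueError("two_deme_split requires positive split_time and deme sizes")


@dataclass
class SimConfig:
    n: int = 30
    L: int = 1140
    ts_tv_kappa: float = 5.33
    seed: int | None = None
    fixed_S: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2 or self.L < 1:
            raise ValueError("need n >= 2 and L >= 1")


@dataclass
class Tree:
    """Rooted genealogy: ``parent[v]`` (-1 at the root), node times ascending
    from the leaves (nodes ``0..n_leaves-1``, time 0 unless grafted)."""

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        b = np.zeros(self.n_nodes)
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p != -1:
                b[v] = self.time[p] - self.time[v]
        return b

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            if self.parent[v] != -1:
                ch[self.parent[v]].append(v)
        return ch

    def leaves_below(self) -> list[np.ndarray]:
        """Leaf index sets per node, computed children-first."""
        order = np.argsort(self.time, kind="stable")
        sets: list[set[int]] = [set() for _ in range(self.n_nodes)]
        ch = self.children()
        for v in order:
            if v < self.n_leaves:
                sets[v] = {int(v)}
            else:
                for c in ch[v]:
                    sets[v] |= sets[c]
        return [np.array(sorted(s), dtype=int) for s in sets]

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())


def _theta_epochs(model: DemographyModel) -> list[tuple[float, float]]:
    """[(epoch start depth, theta)] ascending; last epoch extends to infinity."""
    if model.kind == "constant":
        return [(0.0, model.theta0)]
    if model.kind == "sudden_expansion":
        if model.tau == 0.0:
            return [(0.0, model.theta0)]
        return [(0.0, model.theta1), (model.tau / 2.0, model.theta0)]
    raise ValueError(model.kind)


def _coalesce_single(n: int, epochs, rng, t0: float = 0.0) -> Tree:
    """Kingman coalescent with piecewise-constant theta, waiting times drawn
    epoch by epoch (rate j(j-1)/theta per unit mutational time)."""
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    time[:n] = t0
    t = t0
    nxt = n
    ei = 0
    while len(active) > 1:
        j = len(active)
        while True:
            theta = epochs[ei][1]
            rate = j * (j - 1) / theta
            wait = rng.exponential(1.0 / rate)
            boundary = epochs[ei + 1][0] if ei + 1 < len(epochs) else np.inf
            if t + wait <= boundary:
                t += wait
                break
            t = boundary
            ei += 1
        a, b = rng.choice(len(active), size=2, replace=False)
        u, v = active[a], active[b]
        parent[u] = parent[v] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (u, v)] + [nxt]
        nxt += 1
    return Tree(parent, time, n)


def _coalesce_two_deme(model: DemographyModel, n_per_deme: tuple[int, int], rng) -> Tree:
    n = sum(n_per_deme)
    max_nodes = 2 * n - 1
    parent = np.full(max_nodes, -1, dtype=int)
    time = np.zeros(max_nodes)
    deme_of = {}
    for i in range(n):
        deme_of[i] = 0 if i < n_per_deme[0] else 1
    active = list(range(n))
    t = 0.0
    nxt = n
    merged = False
    while len(active) > 1:
        in_deme = [[x for x in active if deme_of[x] == d] for d in (0, 1)]
        if not merged:
            rates = [
                len(in_deme[d]) * (len(in_deme[d]) - 1) / model.deme_thetas[d]
                for d in (0, 1)
            ]
            mig = model.migration * len(active)
            total = rates[0] + rates[1] + mig
            wait = rng.exponential(1.0 / total) if total > 0 else np.inf
            if t + wait >= model.split_time:
                t = model.split_time
                merged = True
                for x in active:
                    deme_of[x] = 0
                continue
            t += wait
            u01 = rng.uniform(0, total)
            if u01 < mig:
                x = active[int(rng.integers(len(active)))]
                deme_of[x] = 1 - deme_of[x]
                continue
            d = 0 if u01 < mig + rates[0] else 1
            pool = in_deme[d]
        else:
            j = len(active)
            rate = j * (j - 1) / model.theta0
            t += rng.exponential(1.0 / rate)
            pool = active
        a, b = rng.choice(len(pool), size=2, replace=False)
        u, v = pool[a], pool[b]
        parent[u] = parent[v] = nxt
        time[nxt] = t
        deme_of[nxt] = deme_of[u]
        active = [x for x in active if x not in (u, v)] + [nxt]
        nxt += 1
    return Tree(parent, time, n)


def simulate_genealogy(model: DemographyModel, cfg: SimConfig, rng=None) -> Tree:
    """Draw one genealogy for ``cfg.n`` samples under ``model``."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if model.kind == "two_deme_split":
        half = cfg.n // 2
        return _coalesce_two_deme(model, (half, cfg.n - half), rng)
    return _coalesce_single(cfg.n, _theta_epochs(model), rng)


def join_trees(trees: list[Tree], join_time: float, rng=None) -> Tree:
    """Graft subtree roots onto a common ancestor at depth ``join_time``.

    With more than two subtrees the roots coalesce in random order just
    below ``join_time`` (spacing 1e-6), keeping the result binary.
    """
    if rng is None:
        rng = np.random.default_rng()
    n_leaves = sum(t.n_leaves for t in trees)
    parent = np.full(2 * n_leaves - 1, -1, dtype=int)
    time = np.zeros(2 * n_leaves - 1)
    leaf_off = 0
    int_off = n_leaves
    roots = []
    for t in trees:
        if join_time <= float(t.time.max()):
            raise ValueError("join_time must exceed every subtree root time")
        relabel = {}
        for v in range(t.n_nodes):
            relabel[v] = leaf_off + v if v < t.n_leaves else int_off + (v - t.n_leaves)
        for v in range(t.n_nodes):
            nv = relabel[v]
            time[nv] = t.time[v]
            parent[nv] = relabel[int(t.parent[v])] if t.parent[v] != -1 else -1
        roots.append(relabel[t.root])
        leaf_off += t.n_leaves
        int_off += t.n_nodes - t.n_leaves
    order = list(rng.permutation(len(roots)))
    cur = roots[order[0]]
    k = len(roots)
    for step, idx in enumerate(order[1:], start=1):
        node = int_off
        int_off += 1
        tt = join_time - 1e-6 * (k - 1 - step)
        time[node] = tt
        parent[cur] = node
        parent[roots[idx]] = node
        cur = node
    return Tree(parent[:int_off], time[:int_off], n_leaves)


_TS_PARTNER = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T in ACGT coding
_TV_TARGETS = {0: (1, 3), 2: (1, 3), 1: (0, 2), 3: (0, 2)}


def _mutation_counts(tree: Tree, cfg: SimConfig, rng) -> np.ndarray:
    """Mutation count per branch: Poisson(length), or an exact total of
    ``fixed_S`` events multinomially spread proportional to branch length."""
    b = tree.branch_lengths()
    if cfg.fixed_S is not None:
        if b.sum() <= 0:
            raise ValueError("cannot place fixed_S mutations on a zero-length tree")
        return rng.multinomial(cfg.fixed_S, b / b.sum())
    return rng.poisson(b)


def mutate_sequences(tree: Tree, cfg: SimConfig, rng=None, ids=None) -> Alignment:
    """Evolve finite-sites sequences down the genealogy.

    The root sequence is uniform over ACGT; each mutation hits a uniform
    site and is a transition with odds kappa:1 (both transversion targets
    equiprobable).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    kappa = cfg.ts_tv_kappa
    n_mut = _mutation_counts(tree, cfg, rng)
    seqs = {}
    root = tree.root
    seqs[root] = rng.integers(0, 4, size=cfg.L).astype(np.uint8)
    order = np.argsort(-tree.time, kind="stable")
    for v in order:
        if v == root:
            continue
        seq = seqs[int(tree.parent[v])].copy()
        for _ in range(int(n_mut[v])):
            site = int(rng.integers(cfg.L))
            base = int(seq[site])
            if rng.random() < kappa / (kappa + 1.0):
                seq[site] = _TS_PARTNER[base]
            else:
                seq[site] = _TV_TARGETS[base][int(rng.integers(2))]
        seqs[v] = seq
    alphabet = np.array(list("ACGT"))
    if ids is None:
        ids = [f"s{i + 1}" for i in range(tree.n_leaves)]
    out = ["".join(alphabet[seqs[i]]) for i in range(tree.n_leaves)]
    return Alignment(list(ids), out)


def mutate_infinite_sites(tree: Tree, cfg: SimConfig, rng=None) -> np.ndarray:
    """Binary (n_leaves x S) derived-allele matrix: every mutation is a new
    segregating site (columns for mutations shared by all or no leaves are
    dropped, as they are invisible in a sample)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_mut = _mutation_counts(tree, cfg, rng)
    below = tree.leaves_below()
    cols = []
    for v in range(tree.n_nodes):
        for _ in range(int(n_mut[v])):
            col = np.zeros(tree.n_leaves, dtype=np.uint8)
            col[below[v]] = 1
            k = col.sum()
            if 0 < k < tree.n_leaves:
                cols.append(col)
    if not cols:
        return np.zeros((tree.n_leaves, 0), dtype=np.uint8)
    return np.column_stack(cols)


def simulate_alignment(model: DemographyModel, cfg: SimConfig, rng=None, ids=None) -> Alignment:
    """Convenience: genealogy + finite-sites mutation in one call."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return mutate_sequences(simulate_genealogy(model, cfg, rng), cfg, rng, ids=ids)


# --- study-like fixture -----------------------------------------------------

#: Four terminal groups: (name, n samples, expansion tau, post-expansion theta)
_STUDY_GROUPS = [
    ("E1", 94, 6.0, 400.0),
    ("E2", 24, 8.2, 400.0),
    ("W1", 30, 4.4, 400.0),
    ("W2", 50, 12.3, 400.0),
]
#: Join depths in mutational units per lineage, matched to the printed
#: between-clade K2P distances over 1,140 sites (E1/E2 1.9%, W1/W2 1.6%,
#: E/W 3.1% => depths ~10.8, ~9.1, ~17.7).
_JOIN_DEPTHS = {"E": 10.8, "W": 9.1, "EW": 17.7}


def make_study_like_dataset(
    seed: int = 0,
    fasta_path=None,
    popmap_path=None,
    sidecar_path=None,
    structured: bool = True,
) -> tuple[Alignment, PopulationMap]:
    """A deterministic synthetic dataset shaped like a real cyt-b survey.

    Four terminal groups (two clades, each split into two subclades) each
    undergo a recent sudden expansion; sample sizes (94/24/30/50),
    alignment length (1,140), transition bias (5.33) and clade depths match
    the kind of mitochondrial phylogeography survey this package targets.
    Samples are scattered over ~50 local populations of 1-15 individuals.

    With ``structured=False`` all samples are drawn from one panmictic
    constant-size population (negative control: no structure to detect),
    keeping the same population/group labels.
    """
    rng = np.random.default_rng(seed)
    total_n = sum(g[1] for g in _STUDY_GROUPS)
    cfg = SimConfig(n=total_n, L=1140, ts_tv_kappa=5.33)
    if structured:
        subtrees = []
        for _name, n_g, tau, theta1 in _STUDY_GROUPS:
            model = DemographyModel(
                kind="sudden_expansion", theta0=1.0, theta1=theta1, tau=tau
            )
            subtrees.append(
                _coalesce_single(n_g, _theta_epochs(model), rng)
            )
        e = join_trees(subtrees[0:2], _JOIN_DEPTHS["E"], rng)
        w = join_trees(subtrees[2:4], _JOIN_DEPTHS["W"], rng)
        tree = join_trees([e, w], _JOIN_DEPTHS["EW"], rng)
    else:
        tree = _coalesce_single(total_n, [(0.0, 12.0)], rng)

    ids = []
    sample_to_pop = {}
    pop_to_group = {}
    pop_idx = 0
    k = 0
    for name, n_g, _tau, _theta1 in _STUDY_GROUPS:
        remaining = n_g
        while remaining > 0:
            size = int(min(remaining, 15, 1 + rng.poisson(3.0)))
            pop_idx += 1
            pop = f"P{pop_idx:02d}"
            pop_to_group[pop] = name
            for _ in range(size):
                k += 1
                sid = f"{name}_{k:03d}"
                ids.append(sid)
                sample_to_pop[sid] = pop
            remaining -= size
    aln = mutate_sequences(tree, cfg, rng, ids=ids)
    pm = PopulationMap(sample_to_pop, pop_to_group)

    if fasta_path is not None:
        write_fasta(aln, fasta_path)
    if popmap_path is not None:
        write_popmap(pm, popmap_path)
    if sidecar_path is not None:
        meta = {
            "seed": seed,
            "structured": structured,
            "groups": [
                {"name": g[0], "n": g[1], "tau": g[2], "theta1": g[3]}
                for g in _STUDY_GROUPS
            ],
            "join_depths": _JOIN_DEPTHS,
            "L": cfg.L,
            "ts_tv_kappa": cfg.ts_tv_kappa,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)
    return aln, pm


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_popmap(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation_id\tgroup_id\n")
        for sid in pm.sample_to_pop:
            pop = pm.sample_to_pop[sid]
            fh.write(f"{sid}\t{pop}\t{pm.pop_to_group[pop]}\n")
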