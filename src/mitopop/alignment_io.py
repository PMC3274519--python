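"""Aligned-sequence I/O, haplotype collapsing, site classification, and K2P distances.

The unit of analysis is a multiple sequence alignment of a single
mitochondrial locus (equal-length nucleotide strings, one per sample),
together with a two-level sample map: sample -> population -> group,
where a group is a clade, subclade, or geographic region.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
UNAMBIGUOUS = frozenset("ACGT")
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVN")
GAP = frozenset("-.?")
VALID_CHARS = UNAMBIGUOUS | IUPAC_AMBIGUOUS | GAP

# integer codes for vectorized distance computation
_CODE = {c: i for i, c in enumerate("ACGT")}
_MISSING = 255


class SaturationWarning(UserWarning):
    """Emitted when a K2P log argument is non-positive (distance saturated)."""


def is_transition(a: str, b: str) -> bool:
    """True if {a, b} is a purine pair or a pyrimidine pair (a != b)."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes; gaps/ambiguity -> 255."""
    out = np.full(len(seq), _MISSING, dtype=np.uint8)
    for i, c in enumerate(seq):
        code = _CODE.get(c)
        if code is not None:
            out[i] = code
    return out


@dataclass
class Alignment:
    """An equal-length nucleotide alignment with unique sample ids.

    Sequences are stored upper-case over the alphabet {A,C,G,T, IUPAC
    ambiguity codes, -}. Validation happens on construction.
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("empty alignment")
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids/seqs length mismatch")
        self.seqs = [s.upper() for s in self.seqs]
        L = len(self.seqs[0])
        ragged = [i for i, s in zip(self.ids, self.seqs) if len(s) != L]
        if ragged:
            raise ValueError(
                f"ragged alignment: records {ragged} differ in length from "
                f"first record (L={L})"
            )
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        bad = sorted({c for s in self.seqs for c in set(s) if c not in VALID_CHARS})
        if bad:
            raise ValueError(f"invalid characters in alignment: {bad}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def subset(self, ids) -> "Alignment":
        wanted = list(ids)
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"samples not in alignment: {missing}")
        return Alignment(wanted, [self.seqs[index[s]] for s in wanted])

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 matrix; 255 marks gap/ambiguous positions."""
        return np.vstack([encode(s) for s in self.seqs])


@dataclass
class PopulationMap:
    """sample -> population and population -> group assignments."""

    sample_to_pop: dict[str, str]
    pop_to_group: dict[str, str]

    def __post_init__(self) -> None:
        orphan = sorted(set(self.sample_to_pop.values()) - set(self.pop_to_group))
        if orphan:
            raise ValueError(f"populations without a group: {orphan}")

    def population(self, sample_id: str) -> str:
        return self.sample_to_pop[sample_id]

    def group_of_sample(self, sample_id: str) -> str:
        return self.pop_to_group[self.sample_to_pop[sample_id]]

    def populations(self) -> list[str]:
        return sorted(set(self.sample_to_pop.values()))

    def groups(self) -> list[str]:
        return sorted(set(self.pop_to_group.values()))

    def samples_in_group(self, group_id: str) -> list[str]:
        return [s for s in self.sample_to_pop if self.group_of_sample(s) == group_id]

    def validate_against(self, aln: Alignment) -> None:
        unmapped = [s for s in aln.ids if s not in self.sample_to_pop]
        if unmapped:
            raise ValueError(f"samples missing from population map: {unmapped}")


def read_popmap(path) -> PopulationMap:
    """Read a TSV with header ``sample_id<TAB>population_id<TAB>group_id``."""
    sample_to_pop: dict[str, str] = {}
    pop_to_group: dict[str, str] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty population map: {path}")
    start = 1 if lines[0].lower().startswith("sample_id") else 0
    for ln in lines[start:]:
        parts = ln.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed popmap line (need 3 tab-separated fields): {ln!r}")
        sample, pop, group = (p.strip() for p in parts)
        if sample in sample_to_pop:
            raise ValueError(f"duplicate sample in popmap: {sample}")
        sample_to_pop[sample] = pop
        if pop in pop_to_group and pop_to_group[pop] != group:
            raise ValueError(f"population {pop} assigned to two groups")
        pop_to_group[pop] = group
    return PopulationMap(sample_to_pop, pop_to_group)


def read_alignment(fasta_path, popmap_path) -> tuple[Alignment, PopulationMap]:
    """Read and validate a FASTA alignment plus its population map.

    Sequence case is normalized to upper; every FASTA record id must be
    present in the map. Errors name the offending records.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    aln = Alignment([r.id for r in records], [str(r.seq) for r in records])
    pm = read_popmap(popmap_path)
    pm.validate_against(aln)
    return aln, pm


@dataclass
class HaplotypeTable:
    """Distinct sequences with per-population sample counts.

    Haplotype ids are assigned in order of first appearance (H1, H2, ...),
    making the collapse deterministic for a given input order.
    """

    ids: list[str]
    seqs: list[str]
    counts: dict[str, dict[str, int]]  # haplotype_id -> population_id -> count
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return len(self.ids)

    def total_count(self, hap_id: str) -> int:
        return sum(self.counts[hap_id].values())

    @property
    def n_samples(self) -> int:
        return sum(self.total_count(h) for h in self.ids)

    def frequencies(self) -> np.ndarray:
        tot = self.n_samples
        return np.array([self.total_count(h) / tot for h in self.ids])


def collapse_haplotypes(aln: Alignment, pm: PopulationMap | None = None) -> HaplotypeTable:
    """Collapse identical sequences (exact string match over all sites).

    Sequences containing ambiguity codes collapse only with exact matches.
    Counts are partitioned by population when a map is supplied, else pooled
    under population id ``"all"``.
    """
    if pm is not None:
        pm.validate_against(aln)
    ids: list[str] = []
    seqs: list[str] = []
    counts: dict[str, dict[str, int]] = {}
    members: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    for sample, seq in zip(aln.ids, aln.seqs):
        pop = pm.population(sample) if pm is not None else "all"
        hap = seen.get(seq)
        if hap is None:
            hap = f"H{len(ids) + 1}"
            seen[seq] = hap
            ids.append(hap)
            seqs.append(seq)
            counts[hap] = {}
            members[hap] = []
        counts[hap][pop] = counts[hap].get(pop, 0) + 1
        members[hap].append(sample)
    return HaplotypeTable(ids, seqs, counts, members)


@dataclass
class SiteClassSummary:
    conserved_sites: int
    variable_sites: int
    singleton_sites: int
    parsimony_informative_sites: int
    transitions: int
    transversions: int
    ts_tv_ratio: float  # transitions / transversions
    tv_ts_ratio: float
    excluded_sites: int

    @property
    def ratio_reported(self) -> float:
        """Headline substitution-class ratio (transitions : transversions)."""
        return self.ts_tv_ratio


def classify_sites(haps: HaplotypeTable) -> SiteClassSummary:
    """Classify alignment columns as conserved/variable and count ts/tv classes.

    A site is variable iff at least two distinct unambiguous bases occur
    across haplotypes; ambiguous bases and gaps never count as states.
    Columns with no unambiguous base at all are excluded from both counts
    (logged). Substitution-class totals consider, per variable site, every
    unordered pair of distinct observed bases, classified as transition or
    transversion. Singleton/parsimony-informative tallies weight each
    haplotype by its sample count.
    """
    if haps.n_haplotypes < 2:
        raise ValueError("site classification requires at least 2 haplotypes")
    L = len(haps.seqs[0])
    weights = [haps.total_count(h) for h in haps.ids]
    conserved = variable = singleton = pars_inf = excluded = 0
    transitions = transversions = 0
    for site in range(L):
        base_counts: dict[str, int] = {}
        for seq, w in zip(haps.seqs, weights):
            c = seq[site]
            if c in UNAMBIGUOUS:
                base_counts[c] = base_counts.get(c, 0) + w
        if not base_counts:
            excluded += 1
            continue
        states = sorted(base_counts)
        if len(states) == 1:
            conserved += 1
            continue
        variable += 1
        for i in range(len(states)):
            for j in range(i + 1, len(states)):
                if is_transition(states[i], states[j]):
                    transitions += 1
                else:
                    transversions += 1
        freqs = sorted(base_counts.values(), reverse=True)
        if sum(1 for f in freqs if f >= 2) >= 2:
            pars_inf += 1
        elif any(f == 1 for f in freqs[1:]) or freqs[0] == 1:
            singleton += 1
    if excluded:
        logger.info("classify_sites: excluded %d all-gap/ambiguous columns", excluded)
    ts_tv = transitions / transversions if transversions else math.inf
    tv_ts = transversions / transitions if transitions else math.inf
    logger.info("classify_sites: ts/tv = %.4g, tv/ts = %.4g", ts_tv, tv_ts)
    return SiteClassSummary(
        conserved_sites=conserved,
        variable_sites=variable,
        singleton_sites=singleton,
        parsimony_informative_sites=pars_inf,
        transitions=transitions,
        transversions=transversions,
        ts_tv_ratio=ts_tv,
        tv_ts_ratio=tv_ts,
        excluded_sites=excluded,
    )


def _pair_counts(ea: np.ndarray, eb: np.ndarray) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) under pairwise deletion."""
    ok = (ea != _MISSING) & (eb != _MISSING)
    n = int(ok.sum())
    diff = ok & (ea != eb)
    # codes: A=0 C=1 G=2 T=3; transition iff both purine {0,2} or both pyrimidine {1,3}
    purine_a = (ea == 0) | (ea == 2)
    purine_b = (eb == 0) | (eb == 2)
    ts = int((diff & (purine_a == purine_b)).sum())
    tv = int(diff.sum()) - ts
    return n, ts, tv


def raw_distance(seq_a: str, seq_b: str) -> int:
    """Number of differing sites under pairwise deletion of gaps/ambiguity."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    _, ts, tv = _pair_counts(encode(seq_a.upper()), encode(seq_b.upper()))
    return ts + tv


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance in substitutions/site.

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q) with P, Q the transition
    and transversion proportions over sites comparable in both sequences
    (pairwise deletion). A non-positive log argument means the correction
    is saturated: NaN is returned and a :class:`SaturationWarning` issued.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    n, ts, tv = _pair_counts(encode(seq_a.upper()), encode(seq_b.upper()))
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    return _k2p_from_counts(n, ts, tv)


def _k2p_from_counts(n: int, ts: int, tv: int) -> float:
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        warnings.warn(
            f"K2P saturated (P={P:.4g}, Q={Q:.4g}); returning NaN", SaturationWarning
        )
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    model: str  # "k2p" | "raw"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.d[i, j])

    def to_tsv(self, path, lower_triangle: bool = False) -> None:
        with open(path, "w") as fh:
            if lower_triangle:
                fh.write(f"{len(self.ids)}\n")
                for i, sid in enumerate(self.ids):
                    row = "\t".join(f"{self.d[i, j]:.6g}" for j in range(i))
                    fh.write(f"{sid}\t{row}\n" if row else f"{sid}\n")
            else:
                fh.write("id\t" + "\t".join(self.ids) + "\n")
                for i, sid in enumerate(self.ids):
                    fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in self.d[i]) + "\n")


def distance_matrix(aln: Alignment, model: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix (symmetric, zero diagonal).

    model="raw" counts differing comparable sites; model="k2p" applies the
    Kimura two-parameter correction per pair.
    """
    if model not in ("k2p", "raw"):
        raise ValueError(f"unknown distance model: {model}")
    enc = aln.encoded()
    n = aln.n
    d = np.zeros((n, n))
    ok = enc != _MISSING
    purine = (enc == 0) | (enc == 2)
    for i in range(n):
        both = ok[i] & ok[i + 1 :]
        diff = both & (enc[i] != enc[i + 1 :])
        n_comp = both.sum(axis=1)
        ts = (diff & (purine[i] == purine[i + 1 :])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        for off, (nc, t, v) in enumerate(zip(n_comp, ts, tv)):
            j = i + 1 + off
            if model == "raw":
                d[i, j] = d[j, i] = t + v
            else:
                if nc == 0:
                    raise ValueError(
                        f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}"
                    )
                d[i, j] = d[j, i] = _k2p_from_counts(int(nc), int(t), int(v))
    return DistanceMatrix(list(aln.ids), d, model)


def group_mean_k2p(dm: DistanceMatrix, pm: PopulationMap, group_a: str, group_b: str) -> float:
    """Mean K2P distance over all between-group sequence pairs."""
    if group_a not in pm.groups() or group_b not in pm.groups():
        missing = [g for g in (group_a, group_b) if g not in pm.groups()]
        raise ValueError(f"unknown group id(s): {missing}")
    ia = [k for k, sid in enumerate(dm.ids) if pm.group_of_sample(sid) == group_a]
    ib = [k for k, sid in enumerate(dm.ids) if pm.group_of_sample(sid) == group_b]
    if not ia or not ib:
        raise ValueError("both groups must contain at least one sequence")
    vals = dm.d[np.ix_(ia, ib)]
    return float(np.mean(vals))
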