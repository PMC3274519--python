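"""Hierarchical AMOVA and pairwise Fst from inter-individual distances.

Variance in pairwise difference counts is partitioned among groups, among
populations within groups, and within populations (Excoffier-style sums
of squares from the distance matrix, variance components by equating mean
squares to their expectations with unequal-size coefficients). The
Phi-statistics are tested by permutation at the level-appropriate scheme:
individuals anywhere (Phi_ST), individuals within their group (Phi_SC),
whole populations among groups (Phi_CT). The inter-individual distance is
the raw pairwise difference count, the conventional default for
haplotype-level AMOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .alignment_io import DistanceMatrix, PopulationMap


@dataclass
class GroupingScheme:
    name: str
    pop_to_group: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.pop_to_group.values())) < 2:
            raise ValueError("a grouping scheme needs at least 2 groups")


@dataclass
class AmovaResult:
    scheme: str
    sigma2_a: float  # among groups
    sigma2_b: float  # among populations within groups
    sigma2_c: float  # within populations
    pct_a: float
    pct_b: float
    pct_c: float
    Phi_ST: float
    Phi_SC: float
    Phi_CT: float
    p_ST: float | None
    p_SC: float | None
    p_CT: float | None
    df: tuple[int, int, int]
    SS: tuple[float, float, float]
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)


def _within_sums(D: np.ndarray, labels: np.ndarray) -> dict:
    """Sum over i<j pairs sharing each label of D[i, j]."""
    out = {}
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        sub = D[np.ix_(idx, idx)]
        out[lab] = float(sub.sum() / 2.0)
    return out


def _amova_components(D: np.ndarray, pops: np.ndarray, groups: np.ndarray):
    """Variance components (sigma_a, sigma_b, sigma_c) and sums of squares.

    SS are computed from squared-distance analogues: SS(partition) =
    sum_{i<j in partition} d_ij / n_partition.
    """
    N = len(pops)
    total_ss = float(D.sum() / 2.0) / N
    pop_labels, pop_sizes = np.unique(pops, return_counts=True)
    grp_labels = np.unique(groups)
    P, G = len(pop_labels), len(grp_labels)

    within_pop = _within_sums(D, pops)
    ss_wp = sum(within_pop[p] / np.sum(pops == p) for p in pop_labels)
    within_grp = _within_sums(D, groups)
    ss_wg = sum(within_grp[g] / np.sum(groups == g) for g in grp_labels)
    ss_ap = ss_wg - ss_wp   # among populations within groups
    ss_ag = total_ss - ss_wg  # among groups

    df_ag, df_ap, df_wp = G - 1, P - G, N - P

    size_of = dict(zip(pop_labels, pop_sizes))
    group_of_pop = {}
    for p in pop_labels:
        gs = np.unique(groups[pops == p])
        group_of_pop[p] = gs[0]
    Ng = {g: int(np.sum(groups == g)) for g in grp_labels}
    sum_n2_over_Ng = sum(
        sum(size_of[p] ** 2 for p in pop_labels if group_of_pop[p] == g) / Ng[g]
        for g in grp_labels
    )
    sum_n2_over_N = sum(size_of[p] ** 2 for p in pop_labels) / N
    sum_Ng2_over_N = sum(Ng[g] ** 2 for g in grp_labels) / N

    n1 = (N - sum_n2_over_Ng) / df_ap if df_ap > 0 else np.nan
    n2 = (sum_n2_over_Ng - sum_n2_over_N) / df_ag if df_ag > 0 else np.nan
    n3 = (N - sum_Ng2_over_N) / df_ag if df_ag > 0 else np.nan

    ms_wp = ss_wp / df_wp if df_wp > 0 else np.nan
    ms_ap = ss_ap / df_ap if df_ap > 0 else np.nan
    ms_ag = ss_ag / df_ag if df_ag > 0 else np.nan

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1 if df_ap > 0 else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3

    return (sigma_a, sigma_b, sigma_c), (ss_ag, ss_ap, ss_wp), (df_ag, df_ap, df_wp)


def _phis(sig):
    a, b, c = sig
    total = a + b + c
    phi_st = (a + b) / total if total != 0 else np.nan
    phi_ct = a / total if total != 0 else np.nan
    phi_sc = b / (b + c) if (b + c) != 0 else np.nan
    return phi_st, phi_sc, phi_ct


def amova(
    dm: DistanceMatrix,
    pm: PopulationMap,
    scheme: GroupingScheme,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Three-level AMOVA with permutation tests.

    ``dm`` must hold raw pairwise difference counts for the individuals to
    analyze; populations are taken from ``pm`` and groups from ``scheme``.
    Negative variance components are reported as computed (they signal the
    absence of structure at that level, not an error). If every distance
    is zero the Phi-statistics are undefined and flagged degenerate.
    """
    if dm.model != "raw":
        raise ValueError("AMOVA expects the raw difference-count distance matrix")
    pops = np.array([pm.population(s) for s in dm.ids])
    try:
        groups = np.array([scheme.pop_to_group[p] for p in pops])
    except KeyError as e:
        raise ValueError(f"population {e} missing from scheme {scheme.name!r}") from e
    if len(np.unique(groups)) < 2:
        raise ValueError("AMOVA needs >= 2 groups with samples")
    D = dm.d
    notes = []
    for g in np.unique(groups):
        if np.sum(groups == g) < 2:
            notes.append(f"group {g} has a single sequence: among-group level unstable")

    sig, SS, df = _amova_components(D, pops, groups)
    phi_st, phi_sc, phi_ct = _phis(sig)
    total = sum(sig)
    if total == 0 or not np.isfinite(total):
        warnings.warn("total molecular variance is zero: Phi undefined")
        return AmovaResult(scheme.name, *sig, np.nan, np.nan, np.nan,
                           np.nan, np.nan, np.nan, None, None, None, df, SS,
                           degenerate=True, notes=notes)
    pct = tuple(100.0 * s / total for s in sig)

    p_st = p_sc = p_ct = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        ge_st = ge_sc = ge_ct = 0
        pop_labels = np.unique(pops)
        grp_of = np.array([scheme.pop_to_group[p] for p in pop_labels])
        for _ in range(n_perm):
            # Phi_ST: individuals shuffled among populations anywhere
            perm = rng.permutation(len(pops))
            s_i, _, _ = _amova_components(D, pops[perm], groups[perm])
            if _phis(s_i)[0] >= phi_st:
                ge_st += 1
            # Phi_SC: individuals shuffled among populations within groups
            pops_sc = pops.copy()
            for g in np.unique(groups):
                idx = np.where(groups == g)[0]
                pops_sc[idx] = pops_sc[idx][rng.permutation(len(idx))]
            s_i, _, _ = _amova_components(D, pops_sc, groups)
            if _phis(s_i)[1] >= phi_sc:
                ge_sc += 1
            # Phi_CT: whole populations shuffled among groups
            perm_grp = grp_of[rng.permutation(len(grp_of))]
            remap = dict(zip(pop_labels, perm_grp))
            groups_ct = np.array([remap[p] for p in pops])
            s_i, _, _ = _amova_components(D, pops, groups_ct)
            if _phis(s_i)[2] >= phi_ct:
                ge_ct += 1
        p_st = (ge_st + 1) / (n_perm + 1)
        p_sc = (ge_sc + 1) / (n_perm + 1)
        p_ct = (ge_ct + 1) / (n_perm + 1)

    return AmovaResult(scheme.name, *sig, *pct, phi_st, phi_sc, phi_ct,
                       p_st, p_sc, p_ct, df, SS, notes=notes)


@dataclass
class PairwiseFstMatrix:
    populations: list[str]
    fst: np.ndarray
    p: np.ndarray

    def get(self, a: str, b: str) -> tuple[float, float]:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.fst[i, j]), float(self.p[i, j])

    def to_tsv(self, path, fst_threshold: float = 0.25, alpha: float = 0.05) -> None:
        """Square matrix with Fst below and p above the diagonal; pairs over
        the restricted-gene-flow threshold are marked with '*'."""
        with open(path, "w") as fh:
            fh.write("population\t" + "\t".join(self.populations) + "\n")
            for i, a in enumerate(self.populations):
                cells = []
                for j in range(len(self.populations)):
                    if j < i:
                        flag = "*" if self.fst[i, j] >= fst_threshold else ""
                        cells.append(f"{self.fst[i, j]:.4f}{flag}")
                    elif j == i:
                        cells.append("0")
                    else:
                        sig = "*" if self.p[i, j] <= alpha else ""
                        cells.append(f"{self.p[i, j]:.4f}{sig}")
                fh.write(a + "\t" + "\t".join(cells) + "\n")


def two_population_fst(D: np.ndarray, labels: np.ndarray) -> float:
    """Distance-based Fst (two-population AMOVA Phi_ST)."""
    N = len(labels)
    pop_labels, sizes = np.unique(labels, return_counts=True)
    total_ss = float(D.sum() / 2.0) / N
    within = _within_sums(D, labels)
    ss_wp = sum(within[p] / n for p, n in zip(pop_labels, sizes))
    ss_ap = total_ss - ss_wp
    df_ap, df_wp = len(pop_labels) - 1, N - len(pop_labels)
    n_c = (N - np.sum(sizes**2) / N) / df_ap
    sigma_w = ss_wp / df_wp if df_wp > 0 else 0.0
    sigma_a = (ss_ap / df_ap - sigma_w) / n_c
    denom = sigma_a + sigma_w
    return float(sigma_a / denom) if denom != 0 else np.nan


def pairwise_fst(
    dm: DistanceMatrix,
    pm: PopulationMap,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PairwiseFstMatrix:
    """Pairwise distance-based Fst with permutation p-values.

    For each pair of populations, individuals are permuted between the two
    to build the null; p = (b+1)/(m+1) one-tailed. Pairs where both
    populations are singletons are skipped (NaN) with a warning.
    """
    if dm.model != "raw":
        raise ValueError("pairwise Fst expects the raw difference-count matrix")
    pops = np.array([pm.population(s) for s in dm.ids])
    labels = sorted(np.unique(pops))
    P = len(labels)
    fst = np.zeros((P, P))
    pvals = np.ones((P, P))
    rng = np.random.default_rng(seed)
    for i in range(P):
        for j in range(i + 1, P):
            ia = np.where(pops == labels[i])[0]
            ib = np.where(pops == labels[j])[0]
            if len(ia) == 1 and len(ib) == 1:
                warnings.warn(
                    f"populations {labels[i]}/{labels[j]} are both singletons: skipped"
                )
                fst[i, j] = fst[j, i] = np.nan
                pvals[i, j] = pvals[j, i] = np.nan
                continue
            idx = np.concatenate([ia, ib])
            sub = dm.d[np.ix_(idx, idx)]
            lab = np.array([0] * len(ia) + [1] * len(ib))
            obs = two_population_fst(sub, lab)
            fst[i, j] = fst[j, i] = obs
            if n_perm > 0:
                ge = 0
                for _ in range(n_perm):
                    f = two_population_fst(sub, lab[rng.permutation(len(lab))])
                    if np.isnan(obs) or (not np.isnan(f) and f >= obs):
                        ge += 1
                pvals[i, j] = pvals[j, i] = (ge + 1) / (n_perm + 1)
    return PairwiseFstMatrix(labels, fst, pvals)


def amova_report(results: list[AmovaResult], path) -> None:
    """TSV table: one row per grouping scheme, Table-2-style columns."""
    with open(path, "w") as fh:
        fh.write(
            "scheme\tPhi_ST\tPhi_SC\tPhi_CT\tp_ST\tp_SC\tp_CT\t"
            "pct_among_groups\tpct_among_pops_within\tpct_within_pops\t"
            "sigma2_a\tsigma2_b\tsigma2_c\n"
        )
        for r in results:
            fmt = lambda x: "NA" if x is None or not np.isfinite(x) else f"{x:.4g}"
            fh.write(
                "\t".join(
                    [r.scheme, fmt(r.Phi_ST), fmt(r.Phi_SC), fmt(r.Phi_CT),
                     fmt(r.p_ST), fmt(r.p_SC), fmt(r.p_CT),
                     fmt(r.pct_a), fmt(r.pct_b), fmt(r.pct_c),
                     fmt(r.sigma2_a), fmt(r.sigma2_b), fmt(r.sigma2_c)]
                ) + "\n"
            )
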