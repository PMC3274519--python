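"""Molecular-diversity summaries: haplotype diversity, nucleotide diversity,
segregating sites, and mean pairwise differences."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import (
    Alignment,
    PopulationMap,
    classify_sites,
    collapse_haplotypes,
    distance_matrix,
    _MISSING,
)


@dataclass
class DiversitySummary:
    n: int
    n_haplotypes: int
    Hd: float
    pi: float
    S: int
    k_bar: float


def diversity_summary(aln: Alignment) -> DiversitySummary:
    """Standard diversity statistics for a sample of aligned sequences.

    Hd is the unbiased estimator (n/(n-1))(1 - sum p_i^2) over haplotype
    relative frequencies. pi averages per-pair (raw differences / comparable
    sites) with pairwise deletion; k_bar averages raw difference counts;
    S counts variable sites.
    """
    if aln.n < 2:
        raise ValueError("diversity summary requires n >= 2 sequences")
    haps = collapse_haplotypes(aln)
    p = haps.frequencies()
    n = aln.n
    Hd = (n / (n - 1)) * (1.0 - float(np.sum(p**2)))
    Hd = max(Hd, 0.0)

    enc = aln.encoded()
    ok = enc != _MISSING
    diffs = []
    per_site = []
    for i in range(n):
        both = ok[i] & ok[i + 1 :]
        diff = (both & (enc[i] != enc[i + 1 :])).sum(axis=1)
        comp = both.sum(axis=1)
        diffs.extend(diff.tolist())
        per_site.extend((d / c if c else 0.0) for d, c in zip(diff, comp))
    k_bar = float(np.mean(diffs))
    pi = float(np.mean(per_site))

    if haps.n_haplotypes >= 2:
        S = classify_sites(haps).variable_sites
    else:
        S = 0
    return DiversitySummary(n=n, n_haplotypes=haps.n_haplotypes, Hd=Hd, pi=pi, S=S, k_bar=k_bar)


def diversity_report(aln: Alignment, pm: PopulationMap, path=None, by: str = "group"):
    """Per-population/group plus total diversity table; optionally written as TSV.

    Units with fewer than 2 samples are skipped (the estimators are undefined).
    Returns a list of (label, DiversitySummary) rows.
    """
    if by not in ("population", "group"):
        raise ValueError("by must be 'population' or 'group'")
    pm.validate_against(aln)
    labels = {}
    for sid in aln.ids:
        key = pm.population(sid) if by == "population" else pm.group_of_sample(sid)
        labels.setdefault(key, []).append(sid)
    rows = []
    for label in sorted(labels):
        if len(labels[label]) >= 2:
            rows.append((label, diversity_summary(aln.subset(labels[label]))))
    rows.append(("total", diversity_summary(aln)))
    if path is not None:
        with open(path, "w") as fh:
            fh.write("unit\tn\tn_haplotypes\tHd\tpi\tS\tk_bar\n")
            for label, s in rows:
                fh.write(
                    f"{label}\t{s.n}\t{s.n_haplotypes}\t{s.Hd:.6g}\t"
                    f"{s.pi:.6g}\t{s.S}\t{s.k_bar:.6g}\n"
                )
    return rows
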