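# mitopop

Population-genetic analysis of mitochondrial sequence alignments —
haplotype networks, hierarchical AMOVA, and mismatch-distribution
demography for single-locus phylogeography.

`mitopop` is aimed at researchers analysing intraspecific surveys of a
maternally inherited marker (typically cytochrome *b* or the mtDNA
control region): tens to hundreds of aligned sequences, a sample →
population map, and a population → clade/region grouping. It implements
the complete downstream chain such a study runs after alignment, as one
tested, scriptable package:

- **Haplotypes and sites** — exact-match haplotype collapsing with
  per-population counts; conserved/variable/singleton/parsimony-informative
  site classification; transition/transversion tallies.
- **Distances** — Kimura 2-parameter distances with pairwise deletion,
  d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), where P and Q are the transition
  and transversion proportions; raw difference counts; between-group means.
- **Diversity** — haplotype diversity Hd = n(1 − Σp²)/(n − 1), nucleotide
  diversity π, segregating sites S, mean pairwise differences k̄.
- **Median-joining networks** — the Bandelt–Forster–Röhl construction with
  class-weighted distances (transversions weighted 5:1 by default),
  quasi-median insertion, and maximum-parsimony (Steiner) pruning; GraphML,
  DOT and TSV export.
- **Structure** — three-level AMOVA (Φ\_ST, Φ\_SC, Φ\_CT with variance
  percentages) and pairwise distance-based Fst, both with seeded
  permutation tests.
- **Demography** — mismatch-distribution fit of the sudden-expansion model
  (τ, θ₀, θ₁; SSD and Harpending's raggedness tested by parametric
  bootstrap), Fu's Fs via the Ewens sampling formula with exact Stirling
  numbers, the Ramos-Onsins & Rozas R2 statistic with a fixed-S coalescent
  null, and expansion dating t = τ/(2u) with a substitution rate calibrated
  from a dated clade divergence.
- **Simulation** — a coalescent generator (constant size, sudden expansion,
  two-deme split; finite-sites mutation with transition bias) that powers
  the null distributions, bootstraps, and a fully synthetic study-like
  dataset, so every stage is testable offline.

## Worked example

Generate the bundled synthetic survey (198 sequences of 1,140 bp in 51
populations, four subclades from two deep clades, each recently expanded)
and run the main stages:

```python
import mitopop as mp
from mitopop import coalsim, structure, demography

aln, pm = coalsim.make_study_like_dataset(seed=0)
haps = mp.collapse_haplotypes(aln, pm)
div = mp.diversity_summary(aln)
print(haps.n_haplotypes, round(div.Hd, 3), round(div.pi, 4))
# 180 0.999 0.0195

dm = mp.distance_matrix(aln, "raw")
scheme = structure.GroupingScheme("subclades", dict(pm.pop_to_group))
r = structure.amova(dm, pm, scheme, n_perm=999, seed=0)
print(round(r.Phi_ST, 3), round(r.Phi_CT, 3), r.p_CT)
# 0.719 0.72 0.001

w1 = aln.subset([s for s in aln.ids if pm.group_of_sample(s) == "W1"])
fit = demography.fit_sudden_expansion(
    demography.mismatch_histogram(w1), w1.n, seed=0, n_boot=200)
cal = demography.RateCalibration(0.031, 620_000.0, L=1140, generation_time=1.0)
t, ci = demography.date_expansion(fit.tau, cal, fit.tau_CI)
print(round(fit.tau, 3), demography.years_to_mya(t))
# 4.559 0.04
```

Read: 180 of 198 sequences are distinct haplotypes (Hd ≈ 0.999) while
per-site diversity stays low (π ≈ 0.0195) — the classic signature of a
large, recently expanded mitochondrial population. AMOVA places ~72% of
the molecular variance among subclades (Φ\_CT = 0.72, permutation
p ≈ 0.001). The W1 subclade's mismatch distribution fits a sudden
expansion at τ ≈ 4.6 mutational units which, under a rate calibrated
from a 3.1% between-clade K2P distance dated at 0.62 Mya, corresponds to
an expansion roughly 0.040 Mya ago.

The same pipeline runs from the shell:

```sh
mitopop simulate --model study --seed 0 --out-prefix demo
mitopop diversity demo.fasta demo.popmap.tsv
mitopop amova demo.fasta demo.popmap.tsv --permutations 999 --seed 0
mitopop date-expansion --tau 4.389 --calibration 0.031:0.62:1140:1
# 0.039 Mya
```

or end-to-end from a YAML config (`mitopop run config.yaml`), writing
diversity/AMOVA/Fst/demography tables, a GraphML network, and a seeded,
timed run log.

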