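# Methods

This note records the models implemented in `mitopop`, the estimator and
algorithm choices made where conventions differ between tools, and the
limits of what the simulation-based tests demonstrate.

## Data model and site handling

The unit of analysis is an equal-length nucleotide alignment with unique
sample ids, a sample → population map, and a population → group map
(groups are clades, subclades, or geographic regions). Sequences are
upper-cased on input; IUPAC ambiguity codes and gaps are retained but
never counted as states.

Two deletion policies are used consistently throughout:

- **Pairwise deletion** for all distance-type quantities (K2P, raw
  difference counts, π): a site enters a pair's comparison only when both
  sequences carry an unambiguous base there.
- **Column exclusion** for site classification: columns with no
  unambiguous base at all are excluded from conserved/variable counts and
  logged.

Haplotype identity is exact string equality over all sites, so sequences
containing ambiguity codes collapse only with identical records. This is
the strictest reading; tools that treat N as a wildcard will merge more
aggressively and report fewer haplotypes on low-quality data.

Substitution-class tallies classify, per variable site, every unordered
pair of distinct observed bases as a transition or transversion. For
two-state sites this is the obvious assignment; for multi-state sites it
is parsimony-free and deterministic. Both ts/tv and tv/ts are reported;
the headline field is ts/tv, which in mitochondrial protein-coding data
is expected to be well above 1.

## Distances

K2P: d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q) over comparable sites. When a
log argument is non-positive the correction is saturated; the distance is
returned as NaN with a `SaturationWarning` rather than clamped, so
downstream code must decide how to treat saturated pairs. AMOVA and Fst
use raw difference counts (the common default for haplotype-level
analyses of closely related sequences), not K2P: at the within-species
distances involved the correction is nearly linear and the count-based
variance decomposition is the reproducible convention.

## Diversity

Hd uses the unbiased estimator (n/(n−1))(1 − Σp²) over haplotype
frequencies. π averages per-pair (differences / comparable sites); k̄
averages raw counts, so k̄ = π·L exactly only without missing data. S
counts variable sites under the column rules above.

## Median-joining networks

Variable positions are extracted and distances weighted per site class:
transitions 1, transversions 5 by default, mirroring the rarity of
transversions in mitochondrial data (a realized ts:tv near 5:1). The
construction follows the Bandelt–Forster–Röhl iteration:

1. Build the ε-relaxed minimum spanning network: edge (u,v) is kept when
   w(u,v) ≤ T(u,v) + ε, with T the minimax connection weight from
   Kruskal merging. At ε = 0 this is exactly the union of all minimum
   spanning trees.
2. For every linked triplet (a node with two current neighbours),
   generate quasi-medians: per-site majority state, expanding three-way
   ties into all three states (capped at 3⁶ combinations per triplet).
3. Insert candidate medians whose connection cost λ is within ε of the
   round's minimum **and** whose inclusion does not increase the
   parsimony (minimum-spanning) cost of the node set by more than ε. The
   second condition makes network cost non-increasing across rounds and
   guarantees termination; MST(V ∪ {m}) is evaluated incrementally from
   MST(V) plus the candidate's edges.
4. Iterate to fixpoint (a configurable round cap raises an error rather
   than looping), then remove obsolete medians: inferred nodes of degree
   ≤ 1, or degree-2 nodes lying cost-neutrally on a geodesic between
   their neighbours.

Maximum-parsimony pruning keeps only nodes and links that lie on some
minimum-cost spanning subgraph connecting all observed haplotypes. With
at most 12 medians (and ≤ 30 nodes) every median subset is scored
exactly; larger networks fall back to greedy elimination. The retained
graph is the union of all minimum spanning trees over each optimal node
set. All tie-breaks (equal-weight edges, equal-cost medians) are
lexicographic, so output is deterministic.

The exact-Steiner oracle used in tests is a Dreyfus–Wagner dynamic
program over the full candidate space (every combination of observed
states per variable site). On coalescent-generated haplotype sets the
pruned network attains the Steiner optimum in every tested instance; on
adversarial random sequence sets (no genealogical structure) the
median-joining heuristic can exceed it — Steiner minimality is NP-hard
and the algorithm is, by design, a genealogy-oriented heuristic.

## AMOVA and Fst

Sums of squares come from the pairwise difference matrix
(SS of a partition = Σ pairs within / partition size), degrees of freedom
G−1, P−G, N−P, and variance components from equating mean squares to
their expectations with the standard unequal-size coefficients n₁, n₂,
n₃. Φ\_ST = (σ²a+σ²b)/σ²total, Φ\_SC = σ²b/(σ²b+σ²c), Φ\_CT = σ²a/σ²total.
Negative components are reported as computed — they signal absent
structure at a level, and clamping them would bias the percentages.
With one population per group the among-populations level vanishes and
Φ\_ST = Φ\_CT to machine precision.

Permutation schemes per level: Φ\_ST, individuals among populations
anywhere; Φ\_SC, individuals among populations within their group;
Φ\_CT, whole populations among groups (preserving the number of
populations per group). p = (b+1)/(m+1), one-tailed on the observed
statistic; permutation counts are configurable (10⁴ is typical for final
analyses; tests use reduced counts). Pairwise Fst is the two-population
Φ\_ST with individuals permuted between the pair; pairs of two singleton
populations are skipped with a warning. An Fst ≥ 0.25 is flagged in the
TSV export as conventionally indicating strongly restricted gene flow.

## Mismatch distribution and the sudden-expansion model

The observed spectrum is the relative frequency of pairwise difference
counts. The sudden-expansion expectation uses the exact transient for a
stepwise size change θ₀ → θ₁ at mutational time τ:

F_i = F̂_i(θ₁) + e^{−τ(θ₁+1)/θ₁} Σ_{j≤i} (τ^j/j!) [F̂_{i−j}(θ₀) − F̂_{i−j}(θ₁)],

with F̂_i(θ) = θ^i/(θ+1)^{i+1}. The (θ₁+1)/θ₁ factor in the exponent is
the pair's probability of escaping coalescence during the recent epoch;
dropping it (the large-θ₁ approximation often quoted) produces negative
probabilities at small θ₁. Tail mass beyond the last observed class is
folded into it so expectations are proper distributions.

Fitting minimizes SSD = Σ(obs − exp)² by a coarse grid over (τ, θ₀, θ₁)
followed by Nelder–Mead in a square-root parametrization that enforces
τ, θ₀ ≥ 0 and θ₀ ≤ θ₁ ≤ 10⁵ (the cap encodes the near-infinite
post-expansion θ convention). Harpending's raggedness rg = Σ(f_{i+1}−f_i)²
is computed on the observed spectrum. p(SSD) and p(rg) come from a
parametric bootstrap: coalescent samples simulated under the fitted
expansion, each refitted (seeded from the observed solution plus the
grid), p = fraction of simulated statistics ≥ observed, (b+1)/(m+1)
corrected. The τ confidence interval is the bootstrap 2.5–97.5 percentile
range; 1,000 replicates by default, reducible for exploratory runs.

## Neutrality tests

**Fu's Fs.** θ̂ = k̄ (mean pairwise differences). The probability of
observing at least the sampled number of alleles comes from the Ewens
sampling formula, Pr(K=k) = |s(n,k)| θ^k / θ^{(n)}, with unsigned Stirling
numbers of the first kind computed exactly by big-integer recurrence and
converted to logs only at the end (stable to n = 200 and beyond);
S′ = Pr(K ≥ k_obs) and Fs = ln(S′/(1−S′)), with saturation (S′ ∈ {0,1})
flagged. The null simulates constant-size samples at θ̂, recomputing Fs
from each simulated sample's own k̄ and haplotype count;
p = fraction ≤ observed.

**R2.** U_i counts sites where sequence i carries a base of sample
frequency exactly 1 (minority convention — no outgroup polarization, so a
binary site contributes at derived count 1 or n−1); R2 =
√(mean_i (U_i − k̄/2)²)/S. The null fixes the observed S and simulates
constant-size genealogies with exactly S mutations placed proportionally
to branch length.

Calibration: under matched (infinite-sites) null data both tests'
p-values are uniform to Kolmogorov–Smirnov tolerance in the package's own
experiments. Applied to finite-sites data with recurrent mutation, Fu's
Fs drifts mildly liberal because multiple hits depress the haplotype
count and k̄ relative to the infinite-sites null — a property of the
statistic's standard usage, worth remembering at marginal significance.

## Expansion dating

The substitution rate is calibrated internally from a dated clade
divergence: μ = D_K2P/(2T) per site per lineage per year, u = 2μL per
sequence per generation (L sites, generation time in years), and
t = τ/(2u) generations. With the calibration used throughout the examples
(D = 0.031, T = 0.62 Mya, L = 1,140, one-year generations), u = 5.7×10⁻⁵
and τ = 4.389 maps to 0.039 Mya. The conversion is linear in τ, so CI
bounds transform identically. Reported to three decimals in Mya.

## Coalescent simulator

Times are kept in mutational units end to end: with j lineages and scaled
rate θ(t), coalescence occurs at rate j(j−1)/θ, so a constant-θ pair has
expected difference θ and E[S] = θΣ1/i — no absolute N ever enters.
Sudden expansion places the size change at depth τ/2 (pair distance τ);
the two-deme model runs a structured coalescent with optional migration
until the split time, then merges. Mutation is finite-sites over L
positions: Poisson(branch length) events, uniform site choice, transition
with odds κ:1 (default κ = 5.33), both transversion targets equiprobable.
`fixed_S` places exactly S events multinomially by branch length, leaving
topology untouched. An infinite-sites mode (every event a new column)
serves the neutrality-test nulls and bootstraps.

`make_study_like_dataset` grafts four expansion genealogies
(n = 94/24/30/50, τ = 6.0/8.2/4.4/12.3, θ₁ = 400) onto a two-level clade
tree with join depths 10.8/9.1/17.7 mutational units — chosen so that
between-clade K2P distances over 1,140 sites land near 1.9%/1.6%/3.1% —
and scatters samples over ~50 populations of 1–15 individuals. It is a
synthetic stand-in shaped like a real mitochondrial survey of a montane
rodent, not a reconstruction of any particular dataset.

What the simulator does *not* emulate: sequencing error, ambiguity codes
and alignment gaps (real data exercise the missing-data paths; synthetic
data are clean), recombination (appropriate for mtDNA), selection, and
spatially explicit expansion. Tests passing on synthetic data therefore
demonstrate the estimators' internal correctness and calibration under
the stated models, not robustness to artifacts of real sequence data.

## Numerical and design choices

- Permutation/bootstrap p-values always use the (b+1)/(m+1) correction,
  so p ∈ (0,1] and never exactly zero.
- All stochastic procedures take explicit integer seeds; identical seeds
  give byte-identical outputs on a given platform.
- Degenerate inputs fail loudly: monomorphic samples make Fs/R2/AMOVA Φ
  undefined and are flagged or raised, never silently zeroed.
- The sudden-expansion fit flags single-class histograms as degenerate
  instead of optimizing.
- Default reduced replicate counts (10²–10³) keep desk runs fast;
  final analyses should raise permutations/bootstraps to 10⁴.

## Known limitations

- Median-joining is a heuristic; Steiner optimality is verified only on
  genealogy-like inputs (see above).
- The AMOVA distance is fixed to difference counts; a squared-K2P option
  would change Φ values slightly on deeper divergences.
- Mismatch-model CIs are percentile bootstrap; coverage is verified at
  ~95% nominal under the model but, as with the original estimator, τ is
  upward-noisy for small samples.
- Fu's Fs p-values inherit the statistic's finite-sites liberality noted
  above.
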