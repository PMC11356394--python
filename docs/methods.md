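# Methods

This note documents the models and estimators implemented in `mitopop`, the
conventions chosen where the underlying methods literature leaves freedom, and
what the synthetic-data generator does and does not emulate.

## Coordinates, harmonization and site classes

All positions are 1-based coordinates of the donkey reference mitogenome
(DRS, GenBank NC_001788.1); the default analysis window is the 274-bp
hypervariable-I fragment at positions 15476–15749. `trim_to_window` maps
alignment columns to DRS coordinates along a designated reference row
(columns where the reference carries a gap have no coordinate and are
dropped); when the alignment is a fragment shorter than the window start, the
reference's first base is anchored at the window start. `drop_indel_columns`
then removes every column containing a gap in any row, so downstream code
operates on a gapless fixed-width matrix. Both operations are idempotent.

Site classes: a column is *variable* with ≥ 2 distinct unambiguous bases and
*parsimony-informative* when ≥ 2 bases each occur ≥ 2 times; N and IUPAC
ambiguity codes are treated as missing when classifying (the common behaviour
of sequence-polymorphism software). Multi-allelic columns contribute k−1
substitutions, each classified as transition or transversion against the
column's majority base (ties broken alphabetically). The majority-anchored
rule is a documented convention — the substitution-counting rule for
multi-allelic sites is not uniquely fixed by the summary counts it must
reproduce — and is isolated in `alignment.classify_column`.

## Haplogroup classification

Haplogroups are defined by diagnostic motifs: lists of (position, expected
base) states supplied as configuration. The two clades' core haplotypes
differ at 11 positions (15654, 15590, 15579, 15599, 15645, 15699, 15484,
15490, 15503, 15667, 15625); position 15669, which some sources print in
place of 15667, is accepted as an alias. For each haplogroup the match
fraction is computed over informative motif positions (retained in the
alignment and non-N in the haplotype). Label rules:

- exactly one haplogroup completely matched, no other reaching the partial
  floor (default 0.5) → that haplogroup;
- two or more haplogroups at or above the partial floor — whether or not one
  of them is complete — → `intermediate` (the chimeric-motif situation seen
  in rare variants carrying one clade's diagnostic triplet together with most
  of the other's);
- otherwise → `unassigned`.

Meaningful intermediate detection requires per-haplogroup motifs over
*disjoint* position sets (e.g. the two clade-diagnostic triplets
15484/15490/15503 and 15599/15645/15667): if both motifs cover the same
positions with conflicting states, two match fractions ≥ 0.5 are
arithmetically impossible. Sub-haplogroups (B1/B2) are supported through the
same mechanism in coding-region scope. Haplotype names are the haplogroup
prefix plus the zero-padded descending-frequency rank, ties broken by the
lexicographically smaller sequence; intermediate and unassigned haplotypes
share the prefix `U`.

## Diversity estimators

Haplotype diversity is Nei's unbiased `h = N/(N−1)·(1 − Σ (c_i/N)²)` —
equivalently the probability that two individuals drawn without replacement
differ — reported as missing for monomorphic samples or N < 2. Nucleotide
diversity is `π = N/(N−1)·Σ_{i<j} 2 f_i f_j d_ij / L`. By default `d_ij`
counts differences over sites where both sequences are non-N (*pairwise
deletion*) while the denominator stays the fixed number of retained sites L,
so N-bearing records do not deflate diversity asymmetrically; a
`complete_deletion` switch restricts all comparisons to universally non-N
columns and shrinks L accordingly. Values are rounded to 3 decimals only at
report time.

## Mismatch distributions and the sudden-expansion model

The observed mismatch distribution is the normalized histogram of pairwise
differences over all sample pairs (haplotype counts expanded, so
same-haplotype pairs contribute zeros). The sudden-expansion model assumes a
population at mutation-scaled size θ₀ that changed instantaneously to θ₁ at
τ = 2ut mutational units before present. The expected distribution is the
Poisson mixture of the two-epoch pairwise coalescence density; with the
default θ₁ = ∞ it reduces to

    F_i(τ, θ₀) = Σ_{j≤i} Pois(j; τ) · θ₀^{i−j}/(1+θ₀)^{i−j+1},

whose mean is τ + θ₀. For finite θ₁ the recent epoch contributes
`∫₀^τ Pois(i; x) e^{−x/θ₁}/θ₁ dx`, evaluated with the regularized incomplete
gamma function, and the ancestral term is damped by `e^{−τ/θ₁}`. Model mass
beyond the observed maximum difference is folded into the last bin.

Fitting minimizes the sum of squared deviations (SSD) between observed and
expected frequencies with Nelder–Mead from four moment-based starts
(mean ≈ τ + θ₀), parameters folded back to their domain. Goodness of fit uses
a parametric bootstrap: samples of the same size are re-simulated under the
fitted model with the coalescent simulator below, refitted, and
`P(SSD)`/`P(HRI)` are the fractions of simulated statistics at least as large
as the observed ones, with the (b+1)/(B+1) convention; the τ confidence
interval is the 2.5–97.5 percentile range of refitted τ values, widened if
necessary to contain the point estimate. The default replicate count is
1000; the pipeline default is 200, chosen as a routine-analysis compromise
between Monte-Carlo error (≈ ±0.03 on a P-value) and runtime. Harpending's
raggedness is `r = Σ (x_i − x_{i−1})²` with zero-padding on both ends, so a
point mass at 0 scores r = 2.

Degenerate observations with all mass at zero return a trivial fit τ = 0.
Observed distributions must carry their sample size for the bootstrap.

## Fu's Fs

`S′ = Pr(K ≥ k_obs | θ = π̂)` is computed exactly from the Ewens sampling
distribution `Pr(K = k) = |s(N,k)| θ^k / Π_{i<N}(θ+i)`, with unsigned
Stirling numbers of the first kind built by exact integer recurrence and
converted to logs, and both tails evaluated by log-sum-exp so that
`Fs = ln S′ − ln(1−S′)` suffers no cancellation. `k_obs = 1` or π̂ = 0 make
the statistic undefined (NaN, reported as missing). The P-value is the
fraction of constant-size neutral coalescent simulations at θ = π̂ whose Fs
is ≤ the observed value; following the statistic's source, significance is
conventionally claimed at P < 0.02 (reported, not enforced).

## Expansion-time conversion

`t_years = τ / (2 μ L)` with the per-site yearly rate μ = 6.13×10⁻⁸ and
L = 274 sites by default; the per-generation rate u = μ·g·L and generation
interval g (default 8 years) are carried for reporting, but g cancels in the
calendar estimate. All constants are arguments.

## AMOVA

Pairwise difference counts enter as squared Euclidean distances (the
convention of the distance-based variance framework). Sums of squares come
from the distance partition `SS(block) = Σ_{pairs in block} d² / n_block`;
variance components from the expected mean squares with the standard
unbalanced-design coefficients n′, n″, n‴; Φ_ST, Φ_SC, Φ_CT follow. The exact
identity SS(total) = SS(among groups) + SS(among populations within groups) +
SS(within populations) holds on every input and is asserted in tests.
Negative components (possible in unbalanced designs) are reported as-is with
a warning, and percentages are taken over the raw total. Permutation schemes
per level: samples among populations anywhere (Φ_ST), samples among
populations within their group (Φ_SC), whole populations among groups
(Φ_CT); default 10000 permutations, (b+1)/(B+1) P-values.

## Median-joining networks

The construction iterates: (1) the ε-relaxed minimum spanning network over
the current node set — edge (u,v) of weight d is kept iff u and v are not
connected using only edges of weight < d − ε, ε = 0 giving the classic MSN;
(2) quasi-medians (majority state per segregating column, all resolutions of
three-way ties) of every connected triplet are proposed, and the candidate
that most reduces the total network length is added, to a fixpoint; (3)
median vectors of degree ≤ 2 lying on no shortest observed-pair connection
are removed. Position weights (config TSV, default all 1) let hypervariable
columns count less, the published use being reduction of spurious
cross-links; the specific modified weights used in the original analyses were
not published, so neutral defaults ship. All tie-breaks are lexicographic,
making the network a deterministic function of the haplotype set. The greedy
one-median-per-round variant is chosen over batch addition because it keeps
the "total length never increases" invariant trivially true and is
order-independent.

## Consensus calling and QC

Consensus from per-position A/C/G/T counts (assumed base-quality ≥ 20
filtered upstream): depth < 5 (or position absent) → N; else if the second
most frequent base reaches ≥ 0.15 of the passing depth → the two-base IUPAC
code (the ≥ convention implements "reached a frequency of 0.15"); else the
majority base. Exclusion thresholds are Tukey upper whiskers — the largest
observation ≤ Q3 + 1.5·IQR — of the per-metric distributions, with quartiles
by linear interpolation between order statistics; whiskers are
quartile-method-sensitive, so the method is pinned here and configurable.
Per-clade missing-data thresholds and a pooled heteroplasmy threshold mirror
the workflow in which missing counts differ significantly between clades but
heteroplasmy counts do not. Reference-choice effects are compared with the
two-sided Wilcoxon rank-sum (Mann–Whitney) test. Mapping, duplicate removal
and coordinate lift-over between references are out of scope: pileups arrive
already in their tagged reference's coordinates.

## Synthetic-data generator

The coalescent simulator works directly in mutational units: a pair of
lineages coalesces at rate 1/θ per unit time and each lineage mutates at rate
1/2, so a pair with common ancestor at time x carries Poisson(x) differences.
The sudden-expansion demography uses θ₁ for times < τ (θ₁ = ∞ meaning no
coalescence more recent than the expansion — a star phase) and θ₀ beyond;
mean pairwise difference is τ + θ₀ (verified against msprime at constant
size). Mutations are infinite-sites by default, each assigned a distinct free
column; when a genealogy carries more mutations than free columns the
generator resamples columns with replacement and flags finite-sites mode —
expected for full-size datasets, since 274 bp is short relative to worldwide
sample sizes (real hypervariable regions are themselves recurrently mutating).

The two-haplogroup generator draws a random founder, derives the second
founder by substituting the 11 diagnostic positions, and simulates one
expansion genealogy per haplogroup. Diagnostic columns are reserved from
mutation, so motif classification of simulated data is exact truth — real
data can carry back mutations at diagnostic positions (the intermediate
haplotype case), which the generator reproduces only via explicitly
constructed chimeras. Default conditions are the worldwide survey's: 13
regions with their observed sample sizes (N = 1392 total) and haplogroup-A
percentages; expansion parameters default to τ_A = 2.4, θ₀_A = 0.3 and
τ_B = 1.0, θ₀_B = 0.2, giving within-haplogroup mean pairwise differences of
≈ 2.7 and 1.2 — the deeper, more diverse A clade and the shallower,
single-core B clade seen in per-haplogroup nucleotide diversities of roughly
0.01 and 0.005 over 274 sites. Pileups get Poisson depth, symmetric
multinomial errors, configured heteroplasmic mixtures and forced-dropout
positions. All generators are deterministic given their seed, and truth
tables suffice to compute every downstream expected value without
re-simulation.

What passing tests on synthetic data do *not* show: robustness to alignment
errors, NUMT contamination, recurrent mutation at diagnostic sites,
non-stepwise demographies, or geographic sampling bias — none of which the
generator emulates.

## Problem sizes used in the automated checks

The simulation-based checks run at deliberately modest sizes chosen for
routine laptop execution: the τ-recovery study uses 100 replicates of N = 50
samples over L = 274 sites at τ = 3, θ₀ = 1; bootstrap and permutation
plumbing is exercised at tens of replicates, with the 1000/10000 defaults
reserved for real analyses; pipeline tests run on ~26–60-sample synthetic
datasets. The exhaustive oracles (Ewens summation, partition enumeration,
brute-force minimum spanning networks) cover N ≤ 8, where enumeration is
exact.

## Known limitations

- The mismatch fit's τ̂ is upward-biased at these sample sizes when θ₀ is
  near its boundary; the recovery study tracks median relative error ≈ 0.23.
- AMOVA permutation tests recompute the full decomposition per permutation
  (O(n²)); for thousands of samples with 10⁴ permutations, expect minutes.
- The median-joining search proposes quasi-medians greedily; for very dense,
  highly reticulate haplotype sets the candidate enumeration can grow, and
  `max_median_rounds` caps the effort.
- Finite-θ₁ fitting is available but weakly identified from mismatch data
  alone; the default keeps θ₁ = ∞ and reports τ as the headline parameter.
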