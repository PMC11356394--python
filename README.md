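# mitopop

Population-genetic analysis of mitochondrial control-region haplotypes, built
around the kind of worldwide mtDNA diversity survey used for livestock such as
the domestic donkey (*Equus asinus*): hundreds to thousands of short
hypervariable-region sequences, collected by country and geographical region,
that fall into two deeply divergent maternal haplogroups (A and B) whose core
haplotypes differ at 11 diagnostic positions of the reference mitogenome.

The package is for population geneticists who want the full analytic chain of
such a survey as tested, scriptable code rather than a sequence of GUI tools:

- **Harmonization** — trim an externally aligned FASTA to the 274-bp study
  window (reference positions 15476–15749), remove indel columns, summarize
  variable sites, parsimony-informative sites, transitions and transversions.
- **Haplotypes and haplogroups** — collapse identical sequences, assign stable
  frequency-ranked names (`A001`, `B001`, …), classify haplotypes by
  diagnostic-motif matching, with detection of chimeric/intermediate motifs.
- **Diversity** — Nei's unbiased haplotype diversity
  `h = N/(N−1)·(1 − Σ p_i²)` and nucleotide diversity
  `π = N/(N−1)·Σ_{i<j} 2 f_i f_j d_ij / L`, in per-region/per-country tables
  with per-haplogroup blocks and %A/%B.
- **Demography** — mismatch distributions; least-squares fit of the sudden
  population-expansion model (τ, θ₀, optionally θ₁) with SSD and Harpending's
  raggedness index assessed by parametric coalescent bootstrap; Fu's *Fs* from
  the exact Ewens sampling distribution with coalescent P-values; conversion
  of τ to calendar years via `t = τ/2u`.
- **AMOVA** — hierarchical analysis of molecular variance on pairwise
  difference counts, with Φ-statistics and per-level permutation tests.
- **Networks** — weighted median-joining networks with quasi-median vectors,
  regional projections on the global backbone, GraphML/TSV exports.
- **Consensus QC** — clade-aware consensus calling from per-position base
  counts (depth ≥ 5, IUPAC heteroplasmy calls at minor fraction ≥ 0.15),
  Tukey upper-whisker exclusion thresholds, and rank-sum comparison of
  reference-choice effects.
- **Synthetic data** — a coalescent generator (instantaneous-size-change
  n-coalescent, infinite sites with a flagged finite-sites fallback) that
  reproduces the two-haplogroup structure, regional skews and noisy pileups,
  with full truth tables.

## Worked example

```python
import mitopop as mp
from mitopop.simulate import SimConfig, simulate_two_haplogroup_dataset

cfg = SimConfig(n_per_region={"AFE": 24, "AFW": 20, "EUI": 16},
                haplogroup_fractions={"AFE": 60, "AFW": 90, "EUI": 25}, seed=7)
aln, truth = simulate_two_haplogroup_dataset(cfg)

table = mp.collapse_haplotypes(aln)
table, assignments = mp.name_haplotypes(
    table, mp.classify_table(table, truth["motifs"]))
print(mp.diversity_table(mp.summarize_groups(table, assignments)).to_string(index=False))
```

```
group  N  nh     h    pi  N_A  nh_A   h_A  pi_A  pct_A  N_B  nh_B    h_B   pi_B  pct_B
  AFE 24  16 0.924 0.026   14     9 0.835 0.006     58   10     7  0.867  0.005     42
  AFW 20  14 0.937 0.017   18    13 0.928 0.010     90    2     1      ⎯      ⎯     10
  EUI 16  10 0.825 0.022    4     4 1.000 0.013     25   12     6  0.682  0.004     75
  ALL 60  36 0.918 0.026   36    24 0.894 0.009     60   24    12  0.717  0.004     40
```

Each row mirrors the layout of a worldwide summary table: sample size `N`,
haplotype count `nh`, haplotype diversity `h`, nucleotide diversity `pi`, then
the same quartet restricted to each haplogroup and its percentage of the
group; `⎯` marks statistics undefined for monomorphic samples.

Fitting the sudden-expansion model to the haplogroup-A subset:

```python
entries = tuple(e for e in table.entries
                if {a.name: a.label for a in assignments}[e.name] == "A")
sub = mp.HaplotypeTable(entries, sum(e.total_count for e in entries),
                        table.groups, table.positions)
res = mp.SuddenExpansionModel.from_table(sub).fit(n_boot=200, seed=1)
print(res.summary())
```

```
  parameter      value
        tau   1.673736
     theta0   0.685160
 tau_ci_low   0.617775
tau_ci_high   3.202878
        SSD   0.000280
     P(SSD)   0.975124
        HRI   0.042439
     P(HRI)   0.766169
```

The non-significant SSD and raggedness (P ≫ 0.05) mean the observed mismatch
distribution is compatible with a sudden expansion; for the same subset Fu's
*Fs* = −25.08 (P = 0.002), the strong haplotype excess expected after
expansion, and `res.expansion_time()` converts τ to calendar years with the
default per-site rate 6.13×10⁻⁸/year over 274 sites.

A command-line interface mirrors the stages
(`mitopop simulate | harmonize | classify | qc | run`); `mitopop run
--config run.yaml` executes the whole pipeline and writes the report bundle
plus a reproducibility manifest.

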