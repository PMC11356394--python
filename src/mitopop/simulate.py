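"""Synthetic datasets with the statistical structure the analyses assume.

The generator emulates the worldwide control-region study design: two deeply
divergent haplogroups (founders separated at 11 diagnostic positions of the
274-bp window), star-like within-haplogroup expansion structure produced by a
sudden-expansion coalescent, regional sample sizes and haplogroup-frequency
skews configured per region, and noisy per-position pileups with heteroplasmic
and low-coverage positions for the consensus-QC stage.

Mutations follow the infinite-sites model by default; when a realized
genealogy carries more mutations than there are free columns (L = 274 is
short), the generator falls back to finite sites — columns resampled with
replacement — and flags the dataset accordingly.  Diagnostic columns are
reserved and never hit, so the configured motif classification is exact truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._coalescent import Genealogy, simulate_genealogy
from .alignment import WINDOW_END, WINDOW_START, AlignedSequenceSet, SequenceRecord
from .consensus import IUPAC2, PileupTable
from .errors import ConfigurationError, DomainError
from .haplotypes import DIAGNOSTIC_POSITIONS, MotifSet

#: Regional sample sizes of the worldwide control-region dataset (N = 1392).
DEFAULT_N_PER_REGION = {
    "AFE": 103, "AFN": 50, "AFS": 26, "AFW": 84, "AME": 27,
    "ASA": 26, "ASC": 125, "ASE": 293, "ASS": 22,
    "EUB": 172, "EUE": 28, "EUI": 347, "EUW": 89,
}

#: Regional haplogroup-A percentages of the same dataset.
DEFAULT_PCT_A = {
    "AFE": 61, "AFN": 28, "AFS": 19, "AFW": 92, "AME": 52,
    "ASA": 69, "ASC": 34, "ASE": 49, "ASS": 50,
    "EUB": 66, "EUE": 46, "EUI": 26, "EUW": 31,
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the two-haplogroup synthetic dataset.

    Expansion parameters are in mutational units per sequence; the defaults
    give within-haplogroup mean pairwise differences of about tau + theta0
    (more diverse haplogroup A, shallower haplogroup B), star-like genealogies
    in both, and the observed regional sizes and %A skews.
    """

    L: int = 274
    n_per_region: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_REGION))
    haplogroup_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PCT_A))
    founder_separation: tuple[int, ...] = DIAGNOSTIC_POSITIONS
    tau_A: float = 2.4
    theta0_A: float = 0.3
    tau_B: float = 1.0
    theta0_B: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for r, f in self.haplogroup_fractions.items():
            if not 0 <= f <= 100:
                raise ConfigurationError(f"%A for {r} outside [0, 100]")
        window = range(WINDOW_START, WINDOW_END + 1)
        if any(p not in window for p in self.founder_separation):
            raise ConfigurationError("founder separation positions outside window")


def _random_sequence(L: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=L))


def _mutate_base(base: str, rng: np.random.Generator) -> str:
    return rng.choice([b for b in "ACGT" if b != base])


@dataclass
class ExpansionTruth:
    """Truth record returned alongside each simulated expansion sample."""

    genealogy: Genealogy
    n_mutations: int
    finite_sites: bool
    founder: str


def _sequences_from_genealogy(gen: Genealogy, founder: str,
                              free_columns: Sequence[int],
                              rng: np.random.Generator) -> tuple[list[str], ExpansionTruth]:
    """Drop mutations on the tree and propagate sequences root-to-leaves."""
    n_nodes = len(gen.children)
    branch_muts = [rng.poisson(gen.branch_length(v) / 2.0) for v in range(n_nodes - 1)]
    total = int(sum(branch_muts))
    finite = total > len(free_columns)
    if finite:
        cols = rng.choice(free_columns, size=total, replace=True)
    else:
        cols = rng.choice(free_columns, size=total, replace=False)
    col_iter = iter(cols)

    seqs: dict[int, list[str]] = {gen.root: list(founder)}
    # parents always carry higher indices than their children
    order = range(n_nodes - 1, -1, -1)
    for v in order:
        if v == gen.root:
            continue
        parent_seq = seqs[gen.parent[v]]
        s = list(parent_seq)
        for _ in range(branch_muts[v]):
            c = int(next(col_iter))
            s[c] = _mutate_base(s[c], rng)
        seqs[v] = s
    leaves = ["".join(seqs[i]) for i in range(gen.n)]
    truth = ExpansionTruth(gen, total, finite, founder)
    return leaves, truth


def simulate_expansion_sample(n: int, L: int = 274, tau: float = 2.0,
                              theta0: float = 0.5, theta1: float = math.inf,
                              seed: int | None = None,
                              founder: str | None = None,
                              region: str = "AFE",
                              id_prefix: str = "sim") -> tuple[AlignedSequenceSet, ExpansionTruth]:
    """One sudden-expansion coalescent sample as an aligned sequence set.

    Returns the alignment (window coordinates starting at the study window)
    and the truth record (genealogy, mutation count, finite-sites flag).
    """
    if n < 2:
        raise DomainError("need n >= 2")
    rng = np.random.default_rng(seed)
    if founder is None:
        founder = _random_sequence(L, rng)
    gen = simulate_genealogy(n, theta0, tau, theta1, rng)
    leaves, truth = _sequences_from_genealogy(gen, founder, list(range(L)), rng)
    records = tuple(
        SequenceRecord(f"{id_prefix}{i + 1:04d}", s, country="", region=region,
                       population=region)
        for i, s in enumerate(leaves)
    )
    positions = tuple(range(WINDOW_START, WINDOW_START + L))
    aln = AlignedSequenceSet(records, WINDOW_START, WINDOW_START + L - 1, positions)
    return aln, truth


def simulate_two_haplogroup_dataset(cfg: SimConfig) -> tuple[AlignedSequenceSet, dict]:
    """Simulate the full two-haplogroup worldwide dataset.

    Returns the alignment and a truth bundle with per-sample haplogroup and
    region assignments, the founder sequences, the matching diagnostic
    ``MotifSet``, and the finite-sites flags.
    """
    rng = np.random.default_rng(cfg.seed)
    positions = tuple(range(WINDOW_START, WINDOW_START + cfg.L))
    pos_index = {p: i for i, p in enumerate(positions)}
    diag_cols = [pos_index[p] for p in cfg.founder_separation]
    free_cols = [i for i in range(cfg.L) if i not in set(diag_cols)]

    founder_b = _random_sequence(cfg.L, rng)
    founder_a = list(founder_b)
    for c in diag_cols:
        founder_a[c] = _mutate_base(founder_a[c], rng)
    founder_a = "".join(founder_a)

    motifs = MotifSet({
        "A": tuple((p, founder_a[pos_index[p]]) for p in cfg.founder_separation),
        "B": tuple((p, founder_b[pos_index[p]]) for p in cfg.founder_separation),
    })

    # per-region counts of each haplogroup (rounded toward configured %A)
    regions = sorted(cfg.n_per_region)
    n_a_per_region = {
        r: int(round(cfg.n_per_region[r] * cfg.haplogroup_fractions.get(r, 50) / 100.0))
        for r in regions
    }
    n_b_per_region = {r: cfg.n_per_region[r] - n_a_per_region[r] for r in regions}
    n_a, n_b = sum(n_a_per_region.values()), sum(n_b_per_region.values())

    samples: list[tuple[str, str, str]] = []  # (seq, haplogroup, region)
    truth_flags = {}
    for label, founder, n, tau, theta0, per_region in (
        ("A", founder_a, n_a, cfg.tau_A, cfg.theta0_A, n_a_per_region),
        ("B", founder_b, n_b, cfg.tau_B, cfg.theta0_B, n_b_per_region),
    ):
        if n == 0:
            truth_flags[label] = False
            continue
        if n == 1:
            leaves = [founder]
            truth_flags[label] = False
        else:
            gen = simulate_genealogy(n, theta0, tau, math.inf, rng)
            leaves, truth = _sequences_from_genealogy(gen, founder, free_cols, rng)
            truth_flags[label] = truth.finite_sites
        region_labels = [r for r in regions for _ in range(per_region[r])]
        for seq, r in zip(leaves, region_labels):
            samples.append((seq, label, r))

    records = []
    truth_rows = []
    for i, (seq, hg, r) in enumerate(samples):
        sid = f"syn{i + 1:04d}"
        records.append(SequenceRecord(sid, seq, country="", region=r, population=r))
        truth_rows.append({"seq_id": sid, "haplogroup": hg, "region": r, "bases": seq})
    aln = AlignedSequenceSet(tuple(records), WINDOW_START,
                             WINDOW_START + cfg.L - 1, positions)
    truth = {
        "table": pd.DataFrame(truth_rows),
        "motifs": motifs,
        "founders": {"A": founder_a, "B": founder_b},
        "finite_sites": truth_flags,
        "config": cfg,
    }
    return aln, truth


def simulate_pileup(true_seq: str, depth_mean: float = 50.0,
                    error_rate: float = 0.0,
                    het_positions: Sequence[tuple[int, float]] = (),
                    dropout_positions: Sequence[int] = (),
                    seed: int | None = None) -> PileupTable:
    """Noisy per-position base counts for one true sequence.

    Depth is Poisson(``depth_mean``) per position; counts are multinomial
    around the true base with symmetric ``error_rate``; positions listed in
    ``het_positions`` (1-based, with minor fraction in (0, 0.5]) mix the true
    base with a fixed alternative; ``dropout_positions`` are forced below the
    consensus depth threshold.
    """
    for _, frac in het_positions:
        if not 0 < frac <= 0.5:
            raise DomainError("heteroplasmy minor fractions must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    het = dict(het_positions)
    dropout = set(dropout_positions)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    positions, counts = [], []
    for pos in range(1, len(true_seq) + 1):
        depth = rng.poisson(depth_mean)
        if pos in dropout:
            depth = int(rng.integers(0, 5))  # below the default min_depth
        if depth == 0:
            continue
        true_base = true_seq[pos - 1]
        probs = np.full(4, error_rate / 3.0)
        probs[base_idx[true_base]] = 1.0 - error_rate
        if pos in het:
            minor_frac = het[pos]
            alt = "ACGT"[(base_idx[true_base] + 1) % 4]
            probs = np.full(4, error_rate / 3.0)
            probs[base_idx[true_base]] = (1.0 - minor_frac) * (1.0 - error_rate)
            probs[base_idx[alt]] = minor_frac * (1.0 - error_rate)
            probs /= probs.sum()
        row = rng.multinomial(depth, probs)
        positions.append(pos)
        counts.append(row)
    return PileupTable(np.array(positions, dtype=int), np.array(counts, dtype=int))
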