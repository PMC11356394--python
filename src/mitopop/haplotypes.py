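"""Haplotype collapsing, naming, haplogroup classification, and distances.

Worldwide donkey mtDNA control-region variation partitions into two deeply
divergent haplogroups (A and B) whose core haplotypes differ at 11 diagnostic
positions of the DRS.  Classification here is motif-based: each haplogroup is
defined by a set of (position, expected base) diagnostic states, and a
haplotype is assigned to the haplogroup whose motif it matches completely.
Haplotypes matching substantial parts of two motifs — as seen in a rare
variant carrying roughly half of each haplogroup's diagnostic states — are
flagged ``intermediate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignedSequenceSet
from .errors import (
    AlignmentError,
    AssignmentError,
    ConfigurationError,
    InsufficientDataError,
)

#: DRS positions separating the two haplogroup core haplotypes.
DIAGNOSTIC_POSITIONS = (
    15654, 15590, 15579, 15599, 15645, 15699,
    15484, 15490, 15503, 15667, 15625,
)

#: Diagnostic triplets highlighted for clade assignment; 15669 is accepted as
#: an alias of 15667 seen in some sources.
DIAGNOSTIC_TRIPLET_A = (15484, 15490, 15503)
DIAGNOSTIC_TRIPLET_B = (15599, 15645, 15667)
POSITION_ALIASES = {15669: 15667}


@dataclass(frozen=True)
class HaplotypeEntry:
    name: str
    bases: str
    total_count: int
    group_counts: Mapping[str, int]


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct haplotypes with global and per-group counts."""

    entries: tuple[HaplotypeEntry, ...]
    n_samples: int
    groups: tuple[str, ...]
    positions: tuple[int, ...] = ()

    def __post_init__(self):
        if sum(e.total_count for e in self.entries) != self.n_samples:
            raise AssignmentError("haplotype counts do not sum to n_samples")

    @property
    def n_haplotypes(self) -> int:
        return len(self.entries)

    def counts(self) -> list[int]:
        return [e.total_count for e in self.entries]

    def sequences(self) -> list[str]:
        return [e.bases for e in self.entries]

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"name": e.name, "total_count": e.total_count}
            row.update({g: e.group_counts.get(g, 0) for g in self.groups})
            row["bases"] = e.bases
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MotifSet:
    """Haplogroup -> diagnostic (DRS position, expected base) states."""

    motifs: Mapping[str, tuple[tuple[int, str], ...]]
    scope: str = "control-region"

    def __post_init__(self):
        if len(self.motifs) < 2:
            raise ConfigurationError("motif set needs at least two haplogroups")
        for hg, states in self.motifs.items():
            positions = [p for p, _ in states]
            if len(positions) != len(set(positions)):
                raise ConfigurationError(f"duplicate motif positions for {hg}")

    @property
    def labels(self) -> list[str]:
        return sorted(self.motifs)

    @classmethod
    def from_tsv(cls, path: str | Path, scope: str = "control-region") -> "MotifSet":
        df = pd.read_csv(path, sep="\t", dtype={"haplogroup": str, "position": int, "base": str})
        required = {"haplogroup", "position", "base"}
        if not required.issubset(df.columns):
            raise ConfigurationError(f"motif TSV needs columns {sorted(required)}")
        motifs: dict[str, list[tuple[int, str]]] = {}
        for _, row in df.iterrows():
            pos = POSITION_ALIASES.get(int(row["position"]), int(row["position"]))
            motifs.setdefault(row["haplogroup"], []).append((pos, row["base"].upper()))
        return cls({hg: tuple(v) for hg, v in motifs.items()}, scope=scope)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (hg, pos, base)
            for hg in sorted(self.motifs)
            for pos, base in self.motifs[hg]
        ]
        pd.DataFrame(rows, columns=["haplogroup", "position", "base"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class HaplogroupAssignment:
    name: str
    label: str  # A | B | B1 | B2 | intermediate | unassigned
    per_group_matches: Mapping[str, tuple[int, int]]  # label -> (n_match, n_informative)


def collapse_haplotypes(aln: AlignedSequenceSet, group_by: str = "region") -> HaplotypeTable:
    """Merge identical sequences into haplotypes with per-group counts.

    Sequences containing N merge only on exact string identity; no wildcard
    matching.  Provisional names ``H001..`` are assigned by descending count
    (ties broken by sequence) and are replaced by haplogroup-aware names in
    :func:`name_haplotypes`.
    """
    if aln.n_sequences == 0:
        raise InsufficientDataError("cannot collapse an empty alignment")
    if group_by not in ("region", "country", "population"):
        raise AssignmentError(f"unknown grouping field {group_by!r}")
    buckets: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    groups: list[str] = []
    for rec in aln.records:
        g = getattr(rec, group_by)
        if g not in groups:
            groups.append(g)
        totals[rec.bases] = totals.get(rec.bases, 0) + 1
        buckets.setdefault(rec.bases, {})
        buckets[rec.bases][g] = buckets[rec.bases].get(g, 0) + 1
    order = sorted(totals, key=lambda s: (-totals[s], s))
    entries = tuple(
        HaplotypeEntry(f"H{i + 1:03d}", seq, totals[seq], dict(buckets[seq]))
        for i, seq in enumerate(order)
    )
    return HaplotypeTable(entries, aln.n_sequences, tuple(sorted(groups)),
                          tuple(aln.retained_positions))


def classify_haplogroup(bases: str, aln_positions: Sequence[int], motifs: MotifSet,
                        complete_floor: float = 1.0,
                        partial_floor: float = 0.5,
                        name: str = "") -> HaplogroupAssignment:
    """Assign one haplotype to a haplogroup by diagnostic-motif matching.

    For each haplogroup the match fraction is computed over informative motif
    positions (present among the retained positions and non-N in the
    haplotype).  A haplogroup whose motif is matched completely (fraction >=
    ``complete_floor``) wins; when two haplogroups each reach
    ``partial_floor`` but neither is complete the haplotype is
    ``intermediate``; otherwise ``unassigned``.
    """
    if not motifs.motifs:
        raise ConfigurationError("empty motif set")
    pos_index = {p: i for i, p in enumerate(aln_positions)}
    matches: dict[str, tuple[int, int]] = {}
    for hg, states in motifs.motifs.items():
        n_match = n_inf = 0
        for pos, expected in states:
            i = pos_index.get(POSITION_ALIASES.get(pos, pos))
            if i is None:
                continue
            observed = bases[i]
            if observed == "N":
                continue
            n_inf += 1
            n_match += observed == expected.upper()
        matches[hg] = (n_match, n_inf)

    fractions = {
        hg: (m / n if n else 0.0) for hg, (m, n) in matches.items()
    }
    complete = [hg for hg in sorted(fractions)
                if matches[hg][1] > 0 and fractions[hg] >= complete_floor]
    partial = [hg for hg in sorted(fractions)
               if matches[hg][1] > 0 and fractions[hg] >= partial_floor]
    # An unambiguous complete match wins; substantial support for a second
    # haplogroup (as in a chimeric motif) demotes the call to intermediate.
    if len(complete) == 1 and len(partial) == 1:
        label = complete[0]
    elif len(partial) >= 2:
        label = "intermediate"
    else:
        label = "unassigned"
    return HaplogroupAssignment(name=name, label=label, per_group_matches=matches)


def classify_table(table: HaplotypeTable, motifs: MotifSet,
                   complete_floor: float = 1.0,
                   partial_floor: float = 0.5) -> list[HaplogroupAssignment]:
    """Classify every haplotype in a table (by its provisional name)."""
    return [
        classify_haplogroup(e.bases, table.positions, motifs,
                            complete_floor, partial_floor, name=e.name)
        for e in table.entries
    ]


def name_haplotypes(table: HaplotypeTable,
                    assignments: Sequence[HaplogroupAssignment]) -> tuple[HaplotypeTable, list[HaplogroupAssignment]]:
    """Assign stable haplogroup-prefixed names (A001, B001, ...).

    Within each haplogroup, names are the haplogroup prefix plus the
    zero-padded rank by descending total count, ties broken by the
    lexicographically smaller sequence.  Intermediate and unassigned
    haplotypes share the prefix ``U``.  Returns the renamed table and the
    renamed assignments in table order.
    """
    by_name = {a.name: a for a in assignments}
    missing = [e.name for e in table.entries if e.name not in by_name]
    if missing:
        raise AssignmentError(f"haplotypes without assignment: {missing}")

    prefix_of = {}
    for e in table.entries:
        label = by_name[e.name].label
        prefix_of[e.name] = "U" if label in ("intermediate", "unassigned") else label

    new_names: dict[str, str] = {}
    for prefix in sorted(set(prefix_of.values())):
        members = [e for e in table.entries if prefix_of[e.name] == prefix]
        members.sort(key=lambda e: (-e.total_count, e.bases))
        for rank, e in enumerate(members, start=1):
            new_names[e.name] = f"{prefix}{rank:03d}"

    entries = tuple(
        HaplotypeEntry(new_names[e.name], e.bases, e.total_count, e.group_counts)
        for e in table.entries
    )
    # keep entries sorted by name for stable downstream ordering
    entries = tuple(sorted(entries, key=lambda e: e.name))
    renamed = [
        HaplogroupAssignment(new_names[a.name], a.label, a.per_group_matches)
        for a in assignments
    ]
    renamed.sort(key=lambda a: a.name)
    new_table = HaplotypeTable(entries, table.n_samples, table.groups, table.positions)
    return new_table, renamed


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of (optionally position-weighted) difference counts."""

    names: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        if self.d.shape != (len(self.names), len(self.names)):
            raise AlignmentError("distance matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.names), columns=list(self.names))


def pairwise_distances(seq_a: str, seq_b: str,
                       weights: np.ndarray | None = None) -> float:
    """Weighted count of differing columns where both bases are informative."""
    if len(seq_a) != len(seq_b):
        raise AlignmentError("sequences of unequal length")
    total = 0.0
    for i, (a, b) in enumerate(zip(seq_a, seq_b)):
        if a != b and a != "N" and b != "N":
            total += 1.0 if weights is None else weights[i]
    return total


def pairwise_distance_matrix(table: HaplotypeTable,
                             weights: Mapping[int, float] | None = None) -> DistanceMatrix:
    """All-pairs distance matrix over the table's haplotypes.

    ``weights`` maps DRS positions to positive weights (default 1 per site);
    positions absent from the mapping keep weight 1.
    """
    seqs = table.sequences()
    n = len(seqs)
    if n and len({len(s) for s in seqs}) > 1:
        raise AlignmentError("haplotypes of unequal length")
    w = None
    if weights is not None:
        w = np.ones(len(table.positions))
        for i, pos in enumerate(table.positions):
            if pos in weights:
                w[i] = weights[pos]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distances(seqs[i], seqs[j], w)
    return DistanceMatrix(tuple(table.names()), d)


def expand_to_samples(table: HaplotypeTable, dist: DistanceMatrix) -> np.ndarray:
    """Expand a haplotype-level distance matrix to one row/column per sample."""
    idx = np.repeat(np.arange(table.n_haplotypes), table.counts())
    return dist.d[np.ix_(idx, idx)]


def read_weights_tsv(path: str | Path) -> dict[int, float]:
    """Read a position-weight configuration TSV (`position weight`)."""
    df = pd.read_csv(path, sep="\t")
    if not {"position", "weight"}.issubset(df.columns):
        raise ConfigurationError("weights TSV needs columns position, weight")
    if (df["weight"] <= 0).any():
        raise ConfigurationError("weights must be positive")
    return dict(zip(df["position"].astype(int), df["weight"].astype(float)))
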