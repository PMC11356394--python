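"""Haplotype and nucleotide diversity with per-group summary tables.

Both estimators are Nei's unbiased versions.  Haplotype diversity,

    h = N/(N-1) * (1 - sum_i p_i^2),

is the sample-size-corrected probability that two sequences drawn at random
differ; nucleotide diversity,

    pi = N/(N-1) * sum_{i<j} 2 f_i f_j d_ij / L,

is the corrected mean per-site pairwise difference.  Pairwise differences
``d_ij`` are counted over sites where both sequences are non-N (pairwise
deletion) while the denominator stays the fixed number of retained sites L,
so records containing N do not deflate diversity asymmetrically.  A
``complete_deletion`` switch instead restricts all pairs to columns that are
non-N in every sequence.  Groups with a single haplotype or fewer than two
sequences report missing values, rendered as the em-dash marker in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .haplotypes import HaplogroupAssignment, HaplotypeTable, pairwise_distances

MISSING = "⎯"  # horizontal-bar marker used for undefined statistics


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Nei's unbiased haplotype diversity from haplotype counts.

    Returns NaN when only one haplotype is present (undefined, reported as
    missing); raises for N < 2.
    """
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise InsufficientDataError(f"haplotype diversity needs N >= 2, got {n}")
    if len(counts) == 1:
        return math.nan
    freqs = [c / n for c in counts]
    return n / (n - 1) * (1.0 - sum(f * f for f in freqs))


def nucleotide_diversity(table: HaplotypeTable,
                         complete_deletion: bool = False) -> float:
    """Nei's unbiased nucleotide diversity (per site) from a haplotype table."""
    n = table.n_samples
    if n < 2:
        raise InsufficientDataError("nucleotide diversity needs N >= 2")
    seqs = table.sequences()
    length = len(seqs[0]) if seqs else 0
    if length == 0:
        raise InsufficientDataError("no retained positions")
    if complete_deletion:
        keep = [
            i for i in range(length) if all(s[i] != "N" for s in seqs)
        ]
        seqs = ["".join(s[i] for i in keep) for s in seqs]
        length = len(keep)
        if length == 0:
            raise InsufficientDataError("no columns survive complete deletion")
    counts = table.counts()
    total = 0.0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            fi = counts[i] / n
            fj = counts[j] / n
            total += 2.0 * fi * fj * pairwise_distances(seqs[i], seqs[j])
    return n / (n - 1) * total / length


@dataclass(frozen=True)
class DiversityRecord:
    """One row of the per-group summary: overall plus per-haplogroup blocks."""

    group: str
    N: int
    nh: int
    h: float            # NaN when undefined
    pi: float           # NaN when undefined
    by_haplogroup: Mapping[str, dict]  # label -> {N, nh, h, pi, pct}


def _subtable(table: HaplotypeTable, keep_names: set[str],
              group: str | None) -> HaplotypeTable:
    entries = []
    for e in table.entries:
        if e.name not in keep_names:
            continue
        count = e.total_count if group is None else e.group_counts.get(group, 0)
        if count > 0:
            entries.append(type(e)(e.name, e.bases, count,
                                   e.group_counts if group is None else {group: count}))
    return HaplotypeTable(tuple(entries), sum(e.total_count for e in entries),
                          table.groups if group is None else (group,),
                          table.positions)


def _metrics(sub: HaplotypeTable) -> dict:
    out = {"N": sub.n_samples, "nh": sub.n_haplotypes, "h": math.nan, "pi": math.nan}
    if sub.n_samples >= 2 and sub.n_haplotypes >= 2:
        out["h"] = haplotype_diversity(sub.counts())
        out["pi"] = nucleotide_diversity(sub)
    return out


def summarize_groups(table: HaplotypeTable,
                     assignments: Sequence[HaplogroupAssignment],
                     haplogroups: Sequence[str] = ("A", "B")) -> list[DiversityRecord]:
    """Per-group diversity summary with per-haplogroup sub-blocks.

    Groups are the table's grouping labels (regions or countries, as chosen at
    collapse time); an ``ALL`` record aggregating every sample is appended.
    Percentages (%A, %B, ...) are each haplogroup's share of the group's
    samples.
    """
    label_of = {a.name: a.label for a in assignments}
    records = []
    all_names = {e.name for e in table.entries}
    for group in list(table.groups) + [None]:
        sub_all = _subtable(table, all_names, group)
        overall = _metrics(sub_all)
        by_hg = {}
        for hg in haplogroups:
            names = {n for n, lab in label_of.items() if lab == hg}
            sub = _subtable(table, names, group)
            m = _metrics(sub)
            m["pct"] = 100.0 * sub.n_samples / sub_all.n_samples if sub_all.n_samples else math.nan
            by_hg[hg] = m
        records.append(DiversityRecord(
            group=group if group is not None else "ALL",
            N=overall["N"], nh=overall["nh"], h=overall["h"], pi=overall["pi"],
            by_haplogroup=by_hg,
        ))
    return records


def diversity_table(records: Sequence[DiversityRecord],
                    haplogroups: Sequence[str] = ("A", "B")) -> pd.DataFrame:
    """Render summary records as a report table (3-decimal rounding).

    Mirrors the worldwide summary layout: overall N/nh/h/pi columns followed
    by one block per haplogroup with its share of the group.
    """
    def fmt(x, nd=3):
        return MISSING if x is None or (isinstance(x, float) and math.isnan(x)) else round(x, nd)

    rows = []
    for r in records:
        row = {"group": r.group, "N": r.N, "nh": r.nh,
               "h": fmt(r.h), "pi": fmt(r.pi)}
        for hg in haplogroups:
            m = r.by_haplogroup.get(hg, {})
            row[f"N_{hg}"] = m.get("N", 0)
            row[f"nh_{hg}"] = m.get("nh", 0)
            row[f"h_{hg}"] = fmt(m.get("h", math.nan))
            row[f"pi_{hg}"] = fmt(m.get("pi", math.nan))
            pct = m.get("pct", math.nan)
            row[f"pct_{hg}"] = MISSING if math.isnan(pct) else round(pct)
        rows.append(row)
    return pd.DataFrame(rows)
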