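"""Clade-aware mitogenome consensus calling and quality-control filtering.

Consensus sequences are called from per-position base-count tables (already
base-quality filtered upstream): positions below the minimum depth become N,
positions where the second most frequent base reaches the heteroplasmy
fraction (0.15 of the passing depth) are encoded with the two-base IUPAC
ambiguity code, and all other positions take the majority base.  Because the
two mtDNA clades are deeply divergent, mapping a sample against a reference
from the other clade inflates both missing positions and apparent
heteroplasmies; per-clade exclusion thresholds are therefore derived from the
Tukey boxplot upper whisker of each metric's distribution, and paired
reference choices are compared with the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, InsufficientDataError, AssignmentError

#: IUPAC two-base ambiguity codes, keyed by the sorted base pair.
IUPAC2 = {
    ("A", "G"): "R", ("C", "T"): "Y", ("C", "G"): "S",
    ("A", "T"): "W", ("G", "T"): "K", ("A", "C"): "M",
}

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PileupTable:
    """Per-position A/C/G/T counts passing the base-quality filter."""

    positions: np.ndarray       # 1-based, sorted, unique
    counts: np.ndarray          # shape (n_positions, 4), order A C G T

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise FormatError("negative base counts")
        if np.any(np.diff(self.positions) <= 0):
            raise FormatError("pileup positions must be sorted and unique")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PileupTable":
        df = pd.read_csv(path, sep="\t")
        required = {"position", "A", "C", "G", "T"}
        if not required.issubset(df.columns):
            raise FormatError(f"pileup TSV needs columns {sorted(required)}")
        df = df.sort_values("position")
        return cls(df["position"].to_numpy(int),
                   df[list(BASES)].to_numpy(int))

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(self.counts, columns=list(BASES))
        out.insert(0, "position", self.positions)
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ConsensusSequence:
    seq_id: str
    bases: str
    reference_used: str = "DRS"

    @property
    def n_missing(self) -> int:
        return self.bases.count("N")

    @property
    def n_het(self) -> int:
        return sum(1 for b in self.bases if b in "RYSWKM")


def call_consensus(pileup: PileupTable, length: int, min_depth: int = 5,
                   het_frac: float = 0.15, seq_id: str = "consensus",
                   reference_used: str = "DRS") -> ConsensusSequence:
    """Call a consensus of ``length`` positions from a pileup table.

    Positions absent from the table or with depth below ``min_depth`` are N;
    a position whose second most frequent base reaches a fraction
    ``het_frac`` of the passing depth (>=, inclusive) gets the two-base IUPAC
    code; ties between the top two bases resolve to the ambiguity code too.
    """
    out = ["N"] * length
    depth = pileup.depth
    for row, pos in enumerate(pileup.positions):
        if pos < 1 or pos > length:
            continue
        d = depth[row]
        if d < min_depth:
            continue
        counts = pileup.counts[row]
        order = np.argsort(counts, kind="stable")[::-1]
        top, second = order[0], order[1]
        if counts[second] / d >= het_frac:
            pair = tuple(sorted((BASES[top], BASES[second])))
            out[pos - 1] = IUPAC2[pair]
        else:
            out[pos - 1] = BASES[top]
    return ConsensusSequence(seq_id, "".join(out), reference_used)


@dataclass(frozen=True)
class WhiskerDerivation:
    q1: float
    q3: float
    iqr: float
    upper_fence: float
    upper_whisker: float


def derive_threshold(values: Sequence[int | float]) -> WhiskerDerivation:
    """Tukey boxplot upper whisker of a metric distribution.

    Quartiles use linear interpolation between order statistics; the whisker
    is the largest observation not exceeding Q3 + 1.5 * IQR.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        raise InsufficientDataError("need >= 4 values to derive a whisker threshold")
    q1, q3 = np.percentile(vals, [25, 75], method="linear")
    iqr = q3 - q1
    fence = q3 + 1.5 * iqr
    whisker = float(vals[vals <= fence].max())
    return WhiskerDerivation(float(q1), float(q3), float(iqr), float(fence), whisker)


@dataclass(frozen=True)
class QCThresholds:
    """Per-clade exclusion limits for missing positions and heteroplasmies."""

    max_missing: Mapping[str, float]
    max_het: Mapping[str, float]
    derivation: Mapping[str, WhiskerDerivation] | None = None

    @classmethod
    def from_distributions(cls, missing_by_clade: Mapping[str, Sequence[int]],
                           het_all: Sequence[int]) -> "QCThresholds":
        """Derive thresholds: per-clade whisker for missing positions, one
        pooled whisker for heteroplasmies (their reference-choice difference
        being non-significant)."""
        derivation = {}
        max_missing = {}
        for clade, vals in missing_by_clade.items():
            d = derive_threshold(vals)
            derivation[f"missing_{clade}"] = d
            max_missing[clade] = d.upper_whisker
        dh = derive_threshold(het_all)
        derivation["het"] = dh
        max_het = {clade: dh.upper_whisker for clade in missing_by_clade}
        return cls(max_missing, max_het, derivation)


def filter_sequences(consensuses: Sequence[ConsensusSequence],
                     clade_of: Mapping[str, str],
                     thresholds: QCThresholds) -> tuple[list[ConsensusSequence], pd.DataFrame]:
    """Apply per-clade missing/heteroplasmy thresholds.

    Returns the retained sequences and a per-sequence QC report with the
    exclusion reason(s) for dropped ones.
    """
    retained = []
    rows = []
    for cons in consensuses:
        if cons.seq_id not in clade_of:
            raise AssignmentError(f"no clade assignment for {cons.seq_id!r}")
        clade = clade_of[cons.seq_id]
        if clade not in thresholds.max_missing:
            raise AssignmentError(f"no thresholds for clade {clade!r}")
        reasons = []
        if cons.n_missing > thresholds.max_missing[clade]:
            reasons.append(
                f"missing {cons.n_missing} > {thresholds.max_missing[clade]:g}")
        if cons.n_het > thresholds.max_het[clade]:
            reasons.append(f"het {cons.n_het} > {thresholds.max_het[clade]:g}")
        keep = not reasons
        if keep:
            retained.append(cons)
        rows.append({
            "seq_id": cons.seq_id, "clade": clade,
            "n_missing": cons.n_missing, "n_het": cons.n_het,
            "retained": keep, "reason": "; ".join(reasons),
        })
    return retained, pd.DataFrame(rows)


def compare_reference_effects(metrics_ref_a: Mapping[str, Sequence[float]],
                              metrics_ref_b: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Rank-sum comparison of QC metrics under two mapping references.

    ``metrics_ref_a`` / ``metrics_ref_b`` map metric names (e.g. "missing",
    "het") to per-sample values obtained with each reference.  Reports the
    two-sided Wilcoxon rank-sum (Mann-Whitney) P-value, medians and the
    median difference per metric.
    """
    rows = []
    for metric in metrics_ref_a:
        a = np.asarray(metrics_ref_a[metric], dtype=float)
        b = np.asarray(metrics_ref_b[metric], dtype=float)
        if a.size == 0 or b.size == 0:
            raise InsufficientDataError(f"empty metric list for {metric!r}")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        rows.append({
            "metric": metric,
            "median_ref_a": float(np.median(a)),
            "median_ref_b": float(np.median(b)),
            "delta_median": float(np.median(a) - np.median(b)),
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
        })
    return pd.DataFrame(rows)
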