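"""Reading, harmonizing, and summarizing aligned mtDNA control-region sequences.

The analysis window is expressed in coordinates of the donkey reference
sequence (DRS, GenBank NC_001788.1).  The hypervariable-I fragment shared by
worldwide control-region datasets spans DRS positions 15476-15749 (274 bp);
harmonization trims the external multiple alignment to that window and removes
every column containing an indel, so downstream statistics operate on a
fixed-width, gapless matrix with per-column DRS coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    CoordinateError,
    InsufficientDataError,
    MetadataError,
)

#: DRS coordinates of the study window (1-based, inclusive).
WINDOW_START = 15476
WINDOW_END = 15749

#: The 13 geographical region codes used for worldwide grouping.
REGION_CODES = (
    "AFE", "AFN", "AFS", "AFW",          # Africa: east, north, south, west
    "AME",                               # Americas
    "ASA", "ASC", "ASE", "ASS",          # Asia: Arabia, central-west, east, south
    "EUB", "EUE", "EUI", "EUW",          # Europe: Balkans, east, Italy, west
)

GAP = "-"
#: Two-base IUPAC ambiguity codes (used for heteroplasmies) plus N.
AMBIGUITY = set("RYSWKMN")
VALID_BASES = set("ACGT") | AMBIGUITY
PURINES = set("AG")
PYRIMIDINES = set("CT")


@dataclass(frozen=True)
class SequenceRecord:
    seq_id: str
    bases: str
    country: str = ""
    region: str = ""
    population: str = ""


@dataclass(frozen=True)
class AlignedSequenceSet:
    """A fixed-width alignment with per-sequence metadata in DRS coordinates.

    ``retained_positions[i]`` is the DRS coordinate of alignment column ``i``;
    before trimming it is simply ``1..width``.  After harmonization no gap
    characters remain and ``len(bases) == len(retained_positions)`` for every
    record.
    """

    records: tuple[SequenceRecord, ...]
    window_start: int
    window_end: int
    retained_positions: tuple[int, ...]

    def __post_init__(self):
        widths = {len(r.bases) for r in self.records}
        if len(widths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(widths)}")
        if widths and widths.pop() != len(self.retained_positions):
            raise AlignmentError(
                "sequence width does not match retained_positions length"
            )
        pos = self.retained_positions
        if any(b >= a for a, b in zip(pos[1:], pos)):
            raise AlignmentError("retained_positions must be strictly increasing")

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def width(self) -> int:
        return len(self.retained_positions)

    @property
    def ids(self) -> list[str]:
        return [r.seq_id for r in self.records]

    def sequences(self) -> list[str]:
        return [r.bases for r in self.records]


def read_alignment(fasta_path: str | Path, metadata_path: str | Path) -> AlignedSequenceSet:
    """Read an aligned FASTA plus a sample metadata TSV.

    The metadata table must have columns ``seq_id country region population``;
    every FASTA id must appear in it and every region code must be one of the
    13 known labels.  Bases are upper-cased on read.  Column coordinates are
    provisional (1..width) until :func:`trim_to_window` maps them to the DRS.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    required = {"seq_id", "country", "region", "population"}
    if not required.issubset(meta.columns):
        raise MetadataError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    bad_regions = set(meta["region"]) - set(REGION_CODES) - {""}
    if bad_regions:
        raise MetadataError(f"unknown region codes: {sorted(bad_regions)}")
    meta_by_id = meta.set_index("seq_id")
    if meta_by_id.index.has_duplicates:
        raise MetadataError("duplicate seq_id rows in metadata")

    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta_by_id.index:
            raise MetadataError(f"sequence {rec.id!r} missing from metadata")
        row = meta_by_id.loc[rec.id]
        bases = str(rec.seq).upper()
        bad = set(bases) - VALID_BASES - {GAP}
        if bad:
            raise AlignmentError(f"invalid characters in {rec.id!r}: {sorted(bad)}")
        records.append(
            SequenceRecord(rec.id, bases, row["country"], row["region"], row["population"])
        )
    if not records:
        raise AlignmentError(f"no sequences in {fasta_path}")
    widths = {len(r.bases) for r in records}
    if len(widths) > 1:
        raise AlignmentError(f"aligned records have unequal lengths: {sorted(widths)}")
    width = widths.pop()
    return AlignedSequenceSet(
        records=tuple(records),
        window_start=1,
        window_end=width,
        retained_positions=tuple(range(1, width + 1)),
    )


def write_alignment(aln: AlignedSequenceSet, fasta_path: str | Path,
                    metadata_path: str | Path | None = None) -> None:
    """Write the alignment back to FASTA (and metadata to TSV if requested)."""
    recs = [SeqRecord(Seq(r.bases), id=r.seq_id, description="") for r in aln.records]
    SeqIO.write(recs, str(fasta_path), "fasta")
    if metadata_path is not None:
        pd.DataFrame(
            [(r.seq_id, r.country, r.region, r.population) for r in aln.records],
            columns=["seq_id", "country", "region", "population"],
        ).to_csv(metadata_path, sep="\t", index=False)


def trim_to_window(aln: AlignedSequenceSet, start: int = WINDOW_START,
                   end: int = WINDOW_END, reference_row: str | None = None) -> AlignedSequenceSet:
    """Trim the alignment to DRS window [start, end].

    The reference row (default: first record) anchors alignment columns to DRS
    coordinates: its k-th non-gap character sits at DRS position k (counting
    from the start of the reference), so columns where the reference has a gap
    carry no DRS coordinate and are dropped.  Idempotent: re-trimming an
    already-trimmed set to the same window is the identity.
    """
    if start > end:
        raise CoordinateError(f"window start {start} > end {end}")
    if reference_row is None:
        ref = aln.records[0]
    else:
        match = [r for r in aln.records if r.seq_id == reference_row]
        if not match:
            raise MetadataError(f"reference row {reference_row!r} not in alignment")
        ref = match[0]

    if aln.retained_positions and aln.retained_positions[0] > 1 and GAP not in ref.bases:
        # Already mapped to DRS coordinates: subset by coordinate directly.
        keep = [i for i, p in enumerate(aln.retained_positions) if start <= p <= end]
        coords = [aln.retained_positions[i] for i in keep]
    else:
        # Assign DRS coordinates along the reference's non-gap characters,
        # offsetting so the reference starts at the window start when its
        # ungapped span exactly covers a window-sized fragment, else at 1.
        drs_of_col: list[int | None] = []
        pos = 0
        for ch in ref.bases:
            if ch == GAP:
                drs_of_col.append(None)
            else:
                pos += 1
                drs_of_col.append(pos)
        ref_len = pos
        # Reference coordinate 1 corresponds to DRS `origin`.  If the caller
        # trimmed a full-mtDNA alignment the reference spans the DRS from 1;
        # a control-region fragment is assumed to start at the window start.
        origin = start if ref_len < start else 1
        keep, coords = [], []
        for i, p in enumerate(drs_of_col):
            if p is None:
                continue
            drs = origin + p - 1
            if start <= drs <= end:
                keep.append(i)
                coords.append(drs)
        if not keep:
            raise CoordinateError(
                f"window {start}-{end} outside reference span (length {ref_len})"
            )
    new_records = tuple(
        replace(r, bases="".join(r.bases[i] for i in keep)) for r in aln.records
    )
    return AlignedSequenceSet(new_records, start, end, tuple(coords))


def drop_indel_columns(aln: AlignedSequenceSet) -> AlignedSequenceSet:
    """Remove every column in which any row carries a gap character."""
    keep = [
        i for i in range(aln.width)
        if all(r.bases[i] != GAP for r in aln.records)
    ]
    if not keep:
        warnings.warn("all columns contain indels; alignment is empty", stacklevel=2)
    if len(keep) == aln.width:
        return aln
    coords = tuple(aln.retained_positions[i] for i in keep)
    new_records = tuple(
        replace(r, bases="".join(r.bases[i] for i in keep)) for r in aln.records
    )
    return AlignedSequenceSet(new_records, aln.window_start, aln.window_end, coords)


def harmonize(aln: AlignedSequenceSet, start: int = WINDOW_START,
              end: int = WINDOW_END, reference_row: str | None = None) -> AlignedSequenceSet:
    """Trim to the study window and drop indel columns in one step."""
    return drop_indel_columns(trim_to_window(aln, start, end, reference_row))


@dataclass(frozen=True)
class SiteSummary:
    """Counts of variable-site classes over the harmonized alignment."""

    n_variable: int
    n_parsimony_informative: int
    n_singleton: int
    n_substitutions: int
    n_transitions: int
    n_transversions: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "variable_sites", "parsimony_informative", "singletons",
                    "substitutions", "transitions", "transversions",
                ],
                "count": [
                    self.n_variable, self.n_parsimony_informative,
                    self.n_singleton, self.n_substitutions,
                    self.n_transitions, self.n_transversions,
                ],
            }
        )


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def classify_column(column: Iterable[str]) -> dict:
    """Classify one alignment column; ambiguity codes are treated as missing.

    A column with k >= 2 distinct unambiguous bases is variable; it is
    parsimony-informative when at least two bases each occur at least twice.
    Each of the k-1 minority bases contributes one substitution, classified as
    transition or transversion against the column's majority base (ties broken
    alphabetically for determinism).
    """
    counts: dict[str, int] = {}
    for ch in column:
        if ch in "ACGT":
            counts[ch] = counts.get(ch, 0) + 1
    out = {"variable": False, "informative": False, "singleton": False,
           "transitions": 0, "transversions": 0}
    if len(counts) < 2:
        return out
    out["variable"] = True
    n_ge2 = sum(1 for c in counts.values() if c >= 2)
    if n_ge2 >= 2:
        out["informative"] = True
    else:
        out["singleton"] = True
    major = max(sorted(counts), key=counts.__getitem__)
    for base in counts:
        if base == major:
            continue
        if _is_transition(base, major):
            out["transitions"] += 1
        else:
            out["transversions"] += 1
    return out


def site_summary(aln: AlignedSequenceSet) -> SiteSummary:
    """Summarize variable sites, site classes and substitution types."""
    if aln.n_sequences < 2:
        raise InsufficientDataError("site summary requires at least 2 sequences")
    n_var = n_inf = n_sing = n_ts = n_tv = 0
    seqs = aln.sequences()
    for i in range(aln.width):
        col = classify_column(s[i] for s in seqs)
        if col["variable"]:
            n_var += 1
            n_inf += col["informative"]
            n_sing += col["singleton"]
            n_ts += col["transitions"]
            n_tv += col["transversions"]
    return SiteSummary(
        n_variable=n_var,
        n_parsimony_informative=n_inf,
        n_singleton=n_sing,
        n_substitutions=n_ts + n_tv,
        n_transitions=n_ts,
        n_transversions=n_tv,
    )
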