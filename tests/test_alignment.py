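"""Alignment harmonization: reading, window trimming, indel removal, site classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitopop.alignment import (WINDOW_END, WINDOW_START, classify_column,
                               drop_indel_columns, harmonize, read_alignment,
                               site_summary, trim_to_window, write_alignment)
from mitopop.errors import (AlignmentError, InsufficientDataError,
                            MetadataError)

from conftest import make_alignment


def write_inputs(tmp_path, fasta_records, metadata_rows):
    fasta = tmp_path / "aln.fasta"
    fasta.write_text("".join(f">{i}\n{s}\n" for i, s in fasta_records))
    meta = tmp_path / "meta.tsv"
    lines = ["seq_id\tcountry\tregion\tpopulation"]
    lines += ["\t".join(r) for r in metadata_rows]
    meta.write_text("\n".join(lines) + "\n")
    return fasta, meta


class TestReadAlignment:
    def test_round_trip(self, tmp_path):
        seqs = [("a", "ACGTACGTAC"), ("b", "ACGTACGTAA"), ("c", "ACGTACGGAC")]
        fasta, meta = write_inputs(
            tmp_path, seqs, [(i, "Kenya", "AFE", "pop1") for i, _ in seqs])
        aln = read_alignment(fasta, meta)
        assert aln.n_sequences == 3
        assert aln.width == 10
        out_fa = tmp_path / "out.fasta"
        out_meta = tmp_path / "out_meta.tsv"
        write_alignment(aln, out_fa, out_meta)
        again = read_alignment(out_fa, out_meta)
        assert again.sequences() == aln.sequences()
        assert again.ids == aln.ids
        assert again.retained_positions == aln.retained_positions

    def test_mixed_case_uppercased(self, tmp_path):
        fasta, meta = write_inputs(tmp_path, [("a", "acgTt"), ("b", "ACGTT")],
                                   [("a", "", "AFE", "p"), ("b", "", "AFE", "p")])
        aln = read_alignment(fasta, meta)
        assert aln.sequences() == ["ACGTT", "ACGTT"]

    def test_missing_metadata_id_rejected(self, tmp_path):
        fasta, meta = write_inputs(tmp_path, [("a", "ACGT"), ("b", "ACGT")],
                                   [("a", "", "AFE", "p")])
        with pytest.raises(MetadataError, match="b"):
            read_alignment(fasta, meta)

    def test_unknown_region_rejected(self, tmp_path):
        fasta, meta = write_inputs(tmp_path, [("a", "ACGT")],
                                   [("a", "", "XXX", "p")])
        with pytest.raises(MetadataError, match="XXX"):
            read_alignment(fasta, meta)

    def test_unequal_lengths_rejected(self, tmp_path):
        fasta, meta = write_inputs(tmp_path, [("a", "ACGT"), ("b", "ACG")],
                                   [("a", "", "AFE", "p"), ("b", "", "AFE", "p")])
        with pytest.raises(AlignmentError):
            read_alignment(fasta, meta)


class TestTrimToWindow:
    def test_gapless_reference_full_window(self, make_aln):
        width = 300
        seqs = ["A" * width, "A" * width]
        aln = make_alignment(seqs, start=1)  # provisional coords 1..300
        # fragment convention: reference's first base anchors at window start
        trimmed = trim_to_window(aln, WINDOW_START, WINDOW_END)
        assert trimmed.width == 274
        assert trimmed.retained_positions[0] == WINDOW_START
        assert trimmed.retained_positions[-1] == WINDOW_END

    def test_start_equals_end(self, make_aln):
        aln = make_alignment(["ACGTA", "ACGTA"], start=1)
        trimmed = trim_to_window(aln, WINDOW_START, WINDOW_START)
        assert trimmed.width == 1

    def test_reference_gap_columns_dropped(self):
        # 276 columns, reference has 2 internal gaps -> those columns carry no
        # coordinate; remaining 274 map onto the window
        ref = "AC" + "-" + "G" * 135 + "-" + "T" * 137
        other = "AC" + "A" + "G" * 135 + "A" + "T" * 137
        assert len(ref) == 276
        aln = make_alignment([ref, other], start=1)
        trimmed = trim_to_window(aln, WINDOW_START, WINDOW_END)
        assert trimmed.width == 274
        assert "-" not in trimmed.sequences()[0]

    def test_idempotent(self):
        aln = make_alignment(["ACGT" * 70, "ACGT" * 70], start=1)
        once = trim_to_window(aln, WINDOW_START, WINDOW_END)
        twice = trim_to_window(once, WINDOW_START, WINDOW_END)
        assert twice.sequences() == once.sequences()
        assert twice.retained_positions == once.retained_positions


class TestDropIndelColumns:
    def test_no_gaps_identity(self, make_aln):
        aln = make_alignment(["ACGT", "ACGA"])
        assert drop_indel_columns(aln) is aln

    def test_single_gap_column_removed_for_all(self):
        seqs = ["AC-T", "ACGT", "ACGT"]
        aln = make_alignment(seqs)
        out = drop_indel_columns(aln)
        assert out.sequences() == ["ACT", "ACT", "ACT"]
        assert out.retained_positions == (WINDOW_START, WINDOW_START + 1,
                                          WINDOW_START + 3)

    def test_all_columns_gapped_warns(self):
        aln = make_alignment(["-A", "A-"])
        with pytest.warns(UserWarning, match="empty"):
            out = drop_indel_columns(aln)
        assert out.width == 0

    def test_idempotent(self):
        aln = make_alignment(["AC-T", "ACGT"])
        once = drop_indel_columns(aln)
        assert drop_indel_columns(once) is once


def brute_force_column(column):
    """Independent per-column classifier: literal transcription of the rules."""
    bases = [c for c in column if c in "ACGT"]
    distinct = sorted(set(bases))
    res = {"variable": len(distinct) >= 2, "informative": False,
           "singleton": False, "transitions": 0, "transversions": 0}
    if not res["variable"]:
        return res
    if sum(1 for b in distinct if bases.count(b) >= 2) >= 2:
        res["informative"] = True
    else:
        res["singleton"] = True
    counts = {b: bases.count(b) for b in distinct}
    best = max(counts.values())
    major = sorted(b for b in distinct if counts[b] == best)[0]
    for b in distinct:
        if b == major:
            continue
        ts = {frozenset("AG"), frozenset("CT")}
        if frozenset((b, major)) in ts:
            res["transitions"] += 1
        else:
            res["transversions"] += 1
    return res


class TestSiteSummary:
    def test_identical_sequences_all_zero(self):
        aln = make_alignment(["ACGT"] * 4)
        s = site_summary(aln)
        assert (s.n_variable, s.n_substitutions) == (0, 0)

    def test_two_state_informative_column(self):
        aln = make_alignment(["A", "A", "G", "G"])
        s = site_summary(aln)
        assert s.n_parsimony_informative == 1
        assert s.n_transitions == 1
        assert s.n_transversions == 0

    def test_triallelic_singleton_column(self):
        # {A, C, C, C, G}: variable, not informative; against majority C both
        # A and G are transversions
        aln = make_alignment(list("ACCCG"))
        s = site_summary(aln)
        assert s.n_variable == 1
        assert s.n_parsimony_informative == 0
        assert s.n_singleton == 1
        assert s.n_substitutions == 2
        assert s.n_transversions == 2

    def test_requires_two_sequences(self):
        with pytest.raises(InsufficientDataError):
            site_summary(make_alignment(["ACGT"]))

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.sampled_from("ACGTN"), min_size=2, max_size=12))
    def test_column_classifier_matches_brute_force(self, column):
        assert classify_column(column) == brute_force_column(column)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_identities_hold_on_random_alignments(self, seed):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list("ACGTN"), size=20, p=[.24, .24, .24, .24, .04]))
                for _ in range(rng.integers(2, 9))]
        s = site_summary(make_alignment(seqs))
        assert s.n_variable == s.n_parsimony_informative + s.n_singleton
        assert s.n_substitutions == s.n_transitions + s.n_transversions
        assert s.n_substitutions >= s.n_variable
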