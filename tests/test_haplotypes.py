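"""Haplotype collapsing, naming, motif classification, and distances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitopop.alignment import WINDOW_START
from mitopop.errors import AssignmentError, ConfigurationError
from mitopop.haplotypes import (DIAGNOSTIC_POSITIONS, HaplogroupAssignment,
                                MotifSet, classify_haplogroup, classify_table,
                                collapse_haplotypes, name_haplotypes,
                                pairwise_distance_matrix)

from conftest import make_alignment


class TestCollapse:
    def test_counts(self):
        aln = make_alignment(["AAAA", "AAAA", "AAAA", "CCCC", "CCCC"])
        t = collapse_haplotypes(aln)
        assert t.n_haplotypes == 2
        assert sorted(t.counts(), reverse=True) == [3, 2]
        assert t.n_samples == 5

    def test_group_counts_conserved(self):
        aln = make_alignment(
            ["AAAA", "AAAA", "CCCC", "CCCC", "CCCC"],
            regions=["AFE", "AFW", "AFE", "AFE", "AFW"])
        t = collapse_haplotypes(aln, group_by="region")
        for e in t.entries:
            assert sum(e.group_counts.values()) == e.total_count
        totals = {g: 0 for g in t.groups}
        for e in t.entries:
            for g, c in e.group_counts.items():
                totals[g] += c
        assert totals == {"AFE": 3, "AFW": 2}

    def test_n_sequences_collapse_exact_only(self):
        aln = make_alignment(["AANA", "AAAA", "AANA"])
        t = collapse_haplotypes(aln)
        assert t.n_haplotypes == 2
        assert sorted(t.counts(), reverse=True) == [2, 1]

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_collapse_expand_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list("ACG"), size=5))
                for _ in range(rng.integers(1, 12))]
        t = collapse_haplotypes(make_alignment(seqs))
        expanded = [e.bases for e in t.entries for _ in range(e.total_count)]
        assert sorted(expanded) == sorted(seqs)


def default_motifs():
    positions = DIAGNOSTIC_POSITIONS
    return MotifSet({
        "A": tuple((p, "A") for p in positions),
        "B": tuple((p, "G") for p in positions),
    })


def seq_with(states, width=274):
    """A window-wide sequence of 'C' with given {position: base} overrides."""
    s = ["C"] * width
    for pos, base in states.items():
        s[pos - WINDOW_START] = base
    return "".join(s)


class TestClassification:
    positions = tuple(range(WINDOW_START, WINDOW_START + 274))

    def test_complete_match_assigns_haplogroup(self):
        m = default_motifs()
        seq = seq_with({p: "A" for p in DIAGNOSTIC_POSITIONS})
        a = classify_haplogroup(seq, self.positions, m)
        assert a.label == "A"
        assert a.per_group_matches["A"] == (11, 11)

    def test_reference_like_sequence_is_b(self):
        m = default_motifs()
        seq = seq_with({p: "G" for p in DIAGNOSTIC_POSITIONS})
        assert classify_haplogroup(seq, self.positions, m).label == "B"

    def test_chimera_is_intermediate(self):
        # Disjoint triplet motifs (the clade-diagnostic position sets): a
        # chimera carrying the full A triplet plus most of the B triplet gets
        # substantial support for both haplogroups -> intermediate.
        m = MotifSet({
            "A": tuple((p, "A") for p in (15484, 15490, 15503)),
            "B": tuple((p, "G") for p in (15599, 15645, 15667)),
        })
        states = {15484: "A", 15490: "A", 15503: "A",
                  15599: "G", 15645: "G", 15667: "T"}
        a = classify_haplogroup(seq_with(states), self.positions, m)
        assert a.label == "intermediate"
        assert a.per_group_matches["A"] == (3, 3)
        assert a.per_group_matches["B"] == (2, 3)

    def test_no_match_unassigned(self):
        m = default_motifs()
        seq = seq_with({p: "T" for p in DIAGNOSTIC_POSITIONS})
        assert classify_haplogroup(seq, self.positions, m).label == "unassigned"

    def test_n_positions_uninformative(self):
        m = default_motifs()
        states = {p: "A" for p in DIAGNOSTIC_POSITIONS}
        states[15654] = "N"
        a = classify_haplogroup(seq_with(states), self.positions, m)
        assert a.label == "A"
        assert a.per_group_matches["A"] == (10, 10)

    def test_empty_motifs_rejected(self):
        with pytest.raises(ConfigurationError):
            MotifSet({})

    def test_independent_of_non_motif_positions(self):
        m = default_motifs()
        base = {p: "A" for p in DIAGNOSTIC_POSITIONS}
        s1 = seq_with(base)
        s2 = "T" + seq_with(base)[1:]  # change a non-motif column
        a1 = classify_haplogroup(s1, self.positions, m)
        a2 = classify_haplogroup(s2, self.positions, m)
        assert a1.label == a2.label == "A"


class TestNaming:
    def test_rank_by_frequency(self):
        aln = make_alignment(["AAAA"] * 10 + ["AATA"] * 3)
        t = collapse_haplotypes(aln)
        asg = [HaplogroupAssignment(e.name, "A", {}) for e in t.entries]
        t2, _ = name_haplotypes(t, asg)
        named = {e.bases: e.name for e in t2.entries}
        assert named["AAAA"] == "A001"
        assert named["AATA"] == "A002"

    def test_tie_broken_lexicographically(self):
        aln = make_alignment(["TTTT", "AAAA"])
        t = collapse_haplotypes(aln)
        asg = [HaplogroupAssignment(e.name, "B", {}) for e in t.entries]
        t2, _ = name_haplotypes(t, asg)
        named = {e.bases: e.name for e in t2.entries}
        assert named["AAAA"] == "B001"
        assert named["TTTT"] == "B002"

    def test_intermediate_gets_u_prefix(self):
        aln = make_alignment(["AAAA", "CCCC"])
        t = collapse_haplotypes(aln)
        labels = {"AAAA": "A", "CCCC": "intermediate"}
        asg = [HaplogroupAssignment(e.name, labels[e.bases], {}) for e in t.entries]
        t2, asg2 = name_haplotypes(t, asg)
        named = {e.bases: e.name for e in t2.entries}
        assert named["CCCC"] == "U001"

    def test_missing_assignment_rejected(self):
        t = collapse_haplotypes(make_alignment(["AAAA", "CCCC"]))
        with pytest.raises(AssignmentError):
            name_haplotypes(t, [])

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_stable_under_record_permutation(self, seed):
        rng = np.random.default_rng(seed)
        seqs = ["AAAA", "AAAA", "AATA", "GGGG", "GGGG", "GGGG", "GGTA"]
        perm = list(rng.permutation(len(seqs)))
        def names_for(order):
            aln = make_alignment([seqs[i] for i in order])
            t = collapse_haplotypes(aln)
            labels = {"AAAA": "A", "AATA": "A", "GGGG": "B", "GGTA": "B"}
            asg = [HaplogroupAssignment(e.name, labels[e.bases], {})
                   for e in t.entries]
            t2, _ = name_haplotypes(t, asg)
            return {e.bases: e.name for e in t2.entries}
        assert names_for(range(len(seqs))) == names_for(perm)


class TestDistances:
    def test_identical_zero(self):
        t = collapse_haplotypes(make_alignment(["AAAA", "AAAA"]))
        d = pairwise_distance_matrix(t)
        assert d.d.shape == (1, 1)
        assert d.d[0, 0] == 0

    def test_diagnostic_separation_is_eleven(self):
        a = seq_with({p: "A" for p in DIAGNOSTIC_POSITIONS})
        b = seq_with({p: "G" for p in DIAGNOSTIC_POSITIONS})
        t = collapse_haplotypes(make_alignment([a, b]))
        d = pairwise_distance_matrix(t)
        assert d.d[0, 1] == 11

    def test_n_sites_excluded(self):
        t = collapse_haplotypes(make_alignment(["ANAA", "AGCA"]))
        d = pairwise_distance_matrix(t)
        assert d.d[0, 1] == 1  # N column skipped, only the C/A mismatch counts

    def test_position_weights_applied(self):
        a = seq_with({15484: "A"})
        b = seq_with({15484: "G"})
        t = collapse_haplotypes(make_alignment([a, b]))
        d = pairwise_distance_matrix(t, weights={15484: 0.5})
        assert d.d[0, 1] == 0.5

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_matches_hamming_oracle_and_triangle(self, seed):
        rng = np.random.default_rng(seed)
        seqs = list({tuple(rng.choice(list("ACGT"), size=8)) for _ in range(3)})
        seqs = ["".join(s) for s in seqs]
        t = collapse_haplotypes(make_alignment(seqs))
        d = pairwise_distance_matrix(t)
        seq_of = {i: t.sequences()[i] for i in range(t.n_haplotypes)}
        for i, j in itertools.combinations(range(t.n_haplotypes), 2):
            hamming = sum(x != y for x, y in zip(seq_of[i], seq_of[j]))
            assert d.d[i, j] == hamming
        for i, j, k in itertools.permutations(range(t.n_haplotypes), 3):
            assert d.d[i, k] <= d.d[i, j] + d.d[j, k]
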