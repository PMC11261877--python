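"""Dereplication tests, including a pure-python dynamic-programming
oracle for the free-end-gap alignment that the package implements with
a banded numba kernel."""

import functools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrndb import derep

MATCH, MISMATCH, GAP = derep.MATCH_SCORE, derep.MISMATCH_SCORE, derep.GAP_SCORE


def oracle_align(a: str, b: str):
    """Independent recursive implementation of the same alignment:
    free terminal gaps, match +1 / mismatch -1 / gap -2, ties resolved
    diagonal > up > left. Returns the two gapped rows."""

    n, m = len(a), len(b)

    @functools.lru_cache(maxsize=None)
    def best(i, j):
        # optimal score of aligning a[:i] with b[:j]
        if i == 0 or j == 0:
            return 0  # leading gaps are free
        diag = best(i - 1, j - 1) + (MATCH if a[i - 1] == b[j - 1] else MISMATCH)
        up = best(i - 1, j) + (0 if j == m else GAP)
        left = best(i, j - 1) + (0 if i == n else GAP)
        return max(diag, up, left)

    rows_a, rows_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = best(i - 1, j - 1) + (MATCH if a[i - 1] == b[j - 1] else MISMATCH)
            up = best(i - 1, j) + (0 if j == m else GAP)
            left = best(i, j - 1) + (0 if i == n else GAP)
            top = max(diag, up, left)
            if diag == top:
                rows_a.append(a[i - 1]); rows_b.append(b[j - 1]); i -= 1; j -= 1
                continue
            if up == top:
                rows_a.append(a[i - 1]); rows_b.append("-"); i -= 1
                continue
            rows_a.append("-"); rows_b.append(b[j - 1]); j -= 1
        elif i > 0:
            rows_a.append(a[i - 1]); rows_b.append("-"); i -= 1
        else:
            rows_a.append("-"); rows_b.append(b[j - 1]); j -= 1
    return "".join(reversed(rows_a)), "".join(reversed(rows_b))


def oracle_identity(a: str, b: str) -> float:
    # same canonical argument order as the implementation's pinned rule
    if (len(b), b) < (len(a), a):
        a, b = b, a
    row_a, row_b = oracle_align(a, b)
    # trim terminal-gap columns of either row
    first = max(min(i for i, c in enumerate(row_a) if c != "-"),
                min(i for i, c in enumerate(row_b) if c != "-"))
    last = min(max(i for i, c in enumerate(row_a) if c != "-"),
               max(i for i, c in enumerate(row_b) if c != "-"))
    if last < first:
        return 0.0
    cols = range(first, last + 1)
    matches = sum(1 for k in cols if row_a[k] == row_b[k] and row_a[k] != "-")
    return 100.0 * matches / (last - first + 1)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert derep.pairwise_identity("ACGT" * 250, "ACGT" * 250) == 100.0

    def test_single_substitution_in_1000mer(self):
        a = "ACGT" * 250
        b = a[:500] + ("C" if a[500] != "C" else "G") + a[501:]
        assert derep.pairwise_identity(a, b) == pytest.approx(99.9)

    def test_one_mismatch_in_eight(self):
        assert derep.pairwise_identity("ACGTACGT", "ACGAACGT") == pytest.approx(87.5)

    def test_symmetry(self, rng):
        for _ in range(5):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, 55))
            assert derep.pairwise_identity(a, b) == pytest.approx(
                derep.pairwise_identity(b, a))

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            derep.pairwise_identity("", "ACGT")

    @given(st.data())
    @settings(deadline=None, max_examples=150)
    def test_agrees_with_dp_oracle_short(self, data):
        a = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=12))
        b = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=12))
        assert derep.pairwise_identity(a, b) == pytest.approx(oracle_identity(a, b))

    def test_agrees_with_dp_oracle_mutated_pairs(self, rng):
        # mutated/indel pairs up to 20 nt, where banding could matter
        for _ in range(50):
            n = int(rng.integers(8, 21))
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            b = list(a)
            for p in rng.choice(n, size=min(n, 2), replace=False):
                b[p] = "ACGT"[int(rng.integers(0, 4))]
            if rng.random() < 0.5 and len(b) > 3:
                del b[int(rng.integers(0, len(b)))]
            b = "".join(b)
            assert derep.pairwise_identity(a, b) == pytest.approx(
                oracle_identity(a, b))

    def test_banded_matches_unbanded_on_long_mutated_pairs(self, rng):
        # the edlib-sized band must not change results on realistic input
        for _ in range(3):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
            b = list(a)
            for p in rng.choice(3000, size=6, replace=False):
                b[p] = "ACGT"[int(rng.integers(0, 4))]
            del b[1500]
            b = "".join(b)
            banded = derep.pairwise_identity(a, b)
            ea, eb = derep._encode(a), derep._encode(b)
            _, trace = derep._nw_matrix(ea, eb, MATCH, MISMATCH, GAP,
                                        len(a) + len(b))
            # rebuild alignment from the unbanded trace
            i, j = len(a), len(b)
            ra, rb = [], []
            while i > 0 or j > 0:
                t = trace[i, j]
                if t == 0 and i > 0 and j > 0:
                    ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
                elif t == 1 and i > 0:
                    ra.append(a[i - 1]); rb.append("-"); i -= 1
                else:
                    ra.append("-"); rb.append(b[j - 1]); j -= 1
            unbanded = derep.identity_from_alignment(
                "".join(reversed(ra)), "".join(reversed(rb)))
            assert banded == pytest.approx(unbanded)


class TestSorting:
    def test_descending_length(self):
        seqs = [("a", "C" * 5), ("b", "C" * 9), ("c", "C" * 7)]
        assert [len(s) for _, s in derep.sort_by_length(seqs)] == [9, 7, 5]

    def test_ties_break_by_id(self):
        seqs = [("z", "AAAA"), ("a", "CCCC"), ("m", "GGGG")]
        assert [i for i, _ in derep.sort_by_length(seqs)] == ["a", "m", "z"]

    def test_empty(self):
        assert derep.sort_by_length([]) == []


def mutate(seq, n, rng):
    out = list(seq)
    for p in rng.choice(len(seq), size=n, replace=False):
        out[p] = [b for b in "ACGT" if b != out[p]][int(rng.integers(0, 3))]
    return "".join(out)


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        seqs = [("a", "ACGT" * 300), ("b", "ACGT" * 300), ("c", "ACGT" * 300)]
        clusters = derep.greedy_cluster(seqs)
        assert len(clusters) == 1
        assert clusters[0].size == 3

    def test_two_sequences_below_threshold_stay_separate(self, rng):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        b = mutate(a, 50, rng)  # 99.0 % identity
        assert derep.pairwise_identity(a, b) < 99.9
        clusters = derep.greedy_cluster([("a", a), ("b", b)], threshold=99.9)
        assert len(clusters) == 2

    def test_planted_centroids_recovered(self, rng):
        centroid = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
        mutants = [(f"m{i}", mutate(centroid, 1, rng)) for i in range(4)]
        outlier = ("out", mutate(centroid, 400, rng))
        clusters = derep.greedy_cluster(
            [("cen", centroid)] + mutants + [outlier], threshold=99.9)
        assert sorted(cl.size for cl in clusters) == [1, 5]

    def test_representative_is_longest_member(self, rng):
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        longer = base + "ACGT"
        clusters = derep.greedy_cluster([("short", base), ("long", longer)])
        assert clusters[0].representative_id == "long"

    def test_members_meet_threshold_to_representative(self, rng):
        seqs = [("s%d" % i,
                 mutate("".join("ACGT"[k] for k in rng.integers(0, 4, 2000)), 0, rng))
                for i in range(2)]
        base = seqs[0][1]
        seqs += [(f"m{i}", mutate(base, 1, rng)) for i in range(3)]
        clusters = derep.greedy_cluster(seqs, threshold=99.9)
        for cl in clusters:
            for mid, seq in seqs:
                if mid in cl.member_ids:
                    assert derep.pairwise_identity(
                        seq, cl.representative_seq) >= 99.9

    def test_threshold_100_groups_byte_identical_only(self, rng):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        b = mutate(a, 1, rng)
        clusters = derep.greedy_cluster(
            [("a1", a), ("a2", a), ("b", b)], threshold=100.0)
        sizes = {frozenset(cl.member_ids) for cl in clusters}
        assert sizes == {frozenset({"a1", "a2"}), frozenset({"b"})}


class TestAugment:
    def test_identical_new_sequence_absorbed(self, rng):
        rep = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        clusters = derep.augment_clusters([("rep1", rep)], [("new1", rep)])
        assert len(clusters) == 1
        assert set(clusters[0].member_ids) == {"rep1", "new1"}

    def test_divergent_new_sequence_founds_cluster(self, rng):
        rep = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        new = mutate(rep, 100, rng)  # 95 %
        clusters = derep.augment_clusters([("rep1", rep)], [("new1", new)])
        assert len(clusters) == 2

    def test_empty_new_seqs_is_identity(self, rng):
        rep = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        clusters = derep.augment_clusters([("rep1", rep)], [])
        assert len(clusters) == 1
        assert clusters[0].member_ids == ["rep1"]


class TestConsensus:
    def test_single_member_equals_member(self):
        assert derep.consensus_sequence(["ACGTACGT"]) == "ACGTACGT"

    def test_column_majority(self):
        assert derep.consensus_sequence(
            ["ACGT", "ACGT", "ACTT"], representative="ACGT") == "ACGT"

    def test_tie_breaks_by_fixed_base_order(self):
        # 50/50 G vs T in column 3
        assert derep.consensus_sequence(
            ["ACGT", "ACGT", "ACTT", "ACTT"], representative="ACGT") == "ACGT"
        assert derep.consensus_sequence(
            ["ACG", "ACT"], representative="ACG") == "ACG"

    def test_gap_majority_column_dropped(self):
        # two of three members lack the final base
        members = ["ACGTA", "ACGT", "ACGT"]
        assert derep.consensus_sequence(
            members, representative="ACGTA") == "ACGT"

    def test_identical_members_consensus_exact(self):
        members = ["ACGTACGTAA"] * 5
        assert derep.consensus_sequence(members) == "ACGTACGTAA"


class TestReduction:
    @pytest.mark.parametrize("n_full,n_nr,expected", [
        (291365, 103991, 64.3),
        (317986, 103293, 67.5),
        (100, 100, 0.0),
    ])
    def test_reduction_examples(self, n_full, n_nr, expected):
        assert derep.reduction_percent(n_full, n_nr) == expected

    def test_zero_input_is_error(self):
        with pytest.raises(ValueError):
            derep.reduction_percent(0, 0)
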