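"""Length-sorted greedy centroid clustering and non-redundant output.

The dereplication step collapses full-length rrn operon sequences at a
nucleotide-identity threshold (default 99.9 %). Sequences are sorted by
length (descending) so the longest member of every cluster is its
representative, scanned once, and each sequence either joins the
best-matching existing centroid at >= threshold identity or founds a new
cluster. A second phase can append sequences from incomplete assemblies
to the phase-1 representatives and re-cluster, so incomplete-assembly
sequences are only retained when they add diversity.

Identity definition
-------------------
Identity is computed from a global alignment with free terminal gaps
(match +1, mismatch -1, gap -2; terminal gaps unpenalised; traceback
prefers diagonal, then up, then left), as::

    identity = 100 * matching columns / alignment columns

where columns inside a terminal-gap run of either sequence are excluded
from both counts. Internal gap columns count as non-matching columns.
This formula is pinned here because the identity definition used by
general-purpose clustering tools is configuration-dependent; stating it
makes results reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import edlib
import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 99.9

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2

# Letters map to distinct codes so IUPAC/N compare as themselves.
_ALPHABET = "ACGTRYSWKMBDHVNU-"
_ENCODE = {c: i for i, c in enumerate(_ALPHABET)}


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_ENCODE[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character in sequence: {exc}") from None


_NEG_INF = np.int32(-(10 ** 9))


@njit(cache=True)
def _nw_matrix(a, b, match, mismatch, gap, band):  # pragma: no cover - jitted
    n, m = len(a), len(b)
    delta = m - n
    score = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int32)
    trace = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0=diag 1=up 2=left
    score[0, :] = 0  # free terminal gaps
    score[:, 0] = 0
    for i in range(1, n + 1):
        trace[i, 0] = 1
    for j in range(1, m + 1):
        trace[0, j] = 2
    lo_shift = delta if delta < 0 else 0
    hi_shift = delta if delta > 0 else 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        last_row = i == n
        lo = max(1, i + lo_shift - band)
        hi = min(m, i + hi_shift + band)
        for j in range(lo, hi + 1):
            diag = score[i - 1, j - 1] + (match if ai == b[j - 1] else mismatch)
            up = score[i - 1, j] + (0 if j == m else gap)
            left = score[i, j - 1] + (0 if last_row else gap)
            best = diag
            t = 0
            if up > best:
                best = up
                t = 1
            if left > best:
                best = left
                t = 2
            score[i, j] = best
            trace[i, j] = t
    return score, trace


def align(a: str, b: str) -> tuple[str, str]:
    """Globally align two sequences with free terminal gaps.

    Returns the two gapped rows of the alignment ('-' for gaps).
    Deterministic: ties in the DP resolve diagonal > up > left. The DP
    is banded around the diagonal using the unit-cost edit distance to
    size the band generously; for distant pairs it falls back to the
    full matrix.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a_up, b_up = a.upper(), b.upper()
    ea, eb = _encode(a_up), _encode(b_up)
    a, b = a_up, b_up
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    band = 2 * dist + 32
    if band >= min(len(a), len(b)):
        band = len(a) + len(b)  # effectively unbanded
    _, trace = _nw_matrix(ea, eb, MATCH_SCORE, MISMATCH_SCORE, GAP_SCORE, band)
    i, j = len(a), len(b)
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        t = trace[i, j]
        if t == 0 and i > 0 and j > 0:
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i -= 1
            j -= 1
        elif t == 1 and i > 0:
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb))


def identity_from_alignment(row_a: str, row_b: str) -> float:
    """Percent identity over alignment columns, terminal gaps excluded."""
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    arr_a = np.frombuffer(row_a.encode(), dtype="S1")
    arr_b = np.frombuffer(row_b.encode(), dtype="S1")
    gap = b"-"
    nz_a = np.flatnonzero(arr_a != gap)
    nz_b = np.flatnonzero(arr_b != gap)
    if nz_a.size == 0 or nz_b.size == 0:
        raise ValueError("alignment has an all-gap row")
    start = max(nz_a[0], nz_b[0])
    end = min(nz_a[-1], nz_b[-1]) + 1
    if end <= start:
        # Alignments that are pure terminal gaps (no overlapping core).
        return 0.0
    core_a = arr_a[start:end]
    core_b = arr_b[start:end]
    matches = int(np.count_nonzero((core_a == core_b) & (core_a != gap)))
    return 100.0 * matches / (end - start)


def _edlib_prescreen_k(len_a: int, len_b: int, threshold: float) -> int:
    # Conservative: a pair at >= threshold identity over similar-length
    # sequences cannot need more edits than ~3x the mismatch budget plus
    # the length difference plus a safety margin.
    budget = (1.0 - threshold / 100.0) * max(len_a, len_b)
    return math.ceil(3 * budget) + abs(len_a - len_b) + 32


def pairwise_identity(a: str, b: str) -> float:
    """Percent nucleotide identity between two sequences (symmetric).

    Arguments are canonically ordered before alignment so that
    tie-breaking between co-optimal alignments cannot make the result
    depend on argument order.
    """
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    if a == b:
        return 100.0
    if (len(b), b) < (len(a), a):
        a, b = b, a
    return identity_from_alignment(*align(a, b))


def sort_by_length(seqs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Sort (id, sequence) pairs by descending length, ties by ID."""
    return sorted(seqs, key=lambda rec: (-len(rec[1]), rec[0]))


@dataclass
class Cluster:
    """A non-redundant cluster of operon sequences."""

    cluster_id: str
    representative_id: str
    representative_seq: str
    member_ids: list[str] = field(default_factory=list)
    member_identities: list[float] = field(default_factory=list)
    consensus: str | None = None

    @property
    def size(self) -> int:
        return len(self.member_ids)


def greedy_cluster(
    seqs: list[tuple[str, str]],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    presorted: bool = False,
) -> list[Cluster]:
    """Greedy length-sorted centroid clustering.

    Each sequence joins the existing centroid with the highest identity
    >= ``threshold`` (ties: earliest-founded centroid), else founds a new
    cluster. With input sorted longest-first, every representative is the
    longest member of its cluster.
    """
    if not presorted:
        seqs = sort_by_length(seqs)
    clusters: list[Cluster] = []
    for seq_id, seq in seqs:
        best_idx = -1
        best_identity = -1.0
        for idx, cl in enumerate(clusters):
            rep = cl.representative_seq
            if seq != rep:
                k = _edlib_prescreen_k(len(seq), len(rep), threshold)
                res = edlib.align(seq, rep, mode="NW", task="distance", k=k)
                if res["editDistance"] == -1:
                    continue
            ident = pairwise_identity(seq, rep)
            if ident >= threshold and ident > best_identity:
                best_identity = ident
                best_idx = idx
        if best_idx >= 0:
            cl = clusters[best_idx]
            cl.member_ids.append(seq_id)
            cl.member_identities.append(best_identity)
        else:
            clusters.append(Cluster(
                cluster_id=f"NR_{len(clusters):06d}",
                representative_id=seq_id,
                representative_seq=seq,
                member_ids=[seq_id],
                member_identities=[100.0],
            ))
    return clusters


def augment_clusters(
    existing_reps: list[tuple[str, str]],
    new_seqs: list[tuple[str, str]],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[Cluster]:
    """Phase-2 augmentation: pool phase-1 representatives with new
    sequences, re-sort by length, and re-cluster.

    A new sequence only founds a cluster if it is below ``threshold``
    identity to every retained centroid, so new material is kept only
    when it expands sequence diversity.
    """
    return greedy_cluster(list(existing_reps) + list(new_seqs), threshold)


def two_phase_cluster(
    complete_seqs: list[tuple[str, str]],
    incomplete_seqs: list[tuple[str, str]],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[Cluster]:
    """Cluster complete-assembly sequences, then augment with
    incomplete-assembly sequences."""
    phase1 = greedy_cluster(complete_seqs, threshold)
    if not incomplete_seqs:
        return phase1
    reps = [(cl.representative_id, cl.representative_seq) for cl in phase1]
    return augment_clusters(reps, incomplete_seqs, threshold)


def consensus_sequence(members: list[str], representative: str | None = None) -> str:
    """Column-majority consensus from a star alignment to the representative.

    Every member is aligned to the representative; columns are the
    representative positions plus any insertions (stacked by order of
    occurrence). Per column the most frequent symbol wins; columns where
    the gap is strictly the most frequent symbol are dropped; base ties
    break by fixed order A < C < G < T.
    """
    if not members:
        raise ValueError("cannot build a consensus of zero members")
    if representative is None:
        representative = members[0]
    if len(members) == 1:
        return members[0]
    rep_len = len(representative)
    # position columns: rep coordinate -> list of member symbols
    pos_cols: list[list[str]] = [[] for _ in range(rep_len)]
    # insertion columns: (rep position before which it falls, index) -> symbols
    ins_cols: dict[tuple[int, int], list[str]] = {}
    n = len(members)
    for member in members:
        if member == representative:
            for p in range(rep_len):
                pos_cols[p].append(representative[p])
            continue
        row_rep, row_mem = align(representative, member)
        p = 0
        ins_idx = 0
        for cr, cm in zip(row_rep, row_mem):
            if cr == "-":
                key = (p, ins_idx)
                ins_cols.setdefault(key, []).append(cm)
                ins_idx += 1
            else:
                pos_cols[p].append(cm)
                p += 1
                ins_idx = 0
    out: list[str] = []

    def column_symbol(symbols: list[str]) -> str | None:
        # Members without a recorded symbol in this column carry a gap.
        counts: dict[str, int] = {}
        for s in symbols:
            if s != "-":
                counts[s] = counts.get(s, 0) + 1
        gap_count = n - sum(counts.values())
        if not counts:
            return None
        top = max(counts.values())
        if gap_count > top:
            return None
        for base in sorted(counts):
            if counts[base] == top:
                return base
        return None

    for p in range(rep_len + 1):
        ins_idx = 0
        while (p, ins_idx) in ins_cols:
            sym = column_symbol(ins_cols[(p, ins_idx)])
            if sym is not None:
                out.append(sym)
            ins_idx += 1
        if p < rep_len:
            sym = column_symbol(pos_cols[p])
            if sym is not None:
                out.append(sym)
    return "".join(out)


def reduction_percent(n_full: int, n_nr: int) -> float:
    """Percentage reduction from the full to the non-redundant set,
    rounded to one decimal."""
    if n_full == 0:
        raise ValueError("cannot compute reduction of an empty dataset")
    return round(100.0 * (1.0 - n_nr / n_full), 1)


def clusters_to_table(clusters: list[Cluster]):
    """Cluster membership as a DataFrame (cluster_id, member_id,
    representative_flag, identity_to_rep)."""
    import pandas as pd

    rows = []
    for cl in clusters:
        for mid, ident in zip(cl.member_ids, cl.member_identities):
            rows.append({
                "cluster_id": cl.cluster_id,
                "member_id": mid,
                "representative_flag": int(mid == cl.representative_id),
                "identity_to_rep": round(ident, 4),
            })
    return pd.DataFrame(rows, columns=[
        "cluster_id", "member_id", "representative_flag", "identity_to_rep",
    ])


def add_consensus(clusters: list[Cluster], sequences: dict[str, str]) -> None:
    """Fill in ``cluster.consensus`` for every cluster in place."""
    for cl in clusters:
        members = [sequences[m] for m in cl.member_ids]
        cl.consensus = consensus_sequence(members, cl.representative_seq)
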