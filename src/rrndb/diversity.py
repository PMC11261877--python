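"""Intragenomic diversity analytics for rrn operons and their regions.

Most bacterial genomes carry several copies of the rrn operon, and the
copies are rarely identical. For every genome with more than one
surviving operon, this module computes pairwise distance matrices for
the whole operon and its constituent regions (16S, ITS, 23S), converts
distances to identities, and summarises the pooled identities per
region, including cross-region Pearson correlations.

Distances are p-distances scaled to SNVs per 100 comparable sites:
columns where either sequence has a gap or an N are excluded from both
numerator and denominator. With substitution-only variation (no indels)
the distance times the number of comparable columns recovers the SNV
count exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import derep
from .operon_extract import RrnOperon

logger = logging.getLogger(__name__)

REGIONS = ("rrn", "16S", "ITS", "23S")


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of pairwise distances (SNVs per 100
    comparable sites) with operon-region labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def pair_identities(self) -> dict[tuple[str, str], float]:
        """Upper-triangle identities keyed by (label_a, label_b)."""
        out = {}
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                out[(self.labels[i], self.labels[j])] = identity_from_distance(
                    self.values[i, j])
        return out


@dataclass
class RegionDiversitySummary:
    """Pooled summary of pairwise identities for one region."""

    region: str
    mean: float
    median: float
    sd: float
    cv: float
    n_pairs: int
    n_genomes: int
    fraction_genomes_diverse: float


def pairwise_distance(a: str, b: str, aligned: bool = False) -> float:
    """p-distance between two sequences as SNVs per 100 comparable sites.

    Comparable columns are those where both sequences carry a concrete
    base (no gap, no N). With ``aligned=True`` the inputs are gapped
    alignment rows of equal length; otherwise they are aligned first
    with the dereplication module's global aligner.
    """
    if not aligned:
        a, b = derep.align(a, b)
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    arr_a = np.frombuffer(a.upper().encode(), dtype="S1")
    arr_b = np.frombuffer(b.upper().encode(), dtype="S1")
    comparable = (
        (arr_a != b"-") & (arr_b != b"-") & (arr_a != b"N") & (arr_b != b"N")
    )
    n_comp = int(np.count_nonzero(comparable))
    if n_comp == 0:
        raise ValueError("no comparable (gap-free) columns in alignment")
    mismatches = int(np.count_nonzero(comparable & (arr_a != arr_b)))
    return 100.0 * mismatches / n_comp


def identity_from_distance(d: float) -> float:
    """Pairwise identity: 100 minus the distance."""
    return 100.0 - d


def snv_estimate(identity: float, mean_length: float) -> int:
    """Approximate SNV count implied by a percent identity over a
    sequence of the given mean length."""
    return round(mean_length * (100.0 - identity) / 100.0)


def region_sequence(operon: RrnOperon, region: str) -> str:
    """Slice one region out of an operon sequence (which is oriented
    16S->ITS->23S regardless of genomic strand)."""
    len16 = operon.s16.length
    len_its = operon.its_length
    if region == "rrn":
        return operon.sequence
    if region == "16S":
        return operon.sequence[:len16]
    if region == "ITS":
        return operon.sequence[len16:len16 + len_its]
    if region == "23S":
        return operon.sequence[len16 + len_its:]
    raise ValueError(f"unknown region {region!r}")


def intragenomic_matrices(
    operons: list[RrnOperon],
    regions: tuple[str, ...] = REGIONS,
) -> dict[str, DistanceMatrix] | None:
    """Per-region pairwise distance matrices for one genome's operons.

    Returns ``None`` (with a log entry) for genomes with fewer than two
    operons. All matrices share the same label order. Zero-length ITS
    pairs are assigned distance 0 (no sites to differ at).
    """
    if len(operons) < 2:
        logger.info("genome with <2 operons skipped: %s",
                    operons[0].genome_id if operons else "<empty>")
        return None
    labels = [op.operon_id for op in operons]
    out: dict[str, DistanceMatrix] = {}
    for region in regions:
        seqs = [region_sequence(op, region) for op in operons]
        n = len(seqs)
        m = np.zeros((n, n), dtype=float)
        for i in range(n):
            for j in range(i + 1, n):
                if not seqs[i] and not seqs[j]:
                    d = 0.0
                elif not seqs[i] or not seqs[j]:
                    d = 100.0
                elif seqs[i] == seqs[j]:
                    d = 0.0
                else:
                    d = pairwise_distance(seqs[i], seqs[j])
                m[i, j] = m[j, i] = d
        out[region] = DistanceMatrix(labels, m)
    return out


def matrices_by_genome(
    operons: list[RrnOperon],
    regions: tuple[str, ...] = REGIONS,
) -> dict[str, dict[str, DistanceMatrix]]:
    """Group operons by genome and build matrices for every genome with
    at least two operons."""
    grouped: dict[str, list[RrnOperon]] = {}
    for op in operons:
        grouped.setdefault(op.genome_id, []).append(op)
    out = {}
    for genome_id in sorted(grouped):
        mats = intragenomic_matrices(grouped[genome_id], regions)
        if mats is not None:
            out[genome_id] = mats
    return out


def long_format_table(
    genome_matrices: dict[str, dict[str, DistanceMatrix]],
) -> pd.DataFrame:
    """Pooled long-format table: one row per genome, region and operon
    pair, with the pairwise identity."""
    rows = []
    for genome_id, mats in genome_matrices.items():
        for region, mat in mats.items():
            for (id_a, id_b), ident in mat.pair_identities().items():
                rows.append({
                    "genome_id": genome_id,
                    "region": region,
                    "id_a": id_a,
                    "id_b": id_b,
                    "identity": ident,
                })
    return pd.DataFrame(rows, columns=["genome_id", "region", "id_a", "id_b",
                                       "identity"])


def diversity_summary(
    genome_matrices: dict[str, dict[str, DistanceMatrix]],
) -> list[RegionDiversitySummary]:
    """Pooled per-region summaries across all multi-copy genomes.

    ``fraction_genomes_diverse`` is the share of multi-copy genomes with
    any pairwise identity < 100 for that region; mean/median/sd/cv pool
    all pairwise identities across genomes (sd is the population-style
    ddof=1 sample standard deviation; cv = 100*sd/mean).
    """
    table = long_format_table(genome_matrices)
    n_genomes = len(genome_matrices)
    out = []
    for region in REGIONS:
        sub = table[table.region == region]
        if sub.empty:
            continue
        idents = sub.identity.to_numpy()
        diverse_genomes = sub[sub.identity < 100.0].genome_id.nunique()
        mean = float(np.mean(idents))
        sd = float(np.std(idents, ddof=1)) if len(idents) > 1 else 0.0
        out.append(RegionDiversitySummary(
            region=region,
            mean=mean,
            median=float(np.median(idents)),
            sd=sd,
            cv=100.0 * sd / mean if mean > 0 else float("nan"),
            n_pairs=len(idents),
            n_genomes=n_genomes,
            fraction_genomes_diverse=(
                diverse_genomes / n_genomes if n_genomes else float("nan")),
        ))
    return out


def summary_table(summaries: list[RegionDiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def region_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of pairwise identities between regions.

    ``table`` is the long-format output of :func:`long_format_table`;
    identities from the same operon pair are matched across regions.
    Region pairs with fewer than 3 complete pairs or zero variance are
    reported as NaN.
    """
    if table.empty:
        return pd.DataFrame(index=list(REGIONS), columns=list(REGIONS), dtype=float)
    wide = table.pivot_table(
        index=["genome_id", "id_a", "id_b"], columns="region", values="identity")
    wide = wide.reindex(columns=[r for r in REGIONS if r in wide.columns])
    corr = wide.corr(method="pearson", min_periods=3)
    return corr


def plot_identity_histograms(table: pd.DataFrame, path, trim_outliers: bool = True):
    """Histograms of pooled pairwise identities per region (optional
    artifact). IQR-based outlier trimming applies to the plot only,
    never to statistics."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    regions = [r for r in REGIONS if (table.region == r).any()]
    fig, axes = plt.subplots(1, max(len(regions), 1), figsize=(4 * len(regions), 3))
    if len(regions) == 1:
        axes = [axes]
    for ax, region in zip(np.atleast_1d(axes).ravel(), regions):
        vals = table[table.region == region].identity.to_numpy()
        if trim_outliers and len(vals) > 3:
            q1, q3 = np.percentile(vals, [25, 75])
            iqr = q3 - q1
            vals = vals[(vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)]
        ax.hist(vals, bins=30)
        ax.set_title(region)
        ax.set_xlabel("pairwise identity (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
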