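"""Seven-rank lineage handling and cluster taxonomy assignment.

Clusters of operon sequences can mix source genomes whose taxonomy
disagrees (e.g. *Escherichia coli* and *Shigella* spp., which are
phylogenetically inseparable but historically split). Three systems are
provided to label a cluster:

* **taxRep** — the lineage of the representative sequence's source genome;
* **taxLCA** — the lowest common ancestor of all members' lineages;
* **taxMaj** — the lowest rank at which a strict majority (> 50 %) of
  members share one full lineage prefix.

For the classic worked case — a cluster of 97 *E. coli* and 3
*Shigella flexneri* sequences — taxLCA yields f__Enterobacteriaceae
while taxMaj keeps s__Escherichia coli.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
N_RANKS = 7


@dataclass(frozen=True)
class Lineage:
    """An ordered seven-rank lineage (kingdom..species); empty names mark
    unassigned ranks, and an empty rank implies all deeper ranks empty."""

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != N_RANKS:
            raise ValueError(f"lineage must have {N_RANKS} ranks, got {len(self.ranks)}")
        seen_empty = False
        for name in self.ranks:
            if name == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(
                    f"gap in lineage (empty rank above a named one): {self.ranks}")

    @property
    def depth(self) -> int:
        """Number of leading named ranks."""
        d = 0
        for name in self.ranks:
            if name == "":
                break
            d += 1
        return d

    def prefix(self, depth: int) -> "Lineage":
        """The lineage truncated to ``depth`` named ranks."""
        return Lineage(tuple(self.ranks[:depth]) + ("",) * (N_RANKS - depth))

    @property
    def phylum(self) -> str:
        return self.ranks[1]

    @property
    def species(self) -> str:
        return self.ranks[6]


EMPTY_LINEAGE = Lineage(("",) * N_RANKS)


def parse_lineage(text: str) -> Lineage:
    """Parse a semicolon-separated, optionally rank-prefixed lineage."""
    fields = [f.strip() for f in text.strip().split(";")] if text.strip() else []
    if len(fields) > N_RANKS:
        raise ValueError(f"lineage has more than {N_RANKS} fields: {text!r}")
    names = []
    for fld in fields:
        if fld[:3] in RANK_PREFIXES:
            fld = fld[3:]
        names.append(fld)
    names += [""] * (N_RANKS - len(names))
    return Lineage(tuple(names))


def format_lineage(lineage: Lineage) -> str:
    """Serialise with rank prefixes; empty ranks render as bare prefixes."""
    return ";".join(p + n for p, n in zip(RANK_PREFIXES, lineage.ranks))


def tax_rep(representative_genome_id: str,
            genome_lineages: dict[str, Lineage]) -> Lineage:
    """Cluster taxonomy: lineage of the representative's source genome."""
    try:
        return genome_lineages[representative_genome_id]
    except KeyError:
        raise KeyError(
            f"genome {representative_genome_id!r} missing from taxonomy table"
        ) from None


def tax_lca(lineages: list[Lineage]) -> Lineage:
    """Lowest common ancestor: deepest rank at which every lineage shares
    an identical path from the kingdom down."""
    if not lineages:
        raise ValueError("tax_lca of an empty lineage set")
    depth = 0
    for r in range(N_RANKS):
        names = {lin.ranks[r] for lin in lineages}
        if len(names) != 1 or names == {""}:
            break
        depth = r + 1
    return lineages[0].prefix(depth)


def tax_maj(lineages: list[Lineage]) -> Lineage:
    """Lowest rank with a strict-majority full lineage prefix.

    Scanning from species upward, return the first prefix shared by
    strictly more than half of the members. Majority is evaluated over
    full prefixes (never bare names at a rank), so homonymous names in
    different parent taxa cannot pool votes. Exact 50/50 ties fall
    through to the next rank up.
    """
    if not lineages:
        raise ValueError("tax_maj of an empty lineage set")
    n = len(lineages)
    for depth in range(N_RANKS, 0, -1):
        counts = Counter(
            lin.ranks[:depth] for lin in lineages if lin.ranks[depth - 1] != ""
        )
        if not counts:
            continue
        prefix, count = counts.most_common(1)[0]
        if count > n / 2:
            return Lineage(tuple(prefix) + ("",) * (N_RANKS - depth))
    return EMPTY_LINEAGE


def species_agreement_fraction(
    cluster_member_genomes: list[list[str]],
    genome_lineages: dict[str, Lineage],
) -> float:
    """Percent of clusters whose members all carry one identical
    species-level lineage."""
    if not cluster_member_genomes:
        return 100.0
    agree = 0
    for genomes in cluster_member_genomes:
        lineages = {genome_lineages[g].ranks for g in genomes}
        if len(lineages) == 1:
            agree += 1
    return 100.0 * agree / len(cluster_member_genomes)


def phylum_composition(lineages: list[Lineage]) -> pd.DataFrame:
    """Phylum-level composition as (phylum, count, percent), sorted by
    descending count; empty phyla bucket as "unclassified"."""
    counts = Counter(lin.phylum or "unclassified" for lin in lineages)
    if not counts:
        return pd.DataFrame(columns=["phylum", "count", "percent"])
    total = sum(counts.values())
    rows = [
        {"phylum": ph, "count": c, "percent": 100.0 * c / total}
        for ph, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["phylum", "count", "percent"])


def read_taxonomy_tsv(path) -> dict[str, Lineage]:
    """Read a genome_id<TAB>lineage table."""
    table = pd.read_csv(path, sep="\t", header=None, names=["genome_id", "lineage"],
                        dtype=str, comment="#")
    return {row.genome_id: parse_lineage(row.lineage)
            for row in table.itertuples()}


def write_taxonomy_tsv(assignments: dict[str, Lineage], path) -> None:
    """Write an ID<TAB>lineage table (cluster or operon IDs)."""
    with open(path, "w") as fh:
        for key in assignments:
            fh.write(f"{key}\t{format_lineage(assignments[key])}\n")


def assign_cluster_taxonomy(
    clusters,
    operon_genomes: dict[str, str],
    genome_lineages: dict[str, Lineage],
) -> dict[str, dict[str, Lineage]]:
    """All three taxonomy systems for a list of clusters.

    ``operon_genomes`` maps member (operon) IDs to source genome IDs.
    Each member sequence counts once in LCA/majority voting, even when
    several members come from one genome.
    """
    out = {"taxRep": {}, "taxLCA": {}, "taxMaj": {}}
    for cl in clusters:
        member_lineages = [
            genome_lineages[operon_genomes[mid]] for mid in cl.member_ids
        ]
        out["taxRep"][cl.cluster_id] = tax_rep(
            operon_genomes[cl.representative_id], genome_lineages)
        out["taxLCA"][cl.cluster_id] = tax_lca(member_lineages)
        out["taxMaj"][cl.cluster_id] = tax_maj(member_lineages)
    return out
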