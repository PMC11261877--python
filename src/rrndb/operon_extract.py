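"""Identify 16S/23S rRNA features and link them into rrn operons.

An rrn operon is a 16S gene and a 23S gene that are (1) on the same
contig, (2) on the same strand, and (3) in 16S-ITS-23S order along the
direction of transcription. Genes covering less than 80 % of their
canonical length are flagged partial and excluded from linking. Linked
operons are then quality-filtered: pairs separated by an internal
transcribed spacer longer than 1.5 kb are discarded as "unlinked", and
operons whose span is not fully contained in their contig (annotations
wrapping the origin of a circular replicon) are discarded as "boundary".
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field, replace

from .seq_io import ContigRecord, GenomicInterval, GffFeature, reverse_complement

logger = logging.getLogger(__name__)

# Canonical gene lengths used to estimate annotation coverage when the
# annotation itself carries none: the observed mean lengths of full-length
# 16S and 23S genes in large assembly collections.
CANONICAL_16S_LENGTH = 1534
CANONICAL_23S_LENGTH = 2924
PARTIAL_COVERAGE_THRESHOLD = 0.80
DEFAULT_MAX_ITS = 1500


@dataclass(frozen=True)
class RnaFeature:
    """A located rRNA gene with partial/coverage flags."""

    interval: GenomicInterval
    gene: str  # one of {"16S", "23S", "5S", "other"}
    coverage: float
    partial: bool
    genome_id: str = ""
    assembly_level: str = "complete"


@dataclass(frozen=True)
class RrnOperon:
    """A linked 16S-ITS-23S unit with intervals, strand and sequence."""

    genome_id: str
    contig_id: str
    strand: str
    s16: GenomicInterval
    s23: GenomicInterval
    its: GenomicInterval | None
    full: GenomicInterval
    sequence: str = ""
    operon_id: str = ""
    assembly_level: str = "complete"

    @property
    def its_length(self) -> int:
        return 0 if self.its is None else self.its.length


@dataclass
class FilterReport:
    """Tallies of operons removed by each quality filter."""

    n_input: int = 0
    n_kept: int = 0
    n_unlinked: int = 0
    n_boundary: int = 0
    by_genome: dict[str, dict[str, int]] = field(default_factory=dict)

    def record(self, genome_id: str, reason: str) -> None:
        tally = self.by_genome.setdefault(
            genome_id, {"kept": 0, "unlinked": 0, "boundary": 0})
        tally[reason] += 1


_RE_16S = re.compile(r"16S[\s_-]*(?:ribosomal RNA|rRNA)", re.IGNORECASE)
_RE_23S = re.compile(r"23S[\s_-]*(?:ribosomal RNA|rRNA)", re.IGNORECASE)
_RE_5S = re.compile(r"5S[\s_-]*(?:ribosomal RNA|rRNA)", re.IGNORECASE)


def _classify_product(text: str) -> str:
    if _RE_16S.search(text):
        return "16S"
    if _RE_23S.search(text):
        return "23S"
    if _RE_5S.search(text):
        return "5S"
    return "other"


def classify_rrna_features(
    features: list[GffFeature],
    canon_16s: int = CANONICAL_16S_LENGTH,
    canon_23s: int = CANONICAL_23S_LENGTH,
    genome_id: str = "",
    assembly_level: str = "complete",
) -> list[RnaFeature]:
    """Classify GFF3 rRNA features as 16S/23S/5S/other with coverage
    and partial flags.

    Coverage is interval length over the canonical gene length; a gene
    is partial when coverage < 0.80 or the annotation says so
    (``partial=true`` attribute or ``(partial)`` in the product).
    """
    out: list[RnaFeature] = []
    for feat in features:
        if feat.feature_type != "rRNA":
            continue
        text = feat.attributes.get("product", "") or feat.attributes.get("Name", "")
        gene = _classify_product(text)
        if gene == "other":
            logger.warning(
                "unclassifiable rRNA product %r at %s:%d-%d",
                text, feat.interval.contig_id, feat.interval.start, feat.interval.end,
            )
        canon = {"16S": canon_16s, "23S": canon_23s, "5S": 115}.get(gene)
        coverage = feat.interval.length / canon if canon else 0.0
        annotated_partial = (
            feat.attributes.get("partial", "").lower() == "true"
            or "(partial)" in text.lower()
        )
        partial = coverage < PARTIAL_COVERAGE_THRESHOLD or annotated_partial
        out.append(RnaFeature(
            interval=feat.interval,
            gene=gene,
            coverage=coverage,
            partial=partial,
            genome_id=genome_id,
            assembly_level=assembly_level,
        ))
    return out


def link_operons(features: list[RnaFeature]) -> list[RrnOperon]:
    """Pair non-partial 16S genes with their nearest downstream 23S gene.

    Genes are grouped per contig and strand and scanned in transcription
    order; each 16S takes the nearest unconsumed 23S downstream of it
    (greater coordinates on '+', lesser on '-'). Each 23S joins at most
    one operon. Pairs whose annotations overlap (negative spacer) are
    rejected with a warning.
    """
    groups: dict[tuple[str, str], list[RnaFeature]] = defaultdict(list)
    for feat in features:
        if feat.partial or feat.gene not in ("16S", "23S"):
            continue
        groups[(feat.interval.contig_id, feat.interval.strand)].append(feat)

    operons: list[RrnOperon] = []
    for (contig_id, strand), group in sorted(groups.items()):
        group = sorted(group, key=lambda f: f.interval.start)
        if strand == "-":
            group = group[::-1]  # transcription runs right-to-left
        used_23s: set[int] = set()
        genes_16s = [g for g in group if g.gene == "16S"]
        genes_23s = [g for g in group if g.gene == "23S"]
        for g16 in genes_16s:
            candidate = None
            for idx, g23 in enumerate(genes_23s):
                if idx in used_23s:
                    continue
                if strand == "+" and g23.interval.start >= g16.interval.start:
                    candidate = (idx, g23)
                    break
                if strand == "-" and g23.interval.end <= g16.interval.end:
                    candidate = (idx, g23)
                    break
            if candidate is None:
                continue
            idx, g23 = candidate
            if strand == "+":
                gap_start, gap_end = g16.interval.end, g23.interval.start
            else:
                gap_start, gap_end = g23.interval.end, g16.interval.start
            if gap_end < gap_start:
                logger.warning(
                    "rejecting overlapping 16S/23S pair on %s%s (gap %d)",
                    contig_id, strand, gap_end - gap_start,
                )
                continue
            used_23s.add(idx)
            its = None
            if gap_end > gap_start:
                its = GenomicInterval(contig_id, gap_start, gap_end, strand)
            full_start = min(g16.interval.start, g23.interval.start)
            full_end = max(g16.interval.end, g23.interval.end)
            operons.append(RrnOperon(
                genome_id=g16.genome_id,
                contig_id=contig_id,
                strand=strand,
                s16=g16.interval,
                s23=g23.interval,
                its=its,
                full=GenomicInterval(contig_id, full_start, full_end, strand),
                assembly_level=g16.assembly_level,
            ))
    return operons


def filter_operons(
    operons: list[RrnOperon],
    contig_lengths: dict[str, int],
    max_its: int = DEFAULT_MAX_ITS,
) -> tuple[list[RrnOperon], FilterReport]:
    """Remove unlinked (ITS > max_its) and contig-boundary-crossing operons.

    The ITS filter is strict: an ITS of exactly ``max_its`` is kept.
    Boundary containment is linear even for circular replicons —
    origin-wrapping operons are discarded, not re-stitched.
    """
    report = FilterReport(n_input=len(operons))
    kept: list[RrnOperon] = []
    for op in operons:
        if op.its_length > max_its:
            report.n_unlinked += 1
            report.record(op.genome_id, "unlinked")
            continue
        clen = contig_lengths[op.contig_id]
        if op.full.start < 0 or op.full.end > clen:
            report.n_boundary += 1
            report.record(op.genome_id, "boundary")
            continue
        kept.append(op)
        report.record(op.genome_id, "kept")
    report.n_kept = len(kept)
    return kept, report


def extract_operon_sequence(operon: RrnOperon, contig: ContigRecord) -> str:
    """The operon sequence, 5'->3' in 16S->ITS->23S orientation."""
    if operon.full.start < 0 or operon.full.end > contig.length:
        raise ValueError(
            f"operon {operon.full.start}-{operon.full.end} outside contig "
            f"{contig.contig_id} (length {contig.length})"
        )
    sub = contig.sequence[operon.full.start:operon.full.end]
    if operon.strand == "-":
        sub = reverse_complement(sub)
    return sub


def assign_operon_ids(operons: list[RrnOperon]) -> list[RrnOperon]:
    """Assign unique IDs "<genome_id>|<contig_id>|<start>-<end>|<strand>"."""
    seen: set[str] = set()
    out: list[RrnOperon] = []
    for op in operons:
        oid = f"{op.genome_id}|{op.contig_id}|{op.full.start}-{op.full.end}|{op.strand}"
        if oid in seen:
            raise ValueError(f"operon ID collision: {oid}")
        seen.add(oid)
        out.append(replace(op, operon_id=oid))
    return out


def parse_operon_id(operon_id: str) -> tuple[str, str, int, int, str]:
    """Inverse of :func:`assign_operon_ids` ID construction."""
    genome_id, contig_id, span, strand = operon_id.rsplit("|", 3)
    start_s, _, end_s = span.partition("-")
    return genome_id, contig_id, int(start_s), int(end_s), strand


def extract_genome_operons(
    contigs: list[ContigRecord],
    features: list[GffFeature],
    genome_id: str,
    assembly_level: str = "complete",
    max_its: int = DEFAULT_MAX_ITS,
) -> tuple[list[RrnOperon], FilterReport]:
    """Full per-genome extraction: classify, link, filter, sequence, ID."""
    rna = classify_rrna_features(
        features, genome_id=genome_id, assembly_level=assembly_level)
    operons = link_operons(rna)
    contig_lengths = {c.contig_id: c.length for c in contigs}
    kept, report = filter_operons(operons, contig_lengths, max_its=max_its)
    by_id = {c.contig_id: c for c in contigs}
    with_seq = [
        replace(op, sequence=extract_operon_sequence(op, by_id[op.contig_id]))
        for op in kept
    ]
    return assign_operon_ids(with_seq), report
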