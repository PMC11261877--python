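"""Readers/writers for the standard formats the pipeline touches.

All coordinates inside the package are 0-based half-open intervals
(:class:`GenomicInterval`); GFF3 serialisation converts to/from the
1-based inclusive convention at the boundary, and nowhere else.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# IUPAC nucleotide complement table (uppercase only; sequences are
# uppercased on read).
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N", "U": "A",
}
_COMPLEMENT_TRANS = str.maketrans(_COMPLEMENT)
IUPAC_ALPHABET = frozenset(_COMPLEMENT)


@dataclass(frozen=True)
class ContigRecord:
    """A contig/scaffold sequence from an assembly."""

    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig, with strand."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        # Negative starts are tolerated so origin-wrapping annotations can be
        # represented long enough to be rejected by the boundary filter.
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GffFeature:
    """One GFF3 row, with the interval held in internal coordinates."""

    interval: GenomicInterval
    feature_type: str
    attributes: dict[str, str] = field(default_factory=dict)
    source: str = "."
    score: str = "."
    phase: str = "."


def reverse_complement(seq: str) -> str:
    """Reverse-complement an IUPAC nucleotide string.

    Raises ``ValueError`` on any character outside the IUPAC alphabet.
    """
    seq = seq.upper()
    bad = set(seq) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT_TRANS)[::-1]


def read_fasta(path: str | os.PathLike | io.TextIOBase) -> list[ContigRecord]:
    """Read a (multi-)FASTA file into :class:`ContigRecord` objects.

    Sequences are uppercased; record order is preserved. Duplicate IDs are
    a hard error because downstream operon identifiers embed contig IDs.
    """
    if isinstance(path, io.TextIOBase):
        handle = path
        records = list(SeqIO.parse(handle, "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    out: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate contig ID in FASTA: {rec.id}")
        seen.add(rec.id)
        out.append(ContigRecord(rec.id, str(rec.seq).upper()))
    return out


def write_fasta(records: Iterable[ContigRecord | tuple[str, str]],
                path: str | os.PathLike) -> None:
    """Write records as 60-column wrapped FASTA."""
    seqrecords = []
    for rec in records:
        if isinstance(rec, ContigRecord):
            rid, seq = rec.contig_id, rec.sequence
        else:
            rid, seq = rec
        seqrecords.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqrecords, str(path), "fasta")


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
        else:
            attrs[part] = ""
    return attrs


def _format_attributes(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_gff3(path: str | os.PathLike) -> list[GffFeature]:
    """Parse a GFF3 file into :class:`GffFeature` objects.

    1-based inclusive coordinates are converted to 0-based half-open.
    Rows with start > end are rejected with a warning rather than raising.
    An embedded ``##FASTA`` section terminates feature parsing.
    """
    features: list[GffFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                logger.warning("skipping malformed GFF3 row (%d columns)", len(cols))
                continue
            seqid, source, ftype, start, end, score, strand, phase, attrs = cols
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                logger.warning(
                    "rejecting GFF3 row with start > end (%s:%d-%d)",
                    seqid, start_i, end_i,
                )
                continue
            interval = GenomicInterval(
                contig_id=seqid,
                start=start_i - 1,
                end=end_i,
                strand=strand if strand in ("+", "-") else "+",
            )
            features.append(GffFeature(
                interval=interval,
                feature_type=ftype,
                attributes=_parse_attributes(attrs),
                source=source,
                score=score,
                phase=phase,
            ))
    return features


def write_gff3(features: Iterable[GffFeature], path: str | os.PathLike) -> None:
    """Write features as GFF3 (coordinates back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            iv = feat.interval
            fh.write("\t".join([
                iv.contig_id,
                feat.source,
                feat.feature_type,
                str(iv.start + 1),
                str(iv.end),
                feat.score,
                iv.strand,
                feat.phase,
                _format_attributes(feat.attributes),
            ]) + "\n")


def read_gff3_with_fasta(path: str | os.PathLike) -> tuple[list[GffFeature], list[ContigRecord]]:
    """Parse a GFF3 file that may carry an embedded ##FASTA section."""
    features = read_gff3(path)
    contigs: list[ContigRecord] = []
    with open(path) as fh:
        in_fasta = False
        buf: list[str] = []
        for line in fh:
            if line.startswith("##FASTA"):
                in_fasta = True
                continue
            if in_fasta:
                buf.append(line)
    if buf:
        contigs = read_fasta(io.StringIO("".join(buf)))
    return features, contigs


def write_phylip_distmat(labels: list[str], matrix, path: str | os.PathLike) -> None:
    """Write a square distance matrix in relaxed Phylip format.

    One row per line: label followed by whitespace-separated values.
    Non-square or asymmetric-shape input is a hard error.
    """
    import numpy as np

    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {m.shape}")
    if len(labels) != m.shape[0]:
        raise ValueError("label count does not match matrix dimension")
    with open(path, "w") as fh:
        fh.write(f"{m.shape[0]}\n")
        for label, row in zip(labels, m):
            fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip_distmat(path: str | os.PathLike) -> tuple[list[str], "np.ndarray"]:
    """Read a relaxed square Phylip distance matrix written by this module."""
    import numpy as np

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    n = int(lines[0].split()[0])
    labels: list[str] = []
    rows = []
    for line in lines[1:1 + n]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:1 + n]])
    m = np.asarray(rows, dtype=float)
    if m.shape != (n, n):
        raise ValueError(f"expected {n}x{n} matrix, got {m.shape}")
    return labels, m
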