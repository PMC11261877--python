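"""IUPAC-aware degenerate-primer matching and amplicon prediction.

Evaluates PCR primer pairs against an operon sequence database: for
every template, forward-primer sites are located on the sense strand
and paired with the nearest downstream reverse-primer binding site (the
reverse complement of the reverse primer, which is given 5'->3' on the
antisense strand, as is conventional). The reverse complement of the
template is scanned symmetrically. Matching is per-position set
membership over IUPAC expansion sets — degenerate primers are never
expanded combinatorially — and an N in the template matches nothing.

Three primer pairs targeting the full 16S-ITS-23S operon are bundled as
the default panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_io import reverse_complement
from .taxonomy import Lineage, phylum_composition

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_PRIMER_BITS = {code: sum(_BASE_BIT[b] for b in bases)
                for code, bases in IUPAC_SETS.items()}

DEFAULT_MAX_MISMATCHES = 0
DEFAULT_MAX_AMPLICON_LENGTH = 10_000


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair; fwd is sense-strand 5'->3', rev is
    antisense-strand 5'->3'."""

    name: str
    fwd: str
    rev: str
    source: str = ""

    def __post_init__(self) -> None:
        for seq in (self.fwd, self.rev):
            bad = set(seq.upper()) - set(IUPAC_SETS)
            if bad:
                raise ValueError(f"non-IUPAC characters in primer: {sorted(bad)}")


# Standard full-length rrn operon primer panel.
DEFAULT_PRIMER_PAIRS = [
    PrimerPair("16S:27F-23S:2241R", "AGRGTTTGATYHTGGCTCAG", "ACCRCCCCAGTHAAACT",
               source="full-operon pair used in earlier rrn amplicon studies"),
    PrimerPair("16S:27F-23S:2428R", "AGRGTTTGATYHTGGCTCAG", "CCRAMCTGTCTCACGACG",
               source="combined pair producing the longest amplicon"),
    PrimerPair("16S:519F-23S:2428R", "CAGCMGCCGCGGTAA", "CCRAMCTGTCTCACGACG",
               source="broad-range full-operon pair"),
]


@dataclass(frozen=True)
class AmpliconPrediction:
    """A predicted PCR product on a template sequence."""

    template_id: str
    start: int  # 0-based half-open, template orientation
    end: int
    strand: str  # orientation of the operon relative to the template
    fwd_pos: int
    rev_pos: int
    mismatches_fwd: int
    mismatches_rev: int

    @property
    def length(self) -> int:
        return self.end - self.start


def iupac_match_count(primer_window: str, template_window: str) -> int:
    """Number of positions where the template base is NOT in the primer
    code's expansion set. Ambiguous template bases (including N) never
    match."""
    if len(primer_window) != len(template_window):
        raise ValueError("primer and template windows differ in length")
    mismatches = 0
    for p, t in zip(primer_window.upper(), template_window.upper()):
        allowed = IUPAC_SETS.get(p)
        if allowed is None:
            raise ValueError(f"non-IUPAC primer character {p!r}")
        if t not in allowed:
            mismatches += 1
    return mismatches


def _encode_template(template: str) -> np.ndarray:
    # Concrete bases get their bit; ambiguity codes and N get 0 so they
    # match no primer position.
    arr = np.zeros(len(template), dtype=np.uint8)
    for base, bit in _BASE_BIT.items():
        arr[np.frombuffer(template.encode(), dtype="S1") == base.encode()] = bit
    return arr


def find_primer_sites(template: str, primer: str,
                      max_mm: int = DEFAULT_MAX_MISMATCHES) -> list[tuple[int, int]]:
    """All (position, mismatches) windows where the primer matches the
    given strand of the template with at most ``max_mm`` mismatches."""
    template = template.upper()
    primer = primer.upper()
    k = len(primer)
    if k == 0 or len(template) < k:
        return []
    tmpl_bits = _encode_template(template)
    primer_bits = np.array([_PRIMER_BITS[c] for c in primer], dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(tmpl_bits, k)
    matches = (windows & primer_bits[None, :]) != 0
    mismatches = k - matches.sum(axis=1)
    hits = np.flatnonzero(mismatches <= max_mm)
    return [(int(i), int(mismatches[i])) for i in hits]


def _predict_one_strand(template: str, template_id: str, pair: PrimerPair,
                        max_mm: int, max_len: int, strand: str,
                        template_len: int) -> list[AmpliconPrediction]:
    rev_site = reverse_complement(pair.rev)
    fwd_hits = find_primer_sites(template, pair.fwd, max_mm)
    rev_hits = find_primer_sites(template, rev_site, max_mm)
    out = []
    for fpos, fmm in fwd_hits:
        # nearest downstream reverse site whose product stays in bounds
        for rpos, rmm in rev_hits:
            if rpos >= fpos + len(pair.fwd):
                start, end = fpos, rpos + len(rev_site)
                if end - start > max_len:
                    break
                if strand == "-":
                    # map back to the original template's coordinates
                    start, end = template_len - end, template_len - start
                    fpos_t = template_len - fpos - len(pair.fwd)
                    rpos_t = template_len - rpos - len(rev_site)
                else:
                    fpos_t, rpos_t = fpos, rpos
                out.append(AmpliconPrediction(
                    template_id=template_id,
                    start=start, end=end, strand=strand,
                    fwd_pos=fpos_t, rev_pos=rpos_t,
                    mismatches_fwd=fmm, mismatches_rev=rmm,
                ))
                break
    return out


def predict_amplicons(template: str, template_id: str, pair: PrimerPair,
                      max_mm: int = DEFAULT_MAX_MISMATCHES,
                      max_len: int = DEFAULT_MAX_AMPLICON_LENGTH,
                      ) -> list[AmpliconPrediction]:
    """Predict all amplicons for one primer pair on one template.

    Each forward site pairs with the nearest downstream reverse site;
    the reverse-complement strand is scanned symmetrically and reported
    in template coordinates. Products longer than ``max_len`` are
    dropped.
    """
    template = template.upper()
    preds = _predict_one_strand(template, template_id, pair, max_mm, max_len,
                                "+", len(template))
    preds += _predict_one_strand(reverse_complement(template), template_id, pair,
                                 max_mm, max_len, "-", len(template))
    return sorted(preds, key=lambda p: (p.start, p.end, p.strand))


@dataclass
class PanelReport:
    """Per-primer-pair evaluation over a sequence database."""

    pair: PrimerPair
    n_templates: int
    n_amplified: int
    amplicon_lengths: list[int]
    missed_ids: list[str]
    missed_phyla: pd.DataFrame | None = None

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.n_amplified / self.n_templates

    def length_summary(self) -> dict[str, float]:
        if not self.amplicon_lengths:
            return {}
        arr = np.asarray(self.amplicon_lengths)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        return {"min": int(arr.min()), "q1": float(q1), "median": float(med),
                "q3": float(q3), "max": int(arr.max()), "n": len(arr)}


def evaluate_primer_panel(
    db: list[tuple[str, str]],
    pairs: list[PrimerPair] | None = None,
    taxonomy: dict[str, Lineage] | None = None,
    max_mm: int = DEFAULT_MAX_MISMATCHES,
    max_len: int = DEFAULT_MAX_AMPLICON_LENGTH,
) -> list[PanelReport]:
    """Evaluate a primer panel over an (id, sequence) database.

    Per pair: database coverage (percent of sequences yielding at least
    one amplicon), amplicon length distribution, and the phylum
    composition of sequences with no predicted amplicon (when a
    taxonomy mapping from sequence ID to lineage is supplied).
    """
    if not db:
        raise ValueError("empty sequence database")
    if pairs is None:
        pairs = DEFAULT_PRIMER_PAIRS
    reports = []
    for pair in pairs:
        lengths: list[int] = []
        missed: list[str] = []
        n_amp = 0
        for seq_id, seq in db:
            preds = predict_amplicons(seq, seq_id, pair, max_mm, max_len)
            if preds:
                n_amp += 1
                lengths.extend(p.length for p in preds)
            else:
                missed.append(seq_id)
        missed_phyla = None
        if taxonomy is not None:
            missed_phyla = phylum_composition(
                [taxonomy[m] for m in missed if m in taxonomy])
        reports.append(PanelReport(
            pair=pair, n_templates=len(db), n_amplified=n_amp,
            amplicon_lengths=lengths, missed_ids=missed,
            missed_phyla=missed_phyla,
        ))
    return reports


def panel_report_table(reports: list[PanelReport]) -> pd.DataFrame:
    """Panel summary as a DataFrame."""
    rows = []
    for rep in reports:
        summary = rep.length_summary()
        rows.append({
            "primer_pair": rep.pair.name,
            "n_templates": rep.n_templates,
            "n_amplified": rep.n_amplified,
            "coverage_percent": round(rep.coverage_percent, 2),
            "amplicon_min": summary.get("min"),
            "amplicon_median": summary.get("median"),
            "amplicon_max": summary.get("max"),
        })
    return pd.DataFrame(rows)


def read_primer_tsv(path) -> list[PrimerPair]:
    """Read a name<TAB>fwd<TAB>rev primer table."""
    table = pd.read_csv(path, sep="\t", header=None,
                        names=["name", "fwd", "rev"], dtype=str, comment="#")
    return [PrimerPair(r.name, r.fwd, r.rev, source=str(path))
            for r in table.itertuples(index=False)]
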