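"""Synthetic genome fixtures with planted rRNA operons.

Generates FASTA + GFF3 + manifest + truth tables so every pipeline
stage can be tested without downloading real assemblies. Each genome is
one contig carrying a drawn number of 16S-ITS-23S operons built from
fixed synthetic 16S/23S template sequences (canonical lengths 1534 and
2924 nt, carrying intact binding sites for the bundled primer panel),
mutated per region at configured per-site substitution rates, separated
by a per-lineage ITS, and embedded in random flanking DNA.

Default distributions mirror what large assembly collections show:
per-genome copy number Poisson-like with mean 5.29, ITS lengths around
440 +/- 180 nt, and diversity concentrated in the ITS. Anomalies
(partial genes, oversized "unlinked" ITS regions, origin-crossing
operons) are planted at configurable fractions and recorded in the
truth table together with an expected-surviving flag.

Mutations are substitution-only by default, so planted per-region
mutation counts are recovered exactly by the diversity module's
distance arithmetic.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq_io import (ContigRecord, GenomicInterval, GffFeature, reverse_complement,
                     write_fasta, write_gff3)

_TEMPLATE_SEED = 714225  # fixed: templates are constants of the package
_BASES = np.array(list("ACGT"))

CANON_16S = 1534
CANON_23S = 2924
LEN_5S = 115

# Concrete expansions of the bundled primer panel's degenerate primers,
# planted in the templates so in-silico PCR finds intact sites.
_SITE_27F = "AGAGTTTGATCCTGGCTCAG"          # at 16S position 0
_SITE_519F = "CAGCAGCCGCGGTAA"              # at 16S position 500
_PRIMER_2241R = "ACCACCCCAGTAAAACT"         # antisense 5'->3'; site ends at 23S 2241
_PRIMER_2428R = "CCAAACTGTCTCACGACG"        # antisense 5'->3'; site ends at 23S 2428


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def build_templates() -> tuple[str, str]:
    """The fixed synthetic 16S and 23S template sequences."""
    rng = np.random.default_rng(_TEMPLATE_SEED)
    s16 = list(_random_bases(rng, CANON_16S))
    s16[0:len(_SITE_27F)] = _SITE_27F
    s16[500:500 + len(_SITE_519F)] = _SITE_519F
    s23 = list(_random_bases(rng, CANON_23S))
    site_2241 = reverse_complement(_PRIMER_2241R)
    site_2428 = reverse_complement(_PRIMER_2428R)
    s23[2241 - len(site_2241):2241] = site_2241
    s23[2428 - len(site_2428):2428] = site_2428
    return "".join(s16), "".join(s23)


# Primer-site positions inside the templates, kept substitution-free by
# default so the bundled panel finds intact sites on clean fixtures.
PROTECTED_16S = frozenset(range(0, len(_SITE_27F))) | frozenset(
    range(500, 500 + len(_SITE_519F)))
PROTECTED_23S = frozenset(range(2241 - len(_PRIMER_2241R), 2241)) | frozenset(
    range(2428 - len(_PRIMER_2428R), 2428))


def mutate_region(seq: str, n_subs: int, rng: np.random.Generator,
                  forbidden: frozenset[int] | None = None
                  ) -> tuple[str, list[int]]:
    """Apply exactly ``n_subs`` substitutions at distinct positions,
    never restoring the original base; ``forbidden`` positions are
    never mutated."""
    if n_subs == 0:
        return seq, []
    if forbidden:
        candidates = np.array([i for i in range(len(seq)) if i not in forbidden])
    else:
        candidates = np.arange(len(seq))
    if n_subs > len(candidates):
        raise ValueError(f"cannot place {n_subs} substitutions in "
                         f"{len(candidates)} mutable positions")
    positions = sorted(int(p) for p in rng.choice(candidates, n_subs, replace=False))
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(out), positions


@dataclass
class SynthConfig:
    """Parameters of the synthetic fixture generator.

    The seed fully determines the output; all fractions live in [0, 1].
    """

    n_genomes: int = 5
    copy_number: float = 5.29          # mean (poisson) or value (fixed)
    copy_number_dist: str = "poisson"  # "poisson" | "fixed"
    its_mean: float = 440.0
    its_sd: float = 180.0
    its_min: int = 50
    mutation_rates: dict[str, float] = field(
        default_factory=lambda: {"16S": 3e-4, "ITS": 1.5e-3, "23S": 3e-4})
    fraction_minus_strand: float = 0.3
    partial_fraction: float = 0.0
    oversized_its_fraction: float = 0.0
    origin_crossing_fraction: float = 0.0
    incomplete_fraction: float = 0.0
    n_lineages: int = 3
    lineage_divergence: float = 0.05   # per-site, founder templates
    include_5s: bool = True
    protect_primer_sites: bool = True
    flank: int = 500
    spacer_mean: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_minus_strand", "partial_fraction",
                     "oversized_its_fraction", "origin_crossing_fraction",
                     "incomplete_fraction", "lineage_divergence"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_genomes < 1 or self.n_lineages < 1:
            raise ValueError("need at least one genome and one lineage")
        if self.copy_number_dist not in ("poisson", "fixed"):
            raise ValueError("copy_number_dist must be 'poisson' or 'fixed'")


@dataclass
class SynthFixture:
    """In-memory fixture: per-genome contigs and features, plus tables."""

    genomes: dict[str, tuple[list[ContigRecord], list[GffFeature]]]
    manifest: pd.DataFrame
    truth: pd.DataFrame
    lineages: dict[str, str]
    config: SynthConfig


def _lineage_string(i: int) -> str:
    return (f"k__Bacteria;p__Synphylum{i};c__Synclass{i};o__Synorder{i};"
            f"f__Synfamily{i};g__Syngenus{i};s__Syngenus{i} synspecies{i}")


def generate_fixture(config: SynthConfig, outdir: str | os.PathLike | None = None
                     ) -> SynthFixture:
    """Generate a fixture; byte-identical output for equal seeds.

    When ``outdir`` is given, writes <genome>.fasta and <genome>.gff3
    per genome plus manifest.tsv, truth.tsv and config.json.
    """
    rng = np.random.default_rng(config.seed)
    tmpl16, tmpl23 = build_templates()

    # Lineage founder sequences: diverged copies of the templates plus a
    # lineage-specific ITS (and a throwaway 5S).
    founders = []
    for i in range(config.n_lineages):
        protected16 = PROTECTED_16S if config.protect_primer_sites else None
        protected23 = PROTECTED_23S if config.protect_primer_sites else None
        f16, _ = mutate_region(
            tmpl16, int(round(config.lineage_divergence * CANON_16S)), rng,
            forbidden=protected16)
        f23, _ = mutate_region(
            tmpl23, int(round(config.lineage_divergence * CANON_23S)), rng,
            forbidden=protected23)
        its_len = max(config.its_min,
                      int(round(rng.normal(config.its_mean, config.its_sd))))
        f_its = _random_bases(rng, its_len)
        f5s = _random_bases(rng, LEN_5S)
        founders.append((f16, f_its, f23, f5s))

    genomes: dict[str, tuple[list[ContigRecord], list[GffFeature]]] = {}
    lineage_of: dict[str, str] = {}
    manifest_rows = []
    truth_rows = []

    for g in range(config.n_genomes):
        genome_id = f"G{g:03d}"
        contig_id = f"{genome_id}_c1"
        lineage_idx = g % config.n_lineages
        f16, f_its, f23, f5s = founders[lineage_idx]
        assembly_level = ("incomplete"
                          if rng.random() < config.incomplete_fraction
                          else "complete")
        if config.copy_number_dist == "fixed":
            n_copies = max(1, int(round(config.copy_number)))
        else:
            n_copies = max(1, int(rng.poisson(config.copy_number)))

        parts: list[str] = [_random_bases(rng, config.flank)]
        cursor = config.flank
        features: list[GffFeature] = []
        origin_planted = False
        origin_copy = None  # deferred to the contig end

        for c in range(n_copies):
            # Draw anomaly class for this copy.
            u = rng.random()
            p_part = config.partial_fraction
            p_over = config.oversized_its_fraction
            p_orig = config.origin_crossing_fraction
            if u < p_part:
                anomaly = "partial"
            elif u < p_part + p_over:
                anomaly = "unlinked"
            elif u < p_part + p_over + p_orig and not origin_planted:
                anomaly = "boundary"
                origin_planted = True
            else:
                anomaly = "none"

            n16 = int(rng.binomial(CANON_16S, config.mutation_rates["16S"]))
            n23 = int(rng.binomial(CANON_23S, config.mutation_rates["23S"]))
            s16, _ = mutate_region(
                f16, n16, rng,
                forbidden=PROTECTED_16S if config.protect_primer_sites else None)
            s23, _ = mutate_region(
                f23, n23, rng,
                forbidden=PROTECTED_23S if config.protect_primer_sites else None)

            if anomaly == "unlinked":
                its_seq = _random_bases(rng, int(rng.integers(1600, 2800)))
                n_its = 0
            else:
                n_its = int(rng.binomial(len(f_its), config.mutation_rates["ITS"]))
                its_seq, _ = mutate_region(f_its, n_its, rng)

            if anomaly == "partial":
                # Truncate the 16S below the 80 % coverage threshold.
                keep = int(CANON_16S * rng.uniform(0.3, 0.7))
                s16 = s16[:keep]

            strand = "-" if rng.random() < config.fraction_minus_strand else "+"
            if anomaly == "boundary":
                strand = "+"  # origin-wrapping copies are planted on '+'
                origin_copy = (s16, its_seq, s23, n16, n_its, n23)
                continue

            op_seq = s16 + its_seq + s23
            len16, len_its, len23 = len(s16), len(its_seq), len(s23)
            start = cursor
            end = start + len(op_seq)
            if strand == "+":
                parts.append(op_seq)
                iv16 = GenomicInterval(contig_id, start, start + len16, "+")
                iv23 = GenomicInterval(contig_id, end - len23, end, "+")
            else:
                parts.append(reverse_complement(op_seq))
                iv23 = GenomicInterval(contig_id, start, start + len23, "-")
                iv16 = GenomicInterval(contig_id, end - len16, end, "-")
            cursor = end
            features.append(GffFeature(
                interval=iv16, feature_type="rRNA", source="synth",
                attributes={"ID": f"{genome_id}_r{c}_16S",
                            "product": "16S ribosomal RNA"}))
            features.append(GffFeature(
                interval=iv23, feature_type="rRNA", source="synth",
                attributes={"ID": f"{genome_id}_r{c}_23S",
                            "product": "23S ribosomal RNA"}))
            if config.include_5s:
                gap5 = 60
                s5_start = cursor + gap5
                parts.append(_random_bases(rng, gap5) + f5s)
                iv5 = GenomicInterval(contig_id, s5_start, s5_start + LEN_5S, strand)
                features.append(GffFeature(
                    interval=iv5, feature_type="rRNA", source="synth",
                    attributes={"ID": f"{genome_id}_r{c}_5S",
                                "product": "5S ribosomal RNA"}))
                cursor = s5_start + LEN_5S
            spacer = int(rng.integers(config.spacer_mean // 2,
                                      config.spacer_mean * 3 // 2 + 1))
            parts.append(_random_bases(rng, spacer))
            cursor += spacer

            truth_rows.append({
                "genome_id": genome_id, "contig_id": contig_id,
                "start": start, "end": end, "strand": strand,
                "its_len": len_its,
                "n_sub_16s": n16, "n_sub_its": n_its, "n_sub_23s": n23,
                "anomaly": anomaly,
                "expect_survive": anomaly == "none",
            })

        core = "".join(parts)
        if origin_copy is not None:
            s16, its_seq, s23, n16, n_its, n23 = origin_copy
            op_seq = s16 + its_seq + s23
            wrap = 200  # bases of the operon that wrap onto the contig start
            part1, part2 = op_seq[:-wrap], op_seq[-wrap:]
            start = len(core)
            contig_seq = part2 + core[wrap:] + part1
            end = start + len(op_seq)  # virtual: extends past the contig end
            iv16 = GenomicInterval(contig_id, start, start + len(s16), "+")
            iv23 = GenomicInterval(contig_id, end - len(s23), end, "+")
            features.append(GffFeature(
                interval=iv16, feature_type="rRNA", source="synth",
                attributes={"ID": f"{genome_id}_origin_16S",
                            "product": "16S ribosomal RNA"}))
            features.append(GffFeature(
                interval=iv23, feature_type="rRNA", source="synth",
                attributes={"ID": f"{genome_id}_origin_23S",
                            "product": "23S ribosomal RNA"}))
            truth_rows.append({
                "genome_id": genome_id, "contig_id": contig_id,
                "start": start, "end": end, "strand": "+",
                "its_len": len(its_seq),
                "n_sub_16s": n16, "n_sub_its": n_its, "n_sub_23s": n23,
                "anomaly": "boundary",
                "expect_survive": False,
            })
        else:
            contig_seq = core

        contig = ContigRecord(contig_id, contig_seq)
        features.sort(key=lambda f: f.interval.start)
        genomes[genome_id] = ([contig], features)
        lineage_of[genome_id] = _lineage_string(lineage_idx)
        manifest_rows.append({
            "genome_id": genome_id,
            "fasta": f"{genome_id}.fasta",
            "gff": f"{genome_id}.gff3",
            "assembly_level": assembly_level,
            "lineage": lineage_of[genome_id],
        })

    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows, columns=[
        "genome_id", "contig_id", "start", "end", "strand", "its_len",
        "n_sub_16s", "n_sub_its", "n_sub_23s", "anomaly", "expect_survive"])
    fixture = SynthFixture(genomes=genomes, manifest=manifest, truth=truth,
                           lineages=lineage_of, config=config)
    if outdir is not None:
        write_fixture(fixture, outdir)
    return fixture


def write_fixture(fixture: SynthFixture, outdir: str | os.PathLike) -> None:
    """Write a fixture directory: per-genome FASTA/GFF3, manifest.tsv,
    truth.tsv, and the resolved config as JSON."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    for genome_id, (contigs, features) in fixture.genomes.items():
        write_fasta(contigs, os.path.join(outdir, f"{genome_id}.fasta"))
        write_gff3(features, os.path.join(outdir, f"{genome_id}.gff3"))
    fixture.manifest.to_csv(os.path.join(outdir, "manifest.tsv"),
                            sep="\t", index=False)
    fixture.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(dataclasses.asdict(fixture.config), fh, indent=2, sort_keys=True)
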