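# Methods

This note documents the procedures `rrndb` implements, the defaults it
ships, the numerical choices that were genuinely open, and what its
synthetic fixtures do and do not demonstrate about real data.

## Operon model and extraction

An rrn operon is a 16S and a 23S rRNA gene on the same contig and
strand, in 16S→ITS→23S order along the direction of transcription,
with the internal transcribed spacer (ITS) defined as the inter-gene
gap (possibly zero-length). Extraction proceeds per contig and strand:

* **Classification.** GFF3 `rRNA` features are typed by their
  `product`/`Name` text (substring 16S/23S/5S adjacent to "ribosomal
  RNA"/"rRNA", case-insensitive). Coverage is annotated length over a
  canonical length — 16S 1534 nt, 23S 2924 nt, the observed mean
  full-length values in large assembly collections — and genes under
  80 % coverage, or annotated `partial=true`, are flagged partial and
  excluded from linking.
* **Linking.** Genes are scanned in transcription order; each 16S takes
  the nearest unconsumed downstream 23S. "Nearest downstream with each
  gene used once" is a deterministic reading of iterative
  neighbour-association; ties cannot arise because genes are totally
  ordered by coordinate. Pairs whose annotations overlap (negative
  spacer) are rejected: a negative spacer is biologically implausible
  and breaks interval arithmetic.
* **Filters.** Operons with ITS > 1500 nt are removed as "unlinked"
  (the threshold is strict: exactly 1500 is kept, because the rule is
  *longer than* 1.5 kb). Operons not fully contained in `[0, contig
  length)` are removed as "boundary"; containment is linear even for
  circular replicons — origin-wrapping operons are discarded, not
  re-stitched.
* **Sequences and IDs.** Minus-strand operons are reverse-complemented
  so every output sequence reads 16S→ITS→23S. IDs embed genome, contig,
  coordinates and strand, and parse back losslessly.

All internal coordinates are 0-based half-open; GFF3 converts to/from
1-based inclusive only at the serialisation boundary.

## Identity and dereplication

Identity between two sequences is computed from a single global
alignment with **free terminal gaps**, scoring match +1, mismatch −1,
gap −2, ties in the traceback resolved diagonal > up > left, as

```
identity = 100 · matching columns / alignment columns
```

with columns inside a terminal-gap run of either sequence excluded
from both counts (internal gap columns count as differing columns).
Arguments are canonically ordered (by length, then lexicographically)
before alignment, so tie-breaking between co-optimal alignments cannot
make the identity depend on argument order — the function is symmetric
by construction.
General-purpose clustering tools expose several identity definitions;
this one is pinned explicitly so results are reproducible. The
dynamic programme is implemented as a numba kernel, banded around the
diagonal with a band sized from the unit-cost edit distance
(`2·d + 32`, falling back to the full matrix when the band would reach
the sequence length); a fast unit-cost screen (edlib) rejects
obviously sub-threshold candidate pairs during clustering but never
produces a reported identity. Tests check the implementation against
an independent pure-python DP oracle and the banded against the
unbanded kernel.

Clustering is single-pass greedy over sequences sorted by descending
length (ties by ID): a sequence joins the **best-identity** centroid at
or above the threshold (default 99.9 %), else founds a new cluster.
Assignment to the best qualifying centroid, rather than the first
found, keeps results independent of centroid bookkeeping order. The
longest-first scan makes every representative the longest member of
its cluster. Two-phase mode clusters complete-assembly sequences
first, then pools the representatives with incomplete-assembly
sequences and re-clusters, so lower-quality material is retained only
where it expands diversity.

Consensus sequences come from a star alignment of members to the
representative (not a full MSA): per column the most frequent symbol
wins, columns where the gap is strictly most frequent are dropped, and
base ties break by the fixed order A < C < G < T. A star alignment is
deterministic and cheap, and is exact for single-member and
identical-member clusters — the large majority in practice. Stacked
insertions from different members at the same representative position
are ordered by occurrence, a known star-alignment approximation.

## Taxonomy systems

Lineages are seven ranks (kingdom…species) with prefix serialisation
(`k__;p__;…;s__`); an empty rank forces all deeper ranks empty.
Cluster taxonomy:

* **taxRep** — the representative's source-genome lineage, unchanged.
* **taxLCA** — deepest rank at which all members share an identical
  path from the kingdom down.
* **taxMaj** — scanning species→kingdom, the first *full lineage
  prefix* shared by strictly more than half the members. Voting on
  full prefixes (not bare rank names) prevents homonymous names under
  different parents from pooling votes; exact 50/50 ties fall to the
  next rank up, since a "simple majority" conventionally excludes
  ties. Each member sequence votes once, even when several members
  come from one genome.

## Intragenomic diversity

For every genome with ≥ 2 surviving operons, pairwise distances are
computed per region (whole operon, 16S, ITS, 23S) as p-distances
scaled to SNVs per 100 comparable sites: columns where either sequence
carries a gap or an N are excluded from numerator and denominator
(ambiguity codes are not half-matched). Identity is 100 − distance,
and `snv_estimate(identity, mean_length)` converts an identity to an
approximate SNV count.

Two deliberate deviations from an MSA-based workflow: pairs are
aligned pairwise with the dereplication aligner rather than through a
per-genome MSA (removes an alignment-heuristic dependence; exact for
substitution-only comparisons), and summary statistics pool all
pairwise identities across genomes rather than averaging per genome.
`fraction_genomes_diverse` is the share of multi-copy genomes with any
pairwise identity below 100. The IQR outlier rule applies to the
optional plots only, never to statistics. Cross-region Pearson
correlations match identities by operon pair; region pairs with < 3
complete observations or zero variance are reported missing.

## In-silico PCR

Primer matching is per-position IUPAC set membership (R = {A,G}, …);
degenerate primers are never expanded combinatorially. A template
position matches only when it is a concrete base inside the primer
code's set — template N or ambiguity codes never match, so N-runs
cannot fabricate binding sites. Defaults: 0 mismatches (configurable)
and a 10 kb product cap, comfortably above the ~4.9 kb expected
operon amplicon but bounding runaway pairings on concatenated input.
Reverse primers are given 5'→3' on the antisense strand (the
conventional way primer sequences are written) and reverse-complemented
before sense-strand scanning; each forward site pairs with the nearest
downstream reverse site, and the template's reverse complement is
scanned symmetrically with results mapped back to template
coordinates. Coverage is the percentage of database sequences with at
least one predicted product.

## Synthetic fixtures

The generator emulates the layout extraction depends on: one contig
per genome, operons built from two fixed synthetic template genes
(1534/2924 nt, generated once from a fixed internal seed, carrying
intact binding sites for the bundled primer panel), a per-lineage ITS,
random flanks and spacers, an optional trailing 5S gene, and GFF3 rows
with product strings the classifier recognises.

Defaults (chosen once, as study conditions, not tuning knobs):

| parameter | default | rationale |
|---|---|---|
| copy number | Poisson, mean 5.29 (min 1) | observed per-genome rRNA copy-number mean in complete genomes |
| ITS length | normal(440, 180), min 50 | observed ITS mean/SD |
| per-site substitution rates | 16S 3·10⁻⁴, ITS 1.5·10⁻³, 23S 3·10⁻⁴ | places pairwise operon identities near the ~99.9 % major intragenomic peak with the ITS carrying most diversity |
| lineage divergence | 5 % per site | far below the 99.9 % clustering radius, so lineages are unambiguous cluster truth |
| minus-strand fraction | 0.3 | exercises strand handling without dominating |
| anomaly fractions | 0 | anomalies are opt-in per test |

Anomalies: *partial* truncates a 16S below 80 % coverage; *unlinked*
replaces the ITS with a 1.6–2.8 kb spacer; *boundary* wraps one
operon (always plus-strand, at most one per contig) across the contig
origin, annotated with an end coordinate past the contig end. The
truth table records coordinates, strand, per-region substitution
counts, the anomaly class, and an expected-surviving flag.

What the fixtures do **not** model: indels (off by default, so SNV
arithmetic is exact), rate heterogeneity along genes, chimeras,
multi-contig fragmentation of operons, assembly collapse of near-
identical repeats, and realistic phylogenetic structure. Passing
planted-truth tests therefore demonstrates the pipeline's bookkeeping
and arithmetic, not robustness to assembly artefacts.

## Problem sizes and determinism

The test suite and examples run on fixtures of 2–50 genomes (up to
~250 operons, ~5 kb each); the full-pipeline integration test uses 50
genomes and completes in well under five minutes on one CPU. Every
stage is deterministic given inputs, configuration and seed: a single
`numpy` Generator drives all fixture randomness, clustering order is
fixed by the length/ID sort, and alignment tie-breaks are pinned.

## Known limitations

* The identity formula and best-hit assignment are documented stand-ins
  for tool-specific clustering heuristics (accept orders, k-mer
  prescreens); cluster counts on borderline data can differ from any
  particular external tool's output.
* The banded alignment is exact whenever the optimal path stays within
  the band; the band is sized generously from the edit distance, and
  banded-vs-full agreement is tested on mutated pairs, but adversarial
  repeat structures could in principle differ.
* Coverage estimation for partial genes relies on annotated gene
  lengths against canonical means; unusual genes (e.g. large
  intervening sequences) may be misflagged.
* Origin-wrapping operons are discarded rather than re-stitched, so
  genuine operons at the origin of circular replicons are lost — a
  deliberate quality-control trade-off.
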