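# Methods

This note documents the models and contracts behind bgcminer's five
analyses, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions applied
throughout.

## Coordinate model

All internal coordinates are 0-based half-open on the forward strand;
GenBank and GFF3 readers/writers convert at the boundary (GFF3 columns 4/5
are 1-based inclusive). Strand is strictly `+1`/`-1`; strandless CDS
features are rejected because binding-site context and motif scanning need
an orientation. Missing translations are computed with bacterial
translation table 11 (the toolkit targets bacterial genomes); a CDS whose
length is not a multiple of 3, or that contains internal stops, is an
error rather than silently truncated. Joined (multi-interval) CDS
locations are out of scope.

## Rule-based cluster detection

A detection rule is `(name, category, cutoff_kb, neighbourhood_kb,
condition)`. The condition grammar has `and` binding tighter than `or`,
prefix `not`, `minimum(n, [profiles])` and a `cds(...)` scope. Semantics:

- *Gap distance* between two genes is the number of base pairs between
  their nearest boundaries, 0 when they overlap. It is symmetric and
  strand-free, matching the intuition of a "cutoff" distance.
- A gene is **core** iff it carries ≥1 hit to a profile referenced by the
  condition and the condition is true over the multiset of hits on all
  genes within `cutoff_kb` of it. A leaf is true when any windowed gene
  has a hit to that profile; `minimum(n, opts)` counts **distinct profile
  names** (not distinct genes) present in the window; `cds(expr)` is true
  when a *single* windowed gene satisfies `expr` on its own hits.
- Core genes chain by single linkage at the same cutoff distance
  (deterministic and order-independent); each chain's span is extended by
  `neighbourhood_kb` per side and clamped to `[0, contig_length]`.
- Protoclusters whose extended spans strictly overlap merge transitively
  into regions; abutting spans do not merge. Region products are the
  sorted unique rule names.

Rules fire independently; cross-rule superiority/override mechanisms are
not modelled. The shipped rule file is a small illustration of the DSL
(including phosphonate-like and NRP-metallophore-like shapes), not a
curated rule set.

The `minimum` reading (distinct profiles) is the simplest well-defined
one; callers wanting "distinct genes" semantics can express it with
`cds()` conjunctions.

## Dynamic profiles

A dynamic profile is a protein regular expression searched (not anchored)
against each CDS translation. At most one hit per (gene, profile) is
emitted because rule conditions are existence-based. Motif hits carry a
fixed score (default 20.0) so the rule engine treats pHMM-derived and
motif-derived hits uniformly — a short motif has no meaningful bitscore.
The bundled cyanobactin precursor motif is `M.KKN[IL].P....PV.R`; the
four-wildcard spacer is a fixed-length gap, and users can override the
pattern by supplying their own `DynamicProfile`.

External hit tables are 4-column TSV (`locus_tag, profile, bitscore,
evalue`, `#` comments allowed) or genuine HMMER `--domtblout` via a flag
(full-sequence score and E-value are used; per-domain coordinates are not
consumed by the rule engine). Per-profile bitscore cutoffs default to 0.
Rows naming unknown genes are dropped with a warning rather than failing
the run, since hit tables are often produced against a slightly different
annotation.

## TFBS scanning

PWM construction uses the standard pseudocount log-odds form

    log_odds[i,a] = log2((counts[i,a] + p·bg[a]) / (N_i + p) / bg[a])

with pseudocount `p = 1.0` and a uniform background by default; a
GC-matched background is available because real actinobacterial genomes
are strongly GC-biased while the fixtures are uniform.

Confidence tiers are **fractions of the normalised score range**:
`s = (score − min_score)/(max_score − min_score)`, strong ≥ 0.90, medium
≥ 0.75, weak ≥ 0.60, below weak suppressed. Range-normalisation makes the
rule independent of matrix length; boundary scores map to the *higher*
tier (≥ comparisons) as the deterministic tie rule. A matrix with
`max_score == min_score` cannot be tiered and is a hard error. Windows
containing `N` are dropped rather than penalised, avoiding background
artifacts. Reverse-strand scores are computed by scanning with the
reverse-complemented matrix, so a hit's `start` is always the
forward-strand coordinate of the window's left edge; palindromic windows
legitimately produce one hit per strand at the same start.

Context annotation (default `upstream_limit` 300 bp, a generous bacterial
promoter distance): a window overlapping a CDS is `within-gene`, or
`overlaps-start-codon` when it intersects the first three coding bases
(strand-aware). Intergenic windows classify by which flanking 5′ ends face
the site within the limit: both → `upstream-of-both` (divergent promoter
region), exactly one → `upstream-of-one`, none → `downstream-of-both`
(which therefore covers convergent flanks *and* the fallback where no
facing start is within the limit — tandem genes far away, or divergent
genes beyond the limit); a missing flank → `contig-edge`.

## NRPS substrate prediction

Signature extraction aligns the query to a reference A domain with
BLOSUM62, gap open 10, extend 0.5, global mode with free end gaps (A
domains are globally alignable; free end gaps tolerate fragment inputs).
Each reference signature position reads off the aligned query residue, or
`-` when the query has a gap there; `-` never matches during lookup
(deletions are not rewarded). Queries under 100 residues are rejected, and
an alignment identity below 15% of reference length raises a
low-confidence error signalling non-A-domain input.

Lookup: `matches10` is the Hamming-style agreement with each entry's
10-AA code; all entries tied at the table-wide maximum are reported if
that maximum reaches `min_matches10` (default 7 — below 70% the 10-AA code
is known to be unreliable). Ties are grouped by substrate and ranked by
the group's best 34-AA agreement, then substrate name, then source ids —
a total order, so output is reproducible. Entries with identical codes but
conflicting substrates are all reported (grouped by substrate), never
deduplicated away.

The reference domain, its 10/34 positions and the lookup table are **data
files**; the bundled ones are deterministic synthetic stand-ins (filenames
carry `synthetic_`) so a curated, e.g. MIBiG-derived, table in the same
TSV format is a drop-in replacement.

## Core-peptide identity

Scoring is match +1, mismatch −1, gap open −2, gap extension −1 — a
deliberately simple symmetric scheme, since core peptides are short and
the quantity reported is plain percent identity. The identity denominator
is `max(|query|, |hit|)`, so 100% is equivalent to exact equality and
length mismatches are penalised. Among co-optimal alignments the one with
the most identical pairs is selected by a lexicographic (score, matches)
three-state affine dynamic programme; this makes the reported identity a
deterministic, symmetric function of the two sequences instead of an
aligner tie-breaking artifact. Databases are FASTA with `>id|label`
headers; entries with identical core sequences share one group and one
alignment. Multiple databases (e.g. a MIBiG-like and a larger
predicted-precursor set) are reported in separate sections. Rendering
wraps at 60 columns with `|` at identities.

## Synthetic data

The fixtures module generates every input format the toolkit consumes,
deterministically from a spec + seed (child streams are derived per
component name, so adding a generator never perturbs existing outputs).

- **Genomes**: uniform ACGT background; genes are `ATG` + one fixed codon
  per residue + `TAA`, 300–1500 bp for background genes, placed without
  overlap (margin 60 bp). Planted cluster genes sit ~100 bp apart from a
  given anchor and receive hit-table rows (bitscore 100–300); background
  genes receive none. Planted binding sites embed the PWM consensus
  verbatim (reverse-complemented for −-strand plants) in intergenic space.
  Planted precursor genes carry a 20-residue random leader plus the given
  core. The truth table records expected region spans (core span ±
  neighbourhood, clamped), planted site positions/strands and core
  sequences.
- **PWMs**: per column, the consensus base receives `round(100·q)` counts
  (`q` the per-column consensus probability, called *information* in the
  API), the remainder spread uniformly. The default fixture PWM is a
  12-bp consensus at q = 0.9: under the 0.90 strong fraction an off-plant
  strong call needs ≥11/12 consensus bases, whose binomial tail
  (~2·10⁻⁶ per window) keeps expected false strong calls per 100 kb
  strand well below one, while planted consensus windows score the matrix
  maximum. An 8-bp consensus cannot meet that bound (exact-consensus
  background matches alone occur ~1.5 times per 100 kb strand), which is
  why the fixture consensus is 12 bp.
- **Stachelhaus tables**: entries are seeded point-mutated copies
  (default rate 0.15–0.3) of one random base signature with amino-acid
  substrate labels cycling through 20 names.

What the fixtures do *not* emulate: codon usage, GC skew, operons,
overlapping genes, pseudogenes, sequencing noise, homology between
background genes, or realistic PWM shapes. Passing the recovery tests
therefore demonstrates correct coordinate arithmetic, window logic,
scoring and ranking — not detection power on real genomes, where profile
quality and rule curation dominate.

## Output formats

Sideload JSON follows the bundled schema
(`src/bgcminer/data/sideload_schema.json`): a `tool {name, version}` block
and per-record `subregions` with 0-based half-open `start`/`end`, `label`
and string-valued `details`. Documents are validated against the schema
before writing. GFF3 output carries CDS features (with `translation`
attributes so annotation round-trips losslessly), region/protocluster
features with rule names, and TFBS features with score and confidence.
BED6 scores are bits × 100, rounded, since BED scores are integers.

## Limitations

- The rule engine models no rule superiority or cross-rule suppression.
- Dynamic profiles are regex-only (no arbitrary scoring code).
- PWM scores are not calibrated to p-values; tiers are range fractions,
  and per-PWM tier fractions are configuration, not learned thresholds.
- The shipped reference A domain and lookup table are synthetic; real
  predictions require curated data supplied by the user.
- Single-interval CDS only; no fungal (spliced) gene models.
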