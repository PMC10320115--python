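# bgcminer

A compact genome-mining toolkit for microbial secondary metabolism. Given an
annotated genome and a table of profile (pHMM) hits, it detects biosynthetic
gene cluster (BGC) regions with a rule engine, runs protein-regex "dynamic
profile" detectors, annotates transcription-factor binding sites (TFBS) with
position weight matrices, predicts NRPS adenylation-domain substrates from
the Stachelhaus code, and compares RiPP core peptides against precursor
databases.

It is aimed at people building or testing genome-mining pipelines: every
analysis is a plain library function over small dataclasses, every input is
a plain-text format, and a seeded fixtures module generates complete
synthetic datasets with known ground truth.

## What it computes

**Cluster detection.** A detection rule names the core biosynthetic
functions that must co-occur within a genomic window to constitute a BGC,
as a boolean condition over profile hits:

```
RULE nrps CATEGORY NRPS CUTOFF 20 NEIGHBOURHOOD 20
CONDITIONS cds(AMP-binding and Condensation)
```

A gene *c* is a *core* gene iff it has a hit to a profile the rule
references and the condition holds over the hits of all genes within
`CUTOFF` kb of *c* (gap distance between nearest gene boundaries;
`cds(expr)` additionally demands a single gene satisfying `expr` alone,
`minimum(n, [...])` demands hits to ≥ n distinct profiles from the list).
Core genes within `CUTOFF` kb of each other chain into a *protocluster*,
extended by `NEIGHBOURHOOD` kb per side and clamped to the contig;
overlapping protoclusters from different rules merge into hybrid *regions*.
Detectors too small for a reliable pHMM are *dynamic profiles* — protein
regexes over CDS translations; the bundled one recognises cyanobactin
precursor leaders via `M.KKN[IL].P....PV.R`.

**TFBS scanning.** For a count matrix with pseudocount *p* and background
*b*, position *i*, base *a*:

```
log_odds[i,a] = log2( (counts[i,a] + p·b[a]) / (N_i + p) / b[a] )
```

Both strands of every window are scored; the score is normalised over the
matrix's attainable range `[min_score, max_score]` and tiered
strong/medium/weak at fractions 0.90/0.75/0.60 of that range. Each hit is
placed in genomic context (within-gene, overlaps-start-codon,
upstream-of-one/both, downstream-of-both, contig-edge) with distances and
orientations of the flanking genes.

**NRPS substrate prediction.** The query A domain is aligned to a reference
domain (BLOSUM62, end-gap-free global) to read off the 10 active-site
residues of the Stachelhaus code and the extended 34-residue signature
(positions within 8 Å of the active site). Lookup reports *all* table
entries tied at the best 10-AA match count, grouped by substrate and ranked
by the best 34-AA match — the two-level ranking that resolves promiscuous
A domains sharing a 10-AA code.

**RiPP core-peptide comparison.** Database precursors with identical core
sequences are grouped; one global alignment per group (match +1, mismatch
−1, gap open −2, extend −1) yields

```
identity% = 100 · identical pairs / max(|query|, |hit|)
```

so 100% means exact equality (the "self hit"). Matches are ranked by
identity with deterministic tie-breaks and rendered as wrapped
query/midline/hit alignment blocks.

## Worked example

Generate a synthetic genome with one planted NRPS cluster and one planted
binding site, then run detection and TFBS scanning:

```
$ bgcminer fixtures --out-dir demo --seed 5
wrote demo/synthetic_contig_1.gbk, demo/synthetic_contig_1.hits.tsv, demo/pwms.txt, demo/truth.json

$ bgcminer detect --genome demo/synthetic_contig_1.gbk \
                  --hits demo/synthetic_contig_1.hits.tsv \
                  --out-json demo/regions.json --out-gff3 demo/regions.gff3
1 region(s) detected

$ bgcminer tfbs --genome demo/synthetic_contig_1.gbk --pwms demo/pwms.txt \
                --min-confidence strong --out-bed -
synthetic_contig_1	5000	5012	synthetic_regulator_1	2205	+
1 TFBS hit(s)
```

The detected region in `demo/regions.json` spans `[0, 41534)` with product
`nrps` — exactly the span recorded in `demo/truth.json` (planted core genes
extended by the rule's 20 kb neighbourhood, clamped at the contig start).
The BED line reports the planted binding site at position 5000 on the
forward strand; the score column is bits × 100, so 2205 is the matrix's
22.05-bit maximum, a strong-tier hit.

Comparing a core peptide against a precursor database that contains it:

```
$ bgcminer comparippson --query q.faa --db db.faa
## database: db.faa
# query query_core: 2 match(es)
100.0%	nisin A
ITSISSLCTPGCKTGALMGCNMKTATCHCSIHVSK
|||||||||||||||||||||||||||||||||||
ITSISSLCTPGCKTGALMGCNMKTATCHCSIHVSK
37.1%	gallidermin
ITSISSLCTPGC-KTGALMGCNMKTATCHCSIHVSK
| |    ||||| |||     |     | |      
IAS-KFICTPGCAKTG---SFN---SYC-C------
```

The identical entry is the 100% self hit; the homologous lanthipeptide
scores 37.1%.

## Data files

The bundled reference A domain, its signature positions and the Stachelhaus
lookup table (`src/bgcminer/data/synthetic_*`) are deterministic synthetic
stand-ins so the toolkit is testable offline; a curated table in the same
4-column TSV format (`code10 code34 substrate source_id`) drops in via
`--table`/`--reference`/`--positions`. The demo detection rules are
illustrations of the rule DSL, not a curated rule set.
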