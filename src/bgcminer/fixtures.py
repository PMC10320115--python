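"""Seeded generators for every input the toolkit consumes.

Synthetic genomes with planted gene clusters, binding sites and precursor
genes give the test suite (and any user wanting a demo dataset) fully
self-contained inputs with known ground truth: the generator returns a
:class:`TruthTable` alongside the data, and the pipeline is expected to
recover exactly the planted elements.

The emulation is deliberately minimal: background DNA is uniform over ACGT,
genes use one fixed codon per amino acid, and there is no operon structure,
GC skew or realistic codon usage. What the fixtures exercise is the
*coordinate and scoring machinery* — rule-window arithmetic, boundary
clamping, strand handling, PWM tiers — not biological realism.

All generators are pure functions of (spec, seed); child random streams are
derived per component name, so adding a generator never perturbs the output
of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .errors import ValidationError
from .genome_io import AnnotatedRecord, CdsFeature
from .nrps_substrate import StachelhausEntry
from .rule_engine import DetectionRule
from .tfbs_finder import BASES, Pwm, build_pwm

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: one unambiguous codon per amino acid (translation table 11 compatible)
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
STOP_CODON = "TAA"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def child_rng(seed: int, *path: str) -> np.random.Generator:
    """A reproducible child stream named by ``path`` (splittable seeding)."""
    keys = [zlib.crc32(p.encode()) for p in path]
    return np.random.default_rng([int(seed)] + keys)


# ---------------------------------------------------------------------------
# specification and truth


@dataclass(frozen=True)
class PlantedCluster:
    """A cluster to embed: consecutive genes carrying the listed profiles."""

    rule_name: str
    gene_profiles: tuple[tuple[str, ...], ...]  # per planted gene
    start_bp: int


@dataclass(frozen=True)
class PlantedTfbs:
    pwm_name: str
    position: int
    strand: int


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    contig_length: int = 60_000
    n_background_genes: int = 20
    planted_clusters: tuple[PlantedCluster, ...] = ()
    planted_tfbs: tuple[PlantedTfbs, ...] = ()
    planted_precursors: tuple[str, ...] = ()
    seed: int = 0
    record_id: str = "synthetic_contig_1"


@dataclass(frozen=True)
class TruthTable:
    """What the pipeline is expected to recover from a synthetic genome."""

    regions: tuple[tuple[int, int, tuple[str, ...]], ...]  # start, end, products
    tfbs: tuple[PlantedTfbs, ...]
    precursor_cores: tuple[str, ...]


@dataclass
class GenomeFixture:
    record: AnnotatedRecord
    hit_rows: list[tuple[str, str, float, float]]
    truth: TruthTable

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write GenBank + hit-table TSV; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        gbk = out_dir / f"{self.record.record_id}.gbk"
        tsv = out_dir / f"{self.record.record_id}.hits.tsv"
        write_genbank(self.record, gbk)
        lines = ["#locus_tag\tprofile\tbitscore\tevalue"]
        for locus, profile, score, evalue in self.hit_rows:
            lines.append(f"{locus}\t{profile}\t{score:.1f}\t{evalue:.2e}")
        tsv.write_text("\n".join(lines) + "\n")
        return {"genbank": gbk, "hits": tsv}


def write_genbank(record: AnnotatedRecord, path: str | Path) -> None:
    seq_record = SeqRecord(
        Seq(record.sequence), id=record.record_id, name=record.record_id[:16],
        description="synthetic genome fixture",
        annotations={"molecule_type": "DNA"},
    )
    for feat in record.features:
        seq_record.features.append(
            SeqFeature(
                FeatureLocation(feat.start, feat.end, strand=feat.strand),
                type="CDS",
                qualifiers={
                    "locus_tag": [feat.locus_tag],
                    "translation": [feat.translation],
                    "product": [feat.product or "hypothetical protein"],
                },
            )
        )
    SeqIO.write([seq_record], str(path), "genbank")


# ---------------------------------------------------------------------------
# genome generation


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _gene_dna(protein: str) -> str:
    return "".join(CODON[aa] for aa in protein) + STOP_CODON


def generate_genome(
    spec: SyntheticGenomeSpec, rules: Sequence[DetectionRule] | None = None
) -> GenomeFixture:
    """Build a synthetic annotated contig with planted ground truth.

    Planted cluster genes are placed consecutively (about 100 bp apart) from
    each cluster's ``start_bp`` and receive hit-table rows; background genes
    (300-1500 bp, random strand) fill the remaining space and receive none.
    Planted binding sites and precursor genes must not collide with other
    planted elements; an infeasible packing raises :class:`ValidationError`.
    Expected region spans are derived from the rules' cutoff/neighbourhood
    distances. Deterministic for a given spec (the seed is part of it).
    """
    if rules is None:
        rules = demo_rules()
    rules_by_name = {r.name: r for r in rules}
    rng_genes = child_rng(spec.seed, "genes")
    rng_bg = child_rng(spec.seed, "background")
    rng_sites = child_rng(spec.seed, "sites")

    occupied: list[tuple[int, int]] = []  # reserved [start, end) intervals
    features: list[CdsFeature] = []
    hit_rows: list[tuple[str, str, float, float]] = []
    gene_counter = 0

    def reserve(start: int, end: int, what: str):
        if start < 0 or end > spec.contig_length:
            raise ValidationError(f"{what}: [{start}, {end}) outside contig")
        for s, e in occupied:
            if start < e and s < end:
                raise ValidationError(f"{what}: [{start}, {end}) collides with [{s}, {e})")
        occupied.append((start, end))

    def add_gene(start: int, protein: str, strand: int, what: str,
                 product: str = "") -> CdsFeature:
        nonlocal gene_counter
        gene_counter += 1
        dna = _gene_dna("M" + protein)
        end = start + len(dna)
        reserve(start, end, what)
        feat = CdsFeature(
            locus_tag=f"SYN_{gene_counter:04d}", start=start, end=end,
            strand=strand, translation="M" + protein, product=product,
        )
        features.append(feat)
        return feat

    # planted clusters first: genes ~100 bp apart, truth span from the rule
    expected_regions = []
    for cluster in spec.planted_clusters:
        rule = rules_by_name.get(cluster.rule_name)
        if rule is None:
            raise ValidationError(f"unknown rule {cluster.rule_name!r}")
        pos = cluster.start_bp
        core_start, core_end = None, None
        for profiles in cluster.gene_profiles:
            protein = _random_protein(rng_genes, int(rng_genes.integers(120, 400)))
            feat = add_gene(pos, protein, 1, f"cluster {cluster.rule_name}",
                            product=f"{cluster.rule_name} biosynthesis protein")
            for profile in profiles:
                score = 100.0 + float(rng_genes.integers(0, 200))
                hit_rows.append((feat.locus_tag, profile, score, 1e-30))
            if profiles:
                core_start = feat.start if core_start is None else core_start
                core_end = feat.end
            pos = feat.end + 100
        expected_regions.append(
            (
                max(0, core_start - rule.neighbourhood_bp),
                min(spec.contig_length, core_end + rule.neighbourhood_bp),
                (rule.name,),
            )
        )

    # planted binding sites reserve their window so no gene overwrites them
    for site in spec.planted_tfbs:
        reserve(site.position, site.position + _planted_site_length(site, spec),
                f"TFBS {site.pwm_name}")

    # precursor genes: leader + core, so the core is present in a translation
    for core in spec.planted_precursors:
        leader = _random_protein(rng_genes, 20)
        start = _find_free_slot(rng_genes, occupied, spec.contig_length,
                                (21 + len(core)) * 3 + 3)
        add_gene(start, leader + core, 1, "precursor gene",
                 product="RiPP precursor peptide")

    # background genes fill whatever space is left
    placed = 0
    attempts = 0
    while placed < spec.n_background_genes:
        attempts += 1
        if attempts > spec.n_background_genes * 200:
            raise ValidationError("infeasible packing: cannot place background genes")
        length_aa = int(rng_bg.integers(99, 499))  # 300-1500 bp incl. stop
        dna_len = (length_aa + 1) * 3 + 3
        try:
            start = _find_free_slot(rng_bg, occupied, spec.contig_length, dna_len)
        except ValidationError:
            raise ValidationError("infeasible packing: contig too crowded")
        protein = _random_protein(rng_bg, length_aa)
        strand = int(rng_bg.choice([1, -1]))
        add_gene(start, protein, strand, "background gene",
                 product="hypothetical protein")
        placed += 1

    # sequence: uniform background, genes overwritten, then binding sites
    sequence = np.array(list("ACGT"))[
        rng_bg.integers(0, 4, size=spec.contig_length)
    ]
    for feat in features:
        dna = _gene_dna(feat.translation)
        if feat.strand == -1:
            dna = dna.translate(_COMPLEMENT)[::-1]
        sequence[feat.start : feat.end] = list(dna)
    for site in spec.planted_tfbs:
        consensus = _planted_site_sequence(site, spec)
        sequence[site.position : site.position + len(consensus)] = list(consensus)

    record = AnnotatedRecord(spec.record_id, "".join(sequence), features)
    truth = TruthTable(
        regions=tuple(sorted(expected_regions)),
        tfbs=spec.planted_tfbs,
        precursor_cores=spec.planted_precursors,
    )
    _ = rng_sites  # reserved stream, keeps sibling streams stable
    return GenomeFixture(record, hit_rows, truth)


def _find_free_slot(
    rng: np.random.Generator, occupied: list[tuple[int, int]],
    contig_length: int, size: int, margin: int = 60, tries: int = 500,
) -> int:
    for _ in range(tries):
        start = int(rng.integers(0, max(1, contig_length - size)))
        span = (start - margin, start + size + margin)
        if all(not (span[0] < e and s < span[1]) for s, e in occupied):
            return start
    raise ValidationError("no free slot found")


# planted TFBS use the default PWM consensus unless a custom map is provided
_PLANTED_PWM_CONSENSUS: dict[str, str] = {}
DEFAULT_TFBS_CONSENSUS = "TGACGTCATGCA"  # 12-mer, see generate_pwm defaults


def _planted_site_sequence(site: PlantedTfbs, spec: SyntheticGenomeSpec) -> str:
    consensus = _PLANTED_PWM_CONSENSUS.get(site.pwm_name, DEFAULT_TFBS_CONSENSUS)
    if site.strand == -1:
        consensus = consensus.translate(_COMPLEMENT)[::-1]
    return consensus


def _planted_site_length(site: PlantedTfbs, spec: SyntheticGenomeSpec) -> int:
    return len(_planted_site_sequence(site, spec))


# ---------------------------------------------------------------------------
# PWM generation


def generate_pwm(
    consensus: str, information: float = 0.9, seed: int = 0,
    name: str = "synthetic_pwm", total: int = 100,
) -> Pwm:
    """A count matrix concentrating ``information`` probability per column on
    the consensus base, remainder spread uniformly; column totals are
    ``total``. Counts are a deterministic function of (consensus,
    information); the seed names the stream for interface uniformity."""
    if not 0.0 <= information <= 1.0:
        raise ValidationError("information must be in [0, 1]")
    if any(b not in BASES for b in consensus):
        raise ValidationError("consensus must be over ACGT")
    counts = np.zeros((len(consensus), 4), dtype=int)
    consensus_count = int(round(total * information))
    others = total - consensus_count
    for i, base in enumerate(consensus):
        ci = BASES.index(base)
        share, remainder = divmod(others, 3)
        for j in range(4):
            counts[i, j] = share
        counts[i, ci] = consensus_count
        # distribute remainder deterministically over non-consensus bases
        for j in [k for k in range(4) if k != ci][:remainder]:
            counts[i, j] += 1
    return build_pwm(counts, name=name)


def default_tfbs_pwm(name: str = "synthetic_regulator") -> Pwm:
    """The 12-bp, 0.9-information PWM used for planted-site fixtures."""
    return generate_pwm(DEFAULT_TFBS_CONSENSUS, information=0.9, name=name)


# ---------------------------------------------------------------------------
# Stachelhaus table generation


def generate_stachelhaus_table(
    n: int, mutation_rate: float = 0.15, seed: int = 0,
) -> list[StachelhausEntry]:
    """Derive ``n`` entries from one base signature by seeded point mutations.

    Substrate labels cycle through common amino-acid substrates; entries
    sharing a substrate index share mutation positions in code10 but not
    code34, which exercises the two-level ranking.
    """
    substrates = [
        "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    ]
    rng = child_rng(seed, "stachelhaus")
    base10 = _random_protein(rng, 10)
    base34 = _random_protein(rng, 34)
    entries = []
    for i in range(n):
        code10 = _mutate(base10, mutation_rate, rng)
        code34 = _mutate(base34, mutation_rate, rng)
        entries.append(
            StachelhausEntry(code10, code34, substrates[i % len(substrates)],
                             f"SYNREF_{i + 1:04d}")
        )
    return entries


def _mutate(code: str, rate: float, rng: np.random.Generator) -> str:
    out = list(code)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def write_stachelhaus_tsv(entries: Sequence[StachelhausEntry], path: str | Path) -> None:
    lines = ["code10\tcode34\tsubstrate\tsource_id"]
    for e in entries:
        lines.append(f"{e.code10}\t{e.code34}\t{e.substrate}\t{e.source_id}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# reference A domain generation


def generate_reference_adomain(seed: int = 0, length: int = 500):
    """A synthetic reference A domain plus 10/34 signature positions.

    Stand-in for a curated reference (e.g. the gramicidin S synthetase
    PheA domain), with positions spread over the central region the way
    real active-site residues are.
    """
    from .nrps_substrate import SignatureReference

    rng = child_rng(seed, "adomain_reference")
    sequence = _random_protein(rng, length)
    positions34 = tuple(
        sorted(int(p) for p in rng.choice(np.arange(150, 420), size=34, replace=False))
    )
    positions10 = tuple(sorted(rng.choice(positions34, size=10, replace=False).tolist()))
    return SignatureReference(sequence, positions10, positions34)


# ---------------------------------------------------------------------------
# demo rule set


DEMO_RULES_TEXT = """\
# Illustrative detection rules. These mimic the *shape* of curated rules
# (core functions, cutoff and neighbourhood distances in kb) but are not
# the published curated rule set; profile names are generic detector ids.
RULE t1pks CATEGORY PKS CUTOFF 20 NEIGHBOURHOOD 20
CONDITIONS cds(PKS_KS and PKS_AT)
RULE nrps CATEGORY NRPS CUTOFF 20 NEIGHBOURHOOD 20
CONDITIONS cds(AMP-binding and Condensation)
RULE terpene CATEGORY Terpene CUTOFF 20 NEIGHBOURHOOD 10
CONDITIONS Terpene_synth or Lycopene_cycl
RULE lanthipeptide CATEGORY RiPP CUTOFF 20 NEIGHBOURHOOD 10
CONDITIONS LANC_like and DUF4135
RULE cyanobactin CATEGORY RiPP CUTOFF 20 NEIGHBOURHOOD 10
CONDITIONS cyanobactin_synth or cyanobactin_precursor
RULE phosphonate-like CATEGORY Other CUTOFF 20 NEIGHBOURHOOD 20
CONDITIONS PEP_mutase
RULE phosphonate CATEGORY Other CUTOFF 20 NEIGHBOURHOOD 20
CONDITIONS PEP_mutase and minimum(1, [Ppd_decarb, Phosphonate_transfer])
RULE nrp-metallophore CATEGORY NRPS CUTOFF 20 NEIGHBOURHOOD 20
CONDITIONS cds(AMP-binding and Condensation) and minimum(1, [Chelator_mono, Chelator_diox, Salicylate_synth])
RULE betalactone CATEGORY Other CUTOFF 10 NEIGHBOURHOOD 10
CONDITIONS HMG_CoA_synth and Lactonase
"""


def demo_rules() -> list[DetectionRule]:
    """A small illustrative rule set (not the published curated rules)."""
    from .rule_engine import parse_rules

    return parse_rules(DEMO_RULES_TEXT)
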