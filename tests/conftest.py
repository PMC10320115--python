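import numpy as np
import pytest

from bgcminer.fixtures import (
    PlantedCluster,
    PlantedTfbs,
    SyntheticGenomeSpec,
    demo_rules,
    generate_genome,
)
from bgcminer.genome_io import AnnotatedRecord, CdsFeature
from bgcminer.profile_detection import ProfileHit

NISIN_CORE = "ITSISSLCTPGCKTGALMGCNMKTATCHCSIHVSK"


def make_cds(locus, start, end, strand=1, product=""):
    length_aa = max(1, (end - start) // 3)
    return CdsFeature(locus, start, end, strand, "M" * length_aa, product)


@pytest.fixture
def nis_record():
    """Three-gene toy record used in the gene-filtering examples."""
    feats = [
        make_cds("nisA", 100, 400, 1, "nisin precursor"),
        make_cds("nisB", 500, 3500, 1, "lanthipeptide dehydratase"),
        make_cds("nisC", 3600, 4800, -1, "lanthipeptide cyclase"),
    ]
    return AnnotatedRecord("toy_nisin", "A" * 5000, feats)


@pytest.fixture(scope="session")
def demo_rule_set():
    return demo_rules()


@pytest.fixture(scope="session")
def standard_spec():
    return SyntheticGenomeSpec(
        contig_length=60_000,
        n_background_genes=15,
        planted_clusters=(
            PlantedCluster(
                "nrps", (("AMP-binding", "Condensation"), ("AMP-binding",)), 20_000
            ),
        ),
        planted_tfbs=(PlantedTfbs("synthetic_regulator", 5_000, 1),),
        planted_precursors=(NISIN_CORE,),
        seed=42,
    )


@pytest.fixture(scope="session")
def fixture_genome(standard_spec):
    return generate_genome(standard_spec)


def random_record(rng, n_cds=None, contig_length=50_000, max_cds=12):
    """A random small record for oracle tests (genes 300-1500 bp, any gaps)."""
    n = int(rng.integers(1, max_cds + 1)) if n_cds is None else n_cds
    feats = []
    pos = int(rng.integers(0, 2000))
    for i in range(n):
        length = int(rng.integers(100, 500)) * 3
        if pos + length > contig_length:
            break
        feats.append(
            CdsFeature(
                f"g{i}", pos, pos + length, int(rng.choice([1, -1])),
                "M" * (length // 3),
            )
        )
        pos += length + int(rng.integers(0, 30_000))
    if not feats:
        feats = [CdsFeature("g0", 0, 300, 1, "M" * 100)]
    return AnnotatedRecord("rand", "A" * contig_length, feats)


def random_hits(rng, record, profiles=("P1", "P2", "P3", "P4")):
    hits = []
    for feat in record.features:
        for profile in profiles:
            if rng.random() < 0.4:
                hits.append(
                    ProfileHit(feat.locus_tag, profile, float(rng.integers(10, 300)))
                )
    return hits
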