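"""PWM-based transcription-factor binding-site (TFBS) scanning.

Binding-site models are position weight matrices built from aligned-site
base counts. The log-odds score of placing base ``a`` at column ``i`` is

    log2( (counts[i,a] + p * bg[a]) / (N_i + p) / bg[a] )

with pseudocount ``p`` and background distribution ``bg`` (uniform by
default; a GC-matched background is available for GC-rich genomes such as
actinobacterial ones). Every window on both strands is scored; a hit's
confidence tier (strong / medium / weak) is a fraction of the normalized
score range, so the tiering rule is independent of matrix length.

Because a binding site means different things inside a gene, in a shared
promoter, or between convergent terminators, every hit is also annotated
with its genomic context: the flanking genes, their orientation relative to
the site, and the gap distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .errors import DegenerateMatrixError, ValidationError
from .genome_io import AnnotatedRecord, CdsFeature

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

TIERS = ("weak", "medium", "strong")
DEFAULT_TIER_FRACTIONS = {"strong": 0.90, "medium": 0.75, "weak": 0.60}

CONTEXT_CATEGORIES = (
    "within-gene",
    "overlaps-start-codon",
    "upstream-of-one",
    "upstream-of-both",
    "downstream-of-both",
    "contig-edge",
)


@dataclass(frozen=True)
class Pwm:
    """A position weight matrix with per-tier confidence thresholds."""

    name: str
    counts: np.ndarray  # L x 4, order A C G T
    log_odds: np.ndarray  # L x 4, bits
    background: np.ndarray  # 4 probabilities
    tier_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TIER_FRACTIONS)
    )

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


@dataclass(frozen=True)
class ContextAnnotation:
    category: str
    left_gene: str | None = None
    right_gene: str | None = None
    distance_left: int | None = None
    distance_right: int | None = None

    def __post_init__(self):
        if self.category not in CONTEXT_CATEGORIES:
            raise ValidationError(f"unknown context category {self.category!r}")


@dataclass(frozen=True)
class TfbsHit:
    """A scored, stranded, context-annotated binding-site call."""

    pwm_name: str
    start: int  # forward-strand coordinate of the window, 0-based
    length: int
    strand: int
    score: float
    confidence: str
    context: ContextAnnotation | None = None


def build_pwm(
    counts,
    name: str,
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
    tier_fractions: dict[str, float] | None = None,
) -> Pwm:
    """Build a log-odds PWM from an L x 4 count matrix (columns A, C, G, T)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValidationError(f"counts must be L x 4, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValidationError("negative counts")
    if (counts.sum(axis=1) <= 0).any():
        raise ValidationError("every count row must have a positive sum")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    bg = (
        np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    )
    if bg.shape != (4,) or (bg <= 0).any() or not math.isclose(bg.sum(), 1.0):
        raise ValidationError("background must be 4 positive probabilities summing to 1")
    fractions = dict(tier_fractions or DEFAULT_TIER_FRACTIONS)
    if not 0 < fractions["weak"] < fractions["medium"] < fractions["strong"] <= 1:
        raise ValidationError("tier fractions must satisfy 0 < weak < medium < strong <= 1")
    row_sums = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount * bg) / (row_sums + pseudocount)
    log_odds = np.log2(probs / bg)
    return Pwm(name, counts, log_odds, bg, fractions)


def gc_background(record: AnnotatedRecord) -> np.ndarray:
    """Background matched to the contig's GC content (N bases ignored)."""
    seq = record.sequence
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    total = gc + at
    if total == 0:
        return np.full(4, 0.25)
    p_gc, p_at = gc / total / 2, at / total / 2
    return np.array([p_at, p_gc, p_gc, p_at])


def assign_confidence(score: float, pwm: Pwm) -> str | None:
    """Map a bit score onto a tier, or None when below the weak threshold.

    The score is normalized into [0, 1] over the matrix's attainable range;
    boundary values map to the higher tier.
    """
    span = pwm.max_score - pwm.min_score
    if span == 0:
        raise DegenerateMatrixError(
            f"{pwm.name}: max_score equals min_score, cannot assign confidence"
        )
    s = (score - pwm.min_score) / span
    for tier in ("strong", "medium", "weak"):
        if s >= pwm.tier_fractions[tier]:
            return tier
    return None


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(encoded: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every window; windows containing N (code -1) get -inf."""
    L = log_odds.shape[0]
    n_windows = encoded.size - L + 1
    scores = np.zeros(n_windows)
    valid = np.ones(n_windows, dtype=bool)
    for i in range(L):
        col = encoded[i : i + n_windows]
        valid &= col >= 0
        scores += log_odds[i, np.clip(col, 0, 3)]
    scores[~valid] = -np.inf
    return scores


def scan_sequence(
    record: AnnotatedRecord,
    pwm: Pwm,
    min_tier: str = "weak",
    annotate: bool = True,
    upstream_limit: int = 300,
) -> list[TfbsHit]:
    """Score every window on both strands; return tiered hits sorted by
    (start, strand). The reverse-strand score of a window is the forward
    score of its reverse complement; hit starts are always forward-strand
    coordinates of the window's left edge."""
    if min_tier not in TIERS:
        raise ValidationError(f"min_tier must be one of {TIERS}")
    L = pwm.length
    if len(record) < L:
        return []
    encoded = _encode(record.sequence)
    # reverse-complement matrix: scanning forward with it gives the reverse
    # strand score at the same window start
    rc_log_odds = pwm.log_odds[::-1, ::-1]
    min_rank = TIERS.index(min_tier)
    hits = []
    for strand, matrix in ((1, pwm.log_odds), (-1, rc_log_odds)):
        scores = _window_scores(encoded, matrix)
        for start in np.nonzero(np.isfinite(scores))[0]:
            tier = assign_confidence(float(scores[start]), pwm)
            if tier is None or TIERS.index(tier) < min_rank:
                continue
            hits.append(
                TfbsHit(
                    pwm_name=pwm.name,
                    start=int(start),
                    length=L,
                    strand=strand,
                    score=float(scores[start]),
                    confidence=tier,
                )
            )
    hits.sort(key=lambda h: (h.start, -h.strand))
    if annotate:
        hits = [
            TfbsHit(
                h.pwm_name, h.start, h.length, h.strand, h.score, h.confidence,
                annotate_context(h, record, upstream_limit),
            )
            for h in hits
        ]
    return hits


def _start_codon_span(feat: CdsFeature) -> tuple[int, int]:
    if feat.strand == 1:
        return feat.start, feat.start + 3
    return feat.end - 3, feat.end


def annotate_context(
    hit: TfbsHit, record: AnnotatedRecord, upstream_limit: int = 300
) -> ContextAnnotation:
    """Classify a binding site by its position relative to surrounding genes.

    A site overlapping a CDS is ``within-gene`` unless it intersects the
    first three coding bases (strand-aware), which makes it
    ``overlaps-start-codon`` — e.g. a repressor site sitting on the ATG.
    Intergenic sites report the flanking genes and gap distances:
    ``upstream-of-both`` for a divergent promoter region with both starts
    within ``upstream_limit``; ``upstream-of-one`` when exactly one flank's
    5' end faces the site within that limit; ``downstream-of-both``
    otherwise (convergent flanks, or no facing start within the limit);
    ``contig-edge`` when a flank is missing.
    """
    win_start, win_end = hit.start, hit.start + hit.length
    overlapping = [
        f for f in record.features if f.start < win_end and win_start < f.end
    ]
    if overlapping:
        for feat in overlapping:
            cs, ce = _start_codon_span(feat)
            if cs < win_end and win_start < ce:
                return ContextAnnotation("overlaps-start-codon", left_gene=feat.locus_tag)
        return ContextAnnotation("within-gene", left_gene=overlapping[0].locus_tag)
    left = max(
        (f for f in record.features if f.end <= win_start),
        key=lambda f: f.end,
        default=None,
    )
    right = min(
        (f for f in record.features if f.start >= win_end),
        key=lambda f: f.start,
        default=None,
    )
    if left is None or right is None:
        return ContextAnnotation(
            "contig-edge",
            left_gene=left.locus_tag if left else None,
            right_gene=right.locus_tag if right else None,
            distance_left=win_start - left.end if left else None,
            distance_right=right.start - win_end if right else None,
        )
    dist_left = win_start - left.end
    dist_right = right.start - win_end
    left_faces = left.strand == -1 and dist_left <= upstream_limit
    right_faces = right.strand == 1 and dist_right <= upstream_limit
    if left_faces and right_faces:
        category = "upstream-of-both"
    elif left_faces or right_faces:
        category = "upstream-of-one"
    else:
        category = "downstream-of-both"
    return ContextAnnotation(
        category,
        left_gene=left.locus_tag,
        right_gene=right.locus_tag,
        distance_left=dist_left,
        distance_right=dist_right,
    )


# ---------------------------------------------------------------------------
# I/O


def load_pwms(
    path: str | Path,
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
    tier_fractions: dict[str, float] | None = None,
) -> list[Pwm]:
    """Read JASPAR-style plain-text count matrices (``>name`` + 4 base rows)."""
    with open(path) as handle:
        parsed = bio_motifs.parse(handle, "jaspar")
    pwms = []
    for motif in parsed:
        counts = np.array([[motif.counts[b][i] for b in BASES] for i in range(motif.length)])
        pwms.append(
            build_pwm(
                counts,
                name=motif.name or motif.matrix_id,
                pseudocount=pseudocount,
                background=background,
                tier_fractions=tier_fractions,
            )
        )
    return pwms


def write_pwms(pwms: Sequence[Pwm], path: str | Path) -> None:
    """Write count matrices in the JASPAR plain-text dialect."""
    lines = []
    for pwm in pwms:
        lines.append(f">{pwm.name}")
        for bi, base in enumerate(BASES):
            row = " ".join(f"{int(c):d}" for c in pwm.counts[:, bi])
            lines.append(f"{base} [ {row} ]")
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed6(
    hits: Sequence[TfbsHit], record: AnnotatedRecord, path: str | Path
) -> None:
    """Write hits as BED6; the score column is bits x 100, rounded."""
    lines = []
    for i, hit in enumerate(hits, start=1):
        lines.append(
            "\t".join(
                [
                    record.record_id,
                    str(hit.start),
                    str(hit.start + hit.length),
                    f"{hit.pwm_name}_{i}",
                    str(int(round(hit.score * 100))),
                    "+" if hit.strand == 1 else "-",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
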