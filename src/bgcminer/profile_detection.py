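"""Profile hits: external pHMM hit tables and built-in regex "dynamic profiles".

The toolkit does not run a pHMM scanner itself; bitscore hits produced
externally (e.g. by ``hmmsearch``) are loaded from a simple 4-column TSV
dialect, or from genuine HMMER ``--domtblout`` output. Detectors that are too
small or too variable to be captured by a pHMM are expressed instead as
*dynamic profiles*: protein regular expressions run over CDS translations.

The one bundled dynamic profile targets cyanobactin precursor peptides via
the conserved leader motif ``M.KKN[IL].P....PV.R`` (each ``.`` a single
arbitrary residue). The motif is widely conserved across cyanobactin
precursors but far too short for a reliable profile HMM.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ParseError, ValidationError
from .genome_io import AnnotatedRecord

logger = logging.getLogger(__name__)

CYANOBACTIN_PATTERN = "M.KKN[IL].P....PV.R"

#: score attached to motif hits so the rule engine can treat all hits
#: uniformly; motif matches have no meaningful bitscore
DEFAULT_MOTIF_SCORE = 20.0


@dataclass(frozen=True)
class ProfileHit:
    """One detector match (pHMM- or motif-derived) on one CDS."""

    locus_tag: str
    profile_name: str
    score: float
    evalue: float | None = None
    query_span: tuple[int, int] | None = None

    def __post_init__(self):
        if not (self.score == self.score and abs(self.score) != float("inf")):
            raise ValidationError(f"non-finite score for {self.locus_tag}")


@dataclass(frozen=True)
class DynamicProfile:
    """A detector defined by a protein regex instead of a pHMM."""

    name: str
    pattern: str
    fixed_score: float = DEFAULT_MOTIF_SCORE
    min_hits_reported: int = 1

    def __post_init__(self):
        if self.min_hits_reported < 1:
            raise ValidationError(f"{self.name}: min_hits_reported must be >= 1")
        try:
            re.compile(self.pattern)
        except re.error as exc:
            raise ValidationError(f"{self.name}: pattern does not compile: {exc}") from exc

    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern)


def default_dynamic_profiles() -> list[DynamicProfile]:
    """The bundled dynamic-profile set (currently the cyanobactin precursor)."""
    return [DynamicProfile(name="cyanobactin_precursor", pattern=CYANOBACTIN_PATTERN)]


def load_external_hits(
    path: str | Path,
    record: AnnotatedRecord,
    per_profile_cutoffs: Mapping[str, float] | None = None,
    domtblout: bool = False,
) -> list[ProfileHit]:
    """Load a hit table, applying per-profile bitscore cutoffs.

    The native dialect is tab-separated ``locus_tag  profile  bitscore
    evalue`` with ``#`` comment lines. With ``domtblout=True`` genuine HMMER
    ``--domtblout`` output is accepted instead (target name -> locus_tag,
    query name -> profile, full-sequence score and E-value).

    Rows below their profile's cutoff (default 0) are dropped; rows naming a
    locus_tag absent from ``record`` are dropped with a logged warning.
    """
    cutoffs = dict(per_profile_cutoffs or {})
    known = {feat.locus_tag for feat in record.features}
    hits: list[ProfileHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if domtblout:
                cols = line.split()
                if len(cols) < 14:
                    raise ParseError(
                        f"{path}: domtblout row has {len(cols)} columns", line=lineno
                    )
                locus, profile, score_s, evalue_s = cols[0], cols[3], cols[7], cols[6]
            else:
                cols = line.split("\t")
                if len(cols) < 3:
                    raise ParseError(
                        f"{path}: expected >=3 tab-separated columns", line=lineno
                    )
                locus, profile, score_s = cols[0], cols[1], cols[2]
                evalue_s = cols[3] if len(cols) > 3 and cols[3] else None
            try:
                score = float(score_s)
                evalue = float(evalue_s) if evalue_s is not None else None
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric score/evalue {score_s!r}", line=lineno
                ) from exc
            if score < cutoffs.get(profile, 0.0):
                continue
            if locus not in known:
                logger.warning(
                    "%s line %d: unknown locus_tag %r, row dropped", path, lineno, locus
                )
                continue
            hits.append(ProfileHit(locus, profile, score, evalue))
    return hits


def run_dynamic_profiles(
    record: AnnotatedRecord, profiles: Sequence[DynamicProfile] | None = None
) -> list[ProfileHit]:
    """Run protein-regex detectors over every CDS translation.

    At most one hit per (CDS, profile) is emitted even when the pattern
    matches several times: rule conditions are existence-based. Matching is a
    search anywhere in the translation, never an anchored full-match.
    """
    if profiles is None:
        profiles = default_dynamic_profiles()
    hits = []
    for profile in profiles:
        pattern = profile.compiled()
        for feat in record.features:
            match = pattern.search(feat.translation)
            if match is not None:
                hits.append(
                    ProfileHit(
                        locus_tag=feat.locus_tag,
                        profile_name=profile.name,
                        score=profile.fixed_score,
                        query_span=(match.start(), match.end()),
                    )
                )
    return hits


def merge_hits(*hit_lists: Iterable[ProfileHit]) -> list[ProfileHit]:
    """Merge hit lists, deduplicating (locus_tag, profile) on highest score."""
    best: dict[tuple[str, str], ProfileHit] = {}
    for hits in hit_lists:
        for hit in hits:
            key = (hit.locus_tag, hit.profile_name)
            if key not in best or hit.score > best[key].score:
                best[key] = hit
    return sorted(best.values(), key=lambda h: (h.locus_tag, h.profile_name))
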