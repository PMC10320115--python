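"""NRPS adenylation-domain substrate prediction via the Stachelhaus code.

The adenylation (A) domain of a non-ribosomal peptide synthetase module
selects the amino acid that the module incorporates. Its specificity is
fingerprinted by the *Stachelhaus code*: the 10 active-site residues lining
the substrate-binding pocket. An extended 34-residue signature covers all
positions predicted to lie within 8 Å of the active site and resolves ties
when several reference codes match the 10-residue fingerprint equally well
(substrate-promiscuous A domains often share a 10-AA code).

Prediction is a lookup: extract the query's 10/34-residue signatures by
aligning it to a reference A domain with known signature positions, then
rank lookup-table entries first by 10-AA code matches and, among the
equal-best, by 34-AA signature matches.

The reference domain and lookup table are data, not code, so a curated
table (e.g. MIBiG-derived) can be dropped in; the files bundled with this
package are synthetic stand-ins for testing and demonstration.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .errors import LowConfidenceAlignmentError, ValidationError

CODE10_LENGTH = 10
CODE34_LENGTH = 34

#: below this fraction of 10-AA positions matched, the code is known to be
#: unreliable and no prediction is reported
DEFAULT_MIN_MATCHES10 = 7

MIN_ALIGNMENT_IDENTITY = 0.15


@dataclass(frozen=True)
class SignatureReference:
    """A reference A domain with known 10/34 signature positions (0-based)."""

    reference_sequence: str
    positions10: tuple[int, ...]
    positions34: tuple[int, ...]
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        for label, positions, expected in (
            ("positions10", self.positions10, CODE10_LENGTH),
            ("positions34", self.positions34, CODE34_LENGTH),
        ):
            if len(positions) != expected:
                raise ValidationError(f"{label} must have {expected} entries")
            if list(positions) != sorted(set(positions)):
                raise ValidationError(f"{label} must be strictly increasing")
            if positions[-1] >= len(self.reference_sequence):
                raise ValidationError(f"{label} index beyond reference length")


@dataclass(frozen=True)
class StachelhausEntry:
    code10: str
    code34: str
    substrate: str
    source_id: str

    def __post_init__(self):
        if len(self.code10) != CODE10_LENGTH:
            raise ValidationError(
                f"{self.source_id}: code10 must be {CODE10_LENGTH} chars"
            )
        if len(self.code34) != CODE34_LENGTH:
            raise ValidationError(
                f"{self.source_id}: code34 must be {CODE34_LENGTH} chars"
            )


@dataclass(frozen=True)
class SubstratePrediction:
    substrate: str
    matches10: int
    matches34: int
    source_ids: tuple[str, ...]

    @property
    def percent10(self) -> float:
        return self.matches10 / CODE10_LENGTH * 100.0


def _aligner(ref: SignatureReference) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(ref.matrix_name)
    aligner.open_gap_score = -ref.gap_open
    aligner.extend_gap_score = -ref.gap_extend
    # end-gap-free: tolerate fragment queries without terminal-gap penalties
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # attribute names used before Biopython 1.88
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def extract_signatures(a_domain: str, ref: SignatureReference) -> tuple[str, str]:
    """Extract the query's (10-AA, 34-AA) signature strings.

    The query is globally aligned to the reference (end gaps free); each
    reference signature position maps to the aligned query residue, or to
    ``'-'`` when that column is a gap in the query. Queries aligning at
    under 15% identity are rejected as probable non-A-domain input.
    """
    a_domain = a_domain.upper()
    if len(a_domain) < 100:
        raise ValidationError("A-domain query shorter than 100 residues")
    alignment = _aligner(ref).align(ref.reference_sequence, a_domain)[0]
    ref_blocks, query_blocks = alignment.aligned
    ref_to_query: dict[int, str] = {}
    identical = 0
    for (ts, te), (qs, qe) in zip(ref_blocks, query_blocks):
        for k in range(te - ts):
            ref_to_query[ts + k] = a_domain[qs + k]
            if ref.reference_sequence[ts + k] == a_domain[qs + k]:
                identical += 1
    identity = identical / len(ref.reference_sequence)
    if identity < MIN_ALIGNMENT_IDENTITY:
        raise LowConfidenceAlignmentError(
            f"alignment identity {identity:.1%} to the reference A domain is "
            f"below {MIN_ALIGNMENT_IDENTITY:.0%}; input is likely not an A domain"
        )
    code10 = "".join(ref_to_query.get(i, "-") for i in ref.positions10)
    code34 = "".join(ref_to_query.get(i, "-") for i in ref.positions34)
    assert len(code10) == CODE10_LENGTH and len(code34) == CODE34_LENGTH
    return code10, code34


def count_matches(a: str, b: str) -> int:
    """Positions where the codes agree; a gap character never matches."""
    return sum(1 for x, y in zip(a, b) if x == y and x != "-")


def predict_substrate(
    code10: str,
    code34: str,
    table: Sequence[StachelhausEntry],
    min_matches10: int = DEFAULT_MIN_MATCHES10,
) -> list[SubstratePrediction]:
    """Look up a signature pair against a Stachelhaus table.

    All entries tied at the best 10-AA match count (if it reaches
    ``min_matches10``) are reported, grouped by substrate and ranked by
    their best 34-AA signature match, with a deterministic alphabetical
    tie-break. An empty list means no confident prediction.
    """
    if len(code10) != CODE10_LENGTH or len(code34) != CODE34_LENGTH:
        raise ValidationError("query codes must be 10 and 34 characters")
    if not table:
        return []
    scored = [(count_matches(code10, e.code10), e) for e in table]
    best = max(m for m, _ in scored)
    if best < min_matches10:
        return []
    groups: dict[str, list[tuple[int, StachelhausEntry]]] = {}
    for m10, entry in scored:
        if m10 == best:
            groups.setdefault(entry.substrate, []).append(
                (count_matches(code34, entry.code34), entry)
            )
    predictions = [
        SubstratePrediction(
            substrate=substrate,
            matches10=best,
            matches34=max(m34 for m34, _ in members),
            source_ids=tuple(sorted(e.source_id for _, e in members)),
        )
        for substrate, members in groups.items()
    ]
    predictions.sort(key=lambda p: (-p.matches34, p.substrate, p.source_ids))
    return predictions


# ---------------------------------------------------------------------------
# data files


def load_table(path: str | Path) -> list[StachelhausEntry]:
    """Read a lookup table: TSV with header ``code10 code34 substrate source_id``."""
    entries = []
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:4]] != [
            "code10", "code34", "substrate", "source_id",
        ]:
            raise ValidationError(
                f"{path}: expected header 'code10\\tcode34\\tsubstrate\\tsource_id'"
            )
        for rownum, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 4:
                raise ValidationError(f"{path} row {rownum}: expected 4 columns")
            try:
                entries.append(
                    StachelhausEntry(row[0].strip(), row[1].strip(), row[2].strip(), row[3].strip())
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} row {rownum}: {exc}") from exc
    return entries


def load_reference(fasta_path: str | Path, positions_path: str | Path) -> SignatureReference:
    """Read the reference A domain (FASTA) and its positions file (JSON)."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"{fasta_path}: expected exactly one reference sequence")
    with open(positions_path) as handle:
        positions = json.load(handle)
    return SignatureReference(
        reference_sequence=str(records[0].seq),
        positions10=tuple(positions["positions10"]),
        positions34=tuple(positions["positions34"]),
    )


def bundled_reference() -> SignatureReference:
    """The synthetic reference A domain shipped with the package."""
    data = resources.files("bgcminer.data")
    with resources.as_file(data.joinpath("synthetic_adomain_reference.faa")) as faa, \
            resources.as_file(data.joinpath("synthetic_adomain_positions.json")) as pos:
        return load_reference(faa, pos)


def bundled_table() -> list[StachelhausEntry]:
    """The synthetic demonstration lookup table shipped with the package."""
    data = resources.files("bgcminer.data")
    with resources.as_file(data.joinpath("synthetic_stachelhaus_table.tsv")) as tsv:
        return load_table(tsv)
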