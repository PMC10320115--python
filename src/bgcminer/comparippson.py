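"""RiPP core-peptide identity search against precursor databases.

RiPP precursor peptides contain a *core peptide* that is post-translationally
modified into the final natural product. To judge whether a predicted core
peptide is novel, it is compared against databases of known precursors: each
database entry is a (id, label, core sequence) triple, entries with identical
core sequences are grouped (a single alignment represents the whole group),
and matches are ranked by percent identity.

Identity is defined so that 100% means exact sequence equality: a global
alignment is computed under a symmetric scheme (match +1, mismatch -1, gap
open -2, gap extension -1), and

    identity% = 100 * identical aligned pairs / max(len(query), len(hit)).

Among equal-score alignments the one with the most identical pairs is used,
which makes the reported identity a deterministic, symmetric function of the
two sequences rather than an artifact of aligner tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ValidationError

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -2.0  # cost of the first gapped column
GAP_EXTEND = -1.0  # cost of each further gapped column

DEFAULT_MIN_IDENTITY = 20.0


@dataclass(frozen=True)
class PrecursorEntry:
    id: str
    label: str
    core_sequence: str

    def __post_init__(self):
        if not self.core_sequence:
            raise ValidationError(f"{self.id}: empty core sequence")
        if self.core_sequence != self.core_sequence.upper():
            raise ValidationError(f"{self.id}: core sequence must be uppercase")


@dataclass(frozen=True)
class PrecursorDb:
    """Entries partitioned by exact core-sequence equality."""

    groups: dict[str, tuple[PrecursorEntry, ...]]

    def __len__(self) -> int:
        return sum(len(g) for g in self.groups.values())


@dataclass(frozen=True)
class PrecursorMatch:
    identity_percent: float
    group_sequence: str
    group_labels: tuple[str, ...]
    alignment: tuple[str, str]  # gapped query row, gapped hit row


def build_precursor_db(entries: Iterable[PrecursorEntry]) -> PrecursorDb:
    """Group entries by identical core sequence, preserving input order."""
    groups: dict[str, list[PrecursorEntry]] = {}
    seen_ids: set[str] = set()
    for entry in entries:
        if entry.id in seen_ids:
            raise ValidationError(f"duplicate precursor id {entry.id!r}")
        seen_ids.add(entry.id)
        groups.setdefault(entry.core_sequence, []).append(entry)
    return PrecursorDb({seq: tuple(members) for seq, members in groups.items()})


def load_precursor_fasta(path: str | Path) -> list[PrecursorEntry]:
    """Read a precursor database FASTA; headers are ``>id|label``."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ident, _, label = rec.description.partition("|")
        entries.append(PrecursorEntry(ident.strip(), label.strip() or ident.strip(),
                                      str(rec.seq).upper()))
    return entries


# ---------------------------------------------------------------------------
# alignment

_NEG = float("-inf")


def align_global(query: str, hit: str) -> tuple[float, int, tuple[str, str]]:
    """Affine-gap global alignment maximizing (score, identical pairs).

    Three-state (match / gap-in-hit / gap-in-query) dynamic programme over
    lexicographically ordered (score, matches) values, so among co-optimal
    alignments the one with most identities is chosen deterministically.
    Returns (score, identical pairs, (gapped query row, gapped hit row)).
    """
    n, m = len(query), len(hit)
    # cell value: (score, matches); pointers record (state, i-step, j-step)
    M = [[(_NEG, 0)] * (m + 1) for _ in range(n + 1)]
    X = [[(_NEG, 0)] * (m + 1) for _ in range(n + 1)]  # gap in hit row
    Y = [[(_NEG, 0)] * (m + 1) for _ in range(n + 1)]  # gap in query row
    ptr: dict[tuple[str, int, int], tuple[str, int, int]] = {}
    M[0][0] = (0.0, 0)
    for i in range(1, n + 1):
        X[i][0] = (GAP_OPEN + GAP_EXTEND * (i - 1), 0)
        ptr[("X", i, 0)] = ("X", i - 1, 0) if i > 1 else ("M", 0, 0)
    for j in range(1, m + 1):
        Y[0][j] = (GAP_OPEN + GAP_EXTEND * (j - 1), 0)
        ptr[("Y", 0, j)] = ("Y", 0, j - 1) if j > 1 else ("M", 0, 0)
    for i in range(1, n + 1):
        qc = query[i - 1]
        for j in range(1, m + 1):
            sub = MATCH_SCORE if qc == hit[j - 1] else MISMATCH_SCORE
            inc = 1 if qc == hit[j - 1] else 0
            # M: qc aligned to hit[j-1]
            best_state, best_val = None, (_NEG, 0)
            for state, table in (("M", M), ("X", X), ("Y", Y)):
                prev = table[i - 1][j - 1]
                cand = (prev[0] + sub, prev[1] + inc)
                if prev[0] > _NEG and cand > best_val:
                    best_state, best_val = state, cand
            M[i][j] = best_val
            if best_state is not None:
                ptr[("M", i, j)] = (best_state, i - 1, j - 1)
            # X: query[i-1] over a gap
            open_val = (M[i - 1][j][0] + GAP_OPEN, M[i - 1][j][1])
            ext_val = (X[i - 1][j][0] + GAP_EXTEND, X[i - 1][j][1])
            y_open = (Y[i - 1][j][0] + GAP_OPEN, Y[i - 1][j][1])
            choices = [(open_val, ("M", i - 1, j)), (ext_val, ("X", i - 1, j)),
                       (y_open, ("Y", i - 1, j))]
            (val, origin) = max(choices, key=lambda c: c[0])
            X[i][j] = val
            ptr[("X", i, j)] = origin
            # Y: hit[j-1] over a gap
            open_val = (M[i][j - 1][0] + GAP_OPEN, M[i][j - 1][1])
            ext_val = (Y[i][j - 1][0] + GAP_EXTEND, Y[i][j - 1][1])
            x_open = (X[i][j - 1][0] + GAP_OPEN, X[i][j - 1][1])
            choices = [(open_val, ("M", i, j - 1)), (ext_val, ("Y", i, j - 1)),
                       (x_open, ("X", i, j - 1))]
            (val, origin) = max(choices, key=lambda c: c[0])
            Y[i][j] = val
            ptr[("Y", i, j)] = origin
    finals = [("M", M[n][m]), ("X", X[n][m]), ("Y", Y[n][m])]
    state, (score, matches) = max(finals, key=lambda c: c[1])
    # traceback
    qrow, hrow = [], []
    i, j = n, m
    while (i, j) != (0, 0):
        prev = ptr[(state, i, j)]
        if state == "M":
            qrow.append(query[i - 1])
            hrow.append(hit[j - 1])
        elif state == "X":
            qrow.append(query[i - 1])
            hrow.append("-")
        else:
            qrow.append("-")
            hrow.append(hit[j - 1])
        state, i, j = prev
    return score, matches, ("".join(reversed(qrow)), "".join(reversed(hrow)))


def identity_percent(query: str, hit: str) -> float:
    """Percent identity under the module's alignment contract."""
    _, matches, _ = align_global(query, hit)
    return 100.0 * matches / max(len(query), len(hit))


def compare_core_peptide(
    query: str,
    db: PrecursorDb,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[PrecursorMatch]:
    """Rank database groups by percent identity to the query core peptide.

    One alignment is computed per distinct group sequence. Matches below
    ``min_identity`` are dropped; the rest are sorted by identity
    descending, then group sequence ascending (a total, deterministic
    order). A query present verbatim in the database always yields a
    100% top match.
    """
    if not query:
        raise ValidationError("empty query core peptide")
    query = query.upper()
    matches = []
    for seq, members in db.groups.items():
        _, identical, rows = align_global(query, seq)
        ident = 100.0 * identical / max(len(query), len(seq))
        if ident >= min_identity:
            matches.append(
                PrecursorMatch(
                    identity_percent=ident,
                    group_sequence=seq,
                    group_labels=tuple(e.label for e in members),
                    alignment=rows,
                )
            )
    matches.sort(key=lambda m: (-m.identity_percent, m.group_sequence))
    return matches


def render_alignment(match: PrecursorMatch, width: int = 60) -> str:
    """Render a match as query/midline/hit text blocks, wrapped at ``width``.

    The midline carries ``|`` at identical aligned pairs and spaces
    elsewhere. Removing gap characters from the rendered rows reproduces
    the query and the group sequence exactly.
    """
    qrow, hrow = match.alignment
    midline = "".join(
        "|" if q == h and q != "-" else " " for q, h in zip(qrow, hrow)
    )
    blocks = []
    for off in range(0, len(qrow), width):
        blocks.append(
            "\n".join(
                (qrow[off : off + width], midline[off : off + width],
                 hrow[off : off + width])
            )
        )
    return "\n\n".join(blocks)
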