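"""Reading, holding, filtering and writing annotated genomes.

The in-memory model is deliberately tiny: an :class:`AnnotatedRecord` is a
contig sequence plus an ordered list of :class:`CdsFeature` objects. All
internal coordinates are 0-based half-open; the GenBank and GFF3 readers and
writers convert at the boundary, so off-by-one handling lives in exactly one
place.

Supported inputs are GenBank flat files (annotations embedded) or a FASTA
contig file paired with a GFF3 annotation file. Results are written as GFF3
and as "sideload" JSON, the interchange format genome-mining suites use to
let external tools inject subregion annotations into their reports.
"""

from __future__ import annotations

import json
import re
import urllib.parse
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import CoordinateError, ParseError, QueryError, ValidationError

_DNA_OK = set("ACGTN")


@dataclass(frozen=True)
class CdsFeature:
    """A single protein-coding gene on a contig.

    Coordinates are 0-based half-open on the forward strand; ``strand`` is
    ``+1`` or ``-1`` (strandless features are rejected because every
    downstream computation — binding-site context, motif scanning — needs an
    orientation).
    """

    locus_tag: str
    start: int
    end: int
    strand: int
    translation: str
    product: str = ""
    functions: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.locus_tag:
            raise ValidationError("CDS feature requires a locus_tag")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"{self.locus_tag}: invalid coordinates [{self.start}, {self.end})"
            )
        if self.strand not in (1, -1):
            raise ValidationError(f"{self.locus_tag}: strand must be +1 or -1")
        if not self.translation:
            raise ValidationError(f"{self.locus_tag}: empty translation")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedRecord:
    """A contig with its CDS features, sorted by start coordinate."""

    record_id: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _DNA_OK
        if bad:
            raise ValidationError(
                f"{self.record_id}: sequence contains non-ACGTN symbols {sorted(bad)}"
            )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        seen: set[str] = set()
        for feat in self.features:
            if feat.locus_tag in seen:
                raise ValidationError(
                    f"{self.record_id}: duplicate locus_tag {feat.locus_tag!r}"
                )
            seen.add(feat.locus_tag)
            if feat.end > len(self.sequence):
                raise CoordinateError(
                    f"{feat.locus_tag}: CDS end {feat.end} exceeds contig "
                    f"length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def get_feature(self, locus_tag: str) -> CdsFeature:
        for feat in self.features:
            if feat.locus_tag == locus_tag:
                return feat
        raise KeyError(locus_tag)


def translate_cds(record_seq: str, start: int, end: int, strand: int) -> str:
    """Translate a CDS span with the bacterial translation table (11).

    Partial codons are an error rather than silently truncated.
    """
    if (end - start) % 3 != 0:
        raise ValidationError(
            f"CDS [{start}, {end}) length {end - start} is not a multiple of 3"
        )
    seq = Seq(record_seq[start:end])
    if strand == -1:
        seq = seq.reverse_complement()
    protein = str(seq.translate(table=11))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValidationError(f"CDS [{start}, {end}) contains internal stop codons")
    if not protein:
        raise ValidationError(f"CDS [{start}, {end}) translates to an empty protein")
    return protein


# ---------------------------------------------------------------------------
# reading


def load_record(
    genome_path: str | Path, annotation_path: str | Path | None = None
) -> list[AnnotatedRecord]:
    """Load annotated contigs from GenBank, or from FASTA + GFF3.

    CDS features lacking a ``translation`` qualifier/attribute are translated
    from their coordinates with table 11. Records are returned in file order.
    """
    genome_path = Path(genome_path)
    if annotation_path is None:
        return _load_genbank(genome_path)
    return _load_fasta_gff3(genome_path, Path(annotation_path))


def _load_genbank(path: Path) -> list[AnnotatedRecord]:
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed GenBank file: {exc}") from exc
    if not seq_records:
        raise ParseError(f"{path}: no GenBank records found (line 1)")
    out = []
    for rec in seq_records:
        features = []
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if len(feat.location.parts) != 1:
                raise ValidationError(
                    f"{rec.id}: joined (multi-interval) CDS locations are not supported"
                )
            if feat.location.strand not in (1, -1):
                raise ValidationError(f"{rec.id}: CDS without strand")
            start = int(feat.location.start)
            end = int(feat.location.end)
            if end > len(rec.seq):
                raise CoordinateError(
                    f"{rec.id}: CDS [{start}, {end}) extends past contig end"
                )
            locus = feat.qualifiers.get(
                "locus_tag", feat.qualifiers.get("gene", [""])
            )[0]
            translation = feat.qualifiers.get("translation", [None])[0]
            if translation is None:
                translation = translate_cds(str(rec.seq), start, end, feat.location.strand)
            features.append(
                CdsFeature(
                    locus_tag=locus,
                    start=start,
                    end=end,
                    strand=feat.location.strand,
                    translation=translation,
                    product=feat.qualifiers.get("product", [""])[0],
                )
            )
        out.append(AnnotatedRecord(rec.id, str(rec.seq), features))
    return out


def _gff3_unescape(value: str) -> str:
    return urllib.parse.unquote(value)


def _gff3_escape(value: str) -> str:
    return urllib.parse.quote(value, safe=" ()[]/|.:^*$@!+?-_")


def _parse_gff3_attributes(col: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in col.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ParseError(f"malformed GFF3 attribute {chunk!r}", line=lineno)
        key, _, value = chunk.partition("=")
        attrs[key] = _gff3_unescape(value)
    return attrs


def _load_fasta_gff3(fasta_path: Path, gff_path: Path) -> list[AnnotatedRecord]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ParseError(f"{fasta_path}: no FASTA records found (line 1)")
    per_record: dict[str, list[CdsFeature]] = {rid: [] for rid in seqs}
    with open(gff_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{gff_path}: expected 9 tab-separated columns, got {len(cols)}",
                    line=lineno,
                )
            seqid, _source, ftype, start_s, end_s, _score, strand_s, _phase, attr_col = cols
            if ftype != "CDS":
                continue
            if seqid not in seqs:
                raise ValidationError(
                    f"{gff_path} line {lineno}: unknown contig {seqid!r}"
                )
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{gff_path}: non-numeric coordinates", line=lineno
                ) from exc
            if strand_s not in "+-":
                raise ValidationError(
                    f"{gff_path} line {lineno}: CDS strand must be '+' or '-'"
                )
            strand = 1 if strand_s == "+" else -1
            start, end = start1 - 1, end1  # GFF3 is 1-based inclusive
            if end > len(seqs[seqid]):
                raise CoordinateError(
                    f"{gff_path} line {lineno}: CDS extends past contig end"
                )
            attrs = _parse_gff3_attributes(attr_col, lineno)
            locus = attrs.get("locus_tag") or attrs.get("ID") or attrs.get("Name", "")
            translation = attrs.get("translation")
            if translation is None:
                translation = translate_cds(seqs[seqid], start, end, strand)
            per_record[seqid].append(
                CdsFeature(
                    locus_tag=locus,
                    start=start,
                    end=end,
                    strand=strand,
                    translation=translation,
                    product=attrs.get("product", ""),
                )
            )
    return [AnnotatedRecord(rid, seq, per_record[rid]) for rid, seq in seqs.items()]


# ---------------------------------------------------------------------------
# gene filtering


def filter_genes(
    record: AnnotatedRecord, query: str, use_regex: bool = False
) -> list[CdsFeature]:
    """Return features whose locus_tag/product/function annotations match.

    Plain queries are case-insensitive substring matches; regex queries use
    full regular-expression search. An invalid regex is an error, never a
    silent fallback to plain text.
    """
    if not query:
        raise QueryError("empty query")
    if use_regex:
        try:
            pattern = re.compile(query, re.IGNORECASE)
        except re.error as exc:
            raise QueryError(f"invalid regular expression {query!r}: {exc}") from exc
        match = lambda text: pattern.search(text) is not None
    else:
        needle = query.lower()
        match = lambda text: needle in text.lower()
    out = []
    for feat in record.features:
        haystacks = (feat.locus_tag, feat.product, *feat.functions)
        if any(match(h) for h in haystacks):
            out.append(feat)
    return out


# ---------------------------------------------------------------------------
# sideload JSON


@dataclass(frozen=True)
class SideloadSubregion:
    """One labelled genome span destined for the sideload JSON document."""

    start: int
    end: int
    label: str
    details: Mapping[str, str] = field(default_factory=dict)


def _load_schema() -> dict:
    with resources.files("bgcminer.data").joinpath("sideload_schema.json").open() as fh:
        return json.load(fh)


def validate_against_schema(instance, schema: dict, path: str = "$") -> None:
    """Validate ``instance`` against the bundled JSON-schema subset.

    Supports the keywords the sideload schema uses: ``type``, ``properties``,
    ``required``, ``items``, ``minimum``. Raises :class:`ValidationError` with
    a JSON-path on failure.
    """
    stype = schema.get("type")
    if stype is not None:
        type_map = {
            "object": dict,
            "array": list,
            "string": str,
            "integer": int,
            "number": (int, float),
        }
        expected = type_map[stype]
        if not isinstance(instance, expected) or (
            stype in ("integer", "number") and isinstance(instance, bool)
        ):
            raise ValidationError(f"{path}: expected {stype}, got {type(instance).__name__}")
    if "minimum" in schema and instance < schema["minimum"]:
        raise ValidationError(f"{path}: {instance} below minimum {schema['minimum']}")
    for key in schema.get("required", ()):
        if key not in instance:
            raise ValidationError(f"{path}: missing required key {key!r}")
    for key, subschema in schema.get("properties", {}).items():
        if key in instance:
            validate_against_schema(instance[key], subschema, f"{path}.{key}")
    if "items" in schema:
        for i, item in enumerate(instance):
            validate_against_schema(item, schema["items"], f"{path}[{i}]")


def build_sideload_document(
    records: Sequence[AnnotatedRecord],
    regions: Sequence[Sequence[SideloadSubregion]],
    tool_name: str,
    tool_version: str,
) -> dict:
    """Assemble (and validate) the sideload JSON document as a dict."""
    if len(records) != len(regions):
        raise ValidationError("records and regions lists differ in length")
    doc_records = []
    for record, subregions in zip(records, regions):
        subs = []
        for sub in subregions:
            if not (0 <= sub.start < sub.end <= len(record)):
                raise CoordinateError(
                    f"{record.record_id}: subregion [{sub.start}, {sub.end}) "
                    f"outside contig of length {len(record)}"
                )
            subs.append(
                {
                    "start": sub.start,
                    "end": sub.end,
                    "label": sub.label,
                    "details": {k: str(v) for k, v in sub.details.items()},
                }
            )
        doc_records.append({"name": record.record_id, "subregions": subs})
    doc = {
        "tool": {"name": tool_name, "version": tool_version},
        "records": doc_records,
    }
    validate_against_schema(doc, _load_schema())
    return doc


def write_sideload_json(
    records: Sequence[AnnotatedRecord],
    regions: Sequence[Sequence[SideloadSubregion]],
    tool_name: str,
    tool_version: str,
    path: str | Path,
) -> None:
    doc = build_sideload_document(records, regions, tool_name, tool_version)
    with open(path, "w") as handle:
        json.dump(doc, handle, indent=2, sort_keys=True)
        handle.write("\n")


# ---------------------------------------------------------------------------
# GFF3 output


def _gff3_line(
    seqid: str,
    source: str,
    ftype: str,
    start: int,
    end: int,
    score: float | None,
    strand: int | None,
    attrs: Mapping[str, str],
) -> str:
    strand_s = {1: "+", -1: "-", None: "."}[strand]
    score_s = "." if score is None else f"{score:.3f}"
    attr_s = ";".join(f"{k}={_gff3_escape(str(v))}" for k, v in attrs.items())
    # internal 0-based half-open -> GFF3 1-based inclusive
    return "\t".join(
        [seqid, source, ftype, str(start + 1), str(end), score_s, strand_s, ".", attr_s]
    )


def write_gff3(
    records: Sequence[AnnotatedRecord],
    regions: Mapping[str, Sequence] | None = None,
    tfbs_hits: Mapping[str, Sequence] | None = None,
    path: str | Path = "-",
    source: str = "bgcminer",
) -> str:
    """Write contigs, CDS features, detection results and TFBS hits as GFF3.

    ``regions`` and ``tfbs_hits`` map record_id to the rule-engine / scanner
    outputs for that contig; either may be omitted. Returns the text written.
    """
    regions = regions or {}
    tfbs_hits = tfbs_hits or {}
    lines = ["##gff-version 3"]
    for record in records:
        lines.append(f"##sequence-region {record.record_id} 1 {len(record)}")
        for feat in record.features:
            attrs = {
                "ID": feat.locus_tag,
                "locus_tag": feat.locus_tag,
                "translation": feat.translation,
            }
            if feat.product:
                attrs["product"] = feat.product
            lines.append(
                _gff3_line(
                    record.record_id, source, "CDS",
                    feat.start, feat.end, None, feat.strand, attrs,
                )
            )
        for ridx, region in enumerate(regions.get(record.record_id, ()), start=1):
            lines.append(
                _gff3_line(
                    record.record_id, source, "region",
                    region.start, region.end, None, None,
                    {"ID": f"region_{ridx}", "products": ",".join(region.products)},
                )
            )
            for pidx, proto in enumerate(region.protoclusters, start=1):
                lines.append(
                    _gff3_line(
                        record.record_id, source, "protocluster",
                        proto.start, proto.end, None, None,
                        {
                            "ID": f"region_{ridx}_protocluster_{pidx}",
                            "rule": proto.rule_name,
                            "core_start": str(proto.core_start),
                            "core_end": str(proto.core_end),
                            "core_cds": ",".join(proto.core_cds),
                        },
                    )
                )
        for hidx, hit in enumerate(tfbs_hits.get(record.record_id, ()), start=1):
            lines.append(
                _gff3_line(
                    record.record_id, source, "TF_binding_site",
                    hit.start, hit.start + hit.length, hit.score, hit.strand,
                    {
                        "ID": f"tfbs_{hidx}",
                        "pwm": hit.pwm_name,
                        "confidence": hit.confidence,
                    },
                )
            )
    text = "\n".join(lines) + "\n"
    if path != "-":
        Path(path).write_text(text)
    return text
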