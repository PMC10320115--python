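"""Detection-rule DSL and cluster formation.

A detection rule states which biosynthetic functions (profile hits) must
co-occur within a genomic distance window for a stretch of genes to count as
a biosynthetic gene cluster core. Rules are written in a small text DSL::

    RULE t1pks CATEGORY PKS CUTOFF 20 NEIGHBOURHOOD 20
    CONDITIONS PKS_KS and PKS_AT

Condition grammar (``and`` binds tighter than ``or``)::

    expr      ::= term (("and" | "or") term)*
    term      ::= "not" term | "(" expr ")"
                | "minimum(" int "," "[" name ("," name)* "]" ")"
                | "cds(" expr ")" | profile-name

``minimum(n, [...])`` requires hits to at least ``n`` distinct profiles from
the list; ``cds(expr)`` requires a *single* gene satisfying ``expr`` on its
own hits (as opposed to the default window-wide evaluation).

Evaluation semantics: a gene is a cluster core gene iff it carries a hit to
some profile the rule references, and the rule condition holds over the hit
set of all genes within ``cutoff_kb`` of it (gap distance between nearest
feature boundaries, 0 when overlapping). Core genes within ``cutoff_kb`` of
each other chain into a protocluster, whose span is extended by
``neighbourhood_kb`` on each side and clamped to the contig. Protoclusters
from different rules whose extended spans overlap merge into hybrid regions,
the reporting unit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ParseError, ValidationError
from .genome_io import AnnotatedRecord, CdsFeature
from .profile_detection import ProfileHit

# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class ConditionNode:
    kind: str  # leaf | and | or | not | minimum | cds
    profile: str | None = None
    n: int | None = None
    options: tuple[str, ...] = ()
    children: tuple["ConditionNode", ...] = ()

    def __post_init__(self):
        if self.kind == "leaf":
            if not self.profile or self.children:
                raise ValidationError("leaf node must name a profile and have no children")
        elif self.kind == "minimum":
            if self.n is None or not (1 <= self.n <= len(self.options)):
                raise ValidationError(
                    f"minimum requires 1 <= n <= number of options, got n={self.n} "
                    f"with {len(self.options)} options"
                )
        elif self.kind == "not":
            if len(self.children) != 1:
                raise ValidationError("'not' takes exactly one child")
        elif self.kind in ("and", "or"):
            if len(self.children) < 2:
                raise ValidationError(f"{self.kind!r} needs at least two children")
        elif self.kind == "cds":
            if len(self.children) != 1:
                raise ValidationError("'cds' takes exactly one child")
            for node in _walk(self.children[0]):
                if node.kind not in ("leaf", "and", "or"):
                    raise ValidationError(
                        "cds(...) may only contain profile names, 'and' and 'or'"
                    )
        else:
            raise ValidationError(f"unknown condition kind {self.kind!r}")

    def referenced_profiles(self) -> set[str]:
        out = set()
        for node in _walk(self):
            if node.kind == "leaf":
                out.add(node.profile)
            elif node.kind == "minimum":
                out.update(node.options)
        return out


def _walk(node: ConditionNode) -> Iterable[ConditionNode]:
    yield node
    for child in node.children:
        yield from _walk(child)


@dataclass(frozen=True)
class DetectionRule:
    name: str
    category: str
    cutoff_kb: float
    neighbourhood_kb: float
    condition: ConditionNode

    def __post_init__(self):
        if self.cutoff_kb <= 0:
            raise ValidationError(f"{self.name}: cutoff must be positive")
        if self.neighbourhood_kb < 0:
            raise ValidationError(f"{self.name}: neighbourhood must be >= 0")

    @property
    def cutoff_bp(self) -> int:
        return int(round(self.cutoff_kb * 1000))

    @property
    def neighbourhood_bp(self) -> int:
        return int(round(self.neighbourhood_kb * 1000))


@dataclass(frozen=True)
class Protocluster:
    rule_name: str
    core_start: int
    core_end: int
    start: int
    end: int
    core_cds: tuple[str, ...]

    def __post_init__(self):
        if not (self.start <= self.core_start < self.core_end <= self.end):
            raise ValidationError(
                f"{self.rule_name}: span nesting violated "
                f"({self.start}<={self.core_start}<{self.core_end}<={self.end})"
            )
        if not self.core_cds:
            raise ValidationError(f"{self.rule_name}: protocluster without core genes")


@dataclass(frozen=True)
class Region:
    start: int
    end: int
    protoclusters: tuple[Protocluster, ...]
    products: tuple[str, ...]

    def __post_init__(self):
        if not self.protoclusters:
            raise ValidationError("region without protoclusters")


# ---------------------------------------------------------------------------
# DSL parsing

_TOKEN_RE = re.compile(
    r"""(?P<ws>\s+)
      | (?P<punct>[(),\[\]])
      | (?P<number>\d+(?:\.\d+)?)
      | (?P<name>[A-Za-z_][A-Za-z0-9_.\-]*)
    """,
    re.VERBOSE,
)

_KEYWORDS = {"and", "or", "not", "minimum", "cds"}


@dataclass(frozen=True)
class _Token:
    kind: str  # punct | number | name | end
    text: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            raise ParseError(f"unexpected character {text[pos]!r}", column=pos)
        if match.lastgroup != "ws":
            tokens.append(_Token(match.lastgroup, match.group(), pos))
        pos = match.end()
    tokens.append(_Token("end", "", len(text)))
    return tokens


class _Parser:
    """Recursive-descent parser over the token stream of one rule."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    @property
    def current(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.current
        self.i += 1
        return tok

    def fail(self, message: str):
        raise ParseError(message, column=self.current.pos)

    def expect_name(self, expected: str | None = None) -> str:
        tok = self.current
        if tok.kind != "name" or (expected is not None and tok.text != expected):
            self.fail(f"expected {expected or 'a name'}, found {tok.text!r}")
        return self.advance().text

    def expect_punct(self, char: str):
        if not (self.current.kind == "punct" and self.current.text == char):
            self.fail(f"expected {char!r}, found {self.current.text!r}")
        self.advance()

    def expect_number(self) -> float:
        if self.current.kind != "number":
            self.fail(f"expected a number, found {self.current.text!r}")
        return float(self.advance().text)

    def parse_rule(self) -> DetectionRule:
        self.expect_name("RULE")
        name = self.expect_name()
        self.expect_name("CATEGORY")
        category = self.expect_name()
        self.expect_name("CUTOFF")
        cutoff = self.expect_number()
        self.expect_name("NEIGHBOURHOOD")
        neighbourhood = self.expect_number()
        self.expect_name("CONDITIONS")
        condition = self.parse_expr()
        if self.current.kind != "end":
            self.fail(f"trailing input {self.current.text!r}")
        return DetectionRule(name, category, cutoff, neighbourhood, condition)

    def parse_expr(self) -> ConditionNode:
        node = self.parse_and()
        children = [node]
        while self.current.kind == "name" and self.current.text == "or":
            self.advance()
            children.append(self.parse_and())
        if len(children) == 1:
            return node
        return ConditionNode("or", children=tuple(children))

    def parse_and(self) -> ConditionNode:
        node = self.parse_term()
        children = [node]
        while self.current.kind == "name" and self.current.text == "and":
            self.advance()
            children.append(self.parse_term())
        if len(children) == 1:
            return node
        return ConditionNode("and", children=tuple(children))

    def parse_term(self) -> ConditionNode:
        tok = self.current
        if tok.kind == "punct" and tok.text == "(":
            self.advance()
            node = self.parse_expr()
            self.expect_punct(")")
            return node
        if tok.kind != "name":
            self.fail(f"expected a condition, found {tok.text!r}")
        if tok.text == "not":
            self.advance()
            return ConditionNode("not", children=(self.parse_term(),))
        if tok.text == "minimum":
            self.advance()
            self.expect_punct("(")
            n = self.expect_number()
            if n != int(n):
                self.fail("minimum count must be an integer")
            self.expect_punct(",")
            self.expect_punct("[")
            options = [self.expect_name()]
            while self.current.kind == "punct" and self.current.text == ",":
                self.advance()
                options.append(self.expect_name())
            self.expect_punct("]")
            self.expect_punct(")")
            return ConditionNode("minimum", n=int(n), options=tuple(options))
        if tok.text == "cds":
            self.advance()
            self.expect_punct("(")
            inner = self.parse_expr()
            self.expect_punct(")")
            return ConditionNode("cds", children=(inner,))
        if tok.text in _KEYWORDS:
            self.fail(f"keyword {tok.text!r} cannot be used as a profile name")
        self.advance()
        return ConditionNode("leaf", profile=tok.text)


def parse_rule(text: str) -> DetectionRule:
    """Parse one ``RULE ... CONDITIONS ...`` block."""
    return _Parser(text).parse_rule()


def parse_rules(text: str) -> list[DetectionRule]:
    """Parse a rule file: one rule per RULE block, ``#`` comments allowed."""
    stripped = "\n".join(
        line for line in text.splitlines() if not line.lstrip().startswith("#")
    )
    blocks = re.split(r"(?=\bRULE\b)", stripped)
    rules = []
    names = set()
    for block in blocks:
        if not block.strip():
            continue
        rule = parse_rule(block.strip())
        if rule.name in names:
            raise ValidationError(f"duplicate rule name {rule.name!r}")
        names.add(rule.name)
        rules.append(rule)
    return rules


def load_rules(path: str | Path) -> list[DetectionRule]:
    return parse_rules(Path(path).read_text())


def format_condition(node: ConditionNode, parent: str | None = None) -> str:
    if node.kind == "leaf":
        return node.profile
    if node.kind == "minimum":
        return f"minimum({node.n}, [{', '.join(node.options)}])"
    if node.kind == "cds":
        return f"cds({format_condition(node.children[0])})"
    if node.kind == "not":
        return f"not {format_condition(node.children[0], parent='not')}"
    joiner = f" {node.kind} "
    text = joiner.join(format_condition(c, parent=node.kind) for c in node.children)
    # parenthesize when the parent binds at least as tightly
    needs_parens = (
        parent == "not"
        or (parent == "and")
        or (parent == "or" and node.kind == "or")
    )
    return f"({text})" if needs_parens else text


def format_rule(rule: DetectionRule) -> str:
    """Render a rule back to DSL text; reparsing yields an equal tree."""

    def num(x: float) -> str:
        return str(int(x)) if x == int(x) else str(x)

    return (
        f"RULE {rule.name} CATEGORY {rule.category} "
        f"CUTOFF {num(rule.cutoff_kb)} NEIGHBOURHOOD {num(rule.neighbourhood_kb)} "
        f"CONDITIONS {format_condition(rule.condition)}"
    )


# ---------------------------------------------------------------------------
# evaluation

def gap_distance(a: CdsFeature, b: CdsFeature) -> int:
    """Base pairs between nearest feature boundaries; 0 when overlapping."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def _condition_true(
    node: ConditionNode,
    window_profiles: set[str],
    per_cds_profiles: Sequence[set[str]],
) -> bool:
    if node.kind == "leaf":
        return node.profile in window_profiles
    if node.kind == "and":
        return all(
            _condition_true(c, window_profiles, per_cds_profiles) for c in node.children
        )
    if node.kind == "or":
        return any(
            _condition_true(c, window_profiles, per_cds_profiles) for c in node.children
        )
    if node.kind == "not":
        return not _condition_true(node.children[0], window_profiles, per_cds_profiles)
    if node.kind == "minimum":
        return len(window_profiles.intersection(node.options)) >= node.n
    if node.kind == "cds":
        # a single gene must satisfy the subtree on its own hits
        return any(
            _condition_true(node.children[0], profiles, [profiles])
            for profiles in per_cds_profiles
        )
    raise AssertionError(node.kind)


def evaluate_rule(
    rule: DetectionRule, record: AnnotatedRecord, hits: Sequence[ProfileHit]
) -> set[str]:
    """Return the locus_tags of genes that are cluster cores under ``rule``."""
    referenced = rule.condition.referenced_profiles()
    profiles_by_cds: dict[str, set[str]] = {}
    for hit in hits:
        profiles_by_cds.setdefault(hit.locus_tag, set()).add(hit.profile_name)
    core: set[str] = set()
    features = record.features
    for feat in features:
        own = profiles_by_cds.get(feat.locus_tag, set())
        if not (own & referenced):
            continue
        window = [
            g for g in features if gap_distance(feat, g) <= rule.cutoff_bp
        ]
        per_cds = [profiles_by_cds.get(g.locus_tag, set()) for g in window]
        union: set[str] = set().union(*per_cds) if per_cds else set()
        if _condition_true(rule.condition, union, per_cds):
            core.add(feat.locus_tag)
    return core


def form_protoclusters(
    core: Iterable[str], rule: DetectionRule, record: AnnotatedRecord
) -> list[Protocluster]:
    """Chain core genes into protoclusters and extend by the neighbourhood."""
    feats = sorted(
        (record.get_feature(tag) for tag in core), key=lambda f: (f.start, f.end)
    )
    if not feats:
        return []
    chains: list[list[CdsFeature]] = [[feats[0]]]
    for feat in feats[1:]:
        if gap_distance(chains[-1][-1], feat) <= rule.cutoff_bp:
            chains[-1].append(feat)
        else:
            chains.append([feat])
    out = []
    for chain in chains:
        core_start = min(f.start for f in chain)
        core_end = max(f.end for f in chain)
        out.append(
            Protocluster(
                rule_name=rule.name,
                core_start=core_start,
                core_end=core_end,
                start=max(0, core_start - rule.neighbourhood_bp),
                end=min(len(record), core_end + rule.neighbourhood_bp),
                core_cds=tuple(f.locus_tag for f in chain),
            )
        )
    return out


def merge_into_regions(protoclusters: Sequence[Protocluster]) -> list[Region]:
    """Merge overlapping protocluster spans (transitively) into regions."""
    ordered = sorted(protoclusters, key=lambda p: (p.start, p.end, p.rule_name))
    regions: list[Region] = []
    group: list[Protocluster] = []
    group_end = None
    for proto in ordered:
        if group and proto.start < group_end:
            group.append(proto)
            group_end = max(group_end, proto.end)
        else:
            if group:
                regions.append(_finish_region(group))
            group = [proto]
            group_end = proto.end
    if group:
        regions.append(_finish_region(group))
    return regions


def _finish_region(group: list[Protocluster]) -> Region:
    return Region(
        start=min(p.start for p in group),
        end=max(p.end for p in group),
        protoclusters=tuple(group),
        products=tuple(sorted({p.rule_name for p in group})),
    )


def detect(
    record: AnnotatedRecord,
    rules: Sequence[DetectionRule],
    hits: Sequence[ProfileHit],
) -> list[Region]:
    """Full detection pass: evaluate every rule, chain cores, merge regions."""
    protoclusters: list[Protocluster] = []
    for rule in rules:
        core = evaluate_rule(rule, record, hits)
        protoclusters.extend(form_protoclusters(core, rule, record))
    return merge_into_regions(protoclusters)
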