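"""Independent brute-force reference implementations used by the tests.

Everything here deliberately recomputes results the slow, obvious way —
naive window enumeration, graph components, memoized recursion — so the
optimized library code is checked against a second, structurally different
route.
"""

from __future__ import annotations

import functools
import math

import networkx as nx
import numpy as np

# ---------------------------------------------------------------------------
# rule engine


def brute_core_set(rule, record, hits):
    """Naive re-evaluation: per-candidate window enumeration + recursion."""
    profiles_of = {}
    for h in hits:
        profiles_of.setdefault(h.locus_tag, set()).add(h.profile_name)
    referenced = rule.condition.referenced_profiles()
    cutoff = rule.cutoff_bp

    def gap(a, b):
        if a.start < b.end and b.start < a.end:
            return 0
        return min(abs(a.start - b.end), abs(b.start - a.end))

    def truth(node, union, per_cds):
        if node.kind == "leaf":
            return node.profile in union
        if node.kind == "not":
            return not truth(node.children[0], union, per_cds)
        if node.kind == "and":
            return all(truth(c, union, per_cds) for c in node.children)
        if node.kind == "or":
            return any(truth(c, union, per_cds) for c in node.children)
        if node.kind == "minimum":
            return sum(1 for p in set(node.options) if p in union) >= node.n
        if node.kind == "cds":
            return any(truth(node.children[0], s, [s]) for s in per_cds)
        raise AssertionError(node.kind)

    core = set()
    for feat in record.features:
        if not (profiles_of.get(feat.locus_tag, set()) & referenced):
            continue
        window = [g for g in record.features if gap(feat, g) <= cutoff]
        per_cds = [profiles_of.get(g.locus_tag, set()) for g in window]
        union = set()
        for s in per_cds:
            union |= s
        if truth(rule.condition, union, per_cds):
            core.add(feat.locus_tag)
    return core


def brute_chain_partition(features, cutoff_bp):
    """Connected components of the gap-<=cutoff graph over core features."""
    graph = nx.Graph()
    graph.add_nodes_from(f.locus_tag for f in features)
    for a in features:
        for b in features:
            if a.locus_tag >= b.locus_tag:
                continue
            overlap = a.start < b.end and b.start < a.end
            gap = 0 if overlap else min(abs(a.start - b.end), abs(b.start - a.end))
            if gap <= cutoff_bp:
                graph.add_edge(a.locus_tag, b.locus_tag)
    return {frozenset(c) for c in nx.connected_components(graph)}


def brute_region_groups(protoclusters):
    """Connected components of the span-overlap graph over protoclusters."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(protoclusters)))
    for i, a in enumerate(protoclusters):
        for j, b in enumerate(protoclusters):
            if i < j and a.start < b.end and b.start < a.end:
                graph.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(graph)}


# ---------------------------------------------------------------------------
# PWM scanning


def brute_log_odds(counts, pseudocount=1.0, background=None):
    """Recompute the log-odds matrix cell by cell from the formula."""
    counts = np.asarray(counts, dtype=float)
    bg = [0.25] * 4 if background is None else list(background)
    L = counts.shape[0]
    out = np.zeros((L, 4))
    for i in range(L):
        row_sum = sum(counts[i])
        for a in range(4):
            p = (counts[i][a] + pseudocount * bg[a]) / (row_sum + pseudocount)
            out[i, a] = math.log2(p / bg[a])
    return out


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def brute_scan(sequence, log_odds):
    """Per-window scores on both strands, the slow way.

    Returns {(start, strand): score} for all windows free of N.
    """
    L = len(log_odds)
    scores = {}
    for start in range(len(sequence) - L + 1):
        window = sequence[start : start + L]
        if "N" in window:
            continue
        fwd = sum(log_odds[i][_IDX[b]] for i, b in enumerate(window))
        rc = "".join(_COMP[b] for b in reversed(window))
        rev = sum(log_odds[i][_IDX[b]] for i, b in enumerate(rc))
        scores[(start, 1)] = fwd
        scores[(start, -1)] = rev
    return scores


def brute_tier(score, min_score, max_score, fractions):
    s = (score - min_score) / (max_score - min_score)
    if s >= fractions["strong"]:
        return "strong"
    if s >= fractions["medium"]:
        return "medium"
    if s >= fractions["weak"]:
        return "weak"
    return None


# ---------------------------------------------------------------------------
# Stachelhaus ranking


def brute_predictions(code10, code34, table, min_matches10=7):
    """Score-and-sort re-implementation of the two-level lookup."""

    def m(a, b):
        return sum(1 for x, y in zip(a, b) if x == y != "-")

    rows = [(m(code10, e.code10), m(code34, e.code34), e) for e in table]
    if not rows:
        return []
    best = max(r[0] for r in rows)
    if best < min_matches10:
        return []
    survivors = [r for r in rows if r[0] == best]
    by_substrate = {}
    for m10, m34, e in survivors:
        by_substrate.setdefault(e.substrate, []).append((m34, e.source_id))
    out = []
    for substrate, members in by_substrate.items():
        out.append(
            (
                best,
                max(m34 for m34, _ in members),
                substrate,
                tuple(sorted(sid for _, sid in members)),
            )
        )
    out.sort(key=lambda t: (-t[1], t[2], t[3]))
    return out


# ---------------------------------------------------------------------------
# core-peptide identity


def brute_identity(query, hit, match=1.0, mismatch=-1.0, open_=-2.0, extend=-1.0):
    """Memoized-recursion affine aligner maximizing (score, identities).

    Returns (score, identical pairs); forward recursion over suffixes, an
    independent route from the iterative table-filling implementation.
    """

    @functools.lru_cache(maxsize=None)
    def go(i, j, state):
        # state: 0 = free to open, 1 = in query-gap run, 2 = in hit-gap run
        if i == len(query) and j == len(hit):
            return (0.0, 0)
        options = []
        if i < len(query) and j < len(hit):
            sub = match if query[i] == hit[j] else mismatch
            inc = 1 if query[i] == hit[j] else 0
            s, n = go(i + 1, j + 1, 0)
            options.append((s + sub, n + inc))
        if i < len(query):  # query residue over a gap
            cost = extend if state == 1 else open_
            s, n = go(i + 1, j, 1)
            options.append((s + cost, n))
        if j < len(hit):  # hit residue over a gap
            cost = extend if state == 2 else open_
            s, n = go(i, j + 1, 2)
            options.append((s + cost, n))
        return max(options)

    result = go(0, 0, 0)
    go.cache_clear()
    return result


# ---------------------------------------------------------------------------
# cyanobactin motif


def hand_motif_match(translation):
    """Literal positional check of the cyanobactin leader motif.

    Window layout: M . K K N [IL] . P . . . . P V . R  (16 residues).
    """
    fixed = {0: "M", 2: "K", 3: "K", 4: "N", 7: "P", 12: "P", 13: "V", 15: "R"}
    for start in range(len(translation) - 15):
        window = translation[start : start + 16]
        if all(window[i] == c for i, c in fixed.items()) and window[5] in "IL":
            return start
    return None
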