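"""Deliberately naive reference implementations used only as test oracles.

Each function here re-derives its result by direct enumeration or literal
rule reading, independently of the production code paths it checks.
"""

from __future__ import annotations

import itertools


def naive_intermediate_class(tail, gap, d5, d3, downstream_tss_d=None):
    """Literal reading of the four-intermediate decision ladder."""
    if tail > 15:
        return "POLYA"
    # non-poly(A) reads need a trusted 3' end: adapter within 5 nt
    if not (gap < 5):
        return "UNCLASSIFIED"
    in_gene_body = d5 < -50
    past_pa = d3 > 50
    near_pa = (d3 >= -50) and (d3 <= 50)
    if in_gene_body and past_pa:
        return "READTHROUGH"
    if in_gene_body and near_pa:
        return "CLEAVED_5P"
    if (d5 >= 0) and (d5 <= 500):
        guard_ok = True
        if downstream_tss_d is not None and downstream_tss_d <= 500:
            guard_ok = d5 <= downstream_tss_d - 100
        if guard_ok:
            return "CLEAVED_3P"
        return "UNCLASSIFIED"
    return "UNCLASSIFIED"


def transitive_closure_clusters(sites: dict[int, int], gap: int) -> list[dict[int, int]]:
    """Cluster sites by the transitive closure of |a-b| <= gap."""
    positions = sorted(sites)
    parent = {p: p for p in positions}

    def find(p):
        while parent[p] != p:
            p = parent[p]
        return p

    for a, b in itertools.combinations(positions, 2):
        if abs(a - b) <= gap:
            parent[find(a)] = find(b)
    groups: dict[int, dict[int, int]] = {}
    for p in positions:
        groups.setdefault(find(p), {})[p] = sites[p]
    return sorted(groups.values(), key=lambda g: min(g))


def infix_edit_distance(query: str, text: str) -> tuple[int, int, int]:
    """Best Levenshtein distance of query against any substring of text,
    by full enumeration; returns (distance, start, end)."""

    def lev(a: str, b: str) -> int:
        prev = list(range(len(b) + 1))
        for i, ca in enumerate(a, 1):
            cur = [i]
            for j, cb in enumerate(b, 1):
                cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                               prev[j - 1] + (ca != cb)))
            prev = cur
        return prev[-1]

    best = (len(query), 0, 0)
    for i in range(len(text) + 1):
        for j in range(i, min(len(text), i + 2 * len(query)) + 1):
            d = lev(query, text[i:j])
            if d < best[0]:
                best = (d, i, j)
    return best


def exact_mannwhitney_u(a, b) -> float:
    """U statistic for sample a against b by direct pair counting."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def best_tail_interval(segment: str, min_purity=0.85, anchor=5):
    """Longest A-endpointed interval with A purity >= min_purity that is
    within `anchor` non-A bases of either segment boundary; ties toward the
    segment start.  Full O(n^2) enumeration."""
    n = len(segment)
    best = None
    for i in range(n):
        for j in range(i + 1, n + 1):
            sub = segment[i:j]
            if not (sub[0] == "A" and sub[-1] == "A"):
                continue
            a = sub.count("A")
            if a / len(sub) < min_purity:
                continue
            left_non_a = segment[:i].count("C") + segment[:i].count("G") + segment[:i].count("T")
            right_non_a = segment[j:].count("C") + segment[j:].count("G") + segment[j:].count("T")
            if left_non_a > anchor and right_non_a > anchor:
                continue
            key = (-(j - i), i)
            if best is None or key < best[0]:
                best = (key, i, j)
    if best is None:
        return 0, (0, 0)
    _, i, j = best
    return j - i, (i, j)
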