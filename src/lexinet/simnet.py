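"""Thresholded all-vs-all similarity networks and their structural analysis.

Every pair of items is aligned in both global and local mode; an edge is
drawn when the normalized distance in the requested mode does not exceed the
threshold.  Connected components act as putative homolog families; edges
whose local and global alignments disagree flag partial similarity, and
articulation vertices whose neighbor groups align to disjoint spans flag
fused/composite forms.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .align import (ScoringScheme, global_align, local_align, GAP)
from .lexio import WordForm, SequenceRecord

__all__ = [
    "SimilarityGraph",
    "Component",
    "HubGroup",
    "HubReport",
    "build_network",
    "components",
    "flag_concordance",
    "articulation_hubs",
]

SimilarityGraph = nx.Graph


@dataclass(frozen=True)
class Component:
    """A connected component with per-family membership counts."""

    members: tuple[str, ...]
    family_counts: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.members)

    def families(self) -> list[str]:
        return sorted(self.family_counts)


@dataclass(frozen=True)
class HubGroup:
    """One connected sub-group created by removing an articulation hub."""

    members: tuple[str, ...]
    hub_span: tuple[int, int] | None  # union of local windows on the hub


@dataclass(frozen=True)
class HubReport:
    node: str
    groups: tuple[HubGroup, ...]


def _segments(item) -> tuple[str, ...]:
    return tuple(item.segments)


def _alignment_stats(seg_u, seg_v, scheme):
    """Both-mode scores, distances, concordance flag and the local window."""
    ga = global_align(seg_u, seg_v, scheme)
    la = local_align(seg_u, seg_v, scheme)
    su, sv = scheme.self_score(seg_u), scheme.self_score(seg_v)
    denom = su + sv
    if denom <= 0:
        raise ValueError("degenerate scheme: zero or negative self scores")
    gdist = min(1.0, max(0.0, 1.0 - 2.0 * ga.score / denom))
    ldist = min(1.0, max(0.0, 1.0 - 2.0 * la.score / denom))
    # concordant: the local alignment reproduces the global one as a whole --
    # same matched pairs and windows covering both sequences end to end.
    full = (la.span_a == (0, len(seg_u)) and la.span_b == (0, len(seg_v)))
    concordant = full and la.matched_pairs() == ga.matched_pairs()
    return ga, la, gdist, ldist, concordant


def build_network(items: Sequence[WordForm | SequenceRecord],
                  scheme: ScoringScheme,
                  threshold: float = 0.45,
                  mode: str = "global") -> SimilarityGraph:
    """All-vs-all thresholded similarity graph over words or sequences.

    Both global and local statistics are stored on every edge regardless of
    ``mode``; the edge criterion is ``distance(mode) <= threshold``.  Node
    attributes carry label/doculect/family/concept (where available) plus the
    serialized tokens, so the graph alone suffices for later analyses.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    if not items:
        raise ValueError("no items")
    graph = nx.Graph(threshold=threshold, mode=mode)
    graph.graph["_scheme"] = scheme
    ordered = sorted(items, key=lambda it: it.id)
    for it in ordered:
        attrs = {"label": getattr(it, "form", it.id),
                 "tokens": " + ".join(" ".join(m) for m in it.morphemes)}
        for key in ("doculect", "family", "concept"):
            val = getattr(it, key, None)
            if val is not None:
                attrs[key] = val
        graph.add_node(it.id, **attrs)
    cache: dict[tuple, tuple] = {}
    for i, u in enumerate(ordered):
        seg_u = _segments(u)
        for v in ordered[i + 1:]:
            seg_v = _segments(v)
            key = (seg_u, seg_v)
            if key not in cache:
                cache[key] = _alignment_stats(seg_u, seg_v, scheme)
            ga, la, gdist, ldist, concordant = cache[key]
            dist = gdist if mode == "global" else ldist
            if dist <= threshold:
                graph.add_edge(u.id, v.id,
                               gscore=ga.score, lscore=la.score,
                               gdist=gdist, ldist=ldist, distance=dist,
                               concordant=concordant,
                               span_a_start=la.span_a[0], span_a_end=la.span_a[1],
                               span_b_start=la.span_b[0], span_b_end=la.span_b[1])
    return graph


def hub_window(graph: SimilarityGraph, hub: str, neighbor: str) -> tuple[int, int] | None:
    """Local-alignment window on ``hub`` for the edge to ``neighbor``.

    Edge spans are stored relative to the lexicographically smaller endpoint
    (the construction order), so orientation must be resolved here.
    """
    data = graph.get_edge_data(hub, neighbor)
    if data is None:
        return None
    if hub < neighbor:
        return (data["span_a_start"], data["span_a_end"])
    return (data["span_b_start"], data["span_b_end"])


def components(graph: SimilarityGraph, min_size: int = 1) -> list[Component]:
    """Connected components of size >= min_size, largest first.

    Ties are broken by the lexicographically smallest member id so the
    ordering is reproducible byte for byte.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    out = []
    for nodes in nx.connected_components(graph):
        members = tuple(sorted(nodes))
        if len(members) < min_size:
            continue
        fams = Counter(graph.nodes[n].get("family", "?") for n in members)
        out.append(Component(members=members, family_counts=dict(fams)))
    out.sort(key=lambda c: (-c.size, c.members[0]))
    return out


def flag_concordance(graph: SimilarityGraph) -> SimilarityGraph:
    """(Re)annotate every edge with its concordance flag.

    An edge is concordant (gray) when local and global alignment agree: the
    local windows span both sequences completely and the matched token-index
    pairs coincide.  Discordant (black) edges signal partial similarity, e.g.
    a fused form whose local alignment covers only one morpheme.  Normally
    already set by :func:`build_network`; this recomputes from node tokens.
    """
    scheme = graph.graph.get("_scheme")
    if scheme is None:
        raise ValueError("graph carries no scoring scheme; rebuild with build_network")
    from .lexio import parse_tokens

    cache: dict[tuple, bool] = {}
    for u, v in graph.edges():
        seg_u = tuple(t for m in parse_tokens(graph.nodes[u]["tokens"]) for t in m)
        seg_v = tuple(t for m in parse_tokens(graph.nodes[v]["tokens"]) for t in m)
        a, b = (seg_u, seg_v) if u < v else (seg_v, seg_u)
        key = (a, b)
        if key not in cache:
            cache[key] = _alignment_stats(a, b, scheme)[4]
        graph.edges[u, v]["concordant"] = cache[key]
    return graph


def articulation_hubs(graph: SimilarityGraph, component: Component) -> list[HubReport]:
    """Articulation vertices of a component with their neighbor-group split.

    For each articulation vertex the connected groups its removal creates are
    reported together with the hub-span each group aligns to: the union of
    the local-alignment windows on the hub over the group members directly
    adjacent to it.
    """
    sub = graph.subgraph(component.members)
    hubs = sorted(nx.articulation_points(sub))
    reports = []
    for hub in hubs:
        rest = sub.subgraph(n for n in component.members if n != hub)
        groups = []
        for nodes in nx.connected_components(rest):
            members = tuple(sorted(nodes))
            windows = [hub_window(graph, hub, n) for n in members
                       if graph.has_edge(hub, n)]
            windows = [w for w in windows if w is not None and w[1] > w[0]]
            span = (min(w[0] for w in windows), max(w[1] for w in windows)) \
                if windows else None
            groups.append(HubGroup(members=members, hub_span=span))
        groups.sort(key=lambda g: (-len(g.members), g.members[0]))
        reports.append(HubReport(node=hub, groups=tuple(groups)))
    return reports
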