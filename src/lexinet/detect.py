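"""Turn network structure into calls: cognate sets, borrowing candidates,
composite (fused/compound) forms and morpheme-level partial cognacy.

The detectors are deliberately simple, transparent rules over the similarity
graph: connected components per concept approximate cognate sets; words whose
family is in the minority of a family-mixed component are borrowing
candidates (direction left undetermined); articulation hubs whose neighbor
groups align to non-overlapping spans are fused/compound candidates; and a
network over morphemes instead of whole words yields morpheme cognate
classes, i.e. partial cognacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .align import ScoringScheme, sound_class_scheme
from .lexio import WordForm, Wordlist
from .simnet import (Component, SimilarityGraph, articulation_hubs,
                     build_network, components, hub_window)

__all__ = [
    "BorrowingCall",
    "CompositeCall",
    "PartialCognacyResult",
    "cognate_sets",
    "borrowing_candidates",
    "composite_candidates",
    "partial_cognates",
    "PARTIAL_COGNACY_THRESHOLD",
]

# Morphemes are very short (2-5 tokens), which biases the length-normalized
# distance upward; the morpheme-level default is therefore more permissive
# than the whole-word network default of 0.45.
PARTIAL_COGNACY_THRESHOLD = 0.60

DOMINANCE_CUTOFF = 0.60


@dataclass(frozen=True)
class BorrowingCall:
    """A word flagged as a borrowing candidate (direction undetermined)."""

    word_id: str
    component_id: str  # smallest member id of the component
    family_mixture: Mapping[str, int]
    dominant_family: str | None  # None -> unresolved mixed component
    direction: str = "undetermined"


@dataclass(frozen=True)
class CompositeCall:
    """A word called as a fused/compound form.

    ``breakpoints`` are token indices splitting the word into half-open
    parts; ``part_groups`` maps each part index to the ids of the neighbor
    group supporting it.
    """

    word_id: str
    breakpoints: tuple[int, ...]
    part_spans: tuple[tuple[int, int], ...]
    part_groups: tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class PartialCognacyResult:
    """Morpheme-level cognate classes: word id -> one class id per morpheme."""

    classes: Mapping[str, tuple[str, ...]]

    def shared_slots(self, word_a: str, word_b: str) -> list[tuple[int, int]]:
        """Morpheme-slot pairs of the two words that share a cognate class."""
        ca, cb = self.classes[word_a], self.classes[word_b]
        return [(i, j) for i, x in enumerate(ca) for j, y in enumerate(cb)
                if x == y]


def cognate_sets(wordlist: Wordlist, scheme: ScoringScheme | None = None,
                 threshold: float = 0.45, mode: str = "global",
                 ) -> dict[str, dict[str, str]]:
    """Per-concept cognate partitions from connected components.

    Returns ``{concept: {word_id: cognate_class_id}}`` where the class id is
    the smallest contained word id (reproducible under input reordering).
    Singleton classes are allowed.
    """
    if not len(wordlist):
        raise ValueError("empty wordlist")
    scheme = scheme or sound_class_scheme()
    out: dict[str, dict[str, str]] = {}
    for concept in wordlist.concepts():
        forms = wordlist.by_concept(concept)
        graph = build_network(forms, scheme, threshold=threshold, mode=mode)
        mapping: dict[str, str] = {}
        for comp in components(graph, min_size=1):
            label = comp.members[0]
            for member in comp.members:
                mapping[member] = label
        out[concept] = mapping
    return out


def borrowing_candidates(graph: SimilarityGraph,
                         min_size: int = 1) -> list[BorrowingCall]:
    """Flag minority-family members of family-mixed components.

    A component is mixed iff it spans >= 2 families.  If one family holds at
    least 60 % of the members it is dominant and every other member is
    flagged; otherwise the mixture is unresolved and every member is flagged.
    """
    for node, data in graph.nodes(data=True):
        if not data.get("family"):
            raise ValueError(f"node {node!r} has no family label")
    calls: list[BorrowingCall] = []
    for comp in components(graph, min_size=min_size):
        if len(comp.family_counts) < 2:
            continue
        dominant, count = max(sorted(comp.family_counts.items()),
                              key=lambda kv: (kv[1], kv[0]))
        mixture = dict(sorted(comp.family_counts.items()))
        if count / comp.size >= DOMINANCE_CUTOFF:
            flagged = [m for m in comp.members
                       if graph.nodes[m]["family"] != dominant]
            dom: str | None = dominant
        else:
            flagged = list(comp.members)
            dom = None
        for member in flagged:
            calls.append(BorrowingCall(word_id=member,
                                       component_id=comp.members[0],
                                       family_mixture=mixture,
                                       dominant_family=dom))
    return calls


def _snap_breakpoint(point: int, boundaries: Sequence[int],
                     lo: int, hi: int) -> int:
    """Snap a raw breakpoint to the nearest morpheme boundary inside (lo, hi)."""
    inside = [bp for bp in boundaries if lo < bp < hi]
    if not inside:
        return point
    return min(inside, key=lambda bp: (abs(bp - point), bp))


def composite_candidates(wordlist: Wordlist,
                         scheme: ScoringScheme | None = None,
                         threshold: float = 0.45,
                         per_concept: bool = False,
                         max_overlap: int = 1) -> list[CompositeCall]:
    """Detect fused/compound words as articulation hubs with split support.

    A word is called composite iff it is an articulation vertex of its
    component and at least two of the neighbor groups created by its removal
    align (locally) to spans of the word that overlap by at most
    ``max_overlap`` tokens.  Breakpoints sit at the midpoint between adjacent
    group spans, snapped to a morpheme boundary when the word has one.
    The network is built in local mode (cross-concept by default, so that
    e.g. a compound can be supported by its free-standing parts).
    """
    scheme = scheme or sound_class_scheme()
    concepts = wordlist.concepts() if per_concept else [None]
    calls: list[CompositeCall] = []
    for concept in concepts:
        forms = wordlist.by_concept(concept) if concept else list(wordlist)
        if len(forms) < 2:
            continue
        by_id = {f.id: f for f in forms}
        graph = build_network(forms, scheme, threshold=threshold, mode="local")
        for comp in components(graph, min_size=3):
            for report in articulation_hubs(graph, comp):
                word = by_id[report.node]
                groups = [g for g in report.groups if g.hub_span is not None]
                if len(groups) < 2:
                    continue
                groups.sort(key=lambda g: g.hub_span)
                spans = [g.hub_span for g in groups]
                if any(spans[k + 1][0] < spans[k][1] - max_overlap
                       for k in range(len(spans) - 1)):
                    continue
                boundaries = [s for s, _ in word.morpheme_spans()[1:]]
                n_tokens = len(word.segments)
                breakpoints = []
                lo = 0
                for k in range(len(spans) - 1):
                    raw = (spans[k][1] + spans[k + 1][0]) // 2
                    bp = _snap_breakpoint(raw, boundaries, lo, n_tokens)
                    bp = max(lo + 1, min(bp, n_tokens - 1))
                    breakpoints.append(bp)
                    lo = bp
                breakpoints = sorted(set(breakpoints))
                cuts = [0] + breakpoints + [n_tokens]
                part_spans = tuple((cuts[k], cuts[k + 1])
                                   for k in range(len(cuts) - 1))
                if len(part_spans) < 2:
                    continue
                part_groups = tuple(g.members for g in groups[:len(part_spans)])
                calls.append(CompositeCall(word_id=word.id,
                                           breakpoints=tuple(breakpoints),
                                           part_spans=part_spans,
                                           part_groups=part_groups))
    calls.sort(key=lambda c: c.word_id)
    return calls


@dataclass(frozen=True)
class _MorphemeItem:
    """A single morpheme wrapped as a network item (attributes inherited)."""

    id: str
    form: str
    morphemes: tuple[tuple[str, ...], ...]
    doculect: str
    family: str | None
    concept: str

    @property
    def segments(self) -> tuple[str, ...]:
        return tuple(t for m in self.morphemes for t in m)


def partial_cognates(wordlist: Wordlist,
                     scheme: ScoringScheme | None = None,
                     threshold: float = PARTIAL_COGNACY_THRESHOLD,
                     per_concept: bool = False) -> PartialCognacyResult:
    """Morpheme-level cognate classes via a network over morphemes.

    Every morpheme becomes a node (attributes inherited from its word);
    connected components are morpheme cognate classes, labelled by the
    smallest contained (word id, slot) pair.  Words then carry one class id
    per morpheme slot, from which partial cognacy between any word pair can
    be read off (see :meth:`PartialCognacyResult.shared_slots`).
    """
    if not len(wordlist):
        raise ValueError("empty wordlist")
    scheme = scheme or sound_class_scheme()
    items: list[_MorphemeItem] = []
    for f in wordlist:
        for k, morpheme in enumerate(f.morphemes):
            items.append(_MorphemeItem(
                id=f"{f.id}:{k}", form=" ".join(morpheme),
                morphemes=(tuple(morpheme),), doculect=f.doculect,
                family=f.family, concept=f.concept))
    if per_concept:
        grouped: dict[str, list[_MorphemeItem]] = {}
        for it in items:
            grouped.setdefault(it.concept, []).append(it)
        batches = [grouped[c] for c in sorted(grouped)]
    else:
        batches = [items]
    labels: dict[str, str] = {}
    for batch in batches:
        graph = build_network(batch, scheme, threshold=threshold, mode="global")
        for comp in components(graph, min_size=1):
            label = comp.members[0]
            for member in comp.members:
                labels[member] = label
    classes: dict[str, tuple[str, ...]] = {}
    for f in wordlist:
        classes[f.id] = tuple(labels[f"{f.id}:{k}"]
                              for k in range(len(f.morphemes)))
    return PartialCognacyResult(classes=classes)
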