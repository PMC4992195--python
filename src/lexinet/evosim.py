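"""Forward simulator of lexical evolution along a dated tree, with ground truth.

Each concept evolves independently down the tree.  A lineage carries, per
concept, one or more synonymous word forms ("slots").  Continuous-time events
(Gillespie-style exponential waiting times) act on the native slots:

* sound substitution at a per-token rate, class-preserving with probability
  0.8 and class-changing otherwise, so cognates stay detectable under
  sound-class scoring at moderate depths;
* synonym birth (a brand-new root, i.e. a new etymon, joins the concept);
* synonym resolution (a polymorphic concept drops one of its words);
* lexical replacement (a word is swapped for a new etymon);
* compounding/derivation (a word gains a second part: a bound affix from a
  closed pool or the proto-form of another concept);
* borrowing (a coexisting lineage's word is copied verbatim and evolves on
  by substitution only, flagged with its donor).

Rapid divergence with unresolved synonym polymorphism produces the same
tree-discordant trait distributions as incomplete lineage sorting (ILS) in
biology; :func:`ils_discordance` quantifies that, and :func:`evaluate_calls`
scores detector output against the planted truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .lexio import WordForm, Wordlist

__all__ = [
    "SimParams",
    "GroundTruth",
    "EvalReport",
    "simulate",
    "make_rapid_divergence_tree",
    "ils_discordance",
    "evaluate_calls",
    "bcubed",
    "borrowing_rate_for_fraction",
    "random_baseline_f1",
    "assign_families",
]

_CONSONANTS = "p t s k m n r w j h b d z g f v l ʃ ŋ tʃ".split()
_VOWELS = "a e i o u ə".split()
_AFFIXES = [("h","e","t"), ("n","e","s"), ("k","a"), ("l","i","ŋ"), ("t","u","m")]

# class lookup reused from the scoring module so substitutions respect classes
from .align import SOUND_CLASSES

_POOL_BY_CLASS: dict[str, list[str]] = {}
for _t in _CONSONANTS + _VOWELS:
    _POOL_BY_CLASS.setdefault(SOUND_CLASSES[_t], []).append(_t)


@dataclass(frozen=True)
class SimParams:
    """Rates per unit branch length; ``seed`` fixes the whole run."""

    substitution_rate: float = 0.15   # per token
    class_preserving: float = 0.8
    synonym_birth: float = 0.3        # per concept
    synonym_resolution: float = 1.0   # per polymorphic concept
    replacement: float = 0.6          # per concept
    compounding: float = 0.0          # per concept
    borrowing: float = 0.0            # per concept per lineage
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "synonym_birth", "synonym_resolution",
                     "replacement", "compounding", "borrowing"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative rate {name}")
        if not 0.0 <= self.class_preserving <= 1.0:
            raise ValueError("class_preserving must lie in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    etymon: str
    morpheme_etyma: tuple[str, ...]
    borrowed: bool
    donor: str | None
    composite: bool


@dataclass
class GroundTruth:
    """Per-word truth plus the full replayable event log.

    ``events[(branch_id, concept)]`` lists ``(time, kind, info)`` tuples for
    native dynamics; ``borrowing_events`` lists every transfer with its donor.
    """

    words: dict[str, TruthRecord] = field(default_factory=dict)
    events: dict[tuple[str, str], list] = field(default_factory=dict)
    borrowing_events: list = field(default_factory=list)

    def borrowed_ids(self) -> set[str]:
        return {w for w, rec in self.words.items() if rec.borrowed}

    def composite_ids(self) -> set[str]:
        return {w for w, rec in self.words.items() if rec.composite}

    def cognate_partition(self) -> dict[str, str]:
        return {w: rec.etymon for w, rec in self.words.items()}


@dataclass(frozen=True)
class EvalReport:
    precision: float
    recall: float
    f1: float
    n_true: int
    n_called: int
    precision_defined: bool = True


# ---------------------------------------------------------------------------
# light internal tree

@dataclass
class _Node:
    id: str
    length: float
    parent: "_Node | None" = None
    children: list = field(default_factory=list)
    label: str | None = None
    start: float = 0.0  # absolute time at the top of the branch
    end: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _from_dendropy(tree) -> _Node:
    counter = [0]

    def conv(dnode, parent):
        node = _Node(id=f"n{counter[0]}",
                     length=float(dnode.edge.length or 0.0), parent=parent)
        counter[0] += 1
        if dnode.taxon is not None:
            node.label = dnode.taxon.label.replace(" ", "_")
        for child in dnode.child_nodes():
            node.children.append(conv(child, node))
        return node

    root = conv(tree.seed_node, None)

    def set_times(node, t0):
        node.start = t0
        node.end = t0 + node.length
        for ch in node.children:
            set_times(ch, node.end)

    set_times(root, 0.0)
    return root


def _walk(node: _Node):
    yield node
    for ch in node.children:
        yield from _walk(ch)


def _leaves(node: _Node) -> list[_Node]:
    return [n for n in _walk(node) if n.is_leaf]


def _coerce_tree(tree) -> _Node:
    if isinstance(tree, _Node):
        return tree
    if isinstance(tree, str):
        from .lexio import read_newick
        tree = read_newick(tree)
    return _from_dendropy(tree)


def make_rapid_divergence_tree(k: int, eps: float) -> str:
    """Balanced Newick tree: internal branches ``eps``, pendant branches 1.

    Small ``eps`` means splits follow each other faster than synonym
    polymorphisms resolve, the regime in which ILS-like discordance arises.
    """
    if k < 3:
        raise ValueError("need at least 3 tips")
    if eps <= 0:
        raise ValueError("eps must be positive")
    counter = [0]

    def build(n):
        if n == 1:
            counter[0] += 1
            return f"t{counter[0]}:1"
        left = build((n + 1) // 2)
        right = build(n // 2)
        return f"({left},{right}):{eps}"

    left = build((k + 1) // 2)
    right = build(k // 2)
    return f"({left},{right});"


def assign_families(tree, n_families: int = 4) -> dict[str, str]:
    """Cut the tree into ``n_families`` clades; returns tip label -> family."""
    root = _coerce_tree(tree)
    clades: list[_Node] = [root]
    while len(clades) < n_families:
        internal = [c for c in clades if not c.is_leaf]
        if not internal:
            break
        biggest = max(internal, key=lambda c: (len(_leaves(c)), c.id))
        clades.remove(biggest)
        clades.extend(biggest.children)
    clades.sort(key=lambda c: min(n.label or n.id for n in _leaves(c)))
    out = {}
    for idx, clade in enumerate(clades, start=1):
        for leaf in _leaves(clade):
            out[leaf.label or leaf.id] = f"F{idx}"
    return out


# ---------------------------------------------------------------------------
# randomness: one stream per (seed, purpose, branch, concept)

def _rng(seed: int, *key) -> np.random.Generator:
    digest = hashlib.sha256(("|".join([str(seed), *map(str, key)])).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big") % (2 ** 31))


def _new_root_form(rng) -> tuple[str, ...]:
    # disyllabic roots of 5-6 segments: with a single vowel class, shorter
    # (CV/CVCV) roots collide by chance far too often to resemble real lexica
    pattern = ["CVCVC", "CVCCVC", "CVCVCV"][rng.integers(0, 3)]
    toks = []
    for ch in pattern:
        pool = _CONSONANTS if ch == "C" else _VOWELS
        toks.append(pool[rng.integers(0, len(pool))])
    return tuple(toks)


def _substitute(tokens: tuple[str, ...], rng, class_preserving: float) -> tuple[str, ...]:
    pos = int(rng.integers(0, len(tokens)))
    tok = tokens[pos]
    cls = SOUND_CLASSES.get(tok)
    same = _POOL_BY_CLASS.get(cls, [])
    if cls is not None and rng.random() < class_preserving and len(same) > 1:
        choices = [t for t in same if t != tok]
    else:
        choices = [t for c, pool in sorted(_POOL_BY_CLASS.items()) if c != cls
                   for t in pool]
    new = choices[rng.integers(0, len(choices))]
    return tokens[:pos] + (new,) + tokens[pos + 1:]


@dataclass(frozen=True)
class _Slot:
    morphemes: tuple[tuple[str, ...], ...]
    morph_ids: tuple[str, ...]
    etymon: str
    borrowed: bool = False
    donor: str | None = None

    @property
    def n_tokens(self) -> int:
        return sum(len(m) for m in self.morphemes)

    def substituted(self, rng, p_keep) -> "_Slot":
        flat = tuple(t for m in self.morphemes for t in m)
        new = _substitute(flat, rng, p_keep)
        out, pos = [], 0
        for m in self.morphemes:
            out.append(tuple(new[pos:pos + len(m)]))
            pos += len(m)
        return replace(self, morphemes=tuple(out))


class _Simulator:
    def __init__(self, root: _Node, params: SimParams, concepts: list[str]):
        self.root = root
        self.p = params
        self.concepts = concepts
        self.branches = {n.id: n for n in _walk(root)}
        self.timelines: dict[tuple[str, str], list] = {}
        self.truth = GroundTruth()
        self._counters: dict[tuple[str, str], int] = {}

    # -- native dynamics -----------------------------------------------------

    def _fresh_etymon(self, branch: str, concept: str) -> str:
        key = (branch, concept)
        self._counters[key] = self._counters.get(key, 0) + 1
        return f"e:{branch}:{concept}:{self._counters[key]}"

    def _root_state(self, concept: str) -> list[_Slot]:
        rng = _rng(self.p.seed, "root", concept)
        ety = f"e:root:{concept}"
        return [_Slot(morphemes=(_new_root_form(rng),), morph_ids=(ety,),
                      etymon=ety)]

    def _proto_morpheme(self, concept: str, other: str) -> tuple[tuple[str, ...], str]:
        rng = _rng(self.p.seed, "root", other)
        return _new_root_form(rng), f"e:root:{other}"

    def native_timeline(self, node: _Node, concept: str) -> list:
        """Timeline [(abs_time, slots)] of native slots along this branch."""
        key = (node.id, concept)
        if key in self.timelines:
            return self.timelines[key]
        if node.parent is None:
            state = self._root_state(concept)
        else:
            state = list(self.native_timeline(node.parent, concept)[-1][1])
        rng = _rng(self.p.seed, "native", node.id, concept)
        timeline = [(node.start, tuple(state))]
        log = []
        p = self.p
        t = node.start
        while True:
            n_tok = sum(s.n_tokens for s in state)
            rates = {
                "substitution": p.substitution_rate * n_tok,
                "birth": p.synonym_birth,
                "resolution": p.synonym_resolution if len(state) > 1 else 0.0,
                "replacement": p.replacement if state else 0.0,
                "compound": p.compounding if state else 0.0,
            }
            total = sum(rates.values())
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= node.end:
                break
            u = rng.random() * total
            kind = None
            for name, rate in rates.items():
                if u < rate:
                    kind = name
                    break
                u -= rate
            if kind == "substitution":
                weights = np.array([s.n_tokens for s in state], dtype=float)
                idx = int(rng.choice(len(state), p=weights / weights.sum()))
                state[idx] = state[idx].substituted(rng, p.class_preserving)
            elif kind == "birth":
                ety = self._fresh_etymon(node.id, concept)
                state.append(_Slot(morphemes=(_new_root_form(rng),),
                                   morph_ids=(ety,), etymon=ety))
            elif kind == "resolution":
                idx = int(rng.integers(0, len(state)))
                state.pop(idx)
            elif kind == "replacement":
                idx = int(rng.integers(0, len(state)))
                ety = self._fresh_etymon(node.id, concept)
                state[idx] = _Slot(morphemes=(_new_root_form(rng),),
                                   morph_ids=(ety,), etymon=ety)
            else:  # compound
                idx = int(rng.integers(0, len(state)))
                base = state[idx]
                if rng.random() < 0.5 or len(self.concepts) < 2:
                    aff = _AFFIXES[rng.integers(0, len(_AFFIXES))]
                    part, part_id = tuple(aff), f"affix:{'-'.join(aff)}"
                else:
                    others = [c for c in self.concepts if c != concept]
                    other = others[rng.integers(0, len(others))]
                    part, part_id = self._proto_morpheme(concept, other)
                ety = self._fresh_etymon(node.id, concept)
                state.append(_Slot(morphemes=base.morphemes + (part,),
                                   morph_ids=base.morph_ids + (part_id,),
                                   etymon=ety))
            log.append((t, kind, len(state)))
            timeline.append((t, tuple(state)))
        self.timelines[key] = timeline
        self.truth.events[key] = log
        return timeline

    def native_state_at(self, node: _Node, concept: str, t: float) -> tuple[_Slot, ...]:
        timeline = self.native_timeline(node, concept)
        state = timeline[0][1]
        for time, snap in timeline:
            if time <= t:
                state = snap
            else:
                break
        return state

    # -- borrowing -----------------------------------------------------------

    def _alive_at(self, t: float) -> list[_Node]:
        return [n for n in _walk(self.root) if n.start <= t < n.end]

    def borrowings_on(self, node: _Node, concept: str) -> list[tuple[float, _Slot]]:
        """New borrowed slots created on this branch (time, slot)."""
        if self.p.borrowing <= 0:
            return []
        rng = _rng(self.p.seed, "borrow", node.id, concept)
        n_events = rng.poisson(self.p.borrowing * node.length)
        out = []
        for _ in range(n_events):
            t = node.start + rng.random() * node.length
            donors = sorted((d for d in self._alive_at(t) if d.id != node.id),
                            key=lambda d: d.id)
            if not donors:
                continue
            donor = donors[rng.integers(0, len(donors))]
            dstate = self.native_state_at(donor, concept, t)
            if not dstate:
                continue
            src = dstate[rng.integers(0, len(dstate))]
            slot = replace(src, borrowed=True, donor=donor.id)
            out.append((t, slot))
            self.truth.borrowing_events.append(
                {"time": t, "recipient": node.id, "donor": donor.id,
                 "concept": concept, "etymon": src.etymon})
        out.sort(key=lambda pair: pair[0])
        return out

    def _substitute_only(self, slot: _Slot, rng, duration: float) -> _Slot:
        n = rng.poisson(self.p.substitution_rate * slot.n_tokens * duration)
        for _ in range(n):
            slot = slot.substituted(rng, self.p.class_preserving)
        return slot

    # -- emission ------------------------------------------------------------

    def run(self, families: Mapping[str, str] | None) -> Wordlist:
        forms: list[WordForm] = []
        for concept in self.concepts:
            self._emit(self.root, concept, [], forms, families)
        return Wordlist(forms=forms)

    def _emit(self, node: _Node, concept: str, inherited: list[tuple[str, _Slot]],
              forms: list[WordForm], families) -> None:
        # inherited borrowed slots substitute along this whole branch;
        # new ones only from their creation time onward
        rng_b = _rng(self.p.seed, "bsub", node.id, concept)
        borrowed: list[tuple[str, _Slot]] = []
        for uid, slot in inherited:
            borrowed.append((uid, self._substitute_only(slot, rng_b, node.length)))
        for k, (t, slot) in enumerate(self.borrowings_on(node, concept)):
            uid = f"b:{node.id}:{concept}:{k}"
            borrowed.append((uid, self._substitute_only(slot, rng_b, node.end - t)))
        if node.is_leaf:
            tip = node.label or node.id
            native = self.native_timeline(node, concept)[-1][1]
            slots = list(native) + [s for _, s in borrowed]
            for k, slot in enumerate(slots):
                wid = f"{tip}-{concept}-{k}"
                fam = families.get(tip) if families else None
                forms.append(WordForm(
                    id=wid, doculect=tip, concept=concept,
                    form="".join(t for m in slot.morphemes for t in m),
                    morphemes=slot.morphemes, family=fam,
                    cogid=slot.etymon, borrowed=slot.borrowed,
                    morpheme_ids=slot.morph_ids))
                self.truth.words[wid] = TruthRecord(
                    etymon=slot.etymon, morpheme_etyma=slot.morph_ids,
                    borrowed=slot.borrowed, donor=slot.donor,
                    composite=len(slot.morphemes) > 1)
        else:
            for child in node.children:
                self._emit(child, concept, list(borrowed), forms, families)


def simulate(tree, params: SimParams, n_concepts: int = 100,
             n_families: int | None = None) -> tuple[Wordlist, GroundTruth]:
    """Simulate a wordlist with ground truth along ``tree``.

    ``tree`` may be a Newick string/path or a dendropy tree; branch lengths
    are required and must sum to a positive total.  Deterministic under
    ``params.seed``.  When ``n_families`` is given, tips are grouped into
    that many clade-based families (FAMILY column).
    """
    if n_concepts < 1:
        raise ValueError("need at least one concept")
    root = _coerce_tree(tree)
    if sum(n.length for n in _walk(root)) <= 0:
        raise ValueError("zero-length tree")
    concepts = [f"c{idx:03d}" for idx in range(n_concepts)]
    sim = _Simulator(root, params, concepts)
    families = assign_families(root, n_families) if n_families else None
    wordlist = sim.run(families)
    return wordlist, sim.truth


# ---------------------------------------------------------------------------
# ILS discordance

def ils_discordance(wordlist: Wordlist, truth: GroundTruth, tree) -> float:
    """Fraction of multi-tip cognate sets that are not convex on the tree.

    A cognate set is convex when the tips carrying it are exactly the leaves
    of one clade (monophyly); non-convex sets look like they contradict
    tree-like divergence.  Only defined when no borrowing occurred, so the
    discordance is introgression-free.
    """
    if truth.borrowed_ids():
        raise ValueError("borrowing events present; discordance is not "
                         "introgression-free")
    root = _coerce_tree(tree)
    clade_leafsets = set()
    for node in _walk(root):
        clade_leafsets.add(frozenset(l.label or l.id for l in _leaves(node)))
    by_etymon: dict[str, set[str]] = {}
    for f in wordlist:
        by_etymon.setdefault(f.cogid, set()).add(f.doculect)
    multi = [tips for tips in by_etymon.values() if len(tips) >= 2]
    if not multi:
        return 0.0
    bad = sum(frozenset(tips) not in clade_leafsets for tips in multi)
    return bad / len(multi)


# ---------------------------------------------------------------------------
# evaluation

def _binary_report(true_ids: set[str], called_ids: set[str]) -> EvalReport:
    tp = len(true_ids & called_ids)
    if called_ids:
        precision, defined = tp / len(called_ids), True
    else:
        precision, defined = 0.0, False  # undefined precision reported as 0
    recall = tp / len(true_ids) if true_ids else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return EvalReport(precision=precision, recall=recall, f1=f1,
                      n_true=len(true_ids), n_called=len(called_ids),
                      precision_defined=defined)


def bcubed(truth: Mapping[str, str], pred: Mapping[str, str]) -> tuple[float, float, float]:
    """B-cubed precision/recall/F for two partitions over the same items."""
    items = sorted(truth)
    if set(items) != set(pred):
        raise ValueError("partitions cover different items")
    by_true: dict[str, set[str]] = {}
    by_pred: dict[str, set[str]] = {}
    for it in items:
        by_true.setdefault(truth[it], set()).add(it)
        by_pred.setdefault(pred[it], set()).add(it)
    p_sum = r_sum = 0.0
    for it in items:
        same_pred = by_pred[pred[it]]
        same_true = by_true[truth[it]]
        correct = len(same_pred & same_true)
        p_sum += correct / len(same_pred)
        r_sum += correct / len(same_true)
    p, r = p_sum / len(items), r_sum / len(items)
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f


def evaluate_calls(truth: GroundTruth, calls, kind: str) -> EvalReport:
    """Score detector output against the planted truth.

    ``kind`` is one of ``borrowing``, ``composite`` (binary classification
    over word ids) or ``cognates`` (a word id -> class partition scored by
    B-cubed; the F row is carried in the report's f1 field).
    """
    if kind == "borrowing":
        called = {c.word_id for c in calls}
        _check_ids(truth, called)
        return _binary_report(truth.borrowed_ids(), called)
    if kind == "composite":
        called = {c.word_id for c in calls}
        _check_ids(truth, called)
        return _binary_report(truth.composite_ids(), called)
    if kind == "cognates":
        pred = dict(calls)
        _check_ids(truth, set(pred))
        p, r, f = bcubed(truth.cognate_partition(), pred)
        return EvalReport(precision=p, recall=r, f1=f,
                          n_true=len(set(truth.cognate_partition().values())),
                          n_called=len(set(pred.values())))
    raise ValueError(f"unknown call kind {kind!r}")


def _check_ids(truth: GroundTruth, ids: set[str]) -> None:
    unknown = ids - set(truth.words)
    if unknown:
        raise ValueError(f"calls reference unknown word ids: {sorted(unknown)[:5]}")


def borrowing_rate_for_fraction(tree, fraction: float,
                                native_slots_per_tip: float = 1.0) -> float:
    """Borrowing rate making ~``fraction`` of tip words borrowed in expectation.

    Every borrowing event on a root-to-tip path leaves one borrowed slot at
    the tip, so the expected borrowed count per tip per concept is the rate
    times the mean root-to-tip path length L, and
    ``fraction = bL / (bL + native)`` solves to
    ``b = fraction * native / ((1 - fraction) * L)``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    root = _coerce_tree(tree)
    depths = [leaf.end for leaf in _leaves(root)]
    mean_depth = sum(depths) / len(depths)
    return fraction * native_slots_per_tip / ((1 - fraction) * mean_depth)


def random_baseline_f1(prevalence: float, call_rate: float) -> float:
    """Expected F1 of a random classifier flagging items at ``call_rate``.

    Expected precision equals the prevalence, expected recall the call rate,
    so F1 -> 2 p q / (p + q).
    """
    if prevalence + call_rate == 0:
        return 0.0
    return 2 * prevalence * call_rate / (prevalence + call_rate)
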