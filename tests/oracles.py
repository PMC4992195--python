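"""Independent brute-force oracles used by the test suite.

The alignment oracle enumerates every monotone chain of matched token-index
pairs directly (no dynamic programming, no traceback): for linear gap costs
the score of an alignment is fully determined by its chain, so the optimum
over all chains is the optimum over all alignments.  The tree oracle checks
cognate-set convexity by enumerating clades with dendropy, independently of
the simulator's internal tree representation.
"""

from __future__ import annotations

import itertools

import dendropy


def _chains(n: int, m: int):
    """All strictly increasing chains of (i, j) index pairs (incl. empty)."""

    def rec(si, sj):
        yield ()
        for i in range(si, n):
            for j in range(sj, m):
                for rest in rec(i + 1, j + 1):
                    yield ((i, j),) + rest

    yield from rec(0, 0)


def brute_global(a, b, scheme) -> float:
    """Optimal global score by chain enumeration (linear gaps only)."""
    assert scheme.gap_open == scheme.gap_extend, "oracle assumes linear gaps"
    gap = scheme.gap_open
    n, m = len(a), len(b)
    best = gap * (n + m)  # empty chain: everything gapped
    for chain in _chains(n, m):
        if not chain:
            continue
        k = len(chain)
        s = sum(scheme.score(a[i], b[j]) for i, j in chain) + gap * (n + m - 2 * k)
        best = max(best, s)
    return best


def brute_global_chains(a, b, scheme):
    """All chains (as pair sets) achieving the optimal global score."""
    gap = scheme.gap_open
    n, m = len(a), len(b)
    scored = []
    for chain in _chains(n, m):
        k = len(chain)
        s = sum(scheme.score(a[i], b[j]) for i, j in chain) + gap * (n + m - 2 * k)
        scored.append((s, frozenset(chain)))
    best = max(s for s, _ in scored)
    return best, {c for s, c in scored if s == best}


def brute_local(a, b, scheme) -> float:
    """Optimal local score: best window-confined chain, clamped at zero."""
    assert scheme.gap_open == scheme.gap_extend, "oracle assumes linear gaps"
    gap = scheme.gap_open
    best = 0.0
    for chain in _chains(len(a), len(b)):
        if not chain:
            continue
        k = len(chain)
        (i0, j0), (i1, j1) = chain[0], chain[-1]
        span_cost = gap * ((i1 - i0 + 1 - k) + (j1 - j0 + 1 - k))
        s = sum(scheme.score(a[i], b[j]) for i, j in chain) + span_cost
        best = max(best, s)
    return best


def brute_local_optima(a, b, scheme):
    """Best local score plus all optimal (chain, span_a, span_b) triples."""
    gap = scheme.gap_open
    scored = []
    for chain in _chains(len(a), len(b)):
        if not chain:
            continue
        k = len(chain)
        (i0, j0), (i1, j1) = chain[0], chain[-1]
        s = (sum(scheme.score(a[i], b[j]) for i, j in chain)
             + gap * ((i1 - i0 + 1 - k) + (j1 - j0 + 1 - k)))
        scored.append((s, frozenset(chain), (i0, i1 + 1), (j0, j1 + 1)))
    best = max((s for s, *_ in scored), default=0.0)
    if best <= 0.0:
        return 0.0, set()
    return best, {(c, sa, sb) for s, c, sa, sb in scored if s == best}


def convex_on_tree(newick: str, tips: set[str]) -> bool:
    """True iff ``tips`` is exactly the leaf set of one clade (monophyly).

    Enumerates every internal node's leaf set with dendropy -- an exhaustive
    subtree check independent of the simulator's tree code.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for node in tree.preorder_node_iter():
        leafset = {leaf.taxon.label.replace(" ", "_")
                   for leaf in node.leaf_iter()}
        if leafset == tips:
            return True
    return False
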