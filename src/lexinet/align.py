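"""Pairwise global/local alignment over token sequences with pluggable scoring.

Words are aligned as sequences of sound-class-mapped segment tokens; the same
dynamic-programming core handles biological residues when the scheme maps
residues to themselves.  The linguistic default scheme uses Dolgopolsky-style
consonant classes, a single vowel class and a down-weighted tone track, so
that regular sound change within a class (e.g. [s] > [z], [j] > [y]) still
counts as a match while cross-type correspondences are penalized.

Distances are length-normalized:  ``d = 1 - 2 S(a,b) / (S(a,a) + S(b,b))``,
clamped to [0, 1], which makes thresholds comparable across word lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "sound_class_scheme",
    "dna_scheme",
    "protein_scheme",
    "global_align",
    "local_align",
    "normalized_distance",
    "format_alignment",
]

GAP = "-"
WILDCARD = "?"

# ---------------------------------------------------------------------------
# shipped sound-class table: ~10 consonant classes + vowels + tones (digits)

_CLASS_MEMBERS = {
    "P": "p b f v ɸ β pʰ bʱ",
    "T": "t d θ ð ʈ ɖ tʰ dʱ",
    "S": "s z ʃ ʒ ś š ž ts dz tʃ dʒ tɕ dʑ ɕ ʑ c č ç",
    "K": "k g q ɢ x ɣ χ ʁ kʰ gʱ",
    "M": "m ɱ",
    "N": "n ɲ ŋ ɳ ȵ",
    "R": "r l ɾ ʀ ɫ ɬ ʎ ɭ ř ł",
    "W": "w ʋ ʍ",
    "J": "j y ɥ",
    "H": "h ɦ ʔ ħ ʕ",
    "V": ("a e i o u ə ɛ ɔ æ ø œ ɨ ʉ ɯ ɐ ʌ ʊ ɪ ʏ ɑ ɒ ã ẽ ĩ õ ũ "
          "á à ǎ â ä å ā ă é è ě ê ë ē í ì ǐ î ï ī ó ò ǒ ô ö ō "
          "ú ù ǔ û ü ū ý ə̃ ɛ̃ ɔ̃ ɑ̃"),
}

SOUND_CLASSES: dict[str, str] = {}
for _cls, _members in _CLASS_MEMBERS.items():
    for _tok in _members.split():
        SOUND_CLASSES[_tok] = _cls
for _d in "0123456789":
    SOUND_CLASSES[_d] = _d  # every tone digit is its own class on the tone track

_CLASS_TYPE = {cls: "consonant" for cls in _CLASS_MEMBERS if cls != "V"}
_CLASS_TYPE["V"] = "vowel"
for _d in "0123456789":
    _CLASS_TYPE[_d] = "tone"
_CLASS_TYPE[WILDCARD] = "other"


@dataclass(frozen=True)
class ScoringScheme:
    """Token -> class mapping plus the class-pair scores and gap penalties.

    ``gap_open`` is charged for the first gap position of a run and
    ``gap_extend`` for each further position; equal values give linear gaps.
    ``tone_weight`` multiplies every column score involving a tone class.
    Unknown tokens fall back to the wildcard class (weak self-match +1,
    mismatch -1 against everything else).
    """

    class_map: Mapping[str, str]
    class_type: Mapping[str, str]
    match: float = 2.0
    mismatch_same_type: float = -1.0
    mismatch_cross_type: float = -2.0
    gap_open: float = -1.0
    gap_extend: float = -1.0
    tone_weight: float = 0.5
    wildcard: str = WILDCARD
    pair_table: Mapping[tuple[str, str], float] | None = None
    name: str = "sca"

    def token_class(self, token: str) -> str:
        return self.class_map.get(token, self.class_map.get(token.lower(), self.wildcard))

    def score(self, a: str, b: str) -> float:
        """Column score for two (non-gap) tokens."""
        ca, cb = self.token_class(a), self.token_class(b)
        if self.pair_table is not None:
            key = (ca, cb) if (ca, cb) in self.pair_table else (cb, ca)
            return self.pair_table.get(key, self.mismatch_same_type)
        if ca == self.wildcard or cb == self.wildcard:
            return 1.0 if ca == cb else -1.0
        ta = self.class_type.get(ca, "other")
        tb = self.class_type.get(cb, "other")
        if ca == cb:
            raw = self.match
        elif ta == tb:
            raw = self.mismatch_same_type
        else:
            raw = self.mismatch_cross_type
        if ta == "tone" or tb == "tone":
            raw *= self.tone_weight
        return raw

    def self_score(self, seq: Sequence[str]) -> float:
        return sum(self.score(t, t) for t in seq)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize the token -> class table as a two-column TSV."""
        lines = ["TOKEN\tCLASS"]
        lines += [f"{tok}\t{cls}" for tok, cls in sorted(self.class_map.items())]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "ScoringScheme":
        class_map = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines()[1:]:
            if not line.strip():
                continue
            tok, c = line.split("\t")
            class_map[tok] = c
        types = dict(_CLASS_TYPE)
        for c in class_map.values():
            types.setdefault(c, "consonant")
        return cls(class_map=class_map, class_type=types, **kwargs)


def sound_class_scheme() -> ScoringScheme:
    """The shipped linguistic default (Dolgopolsky-style classes)."""
    return ScoringScheme(class_map=dict(SOUND_CLASSES), class_type=dict(_CLASS_TYPE))


def dna_scheme() -> ScoringScheme:
    """Identity scoring over nucleotides (match +2, mismatch -1, gap -1)."""
    bases = "ACGTU"
    cmap = {b: b for b in bases}
    cmap.update({b.lower(): b for b in bases})
    ctype = {b: "nucleotide" for b in bases}
    ctype[WILDCARD] = "other"
    return ScoringScheme(class_map=cmap, class_type=ctype, tone_weight=1.0,
                         name="dna")


def protein_scheme(gap_open: float = -8.0, gap_extend: float = -2.0) -> ScoringScheme:
    """BLOSUM62 scoring over amino acids with affine gaps."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    aas = [a for a in blosum.alphabet if a.isalpha()]
    cmap = {a: a for a in aas}
    cmap.update({a.lower(): a for a in aas})
    ctype = {a: "residue" for a in aas}
    ctype[WILDCARD] = "other"
    table = {(a, b): float(blosum[a][b]) for a in aas for b in aas}
    return ScoringScheme(class_map=cmap, class_type=ctype, pair_table=table,
                         gap_open=gap_open, gap_extend=gap_extend,
                         tone_weight=1.0, name="blosum62")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped rows plus score and aligned spans.

    Spans are half-open [start, end) token indices into the *ungapped*
    sequences; in global mode they cover the full sequences.  No column is
    gap-gap, and removing gaps from a row reproduces the spanned
    sub-sequence.
    """

    row_a: tuple[str, ...]
    row_b: tuple[str, ...]
    mode: str  # "global" | "local"
    score: float
    span_a: tuple[int, int]
    span_b: tuple[int, int]

    def matched_pairs(self) -> frozenset[tuple[int, int]]:
        """Set of (i, j) ungapped token-index pairs aligned in one column."""
        pairs, i, j = [], self.span_a[0], self.span_b[0]
        for a, b in zip(self.row_a, self.row_b):
            if a != GAP and b != GAP:
                pairs.append((i, j))
            if a != GAP:
                i += 1
            if b != GAP:
                j += 1
        return frozenset(pairs)


# DP states: "M" = diagonal (match/mismatch), "X" = gap in b (a consumed),
# "Y" = gap in a (b consumed).  The traceback tie order (diagonal, gap-in-b,
# gap-in-a) is fixed at fill time via the ordering of the candidate lists.

_NEG = float("-inf")


def _fill(a, b, scheme, local):
    n, m = len(a), len(b)
    go, ge = scheme.gap_open, scheme.gap_extend
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    # pM[i][j]: predecessor state at (i-1, j-1); None = path starts here
    pM = [[None] * (m + 1) for _ in range(n + 1)]
    pX = [[None] * (m + 1) for _ in range(n + 1)]
    pY = [[None] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + ge * (i - 1)
        pX[i][0] = "M" if i == 1 else "X"
    for j in range(1, m + 1):
        Y[0][j] = go + ge * (j - 1)
        pY[0][j] = "M" if j == 1 else "Y"
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = scheme.score(ai, b[j - 1])
            # diagonal
            best, src = _NEG, None
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                v = mat[i - 1][j - 1]
                if v > best:
                    best, src = v, st
            if local and best < 0.0:
                best, src = 0.0, None
            if local and best == 0.0:
                src = None
            M[i][j] = best + s
            pM[i][j] = src
            if local and M[i][j] < 0.0:
                M[i][j] = 0.0
                pM[i][j] = None
            # gap in b (consume a)
            best, src = _NEG, None
            for st, mat, pen in (("M", M, go), ("X", X, ge), ("Y", Y, go)):
                v = mat[i - 1][j] + pen
                if v > best:
                    best, src = v, st
            X[i][j] = best
            pX[i][j] = src
            # gap in a (consume b)
            best, src = _NEG, None
            for st, mat, pen in (("M", M, go), ("X", X, go), ("Y", Y, ge)):
                v = mat[i][j - 1] + pen
                if v > best:
                    best, src = v, st
            Y[i][j] = best
            pY[i][j] = src
    return (M, X, Y), (pM, pX, pY)


def _traceback(a, b, mats, ptrs, i, j, state):
    M, X, Y = mats
    pM, pX, pY = ptrs
    row_a: list[str] = []
    row_b: list[str] = []
    while state is not None and (i > 0 or j > 0):
        if state == "M":
            if i == 0 and j == 0:
                break
            row_a.append(a[i - 1])
            row_b.append(b[j - 1])
            state = pM[i][j]
            i, j = i - 1, j - 1
        elif state == "X":
            row_a.append(a[i - 1])
            row_b.append(GAP)
            state = pX[i][j]
            i -= 1
        else:
            row_a.append(GAP)
            row_b.append(b[j - 1])
            state = pY[i][j]
            j -= 1
    row_a.reverse()
    row_b.reverse()
    return tuple(row_a), tuple(row_b), i, j


def global_align(a: Sequence[str], b: Sequence[str],
                 scheme: ScoringScheme) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch / Gotoh) alignment.

    Deterministic traceback, ties broken diagonal > gap-in-b > gap-in-a.
    Either sequence may be empty (all-gap result).
    """
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return PairwiseAlignment((), (), "global", 0.0, (0, 0), (0, 0))
    mats, ptrs = _fill(a, b, scheme, local=False)
    M, X, Y = mats
    score, state = _NEG, "M"
    for st, mat in (("M", M), ("X", X), ("Y", Y)):
        if mat[n][m] > score:
            score, state = mat[n][m], st
    row_a, row_b, _, _ = _traceback(a, b, mats, ptrs, n, m, state)
    return PairwiseAlignment(row_a, row_b, "global", score, (0, n), (0, m))


def local_align(a: Sequence[str], b: Sequence[str],
                scheme: ScoringScheme) -> PairwiseAlignment:
    """Optimal local (Smith–Waterman) alignment, clamped at zero.

    Returns an empty alignment with score 0 when no positive-scoring window
    exists.  Of co-optimal end cells the one with smallest (i, j) is used.
    """
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    mats, ptrs = _fill(a, b, scheme, local=True)
    M = mats[0]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j
    if best <= 0.0:
        return PairwiseAlignment((), (), "local", 0.0, (0, 0), (0, 0))
    row_a, row_b, si, sj = _traceback(a, b, mats, ptrs, bi, bj, "M")
    return PairwiseAlignment(row_a, row_b, "local", best, (si, bi), (sj, bj))


def normalized_distance(a: Sequence[str], b: Sequence[str],
                        scheme: ScoringScheme, mode: str = "global") -> float:
    """Length-normalized distance in [0, 1]; 0 for identical sequences."""
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    sa, sb = scheme.self_score(a), scheme.self_score(b)
    if sa + sb <= 0:
        raise ValueError("degenerate scheme: zero or negative self scores")
    aln = global_align(a, b, scheme) if mode == "global" else local_align(a, b, scheme)
    d = 1.0 - 2.0 * aln.score / (sa + sb)
    return min(1.0, max(0.0, d))


def format_alignment(aln: PairwiseAlignment) -> str:
    """Column-aligned plain-text rendering, '-' for gaps."""
    widths = [max(len(x), len(y)) for x, y in zip(aln.row_a, aln.row_b)]
    top = " ".join(t.ljust(w) for t, w in zip(aln.row_a, widths))
    bot = " ".join(t.ljust(w) for t, w in zip(aln.row_b, widths))
    return f"{top}\n{bot}\n({aln.mode} score {aln.score:g})"
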