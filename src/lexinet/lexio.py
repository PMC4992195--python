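"""Data model, tokenization and file I/O for wordlists, FASTA, GML and Newick.

The central container is the :class:`Wordlist`: a flat table of attested word
forms, one per row, each tied to a doculect (documented language variety), a
concept (gloss) and a segmented phonetic form.  Words are modeled as sequences
of sound segments grouped into morphemes; tone digits are ordinary segment
tokens at the end of a morpheme, which lets tonal material take part in
alignments the same way segmental material does.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "RowError",
    "WordForm",
    "Wordlist",
    "SequenceRecord",
    "tokenize",
    "read_wordlist",
    "write_wordlist",
    "read_fasta",
    "write_gml",
    "read_gml",
    "read_newick",
]

BOUNDARY = "+"

REQUIRED_COLUMNS = ("ID", "DOCULECT", "CONCEPT", "FORM")
OPTIONAL_COLUMNS = ("TOKENS", "FAMILY", "COGID", "BORROWED", "MORPHEMES")
COLUMN_ORDER = ("ID", "DOCULECT", "FAMILY", "CONCEPT", "FORM", "TOKENS",
                "COGID", "BORROWED", "MORPHEMES")


class FormatError(ValueError):
    """Malformed input file (missing column, duplicate id, empty file...)."""


class RowError(ValueError):
    """A single malformed row; the message carries the 1-based row number."""


@dataclass(frozen=True)
class WordForm:
    """One attested word form.

    ``morphemes`` is an ordered list of morphemes, each an ordered, non-empty
    list of segment tokens.  Tone digits are separate tokens at morpheme end.
    """

    id: str
    doculect: str
    concept: str
    form: str
    morphemes: tuple[tuple[str, ...], ...]
    family: str | None = None
    cogid: str | None = None
    borrowed: bool = False
    morpheme_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.morphemes or any(not m for m in self.morphemes):
            raise ValueError(f"word {self.id!r}: morphemes must be non-empty")
        if any(not t for m in self.morphemes for t in m):
            raise ValueError(f"word {self.id!r}: empty segment token")

    @property
    def segments(self) -> tuple[str, ...]:
        """All segment tokens, morpheme boundaries removed."""
        return tuple(t for m in self.morphemes for t in m)

    @property
    def tokens_text(self) -> str:
        """Serialization used in the TOKENS column: ``l i ǎ n + m i á n``."""
        return f" {BOUNDARY} ".join(" ".join(m) for m in self.morphemes)

    def morpheme_spans(self) -> list[tuple[int, int]]:
        """Half-open [start, end) token spans of each morpheme in ``segments``."""
        spans, pos = [], 0
        for m in self.morphemes:
            spans.append((pos, pos + len(m)))
            pos += len(m)
        return spans


@dataclass
class Wordlist:
    """Collection of word forms plus the doculect -> family table."""

    forms: list[WordForm] = field(default_factory=list)
    doculects: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.forms:
            if f.id in seen:
                raise FormatError(f"duplicate ID {f.id!r}")
            seen.add(f.id)
            self.doculects.setdefault(f.doculect, f.family)

    def __len__(self) -> int:
        return len(self.forms)

    def __iter__(self) -> Iterator[WordForm]:
        return iter(self.forms)

    def __getitem__(self, word_id: str) -> WordForm:
        for f in self.forms:
            if f.id == word_id:
                return f
        raise KeyError(word_id)

    def concepts(self) -> list[str]:
        return sorted({f.concept for f in self.forms})

    def by_concept(self, concept: str) -> list[WordForm]:
        return [f for f in self.forms if f.concept == concept]


@dataclass(frozen=True)
class SequenceRecord:
    """A biological sequence processed through the same network machinery."""

    id: str
    residues: tuple[str, ...]
    alphabet: str  # "nucleotide" | "amino-acid"

    @property
    def segments(self) -> tuple[str, ...]:
        return self.residues

    @property
    def morphemes(self) -> tuple[tuple[str, ...], ...]:
        return (self.residues,)


def _nfc(text: str) -> str:
    return unicodedata.normalize("NFC", text)


def _is_combining(ch: str) -> bool:
    return unicodedata.combining(ch) != 0 or unicodedata.category(ch) in ("Mn", "Mc")


def tokenize(form: str, profile: Mapping[str, str] | None = None) -> list[list[str]]:
    """Segment an orthographic/IPA string into morphemes of tokens.

    Grapheme clusters (base character plus combining marks) become single
    tokens; digits become separate tone tokens appended to the current
    morpheme; whitespace and hyphens introduce morpheme boundaries.  A profile
    table may map multi-character digraphs (longest match first) to one token.
    """
    if not form:
        raise ValueError("empty form")
    form = _nfc(form)
    profile = dict(profile or {})
    keys = sorted(profile, key=len, reverse=True)

    morphemes: list[list[str]] = [[]]
    i = 0
    while i < len(form):
        ch = form[i]
        if ch in "-+" or ch.isspace():
            if morphemes[-1]:
                morphemes.append([])
            i += 1
            continue
        matched = False
        for key in keys:
            if form.startswith(key, i):
                morphemes[-1].append(profile[key])
                i += len(key)
                matched = True
                break
        if matched:
            continue
        if ch.isdigit():
            morphemes[-1].append(ch)
            i += 1
            continue
        j = i + 1
        while j < len(form) and _is_combining(form[j]):
            j += 1
        morphemes[-1].append(form[i:j])
        i = j
    if not morphemes[-1]:
        morphemes.pop()
    if not morphemes:
        raise ValueError(f"form {form!r} yields no tokens")
    return morphemes


def parse_tokens(text: str) -> tuple[tuple[str, ...], ...]:
    """Parse a TOKENS cell: space-separated tokens, ``+``/``-`` as boundaries."""
    morphemes: list[list[str]] = [[]]
    for tok in _nfc(text).split(" "):
        if not tok:
            continue
        if tok in ("+", "-"):
            if morphemes[-1]:
                morphemes.append([])
            continue
        morphemes[-1].append(tok)
    if not morphemes[-1]:
        morphemes.pop()
    return tuple(tuple(m) for m in morphemes)


def read_wordlist(path: str | Path, profile: Mapping[str, str] | None = None) -> Wordlist:
    """Read a UTF-8 TSV wordlist.

    Required columns: ID, DOCULECT, CONCEPT, FORM.  Optional: TOKENS, FAMILY,
    COGID, BORROWED, MORPHEMES.  ``#``-prefixed lines are comments.  When
    TOKENS is absent, :func:`tokenize` is applied to FORM.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                        keep_default_na=False, encoding="utf-8")
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"missing required column {col}")
    have = set(table.columns)
    forms: list[WordForm] = []
    seen: set[str] = set()
    for idx, row in enumerate(table.itertuples(index=False), start=1):
        rec = dict(zip(table.columns, row))
        wid = _nfc(rec["ID"]).strip()
        if wid in seen:
            raise FormatError(f"duplicate ID {wid!r}")
        seen.add(wid)
        form = _nfc(rec["FORM"]).strip()
        if not form:
            raise RowError(f"row {idx}: empty FORM")
        if "TOKENS" in have and rec["TOKENS"].strip():
            morphemes = parse_tokens(rec["TOKENS"])
        else:
            morphemes = tuple(tuple(m) for m in tokenize(form, profile))
        family = _nfc(rec["FAMILY"]).strip() or None if "FAMILY" in have else None
        cogid = rec["COGID"].strip() or None if "COGID" in have else None
        borrowed = (rec["BORROWED"].strip() not in ("", "0", "false", "False")
                    if "BORROWED" in have else False)
        mids = None
        if "MORPHEMES" in have and rec["MORPHEMES"].strip():
            mids = tuple(rec["MORPHEMES"].split())
        forms.append(WordForm(id=wid, doculect=_nfc(rec["DOCULECT"]).strip(),
                              concept=_nfc(rec["CONCEPT"]).strip(), form=form,
                              morphemes=morphemes, family=family, cogid=cogid,
                              borrowed=borrowed, morpheme_ids=mids))
    return Wordlist(forms=forms)


def write_wordlist(wordlist: Wordlist, path: str | Path) -> None:
    rows = []
    for f in wordlist:
        rows.append({
            "ID": f.id, "DOCULECT": f.doculect, "FAMILY": f.family or "",
            "CONCEPT": f.concept, "FORM": f.form, "TOKENS": f.tokens_text,
            "COGID": f.cogid or "", "BORROWED": "1" if f.borrowed else "0",
            "MORPHEMES": " ".join(f.morpheme_ids) if f.morpheme_ids else "",
        })
    pd.DataFrame(rows, columns=list(COLUMN_ORDER)).to_csv(
        path, sep="\t", index=False, encoding="utf-8")


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read FASTA records; the alphabet is auto-detected unless given.

    Detection rule: a majority of A/C/G/T/U/N/- residues means nucleotide,
    anything else amino acid.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate ids {rec.id!r}")
        seen.add(rec.id)
        residues = tuple(str(rec.seq).upper())
        if alphabet is None:
            nuc = sum(r in "ACGTUN-" for r in residues)
            kind = "nucleotide" if residues and nuc / len(residues) > 0.5 else "amino-acid"
        else:
            kind = alphabet
        out.append(SequenceRecord(id=rec.id, residues=residues, alphabet=kind))
    return out


_GML_BOOL_KEYS = ("concordant",)


def write_gml(graph: nx.Graph, path: str | Path) -> None:
    """Write a similarity graph as GML (attributes survive a round trip)."""
    g = nx.Graph()
    g.add_nodes_from((n, {k: v for k, v in d.items() if v is not None})
                     for n, d in graph.nodes(data=True))
    for u, v, d in graph.edges(data=True):
        clean = {}
        for k, val in d.items():
            if k.startswith("_") or val is None:
                continue
            clean[k] = int(val) if isinstance(val, bool) else val
        g.add_edge(u, v, **clean)
    nx.write_gml(g, str(path))


def read_gml(path: str | Path) -> nx.Graph:
    g = nx.read_gml(str(path))
    for _, _, d in g.edges(data=True):
        for key in _GML_BOOL_KEYS:
            if key in d:
                d[key] = bool(d[key])
    return g


def read_newick(path_or_string: str | Path) -> "dendropy.Tree":
    """Read a Newick tree (file path or literal string) with branch lengths."""
    import dendropy

    text = None
    p = Path(str(path_or_string))
    try:
        if p.exists():
            text = p.read_text(encoding="utf-8")
    except OSError:
        pass
    if text is None:
        text = str(path_or_string)
    return dendropy.Tree.get(data=text, schema="newick")


def map_sound_classes(morphemes, scheme) -> list[list[str]]:
    """Map every token to its sound class under ``scheme`` (shape-preserving).

    Unknown tokens fall back to the scheme's wildcard class, so the mapping
    is total and deterministic.
    """
    return [[scheme.token_class(tok) for tok in m] for m in morphemes]
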