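# lexinet

Word and sequence similarity networks for historical linguistics: pairwise
alignment under sound-class scoring, thresholded similarity graphs, and
network-structural detection of cognate sets, borrowings (the linguistic
analog of lateral gene transfer), and fused/compound words — plus a forward
simulator of lexical evolution that produces ground-truthed wordlists,
including the rapid-divergence polymorphism-sorting regime analogous to
incomplete lineage sorting (ILS) in biology.

## Who this is for

Computational historical linguists who want to apply sequence-similarity-
network methods from comparative genomics to multilingual wordlists, and
bioinformaticians curious how their tooling transfers: the same machinery
accepts FASTA input (nucleotide identity or BLOSUM62 scoring) through the
identical network pipeline.

## The method

A word is modeled as a sequence of sound-segment tokens grouped into
morphemes, with tone digits as ordinary tokens.  Tokens map to Dolgopolsky-
style sound classes (~10 consonant classes, one vowel class, a tone track);
columns score +2 within a class, −1 across classes of the same type, −2
across types, gaps −1, tone columns down-weighted ×0.5.  Pairs of words are
aligned both globally (Needleman–Wunsch/Gotoh) and locally (Smith–Waterman),
and similarity is expressed as a length-normalized distance

    d(a, b) = 1 − 2·S(a, b) / (S(a, a) + S(b, b))   ∈ [0, 1].

An all-vs-all network draws an edge whenever d ≤ t (default t = 0.45).  On
that graph:

* **connected components** (per concept) approximate cognate sets;
* a component mixing ≥ 2 language families with one family holding ≥ 60 % of
  members flags the minority-family words as **borrowing candidates**;
* an **articulation hub** whose neighbor groups align locally to
  non-overlapping spans of it is a **fused/compound candidate**, with
  breakpoints snapped to morpheme boundaries;
* the same network built over **morphemes** instead of words yields
  **partial cognacy** (words sharing only some morphemes).

The simulator evolves one word slot per concept down a dated tree with
continuous-time events (sound substitution, synonym birth/resolution,
lexical replacement, compounding, cross-lineage borrowing) and emits a
wordlist plus a replayable event log, so every detector can be scored
against planted truth.  `ils_discordance` measures the fraction of cognate
sets whose bearers are not monophyletic — the introgression-free mosaic
patterns that unresolved polymorphisms leave after rapid divergence.

## Worked example

The bundled synthetic `person` wordlist (37 words for 'person' in Germanic,
Romance and Slavic languages) reproduces the classic network demonstration:

```sh
$ lexinet network src/lexinet/data/person_synthetic.tsv --min-size 3 -o out/
37 nodes, 112 edges, 5 components (size >= 3)

$ head -6 out/components.tsv
component  size  families                       members
1          13    Germanic:3,Romance:8,Slavic:2  p01,p02,...,p13
2          7     Slavic:7                       p20,...,p26
3          6     Germanic:6                     p14,...,p19
4          4     Romance:4                      p27,...,p30
5          3     Germanic:1,Romance:2           p31,p32,p33
```

Five large components emerge.  Three are family-homogeneous true cognate
sets (Slavic *člověk*, Germanic *Mensch*, Romance *uomo*); the largest mixes
all three families because it collects the Romance reflexes of Latin
*persona* together with the Germanic and Slavic words *borrowed* from them —
and `lexinet detect borrowings` flags exactly those five loans plus English
*human* in the smaller mixed cluster (precision = recall = 1.0 against the
annotation).

Partial cognacy on the Mandarin/Cantonese 'moon' pair:

```sh
$ lexinet detect partial src/lexinet/data/moon_synthetic.tsv -o out/
$ cat out/partial_cognates.tsv
ID    MORPHEME_CLASSES
m01   m01:0 m01:1
m02   m01:0 m02:1
```

Both words' first morphemes land in one class (`m01:0`: *yuè* ≈ *jyut*,
cognate) while the second morphemes stay apart (*liàng* 'shine' vs *gwong*
'light' are different roots) — the words are partially cognate.

Other subcommands: `lexinet tokenize`, `align`, `detect
cognates|borrowings|composites|partial`, `simulate`, `evaluate`; every run
writes a `run_report.json` with all resolved parameters.

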