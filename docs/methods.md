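# Methods

This note documents the models, parameter choices and numerical conventions
behind `lexinet`, and what the synthetic data used in tests does and does not
establish about real data.

## Words as sequences

A word form is an ordered list of morphemes, each an ordered list of segment
tokens.  Tokenization forms grapheme clusters (base character plus combining
marks, after NFC normalization), emits digits as separate tone tokens, and
treats hyphens and whitespace as morpheme boundaries; a profile table can map
digraphs (e.g. `tsch`) to single tokens, longest match first.  In TSV
wordlists the `TOKENS` column is authoritative when present (`+` or `-`
separate morphemes); otherwise the tokenizer is applied to `FORM`.  Token
indices are 0-based and all spans half-open `[start, end)`.

## Scoring scheme

The default linguistic scheme maps tokens to Dolgopolsky-style classes:
about ten consonant classes (P T S K M N R W H and the glide class J that
unites *j* and *y*), a single vowel class V, and a tone track on which every
digit is its own class.  Column scores: +2 within a class, −1 across classes
of the same type (consonant/consonant or vowel/vowel), −2 across types;
columns involving a tone class are multiplied by the tone weight 0.5, so
tonal agreement helps without dominating.  Unknown tokens fall back to a
wildcard class (self +1, anything else −1), keeping the mapping total.  Gap
costs are affine (`gap_open`, `gap_extend`), −1/−1 by default, i.e. linear —
appropriate for token sequences of length 2–10.  Two consequences worth
keeping in mind:

* a single vowel class means any vowel matches any vowel; this is the
  classical robustness-to-vowel-change choice, but it makes very short
  unrelated forms (≤ 4 tokens) similar by chance fairly often;
* class-preserving sound change (e.g. *s* → *z*) is invisible to the score,
  which is exactly the intended behavior.

Biological modes reuse the identical dynamic program: nucleotide identity
(+2/−1, gap −1) or BLOSUM62 with affine gaps −8/−2 for amino acids (checked
against Biopython's `PairwiseAligner` in the test suite).

## Alignment and distance

Global alignment is Needleman–Wunsch with Gotoh's three-state affine
extension, local alignment the zero-clamped Smith–Waterman variant.
Tracebacks are deterministic: backpointers are fixed at fill time with tie
order diagonal > gap-in-b > gap-in-a, and of co-optimal local end cells the
one with the smallest (i, j) wins, so outputs are bit-stable across runs and
platforms.  An empty local alignment (score 0, empty spans) is returned when
no positive-scoring window exists.

Similarity is converted to the length-normalized distance
`d = 1 − 2S(a,b)/(S(a,a)+S(b,b))`, clamped to [0, 1]; `S(x,x)` is the sum of
self-scores, which is also the alignment optimum because self-scores are
positive.  A scheme whose self-scores are not positive is rejected.  This
normalization makes one threshold usable across word lengths, at the price
of an upward bias for very short sequences (the denominator shrinks faster
than attainable match mass): morphemes of 2–3 segments rarely get below
distance ~0.4 even when fully cognate.  That bias motivates the separate
morpheme-level threshold below.

## Networks and their reading

`build_network` evaluates all pairs, stores global and local score, both
distances, the local windows and the concordance flag on every edge, and
keeps an edge when the requested mode's distance is ≤ the threshold
(default 0.45, chosen so that clearly related forms at moderate divergence
connect while unrelated forms of typical length do not; with +2 matches the
value corresponds to demanding a bit more than half of the attainable match
mass).

An edge is *concordant* when the local alignment reproduces the global one
as a whole — identical matched token pairs and windows covering both
sequences end to end.  A local alignment that is a proper sub-region of
either word signals partial similarity (e.g. one shared morpheme), the
signature rendered as black edges in similarity-network figures.  Defining
concordance through window coverage rather than through matched pairs alone
matters: for a fused form aligned to one of its parts the two alignments can
match exactly the same pairs, differing only in what they leave unaligned.

Components are reported largest-first with lexicographic tie-breaks;
"large" means size ≥ 3 throughout.  Articulation vertices are computed per
component; for each, the groups its removal creates are reported with the
union of the group's local windows on the hub.

## Detectors

* **Cognates** — per-concept components; class id = smallest member id, so
  partitions are invariant under row order.
* **Borrowings** — a component spanning ≥ 2 families is mixed.  If one
  family holds ≥ 60 % of members it is dominant and all other members are
  flagged; otherwise the mixture is unresolved and every member is flagged.
  Direction is always "undetermined": the network carries no arrow.  The
  60 % cutoff operationalizes "a cluster dominated by one family"; at 50 %
  exactly-even two-family clusters would acquire a spurious dominant side.
  Note the detector's deliberate blindness: genuinely vertical cognates
  that survive across family boundaries are flagged too.  On simulated data
  with zero borrowing it therefore still produces calls wherever deep
  cognates (or chance resemblances between short forms) cross family lines;
  its value lies in ranking borrowing-enriched clusters, not in proving
  transfer.
* **Composites** — an articulation hub is called composite when ≥ 2 of its
  neighbor groups align to spans of it overlapping by ≤ 1 token.
  Breakpoints sit at the midpoint between adjacent group spans and snap to
  the nearest morpheme boundary when the word has annotations; parts tile
  the word exactly.  The network is built cross-concept in local mode by
  default so a compound can be supported by its free-standing parts
  (`Krankheitsverlauf` by `Krankheit` and `Verlauf`).
* **Partial cognacy** — the same network over morphemes (attributes
  inherited from their words); components are morpheme cognate classes, and
  a word pair's shared classes per slot express its degree of partial
  cognacy.  Default threshold 0.60 rather than 0.45, compensating the
  short-sequence bias of the normalized distance (a fully cognate CV(C)
  morpheme pair with one tone disagreement sits near 0.58).  For
  morpheme-segmented material of word-like length (e.g. simulator output,
  whose morphemes are disyllabic roots) the word-level 0.45 is the
  appropriate setting.

## The simulator

Each concept evolves independently down a dated rooted tree.  A lineage
carries one or more synonymous slots per concept; native dynamics are a
Gillespie process per branch with exponential waiting times and
state-dependent total rate.  Defaults (per unit branch length):

| process | rate | note |
|---|---|---|
| sound substitution | 0.15 per token | 80 % class-preserving / 20 % class-changing |
| synonym birth | 0.3 per concept | new etymon joins as a synonym |
| synonym resolution | 1.0 per polymorphic concept | a uniformly chosen slot is dropped |
| lexical replacement | 0.6 per concept | slot swapped for a new etymon |
| compounding | 0 (off) | adds a part: bound affix or another concept's proto-form |
| borrowing | 0 (off) | copies a coexisting lineage's slot verbatim |

The rates were chosen once as a regime in which cognates remain detectable
at tree depths of 2–4 units while vocabulary turns over visibly; none is an
empirical estimate.  Root forms are disyllabic (CVCVC/CVCCVC/CVCVCV, 5–6
segments) over a 20-consonant/6-vowel inventory: with a single vowel class,
shorter roots (CV, CVCV) collide by chance in ~20 % of unrelated pairs,
which no realistic basic-vocabulary lexicon does.  Randomness is keyed per
(seed, purpose, branch, concept) through SHA-256, so runs are byte-identical
under a fixed seed and subsetting concepts leaves other concepts' histories
untouched.  For the same reason, a compounding event takes its second part
from a closed affix pool or from the *proto-form* of another concept rather
than from that concept's live form on the same branch: live cross-concept
coupling would break per-concept stream independence (and could recurse).

Borrowing events are Poisson per (branch, concept); the donor is chosen
uniformly among lineages alive at the event time, lends one of its *native*
slots, and the copy thereafter evolves by substitution only, flagged with
its donor.  Donors lending only native material keeps every lineage's
native history self-contained and replayable.  Consequence: borrowed words
never speciate further lexically, a simplification that slightly inflates
their persistence.  The helper `borrowing_rate_for_fraction` inverts
`fraction = bL/(bL + native)` with L the mean root-to-tip length and
`native ≈ 1 + birth/resolution` the quasi-stationary synonym count, to plant
a target borrowed fraction (the recovery experiments use ≈ 20 %, which the
runs reproduce to within ~1 point).

`make_rapid_divergence_tree(k, eps)` builds a balanced tree with pendant
branches 1 and all internal branches `eps`: small `eps` means lineages split
faster than polymorphisms resolve.  `ils_discordance` calls a cognate set
convex when its bearer tips are exactly the leaf set of one clade
(monophyly) and reports the fraction of multi-tip sets that are not; it
refuses data containing borrowing events, so the measured discordance is
introgression-free by construction.  Across eps ∈ {0.01, 0.1, 1.0} the mean
discordance decreases (≈ 0.97 → 0.83 → 0.24 under defaults with birth 0.5),
the qualitative ILS signature: it does not vanish at eps = 1 because
pendant-branch replacement also leaves non-monophyletic presence patterns.

## Evaluation

Borrowing and composite calls are scored as binary classification over word
ids; an empty call set reports precision 0 with an explicit
`precision_defined=False` flag.  Partitions (cognates, morpheme classes)
are scored with B-cubed precision/recall/F.  The reference point for the
borrowing detector is the analytic random-classifier expectation at equal
call rate, F1 ≈ 2pq/(p+q) for prevalence p and call rate q — any deviation
from it measures signal, since a detector can trivially match it by
flagging at random.

## What the synthetic data shows — and does not

The bundled demonstration wordlists are hand-assembled synthetic stand-ins:
real, well-known lexical material (Romance *persona* loans, the Chinese
*liǎn/miàn* variation, the *Krankheitsverlauf* word family), transcribed in
broad IPA-style tokens and curated so that the published style of network
structure appears at the default threshold.  Passing on them shows the
pipeline reproduces the intended structural readings on clean, segmented,
consistently transcribed input.  It does not show robustness to the noise
of real datasets: inconsistent transcription across sources, missing
segmentation, semantic shift, or threshold sensitivity on lexicons with
thousands of concepts.  Likewise the simulator omits speaker populations,
selection, areal pressure and semantic change; its ground truth validates
detector mechanics, not field performance.

## Known limitations

* O(n²) pair evaluation per network; fine to a few thousand forms,
  inadequate beyond (no indexing/banding is attempted).
* The single vowel class makes chance similarity of short forms the main
  false-positive source at the default threshold.
* Minority-family flagging cannot distinguish borrowing from deep vertical
  cognacy or chance resemblance (see Detectors above).
* Problem sizes in tests and in the acceptance script (20 tips, 200
  concepts, 10–20 seeds) were chosen as the smallest sizes at which the
  statistical claims are stable across seeds.
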