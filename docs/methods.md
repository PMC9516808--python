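# Methods

## Task and data model

The package labels each token of a biomedical sentence with an ontology
concept tag. Ground truth comes from CRAFT-style corpora: UTF-8 article
text plus per-article XML listing character spans (0-based, half-open) and
the concept id annotated to each span. Annotations are converted to IOB
sequences at the sentence level; the sentence-final punctuation token (or a
synthetic `<EOS>` token when a title or heading has none) carries the
dedicated `EOS` tag.

### Annotation-format transformation

Corpus annotations come in four structural flavours, resolved in a fixed
precedence — overlap expansion first, then discontinuous collapsing, with
disjoint annotations carried unchanged:

* **Disjoint** spans are tagged in place (`B-` on the first token, `I-` on
  continuations).
* **Overlapping** annotations — a phrase annotated to one concept with a
  sub-phrase annotated to another — cannot coexist in a single tag
  sequence. Each overlap group of n mutually overlapping annotations
  yields n alternatives (nested sub-sub-phrases are flattened into the
  same group); a sentence with m groups expands to n₁ × … × n_m copies,
  one per combination. Each copy deletes the tokens covered only by the
  non-chosen alternatives, so every copy reads as the text needed for its
  own annotation set.
* **Discontinuous** annotations (≥ 2 spans) become contiguous by deleting
  the unannotated tokens strictly between their spans; tokens belonging to
  other surviving annotations are never deleted.
* Span-to-token alignment uses character overlap: a token belongs to an
  annotation if their character ranges intersect at all. This absorbs
  small disagreements between tokenizer and annotation boundaries.
  Annotations crossing a sentence boundary are truncated to the first
  sentence with a warning.

The oversampling introduced by variant expansion is accepted as-is; such
sentences are a small fraction of any realistic corpus.

### Segmentation, tokenization, POS

Segmentation and tokenization are rule-based and shipped inside the
package, so preprocessing has no external model dependency and is
byte-stable: sentences end at `.`/`!`/`?` followed by whitespace and an
upper-case letter, digit or opening bracket (newlines always terminate);
tokens split off enclosing punctuation, keep internal hyphens
("lineage-specific"), and a slash starts a new token that retains its
slash ("v/p" → `v`, `/p`). The POS tagger is a compact Penn-style rule
tagger (closed-class lexicon plus shape/suffix rules, ~20 tags). It is one
of six input channels, not a scientific claim; its value is determinism.

## Input encoding

Each sentence becomes six fixed-shape channels: token ids; a token ×
character id matrix; compressed character-pattern ids (maximal letter runs
reduced to the case classes of their first three characters, digit runs to
`N`, punctuation kept, other symbols `U`); POS ids; four binary
BioThesaurus category flags (protein / biomedical / chemical /
macromolecule); and one binary UMLS flag, where any lexicon phrase of up
to five tokens marks all its member tokens. Geometry defaults to 71
tokens × 15 characters (third standard deviation of the respective length
distributions in the corpus the architecture was designed for); longer
sentences/tokens keep their left prefix. Vocabularies are built from
training data only; unseen symbols map to `<UNK>`, and padded positions
are excluded from the loss and all metrics via a mask. Lexicon lookup is
case-insensitive after Unicode NFC normalization.

## Model

A character-level bidirectional GRU (150 units per direction by default)
reads each token's character embeddings; its two final states summarize
spelling. That vector is concatenated with the token embedding (supervised
by default; pretrained static vectors or a contextual-embedding adapter
can replace it), the character-pattern and POS embeddings, and the raw
BioThesaurus/UMLS flags. The concatenated feature sequence passes through
spatial dropout (whole feature channels dropped along the sequence,
default 30%), a main bidirectional GRU (150 units per direction by
default, 10% dropout, left-to-right and right-to-left states
concatenated), and a time-distributed dense layer with sigmoid activation
and one unit per output tag. Prediction takes the arg-max tag per token;
softmax over the sigmoid activations provides the probability vector and
the normalized entropy H(X)/log K used in the confidence diagnostics. No
IOB-consistency repair is applied by default (an optional post-hoc repair
exists but is off), so predicted sequences may be ill-formed; the
evaluation is positional and unaffected.

### Training objective and schedule

The loss is masked per-tag binary cross-entropy on the sigmoid
activations — the standard pairing for a sigmoid classification head. (A
categorical cross-entropy over softmax-normalized sigmoid outputs was
evaluated first and rejected: with activations bounded in [0, 1] the
softmax cannot express confident predictions, and learning at small scale
stalls.) Optional class weighting (default on) uses standard "balanced"
inverse-frequency weights over the observed tags; the weight scales each
tag's positive term. Optimization is Adam at learning rate 1e-4, batch 16,
with reduce-on-plateau scheduling: the epoch loss (position-weighted
aggregate over the epoch, not a mean of batch means) must strictly improve
on its best value, else a patience counter advances and after four flat
epochs the rate is multiplied by 0.1. The strict-improvement reading
matters: with a small improvement threshold instead, noisy early epochs on
small corpora can cascade the rate to nothing before learning starts.

### Initialization

Short training budgets at lr 1e-4 move each parameter only a few
hundredths in total, so the network must start in a regime where channel
signals are discriminable and only the read-out needs to move:

* embeddings: uniform(-1.5, 1.5) — large enough that the randomly
  initialized GRUs act as informative reservoirs over distinct tokens;
* GRU input kernels: Glorot uniform; recurrent kernels: one orthogonal
  block per gate;
* dense head: Glorot weights, and biases set at `fit()` time to the
  log-odds of each tag's (class-weight-adjusted) base rate, so no budget
  is spent learning the label marginals.

All randomness flows from a single integer seed; two runs with the same
seed produce identical loss histories and predictions.

## Evaluation

* **Modified F1** — micro precision/recall/F1 over token positions,
  omitting positions where `O`/`EOS` is predicted correctly. A true
  positive requires the exact tag, prefix included. 0/0 ratios resolve
  to 0 with a warning.
* **Semantic F1** — identical denominators, but a position where gold and
  prediction are both concept tags earns the Jaccard similarity of the two
  concepts' self-inclusive `is_a` ancestor sets (prefixes not compared).
  Because per-position credit is never below exact credit, semantic
  precision and recall dominate their exact counterparts by construction.
* **Diagnostics** — a confusion matrix over {GO_BP, GO_MF, GO_CC, O, EOS}
  (correct O/EOS counted separately as excluded); the four-way error
  breakdown (correct / concept-missed / spurious-concept / wrong-concept);
  per-concept F1 binned by training-corpus frequency (default edges 1, 10,
  20, 50, 100); and a per-position table of entropy, top probability,
  training frequency and correctness. Evaluation is per token position
  throughout — span-level matching is not defined here.

## Synthetic corpora

`ontogru.fixtures` generates deterministic corpora from a `FixtureSpec`:
articles of template sentences that embed one- or two-word concept mention
phrases at exactly known offsets, with configurable fractions of
overlapping, multiply-overlapping and discontinuous sentences, Zipf-skewed
concept usage, and toy three-namespace ontologies plus
BioThesaurus/UMLS-style lexicons covering the mention vocabulary. The
generator computes its own ground-truth IOB sentences from construction
knowledge, enabling a differential test: the full reader + transformation
pipeline must reproduce the generator's truth exactly.

Design choices worth noting:

* Mention words never collide with template words, so generated corpora
  are *separable*: the mention vocabulary determines the concept. Passing
  learning-recovery tests therefore demonstrates that the architecture and
  optimizer can fit the annotation vocabulary and transfer it to held-out
  articles — not that real biomedical text, with its ambiguity and 80%
  non-lexical matches, is solved.
* Concept usage is sampled i.i.d. from a Zipf distribution with exponent
  2.0 by default, emulating corpora whose concept inventory is dominated
  by concepts seen only a handful of times; at ~250 mentions over 10
  concepts the tail ranks expect one or two mentions, so genuinely starved
  concepts exist and the frequency-binned diagnostic is informative.
  After generation, concept ids are relabeled in realized-frequency order
  (ids are arbitrary), which makes "id rank = frequency rank" an invariant
  of generated corpora.
* A `misaligned` flag shifts annotation starts by one character into the
  phrase to exercise the token-overlap alignment rule.

## Scaled-down study configuration

The end-to-end benchmark in `scripts/acceptance.py` and the learning-
recovery test uses ~200 sentences across 20 articles (80/20 article-level
split), 10 concepts, and a model with 32-dimensional embeddings and 32 GRU
units per direction, trained for 30 epochs at batch 16 and Adam 1e-4 with
the plateau schedule. All three dropouts are set to 0 for this
configuration — dropout is a tuning dimension of the architecture, and at
this corpus size regularization noise only slows the short run; package
defaults keep 10%/30%/10% for realistic corpus sizes. Problem sizes were
chosen so the full study completes in well under a minute on one CPU while
leaving every qualitative phenomenon measurable.

## Known limitations

* The synthetic benchmark is separable by construction; results on it
  upper-bound nothing about real corpora.
* Sentence segmentation and POS tagging are rule-based approximations;
  on real articles a statistical segmenter would disagree on some
  boundaries. Offsets, not linguistic accuracy, are what the pipeline
  depends on.
* Pretrained static vectors are supported via a text-file loader and a
  contextual-embedding adapter interface; no pretrained weights ship with
  the package, and the self-contained default is the supervised embedding.
* Discontinuous-annotation collapsing deletes context tokens; the
  transformed sentence is a training convenience, not a faithful reading
  of the original text.
* The plateau schedule monitors training loss, not validation loss; there
  is no early stopping.
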