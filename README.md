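# ontogru

Recognition of Gene Ontology (GO) concepts in biological full-text articles
with a dual bidirectional-GRU sequence labeler.

Manual ontology annotation — a curator reading a paper and attaching GO
concept ids to words and phrases — does not scale to the pace of
publishing. `ontogru` implements an automated pipeline for this task,
trained on CRAFT-style corpora (plain-text articles plus XML files that map
character spans to concept ids):

1. **Preprocessing** — sentence segmentation and tokenization; conversion
   of character-span annotations to per-token IOB tags (`B-GO:…`,
   `I-GO:…`, `O`, sentence-final `EOS`). Annotation formats beyond the
   simple disjoint case are handled the way concept-annotation guidelines
   require: a phrase annotated to one concept containing a sub-phrase
   annotated to another is expanded into one sentence copy per reading
   (n₁ × n₂ × … copies for multiple overlap groups), and a discontinuous
   annotation is made contiguous by deleting the unannotated tokens
   between its spans.
2. **Encoding** — six fixed-shape channels per sentence (71 tokens × 15
   characters): token ids, character ids, a compressed character pattern
   ("Smith-Lemli-Opitz" → `Ccc-Ccc-Ccc`, "DHCR7" → `CCCN`), POS tags, four
   BioThesaurus category flags and one UMLS presence flag (phrases mark
   all their member tokens).
3. **Model** — a character Bi-GRU summarizes each token's spelling; its
   output is concatenated with the other channel embeddings (the lexicon
   flags enter raw), passed through spatial dropout, a main Bi-GRU, and a
   time-distributed dense layer with sigmoid activation, one unit per
   output tag. Training uses Adam (lr 1e-4), batch 16, and
   reduce-on-plateau scheduling. The network is implemented directly on
   numpy — forward pass, backpropagation through time and the optimizer —
   so training is bit-reproducible for a fixed seed.
4. **Evaluation** — a *modified F1* that omits correctly predicted
   non-annotation tags (the dominant class would otherwise inflate the
   score), and a *semantic F1* that grants partial credit for near-miss
   concepts via the Jaccard similarity of their self-inclusive `is_a`
   ancestor sets: J(a, b) = |Anc(a) ∩ Anc(b)| / |Anc(a) ∪ Anc(b)|.
   Diagnostics: per-sub-ontology (BP/CC/MF) scores and confusion matrix,
   per-concept F1 binned by training frequency, and per-token
   entropy/probability confidence tables.

A seeded synthetic-corpus generator (`ontogru.fixtures`) emulates the
corpus structure — articles with exact character-offset annotations,
overlapping/discontinuous cases, Zipf-skewed concept frequencies, toy
ontologies and lexicons — so the entire pipeline is testable offline.

## Worked example

Overlap expansion on a sentence carrying two overlap groups
(vesicle/vesicle formation × membrane/membrane fusion):

```python
from ontogru.datatypes import ArticleDocument, ConceptAnnotation
from ontogru.annotation_transform import preprocess_article

text = ("Having excluded a direct role in vesicle formation and membrane "
        "fusion, annexin A7 might act by its property as Ca2+-binding protein.")
anns = (
    ConceptAnnotation(((33, 40),), "vesicle", "GO:0031982"),
    ConceptAnnotation(((33, 50),), "vesicle formation", "GO:0006900"),
    ConceptAnnotation(((55, 63),), "membrane", "GO:0016020"),
    ConceptAnnotation(((55, 70),), "membrane fusion", "GO:0061025"),
)
doc = ArticleDocument("pmc_demo", text)
for sent in preprocess_article(doc, anns):
    pairs = [f"{tok}/{tag}" for tok, tag in zip(sent.tokens, sent.tags)
             if tag != "O"]
    print(f"variant {sent.provenance[2]}: {' '.join(pairs)}")
```

prints the four unique annotation combinations (note that each copy keeps
only the tokens of its chosen reading — "formation" is absent from the
copies that annotate bare "vesicle"):

```
variant 0: vesicle/B-GO:0031982 membrane/B-GO:0016020 ./EOS
variant 1: vesicle/B-GO:0031982 membrane/B-GO:0061025 fusion/I-GO:0061025 ./EOS
variant 2: vesicle/B-GO:0006900 formation/I-GO:0006900 membrane/B-GO:0016020 ./EOS
variant 3: vesicle/B-GO:0006900 formation/I-GO:0006900 membrane/B-GO:0061025 fusion/I-GO:0061025 ./EOS
```

## Command line

```bash
ontogru fixtures   --spec spec.yaml --out corpus/          # synthetic corpus
ontogru preprocess --corpus corpus/ --out conll/ --split 0.8 --seed 7
ontogru encode     --conll conll/ --lexicons corpus/lexicons --out enc/
ontogru train      --data conll/ --encoder enc/ --config model.yaml --out model/
ontogru predict    --model model/ --encoder enc/ --conll conll/test.tsv --out pred.tsv
ontogru evaluate   --gold conll/test.tsv --pred pred.tsv \
                   --obo corpus/ontology.obo --out report.json
ontogru stats      --corpus corpus/ --obo corpus/ontology.obo
```

Every stage stamps its output directory with a hash of the configuration
that produced it; later stages refuse mismatched inputs.

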