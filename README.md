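# kret

Knowledge-injected relation extraction for biomedical text: expand an
entity-tagged sentence into a *sentence tree* using triples from one or
more ontologies, encode it with soft positions and a visible matrix, and
classify the candidate relation with a mask-self-attention transformer.

## Who this is for

Researchers in biomedical text mining who want to study *how* structured
domain knowledge (HPO/DO/ChEBI/GO-style `is_a` ontologies) changes the
behaviour of a transformer relation classifier — at desk scale, on a
single CPU, with fully synthetic, seeded fixtures instead of corpus
downloads and GPU fine-tuning.

## The model in brief

A sentence `s = {t0, …, tn}` with two tagged candidate entities is
expanded with knowledge-base triples `e = (t_i, r_j, t_k)` into a depth-1
sentence tree

    st = {t0, …, t_i{(r_i0, t_i0), …, (r_ik, t_ik)}, …, tn}

by multi-token dictionary matching against per-ontology lookup tables
(longest match wins on overlap; at most 2–5 branches per entity, ranked by
the tail concept's information content `IC(c) = −log((desc(c)+1)/N)`).
*Targeted* injection touches only the two candidate entities; *contextual*
injection matches every span.  The flattened tree is encoded with
tree-derived *soft positions* and a boolean *visible matrix* — a branch
token sees only its own branch and its anchor — which becomes a `0/−1e9`
additive attention mask inside a BERT-style encoder (NumPy, hand-written
backprop).  Training uses inverse-frequency class weights, stratified
60/10/30 splits, batch 32, and validation selection on support-weighted
F-measure; run-level comparisons use a one-tailed Welch t-test.

See `docs/methods.md` for the full method description and design
rationale.

## Worked example

```python
from kret import (
    build_lookup, build_sentence_tree, load_knowledge_source,
    parse_tagged_sentence, encode_tree,
)

# tiny ChEBI-like knowledge base as TSV triples
open("kb.tsv", "w").write(
    "dopamine\tis_a\taralkylamino compound\n"
    "seizure\tis_a\tabnormal nervous system physiology\n"
)
table = build_lookup(load_knowledge_source("kb.tsv", format="tsv-triples"))

sent = parse_tagged_sentence(
    "The use of <e>dopamine</e> may cause <e>seizure</e> events .", "effect"
)
tree = build_sentence_tree(sent, [table], mode="contextual", max_entities=2)
flat = encode_tree(tree, max_len=24)
print(flat.tokens)
print(flat.soft_pos)
```

prints

```
['[CLS]', 'The', 'use', 'of', 'dopamine', 'is_a', 'aralkylamino',
 'compound', 'may', 'cause', 'seizure', 'is_a', 'abnormal', 'nervous',
 'system', 'physiology', 'events', '.', '[PAD]', '[PAD]', '[PAD]',
 '[PAD]', '[PAD]', '[PAD]']
[0, 1, 2, 3, 4, 5, 6, 7, 5, 6, 7, 8, 9, 10, 11, 12, 8, 9, 0, 0, 0, 0, 0, 0]
```

The branch tokens (`is_a aralkylamino compound`) continue the soft
numbering of their anchor (`dopamine`, soft 4 → 5 6 7) while the next
trunk token (`may`) resumes at soft 5 — duplicated soft positions are the
point: the encoder sees tree structure through positions and the visible
matrix, not through token order alone.

A command-line interface wraps the library:

```sh
kret simulate --seed 7 --out fixtures/          # toy ontology + corpus
kret build-lookup --kb fixtures/toy.obo --format obo --out lookup.tsv
kret inject --corpus fixtures/corpus.tsv --kb fixtures/toy.obo \
     --mode contextual --max-entities 2 --out trees.jsonl
kret train --corpus fixtures/corpus.tsv --kb fixtures/toy.obo \
     --mode contextual --seed 7 --out run/
kret eval --model run/ --corpus fixtures/corpus.tsv --kb fixtures/toy.obo
```

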