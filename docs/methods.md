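# Methods

## Problem setting

`kret` implements knowledge-injected relation extraction (RE): given a
sentence with two tagged candidate entities, classify the semantic relation
between them, letting the classifier consult one or more ontologies at
prediction time.  The pipeline has four stages:

1. **Knowledge layer** — expand the sentence into a *sentence tree*: the
   original token sequence (trunk) plus depth-1 branches
   `(relation, tail-concept)` attached at entity anchor spans, drawn from
   knowledge-base triples.
2. **Embedding layer** — flatten the tree; each token receives a *hard*
   position (flattened index) and a *soft* position (tree position: branch
   tokens continue numbering from their anchor, so soft positions repeat).
3. **Seeing layer** — a boolean *visible matrix*: trunk tokens see each
   other; a branch token sees only its own branch and its anchor.  This
   stops injected knowledge from perturbing unrelated sentence positions.
4. **Mask transformer** — a BERT-style encoder whose attention adds
   `0 / -1e9` mask terms derived from the visible matrix, with a
   classification head reading a CLS-style token, trained under
   class-weighted cross-entropy.

## Knowledge layer

Multi-token matching enumerates every contiguous span of non-punctuation
tokens (n(n+1)/2 spans for n clean tokens; punctuation tokens act as
separators) and queries each span against every lookup table.  Overlaps are
resolved longest-match-first: spans properly contained in another matched
span are discarded, then remaining overlaps are broken by length, leftmost
start, and summed tail information content.  The sub-span discard happens
before the greedy pass so a kept match is never a proper sub-span of any
matched span, not merely of the kept ones.

Two injection modes exist.  *Targeted* queries only the two candidate
entity spans (as whole spans, however many tokens).  *Contextual* queries
every span, so non-candidate entities also receive branches.

When more triples match an anchor than the per-entity cap (2–5 in normal
use), triples are pooled across sources, de-duplicated, ranked by the
information content of the tail concept, and truncated.  IC is the
intrinsic descendant-count form computed on the `is_a` graph only:

    IC(c) = -log((descendants(c) + 1) / N)

Leaves score highest; a universal root scores 0.  Corpus-frequency IC would
need external corpora, and `is_a` is the one relation every biomedical
ontology in this setting shares, so the intrinsic form is the default and
the only one implemented.  Ties after IC break on source name, then tail
label, making branch selection a total order.

Surface normalization is lowercase + whitespace collapse + outer
punctuation strip, with no stemming: chemical nomenclature
("aralkylamino compound") must match exactly.  OBO synonyms of all scopes
are indexed by default (toggleable at load time).

## Seeing and embedding

Branches are inserted immediately after the last token of their anchor,
each branch emitting its relation token (kept whole, e.g. `is_a`) then the
whitespace-split tail tokens.  Soft positions: trunk token *i* keeps *i*;
a branch continues from its anchor (`anchor end`, `anchor end + 1`, ...),
sibling branches restarting at the same offset.  Visibility: trunk↔trunk
always; branch token ↔ own branch ∪ anchor span; everything else hidden.
Sibling branches of one anchor are mutually invisible (each branch is a
separate tree path); a flag flips this if wanted.

The classification token sits at hard and soft position 0, sees every
trunk token and, by default, no branch token: classification reads the
sentence as contextualized *through* the anchors rather than raw injected
tokens.  `cls_sees_branches` exposes branches to the CLS row directly.

Over-long sequences drop whole branches first (lowest tail IC first), then
truncate the trunk tail; padding tokens are invisible to and from all real
tokens (the diagonal stays true so softmax rows never degenerate).

## Encoder and training

The encoder is deliberately small and self-contained: NumPy forward pass
and hand-written backprop (Adam, linear warmup then linear decay or a
constant rate — the benchmark uses the constant schedule because the
planted relational feature tends to be found late, and decay-to-zero cuts
exactly those epochs; default
peak 1e-3 — appropriate for training from scratch at toy scale, unlike the
5e-5 fine-tuning rates used with pretrained checkpoints).  Float32 is the
default compute dtype; float64 is available and is what the oracle-
equivalence tests use.  The additive mask realizes "invisible" as -1e9
before softmax; a row with no visible positions falls back to self-only
attention with a log message.  Checkpoints are flat name→tensor `.npz`
manifests; loading is best-effort (overlapping tensors copied, the rest
seed-initialized, shape mismatches are hard errors naming the tensor).

Class weights are inverse-frequency, `w_c = N / (L · n_c)`; their
support-weighted mean is identically 1, keeping the weighted loss on the
scale of plain cross-entropy.  The loss is the batch mean of
`w_{y_i} · NLL_i`, so uniform weights reduce exactly to cross-entropy.
Splits are label-stratified 60/10/30 by largest-remainder allocation;
the best epoch is selected on validation weighted F-measure.  Evaluation
reports per-label precision/recall/F with support-weighted averages and
accuracy, computed from the confusion matrix (scikit-learn is used as an
independent cross-check in the tests, never as the implementation).
Run-level comparisons use a one-tailed Welch t-test (the unequal-variance
form; run counts at desk scale are small and nothing guarantees equal
variances across configurations).

## Synthetic fixtures and the planted-signal benchmark

The generator emulates the statistical shape of a biomedical RE corpus
paired with a domain ontology, at desk scale:

* a rooted `is_a` DAG grown by capped preferential attachment — a few
  large concept families and many small ones, the skewed fan-out real
  ontologies show (a regular b-ary backbone is available via
  `attachment="balanced"`) — with partly multi-word labels and a dozen
  synonyms per concept, written as valid OBO.  By default the generator
  materializes the transitive `is_a` closure up to the predicate depth,
  the way GO/ChEBI-style distributions ship inferred transitive edges —
  so every ancestor that can decide a label is itself an injectable
  triple (the closure adds no reachability, so IC is unchanged);
* sentences mentioning two tagged candidate entities amid filler tokens;
  the gold label is "true" iff the two concepts share an `is_a` ancestor
  within depth 2 of the base hierarchy, flipped with probability ε
  (`label_noise`, default 0.1).  Concept pairs are sampled stratified
  (related ≈ 45 % before noise) so both outcomes are well represented
  regardless of ontology shape; `pair_sampling="uniform"` restores plain
  pair sampling;
* entities are mentioned under any of their surface forms (primary label
  or synonym).  This is the lever that makes ontology knowledge genuinely
  informative: the label depends on concept ancestry, the text shows only
  an arbitrary surface form, and only the ontology links surface forms to
  one node and its ancestors;
* a fraction β (`cue_strength`, default 0.2) of sentences carries one
  weakly label-correlated filler token, giving a knowledge-free model
  partial but never full signal;
* some sentences mention extra non-candidate concepts, exercising the
  contextual/targeted distinction.

Everything derives from one integer seed; a spec reproduces byte-identical
OBO and corpus files.

The benchmark (`kret.benchmark`) trains one tiny encoder per injection
mode — none / targeted / contextual — on the same seeded fixture, splits
and initialization, so F-measure gaps are attributable to the injected
knowledge.  Default problem sizes: 2 000 sentences, 40 concepts, encoder
with 2 layers, 2 heads, hidden 64, batch 32, 20 epochs, 5 paired seeds.

The benchmark encodes with `cls_sees_branches=True`.  The default
CLS-blind encoding routes knowledge to the classifier through a two-hop
attention path (branch → anchor in one layer, anchor → CLS in the next);
with a from-scratch encoder at this scale that composition is not reliably
learned, and ablations show the knowledge benefit only expresses itself
when the classification row can attend to branch tokens directly.  With a
pretrained encoder the default setting is the conservative choice; for the
from-scratch benchmark the one-hop exposure is.

**What the benchmark's effect actually is.**  Distillation experiments
with this exact architecture show that *pairwise* relational features —
"do these two arbitrary positions hold the same token" — are not learned
by a 2-layer, 2-head, hidden-64 encoder trained from scratch on ~1 200
sentences once sequences exceed roughly ten tokens; the contrast therefore
cannot and does not rest on coincidence detection.  What a model of this
size does learn well, at any sequence length, are *marginal* presence
features: which tokens are present and how each correlates with the label.
The fixture is designed so that exactly those features separate the arms.
The skewed family structure makes per-concept relatedness rates highly
variable (members of a large family are usually "true", isolated concepts
usually "false"), so ancestor identity is strongly predictive on its own.
The knowledge-injected model reads that identity directly off the ~40
canonical ancestor labels in its branches; the baseline must estimate the
same statistic from ~500 rare synonym surfaces, each seen a handful of
times in training.  The measured gap is thus the statistical-efficiency
value of canonicalizing mentions through an ontology — information the
text alone under-determines — which is the claim the benchmark is meant
to test in miniature.  Sentences are kept telegraphic (2–3 filler tokens)
so runs stay fast and the encoder operates well inside its workable
attention field.

**What the fixture does not emulate:** real biomedical syntax, negation
and speculation, nested or discontinuous entities, abbreviation ambiguity,
cross-sentence relations, and realistic label distributions.  Passing the
benchmark shows the pipeline can exploit ontology structure that text
alone under-determines; it does not predict absolute scores on DDI-style
corpora, which additionally require pretrained encoders.

## Numerical and degenerate-input choices

* `-inf` is `-1e9`; masked attention weights are ≤1e-6 after softmax.
* Branch-drop ties (equal IC) resolve toward the later branch in
  flattened order; span-resolution ties go length → leftmost → summed IC.
* Zero-variance significance inputs: equal means give p = 0.5, otherwise
  p ∈ {0, 1} by direction.
* Labels with fewer examples than splits are assigned round-robin with a
  warning.
* An empty lookup table or a sentence with no matches yields a branchless
  tree; a corpus line failing validation is collected into an error report
  rather than aborting the read.

## Known limitations

* The encoder is CPU-bound NumPy; it is sized for desk-scale experiments,
  not for fine-tuning pretrained BERT-family models, and the checkpoint
  loader maps only tensors that match this encoder's layout.
* IC ignores non-`is_a` relations, so in multi-relation sources
  (ChEBI/GO-like) specificity ranking reflects the subsumption hierarchy
  only.
* Sentence-pair (segment B) inputs and masked-language-model pretraining
  are out of scope; knowledge plays a role only at fine-tuning and
  prediction time.
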