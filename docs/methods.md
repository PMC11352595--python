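# Methods

`relmine` implements a staged, document-level biomedical relation-extraction
pipeline over abstracts: named entity recognition (NER), entity linking (EL),
relation extraction (RE) and novelty detection (ND), run sequentially so each
stage consumes the previous stage's output. This note records the models, the
design decisions taken where the design was genuinely open, the synthetic
study the package trains and evaluates on at desk scale, and the limits of
what those desk-scale results show.

## Data model

A document is a title and abstract; its full text is `title + " " +
abstract`, so abstract offsets start at `len(title) + 1` (the PubTator
convention used by NCBI corpus releases). Mentions are half-open character
spans with one of six entity types (Gene, Disease, Chemical, Species,
Variant, CellLine) and zero or more concept identifiers — zero meaning
unlinked, more than one meaning a composite mention. Relations are
*undirected* typed pairs of identifiers (eight types: Association,
Positive/Negative_Correlation, Bind, Comparison, Conversion, Cotreatment,
Drug_Interaction), held at the document level, optionally labeled Novel/No.
Identifier pairs are stored sorted so undirectedness is structural, not a
matching-time convention. Entity-type and novelty spellings vary across
corpus releases ("GeneOrGeneProduct", novelty "None"); parsing goes through
alias tables that normalise them onto the closed internal sets.

## Encoder

Every neural stage is generic over an encoder contract: deterministic
per-token final-layer vectors, a vocabulary that can grow special tokens, a
512-token cap, and gradients that flow back to the input embeddings. The
bundled `TinyEncoder` is a 2-layer, single-head, pre-norm transformer
(dim 32, FFN 64) over a word-level vocabulary, implemented on a small
reverse-mode autodiff engine written for this package (`relmine.autodiff`);
no installed library exposes input-level gradients for custom architectures,
and those gradients are required for adversarial training. Attention carries
a learned relative-position bias (clipped at ±16) initialised with a
locality decay of −0.3·|offset| (in the spirit of ALiBi's fixed slopes):
without it, softmax attention at random initialisation is uniform over the
sequence, marker tokens carry no local context, and pair classification
stalls in a majority-class plateau; with it, the same budget converges. The
bias is learned, so the prior can be unlearned where unhelpful.

The word-level vocabulary (lowercased; punctuation split off; unknown words
→ `[UNK]`) stands in for subword tokenization. Offsets are tracked through
pre-tokenization, so decoding is offset-exact. This is the main place the
desk-scale stand-in differs from a pretrained biomedical transformer: there
is no subword sharing, so generalisation to unseen word forms must come from
task structure, not morphology.

## NER

*Token classification* (the default head): BIO labels with typed outside
labels scoped by a task tag (`O-ALL`, `O-GENE`, ...), plus wrapper tokens
(`<ALL> ... </ALL>`) announcing which entity types the instance's source
corpus annotates. This lets corpora annotating different type subsets be
merged without unannotated types becoming false negatives. Defaults for real
corpora: lr 3e-5, batch 16, 22 epochs, cross entropy, softmax over a linear
head. Design choices the method description leaves open: wrapper tokens are
labeled `O-<tag>` but masked out of the loss; instances are whole abstracts
for the all-types corpus and sentences for single-type corpora; BIO repair
at decode time treats an orphan `I-` run as a mention and splits runs at a
type change (deterministic and local). Post-processing merges two same-type
mentions with nothing between them, and two Disease mentions separated by a
single non-slash character, repeating to a fixpoint; merged mentions reset
their identifiers since linking happens downstream.

*Span classification* (alternative head): all spans up to 30 tokens,
represented as [start vector; end vector; learned width embedding] and
classified by a two-layer feed-forward network into six types + none
(defaults lr 1e-5, 39 epochs, batch 32). The width embedding and the
negative-subsampling cap (4× positives per document, seeded) are this
package's choices; candidate counts grow quadratically and the original
description does not fix either. Overlaps are resolved greedily by
classifier confidence.

## Entity linking

Disease and Chemical mentions are normalised by dense retrieval: mention and
vocabulary synonyms are embedded by a residual CNN (frozen token embeddings
taken from the contextual model; blocks of a multi-width convolution bank
(widths 1/3/5), position-wise feed-forward and residual connection; max,
mean or attention pooling) and matched by cosine. Tuned defaults follow the
per-type optima (Disease: attention pooling, 4 blocks; Chemical: max
pooling, 3 blocks; both lr 1e-3, feature 256, dropout 0.25; 300 filters,
100 epochs, evaluation every 5). The training objective is not fixed by the
method description; this package uses an online hard-negative triplet loss
on cosine similarity (margin 0.2), with negatives mined from the current
index, refreshed at every evaluation interval. Text is normalised
(lowercase, collapse whitespace, strip outer punctuation) before indexing
and encoding. Gold (identifier, surface) pairs from the training corpus are
appended to the index before development-set evaluation.

Other types go through an external linker's predictions: exact span match
first, then partial overlap of the same type (largest overlap, then
leftmost — the precise rule is this package's choice, the source method says
only "partial matching"), then an exact-surface lookup dictionary built from
the external predictions. Retrieval takes top-1 with no similarity floor by
default (an optional floor is exposed). Ties in retrieval break by (score
descending, identifier ascending).

## Relation extraction

For each candidate pair of entities (unordered identifier pairs whose type
combination has at least one training relation), every mention of both
entities is wrapped in a single untyped marker pair `[E] ... [/E]`, one
marked sequence per candidate pair. The open-marker final-layer vector
represents its mention; the mention pair with the highest dot product is
selected (max pooling over mention pairs). Undirected classification uses
two directional representations, `[e1; e2; e1⊙e2]` and `[e2; e1; e2⊙e1]`,
one shared linear classifier over nine labels (eight types + NoRelation,
NoRelation ordered last; ties break to the lowest label index), training
loss = sum of both cross entropies, prediction = argmax of summed logits —
which makes predictions exactly invariant under exchanging the two entities.
Defaults for real corpora: 5 epochs, lr 3e-5, batch 32, Adam.

Adversarial training perturbs the input token embeddings by projected
gradient ascent: three ascent steps (the step count is fixed by the method),
each of size 0.3 along the normalised gradient, projected onto an L2 ball of
radius 1.0 — step size, radius and norm are this package's choices, exposed
in `AdversarialConfig` — followed by one weight update on the loss at the
final perturbation. The perturbation applies to the whole input embedding
matrix, marker tokens included. Negative (NoRelation) candidate pairs are
not subsampled by default: abstracts are small, so the candidate set per
document is manageable.

## Novelty detection

Novelty classification reuses the marker machinery but pools *all* mention
markers of each entity coordinate-wise with logsumexp (a smooth upper bound
of max: max(x) ≤ pool(x) ≤ max(x) + ln n), concatenates the two pooled
vectors (entity order canonicalised by sorted identifier so the
representation is well defined) and applies a binary linear classifier
(Novel/No; defaults 4 epochs, lr 2e-5, batch 32, Adam). Training uses only
pairs carrying a gold relation — the inputs are already known to be related,
so there are no negative examples; the data loader enforces this. ND
fine-tunes its own encoder copy, separate from RE.

## Evaluation

All tasks are scored by document-level tuple matching with micro-averaged
P/R/F1 on the percent scale, reported at two decimals (half-up; computation
is full precision). NER matches exact (span, type); span-overlapping
same-type non-exact pairs are reported as "partial" but count as errors. EL
matches (document, type, identifier) tuples as per-document sets; composite
mentions expand to multiple tuples. Relation matching keys on the sorted
identifier pair plus, by flag, the relation type and the novelty label.
Retrieval quality is top-k accuracy (k ∈ {1, 5, 10, 20}). Significance:
percentile bootstrap of the overall-F1 difference (100 documents with
replacement, 1000 replicates, seeded single generator) and McNemar's test on
discordant counts (exact binomial two-sided by default, chi-square with
continuity correction by flag). The RE error breakdown splits false
positives (and, separately, false negatives) into type confusion — the pair
is truly related but typed wrong — versus pairs with no relation at all.

## Synthetic study

The generator builds a deterministic toy world from a seed: an inventory of
entities per type (12 genes, 10 diseases, 8 chemicals, 4 species, 5
variants, 3 cell lines by default), each with a unique pronounceable
pseudo-word base and 2–5 vocabulary synonyms (base, cased and suffixed
forms); plural and abbreviated forms occur only in running text, so the
linker must learn them from training mentions rather than exact lookup.
Documents (200 train / 50 dev, seed 7 by default) hold 3–5 entities, 1–3
relations realised as trigger-phrase sentences ("X markedly suppresses Y"),
extra mention sentences, and filler. Relation types are drawn with the
heavily skewed weights seen in real benchmarks (three dominant types ≈ 95%),
so class imbalance is exercised. Novelty is cued lexically ("as previously
reported" ⇒ No, probability 0.4). Noise knobs: a 5% per-document chance of
an unlinked stray mention, optional span-boundary trimming (off by default),
and an external-linker emulation that drops 8% of gold links. A rule-based
trigger reader serves as an upper-bound oracle: on a zero-noise corpus it
recovers the planted relations at F1 = 100, confirming the corpus is
noiseless when configured so.

Desk-scale training configs (in `desk_scale_configs`) differ from the
real-corpus defaults because the tiny encoder trains from random
initialisation rather than fine-tuning a pretrained model: learning rates
around 1e-3–3e-3, 10 epochs for NER and RE, 8 for ND, 30 for the linker with
reduced width (feature 64, 32 filters, 2 blocks). These sizes complete the
full pipeline — generation, four training stages, prediction and scoring —
in a few minutes on one CPU.

What passing at desk scale shows: the mechanisms (tagging scheme, marker
pooling, bidirectional scoring, retrieval, pooling bounds, matching rules)
are implemented correctly and can recover planted structure end-to-end. What
it does not show: performance on real biomedical language, where surface
ambiguity, discontinuous and nested mentions, cross-sentence inference and
vocabulary scale dominate — none of which the generator emulates.

## Numerical choices and degenerate inputs

Logsumexp pooling and cross entropy are max-shifted for stability. Cosine
retrieval unit-normalises with a 1e-12 floor. Empty mention text after
normalisation is an error for the linker encoder and skips lookup in hybrid
linking. P/R/F1 conventions: 0 when a denominator is 0. McNemar returns
p = 1.0 for zero discordance. Training is deterministic given the seed —
all randomness flows through seeded numpy generators — so pipeline reruns
are byte-identical, which the tests assert.

## Known limitations

- The tiny encoder's word-level vocabulary cannot represent unseen word
  forms; real deployments should plug in a pretrained subword encoder
  honouring the encoder contract.
- Sequences longer than 512 tokens are hard-truncated with a warning;
  mentions beyond the cut are dropped from training labels.
- The manual EL error taxonomy (incomplete synset, contextual entity,
  overlapped entity, abbreviation, hypernym/hyponym) is documented but not
  automated; context-sensitive disambiguation is out of scope — the mention
  string alone is encoded.
- BioC XML, full-text articles, cross-document relations and relation
  direction recovery are out of scope.
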