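# Methods

## Task and data model

The system labels ordered pairs of annotated entities (clinical events and
TIMEX3 time expressions) in discharge summaries with one of 12 temporal
relation types, or decides that no relation holds. A document has two
sections (History of Present Illness, Hospital Course), each anchored by a
section creation time (the admission and discharge dates). Character
offsets are 0-based and half-open throughout. Polarity and modality are
carried as open strings with documented canonical values (POS/NEG,
FACTUAL/...), not closed enums.

Relation inversion is an involution over the 12 types. Five inverse pairs
are fixed by the type definitions (Before↔After, Before_Overlap↔
Overlap_After, During↔During_Inv, Begins↔Begun_By, Ends↔Ended_By);
Simultaneous is symmetric by definition, and **Overlap is treated as
self-inverse by convention** — the taxonomy fixes no inverse for it, and the
involution property forces a symmetric choice. The 12 → 3 merge sends
{Overlap, Simultaneous, During} → Overlap′, {Before, Before_Overlap,
Ended_By} → Before′, {After, Begun_By} → After′; the remaining four types
invert the pair first and then merge.

## Linguistic annotations

Constituency trees, dependencies, SRL frames and discourse relations are
consumed as data from a JSON sidecar, one object per document, with every
layer validated against the document text and tokenization on load. The
fallback annotator (whitespace/punctuation tokenization, suffix-rule POS,
flat one-level trees, empty semantic layers) exists so the pipeline always
runs; it is deliberately low-fidelity and features that need the missing
layers degrade to NULL rather than erroring.

Head selection is deterministic: the rightmost noun/verb/adjective token in
the entity span, else the last overlapping token. "Entity is in a discourse
argument" means the head token's span lies inside the argument's character
interval. "Headed by a PP" is read as: the entity's minimal covering node
is labeled PP; "governed by a PP/VP" as: the nearest such ancestor.

## Features

Features are named `family.name`, with set-valued content (context n-grams,
between-words) folded into the name as binary flags. NULL is a legal
categorical value; no extractor raises on a missing layer. Categorical
features are one-hot encoded by a vocabulary frozen at training time
(`DictVectorizer`); unseen test values map to all-zeros.

The per-family membership follows the published inventory (six baseline
families; pairwise; 8 thesaurus + 8 WordNet-style binary relation flags in
both directions; 12 numbered-argument + 8 modifier-argument SRL flags; 4
discourse-sense features; the medical-relation label plus the reusable flat
groups). Exact original feature *counts* per family cannot be reconciled
token-for-token without the original implementation; family-faithful
coverage is the contract and counts are observable via
`FeatureVector.by_family`.

The medical semantic-relation features are gated to TREATMENT–PROBLEM,
TEST–PROBLEM and PROBLEM–PROBLEM pairs. The underlying relation classifier
is trained on intra-sentential pairs only, so the gate defaults to
intra-sentential application (a constructor flag flips it for
cross-sentence pairs; predictions there are out-of-distribution).

## The semantic-relation ensemble

Eleven classes (eight substantive + three no-relation). Three classifiers:

* **Flat**: linear SVM, C = 10 000, over 37 feature groups in five
  categories (Context, Similarity, Single-concept, Wikipedia from an
  offline link/category table, Vicinity). The Similarity groups encode, for
  each of five sequence representations of the pair, the fraction of its
  k = 200 nearest neighbors (token-level Levenshtein) in each class.
* **Tree**: 11 one-vs-rest SVMs (C = 100) with a convolution
  (shared-subtree counting) kernel, decay λ = 0.4, over *simple expansion
  trees*: the parse nodes on the shortest path between the entities plus
  those nodes' immediate non-leaf children, with the entity-covering node
  labels replaced by the entity types. λ = 0.4 is standard convolution-
  kernel practice; it is configurable. A matching leaf pair contributes λ,
  so K(t, t) > 0 even for trivial trees.
* **k-NN**: 200 nearest neighbors over the word-lemma sequence
  representation, vote weights 0.5 for the nearest and 0.5/199 for each of
  the rest. Ties are broken by (distance, bank index) for determinism. A
  bank smaller than k degrades gracefully: the nearest still weighs 0.5 and
  the remainder split 0.5 evenly, with a warning.

Each classifier's 11 confidences are min-max scaled per instance to [0, 1]
and normalized to sum 1 (the scaling map is otherwise unconstrained; an
all-equal vector becomes uniform), then combined with weights
(0.4, 0.5, 0.1) for (tree, flat, knn). The no-relation classes are
downsampled before training: each is randomly capped (seeded) at 2× the
largest substantive class, preserving the negatives' dominance while
bounding the skew. Classes absent from training contribute probability 0
with a warning.

Evaluation is micro P/R/F over the eight substantive classes; correct
no-relation predictions are not counted.

## Rules and their combination with learning

Rules are first-match decision rules over feature values, with a
conjunction/disjunction/negation DSL (equality, inequality, regex over the
inter-entity token string, entity-type and scheme tests; no arithmetic).
Accuracy is measured on the gold-related training instances as
correct/applied; ordering is by decreasing accuracy with ties broken by
higher applied count, then id (the ordering is recomputed from measured
accuracy, so file order never matters). The shipped starter ruleset encodes
the motivating patterns: antonymous clauses joined by "but" (asynchronous →
Before), an SRL A4 destination argument (Begins), implicit RESTATEMENT
between PROBLEM sentences (Overlap), explicit "thereafter"/ASYNCHRONOUS
(Before), TrIP → Ended_By, TeCP/TeRP → Overlap_After, PIP → Simultaneous,
comma-series unrelated PROBLEMs (Overlap), "on <date>" anchoring
(Simultaneous), and an evidential "complained of" pattern (Overlap_After).
Intra-sentential rules carry an explicit same-sentence guard so they cannot
fire on cross-sentence candidates during identification.

Two combination modes: every rule's prediction as an additional categorical
feature (all rules, regardless of accuracy), and the hybrid — rules with
accuracy ≥ 0.75 first, the rule-feature classifier for the rest. Pure-rule
architectures must still label rule-uncovered instances; they take the
scheme's majority (positive) training label.

## Specialized classifiers and identification

Instance schemes bound the negative-class skew: intra-sentence negatives
only from adjacent (no intervening entity) unrelated pairs; adjacent-
sentence negatives only from main-event pairs (first and last event of a
sentence); coreferent pairs (naive coreference: equal head lemmas,
case-insensitive) at any distance, negatives again restricted to main
events. Test candidates are built exactly like the negatives. Event–time
pairs in different sentences are not routed to any classifier and are
skipped.

Each scheme's multiclass SVM picks its regularization constant C from
{0.01, 0.1, 1, 10, 100, 1000, 10000} on a seeded 20% held-out split, then
retrains on all instances.

Identification labels every candidate pair HAS/NO relation. Training
negatives are pruned: intra-sentence pairs whose heads are more than 30
tokens apart and cross-sentence pairs beyond 1 sentence (unless
coreferent) are dropped — the caps mirror the locality the positive
schemes impose and are configurable. Three identifier modes share one SVM
machinery over precomputed kernels: FLAT (normalized linear kernel on the
flat features), TREE (normalized convolution kernel on simple expansion
trees, with the *parent* of each entity node relabeled by the entity
attributes; instances without a parse fragment fall back to the flat
kernel), and COMPOSITE (α·K_flat + (1−α)·K_tree, α = 0.5 by default; the
mixture formula is this package's choice as the published description
names a composite kernel without one). α = 1 reproduces FLAT and α = 0
reproduces TREE on parsed instances by construction.

The decision threshold on the signed distance defaults to 0. Thresholds
are tuned per scheme, independently, on a development split, by grid
search over the observed dev signed distances (plus 0, so tuned dev F
never drops below untuned); separate thresholds maximize micro and
macro F. At prediction time the hybrid identifier applies positive rules
(all classification rules), then negative rules, then the learned
identifier.

## Scoring

12-class scoring matches a predicted link to a gold link when the pair
agrees directly or with order and label both inverted. Micro F is
instance-weighted; when predicted and gold pair sets coincide it equals
accuracy. Macro F averages per-class F over exactly the 12 types; a class
absent from both sides contributes 0 with a warning.

The 3-class scorer verifies links in the other side's temporal closure.
Closure augments inverses (Before′↔After′, Overlap′ symmetric) and
composes Before′ chains transitively to a fixed point. Only sound rules
are used — no Overlap′∘Before′ inference — because the official scorer's
exact rule table is not published; the rule set is isolated in one
function and swappable. Contradictory assertions are retained: the scorer
is containment-based, not consistency-based.

## Synthetic fixtures

Templates transcribe the worked clinical constructions (event/time
anchoring, evidential "complained of", antonymous clauses, "discharged to
rehab", treatment-resolves-problem, implicit restatement, explicit
"thereafter", comma-separated problem series, problem-indicates-problem,
test-for-problem, test-reveals-problem, and the five-way sequence-
generation reference sentence), each with a hand-written sidecar recipe —
POS tags, a plausible constituency tree, dependencies, SRL frames and
discourse relations consistent with the pattern — plus a planted gold
temporal link and, where applicable, a semantic-relation label covering
all 11 classes across the template inventory. One template reproduces the
reference sentence's printed tags verbatim, including its idiosyncratic
comma tag, which the system treats as an opaque string. Word-order in the
treatment-resolves-problem template puts the TREATMENT first so the
text-ordered instance label is Ended_By, matching the rule's output
exactly; the asserted relation is unchanged up to inversion.

Documents have two sections, admission/discharge SECTIMEs, and a seeded
template mix; regeneration from (seed, mix, counts) is deterministic. The
noise planter flips a Bernoulli(rate) fraction of gold fine labels to a
uniformly random *different* type (so measured rule accuracy has
expectation 1 − rate) and records every flip in the manifest.

What the fixtures do **not** emulate: lexical ambiguity, annotation
incompleteness and inconsistency, long-range narrative structure, parser
noise, and the heavy class imbalance of real clinical corpora. Perfect
recovery on fixtures therefore demonstrates the correctness of the
machinery — instance generation, featurization, rule semantics, learning,
identification, scoring — not clinical-grade accuracy; the restricted
corpora the published scores rest on cannot be redistributed, and no
corpus-level score is claimed here.

## Problem sizes and numerical choices

Default study sizes: 50 documents × 8 template instances for end-to-end
recovery; 24 + 8 documents for ensemble train/test; 1000 documents × 10
instances (≈ 10 000 labeled pairs, ≥ 800 applications per rule) for the
noise-accuracy measurement, which puts the binomial standard error of each
measured accuracy near 0.015 so the (0.70, 0.80) window is a reliable
check. Probability vectors are validated to sum to 1 within 1e-9. Sparse
feature matrices are downcast to 32-bit indices for the SVM backends. All
SVMs fix `random_state` where the solver uses one; every sampling step
(template choice, downsampling, splits, noise) draws from a seeded
`random.Random`.
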