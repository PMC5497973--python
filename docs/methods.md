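# Methods

This document describes the factuality model implemented by `semfact`:
its data structures, the composition rules, the numeric choices behind
them, the synthetic fixture generator, and the known failure modes.

## 1. Task and representation

The input is a document with:

- **entities** — text-bound spans with semantic-type and concept
  metadata (brat `T`/`N` lines);
- **predications** — subject–predicate–object triples anchored to a
  predicate trigger span, each with an *indicator type* (`verb`,
  `nominalization`, `preposition`, `modifier-head`, `appositive`,
  `INFER`) (brat `E` lines, `IndicatorType` attributes);
- **a dependency parse** in CoNLL-U with character offsets in `MISC`.

The output per predication is one of seven factuality values —
`fact`, `probable`, `possible`, `doubtful`, `counterfact`,
`uncommitted`, `conditional` — plus, internally, an **enhanced
predication** `[P, S, MV_scale, Args]`: the predicate, the source the
claim is attributed to (`WR` = the writer), a **scalar modality value
(MV)** in [0, 1] on one of five scales (epistemic, deontic, potential,
success, interrogative), and the argument list. Nested *embedding
predications* represent triggers that take other predications in their
scope (e.g. `suggest:deductive(em1, T1)`).

## 2. Embedding dictionary

`semfact/data/embedding_dictionary.yaml` lists trigger lemmas with POS
and one or more senses. Each sense carries:

- `category`: a path under `modal.*` (leaves: speculative, deductive,
  demonstrative, counterfactive, permissive, obligative, potential,
  volitive, success, interrogative) or `valence_shifter.scale_shifter.*`
  (negation, intensifier, diminisher);
- `dep_types`: the dependency relations the sense licenses for scope
  (e.g. `AUX` for modal auxiliaries, `CCOMP`/`DOBJ` for clausal and
  nominal complements, `NEG` for negation);
- for modal senses a `prior` MV; for shifters a `shift` function.

Priors follow a coarse certainty ordering: speculative 0.5, permissive
0.6, deductive 0.75, obligative 0.8, demonstrative and interrogative
1.0, counterfactive 0.0. Lookup normalizes case and collapses inflected
Penn tags (`VBZ`→`VB`, `NNS`→`NN`, …); multiword triggers ("rule out")
are indexed by their head.

## 3. Graph construction

`read_dependencies` parses CoNLL-U (XPOS preferred over UPOS, offsets
from `MISC`). `collapse` rewrites `prep`+`pobj` (and UD `case`+`obl`/
`nmod`) into `prep_X` edges and `cc`+`conj` into `conj_X`, keeping an
anchor map from removed function words.

`transform_to_semantic` then builds a directed semantic graph:

- `AUX`, `AUXPASS` and `NEG` edges are always inverted so the verb
  governs its auxiliaries and negation (they form one verb complex);
- `ADVMOD`, `MARK`, `DET`, `PRECONJ`, `AMOD` edges are inverted only
  when the dependent is a dictionary trigger, so that e.g. "whether"
  scopes over its clause;
- material shared across a coordination is distributed to every
  conjunct;
- entity and predication spans are attached to their head token
  (`AlignmentError` if a span crosses sentences or misses the parse).

`prune_trigger_nodes` removes trigger senses whose token is covered by
an entity or predicate span (e.g. "potential" when it is itself an
annotated entity), so a word never acts as both argument and trigger.
Pruning only touches the sense table; topology is preserved, and the
operation is idempotent.

## 4. Composition

For each predication, innermost-first:

1. the enhanced predication starts at MV 1.0, epistemic, source `WR`;
2. among modal triggers whose licensed dependency path reaches the
   predicate, the **innermost** (graph-closest) one assigns its prior MV
   and scale. Distance is measured over the semantic graph with
   `AUX`/`AUXPASS`/`NEG` edges at cost 0 — an auxiliary is part of the
   verb complex, not a step away from it — and ties break by ascending
   character offset;
3. scale shifters apply: negation maps v to 1−v; intensifiers add 0.15
   and diminishers subtract 0.15, clipped to [0, 1];
4. negation that immediately scopes a modal trigger negates that
   trigger's prior instead of the predication ("do not support": 1 −
   0.75 = 0.25);
5. negation of an argument (rather than the predicate) flips only the
   predications involving that argument ("X2, but not X, inhibited …"
   yields counterfact for X and fact for X2);
6. **path constraint**: an adverb/modal-auxiliary trigger only takes
   scope if no non-light verb intervenes on the path to the predicate
   (light verbs: "have", "associate"). "was not designed to investigate
   the effect" therefore does not negate the effect predication;
7. each remaining outer trigger emits an embedding predication; triggers
   of reporting/deductive type attribute their scope to their
   grammatical subject (source = that entity) rather than the writer.

## 5. Mapping to factuality values

Rule precedence for the final label:

1. `ISA` predications → `fact`;
2. `modifier-head` and `preposition` indicators → `fact` (such
   predications are presented as given, whatever the composed MV);
3. `INFER` predications inherit the value of the non-inferred
   predication over the same argument pair (warn and fall through if
   none exists);
4. scalar mapping by scale:
   - epistemic / success: 1 → `fact`; [0.65, 1) → `probable`;
     (0.25, 0.65) → `possible`; (0, 0.25] → `doubtful`; 0 →
     `counterfact`;
   - potential: > 0 → `probable`; 0 → `counterfact`;
   - interrogative: 1 → `uncommitted`;
   - deontic: (0.65, 1) → `uncommitted`;
5. anything unmapped falls back to `fact` (the majority class).

`conditional` is never predicted; it marks predications whose truth
depends on another predication, which requires discourse-level
reasoning outside this rule inventory.

For the ML baseline features, MV is discretized into 5 bins per scale
(1 → 5, [0.65, 1) → 4, (0.25, 0.65) → 3, (0, 0.25] → 2, 0 → 1), named
e.g. `EPISTEMIC_4` for MV 0.9. A legacy three-level
certainty × polarity mapping (`map_certainty_polarity`) is provided for
comparison with older rule systems.

## 6. ML baseline

`FactualityClassifier` is a one-vs-rest linear SVM (LIBLINEAR, C = 2,
fixed seed) over sparse feature dictionaries:

- **replicated** set: n-grams (up to 4) over the interleaved
  lemma/relation shortest path between the arguments; 2-step trigger
  paths toward the predicate; lemma n-grams in a ±3-token window around
  each argument; sentence position;
- **additional** set adds: argument–predicate and argument–argument
  path lengths, between-argument lemma n-grams, dominating embedding
  triggers, predicate and indicator types, the discretized MV feature,
  and an in-title flag.

A single-class training corpus degenerates (with a warning) to a
constant predictor.

## 7. Evaluation and fixtures

`evaluate` reports per-class precision/recall/F1 (zero denominators
report 0) and accuracy; `cohen_kappa` implements unweighted κ in closed
form (defined as 1.0 under perfect observed agreement).
`majority_baseline` labels every true-positive predication `fact`.

Because the reference corpus is license-restricted, `semfact` ships a
**fixture generator**: a bank of hand-parsed sentence templates per
class, slot-filled with drug/disease/protein names, emitted as
.txt/.ann/.conllu triples. Class counts follow configurable proportions
(default: a realistic, heavily fact-skewed distribution) by
largest-remainder allocation, so the split is exact at any corpus size;
template and filler choice are drawn from a seeded generator, making
corpora byte-identical under the same seed. The templates are chosen so
that the *engine genuinely recovers* each intended label through the
composition rules (the generator and the engine share no code path for
labels); end-to-end label recovery on generated corpora is a standing
parameter-recovery test (≥95%).

## 8. Known limitations

- **Verbless titles** ("Plasmapheresis for collagen diseases.") are
  annotated `uncommitted`, but a bare preposition-indicated predication
  composes to MV 1.0 epistemic and the preposition override maps it to
  `fact`. A title-specific rule was considered and rejected as
  unprincipled; the corresponding regression test is left failing on
  purpose.
- **`conditional`** is out of scope for prediction (see §5); its
  regression sentence composes to `fact` by fallback, and the fixture
  generator's lone conditional template is likewise expected to come
  out `fact`.
- **Dictionary coverage**: "rule out" licenses clausal/nominal
  complements but not `PREP_AS`; "could not rule out X as a cause"
  therefore keeps MV 1.0 and surfaces as `fact` instead of
  `counterfact`. This coverage gap is reproduced deliberately by a
  worked example and its test.
- The ±0.15 intensifier/diminisher step is a fixed, untuned constant;
  values are clipped to [0, 1], so intensifying an MV of 1.0 is a
  no-op.
- Scope resolution assumes a single head per span and one sentence per
  predication; cross-sentence predications are rejected rather than
  guessed.
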