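# semfact

Compositional, rule-based factuality assignment for biomedical
subject–predicate–object predications, plus a linear-SVM baseline and an
evaluation harness.

A relation extractor can tell you that a sentence asserts
`TREATS(Ibuprofen, breast cancer)`, but not whether the text presents
that relation as an established fact, a hypothesis, a negated claim, or a
question. `semfact` assigns one of seven *factuality values* to each
predication — `fact`, `probable`, `possible`, `doubtful`, `counterfact`,
`uncommitted`, `conditional` — by composing lexical *embedding triggers*
("may", "suggest", "not", "whether", …) over a semantic dependency graph
of the sentence.

## How it works

1. **Lexicon** (`semfact.lexicon`) — a YAML dictionary of embedding
   triggers. Each sense has a category (modal leaf such as
   `epistemic.speculative`, or a `scale_shifter` such as negation), the
   dependency relations it licenses for scope, and, for modals, a prior
   scalar *modality value* (MV) in [0, 1].
2. **Graphs** (`semfact.graphs`) — a CoNLL-U reader, collapsing of
   preposition/conjunction relations, and a transformation to a semantic
   graph in which auxiliaries and negation are inverted under their
   verbs and coordinated structure is distributed.
3. **Composition** (`semfact.composition`) — every predication starts at
   MV 1.0 on the epistemic scale; the innermost scoping modal trigger
   assigns its prior, scale shifters negate/intensify/diminish it
   (clipped to [0, 1]), and nested triggers become *embedding
   predications* with attributed sources (`WR` is the document writer).
4. **Factuality** (`semfact.factuality`) — the composed (scale, MV) pair
   maps to a factuality value; `ISA`, modifier-head and preposition
   indicators override to `fact`; inferred predications inherit from
   their partner.
5. **ML baseline** (`semfact.ml_baseline`) — a linear SVM (C=2) over
   shortest-path, trigger-path, token-window and sentence-position
   features, with an extended feature set that adds path lengths,
   dominating triggers and the discretized MV.
6. **Corpus & evaluation** (`semfact.corpus_eval`) — brat standoff
   (.txt/.ann) and CoNLL-U I/O, per-class precision/recall/F1, Cohen's
   kappa, a majority baseline, and a seeded generator of synthetic
   fixture corpora with a realistic label distribution.

## Worked example

```bash
semfact simulate --n 5 --seed 1 --out corpus/      # synthetic corpus
semfact assign corpus/ --out assigned/             # rule-based labels
semfact evaluate --gold corpus/ --pred assigned/labels.tsv --kappa
```

Assigning a single document (text, standoff annotations, and dependency
parse side by side):

```bash
$ semfact assign --conllu doc.conllu --ann doc.ann
ibuprofen-chemoprevention	E1	possible
```

For *"These results suggest that Ibuprofen may have potential in the
chemoprevention and treatment of breast cancer."* the composition
produces three enhanced predications: the TREATS predication at MV
0.5 (epistemic), a speculative embedding for "may" at 0.75, and a
writer-attributed deductive embedding for "suggest" at 1.0; MV 0.5 maps
to the final label `possible`. With `--out`, the assigned standoff
carries both the label and the scalar value:

```
A1	IndicatorType E1 nominalization
A2	Factuality E1 possible
A3	MV E1 0.5_epistemic
```

Training and running the SVM baseline:

```bash
semfact train corpus/ --model model.pkl --features additional
semfact predict corpus/ --model model.pkl --out pred.tsv
```

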