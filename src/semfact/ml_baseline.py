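"""Supervised comparison baseline: a linear SVM over path features.

The classifier predicts the factuality value of each predication
directly from features of the sentence and the semantic document graph,
with no composition at test time. Two feature sets are supported:

* ``replicated`` -- dependency-path n-grams (n = 1..4) between the
  predication's arguments, 2-step path n-grams from each embedding
  trigger toward the predicate, lemma n-grams in a +/-3-token window
  around each argument, and the absolute/relative sentence position;
* ``additional`` -- the replicated set plus semantic-graph path lengths,
  lemma uni/bigrams between the arguments, the list of dominating
  embedding triggers, an in-title flag, the predicate and indicator
  types, and the discretized scalar modality value produced by the
  rule-based composition (its 5-bin name, e.g. EPISTEMIC_4).

Training uses a one-vs-rest linear SVM (LIBLINEAR) with C = 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .composition import semrep_predications
from .factuality import FactualityValue, discretize
from .graphs import DEFAULT_LIGHT_VERBS, path_between
from .lexicon import EmbeddingDictionary, load_dictionary
from .pipeline import AnalysisResult, analyze_document

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "FactualityClassifier",
    "extract_features",
    "FEATURE_SETS",
]

FEATURE_SETS = ("replicated", "additional")


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the linear SVM baseline."""

    C: float = 2.0
    feature_set: str = "replicated"
    seed: int = 13

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(
                f"unknown feature set {self.feature_set!r}; "
                f"expected one of {FEATURE_SETS}"
            )
        if self.C <= 0:
            raise ValueError("C must be positive")


def _ngrams(items: Sequence[str], n_max: int, n_min: int = 1) -> list[str]:
    out = []
    for n in range(n_min, n_max + 1):
        for i in range(len(items) - n + 1):
            out.append("__".join(items[i : i + n]))
    return out


def _path_items(sg, a, b) -> list[str] | None:
    """Interleaved lemma/edge-label sequence along the path a..b."""
    path = path_between(sg, a, b)
    if path is None:
        return None
    items = [sg.token(a).lemma.lower()]
    cur = a
    for u, v, lab in path:
        nxt = v if u == cur else u
        items.append(lab)
        items.append(sg.token(nxt).lemma.lower())
        cur = nxt
    return items


def _sentence_tokens(sg, sent: int) -> list:
    return [n for n in sg.nodes() if n[0] == sent]


def extract_features(
    doc,
    analysis: AnalysisResult,
    feature_set: str = "replicated",
) -> dict[str, dict[str, float]]:
    """Per-predication feature dictionaries (namespaced sparse features)."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    sg = analysis.graph
    n_sents = max((n[0] for n in sg.nodes()), default=0) + 1

    ent_node = {}
    for node, ents in sg.entities.items():
        for e in ents:
            ent_node[e.id] = node
    pred_node = {}
    for node, plist in sg.predications.items():
        for p in plist:
            pred_node[p.id] = node

    out: dict[str, dict[str, float]] = {}
    for ep in semrep_predications(analysis.enhanced):
        pred = ep.predication
        feats: dict[str, float] = {}

        def bump(name: str) -> None:
            feats[name] = feats.get(name, 0.0) + 1.0

        p_node = pred_node[pred.id]
        s_node = ent_node.get(pred.subject)
        o_node = ent_node.get(pred.object)
        sent = p_node[0]
        toks = _sentence_tokens(sg, sent)
        lemmas = [sg.token(n).lemma.lower() for n in toks]

        # shortest-path n-grams between the arguments
        if s_node is not None and o_node is not None:
            items = _path_items(sg, s_node, o_node)
            if items is not None:
                for g in _ngrams(items, 4):
                    bump(f"shortestpath:{g}")

        # 2-step path n-grams from each trigger toward the predicate
        for t_node in sorted(sg.senses):
            path = path_between(sg, t_node, p_node)
            if path is not None and 0 < len(path) <= 2:
                items = _path_items(sg, t_node, p_node) or []
                for g in _ngrams(items, 3):
                    bump(f"trigger:{g}")

        # +/-3-token lemma window n-grams around each argument
        for role, node in (("subj", s_node), ("obj", o_node)):
            if node is None or node[0] != sent:
                continue
            i = node[1] - 1
            window = lemmas[max(0, i - 3) : i + 4]
            for g in _ngrams(window, 2):
                bump(f"pair:{role}:{g}")

        # sentence position
        bump(f"sentence:abs:{sent}")
        feats["sentence:rel"] = (sent + 1) / n_sents

        if feature_set == "additional":
            for name, node in (("subj", s_node), ("obj", o_node)):
                if node is None:
                    continue
                path = path_between(sg, node, p_node)
                if path is not None:
                    feats[f"pathlen:{name}"] = float(len(path))
            if s_node is not None and o_node is not None:
                path = path_between(sg, s_node, o_node)
                if path is not None:
                    feats["pathlen:pair"] = float(len(path))
                lo, hi = sorted((s_node[1], o_node[1]))
                between = lemmas[lo : hi - 1]
                for g in _ngrams(between, 2):
                    bump(f"between:{g}")
            for em in analysis.enhanced:
                if em.kind == "embedding":
                    bump(f"domtrig:{em.predicate}")
            bump(f"predtype:{pred.predicate_type}")
            bump(f"indtype:{pred.indicator_type}")
            feats[f"smv:{discretize(ep.scale, ep.mv).name}"] = 1.0
            feats["title:in_title"] = 1.0 if getattr(doc, "in_title", False) else 0.0

        out[pred.id] = feats
    return out


def _to_int32_indices(X):
    """LIBLINEAR only accepts 32-bit sparse indices."""
    X = X.tocsr()
    X.indices = X.indices.astype("int32")
    X.indptr = X.indptr.astype("int32")
    return X


class FactualityClassifier:
    """One-vs-rest linear SVM over the extracted feature dictionaries."""

    def __init__(
        self,
        config: ClassifierConfig | None = None,
        dictionary: EmbeddingDictionary | None = None,
        light_verbs: frozenset[str] = DEFAULT_LIGHT_VERBS,
    ) -> None:
        self.config = config or ClassifierConfig()
        self.dictionary = dictionary or load_dictionary()
        self.light_verbs = light_verbs
        self._pipeline = None
        self._single_class: FactualityValue | None = None

    # -- helpers -----------------------------------------------------------
    def _featurize_corpus(
        self, docs: Iterable
    ) -> tuple[list[tuple[str, str]], list[dict[str, float]], list[str]]:
        keys: list[tuple[str, str]] = []
        X: list[dict[str, float]] = []
        y: list[str] = []
        for doc in docs:
            analysis = analyze_document(
                doc, dictionary=self.dictionary, light_verbs=self.light_verbs
            )
            feats = extract_features(doc, analysis, self.config.feature_set)
            for pred in doc.true_positive_predications():
                keys.append((doc.id, pred.id))
                X.append(feats[pred.id])
                label = doc.gold.get(pred.id)
                y.append(label.value if label is not None else "")
        return keys, X, y

    # -- API ---------------------------------------------------------------
    def train(self, docs: Iterable) -> "FactualityClassifier":
        from sklearn.feature_extraction import DictVectorizer
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import FunctionTransformer
        from sklearn.svm import LinearSVC

        _keys, X, y = self._featurize_corpus(docs)
        if not X:
            raise ValueError("no labeled predications to train on")
        if len(set(y)) == 1:
            # degenerate corpus: remember the single observed class
            self._single_class = FactualityValue(y[0])
            self._pipeline = None
            logger.warning(
                "training corpus has a single class %s; "
                "classifier degenerates to a constant predictor",
                y[0],
            )
            return self
        self._single_class = None
        self._pipeline = Pipeline(
            [
                ("vec", DictVectorizer()),
                ("cast", FunctionTransformer(_to_int32_indices, accept_sparse=True)),
                (
                    "svm",
                    LinearSVC(
                        C=self.config.C,
                        random_state=self.config.seed,
                        dual=True,
                        max_iter=10000,
                    ),
                ),
            ]
        )
        self._pipeline.fit(X, y)
        return self

    def predict(self, docs: Iterable) -> dict[tuple[str, str], FactualityValue]:
        if self._pipeline is None and self._single_class is None:
            raise RuntimeError("classifier is not trained")
        keys, X, _y = self._featurize_corpus(docs)
        if self._single_class is not None:
            return {k: self._single_class for k in keys}
        labels = self._pipeline.predict(X)
        return {
            k: FactualityValue(label) for k, label in zip(keys, labels)
        }
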