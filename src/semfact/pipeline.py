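"""End-to-end assignment: parsed document in, factuality labels out.

Chains the stages in order: read CoNLL-U dependencies, collapse function
words, build the semantic document graph with entities/predications/
trigger senses attached, prune triggers overlapping extractor spans,
compose enhanced predications, and map each to a discrete factuality
value. Inferred (INFER) predications inherit from the non-inferred
predication sharing their arguments, when one exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .composition import (
    EnhancedPredication,
    Predication,
    compose,
    semrep_predications,
)
from .factuality import FactualityValue, assign_factuality
from .graphs import (
    DEFAULT_LIGHT_VERBS,
    SemanticGraph,
    collapse,
    prune_trigger_nodes,
    read_dependencies,
    transform_to_semantic,
)
from .lexicon import EmbeddingDictionary, load_dictionary

__all__ = ["AnalysisResult", "analyze_document"]


@dataclass
class AnalysisResult:
    """Everything produced while assigning factuality to one document."""

    graph: SemanticGraph
    enhanced: list[EnhancedPredication]
    labels: dict[str, FactualityValue] = field(default_factory=dict)

    def enhanced_by_id(self, ep_id: str) -> EnhancedPredication:
        for ep in self.enhanced:
            if ep.id == ep_id:
                return ep
        raise KeyError(ep_id)


def _infer_partner(
    pred: Predication,
    labels: dict[str, FactualityValue],
    predications: list[Predication],
) -> FactualityValue | None:
    for other in predications:
        if (
            other.id != pred.id
            and other.indicator_type != "INFER"
            and {other.subject, other.object} == {pred.subject, pred.object}
        ):
            return labels.get(other.id)
    return None


def analyze_document(
    doc,
    dictionary: EmbeddingDictionary | None = None,
    light_verbs: frozenset[str] = DEFAULT_LIGHT_VERBS,
    conllu: str | None = None,
    trace: bool = False,
) -> AnalysisResult:
    """Assign factuality to every true-positive predication of ``doc``.

    ``doc`` is an :class:`~semfact.corpus_eval.AnnotatedDocument` (or any
    object with ``entities``, ``true_positive_predications()`` and a
    ``conllu`` parse, which may instead be passed explicitly).
    """
    if dictionary is None:
        dictionary = load_dictionary()
    parse = conllu if conllu is not None else doc.conllu
    if parse is None:
        raise ValueError(f"document {doc.id!r} has no dependency parse")
    graphs = [collapse(g) for g in read_dependencies(parse)]
    predications = list(doc.true_positive_predications())
    sg = transform_to_semantic(graphs, doc.entities, predications, dictionary)
    prune_trigger_nodes(sg, doc.entities, predications)
    enhanced = compose(sg, predications, light_verbs=light_verbs, trace=trace)

    labels: dict[str, FactualityValue] = {}
    deferred = []
    for ep in semrep_predications(enhanced):
        pred = ep.predication
        if pred is not None and pred.indicator_type == "INFER":
            deferred.append(ep)
        else:
            labels[ep.id] = assign_factuality(ep)
    for ep in deferred:
        partner = _infer_partner(ep.predication, labels, predications)
        labels[ep.id] = assign_factuality(ep, inferred_partner=partner)
    return AnalysisResult(graph=sg, enhanced=enhanced, labels=labels)
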