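"""Bottom-up predication composition over the semantic graph.

Every predication starts life on the epistemic scale with scalar modality
value 1 (a fact). Embedding triggers matched in the semantic graph then
modulate that value: a modal trigger places the predications in its
immediate scope on its scale at its prior value, a scale_shifter trigger
shifts the value already on the scale (negation maps v to 1 - v). Scope
is determined by licensed semantic-dependency paths: a predication whose
predicate node is reachable from the trigger along a directed path
carrying one of the sense's licensed dependency types is in the trigger's
scope. Two refinements sharpen scope resolution for relation-extraction
output:

* a path constraint for adverb and modal-auxiliary triggers -- no verbal
  node may sit on the path between trigger and predicate unless it is a
  light verb ("have", "associate");
* negated-argument handling -- a negation trigger attached to an argument
  node (or to non-verbal material on the predicate-argument path) negates
  the predication itself, capturing wide-scope argument negation.

The result is one :class:`EnhancedPredication` per input predication,
``[P, S, MV_sc, Arg1..n]`` (typed predicate, attributed source, scalar
modality value on a scale, logical arguments in object-subject-adjunct
order), plus one embedding predication per scoping modal trigger, with
nesting and attribution recorded. Only the immediate embedding trigger
assigns a predication's value; outer triggers assign to the embedding
predication one level down, not transitively to the inner one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .graphs import (
    DEFAULT_LIGHT_VERBS,
    NodeId,
    SemanticGraph,
    directed_path,
    path_between,
)
from .lexicon import EmbeddingDictionary, EmbeddingSense, ModalityScale

logger = logging.getLogger(__name__)

__all__ = [
    "Predication",
    "EnhancedPredication",
    "WRITER",
    "identify_arguments",
    "satisfies_path_constraint",
    "argument_negated",
    "compose",
    "semrep_predications",
]

#: source symbol for the document's writer
WRITER = "WR"

INDICATOR_TYPES = frozenset(
    {
        "verb",
        "nominalization",
        "adjective",
        "preposition",
        "modifier-head",
        "appositive",
        "INFER",
    }
)


@dataclass(frozen=True)
class Predication:
    """A subject-predicate-object triple from the relation extractor."""

    id: str
    subject: str  # entity id
    predicate_type: str  # TREATS, CAUSES, ISA, ...
    object: str  # entity id
    predicate_span: tuple[int, int]
    indicator_type: str = "verb"

    def __post_init__(self) -> None:
        if self.subject == self.object:
            raise ValueError(f"{self.id}: subject and object must differ")


@dataclass
class EnhancedPredication:
    """Pr := [P, S, MV_sc, Arg1..n] with provenance.

    ``kind`` is "semrep" for enhanced forms of input predications and
    "embedding" for predications introduced by modal triggers themselves.
    """

    id: str
    predicate: str  # "treatment:treats" or "may:speculative"
    source: str  # entity id, literal text, or WR for the writer
    scale: ModalityScale
    mv: float
    args: tuple[str, ...]
    kind: str = "semrep"
    predication: Predication | None = None
    trigger_node: NodeId | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mv <= 1.0:
            raise ValueError(f"{self.id}: MV {self.mv} outside [0,1]")


def _apply_shift(shift: str, v: float) -> float:
    """Shift functions are clipped so values stay in [0,1]."""
    if shift == "negate":
        return 1.0 - v
    if shift == "intensify":
        return min(1.0, v + 0.15)
    if shift == "diminish":
        return max(0.0, v - 0.15)
    raise ValueError(f"unknown shift function {shift!r}")


def _is_adverb_or_modal_aux(sg: SemanticGraph, node: NodeId) -> bool:
    pos = sg.token(node).pos
    return pos.startswith("RB") or pos == "MD"


def _char_offset(sg: SemanticGraph, node: NodeId) -> int:
    span = sg.span_index.get(node)
    return span[0] if span else 10**9


def satisfies_path_constraint(
    sg: SemanticGraph,
    trigger_node: NodeId,
    predicate_node: NodeId,
    light_verbs: frozenset[str] = DEFAULT_LIGHT_VERBS,
) -> bool:
    """True iff no non-light verbal node blocks the trigger's scope.

    Applies only when the trigger is an adverb or modal auxiliary; other
    triggers satisfy it vacuously. With no path at all there is no scope.
    """
    if not _is_adverb_or_modal_aux(sg, trigger_node):
        return True
    path = path_between(sg, trigger_node, predicate_node)
    if path is None:
        return False
    return _intermediates_ok(sg, path, trigger_node, predicate_node, light_verbs)


def _intermediates_ok(
    sg: SemanticGraph,
    path: Sequence[tuple[NodeId, NodeId, str]],
    a: NodeId,
    b: NodeId,
    light_verbs: frozenset[str],
) -> bool:
    nodes: set[NodeId] = set()
    for u, v, _lab in path:
        nodes.update((u, v))
    nodes -= {a, b}
    for n in nodes:
        tok = sg.token(n)
        if tok.is_verbal and tok.lemma.lower() not in light_verbs:
            return False
    return True


def identify_arguments(
    trigger_node: NodeId, sense: EmbeddingSense, sg: SemanticGraph
) -> list[tuple[NodeId, bool]]:
    """Logical arguments of a trigger: dependents via licensed dep types.

    Returns (node, carries_predication) pairs in node order; empty when
    no licensed dependency is present (the trigger is inert).
    """
    args = [
        (v, v in sg.predications)
        for v, label in sg.out_edges(trigger_node)
        if label in sense.dep_types
    ]
    if not args:
        logger.debug(
            "trigger %s has no licensed dependents for sense %s",
            sg.token(trigger_node).text,
            sense.category,
        )
    return args


def _negation_targets(sg: SemanticGraph) -> list[tuple[NodeId, NodeId, EmbeddingSense]]:
    """(negation trigger node, licensed target node, sense) triples."""
    out = []
    for node in sorted(sg.senses):
        for sense in sg.senses[node]:
            if sense.is_negation:
                for target, _pred in identify_arguments(node, sense, sg):
                    out.append((node, target, sense))
                break
    return out


def argument_negated(
    sg: SemanticGraph,
    predicate_node: NodeId,
    argument_node: NodeId,
    negation_targets: Iterable[tuple[NodeId, NodeId, EmbeddingSense]] | None = None,
) -> bool:
    """Wide-scope argument negation check.

    True iff a negation trigger attaches to the argument node itself or
    to a non-verbal node on the path between predicate and argument
    (negation hanging off a verb on the path is clausal negation, which
    the path constraint already adjudicates).
    """
    if negation_targets is None:
        negation_targets = _negation_targets(sg)
    path = path_between(sg, predicate_node, argument_node)
    if path is None:
        return False
    on_path: set[NodeId] = {argument_node}
    for u, v, _lab in path:
        on_path.update((u, v))
    on_path.discard(predicate_node)
    for _neg_node, target, _sense in negation_targets:
        if target == argument_node:
            return True
        if target in on_path and not sg.token(target).is_verbal:
            return True
    return False


@dataclass(frozen=True)
class _ScopingTrigger:
    node: NodeId
    sense: EmbeddingSense
    distance: int
    offset: int


def _modal_chain(
    sg: SemanticGraph,
    predicate_node: NodeId,
    light_verbs: frozenset[str],
) -> list[_ScopingTrigger]:
    """Modal triggers scoping a predicate node, innermost first.

    A trigger scopes the predicate iff a directed path from trigger to
    predicate exists, some edge on it carries a licensed dependency type
    of one of the trigger's senses (first matching sense wins, file
    order), and -- for adverbs and modal auxiliaries -- every verbal node
    strictly between them is a light verb. Ordered by graph distance,
    ties by character offset. Distance counts clause-level edges only:
    AUX/AUXPASS/NEG edges bind a trigger into the verb complex of its
    clause and cost nothing, so in "suggest that X may V ..." the
    auxiliary is closer to the predicate than the matrix verb.
    """
    chain: list[_ScopingTrigger] = []
    for node in sorted(sg.senses):
        if node == predicate_node:
            continue
        path = directed_path(sg, node, predicate_node)
        if not path:
            continue
        labels = {lab for _u, _v, lab in path}
        for sense in sg.senses[node]:
            if not sense.category.is_modal:
                continue
            if not (labels & sense.dep_types):
                continue
            if _is_adverb_or_modal_aux(sg, node) and not _intermediates_ok(
                sg, path, node, predicate_node, light_verbs
            ):
                continue
            distance = sum(
                1
                for _u, _v, lab in path
                if lab not in {"AUX", "AUXPASS", "NEG"}
            )
            chain.append(
                _ScopingTrigger(node, sense, distance, _char_offset(sg, node))
            )
            break
    chain.sort(key=lambda t: (t.distance, t.offset))
    return chain


def _scoping_shifters(
    sg: SemanticGraph,
    predicate_node: NodeId,
    chain: Sequence[_ScopingTrigger],
    arg_nodes: Sequence[NodeId],
    negation_targets: Sequence[tuple[NodeId, NodeId, EmbeddingSense]],
    light_verbs: frozenset[str],
) -> list[tuple[NodeId, EmbeddingSense]]:
    """Scale shifters applying to a predication, in document order.

    A shifter applies when (a) it directly scopes the predicate node via
    a licensed directed path subject to the adverb path constraint, (b)
    its licensed target is the predication's immediate modal trigger
    ("do not support ..."), or (c) it negates an argument (wide-scope
    argument negation). Each shifter node applies at most once.
    """
    applying: dict[NodeId, EmbeddingSense] = {}
    immediate = chain[0].node if chain else None

    for node in sorted(sg.senses):
        for sense in sg.senses[node]:
            if not sense.category.is_scale_shifter:
                continue
            path = directed_path(sg, node, predicate_node)
            if path and (
                {lab for _u, _v, lab in path} & sense.dep_types
            ):
                if not _is_adverb_or_modal_aux(sg, node) or _intermediates_ok(
                    sg, path, node, predicate_node, light_verbs
                ):
                    applying.setdefault(node, sense)
            break

    for neg_node, target, sense in negation_targets:
        if immediate is not None and target == immediate:
            applying.setdefault(neg_node, sense)

    if any(
        argument_negated(sg, predicate_node, arg, negation_targets)
        for arg in arg_nodes
    ):
        for neg_node, target, sense in negation_targets:
            path = path_between(sg, predicate_node, target)
            on_args = any(
                target == arg
                or (
                    (p := path_between(sg, predicate_node, arg)) is not None
                    and target in {n for u, v, _ in p for n in (u, v)} - {predicate_node}
                    and not sg.token(target).is_verbal
                )
                for arg in arg_nodes
            )
            if on_args:
                applying.setdefault(neg_node, sense)

    return sorted(applying.items(), key=lambda kv: _char_offset(sg, kv[0]))


def _entity_node(sg: SemanticGraph, entity_id: str) -> NodeId | None:
    for node, ents in sg.entities.items():
        for ent in ents:
            if getattr(ent, "id", None) == entity_id:
                return node
    return None


def _subject_term(sg: SemanticGraph, trigger_node: NodeId) -> str | None:
    """Nominal subject dependent of a source-introducing trigger."""
    for v, label in sg.out_edges(trigger_node):
        if label == "NSUBJ":
            ents = sg.entities.get(v)
            if ents:
                return getattr(ents[0], "id", sg.token(v).lemma)
            return sg.token(v).lemma
    return None


def compose(
    sg: SemanticGraph,
    predications: Sequence[Predication],
    dictionary: EmbeddingDictionary | None = None,
    light_verbs: frozenset[str] = DEFAULT_LIGHT_VERBS,
    trace: bool = False,
) -> list[EnhancedPredication]:
    """Compose enhanced predications for a pruned semantic document graph.

    Returns one enhanced predication per input predication plus one
    embedding predication per scoping modal trigger (nesting innermost to
    outermost). ``dictionary`` is unused here (senses were attached
    during graph construction) and accepted for interface symmetry.
    Deterministic: traversal follows topological/graph order with ties
    broken by document offset.
    """
    del dictionary  # senses already attached to the graph
    out: list[EnhancedPredication] = []
    negation_targets = _negation_targets(sg)
    em_counter = 0

    for pred in predications:
        pred_node = None
        for node, plist in sg.predications.items():
            if any(p.id == pred.id for p in plist):
                pred_node = node
                break
        if pred_node is None:
            raise KeyError(f"predication {pred.id} not attached to the graph")

        chain = _modal_chain(sg, pred_node, light_verbs)
        arg_nodes = [
            n
            for n in (
                _entity_node(sg, pred.object),
                _entity_node(sg, pred.subject),
            )
            if n is not None
        ]
        shifters = _scoping_shifters(
            sg, pred_node, chain, arg_nodes, negation_targets, light_verbs
        )

        if chain:
            scale = chain[0].sense.scale or ModalityScale.EPISTEMIC
            mv = chain[0].sense.prior_value
        else:
            scale = ModalityScale.EPISTEMIC
            mv = 1.0
        for node, sense in shifters:
            mv = _apply_shift(sense.shift_function, mv)
            if trace:
                logger.info(
                    "shift %s (%s) on %s -> %.2f",
                    sg.token(node).text,
                    sense.shift_function,
                    pred.id,
                    mv,
                )

        # sources: walk the chain outermost-in; a deductive/demonstrative
        # trigger with a nominal subject attributes everything below it
        sources_by_level: list[str] = []
        current = WRITER
        for trig in reversed(chain):  # outermost first
            sources_by_level.append(current)
            if trig.sense.introduces_source:
                term = _subject_term(sg, trig.node)
                if term is not None:
                    current = term
        sources_by_level.reverse()  # now innermost first, aligned with chain
        pred_source = current

        ep = EnhancedPredication(
            id=pred.id,
            predicate=f"{sg.token(pred_node).lemma}:{pred.predicate_type.lower()}",
            source=pred_source,
            scale=scale,
            mv=mv,
            args=(pred.object, pred.subject),
            kind="semrep",
            predication=pred,
            trigger_node=pred_node,
        )
        out.append(ep)
        if trace:
            logger.info(
                "compose %s = %.2f_%s source=%s", pred.id, mv, scale.value, pred_source
            )

        inner_id = ep.id
        for level, trig in enumerate(chain):
            em_counter += 1
            outer = chain[level + 1] if level + 1 < len(chain) else None
            if outer is not None:
                em_scale = outer.sense.scale or ModalityScale.EPISTEMIC
                em_mv = outer.sense.prior_value
                for neg_node, target, nsense in negation_targets:
                    if target == outer.node:
                        em_mv = _apply_shift(nsense.shift_function, em_mv)
            else:
                em_scale = ModalityScale.EPISTEMIC
                em_mv = 1.0
            args: tuple[str, ...] = (inner_id,)
            if trig.sense.introduces_source:
                term = _subject_term(sg, trig.node)
                if term is not None:
                    args = (inner_id, term)
            em = EnhancedPredication(
                id=f"em{em_counter}",
                predicate=(
                    f"{sg.token(trig.node).lemma}:{trig.sense.category.leaf}"
                ),
                source=sources_by_level[level],
                scale=em_scale,
                mv=em_mv,
                args=args,
                kind="embedding",
                trigger_node=trig.node,
            )
            out.append(em)
            if trace:
                logger.info(
                    "assign %s (%s) -> %s = %.2f_%s",
                    sg.token(trig.node).text,
                    trig.sense.category,
                    inner_id,
                    em_mv,
                    em_scale.value,
                )
            inner_id = em.id
    return out


def semrep_predications(
    enhanced: Iterable[EnhancedPredication],
) -> list[EnhancedPredication]:
    """Keep only enhanced forms of input predications.

    Embedding predications are composed for bookkeeping but pruned from
    the output whose factuality is assessed.
    """
    return [ep for ep in enhanced if ep.kind == "semrep"]
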