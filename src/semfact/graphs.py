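"""Dependency and semantic document graphs.

The composition engine does not parse text itself: token-level dependency
parses arrive in CoNLL-U (any parser may produce them; character offsets
are carried in the MISC column as ``start_char``/``end_char``). Per
sentence, a :class:`DependencyGraph` is read, function words are collapsed
into labeled edges (``prep``+``pobj`` -> ``PREP_<prep>``, ``cc``+``conj``
-> ``CONJ_<coordinator>``), and the collapsed graphs of a document are
transformed into one directed acyclic :class:`SemanticGraph` whose edge
direction encodes semantic dependency of the head over the dependent.
Two transformation rules beyond collapsing are applied: the Verb Complex
Transformation (auxiliaries and negators come to govern their content
verb via AUX/NEG edges) and the Coordination Transformation (dependents
and governors shared through a conjunction are distributed to each
conjunct). Named entities, predication predicates, and embedding-trigger
senses are attached to graph nodes; trigger senses whose spans are
subsumed by or overlap entity/predicate spans are pruned so that the
relation extractor's semantics take precedence.
"""

from __future__ import annotations

import io
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx

from .lexicon import EmbeddingDictionary, EmbeddingSense

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "DependencyEdge",
    "DependencyGraph",
    "SemanticGraph",
    "ConllError",
    "AlignmentError",
    "read_dependencies",
    "collapse",
    "transform_to_semantic",
    "prune_trigger_nodes",
    "path_between",
]

#: verbs semantically bleached enough not to block adverb/modal scope
DEFAULT_LIGHT_VERBS = frozenset({"have", "associate"})


class ConllError(ValueError):
    """Malformed CoNLL-U input (cycle, multiple roots, bad columns)."""


class AlignmentError(ValueError):
    """An annotation span cannot be aligned to the token layer."""


@dataclass(frozen=True)
class Token:
    """A surface token with 0-based half-open character offsets."""

    index: int  # 1-based position in its sentence
    text: str
    lemma: str
    pos: str  # Penn Treebank tag
    char_span: tuple[int, int] | None = None

    @property
    def is_verbal(self) -> bool:
        return self.pos.startswith("VB") or self.pos == "MD"


@dataclass(frozen=True)
class DependencyEdge:
    head: int
    dependent: int
    label: str


@dataclass
class DependencyGraph:
    """Syntactic dependencies of one sentence."""

    tokens: list[Token]
    edges: list[DependencyEdge]
    sent_id: str = ""
    position: int = 0  # 0-based sentence position in the document
    # collapsed function-word token -> surviving governor token
    anchor_map: dict[int, int] = field(default_factory=dict)

    def token(self, index: int) -> Token:
        return self.tokens[index - 1]

    @property
    def root(self) -> int:
        roots = [e.dependent for e in self.edges if e.head == 0]
        return roots[0]

    def validate(self) -> None:
        roots = [e.dependent for e in self.edges if e.head == 0]
        if len(roots) != 1:
            raise ConllError(
                f"sentence {self.sent_id!r}: expected a single root, "
                f"found {len(roots)}"
            )
        head_of = {e.dependent: e.head for e in self.edges}
        for tok in self.tokens:
            if tok.index not in head_of:
                raise ConllError(
                    f"sentence {self.sent_id!r}: token {tok.index} has no head"
                )
        # cycle check: follow primary heads up to the root
        for tok in self.tokens:
            seen = set()
            cur = tok.index
            while cur != 0:
                if cur in seen:
                    raise ConllError(
                        f"sentence {self.sent_id!r}: dependency cycle at "
                        f"token {cur}"
                    )
                seen.add(cur)
                cur = head_of.get(cur, 0)


def _parse_misc_offsets(misc: str) -> tuple[int, int] | None:
    start = end = None
    for item in misc.split("|"):
        if "=" in item:
            key, _, value = item.partition("=")
            if key in {"start_char", "TokenRange"} and "-" in value:
                a, _, b = value.partition("-")
                return int(a), int(b)
            if key == "start_char":
                start = int(value)
            elif key == "end_char":
                end = int(value)
    if start is not None and end is not None:
        return start, end
    return None


def read_dependencies(source: str | Path | io.TextIOBase) -> list[DependencyGraph]:
    """Read CoNLL-U into per-sentence dependency graphs, document order.

    Accepts a path, a CoNLL-U string, or an open text stream. Multiword-
    token and empty-node lines are skipped. The XPOS column provides the
    Penn tag (falling back to UPOS); character offsets are recovered from
    the MISC column when present.
    """
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    elif isinstance(source, str):
        p = Path(source)
        is_pathlike = "\n" not in source and "\t" not in source
        text = p.read_text(encoding="utf-8") if is_pathlike and p.exists() else source
    else:
        text = source.read()

    graphs: list[DependencyGraph] = []
    tokens: list[Token] = []
    edges: list[DependencyEdge] = []
    sent_id = ""

    def flush() -> None:
        nonlocal tokens, edges, sent_id
        if tokens:
            g = DependencyGraph(
                tokens=tokens, edges=edges, sent_id=sent_id, position=len(graphs)
            )
            g.validate()
            graphs.append(g)
        tokens, edges, sent_id = [], [], ""

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("sent_id"):
                sent_id = body.partition("=")[2].strip()
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ConllError(f"line {lineno}: expected 10 columns, got {len(cols)}")
        tid, form, lemma, upos, xpos, _feats, head, deprel, _deps, misc = cols
        if "-" in tid or "." in tid:
            continue  # multiword-token range or empty node
        try:
            index = int(tid)
            head_i = int(head)
        except ValueError as exc:
            raise ConllError(f"line {lineno}: bad token/head id ({exc})") from None
        pos = xpos if xpos not in {"_", ""} else upos
        tokens.append(
            Token(
                index=index,
                text=form,
                lemma=lemma if lemma != "_" else form.lower(),
                pos=pos,
                char_span=_parse_misc_offsets(misc),
            )
        )
        edges.append(DependencyEdge(head=head_i, dependent=index, label=deprel))
    flush()
    return graphs


# ---------------------------------------------------------------------------
# Collapsing
# ---------------------------------------------------------------------------

_PREP_LABELS = {"prep"}
_POBJ_LABELS = {"pobj", "pcomp"}


def collapse(g: DependencyGraph) -> DependencyGraph:
    """Emulate the collapsed dependency format.

    ``prep(h, p) + pobj(p, o)`` becomes ``prep_<p>(h, o)`` (likewise for
    UD ``case``-marked ``obl``/``nmod``), and ``cc + conj`` becomes
    ``conj_<coordinator>``. The token set is unchanged; collapsed function
    words are recorded in ``anchor_map`` so that annotation spans over
    them (e.g. a prepositional predicate) can still be anchored to a
    surviving node. A dangling preposition is left unchanged with a
    logged warning.
    """
    edges = list(g.edges)
    anchor: dict[int, int] = {}
    by_head: dict[int, list[DependencyEdge]] = {}
    for e in edges:
        by_head.setdefault(e.head, []).append(e)

    removed: set[DependencyEdge] = set()
    added: list[DependencyEdge] = []

    # Stanford-style prep + pobj
    for e in edges:
        if e.label in _PREP_LABELS:
            prep_tok = g.token(e.dependent)
            objs = [
                x for x in by_head.get(e.dependent, []) if x.label in _POBJ_LABELS
            ]
            if not objs:
                logger.warning(
                    "dangling preposition %r in sentence %s left unchanged",
                    prep_tok.text,
                    g.sent_id,
                )
                continue
            obj = min(objs, key=lambda x: x.dependent)
            removed.update({e, obj})
            added.append(
                DependencyEdge(
                    head=e.head,
                    dependent=obj.dependent,
                    label=f"prep_{prep_tok.lemma.lower()}",
                )
            )
            anchor[e.dependent] = e.head

    # UD-style case-marked obl/nmod
    for e in edges:
        if e.label == "case":
            adp = g.token(e.dependent)
            host_edges = [
                x
                for x in edges
                if x.dependent == e.head and x.label.split(":")[0] in {"obl", "nmod"}
            ]
            if not host_edges:
                continue
            host = host_edges[0]
            removed.update({e, host})
            added.append(
                DependencyEdge(
                    head=host.head,
                    dependent=host.dependent,
                    label=f"prep_{adp.lemma.lower()}",
                )
            )
            anchor[e.dependent] = host.head

    # cc + conj -> conj_<coordinator>
    cc_of: dict[int, DependencyEdge] = {}
    for e in edges:
        if e.label == "cc" and e.head not in cc_of:
            cc_of[e.head] = e
    for e in edges:
        if e.label.split(":")[0] == "conj":
            cc_edge = cc_of.get(e.head)
            coordinator = (
                g.token(cc_edge.dependent).lemma.lower() if cc_edge else "and"
            )
            removed.add(e)
            if cc_edge:
                removed.add(cc_edge)
                anchor[cc_edge.dependent] = e.head
            added.append(
                DependencyEdge(
                    head=e.head, dependent=e.dependent, label=f"conj_{coordinator}"
                )
            )

    new_edges = [e for e in edges if e not in removed] + added
    return DependencyGraph(
        tokens=list(g.tokens),
        edges=new_edges,
        sent_id=g.sent_id,
        position=g.position,
        anchor_map=anchor,
    )


# ---------------------------------------------------------------------------
# Semantic graph
# ---------------------------------------------------------------------------

NodeId = tuple[int, int]  # (sentence position, 1-based token index)

#: labels inverted unconditionally (dependent semantically governs its head)
_ALWAYS_INVERT = {"AUX", "AUXPASS", "NEG"}
#: labels inverted only when the dependent is a matched embedding trigger
_TRIGGER_INVERT = {"ADVMOD", "MARK", "DET", "PRECONJ", "AMOD"}
_COORD_SKIP = {"CC", "PUNCT"}


class SemanticGraph:
    """Directed acyclic document graph of semantically typed textual units.

    Nodes are (sentence, token) pairs carrying the token; attached
    semantics -- entity annotations, predication predicates, embedding
    senses -- live in side tables keyed by node. Edge labels are
    upper-case semantic-dependency types (AUX, DOBJ, NEG, PREP_OF, ...).
    """

    def __init__(self) -> None:
        self.g = nx.DiGraph()
        self.entities: dict[NodeId, list] = {}
        self.predications: dict[NodeId, list] = {}
        self.senses: dict[NodeId, list[EmbeddingSense]] = {}
        self.span_index: dict[NodeId, tuple[int, int]] = {}

    # -- construction -----------------------------------------------------
    def add_node(self, node: NodeId, token: Token) -> None:
        self.g.add_node(node, token=token)
        if token.char_span is not None:
            self.span_index[node] = token.char_span

    def add_edge(self, u: NodeId, v: NodeId, label: str) -> None:
        if u == v:
            return
        self.g.add_edge(u, v, label=label)

    # -- accessors --------------------------------------------------------
    def token(self, node: NodeId) -> Token:
        return self.g.nodes[node]["token"]

    def nodes(self) -> list[NodeId]:
        return sorted(self.g.nodes)

    def edges(self) -> list[tuple[NodeId, NodeId, str]]:
        return sorted((u, v, d["label"]) for u, v, d in self.g.edges(data=True))

    def label(self, u: NodeId, v: NodeId) -> str:
        return self.g.edges[u, v]["label"]

    def successors(self, node: NodeId) -> list[NodeId]:
        return sorted(self.g.successors(node))

    def out_edges(self, node: NodeId) -> list[tuple[NodeId, str]]:
        return sorted(
            (v, d["label"]) for _u, v, d in self.g.out_edges(node, data=True)
        )

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.g)

    def node_at_span(self, span: tuple[int, int]) -> NodeId | None:
        """Node whose token span intersects ``span`` (head of the covered set)."""
        covered = [
            n
            for n, (s, e) in self.span_index.items()
            if s < span[1] and span[0] < e
        ]
        if not covered:
            return None
        if len(covered) == 1:
            return covered[0]
        cov = set(covered)
        # prefer the token governed from outside the covered set
        heads = [
            n
            for n in covered
            if not any(u in cov for u in self.g.predecessors(n))
        ]
        pool = heads or covered
        return max(pool)  # rightmost as deterministic head heuristic

    def to_dot(self) -> str:
        """GraphViz DOT export for debugging."""
        lines = ["digraph semantic {"]
        for n in self.nodes():
            tok = self.token(n)
            marks = []
            if n in self.senses and self.senses[n]:
                marks.append("trigger")
            if n in self.entities:
                marks.append("entity")
            if n in self.predications:
                marks.append("predicate")
            label = tok.text + (f"\\n[{','.join(marks)}]" if marks else "")
            lines.append(f'  "{n}" [label="{label}"];')
        for u, v, lab in self.edges():
            lines.append(f'  "{u}" -> "{v}" [label="{lab}"];')
        lines.append("}")
        return "\n".join(lines)


def _semantic_label(label: str) -> str:
    return label.replace(":", "_").upper()


def _match_triggers(
    g: DependencyGraph, dictionary: EmbeddingDictionary
) -> dict[int, list[EmbeddingSense]]:
    """Match dictionary triggers (incl. multiword heads) against tokens."""
    matches: dict[int, list[EmbeddingSense]] = {}
    multiword = dictionary.multiword_lemmas()
    dependents: dict[int, list[int]] = {}
    for e in g.edges:
        dependents.setdefault(e.head, []).append(e.dependent)
    for tok in g.tokens:
        senses = list(dictionary.lookup_senses(tok.lemma, tok.pos))
        head_lemma = tok.lemma.lower()
        if head_lemma in multiword:
            dep_lemmas = {
                g.token(d).lemma.lower() for d in dependents.get(tok.index, [])
            }
            for full in multiword[head_lemma]:
                rest = full.split()[1:]
                if all(w in dep_lemmas for w in rest):
                    senses = list(dictionary.lookup_senses(full, tok.pos)) + senses
        if senses:
            matches[tok.index] = senses
    return matches


def transform_to_semantic(
    graphs: Sequence[DependencyGraph],
    entities: Iterable = (),
    predications: Iterable = (),
    dictionary: EmbeddingDictionary | None = None,
) -> SemanticGraph:
    """Build the semantic document graph from collapsed dependency graphs.

    ``entities`` are objects with a character ``span`` (and optionally an
    id); ``predications`` are objects with ``predicate_span``. Annotation
    spans crossing sentence boundaries raise :class:`AlignmentError`.
    """
    sg = SemanticGraph()
    sent_ranges: list[tuple[int, int]] = []

    for g in graphs:
        spans = [t.char_span for t in g.tokens if t.char_span]
        if spans:
            sent_ranges.append((min(s for s, _ in spans), max(e for _, e in spans)))
        else:
            sent_ranges.append((0, 0))
        trigger_matches = (
            _match_triggers(g, dictionary) if dictionary is not None else {}
        )
        for tok in g.tokens:
            node = (g.position, tok.index)
            sg.add_node(node, tok)
            if tok.index in trigger_matches:
                sg.senses[node] = list(trigger_matches[tok.index])

        conj_edges = []
        for e in g.edges:
            if e.head == 0:
                continue
            label = _semantic_label(e.label)
            u = (g.position, e.head)
            v = (g.position, e.dependent)
            invert = label in _ALWAYS_INVERT or (
                label in _TRIGGER_INVERT and e.dependent in trigger_matches
            )
            if invert:
                sg.add_edge(v, u, label)
            else:
                sg.add_edge(u, v, label)
            if label.startswith("CONJ_"):
                conj_edges.append((u, v, label))

        # Coordination Transformation: distribute shared material
        for c1, c2, _label in conj_edges:
            for u, _v, d in list(sg.g.in_edges(c1, data=True)):
                lab = d["label"]
                if lab.startswith("CONJ_") or lab in _COORD_SKIP:
                    continue
                if not sg.g.has_edge(u, c2) and not nx.has_path(sg.g, c2, u):
                    sg.add_edge(u, c2, lab)
            for _u, v, d in list(sg.g.out_edges(c1, data=True)):
                lab = d["label"]
                if lab.startswith("CONJ_") or lab in _COORD_SKIP:
                    continue
                if not sg.g.has_edge(c2, v) and not nx.has_path(sg.g, v, c2):
                    sg.add_edge(c2, v, lab)

        # anchor collapsed function words to their surviving governors
        for collapsed, governor in g.anchor_map.items():
            tok = g.token(collapsed)
            sg.g.nodes[(g.position, collapsed)]["anchor"] = (g.position, governor)

    if not sg.is_acyclic():
        cycle = nx.find_cycle(sg.g)
        raise ValueError(f"semantic graph is cyclic: {cycle}")

    def resolve(span: tuple[int, int], what: str, ident: str) -> NodeId:
        sent_hits = [
            i
            for i, (s, e) in enumerate(sent_ranges)
            if s < span[1] and span[0] < e
        ]
        if len(sent_hits) > 1:
            raise AlignmentError(
                f"{what} {ident!r}: span {span} crosses a sentence boundary"
            )
        node = sg.node_at_span(span)
        if node is None:
            raise AlignmentError(
                f"{what} {ident!r}: span {span} does not align to any token"
            )
        anchor = sg.g.nodes[node].get("anchor")
        return anchor if anchor is not None else node

    for ent in entities:
        node = resolve(tuple(ent.span), "entity", getattr(ent, "id", "?"))
        sg.entities.setdefault(node, []).append(ent)
    for pred in predications:
        node = resolve(
            tuple(pred.predicate_span), "predication", getattr(pred, "id", "?")
        )
        sg.predications.setdefault(node, []).append(pred)
    return sg


def prune_trigger_nodes(
    sg: SemanticGraph, entities: Iterable = (), predications: Iterable = ()
) -> SemanticGraph:
    """Drop trigger senses subsumed by or overlapping entity/predicate spans.

    The graph topology and the entity/predication attachments are left
    untouched; the operation is idempotent.
    """
    blocked: list[tuple[int, int]] = [tuple(e.span) for e in entities]
    blocked += [tuple(p.predicate_span) for p in predications]
    for node in list(sg.senses):
        span = sg.span_index.get(node)
        if span is None:
            continue
        if any(s < span[1] and span[0] < e for s, e in blocked):
            del sg.senses[node]
    return sg


def _bfs_path(
    adjacency, a: NodeId, b: NodeId
) -> list[NodeId] | None:
    """Deterministic BFS (neighbors visited in sorted node order)."""
    if a == b:
        return [a]
    prev: dict[NodeId, NodeId] = {a: a}
    queue = deque([a])
    while queue:
        cur = queue.popleft()
        for nxt in sorted(adjacency(cur)):
            if nxt in prev:
                continue
            prev[nxt] = cur
            if nxt == b:
                path = [b]
                while path[-1] != a:
                    path.append(prev[path[-1]])
                return list(reversed(path))
            queue.append(nxt)
    return None


def path_between(
    sg: SemanticGraph, a: NodeId, b: NodeId
) -> list[tuple[NodeId, NodeId, str]] | None:
    """Path between two nodes as a list of labeled edges.

    Tries the directed orientations first (a->b, then b->a), then falls
    back to the shortest undirected path; ties broken by node order.
    Returns ``[]`` for ``a == b`` and ``None`` for disconnected nodes.
    """
    if a not in sg.g or b not in sg.g:
        raise KeyError(f"node not in graph: {a if a not in sg.g else b}")
    if a == b:
        return []
    nodes = _bfs_path(sg.g.successors, a, b)
    if nodes is None:
        nodes = _bfs_path(sg.g.successors, b, a)
        if nodes is not None:
            nodes = list(reversed(nodes))
    if nodes is None:
        undirected = lambda n: set(sg.g.successors(n)) | set(sg.g.predecessors(n))
        nodes = _bfs_path(undirected, a, b)
    if nodes is None:
        return None
    out = []
    for u, v in zip(nodes, nodes[1:]):
        if sg.g.has_edge(u, v):
            out.append((u, v, sg.label(u, v)))
        else:
            out.append((v, u, sg.label(v, u)))
    return out


def directed_path(
    sg: SemanticGraph, a: NodeId, b: NodeId
) -> list[tuple[NodeId, NodeId, str]] | None:
    """Directed path a -> b only (semantic dominance), else ``None``."""
    if a == b:
        return []
    nodes = _bfs_path(sg.g.successors, a, b)
    if nodes is None:
        return None
    return [(u, v, sg.label(u, v)) for u, v in zip(nodes, nodes[1:])]
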