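"""Standoff corpus I/O, evaluation metrics, and the fixture generator.

Documents are exchanged in brat standoff format: a ``.txt`` file with the
document text and a ``.ann`` file with text-bound spans (``T`` lines for
entities and predicate triggers), events (``E`` lines carrying the
predicate type and Subject/Object roles), attributes (``A`` lines for
``Factuality``, ``IndicatorType`` and ``FalsePositive``), and optional
normalizations (``N`` lines carrying concept identifiers). Character
offsets are 0-based half-open.

Evaluation reports per-class precision/recall/F1, overall accuracy over
true-positive predications, and Cohen's kappa for annotator agreement.
The fixture generator emits a synthetic corpus of template sentences --
slot-filled drug/disease/protein fillers over hand-frozen dependency
parses -- whose gold label distribution follows the reference corpus
(88.4% fact) and whose triggers exercise exactly the phenomena the
composition rules target.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .composition import Predication
from .factuality import FactualityValue

__all__ = [
    "Entity",
    "AnnotatedDocument",
    "EvalReport",
    "FixtureConfig",
    "StandoffIntegrityError",
    "read_standoff",
    "write_standoff",
    "evaluate",
    "cohen_kappa",
    "majority_baseline",
    "generate_fixture_corpus",
    "build_document",
    "TABLE6_TOTALS",
]


class StandoffIntegrityError(ValueError):
    """An annotation does not match the document text."""


@dataclass(frozen=True)
class Entity:
    """A text-bound entity with its concept metadata."""

    id: str
    type: str  # semantic type label
    span: tuple[int, int]
    text: str
    cui: str | None = None


@dataclass
class AnnotatedDocument:
    """Document text plus predication annotations and gold factuality."""

    id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    predications: list[Predication] = field(default_factory=list)
    gold: dict[str, FactualityValue] = field(default_factory=dict)
    false_positives: set[str] = field(default_factory=set)
    conllu: str | None = None  # frozen parse, when generated alongside

    def true_positive_predications(self) -> list[Predication]:
        return [p for p in self.predications if p.id not in self.false_positives]

    def entity(self, entity_id: str) -> Entity:
        for e in self.entities:
            if e.id == entity_id:
                return e
        raise KeyError(entity_id)


# ---------------------------------------------------------------------------
# Standoff I/O
# ---------------------------------------------------------------------------

def read_standoff(
    txt: str | Path,
    ann: str | Path,
    doc_id: str = "doc",
    factuality_attribute: str = "Factuality",
) -> AnnotatedDocument:
    """Read a brat ``.txt``/``.ann`` pair into an annotated document.

    ``txt``/``ann`` may be paths or raw contents. Every span is verified
    against the text; a mismatch raises :class:`StandoffIntegrityError`
    naming the annotation id. The attribute carrying the factuality label
    is configurable (released corpora vary in attribute naming).
    """

    def _content(value: str | Path) -> str:
        if isinstance(value, Path):
            return value.read_text(encoding="utf-8")
        p = Path(value)
        if "\n" not in value and "\t" not in value and p.exists():
            return p.read_text(encoding="utf-8")
        return value

    text = _content(txt)
    ann_text = _content(ann)

    spans: dict[str, tuple[str, tuple[int, int], str]] = {}
    events: dict[str, tuple[str, str, dict[str, str]]] = {}
    attributes: list[tuple[str, str, str | None]] = []
    norms: dict[str, str] = {}

    for line in ann_text.splitlines():
        if not line.strip():
            continue
        aid, _, rest = line.partition("\t")
        if aid.startswith("T"):
            header, _, surface = rest.partition("\t")
            # the type may contain spaces (UMLS semantic type names)
            m = re.match(r"(.+?) (\d+) (\d+)$", header)
            if not m:
                raise StandoffIntegrityError(f"{aid}: malformed span line")
            ttype, start, end = m.group(1), int(m.group(2)), int(m.group(3))
            if text[start:end] != surface:
                raise StandoffIntegrityError(
                    f"{aid}: span {start}:{end} reads "
                    f"{text[start:end]!r}, annotation says {surface!r}"
                )
            spans[aid] = (ttype, (start, end), surface)
        elif aid.startswith("E"):
            parts = rest.split()
            etype, _, trigger = parts[0].partition(":")
            roles = {}
            for role_part in parts[1:]:
                role, _, target = role_part.partition(":")
                roles[role] = target
            events[aid] = (etype, trigger, roles)
        elif aid.startswith("A"):
            parts = rest.split()
            attributes.append(
                (parts[0], parts[1], parts[2] if len(parts) > 2 else None)
            )
        elif aid.startswith("N"):
            parts = rest.split("\t")[0].split()
            # e.g. "Reference T1 UMLS:C0020740"
            if len(parts) >= 3:
                norms[parts[1]] = parts[2].partition(":")[2] or parts[2]

    indicator_types: dict[str, str] = {}
    gold: dict[str, FactualityValue] = {}
    false_positives: set[str] = set()
    for name, target, value in attributes:
        if name == factuality_attribute and value is not None:
            gold[target] = FactualityValue(value)
        elif name == "FalsePositive":
            false_positives.add(target)
        elif name == "IndicatorType" and value is not None:
            indicator_types[target] = value

    trigger_ids = {trigger for (_t, trigger, _r) in events.values()}
    entities = [
        Entity(id=tid, type=ttype, span=span, text=surface, cui=norms.get(tid))
        for tid, (ttype, span, surface) in spans.items()
        if tid not in trigger_ids
    ]
    entities.sort(key=lambda e: (e.span, e.id))

    predications = []
    for eid in sorted(events, key=lambda x: int(x[1:])):
        etype, trigger, roles = events[eid]
        if trigger not in spans:
            raise StandoffIntegrityError(f"{eid}: unknown trigger {trigger}")
        predications.append(
            Predication(
                id=eid,
                subject=roles.get("Subject", ""),
                predicate_type=etype,
                object=roles.get("Object", ""),
                predicate_span=spans[trigger][1],
                indicator_type=indicator_types.get(eid, "verb"),
            )
        )

    doc = AnnotatedDocument(
        id=doc_id,
        text=text,
        entities=entities,
        predications=predications,
        gold=gold,
        false_positives=false_positives,
    )
    for p in doc.predications:
        if p.id not in doc.false_positives and p.id not in doc.gold:
            raise StandoffIntegrityError(
                f"{p.id}: true-positive predication without a factuality label"
            )
    return doc


def write_standoff(doc: AnnotatedDocument) -> tuple[str, str]:
    """Canonical serialization back to (txt, ann) contents.

    Entities keep their ids and are emitted sorted by offset; predicate
    triggers are re-assigned deterministic ids after the entities, so
    writing the result of :func:`read_standoff` is stable under
    round-tripping.
    """
    lines: list[str] = []
    for e in sorted(doc.entities, key=lambda x: (x.span, x.id)):
        lines.append(f"{e.id}\t{e.type} {e.span[0]} {e.span[1]}\t{e.text}")
    next_t = 1 + max(
        (int(e.id[1:]) for e in doc.entities if e.id[1:].isdigit()), default=0
    )
    norm_n = 1
    norm_lines = []
    for e in sorted(doc.entities, key=lambda x: (x.span, x.id)):
        if e.cui:
            norm_lines.append(
                f"N{norm_n}\tReference {e.id} CUI:{e.cui}\t{e.text}"
            )
            norm_n += 1
    event_lines = []
    attr_lines = []
    attr_n = 1
    for p in sorted(doc.predications, key=lambda x: int(x.id[1:])):
        tid = f"T{next_t}"
        next_t += 1
        s, e_off = p.predicate_span
        lines.append(f"{tid}\t{p.predicate_type} {s} {e_off}\t{doc.text[s:e_off]}")
        event_lines.append(
            f"{p.id}\t{p.predicate_type}:{tid} "
            f"Subject:{p.subject} Object:{p.object}"
        )
        if p.indicator_type != "verb":
            attr_lines.append(f"A{attr_n}\tIndicatorType {p.id} {p.indicator_type}")
            attr_n += 1
        if p.id in doc.false_positives:
            attr_lines.append(f"A{attr_n}\tFalsePositive {p.id}")
            attr_n += 1
        elif p.id in doc.gold:
            attr_lines.append(
                f"A{attr_n}\tFactuality {p.id} {doc.gold[p.id].value}"
            )
            attr_n += 1
    ann = "\n".join(lines + event_lines + attr_lines + norm_lines)
    if ann:
        ann += "\n"
    return doc.text, ann


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class EvalReport:
    """Per-class precision/recall/F1 plus overall accuracy (fractions)."""

    per_class: dict[str, ClassMetrics]
    accuracy: float
    kappa: float | None = None
    n: int = 0

    def as_percent(self) -> dict[str, dict[str, float]]:
        out = {
            label: {
                "precision": round(100 * m.precision, 1),
                "recall": round(100 * m.recall, 1),
                "f1": round(100 * m.f1, 1),
                "support": m.support,
            }
            for label, m in self.per_class.items()
        }
        out["_overall"] = {"accuracy": round(100 * self.accuracy, 1)}
        return out


def _as_labels(seq: Iterable) -> list[str]:
    return [x.value if isinstance(x, FactualityValue) else str(x) for x in seq]


def evaluate(
    gold: Sequence,
    predicted: Sequence,
    labels: Sequence[str] | None = None,
    kappa: bool = False,
) -> EvalReport:
    """Per-class P/R/F1 and accuracy over aligned label sequences.

    A class with a zero denominator reports 0.0. ``labels`` may name the
    full class inventory so classes absent from both sequences are still
    reported (with support 0).
    """
    from sklearn.metrics import precision_recall_fscore_support

    g = _as_labels(gold)
    p = _as_labels(predicted)
    if len(g) != len(p):
        raise ValueError(f"length mismatch: {len(g)} gold vs {len(p)} predicted")
    if labels is None:
        labels = sorted(set(g) | set(p))
    prec, rec, f1, support = precision_recall_fscore_support(
        g, p, labels=list(labels), zero_division=0
    )
    per_class = {
        label: ClassMetrics(float(pr), float(rc), float(f), int(s))
        for label, pr, rc, f, s in zip(labels, prec, rec, f1, support)
    }
    accuracy = float(np.mean([a == b for a, b in zip(g, p)])) if g else 0.0
    return EvalReport(
        per_class=per_class,
        accuracy=accuracy,
        kappa=cohen_kappa(g, p) if kappa else None,
        n=len(g),
    )


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    Defined as 1.0 under perfect observed agreement (p_o = 1), including
    the degenerate single-category case.
    """
    a = _as_labels(labels_a)
    b = _as_labels(labels_b)
    if len(a) != len(b):
        raise ValueError("sequences must be aligned")
    if not a:
        raise ValueError("cannot compute agreement on empty input")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    if p_o == 1.0:
        return 1.0
    cats = sorted(set(a) | set(b))
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    return (p_o - p_e) / (1.0 - p_e)


def majority_baseline(docs: Iterable[AnnotatedDocument]) -> list[FactualityValue]:
    """All true-positive predications labeled fact (the extractor's default)."""
    out = []
    for doc in docs:
        out.extend(FactualityValue.FACT for _ in doc.true_positive_predications())
    return out


# ---------------------------------------------------------------------------
# Sentence/document construction (shared with the worked examples)
# ---------------------------------------------------------------------------

_NO_SPACE_BEFORE = {".", ",", ";", ":", ")", "?"}
_NO_SPACE_AFTER = {"("}


@dataclass(frozen=True)
class Tok:
    """Authoring shorthand for a frozen parse token."""

    form: str
    lemma: str
    pos: str
    head: int
    deprel: str


@dataclass(frozen=True)
class SentenceSpec:
    tokens: tuple[Tok, ...]


def _detokenize(forms: Sequence[str], offset: int) -> tuple[str, list[tuple[int, int]]]:
    text = ""
    spans = []
    for i, form in enumerate(forms):
        if text and form not in _NO_SPACE_BEFORE and not text.endswith("("):
            text += " "
        start = offset + len(text)
        text += form
        spans.append((start, start + len(form)))
    return text, spans


def build_document(
    doc_id: str,
    sentences: Sequence[SentenceSpec],
    entities: Sequence[tuple[str, str, int, tuple[int, int], str | None]] = (),
    predications: Sequence[
        tuple[str, str, str, str, int, tuple[int, int], str]
    ] = (),
    gold: Mapping[str, FactualityValue] | None = None,
) -> AnnotatedDocument:
    """Assemble a document plus CoNLL-U from frozen parse specs.

    ``entities``: (id, semtype, sentence index, 1-based inclusive token
    range, cui). ``predications``: (id, subject entity id, predicate
    type, object entity id, sentence index, trigger token range,
    indicator type).
    """
    sent_texts: list[str] = []
    token_spans: list[list[tuple[int, int]]] = []
    offset = 0
    for spec in sentences:
        text, spans = _detokenize([t.form for t in spec.tokens], offset)
        sent_texts.append(text)
        token_spans.append(spans)
        offset += len(text) + 1  # single space between sentences
    doc_text = " ".join(sent_texts)

    conllu_lines: list[str] = []
    for si, spec in enumerate(sentences):
        conllu_lines.append(f"# sent_id = {doc_id}-s{si}")
        conllu_lines.append(f"# text = {sent_texts[si]}")
        for ti, tok in enumerate(spec.tokens):
            s, e = token_spans[si][ti]
            conllu_lines.append(
                "\t".join(
                    [
                        str(ti + 1),
                        tok.form,
                        tok.lemma,
                        "_",
                        tok.pos,
                        "_",
                        str(tok.head),
                        tok.deprel,
                        "_",
                        f"start_char={s}|end_char={e}",
                    ]
                )
            )
        conllu_lines.append("")
    conllu = "\n".join(conllu_lines)

    def span_of(si: int, token_range: tuple[int, int]) -> tuple[int, int]:
        lo, hi = token_range
        return (token_spans[si][lo - 1][0], token_spans[si][hi - 1][1])

    ents = []
    for eid, semtype, si, token_range, cui in entities:
        span = span_of(si, token_range)
        ents.append(
            Entity(
                id=eid,
                type=semtype,
                span=span,
                text=doc_text[span[0] : span[1]],
                cui=cui,
            )
        )
    preds = []
    for pid, subj, ptype, obj, si, trig_range, indicator in predications:
        preds.append(
            Predication(
                id=pid,
                subject=subj,
                predicate_type=ptype,
                object=obj,
                predicate_span=span_of(si, trig_range),
                indicator_type=indicator,
            )
        )
    return AnnotatedDocument(
        id=doc_id,
        text=doc_text,
        entities=ents,
        predications=preds,
        gold=dict(gold or {}),
        conllu=conllu,
    )


# ---------------------------------------------------------------------------
# Fixture corpus generator
# ---------------------------------------------------------------------------

#: reference-corpus label counts (total column)
TABLE6_TOTALS: dict[FactualityValue, int] = {
    FactualityValue.FACT: 4713,
    FactualityValue.PROBABLE: 210,
    FactualityValue.POSSIBLE: 127,
    FactualityValue.DOUBTFUL: 14,
    FactualityValue.COUNTERFACT: 92,
    FactualityValue.UNCOMMITTED: 172,
    FactualityValue.CONDITIONAL: 1,
}


def _default_proportions() -> dict[FactualityValue, float]:
    total = sum(TABLE6_TOTALS.values())
    return {k: v / total for k, v in TABLE6_TOTALS.items()}


@dataclass
class FixtureConfig:
    """Configuration for the synthetic fixture corpus."""

    n_documents: int = 100
    proportions: dict[FactualityValue, float] = field(
        default_factory=_default_proportions
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")


_DRUGS = [
    "Ibuprofen", "Losartan", "Metformin", "Tamoxifen", "Nifedipine",
    "Orlistat", "Montelukast", "Enalapril", "Simvastatin", "Naproxen",
]
_DISEASES = [
    "asthma", "obesity", "hypertension", "migraine", "osteoporosis",
    "bronchitis", "dermatitis", "gastritis", "nephropathy", "insomnia",
]
_PROTEINS = ["TNF-alpha", "interleukin-6", "CD40L", "VCAM-1", "leptin"]

_DRUG_TYPE = "Pharmacologic Substance"
_DISEASE_TYPE = "Disease or Syndrome"
_PROTEIN_TYPE = "Amino Acid, Peptide, or Protein"


def _fixture_templates() -> dict[FactualityValue, list]:
    """Template bank; slots {DRUG}, {DRUG2}, {DISEASE}, {PROTEIN}.

    Each template: (sentence token specs, entities, predication); token
    ranges are 1-based. The triggers were chosen so the composition
    rules genuinely recover each gold label: deductive verbs for
    probable, "may" for possible, negated deductives for doubtful,
    predicate or argument negation for counterfact, deontic/interrogative
    triggers for uncommitted. conditional has no predictive rule, so its
    (single, rare) template is expected to come out fact.
    """
    T = Tok
    bank: dict[FactualityValue, list] = {}

    bank[FactualityValue.FACT] = [
        # "{DRUG} reduced mortality in patients with {DISEASE} ."
        (
            (
                T("{DRUG}", "{drug}", "NNP", 2, "nsubj"),
                T("reduced", "reduce", "VBD", 0, "root"),
                T("mortality", "mortality", "NN", 2, "dobj"),
                T("in", "in", "IN", 2, "prep"),
                T("patients", "patient", "NNS", 4, "pobj"),
                T("with", "with", "IN", 5, "prep"),
                T("{DISEASE}", "{disease}", "NN", 6, "pobj"),
                T(".", ".", ".", 2, "punct"),
            ),
            [("T1", _DRUG_TYPE, 0, (1, 1), None), ("T2", _DISEASE_TYPE, 0, (7, 7), None)],
            ("E1", "T1", "TREATS", "T2", 0, (2, 2), "verb"),
        ),
        # "{DRUG} increased renal blood flow in {DISEASE} patients ."
        (
            (
                T("{DRUG}", "{drug}", "NNP", 2, "nsubj"),
                T("increased", "increase", "VBD", 0, "root"),
                T("renal", "renal", "JJ", 5, "amod"),
                T("blood", "blood", "NN", 5, "nn"),
                T("flow", "flow", "NN", 2, "dobj"),
                T("in", "in", "IN", 2, "prep"),
                T("{DISEASE}", "{disease}", "NN", 8, "nn"),
                T("patients", "patient", "NNS", 6, "pobj"),
                T(".", ".", ".", 2, "punct"),
            ),
            [("T1", _DRUG_TYPE, 0, (1, 1), None), ("T2", "Physiologic Function", 0, (3, 5), None)],
            ("E1", "T1", "AUGMENTS", "T2", 0, (2, 2), "verb"),
        ),
        # "{DRUG} is a nonsteroidal agent ." (ISA; static relations are facts)
        (
            (
                T("{DRUG}", "{drug}", "NNP", 5, "nsubj"),
                T("is", "be", "VBZ", 5, "cop"),
                T("a", "a", "DT", 5, "det"),
                T("nonsteroidal", "nonsteroidal", "JJ", 5, "amod"),
                T("agent", "agent", "NN", 0, "root"),
                T(".", ".", ".", 5, "punct"),
            ),
            [("T1", _DRUG_TYPE, 0, (1, 1), None), ("T2", _DRUG_TYPE, 0, (4, 5), None)],
            ("E1", "T1", "ISA", "T2", 0, (2, 2), "verb"),
        ),
    ]

    bank[FactualityValue.PROBABLE] = [
        # "These findings indicate that {DRUG} reduces the risk of {DISEASE} ."
        (
            (
                T("These", "these", "DT", 2, "det"),
                T("findings", "finding", "NNS", 3, "nsubj"),
                T("indicate", "indicate", "VBP", 0, "root"),
                T("that", "that", "IN", 6, "mark"),
                T("{DRUG}", "{drug}", "NNP", 6, "nsubj"),
                T("reduces", "reduce", "VBZ", 3, "ccomp"),
                T("the", "the", "DT", 8, "det"),
                T("risk", "risk", "NN", 6, "dobj"),
                T("of", "of", "IN", 8, "prep"),
                T("{DISEASE}", "{disease}", "NN", 9, "pobj"),
                T(".", ".", ".", 3, "punct"),
            ),
            [("T1", _DRUG_TYPE, 0, (5, 5), None), ("T2", _DISEASE_TYPE, 0, (10, 10), None)],
            ("E1", "T1", "PREVENTS", "T2", 0, (6, 6), "verb"),
        ),
        # "The data suggest that {DRUG} protects against {DISEASE} ."
        (
            (
                T("The", "the", "DT", 2, "det"),
                T("data", "data", "NNS", 3, "nsubj"),
                T("suggest", "suggest", "VBP", 0, "root"),
                T("that", "that", "IN", 6, "mark"),
                T("{DRUG}", "{drug}", "NNP", 6, "nsubj"),
                T("protects", "protect", "VBZ", 3, "ccomp"),
                T("against", "against", "IN", 6, "prep"),
                T("{DISEASE}", "{disease}", "NN", 7, "pobj"),
                T(".", ".", ".", 3, "punct"),
            ),
            [("T1", _DRUG_TYPE, 0, (5, 5), None), ("T2", _DISEASE_TYPE, 0, (8, 8), None)],
            ("E1", "T1", "PREVENTS", "T2", 0, (6, 6), "verb"),
        ),
    ]

    bank[FactualityValue.POSSIBLE] = [
        # "{DRUG} may reduce the severity of {DISEASE} ."
        (
            (
                T("{DRUG}", "{drug}", "NNP", 3, "nsubj"),
                T("may", "may", "MD", 3, "aux"),
                T("reduce", "reduce", "VB", 0, "root"),
                T("the", "the", "DT", 5, "det"),
                T("severity", "severity", "NN", 3, "dobj"),
                T("of", "of", "IN", 5, "prep"),
                T("{DISEASE}", "{disease}", "NN", 6, "pobj"),
                T(".", ".", ".", 3, "punct"),
            ),
            [("T1", _DRUG_TYPE, 0, (1, 1), None), ("T2", _DISEASE_TYPE, 0, (7, 7), None)],
            ("E1", "T1", "TREATS", "T2", 0, (3, 3), "verb"),
        ),
        # "{DRUG} might prevent {DISEASE} in older adults ."
        (
            (
                T("{DRUG}", "{drug}", "NNP", 3, "nsubj"),
                T("might", "might", "MD", 3, "aux"),
                T("prevent", "prevent", "VB", 0, "root"),
                T("{DISEASE}", "{disease}", "NN", 3, "dobj"),
                T("in", "in", "IN", 3, "prep"),
                T("older", "old", "JJR", 7, "amod"),
                T("adults", "adult", "NNS", 5, "pobj"),
                T(".", ".", ".", 3, "punct"),
            ),
            [("T1", _DRUG_TYPE, 0, (1, 1), None), ("T2", _DISEASE_TYPE, 0, (4, 4), None)],
            ("E1", "T1", "PREVENTS", "T2", 0, (3, 3), "verb"),
        ),
    ]

    bank[FactualityValue.DOUBTFUL] = [
        # "These results do not support the efficacy of {DRUG} treatment in {DISEASE} ."
        (
            (
                T("These", "these", "DT", 2, "det"),
                T("results", "result", "NNS", 5, "nsubj"),
                T("do", "do", "VBP", 5, "aux"),
                T("not", "not", "RB", 5, "neg"),
                T("support", "support", "VB", 0, "root"),
                T("the", "the", "DT", 7, "det"),
                T("efficacy", "efficacy", "NN", 5, "dobj"),
                T("of", "of", "IN", 7, "prep"),
                T("{DRUG}", "{drug}", "NNP", 10, "nn"),
                T("treatment", "treatment", "NN", 8, "pobj"),
                T("in", "in", "IN", 10, "prep"),
                T("{DISEASE}", "{disease}", "NN", 11, "pobj"),
                T(".", ".", ".", 5, "punct"),
            ),
            [("T1", _DRUG_TYPE, 0, (9, 9), None), ("T2", _DISEASE_TYPE, 0, (12, 12), None)],
            ("E1", "T1", "TREATS", "T2", 0, (10, 10), "nominalization"),
        ),
    ]

    bank[FactualityValue.COUNTERFACT] = [
        # "{DRUG} did not produce {DISEASE} in these patients ."
        (
            (
                T("{DRUG}", "{drug}", "NNP", 4, "nsubj"),
                T("did", "do", "VBD", 4, "aux"),
                T("not", "not", "RB", 4, "neg"),
                T("produce", "produce", "VB", 0, "root"),
                T("{DISEASE}", "{disease}", "NN", 4, "dobj"),
                T("in", "in", "IN", 4, "prep"),
                T("these", "these", "DT", 8, "det"),
                T("patients", "patient", "NNS", 6, "pobj"),
                T(".", ".", ".", 4, "punct"),
            ),
            [("T1", _DRUG_TYPE, 0, (1, 1), None), ("T2", _DISEASE_TYPE, 0, (5, 5), None)],
            ("E1", "T1", "CAUSES", "T2", 0, (4, 4), "verb"),
        ),
        # "{DRUG2} , but not {DRUG} , inhibited production of {PROTEIN} ."
        (
            (
                T("{DRUG2}", "{drug2}", "NNP", 7, "nsubj"),
                T(",", ",", ",", 1, "punct"),
                T("but", "but", "CC", 1, "cc"),
                T("not", "not", "RB", 5, "neg"),
                T("{DRUG}", "{drug}", "NNP", 1, "conj"),
                T(",", ",", ",", 1, "punct"),
                T("inhibited", "inhibit", "VBD", 0, "root"),
                T("production", "production", "NN", 7, "dobj"),
                T("of", "of", "IN", 8, "prep"),
                T("{PROTEIN}", "{protein}", "NNP", 9, "pobj"),
                T(".", ".", ".", 7, "punct"),
            ),
            [("T1", _DRUG_TYPE, 0, (5, 5), None), ("T2", _PROTEIN_TYPE, 0, (10, 10), None)],
            ("E1", "T1", "INHIBITS", "T2", 0, (7, 7), "verb"),
        ),
    ]

    bank[FactualityValue.UNCOMMITTED] = [
        # "{DRUG} should be administered to patients with {DISEASE} ."
        (
            (
                T("{DRUG}", "{drug}", "NNP", 4, "nsubjpass"),
                T("should", "should", "MD", 4, "aux"),
                T("be", "be", "VB", 4, "auxpass"),
                T("administered", "administer", "VBN", 0, "root"),
                T("to", "to", "TO", 4, "prep"),
                T("patients", "patient", "NNS", 5, "pobj"),
                T("with", "with", "IN", 6, "prep"),
                T("{DISEASE}", "{disease}", "NN", 7, "pobj"),
                T(".", ".", ".", 4, "punct"),
            ),
            [("T1", _DRUG_TYPE, 0, (1, 1), None), ("T2", _DISEASE_TYPE, 0, (8, 8), None)],
            ("E1", "T1", "ADMINISTERED_TO", "T2", 0, (4, 4), "verb"),
        ),
        # "Whether {DRUG} prevents {DISEASE} remains unclear ."
        (
            (
                T("Whether", "whether", "IN", 3, "mark"),
                T("{DRUG}", "{drug}", "NNP", 3, "nsubj"),
                T("prevents", "prevent", "VBZ", 5, "csubj"),
                T("{DISEASE}", "{disease}", "NN", 3, "dobj"),
                T("remains", "remain", "VBZ", 0, "root"),
                T("unclear", "unclear", "JJ", 5, "acomp"),
                T(".", ".", ".", 5, "punct"),
            ),
            [("T1", _DRUG_TYPE, 0, (2, 2), None), ("T2", _DISEASE_TYPE, 0, (4, 4), None)],
            ("E1", "T1", "PREVENTS", "T2", 0, (3, 3), "verb"),
        ),
    ]

    bank[FactualityValue.CONDITIONAL] = [
        # "{DRUG} prevents {DISEASE} if the dose is adequate ."
        (
            (
                T("{DRUG}", "{drug}", "NNP", 2, "nsubj"),
                T("prevents", "prevent", "VBZ", 0, "root"),
                T("{DISEASE}", "{disease}", "NN", 2, "dobj"),
                T("if", "if", "IN", 7, "mark"),
                T("the", "the", "DT", 6, "det"),
                T("dose", "dose", "NN", 7, "nsubj"),
                T("is", "be", "VBZ", 2, "advcl"),
                T("adequate", "adequate", "JJ", 7, "acomp"),
                T(".", ".", ".", 2, "punct"),
            ),
            [("T1", _DRUG_TYPE, 0, (1, 1), None), ("T2", _DISEASE_TYPE, 0, (3, 3), None)],
            ("E1", "T1", "PREVENTS", "T2", 0, (2, 2), "verb"),
        ),
    ]
    return bank


def _allocate_counts(n: int, proportions: Mapping[FactualityValue, float]) -> dict:
    """Largest-remainder allocation so class shares hold at any seed."""
    items = sorted(proportions.items(), key=lambda kv: kv[0].value)
    raw = [(label, n * p) for label, p in items]
    counts = {label: int(x) for label, x in raw}
    short = n - sum(counts.values())
    by_remainder = sorted(raw, key=lambda kv: (-(kv[1] - int(kv[1])), kv[0].value))
    for label, _x in by_remainder[:short]:
        counts[label] += 1
    return counts


def _instantiate(template, fillers: Mapping[str, str]) -> tuple:
    tokens, entities, predication = template

    def fill(value: str) -> str:
        for slot, repl in fillers.items():
            value = value.replace("{" + slot + "}", repl)
            value = value.replace("{" + slot.lower() + "}", repl.lower())
        return value

    toks = tuple(
        Tok(fill(t.form), fill(t.lemma), t.pos, t.head, t.deprel) for t in tokens
    )
    return toks, entities, predication


def generate_fixture_corpus(config: FixtureConfig) -> list[AnnotatedDocument]:
    """Deterministically generate a synthetic standoff+CoNLL-U corpus.

    Label counts follow the configured proportions exactly (largest
    remainder); template choice, slot fillers, and document order are
    drawn from the seeded generator, so the corpus is byte-identical
    under the same seed.
    """
    rng = np.random.default_rng(config.seed)
    bank = _fixture_templates()
    counts = _allocate_counts(config.n_documents, config.proportions)
    labels: list[FactualityValue] = []
    for label in sorted(counts, key=lambda x: x.value):
        labels.extend([label] * counts[label])
    rng.shuffle(labels)  # type: ignore[arg-type]

    docs = []
    for i, label in enumerate(labels):
        templates = bank[label]
        template = templates[int(rng.integers(len(templates)))]
        drug_i = int(rng.integers(len(_DRUGS)))
        drug2_i = (drug_i + 1 + int(rng.integers(len(_DRUGS) - 1))) % len(_DRUGS)
        fillers = {
            "DRUG": _DRUGS[drug_i],
            "DRUG2": _DRUGS[drug2_i],
            "DISEASE": _DISEASES[int(rng.integers(len(_DISEASES)))],
            "PROTEIN": _PROTEINS[int(rng.integers(len(_PROTEINS)))],
        }
        tokens, entities, predication = _instantiate(template, fillers)
        pid = predication[0]
        doc = build_document(
            doc_id=f"doc{i + 1:05d}",
            sentences=[SentenceSpec(tokens)],
            entities=entities,
            predications=[predication],
            gold={pid: label},
        )
        docs.append(doc)
    return docs


def write_corpus(docs: Iterable[AnnotatedDocument], out_dir: str | Path) -> None:
    """Write a corpus as .txt/.ann/.conllu triples under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        txt, ann = write_standoff(doc)
        (out / f"{doc.id}.txt").write_text(txt, encoding="utf-8")
        (out / f"{doc.id}.ann").write_text(ann, encoding="utf-8")
        if doc.conllu is not None:
            (out / f"{doc.id}.conllu").write_text(doc.conllu, encoding="utf-8")
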