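"""Embedding-predicate lexicon.

Embedding predicates (triggers) are lexical items -- modal auxiliaries,
verbs, nouns, adjectives, adverbs -- that take a proposition in their scope
and modulate its extra-propositional meaning: ``may``, ``suggest``, ``not``,
``should``. The lexicon models the four-way embedding categorization
(modal, relational, valence_shifter, propositional), the modality scales
attached to modal subcategories, and the trigger dictionary that drives
semantic composition. Each dictionary entry is keyed by (lemma, Penn
Treebank POS) and carries one or more senses; a modal sense contributes a
prior scalar modality value in [0, 1] on its scale, a scale_shifter sense
contributes a shift function applied to the value already on the scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ModalityScale",
    "CategoryPath",
    "EmbeddingSense",
    "EmbeddingDictionary",
    "DictionaryFormatError",
    "NoScaleError",
    "scale_of",
    "load_dictionary",
    "default_dictionary_path",
    "normalize_pos",
]


class ModalityScale(enum.Enum):
    """A modality scale whose values live in [0, 1].

    1 is the strongest positive association with the scale, 0 is negative
    association (e.g. on the epistemic scale 1 reads as *fact* and 0 as
    *counterfact*).
    """

    EPISTEMIC = "epistemic"
    DEONTIC = "deontic"
    POTENTIAL = "potential"
    SUCCESS = "success"
    INTERROGATIVE = "interrogative"


TOP_LEVEL_CATEGORIES = frozenset(
    {"modal", "relational", "valence_shifter", "propositional"}
)

# modal leaf category -> scale it places its scope on
_LEAF_SCALE: Mapping[str, ModalityScale] = {
    "epistemic": ModalityScale.EPISTEMIC,
    "speculative": ModalityScale.EPISTEMIC,
    "deductive": ModalityScale.EPISTEMIC,
    "demonstrative": ModalityScale.EPISTEMIC,
    "counterfactive": ModalityScale.EPISTEMIC,
    "deontic": ModalityScale.DEONTIC,
    "permissive": ModalityScale.DEONTIC,
    "obligative": ModalityScale.DEONTIC,
    "dynamic": ModalityScale.POTENTIAL,
    "potential": ModalityScale.POTENTIAL,
    "volitive": ModalityScale.POTENTIAL,
    "success": ModalityScale.SUCCESS,
    "interrogative": ModalityScale.INTERROGATIVE,
}

# Leaves whose triggers introduce an attributed source when they govern a
# nominal subject (reporting/inferring predicates: "These results suggest...").
SOURCE_INTRODUCING_LEAVES = frozenset({"deductive", "demonstrative"})

SHIFT_FUNCTIONS = frozenset({"negate", "intensify", "diminish"})


class DictionaryFormatError(ValueError):
    """A dictionary entry is malformed (missing/invalid required field)."""


class NoScaleError(ValueError):
    """Raised when a non-modal category is asked for its modality scale."""


@dataclass(frozen=True)
class CategoryPath:
    """Position of a sense in the embedding categorization tree.

    e.g. ``modal -> epistemic -> speculative`` or
    ``valence_shifter -> scale_shifter -> negation``.
    """

    top_level: str
    subpath: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.top_level not in TOP_LEVEL_CATEGORIES:
            raise DictionaryFormatError(
                f"unknown top-level category {self.top_level!r}"
            )
        if self.top_level in {"modal", "valence_shifter"} and not self.subpath:
            raise DictionaryFormatError(
                f"{self.top_level} categories require a nonempty subpath"
            )

    @classmethod
    def parse(cls, dotted: str) -> "CategoryPath":
        parts = tuple(p.strip() for p in dotted.split(".") if p.strip())
        if not parts:
            raise DictionaryFormatError("empty category path")
        return cls(parts[0], parts[1:])

    @property
    def leaf(self) -> str:
        return self.subpath[-1] if self.subpath else self.top_level

    @property
    def is_modal(self) -> bool:
        return self.top_level == "modal"

    @property
    def is_scale_shifter(self) -> bool:
        return (
            self.top_level == "valence_shifter"
            and bool(self.subpath)
            and self.subpath[0] == "scale_shifter"
        )

    def __str__(self) -> str:
        return ".".join((self.top_level, *self.subpath))


def scale_of(category: CategoryPath) -> ModalityScale:
    """Modality scale for a modal leaf category.

    speculative/deductive/demonstrative are epistemic subcategories,
    potential sits under the dynamic modal category, interrogative and
    success name their own scales.
    """
    if not category.is_modal:
        raise NoScaleError(f"category {category} carries no modality scale")
    try:
        return _LEAF_SCALE[category.leaf]
    except KeyError:
        raise NoScaleError(
            f"modal leaf {category.leaf!r} has no registered scale"
        ) from None


@dataclass(frozen=True)
class EmbeddingSense:
    """One sense of a trigger: category + prior value or shift function.

    ``dep_types`` lists the semantic-dependency labels that license scope:
    a predication is in this sense's scope only when a licensed label occurs
    on the semantic-graph path from the trigger to the predication's
    predicate node.
    """

    lemma: str
    pos: str
    category: CategoryPath
    dep_types: frozenset[str]
    prior_value: float | None = None
    shift_function: str | None = None

    def __post_init__(self) -> None:
        if self.category.is_modal:
            if self.prior_value is None:
                raise DictionaryFormatError(
                    f"{self.lemma}/{self.pos}: modal sense requires a prior value"
                )
            if not 0.0 <= self.prior_value <= 1.0:
                raise DictionaryFormatError(
                    f"{self.lemma}/{self.pos}: prior {self.prior_value} outside [0,1]"
                )
            scale_of(self.category)  # must resolve
        elif self.category.is_scale_shifter:
            if self.shift_function not in SHIFT_FUNCTIONS:
                raise DictionaryFormatError(
                    f"{self.lemma}/{self.pos}: scale_shifter sense requires a "
                    f"shift function from {sorted(SHIFT_FUNCTIONS)}"
                )
            if self.prior_value is not None:
                raise DictionaryFormatError(
                    f"{self.lemma}/{self.pos}: scale_shifter sense takes no prior"
                )

    @property
    def scale(self) -> ModalityScale | None:
        return scale_of(self.category) if self.category.is_modal else None

    @property
    def is_negation(self) -> bool:
        return self.category.is_scale_shifter and self.category.leaf == "negation"

    @property
    def introduces_source(self) -> bool:
        return (
            self.category.is_modal
            and self.category.leaf in SOURCE_INTRODUCING_LEAVES
        )


_POS_NORMALIZATION = {
    "VBD": "VB", "VBZ": "VB", "VBP": "VB", "VBN": "VB", "VBG": "VB",
    "NNS": "NN",
    "NNPS": "NNP",
    "JJR": "JJ", "JJS": "JJ",
    "RBR": "RB", "RBS": "RB",
}


def normalize_pos(pos: str) -> str:
    """Collapse inflectional Penn tags to the base tag used by dictionary keys."""
    return _POS_NORMALIZATION.get(pos, pos)


@dataclass
class EmbeddingDictionary:
    """Trigger dictionary: (lemma, POS) -> ordered senses (file order).

    File order is disambiguation priority: the first sense whose licensed
    dependency types match the graph wins.
    """

    _entries: dict[tuple[str, str], list[EmbeddingSense]] = field(
        default_factory=dict
    )

    def add(self, sense: EmbeddingSense) -> None:
        self._entries.setdefault((sense.lemma, sense.pos), []).append(sense)

    def lookup_senses(self, lemma: str, pos: str) -> tuple[EmbeddingSense, ...]:
        """Senses for a lemma/POS pair; empty tuple for non-triggers."""
        return tuple(self._entries.get((lemma.lower(), normalize_pos(pos)), ()))

    def __contains__(self, key: tuple[str, str]) -> bool:
        lemma, pos = key
        return (lemma.lower(), normalize_pos(pos)) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def entries(self) -> dict[tuple[str, str], list[EmbeddingSense]]:
        return dict(self._entries)

    def trigger_lemmas(self) -> frozenset[str]:
        """All trigger lemmas (used as the meta-knowledge clue list)."""
        return frozenset(lemma for lemma, _pos in self._entries)

    def multiword_lemmas(self) -> dict[str, list[str]]:
        """Head word -> full multiword lemmas (e.g. 'rule' -> ['rule out'])."""
        out: dict[str, list[str]] = {}
        for lemma, _pos in self._entries:
            if " " in lemma:
                out.setdefault(lemma.split()[0], []).append(lemma)
        return out


def default_dictionary_path() -> Path:
    """Path of the starter dictionary shipped with the package."""
    return Path(resources.files("semfact").joinpath("data/embedding_dictionary.yaml"))


def load_dictionary(path: str | Path | None = None) -> EmbeddingDictionary:
    """Load an embedding dictionary from a YAML entry file.

    The file is a sequence of entries, each a mapping with ``lemma``,
    ``pos`` and a ``senses`` list; every sense needs a ``category`` and
    either a ``prior`` (modal) or a ``shift`` (scale_shifter), plus
    ``dep_types``. Malformed entries are rejected with the entry named.
    An empty file yields an empty dictionary. Duplicate (lemma, POS) keys
    concatenate their senses in file order.
    """
    if path is None:
        path = default_dictionary_path()
    raw = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(raw)
    dictionary = EmbeddingDictionary()
    if data is None:
        return dictionary
    if not isinstance(data, list):
        raise DictionaryFormatError(
            f"{path}: expected a sequence of entries, got {type(data).__name__}"
        )
    for i, entry in enumerate(data):
        label = f"entry {i + 1}"
        if not isinstance(entry, dict):
            raise DictionaryFormatError(f"{path}: {label} is not a mapping")
        try:
            lemma = str(entry["lemma"]).lower()
            pos = str(entry["pos"])
            senses = entry["senses"]
        except KeyError as exc:
            raise DictionaryFormatError(
                f"{path}: {label} is missing required field {exc}"
            ) from None
        if not isinstance(senses, list) or not senses:
            raise DictionaryFormatError(
                f"{path}: {label} ({lemma}/{pos}) has no senses"
            )
        for j, s in enumerate(senses):
            slabel = f"{label} ({lemma}/{pos}) sense {j + 1}"
            if not isinstance(s, dict) or "category" not in s:
                raise DictionaryFormatError(
                    f"{path}: {slabel} is missing required field 'category'"
                )
            dep_types = s.get("dep_types")
            if not isinstance(dep_types, list) or not dep_types:
                raise DictionaryFormatError(
                    f"{path}: {slabel} is missing required field 'dep_types'"
                )
            category = CategoryPath.parse(str(s["category"]))
            if category.is_modal and "prior" not in s:
                raise DictionaryFormatError(
                    f"{path}: {slabel} is missing required field 'prior'"
                )
            try:
                sense = EmbeddingSense(
                    lemma=lemma,
                    pos=pos,
                    category=category,
                    dep_types=frozenset(str(d).upper() for d in dep_types),
                    prior_value=(
                        float(s["prior"]) if s.get("prior") is not None else None
                    ),
                    shift_function=s.get("shift"),
                )
            except DictionaryFormatError as exc:
                raise DictionaryFormatError(f"{path}: {slabel}: {exc}") from None
            dictionary.add(sense)
    return dictionary


def write_dictionary(
    dictionary: EmbeddingDictionary, path: str | Path
) -> None:
    """Serialize a dictionary back to the YAML entry format (round-trips)."""
    entries = []
    for (lemma, pos), senses in dictionary.entries.items():
        record: dict = {"lemma": lemma, "pos": pos, "senses": []}
        for s in senses:
            sense_rec: dict = {
                "category": str(s.category),
                "dep_types": sorted(s.dep_types),
            }
            if s.prior_value is not None:
                sense_rec["prior"] = s.prior_value
            if s.shift_function is not None:
                sense_rec["shift"] = s.shift_function
            record["senses"].append(sense_rec)
        entries.append(record)
    Path(path).write_text(
        yaml.safe_dump(entries, sort_keys=False), encoding="utf-8"
    )
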