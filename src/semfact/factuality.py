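"""Mapping composed predications to discrete factuality values.

Seven values are distinguished: five on the factuality scale, totally
ordered counterfact < doubtful < possible < probable < fact, plus two
off-scale values, uncommitted (the text does not commit to the truth of
the proposition) and conditional (truth depends on another predication;
annotated but not predicted). Scalar modality values are mapped to the
scale by per-scale threshold rules; predications whose construction is
predominantly factual (ISA relations, modifier-head and prepositional
indicators) are overridden to fact, and inferred (INFER) predications
inherit the value of their non-inferred counterpart. The module also
provides the legacy certainty-level x polarity mapping used by the
pre-enhancement system and the 5-bin discretization used as a classifier
feature.
"""

from __future__ import annotations

import enum
import logging

from .composition import EnhancedPredication, Predication
from .lexicon import ModalityScale

logger = logging.getLogger(__name__)

__all__ = [
    "FactualityValue",
    "SCALE_ORDER",
    "map_scalar",
    "assign_factuality",
    "map_certainty_polarity",
    "discretize",
    "DiscretizedBin",
]


class FactualityValue(enum.Enum):
    FACT = "fact"
    PROBABLE = "probable"
    POSSIBLE = "possible"
    DOUBTFUL = "doubtful"
    COUNTERFACT = "counterfact"
    UNCOMMITTED = "uncommitted"
    CONDITIONAL = "conditional"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: the five on-scale values from negative to positive pole
SCALE_ORDER = (
    FactualityValue.COUNTERFACT,
    FactualityValue.DOUBTFUL,
    FactualityValue.POSSIBLE,
    FactualityValue.PROBABLE,
    FactualityValue.FACT,
)


def map_scalar(scale: ModalityScale, v: float) -> FactualityValue | None:
    """Threshold rules from scalar modality values to factuality levels.

    Evaluated top to bottom; returns ``None`` when no rule matches (the
    deontic scale at or below 0.65 or exactly 1, the interrogative scale
    below 1), in which case the caller falls back to fact.
    """
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"modality value {v} outside [0,1]")
    if not isinstance(scale, ModalityScale):
        raise ValueError(f"unknown scale {scale!r}")
    if scale in (ModalityScale.EPISTEMIC, ModalityScale.SUCCESS):
        if v == 1.0:
            return FactualityValue.FACT
        if 0.65 <= v < 1.0:
            return FactualityValue.PROBABLE
        if 0.25 < v < 0.65:
            return FactualityValue.POSSIBLE
        if 0.0 < v <= 0.25:
            return FactualityValue.DOUBTFUL
        return FactualityValue.COUNTERFACT  # v == 0
    if scale is ModalityScale.POTENTIAL:
        if v > 0.0:
            return FactualityValue.PROBABLE
        return FactualityValue.COUNTERFACT  # v == 0
    if scale is ModalityScale.INTERROGATIVE:
        if v == 1.0:
            return FactualityValue.UNCOMMITTED
        return None
    if scale is ModalityScale.DEONTIC:
        if 0.65 < v < 1.0:
            return FactualityValue.UNCOMMITTED
        return None
    raise ValueError(f"unknown scale {scale!r}")  # pragma: no cover


def assign_factuality(
    ep: EnhancedPredication,
    pred: Predication | None = None,
    inferred_partner: FactualityValue | None = None,
) -> FactualityValue:
    """Final factuality of an enhanced predication.

    Precedence: (1) ISA relations are facts; (2) modifier-head and
    prepositional indicators are facts (predominantly factual static
    constructions -- this supersedes the composed scalar value); (3)
    inferred (INFER) predications inherit their non-inferred partner's
    value; (4) the scalar threshold rules; (5) fall back to fact (the
    initial value's meaning) when no threshold rule matches. Never
    returns conditional.
    """
    if pred is None:
        pred = ep.predication
    if pred is not None:
        if pred.predicate_type.upper() == "ISA":
            return FactualityValue.FACT
        if pred.indicator_type in {"modifier-head", "preposition"}:
            return FactualityValue.FACT
        if pred.indicator_type == "INFER":
            if inferred_partner is not None:
                return inferred_partner
            logger.warning(
                "%s: INFER predication without a partner; using scalar rules",
                pred.id,
            )
    value = map_scalar(ep.scale, ep.mv)
    if value is None:
        logger.debug(
            "%s: no threshold rule for %.2f_%s; falling back to fact",
            ep.id,
            ep.mv,
            ep.scale.value,
        )
        return FactualityValue.FACT
    return value


_CERTAINTY_POLARITY = {
    ("L3", "Positive"): FactualityValue.FACT,
    ("L2", "Positive"): FactualityValue.PROBABLE,
    ("L1", "Positive"): FactualityValue.POSSIBLE,
    ("L1", "Negative"): FactualityValue.DOUBTFUL,
    ("L2", "Negative"): FactualityValue.DOUBTFUL,
    ("L3", "Negative"): FactualityValue.COUNTERFACT,
}


def map_certainty_polarity(level: str, polarity: str) -> FactualityValue:
    """Legacy mapping from (certainty level, polarity) annotations.

    L3 is full certainty, L2 slight and L1 considerable speculation.
    """
    try:
        return _CERTAINTY_POLARITY[(level, polarity)]
    except KeyError:
        raise ValueError(f"invalid certainty/polarity pair ({level}, {polarity})")


class DiscretizedBin(tuple):
    """(scale, bin index 1..5) with a canonical feature name."""

    def __new__(cls, scale: ModalityScale, bin_index: int):
        return super().__new__(cls, (scale, bin_index))

    @property
    def scale(self) -> ModalityScale:
        return self[0]

    @property
    def bin(self) -> int:
        return self[1]

    @property
    def name(self) -> str:
        return f"{self.scale.value.upper()}_{self.bin}"

    def __str__(self) -> str:
        return self.name


def discretize(scale: ModalityScale, v: float) -> DiscretizedBin:
    """5-bin discretization of a scalar modality value.

    1.0 -> 5, [0.65, 1.0) -> 4, (0.25, 0.65) -> 3, (0, 0.25] -> 2,
    0.0 -> 1; e.g. 0.9 on the epistemic scale becomes EPISTEMIC_4. The
    bins partition [0,1] and are monotone in v.
    """
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"modality value {v} outside [0,1]")
    if v == 1.0:
        b = 5
    elif v >= 0.65:
        b = 4
    elif v > 0.25:
        b = 3
    elif v > 0.0:
        b = 2
    else:
        b = 1
    return DiscretizedBin(scale, b)
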