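"""Domain records for argument-attribution surveys.

A survey item is a dichotomous moral question; each of its two answers is an
*opinion* (issue position). A respondent answers the item, ticks which
concerns' arguments justify their own answer, and then ticks which would
justify the opposite answer — so every response judges both opinions, and a
study with k items defines 2k opinions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .taxonomy import ConcernTaxonomy

AFFIRMATIVE = "affirmative"
NEGATIVE = "negative"
POSITIONS = (AFFIRMATIVE, NEGATIVE)

OWN = "own"
OTHER = "other"


def opposite(position: str) -> str:
    if position == AFFIRMATIVE:
        return NEGATIVE
    if position == NEGATIVE:
        return AFFIRMATIVE
    raise ValueError(f"unknown position {position!r}")


class OpinionId(NamedTuple):
    """One side of a dichotomous item: (item_id, affirmative|negative)."""

    item_id: str
    position: str


@dataclass(frozen=True)
class MoralItem:
    """A dichotomous moral survey question."""

    item_id: str
    text: str
    response_labels: tuple[str, str] = ("yes", "no")

    @property
    def opinions(self) -> tuple[OpinionId, OpinionId]:
        return (OpinionId(self.item_id, AFFIRMATIVE), OpinionId(self.item_id, NEGATIVE))


@dataclass
class ParticipantRecord:
    """A respondent and the demographics used to form population splits.

    Missing attributes are ``None``; a participant missing an attribute is
    simply excluded from splits that require it.
    """

    participant_id: str
    sex: str | None = None
    age: int | None = None
    ideology: str | None = None  # binary liberal/conservative self-id
    ideology_scale: int | None = None  # 0 (left) .. 10 (right)
    education: str | None = None  # higher / lower
    verbal_ability: int | None = None  # Wordsum-style 0..10
    country: str | None = None
    population_label: str = ""

    def __post_init__(self) -> None:
        if self.ideology_scale is not None and not 0 <= self.ideology_scale <= 10:
            raise ValueError(
                f"participant {self.participant_id}: ideology_scale "
                f"{self.ideology_scale} outside 0-10"
            )


@dataclass
class ResponseRecord:
    """One participant's two-sided judgment of one item.

    ``own_side_ticks`` are the concerns ticked as justifying the participant's
    own answer; ``other_side_ticks`` those expected to justify the opposite
    answer. ``shown_arguments`` records which wording of each concern was
    displayed (one random draw per concern).
    """

    participant_id: str
    item_id: str
    own_answer: str
    shown_arguments: Mapping[str, str]
    own_side_ticks: frozenset[str]
    other_side_ticks: frozenset[str]
    other_reason_own: bool = False
    other_reason_other: bool = False

    def validate(self, taxonomy: ConcernTaxonomy) -> None:
        if self.own_answer not in POSITIONS:
            raise ValueError(
                f"response ({self.participant_id}, {self.item_id}): "
                f"own_answer {self.own_answer!r} not in {POSITIONS}"
            )
        concerns = set(taxonomy.concerns)
        for name, ticks in (
            ("own_side_ticks", self.own_side_ticks),
            ("other_side_ticks", self.other_side_ticks),
        ):
            unknown = set(ticks) - concerns
            if unknown:
                raise ValueError(
                    f"response ({self.participant_id}, {self.item_id}): "
                    f"{name} has unknown concern label(s) {sorted(unknown)}"
                )
        if set(self.shown_arguments) != concerns:
            raise ValueError(
                f"response ({self.participant_id}, {self.item_id}): "
                "shown_arguments must contain exactly one argument per concern"
            )
        for concern, text in self.shown_arguments.items():
            if text not in taxonomy.arguments[concern]:
                raise ValueError(
                    f"response ({self.participant_id}, {self.item_id}): "
                    f"argument {text!r} is not a {concern} argument"
                )


class Judgment(NamedTuple):
    """Normalized unit of analysis: does one concern apply to one opinion,
    according to one participant (judging from their own or the other side)?"""

    participant_id: str
    opinion: OpinionId
    concern: str
    applies: bool
    perspective: str  # own | other


def derive_judgments(
    responses: Iterable[ResponseRecord], taxonomy: ConcernTaxonomy
) -> list[Judgment]:
    """Expand two-sided responses into per-(opinion, concern) judgments.

    Each response yields exactly ``2 * n_concerns`` judgments: one per concern
    for the participant's own position (perspective ``own``) and one per
    concern for the opposite position (perspective ``other``). The catch-all
    tick is intentionally not expanded — only the taxonomy's concerns are
    scored.
    """
    out: list[Judgment] = []
    concerns = taxonomy.concerns
    for r in responses:
        own_op = OpinionId(r.item_id, r.own_answer)
        opp_op = OpinionId(r.item_id, opposite(r.own_answer))
        pid = r.participant_id
        own_ticks = r.own_side_ticks
        other_ticks = r.other_side_ticks
        for c in concerns:
            out.append(Judgment(pid, own_op, c, c in own_ticks, OWN))
            out.append(Judgment(pid, opp_op, c, c in other_ticks, OTHER))
    return out


def validate_responses(
    responses: Sequence[ResponseRecord], taxonomy: ConcernTaxonomy
) -> None:
    """Validate a batch of responses, including one-response-per-(participant, item)."""
    seen: set[tuple[str, str]] = set()
    for i, r in enumerate(responses):
        r.validate(taxonomy)
        key = (r.participant_id, r.item_id)
        if key in seen:
            raise ValueError(f"row {i}: duplicate response for (participant, item) {key}")
        seen.add(key)
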